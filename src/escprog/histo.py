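"""Pathology arm: patch tiling, patch vocabulary, PPCR features.

Each large tissue image is tiled into fixed-size non-overlapping patches.
Patches from all patients are pooled, converted to grayscale vectors,
z-scored, projected onto leading principal components and clustered with
K-means into ``k`` groups (the patch vocabulary, default k=20). A patient's
pathological-patches-cluster-ratio (PPCR, also written PCPR) vector is the
fraction of their patches assigned to each cluster — a k-simplex summary of
tissue composition used as the pathology feature block downstream.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

__all__ = [
    "PatchSet",
    "ClusterModel",
    "PPCRVector",
    "tile_image",
    "vectorize_patches",
    "fit_cluster_model",
    "assign_clusters",
    "compute_ppcr",
    "ppcr_table",
]

# Rec. 601 luminance weights for grayscale conversion.
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass
class PatchSet:
    patient_id: str
    patches: np.ndarray      # (n, p, p) or (n, p, p, 3)
    grid_coords: np.ndarray  # (n, 2) row/col on the patch grid


@dataclass
class PPCRVector:
    patient_id: str
    ratios: np.ndarray  # length k, sums to 1

    def __post_init__(self) -> None:
        r = np.asarray(self.ratios, dtype=float)
        if np.any(r < 0) or abs(r.sum() - 1.0) > 1e-9:
            raise ValueError("PPCR ratios must be non-negative and sum to 1")
        self.ratios = r


@dataclass
class ClusterModel:
    """Pooled patch vocabulary: standardization + PCA basis + K-means centroids."""

    mean: np.ndarray           # per retained input dimension
    sd: np.ndarray
    keep: np.ndarray           # bool mask of non-zero-variance input dimensions
    components: np.ndarray     # (d, n_kept) principal axes
    explained_variance_ratio: np.ndarray
    centroids: np.ndarray      # (k, d)
    k: int
    d: int
    seed: int

    def transform(self, vectors: np.ndarray) -> np.ndarray:
        if vectors.shape[1] != self.keep.size:
            raise ValueError(
                f"patch vectors have {vectors.shape[1]} dims, model expects {self.keep.size}"
            )
        z = (vectors[:, self.keep] - self.mean) / self.sd
        return z @ self.components.T

    def save(self, path: str | Path) -> None:
        np.savez_compressed(
            path,
            mean=self.mean,
            sd=self.sd,
            keep=self.keep,
            components=self.components,
            explained_variance_ratio=self.explained_variance_ratio,
            centroids=self.centroids,
            k=self.k,
            d=self.d,
            seed=self.seed,
        )

    @classmethod
    def load(cls, path: str | Path) -> "ClusterModel":
        with np.load(path) as z:
            return cls(
                mean=z["mean"],
                sd=z["sd"],
                keep=z["keep"],
                components=z["components"],
                explained_variance_ratio=z["explained_variance_ratio"],
                centroids=z["centroids"],
                k=int(z["k"]),
                d=int(z["d"]),
                seed=int(z["seed"]),
            )


def tile_image(
    image: np.ndarray, patch_size: int, patient_id: str = ""
) -> PatchSet:
    """Cut ``image`` into non-overlapping ``patch_size``-square patches.

    Row-major order from the top-left; trailing remainder pixels are dropped,
    so the count is ``floor(H/p) * floor(W/p)`` (a 6000 px square image with
    50 px patches yields 14,400).
    """
    h, w = image.shape[:2]
    p = int(patch_size)
    if h < p or w < p:
        raise ValueError(f"image {h}x{w} smaller than one {p}x{p} patch")
    gh, gw = h // p, w // p
    trimmed = image[: gh * p, : gw * p]
    if image.ndim == 3:
        patches = (
            trimmed.reshape(gh, p, gw, p, -1).swapaxes(1, 2).reshape(gh * gw, p, p, -1)
        )
    else:
        patches = trimmed.reshape(gh, p, gw, p).swapaxes(1, 2).reshape(gh * gw, p, p)
    rows, cols = np.divmod(np.arange(gh * gw), gw)
    return PatchSet(
        patient_id=patient_id,
        patches=patches,
        grid_coords=np.stack([rows, cols], axis=1),
    )


def vectorize_patches(patchset: PatchSet) -> np.ndarray:
    """Grayscale (Rec. 601) and flatten each patch to a length-p^2 vector."""
    patches = patchset.patches
    if patches.shape[0] == 0:
        raise ValueError("empty patch set")
    if patches.ndim == 4:
        gray = patches.astype(float) @ _LUMA
    else:
        gray = patches.astype(float)
    return gray.reshape(gray.shape[0], -1)


def fit_cluster_model(
    patch_vectors: np.ndarray,
    k: int = 20,
    d: int | None = None,
    variance_target: float = 0.95,
    d_cap: int = 50,
    seed: int = 0,
) -> ClusterModel:
    """Fit the pooled patch vocabulary.

    Vectors are z-scored per dimension (zero-variance dimensions dropped),
    projected onto ``d`` leading principal components — by default the smaller
    of ``d_cap`` and the count reaching ``variance_target`` explained variance
    — then clustered with seeded k-means++ (10 restarts, 300 iterations).
    """
    X = np.asarray(patch_vectors, dtype=float)
    if X.shape[0] < k:
        raise ValueError(f"need at least k={k} patch vectors, got {X.shape[0]}")
    sd = X.std(axis=0)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all patch-vector dimensions have zero variance")
    mean = X[:, keep].mean(axis=0)
    sd = sd[keep]
    Z = (X[:, keep] - mean) / sd

    max_d = min(d_cap, Z.shape[1], Z.shape[0] - 1)
    pca = PCA(n_components=max_d, random_state=seed)
    proj = pca.fit_transform(Z)
    if d is None:
        cum = np.cumsum(pca.explained_variance_ratio_)
        d_eff = int(np.searchsorted(cum, variance_target) + 1)
        d_eff = min(d_eff, max_d)
    else:
        d_eff = min(int(d), max_d)
    proj = proj[:, :d_eff]

    km = KMeans(
        n_clusters=k, init="k-means++", n_init=10, max_iter=300, tol=1e-4,
        random_state=seed,
    ).fit(proj)
    return ClusterModel(
        mean=mean,
        sd=sd,
        keep=keep,
        components=pca.components_[:d_eff],
        explained_variance_ratio=pca.explained_variance_ratio_[:d_eff],
        centroids=km.cluster_centers_,
        k=k,
        d=d_eff,
        seed=seed,
    )


def assign_clusters(model: ClusterModel, patchset: PatchSet) -> np.ndarray:
    """Nearest-centroid label per patch; ties go to the lowest cluster index."""
    proj = model.transform(vectorize_patches(patchset))
    d2 = ((proj[:, None, :] - model.centroids[None, :, :]) ** 2).sum(axis=2)
    return np.argmin(d2, axis=1)  # argmin takes the first (lowest) index on ties


def compute_ppcr(labels: Sequence[int], k: int, patient_id: str = "") -> PPCRVector:
    """Fraction of patches in each of the ``k`` clusters."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("empty label array")
    if labels.min() < 0 or labels.max() >= k:
        raise ValueError(f"labels must lie in [0, {k})")
    counts = np.bincount(labels, minlength=k).astype(float)
    return PPCRVector(patient_id=patient_id, ratios=counts / counts.sum())


def ppcr_table(vectors: Sequence[PPCRVector]) -> pd.DataFrame:
    """PPCR vectors as a patients x clusters table (Cluster_1 ... Cluster_k).

    Clusters are 1-indexed in reports, 0-indexed internally.
    """
    if not vectors:
        raise ValueError("no PPCR vectors")
    k = vectors[0].ratios.size
    df = pd.DataFrame(
        [v.ratios for v in vectors],
        columns=[f"Cluster_{j + 1}" for j in range(k)],
    )
    df.insert(0, "patient_id", [v.patient_id for v in vectors])
    return df
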