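"""Synthetic cohort generator.

Emulates the data modalities of a resected-ESCC prognostic study so the whole
analysis pipeline is testable without patient data:

* per-patient tissue-microarray-like RGB images composed of a small vocabulary
  of separable textures mixed in patient-specific proportions (the ground-truth
  analogue of the patch-cluster composition the pathology arm recovers);
* CT-like intensity volumes containing one rasterized ellipsoidal lesion with a
  binary region-of-interest mask and known semi-axes;
* binary/ordinal clinical covariates with configurable marginals (defaults set
  to the cohort prevalences of the emulated study population);
* right-censored survival times from a proportional-hazards model whose linear
  predictor loads on known image-derived and clinical features.

Everything is a pure function of ``(config, seed)`` via named substreams.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ._rng import substream

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "PatientRecord",
    "CLINICAL_MARGINALS",
    "TNM_STAGE_PROBS",
    "generate_histology_image",
    "generate_ct_case",
    "generate_clinical_table",
    "generate_survival",
    "make_cohort",
]

# Cohort prevalences for the binary covariates (fraction with the risk class).
CLINICAL_MARGINALS: dict[str, float] = {
    "sex_male": 0.804,
    "age_gt_65": 0.275,
    "smoking": 0.595,
    "drinking": 0.418,
    "crp": 0.307,   # C-reactive protein > 5 mg/ml
    "agr": 0.373,   # albumin-globulin ratio > 1.5
}

# Ordinal TNM stage (IB, IIA, IIB, IIIA, IIIB, IV) encoded 1..6.
TNM_STAGE_PROBS: tuple[float, ...] = (0.033, 0.366, 0.052, 0.052, 0.418, 0.078)

#: Covariates used by the clinical feature block of the prognostic models.
CLINICAL_MODEL_FEATURES: tuple[str, ...] = ("drinking", "crp", "agr", "tnm_stage")


def _default_beta() -> dict[str, float]:
    # Hazard loads on all three blocks: texture mixing (pathology arm),
    # lesion size (CT arm) and two clinical covariates.
    return {
        "mixing_0": 1.0,
        "mixing_1": -0.7,
        "lesion_log_volume": 0.8,
        "tnm_stage": 0.6,
        "crp": 0.4,
    }


@dataclass
class SyntheticConfig:
    """All knobs of the cohort generator.

    Defaults describe the full-scale cohort (153 patients, 6000 px images);
    :meth:`test_scale` returns the small profile used in the test suite.
    """

    n_patients: int = 153
    image_size: int = 6000
    patch_size: int = 50
    n_texture_classes: int = 6
    mixing_concentration: float | Sequence[float] = 1.0
    volume_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    #: (min, max) lesion semi-axis in mm, one pair per axis.
    lesion_axes_range: tuple[tuple[float, float], ...] = (
        (5.0, 18.0),
        (4.0, 14.0),
        (3.0, 10.0),
    )
    texture_noise_sd: float = 8.0
    separability: str = "easy"  # texture class contrast: "easy" or "hard"
    true_beta: dict[str, float] = field(default_factory=_default_beta)
    baseline_rate: float = np.log(2) / 30.0  # events per month
    censor_rate: float = 0.015               # per month
    admin_censor_time: float = 60.0           # months
    clinical_marginals: dict[str, float] = field(
        default_factory=lambda: dict(CLINICAL_MARGINALS)
    )
    tnm_stage_probs: tuple[float, ...] = TNM_STAGE_PROBS
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if self.image_size % self.patch_size != 0:
            raise ValueError(
                f"image_size {self.image_size} not divisible by patch_size {self.patch_size}"
            )
        if self.baseline_rate <= 0:
            raise ValueError("baseline_rate must be > 0")
        if self.separability not in ("easy", "hard"):
            raise ValueError("separability must be 'easy' or 'hard'")
        for lo, hi in self.lesion_axes_range:
            if lo > hi:
                raise ValueError(f"lesion semi-axis min {lo} > max {hi}")
        half_extent = [
            s * n / 2.0 for s, n in zip(self.voxel_spacing, self.volume_shape)
        ]
        for (lo, hi), ext in zip(self.lesion_axes_range, half_extent):
            if hi >= ext:
                raise ValueError(
                    f"max lesion semi-axis {hi} mm does not fit in half-extent {ext} mm"
                )

    @classmethod
    def test_scale(cls, n_patients: int = 20, seed: int = 0, **kwargs) -> "SyntheticConfig":
        """Small profile (600 px images, 32^3 volumes) for fast runs."""
        defaults = dict(
            n_patients=n_patients,
            image_size=600,
            patch_size=50,
            volume_shape=(32, 32, 32),
            lesion_axes_range=((4.0, 10.0), (3.0, 8.0), (3.0, 7.0)),
            seed=seed,
        )
        defaults.update(kwargs)
        return cls(**defaults)

    def mixing_alpha(self) -> np.ndarray:
        a = np.asarray(self.mixing_concentration, dtype=float)
        if a.ndim == 0:
            a = np.full(self.n_texture_classes, float(a))
        if a.shape != (self.n_texture_classes,):
            raise ValueError("mixing_concentration length must equal n_texture_classes")
        return a

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["baseline_rate"] = float(d["baseline_rate"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("volume_shape", "voxel_spacing", "tnm_stage_probs"):
            if key in d:
                d[key] = tuple(d[key])
        if "lesion_axes_range" in d:
            d["lesion_axes_range"] = tuple(tuple(p) for p in d["lesion_axes_range"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Latent quantities the pipeline is supposed to recover."""

    patient_ids: list[str]
    true_mixing: np.ndarray            # (n, n_texture_classes), rows sum to 1
    true_lesion_semiaxes: np.ndarray   # (n, 3) mm
    true_linear_predictor: np.ndarray  # (n,)
    true_event_time: np.ndarray        # (n,) months, pre-censoring
    true_beta: dict[str, float]
    hazard_features: pd.DataFrame      # the feature table the hazard loaded on

    def to_json(self, path: str | Path) -> None:
        payload = {
            "patient_ids": self.patient_ids,
            "true_mixing": self.true_mixing.tolist(),
            "true_lesion_semiaxes": self.true_lesion_semiaxes.tolist(),
            "true_linear_predictor": self.true_linear_predictor.tolist(),
            "true_event_time": self.true_event_time.tolist(),
            "true_beta": self.true_beta,
            "hazard_features": self.hazard_features.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


@dataclass
class PatientRecord:
    patient_id: str
    histology_image: np.ndarray | str | Path
    ct_volume: np.ndarray | str | Path
    ct_mask: np.ndarray | str | Path
    voxel_spacing: tuple[float, float, float]
    clinical: dict[str, float]
    time: float    # months
    event: int     # 1 = death observed, 0 = censored

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError("survival time must be > 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


# ---------------------------------------------------------------------------
# histology


def _class_palette(n_classes: int, separability: str) -> np.ndarray:
    """RGB base color per texture class, separable in Rec.601 luminance."""
    if separability == "easy":
        lum = np.linspace(40.0, 220.0, n_classes)
    else:
        lum = np.linspace(100.0, 160.0, n_classes)
    # distinct fixed hue weights, rescaled so luminance matches the target
    hues = np.array(
        [
            [1.00, 0.85, 0.90],  # eosin-like pink
            [0.65, 0.55, 1.00],  # hematoxylin-like purple
            [0.90, 1.00, 0.80],
            [1.00, 1.00, 0.70],
            [0.70, 0.95, 1.00],
            [1.00, 0.75, 0.75],
            [0.80, 0.80, 1.00],
            [0.95, 1.00, 1.00],
        ]
    )
    rec601 = np.array([0.299, 0.587, 0.114])
    palette = np.empty((n_classes, 3))
    for c in range(n_classes):
        h = hues[c % len(hues)]
        palette[c] = h * (lum[c] / float(h @ rec601))
    return palette


def generate_histology_image(
    config: SyntheticConfig,
    mixing: Sequence[float],
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Render one patch-mosaic image with per-patch class labels.

    Each patch draws its class i.i.d. from ``mixing``; a patch of class c is
    the class base color plus a class-specific sinusoidal texture (random
    phase) plus i.i.d. Gaussian noise. Returns ``(H, W, 3) uint8`` image and
    the ``(H/p, W/p)`` integer label grid.
    """
    mixing = np.asarray(mixing, dtype=float)
    if mixing.ndim != 1 or np.any(mixing < 0) or abs(mixing.sum() - 1.0) > 1e-8:
        raise ValueError("mixing must be a non-negative vector summing to 1")
    if config.image_size % config.patch_size != 0:
        raise ValueError("image_size must be divisible by patch_size")
    p = config.patch_size
    g = config.image_size // p
    rng = substream(config.seed, "histology", seed)
    labels = rng.choice(len(mixing), size=(g, g), p=mixing)

    palette = _class_palette(config.n_texture_classes, config.separability)
    freqs = 1.0 + np.arange(config.n_texture_classes)  # cycles per patch
    yy = np.arange(p)[:, None] / p
    xx = np.arange(p)[None, :] / p

    image = np.empty((config.image_size, config.image_size, 3), dtype=np.uint8)
    for i in range(g):
        for j in range(g):
            c = labels[i, j]
            phase = rng.uniform(0, 2 * np.pi)
            wave = 10.0 * np.sin(2 * np.pi * freqs[c] * (xx + 0.3 * yy) + phase)
            patch = palette[c][None, None, :] + wave[:, :, None]
            patch = patch + rng.normal(0.0, config.texture_noise_sd, (p, p, 3))
            image[i * p : (i + 1) * p, j * p : (j + 1) * p] = np.clip(
                patch, 0, 255
            ).astype(np.uint8)
    return image, labels


# ---------------------------------------------------------------------------
# CT


def generate_ct_case(
    config: SyntheticConfig, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One CT-like volume: textured ellipsoidal lesion on a noisy background.

    Returns ``(volume, mask, semi_axes_mm)``. The mask is the rasterized
    ellipsoid; intensities inside it follow a stationary correlated-noise
    texture around a lesion mean distinct from the background.
    """
    from scipy.ndimage import gaussian_filter

    rng = substream(config.seed, "ct", seed)
    shape = config.volume_shape
    spacing = np.asarray(config.voxel_spacing, dtype=float)
    semi = np.array([rng.uniform(lo, hi) for lo, hi in config.lesion_axes_range])
    half_extent = spacing * np.asarray(shape) / 2.0
    if np.any(semi >= half_extent):
        raise ValueError("lesion does not fit inside the volume")

    center = (np.asarray(shape) - 1) / 2.0
    coords = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    dist2 = sum(
        ((c - c0) * s / a) ** 2 for c, c0, s, a in zip(coords, center, spacing, semi)
    )
    mask = (dist2 <= 1.0).astype(np.uint8)
    if mask.sum() == 0:  # degenerate floor: keep at least the center voxel
        mask[tuple(int(round(c)) for c in center)] = 1

    background = 30.0 + gaussian_filter(rng.normal(0.0, 12.0, shape), 1.0)
    corr = rng.uniform(0.5, 2.0)  # per-case texture correlation length (voxels)
    tex = gaussian_filter(rng.normal(0.0, 1.0, shape), corr)
    sd = tex[mask.astype(bool)].std()
    tex = tex / (sd if sd > 0 else 1.0) * config.texture_noise_sd * 2.0
    volume = np.where(mask.astype(bool), 100.0 + tex, background)
    return volume.astype(np.float32), mask, semi


# ---------------------------------------------------------------------------
# clinical covariates and survival


def generate_clinical_table(
    n: int,
    seed: int,
    marginals: Mapping[str, float] | None = None,
    tnm_probs: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Independent binary covariates plus an ordinal TNM stage (1..6)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    marginals = dict(CLINICAL_MARGINALS if marginals is None else marginals)
    tnm = np.asarray(TNM_STAGE_PROBS if tnm_probs is None else tnm_probs, dtype=float)
    tnm = tnm / tnm.sum()
    rng = substream(seed, "clinical")
    data = {
        name: (rng.random(n) < prev).astype(int) for name, prev in marginals.items()
    }
    data["tnm_stage"] = rng.choice(np.arange(1, len(tnm) + 1), size=n, p=tnm)
    df = pd.DataFrame(data)
    df.insert(0, "patient_id", [f"P{i:04d}" for i in range(n)])
    return df


def generate_survival(
    features: pd.DataFrame,
    true_beta: Mapping[str, float],
    config: SyntheticConfig,
    seed: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Sample survival outcomes under proportional hazards.

    Event times are exponential with rate ``baseline_rate * exp(x'beta)`` on
    z-scored features; censoring is the minimum of an exponential clock and an
    administrative horizon. Returns ``(time, event, linear_predictor,
    latent_event_time)`` — the last is the pre-censoring event time.
    """
    missing = [k for k in true_beta if k not in features.columns]
    if missing:
        raise KeyError(f"true_beta names not in features: {missing}")
    rng = substream(config.seed, "survival", seed)
    n = len(features)
    lp = np.zeros(n)
    for name, beta in true_beta.items():
        x = features[name].to_numpy(dtype=float)
        sd = x.std()
        z = (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
        lp += beta * z
    rate = config.baseline_rate * np.exp(lp)
    t_event = rng.exponential(1.0 / rate)
    if config.censor_rate > 0:
        t_cens = np.minimum(
            rng.exponential(1.0 / config.censor_rate, n), config.admin_censor_time
        )
    else:
        t_cens = np.full(n, config.admin_censor_time)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    time = np.maximum(time, 1e-6)
    return time, event, lp, t_event


# ---------------------------------------------------------------------------
# cohort assembly


def make_cohort(
    config: SyntheticConfig, out_dir: str | Path | None = None
) -> tuple[list[PatientRecord], GroundTruth]:
    """Generate a full cohort; optionally persist it to ``out_dir``.

    On disk the cohort is ``images/P####.png``, ``ct/P####_{vol,mask}.nii.gz``,
    ``clinical.csv`` (covariates + time_months + event), ``ground_truth.json``
    and ``config.yaml``. In-memory records hold arrays instead of paths.
    """
    rng = substream(config.seed, "mixing")
    alpha = config.mixing_alpha()
    n = config.n_patients
    mixing = rng.dirichlet(alpha, size=n)

    clinical = generate_clinical_table(
        n, config.seed, config.clinical_marginals, config.tnm_stage_probs
    )
    ids = clinical["patient_id"].tolist()

    images, labels_true = [], []
    volumes, masks, semiaxes = [], [], []
    for i in range(n):
        img, lab = generate_histology_image(config, mixing[i], i)
        images.append(img)
        labels_true.append(lab)
        vol, msk, semi = generate_ct_case(config, i)
        volumes.append(vol)
        masks.append(msk)
        semiaxes.append(semi)
    semiaxes = np.asarray(semiaxes)

    hazard_features = pd.DataFrame(
        {f"mixing_{c}": mixing[:, c] for c in range(config.n_texture_classes)}
    )
    vol_mm3 = (
        4.0 / 3.0 * np.pi * semiaxes.prod(axis=1)
    )  # analytic ellipsoid volume, mm^3
    hazard_features["lesion_log_volume"] = np.log(vol_mm3)
    for name in CLINICAL_MODEL_FEATURES:
        hazard_features[name] = clinical[name].to_numpy(dtype=float)

    time, event, lp, t_event_latent = generate_survival(
        hazard_features, config.true_beta, config, seed=0
    )
    truth = GroundTruth(
        patient_ids=ids,
        true_mixing=mixing,
        true_lesion_semiaxes=semiaxes,
        true_linear_predictor=lp,
        true_event_time=t_event_latent,
        true_beta=dict(config.true_beta),
        hazard_features=hazard_features,
    )

    surv_df = clinical.copy()
    surv_df["time_months"] = time
    surv_df["event"] = event

    records: list[PatientRecord] = []
    if out_dir is not None:
        from . import io as _io

        out = Path(out_dir)
        (out / "images").mkdir(parents=True, exist_ok=True)
        (out / "ct").mkdir(parents=True, exist_ok=True)
        for i, pid in enumerate(ids):
            img_path = out / "images" / f"{pid}.png"
            vol_path = out / "ct" / f"{pid}_vol.nii.gz"
            mask_path = out / "ct" / f"{pid}_mask.nii.gz"
            _io.write_png(img_path, images[i])
            _io.write_nifti(vol_path, volumes[i], config.voxel_spacing)
            _io.write_nifti(mask_path, masks[i], config.voxel_spacing)
            records.append(
                PatientRecord(
                    patient_id=pid,
                    histology_image=img_path,
                    ct_volume=vol_path,
                    ct_mask=mask_path,
                    voxel_spacing=config.voxel_spacing,
                    clinical={
                        k: float(clinical.loc[i, k])
                        for k in clinical.columns
                        if k != "patient_id"
                    },
                    time=float(time[i]),
                    event=int(event[i]),
                )
            )
        surv_df.to_csv(out / "clinical.csv", index=False)
        truth.to_json(out / "ground_truth.json")
        config.to_yaml(out / "config.yaml")
    else:
        for i, pid in enumerate(ids):
            records.append(
                PatientRecord(
                    patient_id=pid,
                    histology_image=images[i],
                    ct_volume=volumes[i],
                    ct_mask=masks[i],
                    voxel_spacing=config.voxel_spacing,
                    clinical={
                        k: float(clinical.loc[i, k])
                        for k in clinical.columns
                        if k != "patient_id"
                    },
                    time=float(time[i]),
                    event=int(event[i]),
                )
            )
    return records, truth
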