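"""Config-driven orchestration: simulate -> featurize -> select -> model -> report.

Stages communicate through plain files in the run directory (PNG / NIfTI /
CSV / JSON), every stage's outputs are content-hashed into a run manifest,
and a completed stage is skipped on re-run when its outputs still match the
manifest. All randomness flows from the master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as _io
from .histo import (
    assign_clusters,
    compute_ppcr,
    fit_cluster_model,
    ppcr_table,
    tile_image,
    vectorize_patches,
)
from .radiomics import RadiomicsConfig, ROIMask, VoxelGrid, extract_all
from .selection import DEFAULT_BLOCK_TARGETS, FeatureTable, select_features
from .survival import ModelConfig, ModelReport, SurvivalData, compare_models
from .synthetic import CLINICAL_MODEL_FEATURES, SyntheticConfig, make_cohort

logger = logging.getLogger("escprog")

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "run_pipeline",
    "infer_blocks",
    "build_feature_table",
    "export_cluster_heatmap_matrix",
]


@dataclass
class PipelineConfig:
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig.test_scale)
    k_clusters: int = 8               # paper-scale profile uses 20
    pca_components_cap: int = 50
    pca_variance_target: float = 0.95
    radiomics: RadiomicsConfig = field(default_factory=RadiomicsConfig)
    screen_alpha: float = 0.2
    block_targets: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_BLOCK_TARGETS)
    )
    model: ModelConfig = field(default_factory=ModelConfig)
    out_dir: str | Path = "run"
    seed: int = 0
    run_loocv: bool = True

    def config_hash(self) -> str:
        payload = json.dumps(
            dataclasses.asdict(self), sort_keys=True, default=str
        ).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        from .synthetic import SyntheticConfig

        d = yaml.safe_load(Path(path).read_text())
        if "synthetic" in d:
            s = d["synthetic"]
            for key in ("volume_shape", "voxel_spacing", "tnm_stage_probs"):
                if key in s:
                    s[key] = tuple(s[key])
            if "lesion_axes_range" in s:
                s["lesion_axes_range"] = tuple(tuple(p) for p in s["lesion_axes_range"])
            d["synthetic"] = SyntheticConfig(**s)
        if "radiomics" in d:
            d["radiomics"] = RadiomicsConfig(**d["radiomics"])
        if "model" in d:
            d["model"] = ModelConfig(**d["model"])
        return cls(**d)


@dataclass
class RunManifest:
    config_hash: str
    stages: dict[str, dict[str, str]] = field(default_factory=dict)  # stage -> {file: hash}
    timestamps: dict[str, str] = field(default_factory=dict)         # stage -> ISO time
    version: str = "0.1.0"

    def record(self, stage: str, files: list[Path]) -> None:
        import datetime

        self.stages[stage] = {str(f): _sha256(f) for f in files}
        self.timestamps[stage] = datetime.datetime.now().isoformat(
            timespec="seconds"
        )

    def stage_is_current(self, stage: str) -> bool:
        recorded = self.stages.get(stage)
        if not recorded:
            return False
        return all(
            Path(f).exists() and _sha256(Path(f)) == h for f, h in recorded.items()
        )

    def save(self, path: Path) -> None:
        path.write_text(
            json.dumps(
                {
                    "config_hash": self.config_hash,
                    "stages": self.stages,
                    "timestamps": self.timestamps,
                    "version": self.version,
                },
                indent=1,
            )
        )

    @classmethod
    def load(cls, path: Path) -> "RunManifest":
        d = json.loads(path.read_text())
        return cls(
            config_hash=d["config_hash"],
            stages=d["stages"],
            timestamps=d.get("timestamps", {}),
            version=d["version"],
        )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def infer_blocks(columns) -> dict[str, str]:
    """Block tag from naming convention: ``original_*`` -> CT,
    ``Cluster_*`` -> pathology, anything else -> clinical."""
    blocks = {}
    for c in columns:
        if c.startswith("original_"):
            blocks[c] = "CT"
        elif c.startswith("Cluster_"):
            blocks[c] = "pathology"
        else:
            blocks[c] = "clinical"
    return blocks


def featurize_histology(
    image_paths: list[Path],
    patient_ids: list[str],
    patch_size: int,
    k: int,
    seed: int,
    d_cap: int = 50,
    variance_target: float = 0.95,
):
    """Pooled vocabulary fit + per-patient PPCR table from image files."""
    patchsets = []
    pooled = []
    for pid, path in zip(patient_ids, image_paths):
        ps = tile_image(_io.read_image(path), patch_size, patient_id=pid)
        patchsets.append(ps)
        pooled.append(vectorize_patches(ps))
    model = fit_cluster_model(
        np.vstack(pooled), k=k, d_cap=d_cap, variance_target=variance_target,
        seed=seed,
    )
    vectors = [
        compute_ppcr(assign_clusters(model, ps), k, patient_id=ps.patient_id)
        for ps in patchsets
    ]
    return ppcr_table(vectors), model


def featurize_ct(
    volume_paths: list[Path],
    mask_paths: list[Path],
    patient_ids: list[str],
    config: RadiomicsConfig,
) -> tuple[pd.DataFrame, dict]:
    """Radiomic feature table from volume/mask files."""
    rows = []
    meta = config.metadata()
    for pid, vp, mp in zip(patient_ids, volume_paths, mask_paths):
        vol, spacing = _io.read_volume(vp)
        mask, _ = _io.read_volume(mp)
        vec = extract_all(
            VoxelGrid(vol.astype(float), spacing), ROIMask(mask > 0), config
        )
        row = {"patient_id": pid, **vec.values}
        rows.append(row)
    return pd.DataFrame(rows), meta


def build_feature_table(
    ppcr: pd.DataFrame, ct: pd.DataFrame, clinical: pd.DataFrame
) -> FeatureTable:
    """Join the three blocks on patient_id and attach survival columns."""
    merged = clinical.merge(ppcr, on="patient_id").merge(ct, on="patient_id")
    if len(merged) != len(clinical):
        raise ValueError("patient_id mismatch across feature tables")
    surv = SurvivalData(
        merged["time_months"].to_numpy(), merged["event"].to_numpy()
    )
    feature_cols = (
        [c for c in ct.columns if c != "patient_id"]
        + [c for c in ppcr.columns if c != "patient_id"]
        + list(CLINICAL_MODEL_FEATURES)
    )
    # drop features that are undefined (NaN) for any patient
    usable = [c for c in feature_cols if np.isfinite(merged[c]).all()]
    dropped = sorted(set(feature_cols) - set(usable))
    if dropped:
        logger.info("dropping %d features with undefined values: %s",
                    len(dropped), dropped[:5])
    return FeatureTable(
        features=merged[usable], blocks=infer_blocks(usable), surv=surv
    )


def export_cluster_heatmap_matrix(
    ppcr: pd.DataFrame, surv: SurvivalData
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split the patients x clusters occupancy matrix by vital status
    (alive = censored, dead = event)."""
    if len(ppcr) != len(surv):
        raise ValueError("PPCR table does not align with survival data")
    alive = ppcr.loc[surv.event == 0].reset_index(drop=True)
    dead = ppcr.loc[surv.event == 1].reset_index(drop=True)
    return alive, dead


def analyze_records(
    records,
    k_clusters: int = 8,
    patch_size: int = 50,
    radiomics_config: RadiomicsConfig | None = None,
    screen_alpha: float = 0.2,
    block_targets: dict[str, int] | None = None,
    seed: int = 0,
) -> tuple[FeatureTable, "pd.DataFrame"]:
    """Featurize + select on in-memory PatientRecords (no disk round-trip).

    Returns the post-selection FeatureTable (ready for ``compare_models`` /
    ``evaluate_model``) and the full PPCR table.
    """
    patchsets, pooled = [], []
    for rec in records:
        img = (
            rec.histology_image
            if isinstance(rec.histology_image, np.ndarray)
            else _io.read_image(rec.histology_image)
        )
        ps = tile_image(img, patch_size, patient_id=rec.patient_id)
        patchsets.append(ps)
        pooled.append(vectorize_patches(ps))
    model = fit_cluster_model(np.vstack(pooled), k=k_clusters, seed=seed)
    ppcr = ppcr_table(
        [
            compute_ppcr(assign_clusters(model, ps), k_clusters, ps.patient_id)
            for ps in patchsets
        ]
    )

    rcfg = radiomics_config or RadiomicsConfig()
    rows = []
    for rec in records:
        vol = (
            rec.ct_volume
            if isinstance(rec.ct_volume, np.ndarray)
            else _io.read_volume(rec.ct_volume)[0]
        )
        msk = (
            rec.ct_mask
            if isinstance(rec.ct_mask, np.ndarray)
            else _io.read_volume(rec.ct_mask)[0]
        )
        vec = extract_all(
            VoxelGrid(np.asarray(vol, float), rec.voxel_spacing),
            ROIMask(np.asarray(msk) > 0),
            rcfg,
        )
        rows.append({"patient_id": rec.patient_id, **vec.values})
    ct = pd.DataFrame(rows)

    clinical = pd.DataFrame(
        [{"patient_id": r.patient_id, **r.clinical} for r in records]
    )
    clinical["time_months"] = [r.time for r in records]
    clinical["event"] = [r.event for r in records]

    table = build_feature_table(ppcr, ct, clinical)
    _, sel = select_features(table, alpha=screen_alpha, targets=block_targets)
    retained = sel.all_retained()
    sub = FeatureTable(
        features=table.features[retained],
        blocks={k: table.blocks[k] for k in retained},
        surv=table.surv,
    )
    return sub, ppcr


def run_pipeline(config: PipelineConfig):
    """Execute all stages; returns ``(manifest, reports)``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    chash = config.config_hash()
    if manifest_path.exists():
        manifest = RunManifest.load(manifest_path)
        if manifest.config_hash != chash:
            manifest = RunManifest(config_hash=chash)
    else:
        manifest = RunManifest(config_hash=chash)

    syn = dataclasses.replace(config.synthetic, seed=config.seed)
    n = syn.n_patients
    ids = [f"P{i:04d}" for i in range(n)]
    cohort_dir = out / "cohort"
    clinical_csv = cohort_dir / "clinical.csv"

    # ---- stage: simulate
    stage = "simulate"
    cohort_files = (
        [cohort_dir / "images" / f"{p}.png" for p in ids]
        + [cohort_dir / "ct" / f"{p}_vol.nii.gz" for p in ids]
        + [cohort_dir / "ct" / f"{p}_mask.nii.gz" for p in ids]
        + [clinical_csv, cohort_dir / "ground_truth.json", cohort_dir / "config.yaml"]
    )
    if manifest.stage_is_current(stage):
        logger.info("stage %s: outputs current, skipped", stage)
    else:
        logger.info("stage %s: generating %d patients", stage, n)
        make_cohort(syn, cohort_dir)
        manifest.record(stage, cohort_files)
        manifest.save(manifest_path)

    clinical = pd.read_csv(clinical_csv)
    surv = SurvivalData(
        clinical["time_months"].to_numpy(), clinical["event"].to_numpy()
    )

    # ---- stage: featurize-histo
    stage = "featurize-histo"
    ppcr_csv = out / "ppcr.csv"
    model_file = out / "cluster_model.npz"
    alive_csv = out / "ppcr_alive.csv"
    dead_csv = out / "ppcr_dead.csv"
    if manifest.stage_is_current(stage):
        logger.info("stage %s: skipped", stage)
        ppcr = pd.read_csv(ppcr_csv)
    else:
        logger.info("stage %s: k=%d", stage, config.k_clusters)
        ppcr, cluster_model = featurize_histology(
            [cohort_dir / "images" / f"{p}.png" for p in ids],
            ids,
            patch_size=syn.patch_size,
            k=config.k_clusters,
            seed=config.seed,
            d_cap=config.pca_components_cap,
            variance_target=config.pca_variance_target,
        )
        ppcr.to_csv(ppcr_csv, index=False)
        cluster_model.save(model_file)
        alive, dead = export_cluster_heatmap_matrix(ppcr, surv)
        alive.to_csv(alive_csv, index=False)
        dead.to_csv(dead_csv, index=False)
        manifest.record(stage, [ppcr_csv, model_file, alive_csv, dead_csv])
        manifest.save(manifest_path)

    # ---- stage: featurize-ct
    stage = "featurize-ct"
    ct_csv = out / "ct_features.csv"
    ct_meta_json = out / "ct_features_meta.json"
    if manifest.stage_is_current(stage):
        logger.info("stage %s: skipped", stage)
        ct = pd.read_csv(ct_csv)
    else:
        logger.info("stage %s", stage)
        ct, meta = featurize_ct(
            [cohort_dir / "ct" / f"{p}_vol.nii.gz" for p in ids],
            [cohort_dir / "ct" / f"{p}_mask.nii.gz" for p in ids],
            ids,
            config.radiomics,
        )
        ct.to_csv(ct_csv, index=False)
        ct_meta_json.write_text(json.dumps(meta, indent=1))
        manifest.record(stage, [ct_csv, ct_meta_json])
        manifest.save(manifest_path)

    # ---- stages: select + models (cached jointly)
    uni_csv = out / "univariate.csv"
    sel_json = out / "selection.json"
    reports_json = out / "reports.json"
    km_csv = out / "km_curves.csv"
    cache_json = out / "models_cache.json"
    if (
        manifest.stage_is_current("select")
        and manifest.stage_is_current("models")
        and cache_json.exists()
    ):
        logger.info("stages select/models: skipped")
        reports = _reports_from_cache(cache_json)
        return manifest, reports

    table = build_feature_table(ppcr, ct, clinical)
    logger.info("stage select: alpha=%.2g targets=%s", config.screen_alpha,
                config.block_targets)
    uni, sel = select_features(
        table, alpha=config.screen_alpha, targets=config.block_targets
    )
    uni.to_csv(uni_csv)
    sel.to_json(sel_json)
    manifest.record("select", [uni_csv, sel_json])
    manifest.save(manifest_path)

    retained = sel.all_retained()
    sub = FeatureTable(
        features=table.features[retained],
        blocks={k: table.blocks[k] for k in retained},
        surv=surv,
    )
    mcfg = dataclasses.replace(config.model, seed=config.seed)
    reports = compare_models(
        sub.features, sub.blocks, surv, mcfg, run_loocv=config.run_loocv
    )
    reports_json.write_text(
        json.dumps({k: r.to_dict() for k, r in reports.items()}, indent=1)
    )
    # KM step curves per model/group as plain CSV
    km_rows = []
    for mname, rep in reports.items():
        for gname, g in rep.groups.items():
            for t, s in zip(g["times"], g["survival"]):
                km_rows.append(
                    {"model": mname, "group": gname, "time": float(t),
                     "survival": float(s)}
                )
    pd.DataFrame(km_rows).to_csv(km_csv, index=False)
    _reports_to_cache(reports, cache_json)
    manifest.record("models", [reports_json, km_csv, cache_json])
    manifest.save(manifest_path)
    logger.info("pipeline complete: %s", out)
    return manifest, reports


def _reports_to_cache(reports: dict[str, ModelReport], path: Path) -> None:
    payload = {}
    for name, rep in reports.items():
        d = dataclasses.asdict(rep)
        for g in d["groups"].values():
            g["times"] = np.asarray(g["times"]).tolist()
            g["survival"] = np.asarray(g["survival"]).tolist()
            g["os_at"] = {str(k): v for k, v in g["os_at"].items()}
        payload[name] = d
    path.write_text(json.dumps(payload, indent=1))


def _reports_from_cache(path: Path) -> dict[str, ModelReport]:
    payload = json.loads(path.read_text())
    reports = {}
    for name, d in payload.items():
        for g in d["groups"].values():
            g["times"] = np.asarray(g["times"], dtype=float)
            g["survival"] = np.asarray(g["survival"], dtype=float)
            g["os_at"] = {float(k): v for k, v in g["os_at"].items()}
        reports[name] = ModelReport(**d)
    return reports
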