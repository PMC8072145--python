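"""Feature screening and recursive feature elimination for survival features.

The selection stage mirrors the reported structure: a univariate Cox screen
keeps features with two-sided p < 0.2, then recursive feature elimination
(RFE) runs independently within each feature block (CT radiomics, pathology
PPCR, clinical), repeatedly fitting a ridge-stabilized multivariable Cox
model on standardized features and dropping the smallest-|coefficient|
feature until the per-block target count (default CT=8, pathology=5,
clinical=4, giving the 17-feature combined list) is reached.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .survival import ModelConfig, SurvivalData, fit_cox_l1, loocv_c

__all__ = [
    "FeatureTable",
    "UnivariateResult",
    "SelectionResult",
    "univariate_cox_screen",
    "rfe_cox",
    "select_features",
    "DEFAULT_BLOCK_TARGETS",
]

DEFAULT_BLOCK_TARGETS: dict[str, int] = {"CT": 8, "pathology": 5, "clinical": 4}


@dataclass
class FeatureTable:
    """Patients x named features, each feature tagged with a block, plus
    aligned survival columns."""

    features: pd.DataFrame            # columns = feature names
    blocks: dict[str, str]            # feature name -> block tag
    surv: SurvivalData

    def __post_init__(self) -> None:
        cols = list(self.features.columns)
        if len(set(cols)) != len(cols):
            raise ValueError("duplicate feature names")
        unknown = [c for c in cols if c not in self.blocks]
        if unknown:
            raise ValueError(f"features without a block tag: {unknown}")
        if len(self.features) != len(self.surv):
            raise ValueError("feature rows do not align with survival data")

    def block_columns(self, block: str) -> list[str]:
        return sorted(c for c in self.features.columns if self.blocks[c] == block)


@dataclass
class UnivariateResult:
    table: pd.DataFrame               # Feature, HR, p, CI_low, CI_high, block
    flagged: list[str] = field(default_factory=list)  # unestimable features

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class SelectionResult:
    retained: dict[str, list[str]]          # block -> kept feature names
    elimination_order: dict[str, list[str]]  # block -> dropped, in drop order
    trace: dict[str, list[dict]]            # block -> per-step criterion values

    def all_retained(self) -> list[str]:
        return [f for block in sorted(self.retained) for f in self.retained[block]]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "retained": self.retained,
                    "elimination_order": self.elimination_order,
                    "trace": self.trace,
                },
                indent=1,
            )
        )


def univariate_cox_screen(
    table: FeatureTable, alpha: float = 0.2
) -> tuple[UnivariateResult, list[str]]:
    """One-covariate Cox model per feature (z-scored); keep p < ``alpha``.

    Reports HR = exp(coefficient) with Wald p and 95% CI per feature.
    Zero-variance or non-converging features are flagged and excluded.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    if table.surv.event.sum() < 2:
        raise ValueError("need at least 2 events to screen")
    rows = []
    flagged: list[str] = []
    time, event = table.surv.time, table.surv.event
    for name in sorted(table.features.columns):
        x = table.features[name].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0 or not np.all(np.isfinite(x)):
            flagged.append(name)
            warnings.warn(f"feature '{name}' has no usable variation; excluded")
            continue
        df = pd.DataFrame({"x": (x - x.mean()) / sd, "T": time, "E": event})
        cph = CoxPHFitter()
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph.fit(df, duration_col="T", event_col="E")
        except (ConvergenceError, Exception) as exc:  # noqa: BLE001
            flagged.append(name)
            warnings.warn(f"univariate Cox fit failed for '{name}': {exc}")
            continue
        s = cph.summary.loc["x"]
        rows.append(
            {
                "Feature": name,
                "block": table.blocks[name],
                "HR": float(s["exp(coef)"]),
                "p": float(s["p"]),
                "CI_low": float(np.exp(s["coef lower 95%"])),
                "CI_high": float(np.exp(s["coef upper 95%"])),
            }
        )
    result = UnivariateResult(table=pd.DataFrame(rows), flagged=flagged)
    retained = (
        result.table.loc[result.table["p"] < alpha, "Feature"].tolist()
        if len(result.table)
        else []
    )
    return result, retained


def _rfe_block(
    X: pd.DataFrame, surv: SurvivalData, target: int, ridge: float
) -> tuple[list[str], list[str], list[dict]]:
    """Eliminate down to ``target`` features inside one block."""
    current = sorted(X.columns)
    dropped: list[str] = []
    trace: list[dict] = []
    while len(current) > target:
        model = fit_cox_l1(X[current], surv, lam=0.0, lam_l2=ridge)
        coefs = dict(zip(model.feature_names, np.abs(model.beta)))
        min_abs = min(coefs.values())
        # ties on |coefficient|: drop the lexicographically last name
        candidates = sorted(n for n, v in coefs.items() if v == min_abs)
        victim = candidates[-1]
        trace.append({"n_features": len(current), "dropped": victim,
                      "abs_coef": float(min_abs)})
        current.remove(victim)
        dropped.append(victim)
    return current, dropped, trace


def rfe_cox(
    table: FeatureTable,
    target_count: Mapping[str, int] | int | str = "auto",
    ridge: float = 0.1,
    config: ModelConfig | None = None,
    pooled: bool = False,
) -> SelectionResult:
    """Per-block recursive feature elimination.

    ``target_count`` is a per-block mapping, a single int applied to every
    block, or ``"auto"`` (pick the count maximizing LOOCV concordance along
    the elimination path — considerably slower). Raises if a block holds
    fewer features than its target. With ``pooled=True`` all features compete
    in one elimination pass instead of within their blocks.
    """
    if pooled:
        table = FeatureTable(
            features=table.features,
            blocks={c: "pooled" for c in table.features.columns},
            surv=table.surv,
        )
        if isinstance(target_count, Mapping):
            target_count = sum(target_count.values())
    blocks = sorted(set(table.blocks[c] for c in table.features.columns))
    retained: dict[str, list[str]] = {}
    order: dict[str, list[str]] = {}
    trace: dict[str, list[dict]] = {}
    for block in blocks:
        cols = table.block_columns(block)
        if target_count == "auto":
            retained[block], order[block], trace[block] = _rfe_auto(
                table.features[cols], table.surv, ridge, config or ModelConfig()
            )
            continue
        target = (
            target_count if isinstance(target_count, int) else target_count[block]
        )
        if target > len(cols):
            raise ValueError(
                f"block '{block}' has {len(cols)} features, fewer than target {target}"
            )
        if target < 1:
            raise ValueError("per-block target must be >= 1")
        retained[block], order[block], trace[block] = _rfe_block(
            table.features[cols], table.surv, target, ridge
        )
    return SelectionResult(retained=retained, elimination_order=order, trace=trace)


def _rfe_auto(
    X: pd.DataFrame, surv: SurvivalData, ridge: float, config: ModelConfig
) -> tuple[list[str], list[str], list[dict]]:
    """Elimination path down to one feature; keep the LOOCV-C-best prefix."""
    full_path_sets: list[list[str]] = []
    current = sorted(X.columns)
    dropped_all: list[str] = []
    trace: list[dict] = []
    full_path_sets.append(list(current))
    while len(current) > 1:
        kept, dropped, t = _rfe_block(X[current], surv, len(current) - 1, ridge)
        trace.extend(t)
        current = kept
        dropped_all.extend(dropped)
        full_path_sets.append(list(current))
    best_c, best_set = -np.inf, full_path_sets[0]
    for s in full_path_sets:
        c, _ = loocv_c(X[s], surv, config)
        if c > best_c:
            best_c, best_set = c, s
    n_drop = len(X.columns) - len(best_set)
    return best_set, dropped_all[:n_drop], trace


def select_features(
    table: FeatureTable,
    alpha: float = 0.2,
    targets: Mapping[str, int] | None = None,
    ridge: float = 0.1,
) -> tuple[UnivariateResult, SelectionResult]:
    """Screen at p < ``alpha`` then RFE each block to its target count.

    Targets larger than what the screen leaves in a block are clamped (with a
    warning) so small cohorts remain analyzable.
    """
    targets = dict(DEFAULT_BLOCK_TARGETS if targets is None else targets)
    uni, kept = univariate_cox_screen(table, alpha)
    # every block must contribute >= 1 feature; if the screen empties one,
    # fall back to its smallest-p feature
    for block in sorted(set(table.blocks.values())):
        if any(table.blocks[k] == block for k in kept):
            continue
        cand = uni.table[uni.table["block"] == block]
        if len(cand) == 0:
            raise ValueError(f"block '{block}' has no estimable feature")
        best = cand.sort_values(["p", "Feature"]).iloc[0]["Feature"]
        warnings.warn(
            f"screen emptied block '{block}'; keeping its smallest-p feature "
            f"'{best}'"
        )
        kept.append(best)
    if not kept:
        raise ValueError("screening retained no features")
    screened = FeatureTable(
        features=table.features[sorted(kept)],
        blocks={k: table.blocks[k] for k in kept},
        surv=table.surv,
    )
    effective: dict[str, int] = {}
    for block in sorted(set(screened.blocks.values())):
        avail = len(screened.block_columns(block))
        want = targets.get(block, avail)
        if want > avail:
            warnings.warn(
                f"block '{block}': target {want} clamped to {avail} screened features"
            )
            want = avail
        effective[block] = max(1, want)
    sel = rfe_cox(screened, effective, ridge=ridge)
    return uni, sel
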