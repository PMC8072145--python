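"""Survival modeling: L1-penalized Cox, risk scores, validation, stratification.

The estimator maximizes the Breslow-ties Cox partial log-likelihood minus an
L1 penalty by iteratively reweighted least squares with cyclic coordinate
descent and soft-thresholding (the glmnet-style quadratic approximation).
Around it: cross-validated penalty selection, the scalar survival score
SC = x'beta on standardized features, median-split risk stratification,
Harrell's concordance index (apparent and pooled leave-one-out
cross-validated), Kaplan-Meier overall-survival summaries and the two-group
log-rank test, assembled into a four-model comparison (clinical / CT+clinical
/ pathology+clinical / combined).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SurvivalData",
    "CoxModel",
    "RiskStrata",
    "ModelReport",
    "ModelConfig",
    "fit_cox_l1",
    "select_lambda",
    "lambda_max",
    "survival_score",
    "median_split",
    "harrell_c",
    "loocv_c",
    "km_estimate",
    "logrank_test",
    "compare_models",
    "MODEL_BLOCKS",
]


@dataclass
class SurvivalData:
    time: np.ndarray   # months, > 0
    event: np.ndarray  # 1 = event observed, 0 = censored

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape:
            raise ValueError("time and event lengths differ")
        if np.any(self.time <= 0):
            raise ValueError("survival times must be > 0")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event must be 0/1")

    def __len__(self) -> int:
        return len(self.time)

    def subset(self, idx) -> "SurvivalData":
        return SurvivalData(self.time[idx], self.event[idx])


@dataclass
class CoxModel:
    feature_names: list[str]
    beta: np.ndarray          # on standardized scale
    lam: float                # L1 penalty
    mean: np.ndarray          # standardization parameters
    sd: np.ndarray
    ties: str = "breslow"
    n_iter: int = 0


@dataclass
class RiskStrata:
    scores: np.ndarray
    threshold: float          # cohort median of SC
    labels: np.ndarray        # "low" / "high"


# ---------------------------------------------------------------------------
# Breslow partial likelihood machinery


def _breslow_suffstats(time: np.ndarray, event: np.ndarray):
    """Sort order and tie grouping reused across IRLS iterations."""
    order = np.argsort(time, kind="stable")
    t_sorted = time[order]
    # first index of each tied block (ascending time)
    first_of_block = np.searchsorted(t_sorted, t_sorted, side="left")
    last_of_block = np.searchsorted(t_sorted, t_sorted, side="right") - 1
    return order, t_sorted, first_of_block, last_of_block


def breslow_loglik(
    eta: np.ndarray, time: np.ndarray, event: np.ndarray
) -> float:
    """Breslow-ties Cox partial log-likelihood at linear predictor ``eta``."""
    order, _, first, _ = _breslow_suffstats(time, event)
    eta_s = eta[order]
    ev_s = event[order].astype(bool)
    r = np.exp(eta_s)
    suffix = np.cumsum(r[::-1])[::-1]
    s0 = suffix[first]  # risk-set sum at each subject's time
    return float(eta_s[ev_s].sum() - np.log(s0[ev_s]).sum())


def _grad_weights(eta, time, event, stats):
    """Per-subject score residual g and diagonal Hessian weight w."""
    order, _, first, last = stats
    eta_s = eta[order]
    ev_s = event[order].astype(float)
    r = np.exp(np.clip(eta_s, -200, 200))
    suffix = np.cumsum(r[::-1])[::-1]
    s0 = suffix[first]
    h1 = np.cumsum(ev_s / s0)          # sum of d_i/S0 over times <= t_k
    h2 = np.cumsum(ev_s / s0**2)
    G1 = h1[last]  # include all events at tied times
    G2 = h2[last]
    g_s = ev_s - r * G1
    w_s = r * G1 - r**2 * G2
    g = np.empty_like(g_s)
    w = np.empty_like(w_s)
    g[order] = g_s
    w[order] = w_s
    return g, np.maximum(w, 1e-10)


def lambda_max(X: np.ndarray, surv: SurvivalData) -> float:
    """Smallest L1 penalty that zeroes every coefficient (at beta = 0)."""
    stats = _breslow_suffstats(surv.time, surv.event)
    g, _ = _grad_weights(np.zeros(len(surv)), surv.time, surv.event, stats)
    return float(np.abs(X.T @ g).max() / len(surv))


def _fit_cd(
    X: np.ndarray,
    surv: SurvivalData,
    lam: float,
    lam_l2: float = 0.0,
    beta0: np.ndarray | None = None,
    tol: float = 1e-6,
    max_cycles: int = 10_000,
    strict: bool = True,
) -> tuple[np.ndarray, int]:
    """IRLS + cyclic coordinate descent with soft-thresholding (columns assumed
    standardized). Returns (beta, total CD cycles)."""
    from ._coxnet import NO_OUTER_CONV, OK, STALLED, cd_kernel

    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    stats = _breslow_suffstats(surv.time, surv.event)
    if lam == 0.0:
        # no soft-thresholding needed: solve each IRLS quadratic exactly,
        # which is far more robust under collinear feature blocks
        eta = X @ beta
        for it in range(200):
            g, w = _grad_weights(eta, surv.time, surv.event, stats)
            H = (X.T * w) @ X / n + lam_l2 * np.eye(p)
            rhs = X.T @ (w * eta + g) / n
            beta_new = np.linalg.solve(H, rhs)
            delta = np.abs(beta_new - beta).max()
            beta = beta_new
            eta = X @ beta
            if delta < tol:
                return beta, it + 1
        raise RuntimeError("IRLS ridge fit did not converge in 200 iterations")

    order, _, first, last = stats
    X = np.ascontiguousarray(X, dtype=np.float64)
    cycles, status, last_delta = cd_kernel(
        X, order.astype(np.int64), first.astype(np.int64), last.astype(np.int64),
        surv.event.astype(np.int64), float(lam), float(lam_l2), beta,
        float(tol), int(max_cycles),
    )
    if status != OK:
        # convergence certificate: max violation of the L1 subgradient
        # optimality conditions — near-duplicate columns create long flat
        # valleys where coefficient deltas crawl long after the solution is
        # optimal for every practical purpose
        g, _ = _grad_weights(X @ beta, surv.time, surv.event, stats)
        grad = -(X.T @ g) / n + lam_l2 * beta
        kkt = np.where(
            beta != 0,
            np.abs(grad + lam * np.sign(beta)),
            np.maximum(0.0, np.abs(grad) - lam),
        ).max()
        if kkt < 1e-4:
            status = OK
    if status == STALLED:
        # near-duplicate columns make the L1 solution non-unique and CD can
        # plateau just above tol while the linear predictor is long settled;
        # accept a stalled solution whose remaining change is negligible on
        # the coefficient scale (always, in non-strict path fits where only
        # the deviance is consumed), error otherwise
        scale = max(1.0, float(np.abs(beta).max()))
        if not strict or last_delta < max(100 * tol, 1e-3 * scale):
            warnings.warn(
                f"coordinate descent stalled at max delta {last_delta:.2g} "
                f"after {max_cycles} cycles (lam={lam:.3g}); accepting"
            )
            return beta, cycles
        raise RuntimeError(
            f"coordinate descent did not converge in {max_cycles} cycles "
            f"(lam={lam:.3g}, last sweep max delta={last_delta:.3g})"
        )
    if status == NO_OUTER_CONV and strict:
        raise RuntimeError(
            f"IRLS did not converge (lam={lam:.3g}, cycles={cycles})"
        )
    return beta, cycles


def _standardize(X: np.ndarray):
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mean) / sd_safe, mean, sd_safe


def fit_cox_l1(
    X: pd.DataFrame | np.ndarray,
    surv: SurvivalData,
    lam: float,
    lam_l2: float = 0.0,
    feature_names: Sequence[str] | None = None,
) -> CoxModel:
    """LASSO-Cox fit at penalty ``lam`` (features z-scored internally).

    ``lam`` is on the per-observation scale: the objective is
    ``-(1/n) loglik + lam * sum|beta_j| (+ lam_l2/2 * sum beta_j^2)``.
    """
    if lam < 0 or lam_l2 < 0:
        raise ValueError("penalties must be >= 0")
    if surv.event.sum() < 1:
        raise ValueError("need at least one observed event")
    if isinstance(X, pd.DataFrame):
        feature_names = list(X.columns)
        X = X.to_numpy(dtype=float)
    elif feature_names is None:
        feature_names = [f"x{j}" for j in range(X.shape[1])]
    Xz, mean, sd = _standardize(np.asarray(X, dtype=float))
    beta, cycles = _fit_cd(Xz, surv, lam, lam_l2)
    if lam > 0:
        beta[np.abs(beta) < 1e-10] = 0.0  # numerical dust at the threshold
    return CoxModel(
        feature_names=list(feature_names),
        beta=beta,
        lam=float(lam),
        mean=mean,
        sd=sd,
        n_iter=cycles,
    )


def _cv_folds(n: int, k: int, event: np.ndarray, rng: np.random.Generator):
    """Seeded fold assignment; refolds (with warning) if a training split
    would contain no events."""
    for attempt in range(20):
        perm = rng.permutation(n)
        folds = [perm[i::k] for i in range(k)]
        ok = all(event[np.setdiff1d(np.arange(n), f)].sum() >= 2 for f in folds)
        if ok:
            if attempt > 0:
                warnings.warn("degenerate folds (no events) — refolded")
            return folds
    raise ValueError("cannot build folds with events in every training split")


def default_lambda_grid(
    X: np.ndarray,
    surv: SurvivalData,
    n_lambda: int = 50,
    min_ratio: float | None = None,
) -> np.ndarray:
    """50 log-spaced penalties from lambda_max down to ``min_ratio`` of it
    (0.001, or 0.01 when p >= n — the usual high-dimensional convention)."""
    if min_ratio is None:
        min_ratio = 0.001 if X.shape[0] > X.shape[1] else 0.01
    lmax = lambda_max(X, surv)
    return np.geomspace(lmax, lmax * min_ratio, n_lambda)


def select_lambda(
    X: pd.DataFrame | np.ndarray,
    surv: SurvivalData,
    grid: Sequence[float] | None = None,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Penalty minimizing cross-validated partial-likelihood deviance.

    Uses the Verweij–van Houwelingen deviance
    ``-2 [l_all(beta_train) - l_train(beta_train)]`` summed over folds, with
    warm starts down the path; ties resolve to the larger penalty.
    """
    if isinstance(X, pd.DataFrame):
        X = X.to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    Xz, _, _ = _standardize(X)
    if grid is None:
        grid = default_lambda_grid(Xz, surv)
    grid = np.sort(np.asarray(grid, dtype=float))[::-1]
    if grid.size == 0:
        raise ValueError("empty lambda grid")
    if grid.size == 1:
        return float(grid[0])

    rng = np.random.default_rng(seed)
    fold_idx = _cv_folds(len(surv), folds, surv.event, rng)
    dev = np.zeros(grid.size)
    all_idx = np.arange(len(surv))
    for test in fold_idx:
        train = np.setdiff1d(all_idx, test)
        Xtr, _, _ = _standardize(X[train])
        # evaluate l_all on the same standardization as the training fit
        mean_tr = X[train].mean(axis=0)
        sd_tr = np.where(X[train].std(axis=0) > 0, X[train].std(axis=0), 1.0)
        Xall = (X - mean_tr) / sd_tr
        surv_tr = surv.subset(train)
        beta = np.zeros(X.shape[1])
        for gi, lam in enumerate(grid):
            # loose tolerance: only the CV deviance is consumed here, and a
            # 1e-4 coefficient error is far below its fold-to-fold noise
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                beta, _ = _fit_cd(
                    Xtr, surv_tr, lam, beta0=beta, tol=1e-4, max_cycles=250,
                    strict=False,
                )
            l_train = breslow_loglik(Xtr @ beta, surv_tr.time, surv_tr.event)
            l_all = breslow_loglik(Xall @ beta, surv.time, surv.event)
            dev[gi] += -2.0 * (l_all - l_train)
    best = int(np.argmin(dev))  # grid descending: first minimum = largest lambda
    return float(grid[best])


def survival_score(model: CoxModel, X: pd.DataFrame | np.ndarray) -> np.ndarray:
    """SC = standardized(x)' beta per patient."""
    if isinstance(X, pd.DataFrame):
        missing = [f for f in model.feature_names if f not in X.columns]
        if missing:
            raise KeyError(f"features missing from input: {missing}")
        X = X[model.feature_names].to_numpy(dtype=float)
    X = np.asarray(X, dtype=float)
    return (X - model.mean) / model.sd @ model.beta


def median_split(scores: np.ndarray) -> RiskStrata:
    """High risk: SC > cohort median; scores at the median go to low risk."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least 2 patients")
    med = float(np.median(scores))
    labels = np.where(scores > med, "high", "low")
    if (labels == "low").all():
        warnings.warn("all survival scores identical: single low-risk group")
    return RiskStrata(scores=scores, threshold=med, labels=labels)


def harrell_c(scores: np.ndarray, surv: SurvivalData) -> float:
    """Harrell's concordance index by exhaustive pair counting.

    Comparable pairs: the strictly shorter time carries an event. Concordant
    when the shorter-lived patient has the higher risk score; score ties
    count 1/2.
    """
    s = np.asarray(scores, dtype=float)
    t, e = surv.time, surv.event.astype(bool)
    # pair (i, j): t_i < t_j and event_i
    shorter = (t[:, None] < t[None, :]) & e[:, None]
    n_comp = int(shorter.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    conc = int((shorter & (s[:, None] > s[None, :])).sum())
    ties = int((shorter & (s[:, None] == s[None, :])).sum())
    return (conc + 0.5 * ties) / n_comp


@dataclass
class ModelConfig:
    """Settings for penalty search and cross-validation."""

    n_lambda: int = 50
    lambda_min_ratio: float = 0.001
    inner_folds: int = 5
    seed: int = 0


def loocv_c(
    X: pd.DataFrame,
    surv: SurvivalData,
    config: ModelConfig | None = None,
) -> tuple[float, int]:
    """Leave-one-out cross-validated Harrell's C.

    Per held-out patient: standardize on the rest, select the penalty by
    inner cross-validation, fit, and score the held-out row; one concordance
    is computed on the pooled out-of-fold scores. Returns ``(C, n_skipped)``;
    folds whose training data cannot be fitted are skipped with a warning.
    """
    config = config or ModelConfig()
    n = len(surv)
    if n < 3:
        raise ValueError("LOOCV needs n >= 3")
    scores = np.full(n, np.nan)
    for i in range(n):
        train = np.delete(np.arange(n), i)
        surv_tr = surv.subset(train)
        if surv_tr.event.sum() < 2:
            warnings.warn(f"fold {i} skipped: too few events in training data")
            continue
        Xtr = X.iloc[train]
        lam = select_lambda(
            Xtr, surv_tr, folds=config.inner_folds, seed=config.seed + i
        )
        model = fit_cox_l1(Xtr, surv_tr, lam)
        scores[i] = survival_score(model, X.iloc[[i]])[0]
    ok = np.isfinite(scores)
    n_skipped = int((~ok).sum())
    c = harrell_c(scores[ok], surv.subset(ok))
    return c, n_skipped


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank (lifelines-backed)


def km_estimate(
    surv: SurvivalData, groups: np.ndarray, horizons: Sequence[float] = (12.0, 36.0)
) -> dict[str, dict]:
    """Product-limit curves per group with OS at the horizons and the median
    survival time (None when the curve never reaches 0.5)."""
    from lifelines import KaplanMeierFitter

    groups = np.asarray(groups)
    out: dict[str, dict] = {}
    for g in np.unique(groups):
        sel = groups == g
        if sel.sum() == 0:
            raise ValueError(f"empty group {g}")
        kmf = KaplanMeierFitter()
        kmf.fit(surv.time[sel], surv.event[sel])
        sf = kmf.survival_function_.iloc[:, 0]
        os_at = {
            float(h): float(kmf.predict(h)) for h in horizons
        }
        med = kmf.median_survival_time_
        out[str(g)] = {
            "n": int(sel.sum()),
            "times": sf.index.to_numpy(),
            "survival": sf.to_numpy(),
            "os_at": os_at,
            "median_survival": None if np.isinf(med) else float(med),
        }
    return out


def logrank_test(surv: SurvivalData, groups: np.ndarray) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p)."""
    from lifelines.statistics import logrank_test as _lr

    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"log-rank needs exactly 2 groups, got {len(labels)}")
    if surv.event.sum() == 0:
        raise ValueError("no events")
    a = groups == labels[0]
    res = _lr(
        surv.time[a], surv.time[~a], event_observed_A=surv.event[a],
        event_observed_B=surv.event[~a],
    )
    return float(res.test_statistic), float(res.p_value)


# ---------------------------------------------------------------------------
# four-model comparison

#: model name -> feature blocks used
MODEL_BLOCKS: dict[str, tuple[str, ...]] = {
    "clinical": ("clinical",),
    "ct_clinical": ("CT", "clinical"),
    "pathology_clinical": ("pathology", "clinical"),
    "combined": ("CT", "pathology", "clinical"),
}


@dataclass
class ModelReport:
    name: str
    features: list[str]
    lam: float
    apparent_c: float
    loocv_c: float
    loocv_skipped: int
    groups: dict[str, dict]       # per risk group: OS at horizons, median, n
    logrank_stat: float
    logrank_p: float
    threshold: float
    coefficients: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        groups = {
            g: {
                "n": v["n"],
                "os_12m": v["os_at"][12.0],
                "os_36m": v["os_at"][36.0],
                "median_survival": v["median_survival"],
            }
            for g, v in self.groups.items()
        }
        return {
            "model": self.name,
            "features": self.features,
            "lambda": self.lam,
            "apparent_c": self.apparent_c,
            "loocv_c": self.loocv_c,
            "loocv_skipped": self.loocv_skipped,
            "groups": groups,
            "logrank_stat": self.logrank_stat,
            "logrank_p": self.logrank_p,
            "coefficients": self.coefficients,
        }


def evaluate_model(
    name: str,
    X: pd.DataFrame,
    surv: SurvivalData,
    config: ModelConfig | None = None,
    run_loocv: bool = True,
) -> ModelReport:
    """Full chain for one feature set: penalty search, fit, scores, median
    split, KM summaries, log-rank, apparent and (optionally) LOOCV C."""
    config = config or ModelConfig()
    lam = select_lambda(X, surv, folds=config.inner_folds, seed=config.seed)
    model = fit_cox_l1(X, surv, lam)
    sc = survival_score(model, X)
    strata = median_split(sc)
    apparent = harrell_c(sc, surv)
    if run_loocv:
        cv_c, skipped = loocv_c(X, surv, config)
    else:
        cv_c, skipped = float("nan"), 0
    if len(np.unique(strata.labels)) == 2:
        km = km_estimate(surv, strata.labels)
        stat, p = logrank_test(surv, strata.labels)
    else:
        km = km_estimate(surv, strata.labels)
        stat, p = float("nan"), float("nan")
    return ModelReport(
        name=name,
        features=list(X.columns),
        lam=lam,
        apparent_c=apparent,
        loocv_c=cv_c,
        loocv_skipped=skipped,
        groups=km,
        logrank_stat=stat,
        logrank_p=p,
        threshold=strata.threshold,
        coefficients=dict(zip(model.feature_names, model.beta.tolist())),
    )


def compare_models(
    features: pd.DataFrame,
    blocks: Mapping[str, str],
    surv: SurvivalData,
    config: ModelConfig | None = None,
    run_loocv: bool = True,
) -> dict[str, ModelReport]:
    """Evaluate the four nested models on identical data, folds and seeds.

    ``blocks`` maps feature name -> block tag (CT / pathology / clinical);
    pass the post-selection feature table so the combined model uses the
    full retained list.
    """
    config = config or ModelConfig()
    missing_blocks = {"CT", "pathology", "clinical"} - set(blocks.values())
    if missing_blocks:
        raise ValueError(f"feature blocks absent: {sorted(missing_blocks)}")
    reports = {}
    for name, wanted in MODEL_BLOCKS.items():
        cols = [c for c in features.columns if blocks.get(c) in wanted]
        try:
            reports[name] = evaluate_model(
                name, features[cols], surv, config, run_loocv
            )
        except Exception as exc:
            raise RuntimeError(f"model '{name}' failed: {exc}") from exc
    return reports
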