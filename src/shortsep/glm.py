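"""Task/nuisance design construction and per-channel OLS GLMs.

Ten pipelines differ only in how short-channel (SC) nuisance regressors are
built:

====  =======  ============  ==========================================
id    scope    method        nuisance regressors per fit
====  =======  ============  ==========================================
1     none     none          0
2     limited  nearest       1 (lobe's SC, same chromophore)
3     limited  correlated    1 (most-correlated of the 3, same chromophore)
4     limited  mean          2 (mean SC-HbO, mean SC-HbR)
5     limited  pooled_pca    6 (all PCs of the 3-SC x 2-chromophore matrix)
6     full     nearest       1 (SC at the channel's own source)
7     full     correlated    1 (most-correlated of the 8)
8     full     mean          2
9     full     pooled_raw    16 (all 8 SCs, both chromophores, raw)
10    full     pooled_pca    16 (all PCs of the 16-column matrix)
====  =======  ============  ==========================================

Fitting is plain OLS (no prewhitening), one model per long channel and
chromophore, with the three HRF-convolved condition regressors plus an
intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from .montage import Montage, nearest_sc, scope_sc_ids
from .preprocess import CHROMOPHORES, HemoSeries, bandpass_array

CONDITIONS = ("A", "V", "AV")


class DesignError(ValueError):
    pass


class DegenerateFitError(ValueError):
    pass


# ---------------------------------------------------------------------------
# HRF and task design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HrfParams:
    """Canonical double-gamma HRF parameters (seconds)."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    length: float = 32.0


def canonical_hrf(fs: float, params: HrfParams = HrfParams()) -> np.ndarray:
    """Double-gamma HRF kernel sampled at ``fs``, peak-normalized to 1."""
    if fs <= 0:
        raise DesignError("fs must be positive")
    t = np.arange(0.0, params.length, 1.0 / fs)
    peak = gamma_dist.pdf(t, params.peak_delay / params.peak_dispersion, scale=params.peak_dispersion)
    under = gamma_dist.pdf(
        t, params.undershoot_delay / params.undershoot_dispersion, scale=params.undershoot_dispersion
    )
    h = peak - params.undershoot_ratio * under
    return h / h.max()


@dataclass
class TaskDesign:
    columns: dict  # condition -> (n_samples,) regressor; plus "intercept"
    fs: float
    hrf_params: HrfParams = HrfParams()

    def matrix(self) -> np.ndarray:
        return np.column_stack([self.columns[c] for c in CONDITIONS] + [self.columns["intercept"]])

    @property
    def names(self) -> list[str]:
        return list(CONDITIONS) + ["intercept"]


def condition_regressor(
    onsets: np.ndarray,
    durations: np.ndarray,
    fs: float,
    n_samples: int,
    hrf: np.ndarray | None = None,
    params: HrfParams = HrfParams(),
) -> np.ndarray:
    """Boxcar at (onsets, durations) convolved with the canonical HRF."""
    if hrf is None:
        hrf = canonical_hrf(fs, params)
    box = np.zeros(n_samples)
    for onset, dur in zip(onsets, durations):
        i0 = int(np.round(onset * fs))
        i1 = int(np.round((onset + dur) * fs))
        if i1 > n_samples:
            raise DesignError(f"event at {onset:.1f} s extends beyond the recording")
        box[i0:i1] = 1.0
    return np.convolve(box, hrf)[:n_samples]


def build_task_design(
    schedule,
    fs: float,
    n_samples: int,
    hrf_params: HrfParams = HrfParams(),
    design_band: tuple[float, float] | None = (0.01, 0.12),
) -> TaskDesign:
    """One HRF-convolved regressor per condition (A, V, AV) plus an intercept.

    With ``design_band`` set (the default, matching the preprocessing band),
    the condition regressors receive the same zero-phase band-pass that the
    data receive, so the estimator compares like with like and condition betas
    stay unbiased; the intercept is left untouched.
    """
    hrf = canonical_hrf(fs, hrf_params)
    cols: dict = {}
    for cond in CONDITIONS:
        mask = np.asarray([c == cond for c in schedule.conditions], dtype=bool)
        col = condition_regressor(
            np.asarray(schedule.onsets)[mask], np.asarray(schedule.durations)[mask], fs, n_samples, hrf
        )
        if design_band is not None and np.any(col):
            col = bandpass_array(col, fs, *design_band)
        cols[cond] = col
    cols["intercept"] = np.ones(n_samples)
    return TaskDesign(cols, fs, hrf_params)


# ---------------------------------------------------------------------------
# Pipelines and nuisance sets
# ---------------------------------------------------------------------------

SC_METHODS = ("none", "nearest", "correlated", "mean", "pooled_raw", "pooled_pca")


@dataclass(frozen=True)
class PipelineConfig:
    id: int
    sc_scope: str  # none | limited | full
    method: str
    label: str = ""

    def __post_init__(self):
        if self.method not in SC_METHODS:
            raise DesignError(f"unknown SC method {self.method!r}")
        if self.sc_scope == "limited" and self.method == "pooled_raw":
            raise DesignError("the limited scope pools SCs only via PCA")
        if (self.sc_scope == "none") != (self.method == "none"):
            raise DesignError("scope 'none' pairs only with method 'none'")


PIPELINES: dict[int, PipelineConfig] = {
    1: PipelineConfig(1, "none", "none", "no SC correction"),
    2: PipelineConfig(2, "limited", "nearest", "3 SCs - nearest"),
    3: PipelineConfig(3, "limited", "correlated", "3 SCs - most correlated"),
    4: PipelineConfig(4, "limited", "mean", "3 SCs - mean"),
    5: PipelineConfig(5, "limited", "pooled_pca", "3 SCs - pooled with PCA"),
    6: PipelineConfig(6, "full", "nearest", "all SCs - nearest"),
    7: PipelineConfig(7, "full", "correlated", "all SCs - most correlated"),
    8: PipelineConfig(8, "full", "mean", "all SCs - mean"),
    9: PipelineConfig(9, "full", "pooled_raw", "all SCs - pooled without PCA"),
    10: PipelineConfig(10, "full", "pooled_pca", "all SCs - pooled with PCA"),
}

EXPECTED_NUISANCE_COUNT = {
    ("none", "none"): 0,
    ("limited", "nearest"): 1,
    ("limited", "correlated"): 1,
    ("limited", "mean"): 2,
    ("limited", "pooled_pca"): 6,
    ("full", "nearest"): 1,
    ("full", "correlated"): 1,
    ("full", "mean"): 2,
    ("full", "pooled_raw"): 16,
    ("full", "pooled_pca"): 16,
}


@dataclass
class NuisanceSet:
    names: list[str]
    columns: np.ndarray  # (n_samples, count); count may be 0

    @property
    def count(self) -> int:
        return 0 if self.columns.size == 0 else self.columns.shape[1]


def _sc_matrix(sc_hemo: HemoSeries, sc_ids: list[int]) -> tuple[np.ndarray, list[str]]:
    """Concatenated (time x signals) SC matrix: all HbO columns then all HbR."""
    cols, names = [], []
    for chromo in CHROMOPHORES:
        for sc_id in sc_ids:
            cols.append(sc_hemo.trace(f"S{sc_id}", chromo))
            names.append(f"SC{sc_id}-{chromo}")
    return np.column_stack(cols), names


def sc_pca_components(sc_hemo: HemoSeries, sc_ids: list[int]) -> tuple[np.ndarray, list[str]]:
    """All principal-component scores of the column-centered SC matrix.

    Components are ordered by decreasing explained variance; components with a
    singular value below 1e-10 x the largest are dropped with a warning.
    """
    X, _ = _sc_matrix(sc_hemo, sc_ids)
    Xc = X - X.mean(axis=0)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    keep = s > 1e-10 * s[0]
    if not np.all(keep):
        warnings.warn(f"dropping {np.sum(~keep)} rank-deficient PCA component(s)")
    scores = U[:, keep] * s[keep]
    names = [f"PC-{k + 1}" for k in range(int(keep.sum()))]
    return scores, names


def build_nuisance(
    config: PipelineConfig,
    sc_hemo: HemoSeries | None,
    target_channel,
    target_chromophore: str,
    lc_trace: np.ndarray | None,
    montage: Montage,
    _pca_cache: dict | None = None,
) -> NuisanceSet:
    """Nuisance regressors for one long channel / chromophore fit.

    ``lc_trace`` (the target's preprocessed series) is needed only by the
    signal-specific 'correlated' method.  ``_pca_cache`` lets callers reuse the
    per-subject PCA/mean columns across channels.
    """
    n = None if sc_hemo is None else sc_hemo.values.shape[-1]
    if config.method == "none":
        return NuisanceSet([], np.empty((0, 0)))
    if sc_hemo is None:
        raise DesignError(f"pipeline {config.id} requires short-channel data")
    sc_ids = scope_sc_ids(montage, config.sc_scope)
    missing = [i for i in sc_ids if f"S{i}" not in sc_hemo.channel_names]
    if missing:
        raise DesignError(f"scope {config.sc_scope!r} needs SC ids {missing} not present in data")

    if config.method == "nearest":
        sc = nearest_sc(target_channel, config.sc_scope, montage)
        col = sc_hemo.trace(f"S{sc.id}", target_chromophore)
        return NuisanceSet([f"SC{sc.id}-{target_chromophore}"], col[:, None])

    if config.method == "correlated":
        if lc_trace is None:
            raise DesignError("the 'correlated' method needs the target channel trace")
        best_id, best_r = sc_ids[0], -np.inf
        for sc_id in sc_ids:  # ties broken by lowest SC id (strict >)
            trace = sc_hemo.trace(f"S{sc_id}", target_chromophore)
            r = np.corrcoef(lc_trace, trace)[0, 1]
            if np.isfinite(r) and r > best_r:
                best_id, best_r = sc_id, r
        col = sc_hemo.trace(f"S{best_id}", target_chromophore)
        return NuisanceSet([f"SC{best_id}-{target_chromophore}"], col[:, None])

    cache_key = (config.sc_scope, config.method)
    if _pca_cache is not None and cache_key in _pca_cache:
        return _pca_cache[cache_key]

    if config.method == "mean":
        cols, names = [], []
        for chromo in CHROMOPHORES:
            stack = np.vstack([sc_hemo.trace(f"S{i}", chromo) for i in sc_ids])
            cols.append(stack.mean(axis=0))
            names.append(f"mean-{chromo}")
        out = NuisanceSet(names, np.column_stack(cols))
    elif config.method == "pooled_raw":
        X, names = _sc_matrix(sc_hemo, sc_ids)
        out = NuisanceSet(names, X)
    elif config.method == "pooled_pca":
        scores, names = sc_pca_components(sc_hemo, sc_ids)
        out = NuisanceSet(names, scores)
    else:  # pragma: no cover
        raise DesignError(f"unhandled method {config.method!r}")

    if _pca_cache is not None:
        _pca_cache[cache_key] = out
    return out


# ---------------------------------------------------------------------------
# OLS
# ---------------------------------------------------------------------------

@dataclass
class GlmFit:
    beta: dict  # regressor name -> estimate
    residual_variance: float
    dof: int
    condition_betas: dict  # condition -> beta

    @property
    def names(self) -> list[str]:
        return list(self.beta)


def fit_ols(y: np.ndarray, task: TaskDesign, nuisance: NuisanceSet) -> GlmFit:
    """OLS via SVD least squares; minimum-norm solution if rank deficient."""
    y = np.asarray(y, dtype=float)
    Xt = task.matrix()
    blocks = [Xt] if nuisance.count == 0 else [Xt, nuisance.columns]
    X = np.column_stack(blocks)
    names = task.names + nuisance.names
    n, p = X.shape
    if not (np.all(np.isfinite(X)) and np.all(np.isfinite(y))):
        raise DegenerateFitError("design or data contain non-finite values")
    if n <= p:
        raise DesignError(f"need more samples ({n}) than regressors ({p})")
    nontrivial = np.ptp(X, axis=0) > 0
    if np.max(np.abs(y)) == 0 and not np.any(nontrivial):
        raise DegenerateFitError("all-zero data with zero-variance design")
    beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < p:
        warnings.warn(f"rank-deficient design (rank {rank} < {p}); minimum-norm solution used")
    resid = y - X @ beta
    dof = n - p
    fit = GlmFit(
        beta=dict(zip(names, beta)),
        residual_variance=float(resid @ resid) / dof,
        dof=dof,
        condition_betas={c: float(b) for c, b in zip(CONDITIONS, beta[: len(CONDITIONS)])},
    )
    return fit


def run_pipeline(
    cohort_hemo: list[HemoSeries],
    config: PipelineConfig,
    montage: Montage,
    schedules: list,
    hrf_params: HrfParams = HrfParams(),
    design_band: tuple[float, float] | None = (0.01, 0.12),
) -> pd.DataFrame:
    """Fit one SC strategy for every subject x long channel x chromophore.

    Returns a tidy beta table with columns (subject, channel, roi, condition,
    chromophore, beta, pipeline_id).
    """
    if not cohort_hemo:
        raise DesignError("empty cohort")
    if len(schedules) != len(cohort_hemo):
        raise DesignError("one schedule per subject required")
    rows = []
    for subj, (hemo, schedule) in enumerate(zip(cohort_hemo, schedules), start=1):
        n_samples = hemo.values.shape[-1]
        task = build_task_design(schedule, hemo.fs, n_samples, hrf_params, design_band)
        has_sc = any(name.startswith("S") for name in hemo.channel_names)
        sc_hemo = hemo if has_sc else None
        pca_cache: dict = {}
        for ch in montage.analyzed_channels:
            for chromo in CHROMOPHORES:
                y = hemo.trace(f"L{ch.id}", chromo)
                nuis = build_nuisance(config, sc_hemo, ch, chromo, y, montage, pca_cache)
                fit = fit_ols(y, task, nuis)
                for cond, b in fit.condition_betas.items():
                    rows.append((subj, ch.id, ch.roi, cond, chromo, b, config.id))
    return pd.DataFrame(
        rows, columns=["subject", "channel", "roi", "condition", "chromophore", "beta", "pipeline_id"]
    )
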