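"""Directional JZS Bayes-factor t-tests and the two validation metrics.

Bayes factors use the Jeffreys-Zellner-Siow default: a Cauchy prior with scale
r = sqrt(2)/2 on the standardized effect size, the point null at zero, and
one-sided tests obtained by truncating the prior to the stated direction.  The
marginal likelihood is integrated numerically (substituting δ = r·tan θ turns
the Cauchy-weighted integral into a bounded one), so the one-sided pair always
averages exactly to the two-sided factor.

Metric 1 ("emergence") flags a channel when the directional BF10 against zero
exceeds 3 for a modality-appropriate condition (A or AV in temporal channels,
V or AV in occipital ones; positive effects for HbO, negative for HbR).
Metric 2 ("contrasts") is evaluated only within emergent channels and flags
directional between-condition differences (A>V or AV>V temporal, V>A or AV>A
occipital for HbO; reversed signs for HbR) via two-sample tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import stats

from .montage import Montage, roi_channels, ROIS

DEFAULT_RSCALE = math.sqrt(2.0) / 2.0
EVIDENCE_THRESHOLD = 3.0


class BayesError(ValueError):
    pass


@dataclass(frozen=True)
class BfResult:
    t: float
    n: tuple[int, ...]  # (n,) one-sample, (n1, n2) two-sample
    direction: str | None
    bf10: float


# ---------------------------------------------------------------------------
# JZS Bayes factors
# ---------------------------------------------------------------------------

def _jzs_bf(t: float, df: int, n_eff: float, direction: str | None,
            rscale: float = DEFAULT_RSCALE) -> float:
    """BF10 for a t-statistic with ``df`` degrees of freedom.

    Marginal likelihood under H1: ∫ f_nct(t; df, δ√n_eff) π(δ) dδ with
    π = Cauchy(0, rscale), truncated to δ>0 ('positive') or δ<0 ('negative').
    """
    if not np.isfinite(t):
        raise BayesError("t statistic is not finite")

    def integrand(theta: float) -> float:
        delta = rscale * math.tan(theta)
        return stats.nct.pdf(t, df, delta * math.sqrt(n_eff))

    half = math.pi / 2
    if direction is None:
        marg, _ = integrate.quad(integrand, -half, half, epsabs=0, epsrel=1e-6, limit=200)
        marg /= math.pi
    elif direction == "positive":
        marg, _ = integrate.quad(integrand, 0.0, half, epsabs=0, epsrel=1e-6, limit=200)
        marg *= 2.0 / math.pi
    elif direction == "negative":
        marg, _ = integrate.quad(integrand, -half, 0.0, epsabs=0, epsrel=1e-6, limit=200)
        marg *= 2.0 / math.pi
    else:
        raise BayesError(f"unknown direction {direction!r}")
    null = stats.t.pdf(t, df)
    return float(marg / null)


def bf_one_sample(x, direction: str | None, rscale: float = DEFAULT_RSCALE) -> BfResult:
    """Directional one-sample JZS Bayes factor against a zero mean."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 3:
        raise BayesError("need at least 3 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise BayesError("degenerate sample: zero variance")
    t = x.mean() / (sd / math.sqrt(n))
    return BfResult(float(t), (n,), direction, _jzs_bf(t, n - 1, n, direction, rscale))


def bf_two_sample(x, y, direction: str | None, rscale: float = DEFAULT_RSCALE) -> BfResult:
    """Directional independent-samples JZS Bayes factor (equal variances).

    ``direction='positive'`` favours mean(x) > mean(y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 3 or n2 < 3:
        raise BayesError("need at least 3 observations per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / df
    if sp2 == 0:
        raise BayesError("degenerate samples: zero pooled variance")
    n_eff = n1 * n2 / (n1 + n2)
    t = (x.mean() - y.mean()) / math.sqrt(sp2 / n_eff)
    return BfResult(float(t), (n1, n2), direction, _jzs_bf(t, df, n_eff, direction, rscale))


def evidence_category(bf10: float) -> str:
    """Conventional evidence label for a BF10 value.

    H1 side: weak (1, 3], positive (3, 10], strong (10, 100], decisive > 100;
    null side mirrors at 1/3, 1/100 (sic: 0.33, 0.01, 0.001 per convention).
    """
    if bf10 <= 0 or not np.isfinite(bf10):
        raise BayesError("BF10 must be positive and finite")
    if bf10 > 100:
        return "decisive"
    if bf10 > 10:
        return "strong"
    if bf10 > 3:
        return "positive"
    if bf10 > 1:
        return "weak"
    if bf10 >= 0.33:
        return "weak_null"
    if bf10 >= 0.01:
        return "positive_null"
    if bf10 >= 0.001:
        return "strong_null"
    return "decisive_null"


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

#: conditions tested against zero, per ROI kind
EMERGENCE_CONDITIONS = {
    "left_temporal": ("A", "AV"),
    "right_temporal": ("A", "AV"),
    "occipital": ("V", "AV"),
}

#: (numerator, reference) condition pairs for metric 2, per ROI kind
CONTRAST_PAIRS = {
    "left_temporal": (("A", "V"), ("AV", "V")),
    "right_temporal": (("A", "V"), ("AV", "V")),
    "occipital": (("V", "A"), ("AV", "A")),
}


@dataclass
class ChannelVerdict:
    channel: int
    roi: str
    chromophore: str
    emergence: bool = False
    emergence_bfs: dict = field(default_factory=dict)  # condition -> bf10
    contrast: bool | None = None  # None when not evaluated
    contrast_bfs: dict = field(default_factory=dict)  # "X>Y" -> bf10


def _direction(chromophore: str) -> str:
    return "positive" if chromophore == "HbO" else "negative"


def metric1_emergence(betas: pd.DataFrame, montage: Montage, chromophore: str) -> list[ChannelVerdict]:
    """Emergence-of-activity test per channel (one-sample directional BFs)."""
    direction = _direction(chromophore)
    verdicts = []
    for roi in ROIS:
        for ch in roi_channels(montage, roi):
            v = ChannelVerdict(ch.id, roi, chromophore)
            for cond in EMERGENCE_CONDITIONS[roi]:
                sel = betas[
                    (betas.channel == ch.id)
                    & (betas.condition == cond)
                    & (betas.chromophore == chromophore)
                ].sort_values("subject")
                if len(sel) < 3:
                    raise BayesError("need at least 3 subjects")
                res = bf_one_sample(sel.beta.to_numpy(), direction)
                v.emergence_bfs[cond] = res.bf10
            v.emergence = any(bf > EVIDENCE_THRESHOLD for bf in v.emergence_bfs.values())
            verdicts.append(v)
    return verdicts


def metric2_contrasts(betas: pd.DataFrame, verdicts: list[ChannelVerdict], chromophore: str) -> list[ChannelVerdict]:
    """Between-condition tests, evaluated only within emergent channels."""
    direction = _direction(chromophore)
    for v in verdicts:
        if v.chromophore != chromophore:
            continue
        if not v.emergence:
            v.contrast = None  # not evaluated, by design
            continue
        for num, ref in CONTRAST_PAIRS[v.roi]:
            x = betas[
                (betas.channel == v.channel) & (betas.condition == num) & (betas.chromophore == chromophore)
            ].sort_values("subject").beta.to_numpy()
            y = betas[
                (betas.channel == v.channel) & (betas.condition == ref) & (betas.chromophore == chromophore)
            ].sort_values("subject").beta.to_numpy()
            res = bf_two_sample(x, y, direction)
            v.contrast_bfs[f"{num}>{ref}"] = res.bf10
        v.contrast = any(bf > EVIDENCE_THRESHOLD for bf in v.contrast_bfs.values())
    return verdicts


def evaluate_pipeline(betas: pd.DataFrame, montage: Montage) -> list[ChannelVerdict]:
    """Both metrics for both chromophores on one pipeline's beta table."""
    out = []
    for chromo in ("HbO", "HbR"):
        verdicts = metric1_emergence(betas, montage, chromo)
        out.extend(metric2_contrasts(betas, verdicts, chromo))
    return out


def summarize(verdicts_by_pipeline: dict[int, list[ChannelVerdict]]) -> pd.DataFrame:
    """Per-pipeline channel counts for both metrics (machine twin of the
    summary-figure layout): columns (pipeline_id, roi, chromophore, metric, count)."""
    rows = []
    for pid, verdicts in sorted(verdicts_by_pipeline.items()):
        for chromo in ("HbO", "HbR"):
            for roi in ROIS:
                vs = [v for v in verdicts if v.roi == roi and v.chromophore == chromo]
                m1 = sum(v.emergence for v in vs)
                m2 = sum(bool(v.contrast) for v in vs if v.contrast is not None)
                rows.append((pid, roi, chromo, 1, m1))
                rows.append((pid, roi, chromo, 2, m2))
    df = pd.DataFrame(rows, columns=["pipeline_id", "roi", "chromophore", "metric", "count"])
    return df


def metric_total(summary: pd.DataFrame, pipeline_id: int, chromophore: str, metric: int) -> int:
    sel = summary[
        (summary.pipeline_id == pipeline_id)
        & (summary.chromophore == chromophore)
        & (summary.metric == metric)
    ]
    return int(sel["count"].sum())


def verdicts_to_frame(verdicts_by_pipeline: dict[int, list[ChannelVerdict]]) -> pd.DataFrame:
    """Tidy per-channel verdict table with BF values, for export."""
    rows = []
    for pid, verdicts in sorted(verdicts_by_pipeline.items()):
        for v in verdicts:
            for cond, bf in v.emergence_bfs.items():
                rows.append((pid, v.channel, v.roi, v.chromophore, "emergence", f"{cond}>0", bf,
                             bf > EVIDENCE_THRESHOLD))
            for pair, bf in v.contrast_bfs.items():
                rows.append((pid, v.channel, v.roi, v.chromophore, "contrast", pair, bf,
                             bf > EVIDENCE_THRESHOLD))
    return pd.DataFrame(
        rows, columns=["pipeline_id", "channel", "roi", "chromophore", "metric", "test", "bf10", "flag"]
    )
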