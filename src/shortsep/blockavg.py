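"""Event-locked block averages of preprocessed hemoglobin signals.

Epochs span -5 to 25 s around stimulus onset and are mean-centered on the
-5 to 0 s baseline.  Averaging proceeds epochs -> channels within ROI ->
subjects, with standard errors computed across subjects.  Optionally each long
channel is residualized on a pipeline's short-channel nuisance set (plus an
intercept) before epoching, mirroring SC correction prior to averaging.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import ROIS
from .glm import CONDITIONS, PipelineConfig, build_nuisance
from .montage import Montage, roi_channels
from .preprocess import CHROMOPHORES, HemoSeries

logger = logging.getLogger(__name__)


@dataclass
class EpochAverage:
    times: np.ndarray  # seconds relative to onset
    mean: dict  # (condition, roi, chromophore) -> curve
    sem: dict  # same keys; zeros for a single subject
    n_subjects: int
    n_dropped: int = 0

    def frame(self) -> pd.DataFrame:
        rows = []
        for (cond, roi, chromo), curve in self.mean.items():
            sem = self.sem[(cond, roi, chromo)]
            for t, m, s in zip(self.times, curve, sem):
                rows.append((cond, roi, chromo, t, m, s))
        return pd.DataFrame(rows, columns=["condition", "roi", "chromophore", "time", "mean", "sem"])


def _window_offsets(fs: float, window: tuple[float, float]) -> np.ndarray:
    start = int(np.floor(window[0] * fs))
    count = int(np.floor((window[1] - window[0]) * fs)) + 1
    return np.arange(start, start + count)


def _subject_roi_curves(
    hemo: HemoSeries,
    schedule,
    montage: Montage,
    window: tuple[float, float],
    baseline: tuple[float, float],
) -> tuple[dict, int]:
    """Per-subject mean curve per (condition, roi, chromophore)."""
    fs = hemo.fs
    offsets = _window_offsets(fs, window)
    n = hemo.values.shape[-1]
    base_mask = (offsets / fs >= baseline[0]) & (offsets / fs <= baseline[1])
    curves: dict = {}
    dropped = 0
    for cond in CONDITIONS:
        onset_idx = [
            int(np.round(o * fs))
            for o, c in zip(schedule.onsets, schedule.conditions)
            if c == cond
        ]
        valid = [i for i in onset_idx if i + offsets[0] >= 0 and i + offsets[-1] < n]
        dropped += len(onset_idx) - len(valid)
        for roi in ROIS:
            ch_idx = [hemo.channel_names.index(f"L{ch.id}") for ch in roi_channels(montage, roi)]
            for j, chromo in enumerate(CHROMOPHORES):
                epochs = []
                for i0 in valid:
                    seg = hemo.values[ch_idx, j][:, i0 + offsets]
                    seg = seg - seg[:, base_mask].mean(axis=1, keepdims=True)
                    epochs.append(seg)
                # epochs -> channels within ROI
                curves[(cond, roi, chromo)] = np.mean(epochs, axis=(0, 1))
    if dropped:
        logger.info("dropped %d epochs exceeding recording bounds", dropped)
    return curves, dropped


def epoch_and_average(
    hemo: HemoSeries | list[HemoSeries],
    schedule,
    montage: Montage,
    window: tuple[float, float] = (-5.0, 25.0),
    baseline: tuple[float, float] = (-5.0, 0.0),
) -> EpochAverage:
    """Baseline-corrected event-locked averages; accepts one subject or a cohort."""
    hemos = hemo if isinstance(hemo, list) else [hemo]
    schedules = schedule if isinstance(schedule, list) else [schedule]
    if len(hemos) != len(schedules):
        raise ValueError("one schedule per subject required")
    fs = hemos[0].fs
    times = _window_offsets(fs, window) / fs
    per_subject = []
    dropped = 0
    for h, s in zip(hemos, schedules):
        curves, d = _subject_roi_curves(h, s, montage, window, baseline)
        per_subject.append(curves)
        dropped += d
    mean, sem = {}, {}
    for key in per_subject[0]:
        stack = np.vstack([c[key] for c in per_subject])
        mean[key] = stack.mean(axis=0)
        sem[key] = stack.std(axis=0, ddof=1) / np.sqrt(len(stack)) if len(stack) > 1 else np.zeros(stack.shape[1])
    return EpochAverage(times, mean, sem, len(hemos), dropped)


def plot_epoch_average(avg: EpochAverage, rois=ROIS, ax_grid=None):
    """Render ROI x condition average curves (HbO solid, HbR dashed).

    Requires matplotlib (optional dependency); returns the figure.
    """
    import matplotlib.pyplot as plt

    colors = {"A": "tab:orange", "V": "tab:blue", "AV": "tab:purple"}
    fig, axes = plt.subplots(1, len(rois), figsize=(4 * len(rois), 3), sharey=True,
                             squeeze=False)
    for ax, roi in zip(axes[0], rois):
        for cond in CONDITIONS:
            for chromo, style in (("HbO", "-"), ("HbR", "--")):
                m = avg.mean[(cond, roi, chromo)]
                s = avg.sem[(cond, roi, chromo)]
                ax.plot(avg.times, m, style, color=colors[cond],
                        label=f"{cond} {chromo}" if chromo == "HbO" else None)
                ax.fill_between(avg.times, m - s, m + s, color=colors[cond], alpha=0.15)
        ax.axvline(0.0, color="k", lw=0.5)
        ax.set_title(roi.replace("_", " "))
        ax.set_xlabel("time from onset (s)")
    axes[0][0].set_ylabel("ΔHb (µM)")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    return fig


def residualize_on_nuisance(hemo: HemoSeries, config: PipelineConfig, montage: Montage) -> HemoSeries:
    """Project each long channel on (intercept + nuisance set), keep residuals.

    Short channels are passed through unchanged.  With no nuisance regressors
    only the mean is removed, which the epoch baseline correction would remove
    anyway, so the 'none' pipeline reproduces the plain average.
    """
    out = hemo.copy()
    has_sc = any(name.startswith("S") for name in hemo.channel_names)
    sc_hemo = hemo if has_sc else None
    cache: dict = {}
    for ch in montage.analyzed_channels:
        for j, chromo in enumerate(CHROMOPHORES):
            i = hemo.channel_names.index(f"L{ch.id}")
            y = hemo.values[i, j]
            nuis = build_nuisance(config, sc_hemo, ch, chromo, y, montage, cache)
            X = np.column_stack([np.ones_like(y)] + ([nuis.columns] if nuis.count else []))
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            out.values[i, j] = y - X @ beta
    return out


def corrected_block_average(
    hemo: HemoSeries | list[HemoSeries],
    config: PipelineConfig,
    montage: Montage,
    schedule,
    window: tuple[float, float] = (-5.0, 25.0),
    baseline: tuple[float, float] = (-5.0, 0.0),
) -> EpochAverage:
    """Short-channel correction (residualization) prior to block averaging."""
    hemos = hemo if isinstance(hemo, list) else [hemo]
    corrected = [residualize_on_nuisance(h, config, montage) for h in hemos]
    return epoch_and_average(corrected if isinstance(hemo, list) else corrected[0],
                             schedule, montage, window, baseline)
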