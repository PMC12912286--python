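"""End-to-end orchestration: simulate -> preprocess -> fit all pipelines -> score.

Preprocessing is computed once per subject and shared by every pipeline; only
the nuisance construction and the GLM differ between pipelines.
"""

from __future__ import annotations

import logging
import time as _time
from dataclasses import dataclass

import pandas as pd

from . import bayes
from .glm import PIPELINES, HrfParams, run_pipeline
from .montage import Montage, build_standard_montage
from .preprocess import HemoSeries, preprocess_session
from .simulate import Cohort, GroundTruth, NoiseSpec, SessionSpec, default_ground_truth, make_cohort

logger = logging.getLogger(__name__)


@dataclass
class ComparisonResult:
    summary: pd.DataFrame  # pipeline_id, roi, chromophore, metric, count
    beta_tables: dict  # pipeline id -> tidy beta DataFrame
    verdicts: dict  # pipeline id -> list[ChannelVerdict]
    subject_truth: pd.DataFrame
    montage: Montage = None

    def verdict_frame(self) -> pd.DataFrame:
        return bayes.verdicts_to_frame(self.verdicts)

    def betas_frame(self) -> pd.DataFrame:
        return pd.concat(self.beta_tables.values(), ignore_index=True)


def select_pipelines(selection) -> list[int]:
    """Normalize a pipeline selection ('all', id list, or comma string)."""
    if selection in (None, "all"):
        return sorted(PIPELINES)
    if isinstance(selection, str):
        ids = [int(s) for s in selection.split(",") if s.strip()]
    else:
        ids = [int(s) for s in selection]
    unknown = [i for i in ids if i not in PIPELINES]
    if unknown:
        raise ValueError(f"unknown pipeline id(s) {unknown}; valid ids are 1-10")
    return ids


def preprocess_cohort(cohort: Cohort) -> list[HemoSeries]:
    t0 = _time.perf_counter()
    hemos = [preprocess_session(raw) for raw in cohort.sessions]
    logger.info(
        "preprocessing computed once for %d subjects (%.1f s); reused by all pipelines",
        len(hemos), _time.perf_counter() - t0,
    )
    return hemos


def run_comparison(
    spec: SessionSpec | None = None,
    truth: GroundTruth | None = None,
    noise: NoiseSpec | None = None,
    montage: Montage | None = None,
    seed: int = 0,
    pipelines="all",
    hrf_params: HrfParams = HrfParams(),
    cohort: Cohort | None = None,
    hemos: list[HemoSeries] | None = None,
) -> ComparisonResult:
    """Run the selected SC-regression pipelines on one simulated cohort.

    A pre-built ``cohort`` (and optionally its preprocessed ``hemos``) may be
    supplied to reuse data across calls; otherwise a cohort is simulated from
    ``spec``/``truth``/``noise`` with ``seed``.
    """
    montage = montage or build_standard_montage()
    spec = spec or SessionSpec()
    truth = truth if truth is not None else default_ground_truth(montage)
    noise = noise if noise is not None else NoiseSpec()
    ids = select_pipelines(pipelines)

    if cohort is None:
        t0 = _time.perf_counter()
        cohort = make_cohort(spec, truth, noise, seed, montage)
        logger.info("simulated %d subjects (%.1f s)", spec.n_subjects, _time.perf_counter() - t0)
    if hemos is None:
        hemos = preprocess_cohort(cohort)

    beta_tables, verdicts = {}, {}
    for pid in ids:
        t0 = _time.perf_counter()
        config = PIPELINES[pid]
        betas = run_pipeline(hemos, config, montage, cohort.schedules, hrf_params)
        beta_tables[pid] = betas
        if spec.n_subjects >= 3:
            verdicts[pid] = bayes.evaluate_pipeline(betas, montage)
        logger.info("pipeline %d (%s): %.1f s", pid, config.label, _time.perf_counter() - t0)
    if spec.n_subjects < 3:
        logger.warning("fewer than 3 subjects: group-level Bayes metrics disabled")
        summary = pd.DataFrame(columns=["pipeline_id", "roi", "chromophore", "metric", "count"])
    else:
        summary = bayes.summarize(verdicts)
    return ComparisonResult(summary, beta_tables, verdicts, cohort.subject_betas, montage)
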