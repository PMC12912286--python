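"""Synthetic two-wavelength fNIRS sessions with known ground truth.

The forward model composes, per channel and in µM hemoglobin units:

* neural responses: HRF-convolved stimulus boxcars scaled by the true
  condition amplitudes, confined to modality-appropriate ROIs (visual ->
  occipital, auditory -> temporal, audiovisual -> both), with ΔHbR a negative
  fraction of ΔHbO; long channels only;
* globally shared systemic physiology: a stochastic narrow-band Mayer wave
  (~0.1 Hz), cardiac (~1.2 Hz) and respiratory (~0.25 Hz) oscillations, and a
  slow drift, each loading on every channel (short channels fully, long
  channels scaled by ``superficial_share``) with per-channel loading spread;
* channel-local systemic noise, white sensor noise, and sparse motion
  artifacts (spikes and occasional step changes, shared event times).

Hemoglobin is mapped to optical density with the same MBLL constants the
preprocessing chain inverts, and to intensity via I = I0 * exp(-ΔOD), so a
noise-free session is exactly recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .glm import CONDITIONS, HrfParams, canonical_hrf, condition_regressor
from .montage import Montage, build_standard_montage
from .preprocess import MbllConstants, conc_to_od


class SimulationError(ValueError):
    pass


@dataclass(frozen=True)
class SessionSpec:
    """Block-design session parameters (defaults are the reference conditions)."""

    fs: float = 7.81
    n_trials_per_condition: int = 15
    stim_duration: float = 10.0
    isi_range: tuple[float, float] = (8.0, 12.0)
    baseline_duration: float = 60.0
    tail_duration: float = 30.0
    n_subjects: int = 16

    def __post_init__(self):
        if self.fs <= 0:
            raise SimulationError("fs must be positive")
        if self.isi_range[0] > self.isi_range[1]:
            raise SimulationError("isi_range must be ordered")
        if min(self.stim_duration, self.baseline_duration, self.tail_duration) <= 0:
            raise SimulationError("durations must be positive")


@dataclass(frozen=True)
class NoiseSpec:
    """Amplitudes (µM ΔHbO-equivalent) and rates of the nuisance processes."""

    mayer_freq: float = 0.095
    mayer_amp: float = 30.0
    mayer_bandwidth: float = 0.035
    cardiac_freq: float = 1.2
    cardiac_amp: float = 2.0
    resp_freq: float = 0.25
    resp_amp: float = 1.5
    drift_amp: float = 1200.0
    white_sd: float = 0.4
    systemic_local_sd: float = 0.3
    loading_spread: float = 0.3
    superficial_share: float = 0.7
    hbr_systemic_ratio: float = 0.05
    motion_rate_per_min: float = 0.5
    motion_spike_amp: float = 5.0
    motion_step_prob: float = 0.25

    def __post_init__(self):
        amps = (self.mayer_amp, self.cardiac_amp, self.resp_amp, self.drift_amp,
                self.white_sd, self.systemic_local_sd)
        if any(a < 0 for a in amps):
            raise SimulationError("amplitudes must be non-negative")
        if not 0 <= self.superficial_share <= 1:
            raise SimulationError("superficial_share must lie in [0, 1]")


ZERO_NOISE = NoiseSpec(
    mayer_amp=0.0, cardiac_amp=0.0, resp_amp=0.0, drift_amp=0.0,
    white_sd=0.0, systemic_local_sd=0.0, loading_spread=0.0,
    superficial_share=0.0, motion_rate_per_min=0.0,
)


@dataclass
class EventSchedule:
    onsets: np.ndarray
    durations: np.ndarray
    conditions: list[str]

    @property
    def n_events(self) -> int:
        return len(self.conditions)

    @property
    def end_time(self) -> float:
        return float(self.onsets[-1] + self.durations[-1])


@dataclass
class GroundTruth:
    """True condition amplitudes per (channel, condition, chromophore), µM."""

    beta: pd.DataFrame  # columns: channel, condition, chromophore, beta
    hbr_ratio: float = -1.0 / 3.0
    between_subject_sd: float = 0.1

    def lookup(self, channel: int, condition: str, chromophore: str) -> float:
        df = self.beta
        sel = df[
            (df.channel == channel) & (df.condition == condition) & (df.chromophore == chromophore)
        ]
        return float(sel.beta.iloc[0]) if len(sel) else 0.0


def default_ground_truth(
    montage: Montage | None = None,
    hbo_amp: float = 0.5,
    hbr_ratio: float = -1.0 / 3.0,
    between_subject_sd: float = 0.1,
) -> GroundTruth:
    """Modality-appropriate truth: V/AV in occipital, A/AV in temporal channels."""
    montage = montage or build_standard_montage()
    rows = []
    for ch in montage.analyzed_channels:
        active = {"occipital": ("V", "AV")}.get(ch.roi, ("A", "AV"))
        for cond in CONDITIONS:
            hbo = hbo_amp if cond in active else 0.0
            rows.append((ch.id, cond, "HbO", hbo))
            rows.append((ch.id, cond, "HbR", hbr_ratio * hbo))
    beta = pd.DataFrame(rows, columns=["channel", "condition", "chromophore", "beta"])
    return GroundTruth(beta, hbr_ratio, between_subject_sd)


@dataclass
class RawSession:
    time: np.ndarray
    intensity: np.ndarray  # (n_channels, 2 wavelengths, n_samples), positive
    channel_names: list[str]  # 'L1'..'L16' then 'S1'..'S8'
    fs: float
    montage: Montage
    schedule: EventSchedule
    wavelengths_nm: tuple[float, float] = (760.0, 850.0)
    subject: int = 1

    def distance_cm(self, channel_name: str) -> float:
        kind, idx = channel_name[0], int(channel_name[1:])
        if kind == "L":
            return self.montage.channel(idx).distance_cm
        return self.montage.short_channel(idx).distance_cm


# ---------------------------------------------------------------------------
# Schedule
# ---------------------------------------------------------------------------

def generate_schedule(spec: SessionSpec, seed: int) -> EventSchedule:
    """Triplet-constrained pseudorandom A/V/AV schedule with jittered ISIs.

    Each consecutive triplet of trials contains all three conditions in a
    random order; ISIs are uniform on ``isi_range``; the first onset falls at
    the end of the initial baseline.
    """
    rng = np.random.default_rng(seed)
    conds: list[str] = []
    for _ in range(spec.n_trials_per_condition):
        conds.extend(rng.permutation(CONDITIONS))
    n = len(conds)
    onsets = np.empty(n)
    t = spec.baseline_duration
    for i in range(n):
        onsets[i] = t
        t += spec.stim_duration + rng.uniform(*spec.isi_range)
    durations = np.full(n, spec.stim_duration)
    return EventSchedule(onsets, durations, conds)


def session_n_samples(spec: SessionSpec, schedule: EventSchedule) -> int:
    return int(np.round((schedule.end_time + spec.tail_duration) * spec.fs))


# ---------------------------------------------------------------------------
# Systemic physiology
# ---------------------------------------------------------------------------

def _narrowband(rng: np.random.Generator, n: int, fs: float, freq: float, bandwidth: float) -> np.ndarray:
    """Unit-SD stochastic oscillation: drifting phase and slow AM around ``freq``."""
    phase_noise = np.cumsum(rng.normal(0.0, np.sqrt(2 * np.pi * bandwidth / fs), n))
    t = np.arange(n) / fs
    am = 1.0 + 0.3 * _slow_noise(rng, n, fs, cutoff=bandwidth)
    x = am * np.sin(2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi) + phase_noise)
    sd = x.std()
    return x / sd if sd > 0 else x


def _slow_noise(rng: np.random.Generator, n: int, fs: float, cutoff: float = 0.02) -> np.ndarray:
    """Unit-SD low-frequency (1/f-like) noise via low-passed white noise."""
    from scipy import signal as sps

    white = rng.normal(size=n + max(256, int(4 * fs / cutoff)))
    sos = sps.butter(2, cutoff, btype="low", fs=fs, output="sos")
    x = sps.sosfilt(sos, white)[-n:]
    sd = x.std()
    return x / sd if sd > 0 else x


@dataclass
class SystemicSet:
    components: dict  # name -> (n,) global time course, already amplitude-scaled
    loadings: np.ndarray  # (n_channels, n_components)
    hbo: np.ndarray  # (n_channels, n) per-channel systemic HbO, µM
    hbr: np.ndarray


def simulate_systemics(
    spec: SessionSpec,
    noise: NoiseSpec,
    n_samples: int,
    seed: int,
    n_channels: int | None = None,
) -> SystemicSet:
    """Global systemic components with per-channel loadings plus local noise.

    Every channel's systemic HbO trace is a loading-weighted sum of the shared
    Mayer/cardiac/respiratory/drift components plus channel-local slow noise;
    the HbR trace is the HbO trace scaled by ``hbr_systemic_ratio`` (systemic
    fluctuations hit HbO hardest).
    """
    if n_samples <= 0:
        raise SimulationError("n_samples must be positive")
    montage = build_standard_montage()
    if n_channels is None:
        n_channels = len(montage.channels) + len(montage.short_channels)
    rng = np.random.default_rng(seed)
    comps = {
        "mayer": noise.mayer_amp * _narrowband(rng, n_samples, spec.fs, noise.mayer_freq, noise.mayer_bandwidth),
        "cardiac": noise.cardiac_amp * _narrowband(rng, n_samples, spec.fs, noise.cardiac_freq, 0.05),
        "respiratory": noise.resp_amp * _narrowband(rng, n_samples, spec.fs, noise.resp_freq, 0.03),
        "drift": noise.drift_amp * _slow_noise(rng, n_samples, spec.fs),
    }
    names = list(comps)
    loadings = 1.0 + noise.loading_spread * rng.normal(size=(n_channels, len(names)))
    loadings = np.clip(loadings, 0.0, None)
    G = np.vstack([comps[k] for k in names])  # (k, n)
    shared = loadings @ G
    hbo = shared.copy()
    hbr = noise.hbr_systemic_ratio * shared
    if noise.systemic_local_sd > 0:
        # channel-local slow noise, independent between chromophores
        for arr, sd in ((hbo, noise.systemic_local_sd),
                        (hbr, noise.systemic_local_sd * abs(noise.hbr_systemic_ratio))):
            arr += np.vstack(
                [sd * _slow_noise(rng, n_samples, spec.fs, cutoff=0.08)
                 for _ in range(n_channels)]
            )
    return SystemicSet(comps, loadings, hbo, hbr)


def _motion_artifacts(rng, n_channels, n_samples, fs, noise: NoiseSpec) -> np.ndarray:
    """Sparse shared-time spikes (1-3 samples) and occasional step changes."""
    art = np.zeros((n_channels, n_samples))
    duration_min = n_samples / fs / 60.0
    n_events = rng.poisson(noise.motion_rate_per_min * duration_min)
    for _ in range(n_events):
        idx = rng.integers(int(fs), n_samples - int(fs))
        amps = noise.motion_spike_amp * rng.normal(size=n_channels)
        if rng.uniform() < noise.motion_step_prob:
            art[:, idx:] += 0.4 * amps[:, None]
        else:
            width = rng.integers(1, 4)
            art[:, idx : idx + width] += amps[:, None]
    return art


# ---------------------------------------------------------------------------
# Forward model
# ---------------------------------------------------------------------------

def simulate_session(
    spec: SessionSpec,
    truth: GroundTruth,
    noise: NoiseSpec,
    montage: Montage | None = None,
    seed: int = 0,
    constants: MbllConstants | None = None,
    hrf_params: HrfParams = HrfParams(),
    schedule: EventSchedule | None = None,
) -> tuple[RawSession, EventSchedule]:
    """Generate one subject's raw two-wavelength intensity recording."""
    montage = montage or build_standard_montage()
    constants = constants or MbllConstants(wavelengths_nm=montage.wavelengths_nm)
    rng = np.random.default_rng(seed)
    if schedule is None:
        schedule = generate_schedule(spec, int(rng.integers(2**31)))
    n = session_n_samples(spec, schedule)
    time = np.arange(n) / spec.fs

    channel_names = [f"L{ch.id}" for ch in montage.channels] + [
        f"S{sc.id}" for sc in montage.short_channels
    ]
    n_long = len(montage.channels)
    n_ch = len(channel_names)

    # neural signal, long channels only
    hrf = canonical_hrf(spec.fs, hrf_params)
    regressors = {}
    for cond in CONDITIONS:
        mask = np.asarray([c == cond for c in schedule.conditions], dtype=bool)
        regressors[cond] = condition_regressor(
            schedule.onsets[mask], schedule.durations[mask], spec.fs, n, hrf
        )
    hbo = np.zeros((n_ch, n))
    hbr = np.zeros((n_ch, n))
    for i, ch in enumerate(montage.channels):
        for cond in CONDITIONS:
            hbo[i] += truth.lookup(ch.id, cond, "HbO") * regressors[cond]
            hbr[i] += truth.lookup(ch.id, cond, "HbR") * regressors[cond]

    # shared systemic physiology: full amplitude on SCs, scaled share on LCs
    systemic = simulate_systemics(spec, noise, n, int(rng.integers(2**31)), n_channels=n_ch)
    share = np.concatenate([np.full(n_long, noise.superficial_share), np.ones(n_ch - n_long)])
    hbo += share[:, None] * systemic.hbo
    hbr += share[:, None] * systemic.hbr

    if noise.white_sd > 0:
        hbo += rng.normal(0.0, noise.white_sd, size=(n_ch, n))
        hbr += rng.normal(0.0, noise.white_sd * abs(noise.hbr_systemic_ratio), size=(n_ch, n))
    if noise.motion_rate_per_min > 0:
        art = _motion_artifacts(rng, n_ch, n, spec.fs, noise)
        hbo += art
        hbr += noise.hbr_systemic_ratio * art

    # hemoglobin -> ΔOD -> intensity
    intensity = np.empty((n_ch, 2, n))
    for i, name in enumerate(channel_names):
        kind, idx = name[0], int(name[1:])
        d_cm = montage.channel(idx).distance_cm if kind == "L" else montage.short_channel(idx).distance_cm
        od = conc_to_od(hbo[i], hbr[i], d_cm, constants)
        if np.max(np.abs(od)) > 50:
            raise SimulationError("unphysical forward model: |ΔOD| > 50")
        intensity[i] = np.exp(-od)  # I0 = 1 per channel/wavelength
    if not np.all(np.isfinite(intensity)) or np.any(intensity <= 0):
        raise SimulationError("forward model produced non-positive intensity")

    raw = RawSession(time, intensity, channel_names, spec.fs, montage, schedule,
                     montage.wavelengths_nm)
    return raw, schedule


@dataclass
class Cohort:
    sessions: list[RawSession]
    schedules: list[EventSchedule]
    truth: GroundTruth
    subject_betas: pd.DataFrame  # per-subject true betas (tidy)


def make_cohort(
    spec: SessionSpec,
    truth: GroundTruth,
    noise: NoiseSpec,
    seed: int,
    montage: Montage | None = None,
) -> Cohort:
    """Independent per-subject sessions with optional between-subject variability.

    Each subject's HbO amplitudes are perturbed by N(0, between_subject_sd),
    clipped at zero; HbR amplitudes follow via the HbR/HbO ratio.
    """
    if spec.n_subjects < 1:
        raise SimulationError("need at least one subject")
    montage = montage or build_standard_montage()
    master = np.random.default_rng(seed)
    sessions, schedules, truth_rows = [], [], []
    for subj in range(1, spec.n_subjects + 1):
        sub_rng = np.random.default_rng(master.integers(2**31))
        beta = truth.beta.copy()
        if truth.between_subject_sd > 0:
            hbo_mask = beta.chromophore == "HbO"
            jitter = {}
            for i in beta.index[hbo_mask]:
                key = (beta.at[i, "channel"], beta.at[i, "condition"])
                if key not in jitter:
                    jitter[key] = sub_rng.normal(0.0, truth.between_subject_sd)
                if beta.at[i, "beta"] != 0.0:
                    beta.at[i, "beta"] = max(0.0, beta.at[i, "beta"] + jitter[key])
            for i in beta.index[~hbo_mask]:
                sel = beta[
                    hbo_mask
                    & (beta.channel == beta.at[i, "channel"])
                    & (beta.condition == beta.at[i, "condition"])
                ]
                beta.at[i, "beta"] = truth.hbr_ratio * float(sel.beta.iloc[0])
        sub_truth = GroundTruth(beta, truth.hbr_ratio, truth.between_subject_sd)
        raw, schedule = simulate_session(
            spec, sub_truth, noise, montage, seed=int(sub_rng.integers(2**31))
        )
        raw.subject = subj
        sessions.append(raw)
        schedules.append(schedule)
        b = beta.copy()
        b.insert(0, "subject", subj)
        truth_rows.append(b)
    return Cohort(sessions, schedules, truth, pd.concat(truth_rows, ignore_index=True))
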