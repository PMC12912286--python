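"""Signal conditioning chain: intensity -> ΔOD -> TDDR -> band-pass -> ΔHb.

The chain mirrors standard continuous-wave fNIRS practice: raw intensities are
log-ratioed into optical-density changes, motion artifacts are repaired with
Temporal Derivative Distribution Repair (TDDR; robust reweighting of the
low-frequency temporal derivative), the series is band-pass filtered to
0.01-0.12 Hz (removing drift, respiratory ~0.25 Hz and cardiac ~1.2 Hz
activity while keeping the block-design response band), and the two-wavelength
ΔOD is inverted to ΔHbO/ΔHbR with the modified Beer-Lambert law (MBLL) using a
fixed pathlength factor of 0.1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .montage import Montage

CHROMOPHORES = ("HbO", "HbR")

#: Molar extinction coefficients [1/(cm * M)] at the two laser lines,
#: Gratzer-compiled values as shipped by the standard fNIRS toolboxes.
GRATZER_EXTINCTION = {
    (760.0, "HbO"): 586.0,
    (760.0, "HbR"): 1548.52,
    (850.0, "HbO"): 1058.0,
    (850.0, "HbR"): 691.32,
}


class PreprocessError(ValueError):
    pass


class ConfigurationError(ValueError):
    """Unsupported stage configuration (e.g. permuted chain order)."""


@dataclass
class OdSeries:
    """Optical-density changes, shape (n_channels, n_wavelengths, n_samples)."""

    values: np.ndarray
    fs: float
    channel_names: list[str]
    wavelengths_nm: tuple[float, float] = (760.0, 850.0)

    def copy(self) -> "OdSeries":
        return OdSeries(self.values.copy(), self.fs, list(self.channel_names), self.wavelengths_nm)


@dataclass
class HemoSeries:
    """Hemoglobin concentration changes in µM, shape (n_channels, 2, n_samples).

    Chromophore axis is ordered (HbO, HbR).
    """

    values: np.ndarray
    fs: float
    channel_names: list[str]
    chromophores: tuple[str, str] = CHROMOPHORES

    def trace(self, channel_name: str, chromophore: str) -> np.ndarray:
        i = self.channel_names.index(channel_name)
        j = self.chromophores.index(chromophore)
        return self.values[i, j]

    def copy(self) -> "HemoSeries":
        return HemoSeries(self.values.copy(), self.fs, list(self.channel_names), self.chromophores)


@dataclass
class MbllConstants:
    """Extinction table, pathlength factor and per-channel distances (cm)."""

    extinction: dict = field(default_factory=lambda: dict(GRATZER_EXTINCTION))
    ppf: float = 0.1
    wavelengths_nm: tuple[float, float] = (760.0, 850.0)

    def matrix(self) -> np.ndarray:
        """2x2 extinction matrix E with E[i, j] = ε(λ_i, chromophore_j)."""
        E = np.array(
            [
                [self.extinction[(lam, ch)] for ch in CHROMOPHORES]
                for lam in self.wavelengths_nm
            ]
        )
        if abs(np.linalg.det(E)) < 1e-12:
            raise PreprocessError("extinction matrix is singular")
        return E


def intensity_to_od(raw) -> OdSeries:
    """ΔOD(t) = -ln(I(t) / mean_t I), per channel and wavelength."""
    intensity = np.asarray(raw.intensity, dtype=float)
    if np.any(intensity <= 0) or not np.all(np.isfinite(intensity)):
        raise PreprocessError("intensity must be finite and strictly positive")
    ref = intensity.mean(axis=-1, keepdims=True)
    od = -np.log(intensity / ref)
    return OdSeries(od, raw.fs, list(raw.channel_names), tuple(raw.wavelengths_nm))


# ---------------------------------------------------------------------------
# TDDR
# ---------------------------------------------------------------------------

_TDDR_SPLIT_HZ = 0.5
_TDDR_TUKEY_C = 4.685
_TDDR_TOL = 1e-3
_TDDR_MAX_ITER = 50
# repair (outlier-replacement) point, in units of the Tukey cutoff c*sigma:
# smooth block-design transitions reach ~1.3 c*sigma on noise-free data while
# spike/step artifacts exceed 2.5 c*sigma, so 2 separates them with margin
_TDDR_REJECT = 2.0


def tddr_trace(x: np.ndarray, fs: float) -> np.ndarray:
    """Temporal Derivative Distribution Repair on a single 1-D series.

    The series is split at 0.5 Hz.  On the low-frequency part, a robust
    location/scale of the first difference is found by iteratively reweighted
    estimation with the Tukey biweight (c = 4.685, MAD-based scale) until the
    weights converge.  Derivative samples far beyond the Tukey rejection point
    (twice the cutoff c*sigma) — statistically improbable rates of change,
    i.e. motion spikes and step artifacts — are replaced by the robust mean
    derivative; all other samples are kept verbatim.  The repaired derivative is re-integrated and the
    untouched high-frequency part added back, so artifact-free signals pass
    through exactly unchanged (the weights reduce to identity and nothing is
    rejected).
    """
    x = np.asarray(x, dtype=float)
    if not np.all(np.isfinite(x)):
        raise PreprocessError("TDDR input must be finite")
    if x.size < 10:
        raise PreprocessError("TDDR needs at least 10 samples")
    if np.ptp(x) == 0:
        return x.copy()

    if fs / 2 > _TDDR_SPLIT_HZ:
        sos = sps.butter(3, _TDDR_SPLIT_HZ, btype="low", fs=fs, output="sos")
        low = sps.sosfiltfilt(sos, x, padlen=min(x.size - 1, int(10 * fs)))
    else:
        low = x.copy()
    high = x - low

    deriv = np.diff(low)
    w = np.ones_like(deriv)
    mu = 0.0
    r = np.zeros_like(deriv)
    for _ in range(_TDDR_MAX_ITER):
        mu = np.sum(w * deriv) / np.sum(w)
        dev = deriv - mu
        sigma = 1.4826 * np.median(np.abs(dev))
        if sigma == 0:  # derivative constant: nothing to repair
            r = np.zeros_like(deriv)
            w_new = np.ones_like(deriv)
        else:
            r = dev / (_TDDR_TUKEY_C * sigma)
            w_new = np.where(np.abs(r) < 1, (1 - r**2) ** 2, 0.0)
        change = np.linalg.norm(w_new - w) / max(np.linalg.norm(w), 1e-12)
        w = w_new
        if change < _TDDR_TOL:
            break

    repaired = np.where(np.abs(r) < _TDDR_REJECT, deriv, mu)
    corrected = np.concatenate(([0.0], np.cumsum(repaired)))
    corrected += low[0] - corrected[0]
    return corrected + high


def tddr(od: OdSeries, fs: float | None = None) -> OdSeries:
    """Apply TDDR to every channel/wavelength of an OD series."""
    fs = od.fs if fs is None else fs
    out = od.copy()
    flat = out.values.reshape(-1, out.values.shape[-1])
    for i in range(flat.shape[0]):
        flat[i] = tddr_trace(flat[i], fs)
    return out


# ---------------------------------------------------------------------------
# Band-pass
# ---------------------------------------------------------------------------

def _bandpass_sos(fs: float, low: float, high: float, order: int = 4):
    if not 0 < low < high < fs / 2:
        raise PreprocessError(
            f"band ({low}, {high}) Hz invalid for fs = {fs} Hz (Nyquist {fs / 2})"
        )
    return sps.butter(order, [low, high], btype="bandpass", fs=fs, output="sos")


def bandpass_array(x: np.ndarray, fs: float, low: float = 0.01, high: float = 0.12) -> np.ndarray:
    """Zero-phase 4th-order Butterworth band-pass (applied forward-backward)."""
    x = np.asarray(x, dtype=float)
    sos = _bandpass_sos(fs, low, high)
    n = x.shape[-1]
    # long reflect padding: the 0.01 Hz corner has a multi-minute transient
    padlen = min(n - 1, int(3 * fs / low))
    return sps.sosfiltfilt(sos, x, axis=-1, padtype="odd", padlen=padlen)


def bandpass(od: OdSeries, fs: float | None = None, low: float = 0.01, high: float = 0.12) -> OdSeries:
    fs = od.fs if fs is None else fs
    out = od.copy()
    out.values = bandpass_array(out.values, fs, low, high)
    return out


# ---------------------------------------------------------------------------
# MBLL
# ---------------------------------------------------------------------------

def conc_to_od(hbo: np.ndarray, hbr: np.ndarray, distance_cm: float, constants: MbllConstants) -> np.ndarray:
    """Forward MBLL: µM concentrations -> ΔOD at both wavelengths, shape (2, n)."""
    E = constants.matrix()
    conc_molar = np.vstack([hbo, hbr]) * 1e-6
    return (E @ conc_molar) * distance_cm * constants.ppf


def od_to_conc(od: OdSeries, constants: MbllConstants, distances_cm: np.ndarray) -> HemoSeries:
    """Invert the 2x2 MBLL system per channel; returns µM."""
    E = constants.matrix()
    Einv = np.linalg.inv(E)
    vals = od.values
    if vals.shape[1] != 2:
        raise PreprocessError("MBLL inversion needs exactly two wavelengths")
    distances_cm = np.asarray(distances_cm, dtype=float)
    if np.any(distances_cm <= 0):
        raise PreprocessError("distances must be positive")
    # (n_ch, 2, n) -> solve per channel: conc = Einv @ od / (d * ppf)
    conc = np.einsum("ij,cjt->cit", Einv, vals)
    conc /= (distances_cm[:, None, None] * constants.ppf)
    return HemoSeries(conc * 1e6, od.fs, list(od.channel_names))


DEFAULT_CHAIN = ("od", "tddr", "bandpass", "mbll")


def preprocess_session(
    raw,
    constants: MbllConstants | None = None,
    low: float = 0.01,
    high: float = 0.12,
    chain: tuple[str, ...] = DEFAULT_CHAIN,
) -> HemoSeries:
    """Full chain: intensity -> ΔOD -> TDDR -> band-pass -> ΔHbO/ΔHbR.

    Long and short channels are processed identically.  The stage order is a
    contract; any other ``chain`` raises :class:`ConfigurationError`.
    """
    if tuple(chain) != DEFAULT_CHAIN:
        raise ConfigurationError(
            f"unsupported stage order {chain!r}; the supported chain is {DEFAULT_CHAIN!r}"
        )
    constants = constants or MbllConstants(wavelengths_nm=tuple(raw.wavelengths_nm))
    od = intensity_to_od(raw)
    od = tddr(od)
    od = bandpass(od, low=low, high=high)
    distances = np.array([raw.distance_cm(name) for name in raw.channel_names])
    return od_to_conc(od, constants, distances)


def channel_distances_cm(montage: Montage, channel_names: list[str]) -> np.ndarray:
    """Distances for 'L<k>' long-channel / 'S<k>' short-channel names."""
    out = []
    for name in channel_names:
        kind, idx = name[0], int(name[1:])
        if kind == "L":
            out.append(montage.channel(idx).distance_cm)
        elif kind == "S":
            out.append(montage.short_channel(idx).distance_cm)
        else:
            raise PreprocessError(f"unrecognized channel name {name!r}")
    return np.array(out)
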