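"""Spectral and time-domain feature extraction from raw ECoG.

Raw multichannel recordings (1 kHz, microvolts) are re-referenced to a
common average reference (CAR) and turned into eight feature traces per
channel at the kinematic rate (100 Hz):

* seven band powers — delta (0–4 Hz), theta (4–8), mu (7–13), beta (14–30),
  low gamma (30–50), high gamma 1 (70–110) and high gamma 2 (130–200) —
  computed by zero-phase FIR band filtering, decimation to 100 Hz, squaring,
  a 1-s bidirectional moving average and a log transform;
* the local motor potential (LMP), a 2-s bidirectional moving average of the
  CAR signal, kept in microvolts.

All operations are non-causal by design (forward-backward filtering, centred
smoothing): outputs at time t may depend on samples after t. Band edges are
chosen to avoid 60 Hz line noise and its harmonics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "BandDef",
    "BANDS",
    "FEATURE_TYPES",
    "FeatureTensor",
    "common_average_reference",
    "design_bandpass",
    "zero_phase_filter",
    "moving_average",
    "band_power_feature",
    "lmp_feature",
    "extract_features",
]

#: Number of FIR taps (filter order 400 = 401 coefficients).
FIR_TAPS = 401

#: Guard added to band power before the log transform (µV²).
LOG_EPS = 1e-12


@dataclass(frozen=True)
class BandDef:
    """A named frequency band with edges in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo < self.hi):
            raise ValueError(f"invalid band edges for {self.name}: [{self.lo}, {self.hi}]")


BANDS: tuple[BandDef, ...] = (
    BandDef("delta", 0.0, 4.0),
    BandDef("theta", 4.0, 8.0),
    BandDef("mu", 7.0, 13.0),
    BandDef("beta", 14.0, 30.0),
    BandDef("low_gamma", 30.0, 50.0),
    BandDef("high_gamma_1", 70.0, 110.0),
    BandDef("high_gamma_2", 130.0, 200.0),
)

#: Feature-type order used throughout: the seven bands, then the LMP.
FEATURE_TYPES: tuple[str, ...] = tuple(b.name for b in BANDS) + ("lmp",)


def band_by_name(name: str) -> BandDef:
    for b in BANDS:
        if b.name == name:
            return b
    raise KeyError(name)


@dataclass
class FeatureTensor:
    """Per-channel, per-feature-type traces at the kinematic rate.

    ``values`` has shape (channels, 8, samples); the first seven feature
    types are log band powers (dimensionless), the eighth is the LMP (µV).
    ``kinematics`` carries the jointly trimmed 3×samples position traces so
    that features and kinematics stay on one clock.
    """

    values: np.ndarray
    channel_labels: list[str]
    feature_types: tuple[str, ...] = FEATURE_TYPES
    fs: float = 100.0
    trim_margin_s: float = 0.0
    kinematics: np.ndarray | None = None

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[2]

    def flat(self) -> tuple[np.ndarray, list[tuple[int, str]]]:
        """Flatten to (channels*8, samples) plus (channel index, type) keys."""
        keys = [(c, ft) for c in range(self.n_channels) for ft in self.feature_types]
        return self.values.reshape(-1, self.n_samples), keys


def common_average_reference(neural: np.ndarray) -> np.ndarray:
    """Subtract the instantaneous cross-channel mean from every channel.

    Parameters
    ----------
    neural : (channels, samples) array

    Raises
    ------
    ValueError
        With fewer than two channels the reference is the channel itself.
    """
    neural = np.asarray(neural, dtype=float)
    if neural.ndim != 2 or neural.shape[0] < 2:
        raise ValueError("common average reference requires >= 2 channels")
    return neural - neural.mean(axis=0, keepdims=True)


def design_bandpass(band: BandDef, fs: float) -> np.ndarray:
    """Design the 401-tap Hamming-windowed linear-phase FIR for one band.

    The delta band (lower edge at 0 Hz) is realized as a low-pass at its
    upper edge; all others are band-passes. Coefficients are symmetric
    (type-I linear phase).
    """
    nyq = fs / 2.0
    if band.hi >= nyq:
        raise ValueError(f"band {band.name} upper edge {band.hi} Hz >= Nyquist {nyq} Hz")
    if band.lo <= 0:
        return signal.firwin(FIR_TAPS, band.hi, window="hamming", fs=fs)
    return signal.firwin(FIR_TAPS, [band.lo, band.hi], pass_zero=False, window="hamming", fs=fs)


def zero_phase_filter(x: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Apply an FIR filter forward and backward (zero net phase).

    The effective impulse response is the autocorrelation of ``b``; a
    passband sinusoid comes out with zero delay and squared magnitude gain.
    """
    x = np.asarray(x, dtype=float)
    minlen = 3 * len(b) + 1
    if x.shape[-1] < minlen:
        raise ValueError(f"input too short for zero-phase filtering: need >= {minlen} samples, got {x.shape[-1]}")
    return signal.filtfilt(b, [1.0], x, axis=-1)


def moving_average(x: np.ndarray, window_s: float, fs: float, bidirectional: bool = True) -> np.ndarray:
    """Boxcar moving average, optionally applied forward then backward.

    The bidirectional pass has zero net phase and an effective triangular
    kernel of half-width ``w−1`` samples summing to one. Output length equals
    input length; edges carry the usual zero-state startup transient.
    """
    x = np.asarray(x, dtype=float)
    w = int(round(window_s * fs))
    if w < 1:
        raise ValueError("moving-average window must span at least one sample")
    if x.shape[-1] < w:
        raise ValueError(f"window ({w} samples) longer than signal ({x.shape[-1]} samples)")
    b = np.full(w, 1.0 / w)
    y = signal.lfilter(b, [1.0], x, axis=-1)
    if bidirectional:
        y = signal.lfilter(b, [1.0], y[..., ::-1], axis=-1)[..., ::-1]
    return y


def _decimate(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Keep every (fs_in/fs_out)-th sample starting at sample 0."""
    step = fs_in / fs_out
    if abs(step - round(step)) > 1e-9:
        raise ValueError(f"fs ratio {fs_in}/{fs_out} is not integer")
    return x[..., :: int(round(step))]


def band_power_feature(
    x: np.ndarray,
    band: BandDef,
    fs: float = 1000.0,
    fs_out: float = 100.0,
    smooth_s: float = 1.0,
    order: str = "paper",
) -> np.ndarray:
    """Smoothed log band power of one channel at the kinematic rate.

    ``order='paper'`` follows filter → decimate → square → smooth → log.
    ``order='envelope_first'`` squares and smooths at the neural rate before
    decimating, which avoids aliasing the high-gamma carriers; the aliased
    carrier still preserves band variance, so both orders give equivalent
    smoothed envelopes on band-limited signals.
    """
    if order not in ("paper", "envelope_first"):
        raise ValueError(f"unknown pipeline order {order!r}")
    b = design_bandpass(band, fs)
    y = zero_phase_filter(x, b)
    if order == "paper":
        y = _decimate(y, fs, fs_out)
        y = moving_average(np.square(y), smooth_s, fs_out, bidirectional=True)
    else:
        y = moving_average(np.square(y), smooth_s, fs, bidirectional=True)
        y = _decimate(y, fs, fs_out)
    return np.log(y + LOG_EPS)


def lmp_feature(
    x: np.ndarray,
    fs: float = 1000.0,
    fs_out: float = 100.0,
    window_s: float = 2.0,
) -> np.ndarray:
    """Local motor potential: 2-s bidirectional moving average, downsampled.

    Units remain microvolts; the heavy smoothing keeps only sub-hertz
    structure of the time-domain signal.
    """
    x = np.asarray(x, dtype=float)
    if x.shape[-1] <= 4 * fs:
        raise ValueError("LMP requires more than 4 s of signal")
    y = moving_average(x, window_s, fs, bidirectional=True)
    return _decimate(y, fs, fs_out)


def extract_features(session, trim_margin_s: float = 2.0, order: str = "paper") -> FeatureTensor:
    """Run the full feature chain on a recording session.

    CAR → per-channel band powers and LMP at 100 Hz, then the first and last
    ``trim_margin_s`` seconds are removed jointly from the features and the
    kinematics to discard filter startup transients. Z-scoring is deferred to
    the decoding stage (it must be fit on training folds only).
    """
    neural = common_average_reference(session.neural)
    fs, fs_out = session.fs_neural, session.fs_kin
    n_kin = session.kinematics.shape[1]

    feats = np.empty((neural.shape[0], len(FEATURE_TYPES), 0))
    rows = []
    for ch in neural:
        per_type = [band_power_feature(ch, b, fs=fs, fs_out=fs_out, order=order) for b in BANDS]
        per_type.append(lmp_feature(ch, fs=fs, fs_out=fs_out))
        rows.append(np.stack(per_type))
    feats = np.stack(rows)
    # decimation yields ceil(n/10) samples; align to the kinematic clock
    n = min(feats.shape[2], n_kin)
    feats, kin = feats[:, :, :n], np.asarray(session.kinematics, dtype=float)[:, :n]

    m = int(round(trim_margin_s * fs_out))
    if n - 2 * m < 10 * fs_out:
        raise ValueError(f"trimming {trim_margin_s} s per edge leaves under 10 s of data")
    sl = slice(m, n - m) if m else slice(None)
    return FeatureTensor(
        values=np.ascontiguousarray(feats[:, :, sl]),
        channel_labels=list(session.channel_labels),
        fs=fs_out,
        trim_margin_s=trim_margin_s,
        kinematics=np.ascontiguousarray(kin[:, sl]),
    )
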