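"""Surrogate recording sessions: reach kinematics plus encoding ECoG.

No public ECoG/kinematics dataset accompanies the decoding method this
package implements, so every downstream stage is exercised on surrogate
sessions built here. A session emulates a point-to-point reaching paradigm:
the hand rests at a home position for a variable interval (0–16.7 s), then
performs a minimum-jerk reach to a uniformly drawn target in a bounded 3-D
workspace and returns, with reach durations drawn from a configurable
interval inside 1.2–6.2 s.

Neural channels are pink (1/f) background noise plus band-limited Gaussian
carriers, one per frequency band. Channels listed as *informative* have the
carrier amplitude of one band multiplied by ``max(1 + gain·d(t − lag), 0)``
where d(t) is the first principal component of the z-scored kinematics
rescaled to [0, 1] — positive gains emulate movement-related power increases
(high gamma), negative gains emulate desynchronization (mu/beta/delta). LMP
information is injected as a slow additive offset proportional to the lagged
drive. An optional 60 Hz line component is available to exercise the band
definitions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import BANDS, FEATURE_TYPES, band_by_name

__all__ = [
    "SynthConfig",
    "RecordingSession",
    "generate_reach_kinematics",
    "generate_ecog",
    "generate_session",
    "minimum_jerk",
]

#: Informative entry: (channel index, feature type, gain, lag in ms).
Informative = tuple[int, str, float, float]

DEFAULT_INFORMATIVE: tuple[Informative, ...] = (
    (0, "high_gamma_1", 0.8, -100.0),
    (5, "mu", -0.75, -50.0),
    (10, "beta", -0.75, 100.0),
)


@dataclass
class SynthConfig:
    """Parameters of one surrogate session.

    Defaults describe the study conditions the generator emulates: 16
    channels, 40 reaches of 2–5 s separated by rests of 0–16.7 s (about
    eight minutes of recording), three informative channel–band pairs at
    moderate signal-to-noise ratio, 1 kHz neural and 100 Hz kinematic
    sampling.
    """

    n_channels: int = 16
    informative: tuple[Informative, ...] = DEFAULT_INFORMATIVE
    n_reaches: int = 40
    reach_duration_s: tuple[float, float] = (2.0, 5.0)
    rest_duration_s: tuple[float, float] = (0.0, 16.7)
    workspace: tuple[tuple[float, float], ...] = ((90.0, 130.0), (20.0, 60.0), (-30.0, 30.0))
    home_fraction: tuple[float, float, float] = (0.05, 0.05, 0.5)
    pink_rms_uv: float = 15.0
    carrier_rms_uv: float = 8.0
    lmp_scale_uv: float = 5.0
    line_60hz_uv: float = 0.0
    fs_neural: float = 1000.0
    fs_kin: float = 100.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.reach_duration_s
        if not (1.2 <= lo <= hi <= 6.2):
            raise ValueError("reach durations must lie within [1.2, 6.2] s")
        lo, hi = self.rest_duration_s
        if not (0.0 <= lo <= hi <= 16.7):
            raise ValueError("rest durations must lie within [0, 16.7] s")
        if len(self.workspace) != 3:
            raise ValueError("workspace needs 3 axis intervals (height, depth, lateral)")
        for lo, hi in self.workspace:
            if not hi > lo:
                raise ValueError("degenerate workspace: every axis needs positive width")
        if len(self.home_fraction) != 3 or not all(0.0 <= f <= 1.0 for f in self.home_fraction):
            raise ValueError("home_fraction must be three values in [0, 1]")
        for ch, ftype, gain, lag in self.informative:
            if not 0 <= ch < self.n_channels:
                raise ValueError(f"informative channel {ch} outside 0..{self.n_channels - 1}")
            if ftype not in FEATURE_TYPES:
                raise ValueError(f"unknown feature type {ftype!r}")
            if not np.isfinite(gain):
                raise ValueError("informative gains must be finite")
            if abs(lag) > 1000:
                raise ValueError("|lag| must be <= 1000 ms")


@dataclass
class RecordingSession:
    """Synchronized raw neural matrix and 3-D hand position.

    ``neural`` is channels × samples in µV at ``fs_neural``; ``kinematics``
    is 3 × samples in cm (height, depth, lateral) at ``fs_kin``. For
    generated sessions ``ground_truth`` holds the informative-entry table,
    the latent drive and the per-reach event table.
    """

    neural: np.ndarray
    kinematics: np.ndarray
    fs_neural: float = 1000.0
    fs_kin: float = 100.0
    channel_labels: list[str] = field(default_factory=list)
    ground_truth: dict | None = None

    def __post_init__(self) -> None:
        self.neural = np.asarray(self.neural, dtype=float)
        self.kinematics = np.asarray(self.kinematics, dtype=float)
        if self.neural.ndim != 2 or self.neural.shape[0] < 2:
            raise ValueError("neural matrix must be channels x samples with >= 2 channels")
        if self.kinematics.ndim != 2 or self.kinematics.shape[0] != 3:
            raise ValueError("kinematics must be 3 x samples")
        if not (np.isfinite(self.neural).all() and np.isfinite(self.kinematics).all()):
            raise ValueError("session contains NaN or Inf")
        dur_n = self.neural.shape[1] / self.fs_neural
        dur_k = self.kinematics.shape[1] / self.fs_kin
        if abs(dur_n - dur_k) > 1.0 / self.fs_kin + 1e-9:
            raise ValueError(
                f"neural ({dur_n:.3f} s) and kinematic ({dur_k:.3f} s) durations "
                "differ by more than one kinematic sample"
            )
        if not self.channel_labels:
            self.channel_labels = [f"ch{c:02d}" for c in range(self.neural.shape[0])]

    @property
    def duration_s(self) -> float:
        return self.kinematics.shape[1] / self.fs_kin


def minimum_jerk(tau: np.ndarray) -> np.ndarray:
    """Minimum-jerk position profile 10τ³ − 15τ⁴ + 6τ⁵ on τ ∈ [0, 1].

    Boundary conditions: zero velocity and acceleration at both endpoints.
    """
    tau = np.asarray(tau, dtype=float)
    return tau**3 * (10.0 - 15.0 * tau + 6.0 * tau**2)


def generate_reach_kinematics(
    config: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Simulate the 3-D hand-position trace of one session.

    The trace alternates rests at a fixed home position with out-and-back
    minimum-jerk reaches to uniformly drawn targets; every sample lies inside
    the workspace box. Returns the 3×T trace (cm, ``fs_kin``) and a per-reach
    table with columns onset_s, offset_s, target_height, target_depth,
    target_lateral.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    fs = config.fs_kin
    box = np.asarray(config.workspace, dtype=float)
    # resting hand position: by default low height/depth corner, laterally
    # centred, so reaches go up and forward but vary to the left and right
    frac = np.asarray(config.home_fraction, dtype=float)
    home = box[:, 0] + frac * (box[:, 1] - box[:, 0])

    segments: list[np.ndarray] = []
    events = []
    t = 0.0

    def rest() -> float:
        dur = rng.uniform(*config.rest_duration_s)
        n = int(round(dur * fs))
        segments.append(np.tile(home[:, None], (1, n)))
        return n / fs

    t += rest()
    for _ in range(config.n_reaches):
        dur = rng.uniform(*config.reach_duration_s)
        target = rng.uniform(box[:, 0], box[:, 1])
        n = int(round(dur * fs))
        n_out = n // 2
        tau_out = np.arange(1, n_out + 1) / n_out
        tau_back = np.arange(1, n - n_out + 1) / (n - n_out)
        s = np.concatenate([minimum_jerk(tau_out), 1.0 - minimum_jerk(tau_back)])
        segments.append(home[:, None] + np.outer(target - home, s))
        events.append((t, t + n / fs, *target))
        t += n / fs
        t += rest()

    trace = np.concatenate(segments, axis=1) if segments else home[:, None] * np.ones((1, 0))
    table = pd.DataFrame(
        events,
        columns=["onset_s", "offset_s", "target_height", "target_depth", "target_lateral"],
    )
    return trace, table


def _pc1_drive(kin: np.ndarray) -> np.ndarray:
    """First PC of the z-scored kinematics, min-max rescaled to [0, 1]."""
    z = (kin - kin.mean(axis=1, keepdims=True)) / kin.std(axis=1, ddof=1, keepdims=True)
    cov = np.cov(z)
    vals, vecs = np.linalg.eigh(cov)
    pc1 = vecs[:, np.argmax(vals)]
    if pc1[np.argmax(np.abs(pc1))] < 0:
        pc1 = -pc1
    d = pc1 @ z
    lo, hi = d.min(), d.max()
    return (d - lo) / (hi - lo) if hi > lo else np.zeros_like(d)


def _shift(x: np.ndarray, n: int) -> np.ndarray:
    """Shift right by n samples (delay for n > 0), holding edge values."""
    if n == 0:
        return x
    out = np.empty_like(x)
    if n > 0:
        out[:n], out[n:] = x[0], x[:-n]
    else:
        out[n:], out[:n] = x[-1], x[-n:]
    return out


def _spectral_noise(n: int, shape_fn, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise with spectral amplitude given by ``shape_fn``.

    Synthesized directly in the frequency domain (complex Gaussian bins
    scaled by the target spectrum) at an FFT-friendly length and truncated
    to ``n``; truncating stationary noise leaves its statistics unchanged.
    """
    from scipy.fft import irfft, next_fast_len

    m = next_fast_len(n)
    nbins = m // 2 + 1
    spec = rng.standard_normal(nbins) + 1j * rng.standard_normal(nbins)
    spec *= shape_fn(np.fft.rfftfreq(m))
    x = irfft(spec, m)[:n]
    sd = x.std()
    return x / sd if sd > 0 else x


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f noise."""

    def shape(f: np.ndarray) -> np.ndarray:
        s = np.zeros_like(f)
        s[1:] = 1.0 / np.sqrt(f[1:])
        return s

    return _spectral_noise(n, shape, rng)


def _band_carrier(n: int, lo: float, hi: float, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise band-limited to [lo, hi] Hz."""
    return _spectral_noise(n, lambda f: ((f * fs >= lo) & (f * fs <= hi)).astype(float), rng)


def generate_ecog(
    kin: np.ndarray, config: SynthConfig, rng: np.random.Generator | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Synthesize the neural matrix encoding the first PC of ``kin``.

    Returns (neural matrix in µV at ``fs_neural``, latent drive at
    ``fs_kin``). Raises if an informative gain drives the amplitude
    modulation non-positive at every sample (no carrier would survive).
    """
    kin = np.asarray(kin, dtype=float)
    if not np.isfinite(kin).all():
        raise ValueError("kinematics contain NaN/Inf")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)

    drive = _pc1_drive(kin)
    upsample = int(round(config.fs_neural / config.fs_kin))
    n = kin.shape[1] * upsample
    t_neural = np.arange(n) / config.fs_neural
    t_kin = np.arange(kin.shape[1]) / config.fs_kin
    drive_hi = np.interp(t_neural, t_kin, drive)

    info = {(ch, ftype): (gain, lag) for ch, ftype, gain, lag in config.informative}
    neural = np.empty((config.n_channels, n))
    for ch in range(config.n_channels):
        x = config.pink_rms_uv * _pink_noise(n, rng)
        for band in BANDS:
            carrier = config.carrier_rms_uv * _band_carrier(n, band.lo, band.hi, config.fs_neural, rng)
            if (ch, band.name) in info:
                gain, lag = info[(ch, band.name)]
                lagged = _shift(drive_hi, int(round(lag / 1000.0 * config.fs_neural)))
                mod = np.maximum(1.0 + gain * lagged, 0.0)
                if not np.any(mod > 0):
                    raise ValueError(
                        f"gain {gain} on channel {ch} band {band.name} kills the carrier everywhere"
                    )
                carrier = carrier * mod
            x += carrier
        if (ch, "lmp") in info:
            gain, lag = info[(ch, "lmp")]
            lagged = _shift(drive_hi, int(round(lag / 1000.0 * config.fs_neural)))
            x += config.lmp_scale_uv * gain * lagged
        if config.line_60hz_uv:
            x += config.line_60hz_uv * np.sin(2 * np.pi * 60.0 * t_neural)
        neural[ch] = x
    return neural, drive


def generate_session(config: SynthConfig) -> RecordingSession:
    """Generate a full surrogate session, deterministic for a fixed seed."""
    rng = np.random.default_rng(config.seed)
    kin, reaches = generate_reach_kinematics(config, rng)
    neural, drive = generate_ecog(kin, config, rng)
    return RecordingSession(
        neural=neural,
        kinematics=kin,
        fs_neural=config.fs_neural,
        fs_kin=config.fs_kin,
        channel_labels=[f"ch{c:02d}" for c in range(config.n_channels)],
        ground_truth={
            "informative": pd.DataFrame(
                list(config.informative), columns=["channel", "feature_type", "gain", "lag_ms"]
            ),
            "drive": drive,
            "reaches": reaches,
        },
    )
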