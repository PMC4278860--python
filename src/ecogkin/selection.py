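"""Lagged-correlation ranking of candidate decoder inputs.

Each (channel, feature type) trace is scored by its Pearson correlation
with the kinematic target over a grid of time lags (±1 s at 50 ms steps by
default) and enters the ranking once, at its best lag. Lag convention:
r(ℓ) is the correlation between feature(t + ℓ) and target(t), so a
*negative* best lag means the neural feature changes before the kinematics
(motor-like) and a positive one means it follows them (sensory-like).

Ranking uses |r|: low-frequency band powers carry movement information with
negative correlations (desynchronization) and are as valid as inputs as the
positively correlated high-gamma features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .features import FeatureTensor

__all__ = ["LagGrid", "SelectedFeature", "lagged_correlation", "lagged_correlation_matrix", "select_features"]


@dataclass(frozen=True)
class LagGrid:
    """Symmetric grid of signed lags in milliseconds."""

    max_lag_ms: float = 1000.0
    step_ms: float = 50.0

    def __post_init__(self) -> None:
        n = self.max_lag_ms / self.step_ms
        if abs(n - round(n)) > 1e-9:
            raise ValueError("lag step must divide the maximum lag")

    @property
    def lags_ms(self) -> np.ndarray:
        return np.arange(-self.max_lag_ms, self.max_lag_ms + self.step_ms / 2, self.step_ms)

    def lags_samples(self, fs: float) -> np.ndarray:
        return np.round(self.lags_ms / 1000.0 * fs).astype(int)


@dataclass(frozen=True)
class SelectedFeature:
    """One ranked decoder input: a channel/feature-type pair at its best lag."""

    channel: str
    channel_index: int
    feature_type: str
    feature_index: int
    best_lag_ms: float
    train_r: float


def _overlap_slices(n: int, lag: int) -> tuple[slice, slice]:
    """Index slices pairing feature[t + lag] with target[t], overlap only."""
    if lag >= 0:
        return slice(lag, n), slice(0, n - lag)
    return slice(0, n + lag), slice(-lag, n)


def _lag_sums(F: np.ndarray, t: np.ndarray, lags: np.ndarray) -> dict:
    """Overlap-only sufficient statistics for every lag at once.

    For each lag ℓ the overlap pairs feature[i + ℓ] with target[i]. The
    cross terms for all lags come from one matrix product of the features
    against a bank of shifted copies of the target (zero outside the
    overlap); the marginal sums come from prefix sums.
    """
    F = np.atleast_2d(F)
    n = t.shape[0]
    csF = np.cumsum(F, axis=1)
    csF2 = np.cumsum(F * F, axis=1)
    cst = np.cumsum(t)
    cst2 = np.cumsum(t * t)

    nf, nl = F.shape[0], lags.size
    shifted = np.zeros((nl, n))
    for j, lag in enumerate(int(l) for l in lags):
        if lag >= 0:
            shifted[j, lag:] = t[: n - lag]
        else:
            shifted[j, : n + lag] = t[-lag:]
    cross_all = F @ shifted.T
    out = {
        "m": np.empty(nl, dtype=int),
        "fsum": np.empty((nf, nl)),
        "f2sum": np.empty((nf, nl)),
        "tsum": np.empty(nl),
        "t2sum": np.empty(nl),
        "cross": np.empty((nf, nl)),
    }
    for j, lag in enumerate(int(l) for l in lags):
        out["m"][j] = n - abs(lag)
        if lag >= 0:
            out["fsum"][:, j] = csF[:, -1] - (csF[:, lag - 1] if lag else 0.0)
            out["f2sum"][:, j] = csF2[:, -1] - (csF2[:, lag - 1] if lag else 0.0)
            out["tsum"][j] = cst[n - lag - 1]
            out["t2sum"][j] = cst2[n - lag - 1]
        else:
            out["fsum"][:, j] = csF[:, n + lag - 1]
            out["f2sum"][:, j] = csF2[:, n + lag - 1]
            out["tsum"][j] = cst[-1] - cst[-lag - 1]
            out["t2sum"][j] = cst2[-1] - cst2[-lag - 1]
    out["cross"] = cross_all
    return out


def _corr_from_sums(s: dict) -> np.ndarray:
    """Pearson r table from pooled overlap sums; degenerate traces give 0."""
    m = s["m"].astype(float)
    fvar = np.maximum(s["f2sum"] - s["fsum"] ** 2 / m, 0.0)
    tvar = np.maximum(s["t2sum"] - s["tsum"] ** 2 / m, 0.0)
    cross = s["cross"] - s["fsum"] * s["tsum"] / m
    # relative floor: constant traces leave only cancellation residue
    bad = (fvar <= s["f2sum"] * 1e-13) | (tvar <= s["t2sum"] * 1e-13)[None, :]
    if np.any(bad):
        warnings.warn("constant trace in lag overlap: correlation undefined, returning 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = cross / np.sqrt(fvar * tvar[None, :])
    return np.where(bad | ~np.isfinite(r), 0.0, np.clip(r, -1.0, 1.0))


def lagged_correlation_matrix(features: np.ndarray, target: np.ndarray, grid: LagGrid, fs: float) -> np.ndarray:
    """Pearson r for every feature row at every grid lag.

    Parameters
    ----------
    features : (n_features, T) array
    target : (T,) array
    fs : sampling rate (Hz) shared by both

    Returns
    -------
    (n_features, n_lags) array. A constant trace in the overlap yields r = 0
    with a warning rather than NaN.
    """
    F = np.atleast_2d(np.asarray(features, dtype=float))
    t = np.asarray(target, dtype=float)
    n = t.shape[0]
    if F.shape[1] != n:
        raise ValueError("feature and target traces must have equal length")
    lags = grid.lags_samples(fs)
    if n <= 2 * int(np.abs(lags).max()):
        raise ValueError("traces shorter than twice the maximum lag")
    return _corr_from_sums(_lag_sums(F, t, lags))


def lagged_correlation(feature: np.ndarray, target: np.ndarray, grid: LagGrid, fs: float = 100.0) -> np.ndarray:
    """Correlation of a single feature trace with the target at each lag."""
    return lagged_correlation_matrix(feature[None, :], target, grid, fs)[0]


def select_features(
    features: FeatureTensor,
    target: np.ndarray,
    n: int,
    grid: LagGrid | None = None,
) -> list[SelectedFeature]:
    """Rank all (channel, feature type) pairs and return the top n.

    Each pair is scored by max |r| over the lag grid and included once, at
    that best lag. Ties are broken deterministically: within a pair by
    smaller |lag| (then earlier lag); across pairs by lower channel index
    then feature-type order.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    grid = grid or LagGrid()
    flat, keys = features.flat()
    if n > flat.shape[0]:
        raise ValueError(f"requested {n} inputs but only {flat.shape[0]} candidates exist")
    R = lagged_correlation_matrix(flat, np.asarray(target, dtype=float), grid, features.fs)
    return rank_features(R, keys, grid.lags_ms, features.channel_labels, n)


def rank_features(
    R: np.ndarray,
    keys: list[tuple[int, str]],
    lags_ms: np.ndarray,
    channel_labels: list[str],
    n: int,
) -> list[SelectedFeature]:
    """Turn a (features × lags) correlation table into the top-n selection."""
    picks = []
    for i, (ch, ftype) in enumerate(keys):
        absr = np.abs(R[i])
        best = absr.max()
        tied = np.flatnonzero(absr >= best - 1e-15)
        j = tied[np.lexsort((lags_ms[tied], np.abs(lags_ms[tied])))[0]]
        picks.append((best, ch, i, ftype, lags_ms[j], R[i, j]))

    picks.sort(key=lambda p: (-p[0], p[1], p[2]))
    return [
        SelectedFeature(
            channel=channel_labels[ch],
            channel_index=ch,
            feature_type=ftype,
            feature_index=i,
            best_lag_ms=float(lag),
            train_r=float(r),
        )
        for _, ch, i, ftype, lag, r in picks[:n]
    ]
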