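"""Cross-validated linear decoding of kinematics from neural features.

The kinematic target at each time step is modelled as a linear combination
of the selected, lag-aligned neural features plus a constant offset and
Gaussian noise; parameters are fit by ordinary least squares. Accuracy is
the Pearson correlation r between observed and predicted kinematics on
held-out data, optionally Fisher-transformed to z = atanh(r)·sqrt(n − 3).

Cross-validation uses five contiguous 20% test blocks rather than random
samples: the 1–2 s smoothing windows in feature extraction induce strong
autocorrelation that sample-wise splits would leak across the train/test
boundary. Within every fold the feature/kinematic normalizers, the PCA, the
feature selection and the decoder weights are all re-fit on the training
block only, and lagged samples are taken strictly from within each block so
that no statistic depends on held-out data.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import kinpca
from .features import FeatureTensor
from .selection import LagGrid, SelectedFeature, _corr_from_sums, _lag_sums, rank_features

__all__ = ["LinearDecoder", "FoldResult", "CVResult", "fit_linear", "pearson_r", "fisher_z", "crossvalidate"]

TARGETS = ("pc1", "pc2", "pc3", "height", "depth", "lateral")


@dataclass
class LinearDecoder:
    """OLS weights, intercept and residual variance for one target."""

    weights: np.ndarray
    intercept: float
    residual_variance: float
    target: str = "pc1"

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights + self.intercept


@dataclass
class FoldResult:
    r: float
    z: float
    n_test: int
    selected: list[SelectedFeature]
    decoder: LinearDecoder
    test_span: tuple[int, int]
    predicted: np.ndarray
    observed: np.ndarray


@dataclass
class CVResult:
    """Per-fold accuracies and the session-level summary."""

    folds: list[FoldResult]
    target: str
    n_inputs: int

    @property
    def fold_r(self) -> np.ndarray:
        return np.array([f.r for f in self.folds])

    @property
    def fold_z(self) -> np.ndarray:
        return np.array([f.z for f in self.folds])

    @property
    def median_r(self) -> float:
        return float(np.median(self.fold_r))

    @property
    def median_z(self) -> float:
        return float(np.median(self.fold_z))


def fit_linear(X: np.ndarray, y: np.ndarray, target: str = "pc1") -> LinearDecoder:
    """Ordinary least squares with a constant offset.

    Rank-deficient designs fall back to the minimum-norm solution with a
    warning. Residuals are orthogonal to the design columns and the constant.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ValueError(f"need more than {p + 1} samples to fit {p} weights plus offset")
    A = np.column_stack([np.ones(n), X])
    coef, _, rank, _ = np.linalg.lstsq(A, y, rcond=None)
    if rank < p + 1:
        warnings.warn(f"rank-deficient design (rank {rank} < {p + 1}); minimum-norm solution")
    resid = y - A @ coef
    dof = max(n - rank, 1)
    return LinearDecoder(
        weights=coef[1:], intercept=float(coef[0]), residual_variance=float(resid @ resid / dof), target=target
    )


def pearson_r(y_hat: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation between predicted and observed traces."""
    y_hat = np.asarray(y_hat, dtype=float)
    y = np.asarray(y, dtype=float)
    if y_hat.shape != y.shape or y.size < 3:
        raise ValueError("inputs must be equal-length with at least 3 samples")
    a = y_hat - y_hat.mean()
    b = y - y.mean()
    denom = np.sqrt((a @ a) * (b @ b))
    if denom == 0:
        raise ValueError("correlation undefined for a constant input")
    return float(np.clip(a @ b / denom, -1.0, 1.0))


def fisher_z(r: float, n: int) -> float:
    """Variance-stabilized accuracy: atanh(r) scaled by sqrt(n − 3)."""
    if abs(r) >= 1.0:
        raise ValueError("|r| must be < 1 for the Fisher transform")
    if n <= 3:
        raise ValueError("need n > 3 samples")
    return float(np.arctanh(r) * np.sqrt(n - 3))


def fold_spans(n_samples: int, folds: int) -> list[tuple[int, int]]:
    """Contiguous test blocks partitioning [0, n_samples)."""
    edges = np.round(np.linspace(0, n_samples, folds + 1)).astype(int)
    return [(int(edges[i]), int(edges[i + 1])) for i in range(folds)]


def _pooled_lagged_corr(
    flat: np.ndarray, target: np.ndarray, segments: list[tuple[int, int]], lags: np.ndarray
) -> np.ndarray:
    """Lagged correlations pooling sample pairs across disjoint segments.

    Only pairs (t + ℓ, t) with both indices inside one segment contribute, so
    the statistic never mixes training segments across the excised test
    block, nor touches test samples.
    """
    nf = flat.shape[0]
    total = None
    for s0, s1 in segments:
        if s1 - s0 <= int(np.abs(lags).max()) + 2:
            continue
        s = _lag_sums(flat[:, s0:s1], target[s0:s1], lags)
        if total is None:
            total = s
        else:
            for key in total:
                total[key] = total[key] + s[key]
    if total is None:
        raise ValueError("every training segment is shorter than the maximum lag")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # degenerate columns become r = 0
        return _corr_from_sums(total)


def _lagged_rows(
    flat: np.ndarray,
    target: np.ndarray,
    segments: list[tuple[int, int]],
    feat_idx: np.ndarray,
    lag_samp: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix/target rows whose lagged samples stay inside a segment."""
    lo = int(max(0, -lag_samp.min(initial=0)))
    hi = int(max(0, lag_samp.max(initial=0)))
    Xs, ys = [], []
    for s0, s1 in segments:
        t = np.arange(s0 + lo, s1 - hi)
        if t.size == 0:
            continue
        X = np.empty((t.size, feat_idx.size))
        for j, lag in enumerate(lag_samp):
            X[:, j] = flat[feat_idx[j], t + lag]
        Xs.append(X)
        ys.append(target[t])
    if not Xs:
        raise ValueError("no usable samples after lag alignment")
    return np.vstack(Xs), np.concatenate(ys)


def _target_trace(kin: np.ndarray, norm: kinpca.Normalizer, pca: kinpca.PCATransform, target: str) -> np.ndarray:
    z = kinpca.apply_normalizer(norm, kin)
    if target.startswith("pc"):
        return kinpca.project(pca, z)[int(target[2]) - 1]
    return z[("height", "depth", "lateral").index(target)]


def crossvalidate(
    features: FeatureTensor,
    kin: np.ndarray | None = None,
    n_inputs: int = 9,
    target: str = "pc1",
    folds: int = 5,
    grid: LagGrid | None = None,
) -> CVResult:
    """Fivefold contiguous-block cross-validation of the linear decoder.

    For every fold the held-out block is the test set; on the remainder the
    kinematic normalizer and PCA, the per-feature normalization, the lagged
    feature selection (``n_inputs`` best by |r|) and the OLS weights are
    fit, then accuracy is evaluated on the held-out block with those frozen
    transforms.
    """
    if target not in TARGETS:
        raise ValueError(f"target must be one of {TARGETS}")
    if kin is None:
        kin = features.kinematics
    if kin is None:
        raise ValueError("no kinematics supplied")
    kin = np.asarray(kin, dtype=float)
    grid = grid or LagGrid()
    flat, keys = features.flat()
    if n_inputs > flat.shape[0]:
        raise ValueError(f"n_inputs={n_inputs} exceeds the {flat.shape[0]} available features")
    T = flat.shape[1]
    if kin.shape[1] != T:
        raise ValueError("features and kinematics are not aligned")
    lags = grid.lags_samples(features.fs)

    results = []
    for a, b in fold_spans(T, folds):
        train_segs = [(s0, s1) for s0, s1 in ((0, a), (b, T)) if s1 > s0]
        train_idx = np.concatenate([np.arange(s0, s1) for s0, s1 in train_segs])

        norm = kinpca.fit_normalizer(kin[:, train_idx])
        pca = kinpca.fit_pca(kinpca.apply_normalizer(norm, kin[:, train_idx]))
        y_full = _target_trace(kin, norm, pca, target)

        R = _pooled_lagged_corr(flat, y_full, train_segs, lags)
        selected = rank_features(R, keys, grid.lags_ms, features.channel_labels, n_inputs)
        feat_idx = np.array([s.feature_index for s in selected])
        lag_samp = np.round(np.array([s.best_lag_ms for s in selected]) / 1000.0 * features.fs).astype(int)

        X_tr, y_tr = _lagged_rows(flat, y_full, train_segs, feat_idx, lag_samp)
        mu, sd = X_tr.mean(axis=0), X_tr.std(axis=0, ddof=1)
        sd[sd <= 0] = 1.0
        decoder = fit_linear((X_tr - mu) / sd, y_tr, target=target)

        X_te, y_te = _lagged_rows(flat, y_full, [(a, b)], feat_idx, lag_samp)
        y_hat = decoder.predict((X_te - mu) / sd)
        r = pearson_r(y_hat, y_te)
        results.append(
            FoldResult(
                r=r,
                z=fisher_z(r, y_te.shape[0]),
                n_test=int(y_te.shape[0]),
                selected=selected,
                decoder=decoder,
                test_span=(a, b),
                predicted=y_hat,
                observed=y_te,
            )
        )
    return CVResult(folds=results, target=target, n_inputs=n_inputs)
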