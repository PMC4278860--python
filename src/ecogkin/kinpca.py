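"""Kinematic normalization and principal-component decomposition.

The three Cartesian position axes (height, depth, lateral) of natural
reaches are correlated, so decoding targets are defined on the principal
components of the z-scored kinematics instead: PC1 is the direction the
hand moved most. Both the normalizer and the PCA loadings are fit on
training data only and re-fit in every cross-validation fold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["Normalizer", "PCATransform", "fit_normalizer", "apply_normalizer", "fit_pca", "project"]

AXIS_NAMES = ("height", "depth", "lateral")


@dataclass(frozen=True)
class Normalizer:
    """Per-dimension means and sample standard deviations of training data."""

    means: np.ndarray
    sds: np.ndarray

    def inverse(self, z: np.ndarray) -> np.ndarray:
        return z * self.sds[:, None] + self.means[:, None]


@dataclass(frozen=True)
class PCATransform:
    """Orthonormal loadings (rows = PCs) and descending explained variances."""

    loadings: np.ndarray
    explained_variance: np.ndarray


def fit_normalizer(train_kin: np.ndarray) -> Normalizer:
    """Fit per-dimension mean/sd (ddof=1) on training kinematics (dims × T)."""
    train_kin = np.atleast_2d(np.asarray(train_kin, dtype=float))
    if train_kin.shape[1] < 2:
        raise ValueError("need at least 2 samples to fit a normalizer")
    means = train_kin.mean(axis=1)
    sds = train_kin.std(axis=1, ddof=1)
    zero = np.flatnonzero(sds <= 0)
    if zero.size:
        names = ", ".join(AXIS_NAMES[i] if i < 3 else str(i) for i in zero)
        raise ValueError(f"zero variance in dimension(s): {names}")
    return Normalizer(means=means, sds=sds)


def apply_normalizer(norm: Normalizer, kin: np.ndarray) -> np.ndarray:
    kin = np.atleast_2d(np.asarray(kin, dtype=float))
    return (kin - norm.means[:, None]) / norm.sds[:, None]


def fit_pca(train_kin_z: np.ndarray) -> PCATransform:
    """Eigendecompose the (n−1)-normalized covariance of z-scored kinematics.

    PCs are sorted by descending variance; each loading vector is flipped so
    its largest-magnitude element is positive, making the (arbitrary) sign
    stable across cross-validation folds. A zero eigenvalue (rank-deficient
    covariance) is allowed.
    """
    z = np.atleast_2d(np.asarray(train_kin_z, dtype=float))
    cov = np.cov(z, ddof=1)
    vals, vecs = np.linalg.eigh(np.atleast_2d(cov))
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    loadings = vecs.T.copy()
    for row in loadings:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1.0
    return PCATransform(loadings=loadings, explained_variance=np.maximum(vals, 0.0))


def project(pca: PCATransform, kin_z: np.ndarray) -> np.ndarray:
    """Project z-scored kinematics onto the PCs (rows = PC scores)."""
    return pca.loadings @ np.atleast_2d(np.asarray(kin_z, dtype=float))
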