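"""Chance calibration and significance analyses for decoding accuracies.

Chance performance is estimated by decoupling the neural features from the
kinematics and rerunning the *entire* cross-validated decoding — including
feature selection — for each of many shuffles, yielding a null distribution
of median accuracies. Two decoupling modes are provided:

* ``circular_shift`` (default): each feature trace is rotated in time by a
  random offset at least 5 s away from identity. This preserves each
  trace's autocorrelation, which sample-wise permutation of heavily
  smoothed features would destroy (making chance look unrealistically bad).
* ``permute``: literal sample-wise shuffling of each feature trace.

Observed fold accuracies are compared with the null by a Bonferroni-
corrected Wilcoxon rank-sum test. Accuracies across conditions are compared
with a two-way fixed-effects ANOVA (factors: number of inputs, feature
type) on Fisher-z values with Dunn-Šidák-corrected post-hoc tests, and the
saturation of performance with model order is located with a
Kruskal–Wallis test followed by a least-significant-difference (Conover
rank) post-hoc rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .features import FeatureTensor
from .decode import crossvalidate
from .selection import LagGrid

__all__ = [
    "NullDistribution",
    "shuffle_null",
    "wilcoxon_vs_chance",
    "dunn_sidak_alpha",
    "anova_inputs_by_featuretype",
    "saturation_point",
]


@dataclass
class NullDistribution:
    """Decoding accuracies (median r over folds) under feature shuffling.

    ``fold_r`` additionally keeps every per-fold accuracy (n_shuffles ×
    folds); rank tests against observed per-fold accuracies use these so
    that like is compared with like (a fold accuracy has more spread than a
    median over folds).
    """

    r: np.ndarray
    mode: str
    seed: int
    fold_r: np.ndarray | None = None

    @property
    def n(self) -> int:
        return self.r.size

    def interval(self, coverage: float = 0.95) -> tuple[float, float]:
        lo = (1.0 - coverage) / 2.0
        return (float(np.quantile(self.r, lo)), float(np.quantile(self.r, 1.0 - lo)))

    def contains(self, value: float, coverage: float = 0.95) -> bool:
        lo, hi = self.interval(coverage)
        return lo <= value <= hi

    @property
    def max(self) -> float:
        return float(self.r.max())


def _decouple(values: np.ndarray, mode: str, fs: float, rng: np.random.Generator) -> np.ndarray:
    C, F, T = values.shape
    flat = values.reshape(C * F, T)
    out = np.empty_like(flat)
    if mode == "circular_shift":
        margin = int(round(5.0 * fs))
        if T <= 2 * margin:
            raise ValueError("trace too short for a >= 5 s circular shift")
        shifts = rng.integers(margin, T - margin, size=C * F)
        for i, s in enumerate(shifts):
            out[i] = np.roll(flat[i], int(s))
    elif mode == "permute":
        for i in range(C * F):
            out[i] = flat[i, rng.permutation(T)]
    else:
        raise ValueError(f"unknown shuffle mode {mode!r}")
    return out.reshape(C, F, T)


def shuffle_null(
    features: FeatureTensor,
    kin: np.ndarray | None = None,
    n_inputs: int = 9,
    n_shuffles: int = 1024,
    mode: str = "circular_shift",
    target: str = "pc1",
    folds: int = 5,
    grid: LagGrid | None = None,
    seed: int = 0,
) -> NullDistribution:
    """Null distribution of cross-validated accuracy under feature shuffling.

    Every shuffle decouples the features from the kinematics *before*
    selection and training, then reruns the full fivefold cross-validation;
    the true feature–kinematics coupling therefore never leaks into the
    null.
    """
    import warnings

    if n_shuffles < 100:
        warnings.warn(f"{n_shuffles} shuffles gives an unstable null tail; 1024 is the reference count")
    rng = np.random.default_rng(seed)
    rs = np.empty(n_shuffles)
    fold_rs = []
    for k in range(n_shuffles):
        shuffled = FeatureTensor(
            values=_decouple(features.values, mode, features.fs, rng),
            channel_labels=features.channel_labels,
            feature_types=features.feature_types,
            fs=features.fs,
            trim_margin_s=features.trim_margin_s,
            kinematics=features.kinematics,
        )
        cv = crossvalidate(shuffled, kin=kin, n_inputs=n_inputs, target=target, folds=folds, grid=grid)
        rs[k] = cv.median_r
        fold_rs.append(cv.fold_r)
    return NullDistribution(r=rs, mode=mode, seed=seed, fold_r=np.vstack(fold_rs))


def wilcoxon_vs_chance(
    actual_r: np.ndarray, null: NullDistribution, n_comparisons: int = 1, alpha: float = 0.05
) -> tuple[float, bool]:
    """Bonferroni-corrected rank-sum test of fold accuracies against the null.

    Returns the corrected p-value (capped at 1) and whether it clears
    ``alpha``.
    """
    actual_r = np.asarray(actual_r, dtype=float)
    if actual_r.size < 3:
        raise ValueError("need at least 3 observed accuracies")
    if null.n == 0:
        raise ValueError("empty null distribution")
    if n_comparisons < 1:
        raise ValueError("n_comparisons must be >= 1")
    reference = null.fold_r.ravel() if null.fold_r is not None else null.r
    p = sps.ranksums(actual_r, reference).pvalue
    p_corr = min(1.0, p * n_comparisons)
    return float(p_corr), bool(p_corr < alpha)


def dunn_sidak_alpha(alpha: float, m: int) -> float:
    """Per-test level 1 − (1 − α)^(1/m) controlling family-wise error at α."""
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def anova_inputs_by_featuretype(df: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Two-way fixed-effects ANOVA of Fisher-z accuracies.

    ``df`` needs columns ``z`` (Fisher-transformed accuracy), ``n_inputs``
    and ``feature_type``; both factors need at least two levels and every
    cell at least two replicates. Returns the ANOVA table plus Dunn-Šidák
    post-hoc pairwise comparisons (Welch t-tests pooled over the other
    factor) for each factor.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for col in ("z", "n_inputs", "feature_type"):
        if col not in df.columns:
            raise ValueError(f"missing column {col!r}")
    counts = df.groupby(["n_inputs", "feature_type"], observed=True).size()
    levels_n = df["n_inputs"].unique()
    levels_f = df["feature_type"].unique()
    if len(levels_n) < 2 or len(levels_f) < 2:
        raise ValueError("both factors need at least two levels")
    full = pd.MultiIndex.from_product([levels_n, levels_f], names=["n_inputs", "feature_type"])
    missing = [idx for idx in full if idx not in counts.index or counts[idx] < 2]
    if missing:
        raise ValueError(f"cells with fewer than 2 replicates: {missing}")

    data = df.copy()
    data["n_inputs"] = data["n_inputs"].astype(str)
    model = smf.ols("z ~ C(n_inputs) + C(feature_type)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=2)

    posthoc_rows = []
    for factor in ("n_inputs", "feature_type"):
        levels = sorted(df[factor].unique(), key=str)
        m = len(levels) * (len(levels) - 1) // 2
        a_ds = dunn_sidak_alpha(alpha, m) if m else alpha
        for i in range(len(levels)):
            for j in range(i + 1, len(levels)):
                gi = df.loc[df[factor] == levels[i], "z"]
                gj = df.loc[df[factor] == levels[j], "z"]
                p = sps.ttest_ind(gi, gj, equal_var=False).pvalue
                posthoc_rows.append(
                    {
                        "factor": factor,
                        "level_a": levels[i],
                        "level_b": levels[j],
                        "p": float(p),
                        "alpha_corrected": a_ds,
                        "significant": bool(p < a_ds),
                    }
                )
    return {
        "anova": table,
        "p_n_inputs": float(table.loc["C(n_inputs)", "PR(>F)"]),
        "p_feature_type": float(table.loc["C(feature_type)", "PR(>F)"]),
        "posthoc": pd.DataFrame(posthoc_rows),
    }


def saturation_point(groups: dict[int, np.ndarray], alpha: float = 0.05) -> int:
    """Smallest model order beyond which more inputs stop helping.

    Runs a Kruskal–Wallis test across the accuracy groups (keyed by number
    of inputs). If it is not significant, the smallest order already
    saturates. Otherwise pairwise least-significant-difference comparisons
    on rank means (Conover) find the smallest n such that no larger model
    is significantly better.
    """
    keys = sorted(groups)
    if len(keys) < 2:
        raise ValueError("need at least 2 model orders")
    arrays = [np.asarray(groups[k], dtype=float) for k in keys]
    if any(a.size < 3 for a in arrays):
        raise ValueError("need at least 3 accuracies per model order")
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        return keys[0]
    H, p_kw = sps.kruskal(*arrays)
    if p_kw >= alpha:
        return keys[0]

    ranks = sps.rankdata(pooled)
    sizes = np.array([a.size for a in arrays])
    N, k = pooled.size, len(arrays)
    splits = np.cumsum(sizes)[:-1]
    mean_ranks = np.array([r.mean() for r in np.split(ranks, splits)])
    s2 = np.var(ranks, ddof=1)
    scale = s2 * (N - 1 - H) / (N - k)

    def better(j: int, i: int) -> bool:
        """Is group j significantly better (higher ranks) than group i?"""
        se = np.sqrt(scale * (1.0 / sizes[i] + 1.0 / sizes[j]))
        if se == 0:
            return mean_ranks[j] > mean_ranks[i]
        t = (mean_ranks[j] - mean_ranks[i]) / se
        return sps.t.sf(t, N - k) < alpha

    for i, n in enumerate(keys):
        if not any(better(j, i) for j in range(i + 1, len(keys))):
            return n
    return keys[-1]
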