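"""Permutation and bootstrap statistics on decoder weight vectors.

Covers the bespoke analyses applied to linear SVR coefficient profiles:
performance-weighted averaging of max-normalized weight vectors, a
contiguity-sensitive permutation test that hunts for runs of 3-7 adjacent
frequency features with unexpectedly high or low mean weight, a
cross-frequency weight correlation matrix with a per-cell shuffle null,
plus the shared nonparametric utilities (Benjamini-Hochberg FDR,
Mann-Whitney U, Wilcoxon signed-rank).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats


@dataclass
class WeightProfile:
    """Mean weight per frequency feature across contributing models."""

    mean: np.ndarray  # (n_features,)
    sem: np.ndarray  # standard error across contributors
    n_contributors: int
    max_normalized: bool = True


@dataclass
class ClusterWindow:
    start: int
    length: int
    observed_mean: float
    p: float
    flag: str  # "high" | "low" | ""


@dataclass
class ClusterTestResult:
    windows: list[ClusterWindow]
    alpha: float
    n_perm: int

    @property
    def high(self) -> list[ClusterWindow]:
        return [w for w in self.windows if w.flag == "high"]

    @property
    def low(self) -> list[ClusterWindow]:
        return [w for w in self.windows if w.flag == "low"]

    @property
    def flagged_fraction(self) -> float:
        return sum(w.flag != "" for w in self.windows) / len(self.windows)


@dataclass
class WeightCorrMatrix:
    corr: np.ndarray  # (f, f), symmetric; diagonal is non-data
    p: np.ndarray  # (f, f) two-sided bootstrap p per cell
    display: np.ndarray  # diagonal imputed for visualization only
    mean_abs_off_diag: np.ndarray  # (f,) mean |corr| per frequency
    n_boot: int


def max_normalize(w: np.ndarray) -> np.ndarray:
    """Divide a weight vector by its maximum absolute entry."""
    w = np.asarray(w, dtype=float)
    m = np.max(np.abs(w))
    return w if m == 0 else w / m


def performance_weighted_mean(
    weights: np.ndarray, accuracies: np.ndarray
) -> WeightProfile:
    """Performance-weighted mean of max-normalized weight vectors.

    Weights are ``max(r, 0)`` so anti-predictive models contribute
    nothing; standard errors are computed across contributors.
    """
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    acc = np.asarray(accuracies, dtype=float)
    if weights.shape[0] != acc.size:
        raise ValueError("one accuracy per weight vector required")
    wts = np.maximum(acc, 0.0)
    if wts.sum() <= 0:
        raise ValueError("no contributor has positive accuracy")
    normed = np.vstack([max_normalize(v) for v in weights])
    mean = wts @ normed / wts.sum()
    n = weights.shape[0]
    sem = normed.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros(mean.size)
    return WeightProfile(mean=mean, sem=sem, n_contributors=n)


def _window_means(x: np.ndarray, length: int) -> np.ndarray:
    """Means over all contiguous windows of ``length`` along the last axis."""
    c = np.cumsum(x, axis=-1)
    c = np.concatenate([np.zeros(x.shape[:-1] + (1,)), c], axis=-1)
    return (c[..., length:] - c[..., :-length]) / length


def contiguity_permutation_test(
    profile: WeightProfile | np.ndarray,
    window_lengths: range = range(3, 8),
    n_perm: int = 10_000,
    alpha: float = 0.05,
    seed: int = 0,
) -> ClusterTestResult:
    """Detect spectrally contiguous runs of extreme mean weight.

    The profile's entries are shuffled across frequency positions
    ``n_perm`` times; for each window length the null distribution of
    window means is pooled over all start positions.  Observed windows
    beyond the two-sided ``alpha`` quantiles are flagged, with add-one
    permutation p-values ``(k + 1) / (n + 1)``.
    """
    x = profile.mean if isinstance(profile, WeightProfile) else np.asarray(profile, float)
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if x.size < max(window_lengths):
        raise ValueError("profile shorter than the longest window")
    rng = np.random.default_rng(seed)
    perms = rng.permuted(np.broadcast_to(x, (n_perm, x.size)).copy(), axis=1)
    windows: list[ClusterWindow] = []
    for length in window_lengths:
        obs = _window_means(x, length)
        null = _window_means(perms, length).ravel()
        n_null = null.size
        lo_q, hi_q = np.quantile(null, [alpha / 2.0, 1.0 - alpha / 2.0])
        for start, o in enumerate(obs):
            tol = 1e-12 * max(1.0, abs(o))  # ties up to fp error count as ties
            k_hi = int(np.sum(null >= o - tol))
            k_lo = int(np.sum(null <= o + tol))
            p = min(1.0, 2.0 * (min(k_hi, k_lo) + 1) / (n_null + 1))
            flag = "high" if o > hi_q + tol else ("low" if o < lo_q - tol else "")
            windows.append(
                ClusterWindow(start=start, length=length, observed_mean=float(o), p=p, flag=flag)
            )
    return ClusterTestResult(windows=windows, alpha=alpha, n_perm=n_perm)


def _offdiag_corr(w: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.corrcoef(w.T)
    return np.nan_to_num(c)


def weight_cross_correlation(
    weights: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> WeightCorrMatrix:
    """Cross-frequency correlation of weight assignments across models.

    Cell (i, j), i != j, is the correlation over models between the
    weights at features i and j.  The null shuffles each model's
    frequency labels independently ``n_boot`` times; the per-cell
    two-sided p is the add-one fraction of null magnitudes at least as
    large as observed.  The diagonal is non-data; for display it is
    imputed as the mean of the adjacent off-diagonal cells.
    """
    w = np.atleast_2d(np.asarray(weights, dtype=float))
    n_models, f = w.shape
    if n_models < 10:
        raise ValueError("need at least 10 models for stable weight correlations")
    rng = np.random.default_rng(seed)
    obs = _offdiag_corr(w)
    count = np.zeros((f, f))
    for _ in range(n_boot):
        null = _offdiag_corr(rng.permuted(w, axis=1))
        count += np.abs(null) >= np.abs(obs)
    p = (count + 1.0) / (n_boot + 1.0)

    display = obs.copy()
    for i in range(f):
        adj = []
        if i > 0:
            adj.append(obs[i, i - 1])
        if i < f - 1:
            adj.append(obs[i, i + 1])
        display[i, i] = float(np.mean(adj))
    off = obs.copy()
    np.fill_diagonal(off, np.nan)
    mean_abs = np.nanmean(np.abs(off), axis=1)
    return WeightCorrMatrix(
        corr=obs, p=p, display=display, mean_abs_off_diag=mean_abs, n_boot=n_boot
    )


def bh_correct(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR control.

    Returns ``(reject, adjusted)``; adjusted p-values are monotone
    non-decreasing in rank and capped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool), np.zeros(0)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    thresh = q * np.arange(1, m + 1) / m
    passing = np.where(ranked <= thresh)[0]
    reject = np.zeros(m, dtype=bool)
    if passing.size:
        reject[order[: passing[-1] + 1]] = True
    adj = np.minimum.accumulate((ranked * m / np.arange(1, m + 1))[::-1])[::-1]
    adjusted = np.empty(m)
    adjusted[order] = np.minimum(adj, 1.0)
    return reject, adjusted


def rank_tests(
    a,
    b,
    paired: bool = False,
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Mann-Whitney U (unpaired) or Wilcoxon signed-rank (paired).

    Midrank tie handling; paired zero differences are dropped, and a
    fully-zero paired difference returns (0, 1) by convention.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(a.size, b.size) < 3:
        raise ValueError("rank tests need at least 3 observations per sample")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal-length samples")
        d = a - b
        d = d[d != 0.0]
        if d.size == 0:
            return 0.0, 1.0
        res = stats.wilcoxon(d, alternative=alternative, mode="auto")
    else:
        res = stats.mannwhitneyu(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
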