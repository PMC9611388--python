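"""Monte-Carlo resampling tests.

Two one-tailed engines built from the same primitive — a difference of
means ranked inside a resampled null — plus an exhaustive-enumeration
oracle for the permutation engine and a classical one-way ANOVA with Tukey
pairwise comparisons.

Both engines use the same "rank of the first sorted value strictly greater
than the statistic" rule:

* independent-samples permutation test: statistic v0 = mean(A) − mean(B);
  the pooled sample is randomly re-split N times into groups of the
  original sizes, the null differences are sorted ascending, and
  p = 1 − location/N where ``location`` is the 1-based rank of the first
  null value strictly greater than v0.  With G = #{null > v0} this is
  p = (G − 1)/N; when G = 0 the rank is undefined and p := 0 (the limit of
  the formula).  An optional conservative floor of 1/(N+1) is available.
* paired bootstrap test: the paired differences P = C − D are resampled
  with replacement N times; the resampled means are sorted ascending and
  p′ = index/N with ``index`` the 1-based rank of the first mean strictly
  greater than zero, i.e. p′ = (N − G + 1)/N with G = #{means > 0}; when
  G = 0 (no resampled mean exceeds zero, e.g. C ≡ D) p′ := 1.

Small p is evidence against H0: mean(first) ≤ mean(second) in both cases.
All randomness flows from the explicit ``seed`` argument; no global state.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

__all__ = [
    "ResamplingResult", "permutation_test_independent", "permutation_test_exhaustive",
    "bootstrap_paired_test", "anova_one_way", "type_i_error_rate",
]


@dataclass
class ResamplingResult:
    """A test statistic, its resampled null, and the rank-based p-value."""

    statistic_v0: float
    null_values: np.ndarray       # sorted ascending
    n_resamples: int
    p_value: float
    location_or_index: int | None  # 1-based rank used by the p formula
    seed: int | None
    method: str


def _count_strictly_greater(values: np.ndarray, threshold: float) -> int:
    """#{values strictly greater than threshold}, with an ulp-scale guard.

    Resampled statistics that recreate the observed grouping can differ from
    the observed statistic by a few ulp depending on summation order; both
    engines must resolve such ties identically (as not-greater) or the
    Monte-Carlo and exhaustive p-values drift apart on tied data.
    """
    eps = 1e-9 * (1.0 + abs(threshold))
    return int(np.sum(values > threshold + eps))


def _as_sample(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    return arr


def permutation_test_independent(samp_a, samp_b, n_resamples: int = 10_000,
                                 seed: int | None = None,
                                 conservative_floor: bool = False) -> ResamplingResult:
    """One-tailed Monte-Carlo permutation test of mean(A) > mean(B).

    H0: mean(A) ≤ mean(B).  Each resample pools A∪B and randomly splits it
    into groups of the original sizes.
    """
    a = _as_sample(samp_a, "sampA")
    b = _as_sample(samp_b, "sampB")
    v0 = a.mean() - b.mean()
    pooled = np.concatenate([a, b])
    rng = np.random.default_rng(seed)
    # vectorized random splits: argsort of uniforms = uniform permutation
    order = np.argsort(rng.random((n_resamples, pooled.size)), axis=1)
    shuffled = pooled[order]
    null = shuffled[:, : a.size].mean(axis=1) - shuffled[:, a.size:].mean(axis=1)
    null.sort()
    greater = _count_strictly_greater(null, v0)
    if greater == 0:
        location = None
        p = 1.0 / (n_resamples + 1) if conservative_floor else 0.0
    else:
        location = n_resamples - greater + 1
        p = 1.0 - location / n_resamples
    return ResamplingResult(float(v0), null, n_resamples, float(p), location,
                            seed, "permutation_independent")


def permutation_test_exhaustive(samp_a, samp_b,
                                max_splits: int = 1_000_000) -> ResamplingResult:
    """Enumerate every split of the pooled sample (oracle for the MC engine).

    p = #{splits with mean difference strictly greater than v0} / #splits.
    """
    a = _as_sample(samp_a, "sampA")
    b = _as_sample(samp_b, "sampB")
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    total = comb(n, na)
    if total > max_splits:
        raise ValueError(f"{total} splits exceed the enumeration bound {max_splits}")
    v0 = a.mean() - b.mean()
    nb = n - na
    s_all = pooled.sum()
    diffs = np.empty(total)
    for i, idx in enumerate(combinations(range(n), na)):
        sa = pooled[list(idx)].sum()
        diffs[i] = sa / na - (s_all - sa) / nb
    diffs.sort()
    greater = _count_strictly_greater(diffs, v0)
    return ResamplingResult(float(v0), diffs, total, greater / total,
                            total - greater + 1 if greater else None,
                            None, "exhaustive")


def bootstrap_paired_test(samp_c, samp_d, n_resamples: int = 10_000,
                          seed: int | None = None) -> ResamplingResult:
    """One-tailed paired bootstrap test of mean(C) > mean(D).

    H0: mean(C) ≤ mean(D).  Resamples the paired differences P = C − D with
    replacement and ranks zero inside the distribution of resampled means.
    """
    c = _as_sample(samp_c, "sampC")
    d = _as_sample(samp_d, "sampD")
    if c.size != d.size:
        raise ValueError(f"paired samples differ in length ({c.size} vs {d.size})")
    p_diff = c - d
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, p_diff.size, size=(n_resamples, p_diff.size))
    means = p_diff[idx].mean(axis=1)
    means.sort()
    greater = _count_strictly_greater(means, 0.0)
    if greater == 0:
        index = None
        p = 1.0
    else:
        index = n_resamples - greater + 1
        p = index / n_resamples
    return ResamplingResult(float(p_diff.mean()), means, n_resamples, float(p),
                            index, seed, "bootstrap_paired")


def bootstrap_paired_pvalues(p_diff: np.ndarray, n_resamples: int,
                             rng: np.random.Generator) -> np.ndarray:
    """Vectorized paired-bootstrap p′ for many tests sharing a subject axis.

    ``p_diff`` is (n_tests, n_subjects); returns p′ per test using the same
    strict-rank rule as :func:`bootstrap_paired_test`.
    """
    n_tests, n_sub = p_diff.shape
    idx = rng.integers(0, n_sub, size=(n_tests, n_resamples, n_sub))
    means = np.take_along_axis(p_diff[:, None, :], idx, axis=2).mean(axis=2)
    greater = (means > 0.0).sum(axis=1)
    p = (n_resamples - greater + 1) / n_resamples
    p[greater == 0] = 1.0
    return p


def anova_one_way(groups: list[np.ndarray], alpha: float = 0.05):
    """Classical one-way ANOVA plus Tukey-HSD pairwise flags.

    Returns ``(F, p, pairwise)`` where ``pairwise`` maps (i, j) group-index
    pairs to a significance flag at ``alpha``.
    """
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("need at least 2 groups with at least 2 values each")
    f_stat, p = sps.f_oneway(*groups)
    from statsmodels.stats.multicomp import pairwise_tukeyhsd
    values = np.concatenate(groups)
    labels = np.concatenate([np.full(g.size, i) for i, g in enumerate(groups)])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pairwise = {}
    for (i, j), reject in zip(combinations(range(len(groups)), 2), tukey.reject):
        pairwise[(i, j)] = bool(reject)
    return float(f_stat), float(p), pairwise


def type_i_error_rate(n_simulations: int = 1000, sample_size: int = 19,
                      alpha: float = 0.05, n_resamples: int = 2000,
                      seed: int = 0) -> float:
    """Empirical rejection rate of the permutation test under H0.

    Simulates independent N(0,1) samples and counts p ≤ alpha; used as a
    calibration self-test.
    """
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_simulations):
        a = rng.standard_normal(sample_size)
        b = rng.standard_normal(sample_size)
        res = permutation_test_independent(
            a, b, n_resamples=n_resamples, seed=int(rng.integers(2**31)))
        rejections += res.p_value <= alpha
    return rejections / n_simulations
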