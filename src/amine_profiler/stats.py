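"""Group-comparison statistics for descriptor distributions.

Linear quantities (SASA, shell densities) are compared with pairwise
two-sided Wilcoxon rank-sum tests, Benjamini-Hochberg adjusted within one
family per figure-panel analogue. Circular quantities (glycosidic chi) use
Watson's two-sample U^2 homogeneity test, whose tabulated critical values
yield a p-value *range* rather than a point p (so no FDR adjustment is
applied there); an exact permutation p-value is available as the oracle.
"""

from __future__ import annotations

import importlib.resources
import itertools
import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .errors import ContractViolation

__all__ = [
    "TestResult",
    "SmallSampleWarning",
    "pairwise_wilcoxon_fdr",
    "watson_u2_statistic",
    "watsons_u2",
    "benjamini_hochberg",
]


class SmallSampleWarning(UserWarning):
    """Sample too small for tabulated critical values."""


@dataclass
class TestResult:
    group_a: str
    group_b: str
    statistic: float
    p: float | None = None
    p_adj: float | None = None
    p_range: tuple[float, float] | None = None
    family: str = "default"
    method: str = ""


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (monotone step-up)."""
    p = np.asarray(pvalues, float)
    return multipletests(p, method="fdr_bh")[1]


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided rank-sum p: exact enumeration for small tie-free samples,
    tie-corrected normal approximation otherwise."""
    ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
    if not ties and max(len(x), len(y)) <= 50:
        res = mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def pairwise_wilcoxon_fdr(groups: dict, family: str = "default"
                          ) -> list[TestResult]:
    """All pairwise Wilcoxon rank-sum tests with BH adjustment.

    ``groups`` maps label -> 1-D sample. The BH family is the full set of
    pairwise comparisons passed in one call.
    """
    if len(groups) < 2:
        raise ContractViolation("need at least two groups")
    clean = {}
    for name, values in groups.items():
        v = np.asarray(values, float)
        if v.size == 0:
            raise ContractViolation(f"group {name!r} is empty")
        clean[name] = v
    results = []
    for a, b in itertools.combinations(sorted(clean), 2):
        stat, p = _rank_sum_p(clean[a], clean[b])
        results.append(TestResult(group_a=a, group_b=b, statistic=stat, p=p,
                                  family=family, method="wilcoxon-rank-sum"))
    adj = benjamini_hochberg([r.p for r in results])
    for r, pa in zip(results, adj):
        r.p_adj = float(pa)
    return results


def watson_u2_statistic(sample1, sample2) -> float:
    """Two-sample Watson U^2 on circular data (degrees, any branch).

    Tie-aware formulation over the pooled unique support:
    U^2 = (n1 n2 / N^2) [ sum_k w_k d_k^2 - (sum_k w_k d_k)^2 / N ]
    with d_k the running difference of the two empirical CDFs and w_k the
    pooled multiplicity at the k-th unique value. Invariant under a common
    rotation of both samples.
    """
    a = np.sort(np.asarray(sample1, float) % 360.0)
    b = np.sort(np.asarray(sample2, float) % 360.0)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ContractViolation("empty sample")
    n = n1 + n2
    support = np.unique(np.concatenate([a, b]))
    c1 = np.searchsorted(a, support, side="right")
    c2 = np.searchsorted(b, support, side="right")
    d = c1 / n1 - c2 / n2
    w = np.diff(np.concatenate([[0], np.searchsorted(
        np.sort(np.concatenate([a, b])), support, side="right")]))
    u2 = (n1 * n2) / n**2 * (np.sum(w * d**2) - np.sum(w * d) ** 2 / n)
    return float(u2)


@lru_cache(maxsize=1)
def _critical_table() -> list[tuple[float, float]]:
    rows = []
    with importlib.resources.files("amine_profiler.data").joinpath(
            "watson_u2_critical.csv").open() as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#") or line.startswith("alpha"):
                continue
            alpha, crit = line.split(",")
            rows.append((float(alpha), float(crit)))
    return sorted(rows, reverse=True)  # descending alpha


def _bracket(u2: float) -> tuple[float, float]:
    table = _critical_table()  # descending alpha = ascending critical
    lo, hi = 0.0, 1.0
    for alpha, crit in table:
        if u2 >= crit:
            hi = min(hi, alpha)
        else:
            lo = max(lo, alpha)
    if hi < lo:  # numerically impossible with a monotone table
        lo, hi = hi, lo
    return (lo, hi)


def watsons_u2(sample1, sample2, family: str = "default",
               permutation: bool = False, n_permutations: int = 999,
               seed: int | None = None) -> TestResult:
    """Watson's two-sample U^2 with a tabulated p-value range.

    Samples are angles in degrees (mapped to [0, 360)). With fewer than 8
    observations per group the tabulated range is unreliable; a
    :class:`SmallSampleWarning` is issued and the permutation p-value is
    computed regardless. ``permutation=True`` adds an exact Monte-Carlo p
    (reassignment of pooled angles, seeded).
    """
    a = np.asarray(sample1, float)
    b = np.asarray(sample2, float)
    u2 = watson_u2_statistic(a, b)
    small = min(len(a), len(b)) < 8
    if small:
        warnings.warn("sample smaller than 8; using permutation p-value",
                      SmallSampleWarning, stacklevel=2)
    result = TestResult(group_a="sample1", group_b="sample2", statistic=u2,
                        p_range=_bracket(u2), family=family,
                        method="watson-u2")
    if permutation or small:
        rng = np.random.default_rng(seed)
        pooled = np.concatenate([a, b])
        n1 = len(a)
        count = 0
        for _ in range(n_permutations):
            perm = rng.permutation(pooled)
            if watson_u2_statistic(perm[:n1], perm[n1:]) >= u2 - 1e-12:
                count += 1
        result.p = (1 + count) / (n_permutations + 1)
        result.method = "watson-u2-permutation"
    return result
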