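"""Rank statistics and the per-complex permutation test.

Wraps the standard rank statistics (Spearman's rho, Mann-Whitney/Wilcoxon
rank-sum) and adds the two analysis-specific procedures: the maximum SRCC
attainable against a binary essentiality vector (a ceiling imposed by the
mass of tied labels), and a per-complex permutation test asking whether,
within complexes containing both essential and non-essential interacting
proteins, the essential members have higher mean intracomplex degree more
often than label shuffling would produce.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats as sps

from .catalog import ModuleSet
from .network_io import EssentialityMap, Interactome

__all__ = [
    "CorrelationResult",
    "RankSumResult",
    "PermutationTestResult",
    "spearman_rcc",
    "max_attainable_srcc",
    "partial_spearman",
    "wilcoxon_rank_sum",
    "per_complex_permutation_test",
]


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int
    controlled_for: Optional[str] = None

    @property
    def defined(self) -> bool:
        return not math.isnan(self.rho)


@dataclass(frozen=True)
class RankSumResult:
    statistic: float
    p_value: float
    method: str  # "exact" | "asymptotic"


@dataclass(frozen=True)
class PermutationTestResult:
    n_complexes_tested: int
    n_higher_essential: int
    empirical_p: float
    n_permutations: int
    scheme: str = "within_complex"

    @property
    def empty(self) -> bool:
        return self.n_complexes_tested == 0


def _as_float(x) -> np.ndarray:
    return np.asarray(x, dtype=float)


def spearman_rcc(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Spearman rank correlation (average ranks for ties).

    A constant input vector leaves rho undefined (NaN), flagged through
    :attr:`CorrelationResult.defined`.
    """
    x, y = _as_float(x), _as_float(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 2 or np.ptp(x) == 0 or np.ptp(y) == 0:
        return CorrelationResult(float("nan"), float("nan"), n)
    rho, p = sps.spearmanr(x, y)
    return CorrelationResult(float(rho), float(p), n)


def max_attainable_srcc(essential: Sequence[int], degrees: Sequence[float]) -> float:
    """Ceiling on SRCC(essentiality, degree) for a binary label vector.

    The labels are rearranged so all essential proteins occupy the highest
    degree ranks; degree ties keep their tied ranks, so the result depends
    only on the degree rank vector and the number of essentials.
    """
    essential, degrees = _as_float(essential), _as_float(degrees)
    if essential.shape != degrees.shape:
        raise ValueError("essential and degrees must have equal length")
    if np.ptp(degrees) == 0 or np.ptp(essential) == 0:
        return float("nan")
    k = int(round(essential.sum()))
    order = np.argsort(-degrees, kind="stable")
    best = np.zeros(len(degrees))
    best[order[:k]] = 1.0
    return spearman_rcc(best, degrees).rho


def partial_spearman(
    x: Sequence[float],
    y: Sequence[float],
    z: Sequence[float],
    controlled_for: str = "z",
) -> CorrelationResult:
    """First-order partial Spearman correlation of x and y given z.

    All three vectors are rank-transformed (average ties), then
    rho_xy.z = (r_xy - r_xz r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)).
    The p-value uses the t approximation with n - 3 degrees of freedom.
    Undefined (NaN) when either control correlation is +-1.
    """
    x, y, z = _as_float(x), _as_float(y), _as_float(z)
    if not (x.shape == y.shape == z.shape):
        raise ValueError("x, y and z must have equal length")
    n = len(x)
    if n < 4:
        raise ValueError("partial correlation needs n >= 4")
    if np.ptp(x) == 0 or np.ptp(y) == 0 or np.ptp(z) == 0:
        return CorrelationResult(float("nan"), float("nan"), n, controlled_for)
    rx, ry, rz = (sps.rankdata(v, method="average") for v in (x, y, z))
    r_xy = np.corrcoef(rx, ry)[0, 1]
    r_xz = np.corrcoef(rx, rz)[0, 1]
    r_yz = np.corrcoef(ry, rz)[0, 1]
    if abs(r_xz) >= 1.0 - 1e-12 or abs(r_yz) >= 1.0 - 1e-12:
        # perfect control correlation: partial correlation is undefined
        return CorrelationResult(float("nan"), float("nan"), n, controlled_for)
    denom = (1.0 - r_xz**2) * (1.0 - r_yz**2)
    rho = (r_xy - r_xz * r_yz) / math.sqrt(denom)
    rho = min(1.0, max(-1.0, rho))
    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 3) / (1.0 - rho**2))
        p = 2.0 * sps.t.sf(abs(t), df=n - 3)
    return CorrelationResult(float(rho), float(p), n, controlled_for)


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float], exact_limit: int = 20
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) test.

    The exact null is used for combined n <= ``exact_limit`` without ties;
    otherwise the tie-corrected normal approximation.
    """
    a, b = _as_float(a), _as_float(b)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (len(pooled) <= exact_limit and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return RankSumResult(float(res.statistic), float(res.pvalue), method)


def _complex_eligibility(
    net: Interactome,
    complexes: ModuleSet,
    ess: EssentialityMap,
    min_essential: int,
    min_nonessential: int,
):
    """Per eligible complex: (within-complex degrees, n essential members).

    Membership is restricted to proteins present in the network with at
    least one intracomplex interaction.
    """
    graph = net.graph
    eligible = []
    for cx in complexes:
        members = [p for p in sorted(cx.members) if p in graph]
        degs, labels = [], []
        member_set = cx.members
        for p in members:
            d = sum(1 for q in graph.neighbors(p) if q in member_set)
            if d >= 1:
                degs.append(d)
                labels.append(ess.is_essential(p))
        n_ess = sum(labels)
        n_non = len(labels) - n_ess
        if n_ess >= min_essential and n_non >= min_nonessential:
            eligible.append(
                (
                    cx.id,
                    np.asarray(degs, dtype=float),
                    np.asarray(labels, dtype=bool),
                )
            )
    return eligible


def per_complex_permutation_test(
    net: Interactome,
    complexes: ModuleSet,
    ess: EssentialityMap,
    min_essential: int = 2,
    min_nonessential: int = 2,
    n_perm: int = 10_000,
    seed: Optional[int] = None,
    scheme: str = "within_complex",
) -> PermutationTestResult:
    """Permutation test for higher essential intracomplex degree.

    A complex is tested if it has at least ``min_essential`` essential and
    ``min_nonessential`` non-essential members, each with at least one
    intracomplex interaction.  The statistic is the number of tested
    complexes where the essential members' mean within-complex degree
    strictly exceeds the non-essential members'.  Under the default
    ``within_complex`` null, essentiality labels are shuffled independently
    within each tested complex, preserving its essential count; the
    ``global`` scheme shuffles the pooled labels across all tested
    complexes instead.  The empirical p-value uses the (count + 1) /
    (n_perm + 1) correction, so it is never zero.
    """
    eligible = _complex_eligibility(net, complexes, ess, min_essential, min_nonessential)
    if not eligible:
        return PermutationTestResult(0, 0, float("nan"), n_perm, scheme)
    rng = np.random.default_rng(seed)

    observed = 0
    for _, degs, labels in eligible:
        if degs[labels].mean() > degs[~labels].mean():
            observed += 1

    stat = np.zeros(n_perm, dtype=np.int64)
    if scheme == "within_complex":
        for _, degs, labels in eligible:
            m, k = len(degs), int(labels.sum())
            total = degs.sum()
            # k random positions per permutation via argpartition of noise
            noise = rng.random((n_perm, m))
            idx = np.argpartition(noise, k - 1, axis=1)[:, :k]
            ess_sum = degs[idx].sum(axis=1)
            mean_ess = ess_sum / k
            mean_non = (total - ess_sum) / (m - k)
            stat += (mean_ess > mean_non).astype(np.int64)
    elif scheme == "global":
        pooled = np.concatenate([labels for _, _, labels in eligible])
        sizes = [len(labels) for _, _, labels in eligible]
        offsets = np.cumsum([0] + sizes)
        for r in range(n_perm):
            perm = rng.permutation(pooled)
            count = 0
            for i, (_, degs, _) in enumerate(eligible):
                lab = perm[offsets[i] : offsets[i + 1]]
                k = lab.sum()
                if 0 < k < len(lab):
                    if degs[lab].mean() > degs[~lab].mean():
                        count += 1
            stat[r] = count
    else:
        raise ValueError(f"unknown permutation scheme {scheme!r}")

    empirical_p = (int((stat >= observed).sum()) + 1) / (n_perm + 1)
    return PermutationTestResult(len(eligible), observed, empirical_p, n_perm, scheme)
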