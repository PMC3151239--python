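"""Factor analyses, transfer dating, and rate-of-displacement statistics.

Ancestral trait states are simple clade summaries, exactly as the
analyses they reproduce: the GC% or genome size of the hypothetical
ancestor at an internal branch is the unweighted mean over the extant
species of its clade, and its habitat profile is the clade's summed
observation counts in six habitat categories (Aquatic, Extreme,
Foodstuff, Internal, Agricultural runoff, Terrestrial) converted to
proportions.  No model-based ancestral reconstruction is attempted.

Dating uses the transfer itself as a time anchor: donor and acceptor
coexisted, so on a clock-like tree the path lengths from their last
common ancestor to the midpoint of each branch -- widened by half the
branch length on each side, since the transfer may have happened anywhere
along either branch -- must overlap.

The rate analysis regresses the number of displacements accepted into a
clade on the clade's total branch length (evolutionary opportunity), and
interrogates linearity with a quadratic-term F-test and a Wald-Wolfowitz
runs test on residual signs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import treecore
from .scan import OGDCall
from .treecore import BranchRef, Tree, branch_midpoint

__all__ = [
    "HABITAT_CATEGORIES",
    "ancestral_mean",
    "habitat_profile",
    "habitat_distance",
    "donor_acceptor_distance",
    "all_pairs_distances",
    "ks_two_sample",
    "wilcoxon_rank_sum",
    "pearson_correlation",
    "runs_test",
    "DatingInterval",
    "dating_intervals",
    "RatePoint",
    "rate_points",
    "rate_linearity",
    "RateLinearity",
]

HABITAT_CATEGORIES = [
    "hab_aquatic",
    "hab_extreme",
    "hab_foodstuff",
    "hab_internal",
    "hab_runoff",
    "hab_terrestrial",
]


# ---------------------------------------------------------------------------
# Ancestral trait summaries
# ---------------------------------------------------------------------------


def ancestral_mean(tree: Tree, branch: BranchRef, trait: Mapping[str, float]) -> float:
    """Unweighted mean of a trait over the branch's clade (a leaf's own value)."""
    leaves = sorted(branch.clade)
    missing = [l for l in leaves if l not in trait or pd.isna(trait[l])]
    if missing:
        raise ValueError(f"trait undefined for taxa: {missing}")
    return float(np.mean([trait[l] for l in leaves]))


def habitat_profile(
    tree: Tree, branch: BranchRef, habitat: pd.DataFrame
) -> np.ndarray:
    """Summed habitat counts over the clade, as proportions of total observations."""
    leaves = sorted(branch.clade)
    missing = [l for l in leaves if l not in habitat.index]
    if missing:
        raise ValueError(f"habitat counts undefined for taxa: {missing}")
    counts = habitat.loc[leaves, HABITAT_CATEGORIES].to_numpy(dtype=float).sum(axis=0)
    total = counts.sum()
    if total <= 0:
        raise ValueError(f"clade {leaves} has zero habitat observations")
    return counts / total


def habitat_distance(p: np.ndarray, q: np.ndarray) -> float:
    """Euclidean distance between two habitat profiles; range [0, sqrt(2)]."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    for vec in (p, q):
        if abs(vec.sum() - 1.0) > 1e-8 or np.any(vec < -1e-12):
            raise ValueError("habitat profiles must be normalised proportions")
    return float(np.linalg.norm(p - q))


# ---------------------------------------------------------------------------
# Evolutionary distances
# ---------------------------------------------------------------------------


def donor_acceptor_distance(tree: Tree, call: OGDCall) -> float:
    """Path length between donor and acceptor branch midpoints on the full tree."""
    return treecore.path_length(
        tree, branch_midpoint(tree, call.donor), branch_midpoint(tree, call.recipient)
    )


def all_pairs_distances(tree: Tree) -> np.ndarray:
    """Null distribution: midpoint distances of all unordered, non-nested branch pairs.

    Nested (ancestral) pairs are excluded so the null is drawn from the same
    support as the observed calls, which have ancestral donors filtered out.
    """
    branches = tree.branches()
    out = []
    for a, b in combinations(branches, 2):
        if a.clade < b.clade or b.clade < a.clade:
            continue
        out.append(
            treecore.path_length(tree, branch_midpoint(tree, a), branch_midpoint(tree, b))
        )
    return np.asarray(out)


# ---------------------------------------------------------------------------
# Statistical tests
# ---------------------------------------------------------------------------


def ks_two_sample(observed: Sequence[float], null: Sequence[float]) -> Tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov test: (D, asymptotic p)."""
    observed = np.asarray(observed, dtype=float)
    null = np.asarray(null, dtype=float)
    if observed.size == 0 or null.size == 0:
        raise ValueError("both samples must be nonempty")
    d = float(sps.ks_2samp(observed, null, method="asymp").statistic)
    # classical Kolmogorov limiting distribution (R's ks.test, exact=FALSE)
    en = math.sqrt(observed.size * null.size / (observed.size + null.size))
    p = float(sps.kstwobign.sf(en * d))
    return d, min(1.0, p)


def wilcoxon_rank_sum(
    x: Sequence[float], y: Sequence[float], continuity: bool = True
) -> Tuple[float, float]:
    """Wilcoxon rank-sum / Mann-Whitney test, two-sided.

    Returns (W, p) with W the rank-sum statistic of ``x`` (the U statistic,
    matching R's ``wilcox.test``).  Exact enumeration is used when
    ``len(x)*len(y) <= 400`` and there are no ties; otherwise the normal
    approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    exact = (x.size * y.size <= 400) and not has_ties
    res = sps.mannwhitneyu(
        x,
        y,
        alternative="two-sided",
        use_continuity=continuity,
        method="exact" if exact else "asymptotic",
    )
    return float(res.statistic), float(res.pvalue)


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Pearson correlation with its t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def _runs_exact_tail(n1: int, n2: int, r_obs: int) -> Tuple[float, float]:
    """Exact P(R <= r_obs) and P(R >= r_obs) for the Wald-Wolfowitz runs count."""
    total = math.comb(n1 + n2, n1)

    def prob(r: int) -> float:
        if r < 2 or r > n1 + n2:
            return 0.0
        if r % 2 == 0:
            k = r // 2
            ways = 2 * math.comb(n1 - 1, k - 1) * math.comb(n2 - 1, k - 1)
        else:
            k = (r - 1) // 2
            ways = math.comb(n1 - 1, k - 1) * math.comb(n2 - 1, k) + math.comb(
                n1 - 1, k
            ) * math.comb(n2 - 1, k - 1)
        return ways / total

    lo = sum(prob(r) for r in range(2, r_obs + 1))
    hi = sum(prob(r) for r in range(r_obs, n1 + n2 + 1))
    return lo, hi


def runs_test(signs: Sequence[int], exact_max: int = 20) -> Tuple[int, float]:
    """Wald-Wolfowitz runs test on a +/- sequence; (runs count, two-sided p).

    Exact tail probabilities are used for sequences up to ``exact_max``
    elements, the normal approximation with continuity correction beyond.
    Sequences with fewer than two elements of either sign are degenerate and
    report p = 1.
    """
    signs = [int(np.sign(s)) for s in signs if s != 0]
    n1 = sum(1 for s in signs if s > 0)
    n2 = sum(1 for s in signs if s < 0)
    n = n1 + n2
    if n1 == 0 or n2 == 0:
        return (1 if n else 0), 1.0
    runs = 1 + sum(1 for i in range(1, n) if signs[i] != signs[i - 1])
    if n <= exact_max:
        lo, hi = _runs_exact_tail(n1, n2, runs)
        p = min(1.0, 2.0 * min(lo, hi))
        return runs, p
    mu = 1.0 + 2.0 * n1 * n2 / n
    var = 2.0 * n1 * n2 * (2.0 * n1 * n2 - n) / (n**2 * (n - 1.0))
    if var <= 0:
        return runs, 1.0
    z = (runs - mu + (0.5 if runs < mu else -0.5)) / math.sqrt(var)
    return runs, float(min(1.0, 2.0 * sps.norm.sf(abs(z))))


# ---------------------------------------------------------------------------
# Dating
# ---------------------------------------------------------------------------


@dataclass
class DatingInterval:
    """Per call: LCA-to-midpoint distances with branch-length half-widths."""

    call: OGDCall
    lca_node: Optional[int]
    donor_midpoint_distance: float
    acceptor_midpoint_distance: float
    donor_branch_length: float
    acceptor_branch_length: float
    overlaps: bool


def dating_intervals(tree: Tree, calls: Sequence[OGDCall]) -> List[DatingInterval]:
    """Date each call by its donor/acceptor distances to their common ancestor.

    Each branch contributes the interval (distance to its midpoint) +/- half
    its length; under a strict clock the two intervals must intersect.
    Nested donor/acceptor pairs are rejected -- they should have been removed
    by the ancestral-donor filter.
    """
    if not tree.is_rooted:
        raise ValueError("dating requires a rooted tree")
    out = []
    for call in calls:
        node, nested = treecore.lca(tree, call.donor, call.recipient)
        if nested:
            raise ValueError(
                f"nested donor/acceptor in family {call.family!r}; filter ancestral donors first"
            )
        anchor = treecore.lca_point(tree, node)
        d_don = treecore.path_length(tree, anchor, branch_midpoint(tree, call.donor))
        d_acc = treecore.path_length(tree, anchor, branch_midpoint(tree, call.recipient))
        len_don = tree.branch_length(call.donor)
        len_acc = tree.branch_length(call.recipient)
        lo_d, hi_d = d_don - len_don / 2, d_don + len_don / 2
        lo_a, hi_a = d_acc - len_acc / 2, d_acc + len_acc / 2
        overlaps = (lo_d <= hi_a + 1e-12) and (lo_a <= hi_d + 1e-12)
        out.append(
            DatingInterval(
                call=call,
                lca_node=node,
                donor_midpoint_distance=d_don,
                acceptor_midpoint_distance=d_acc,
                donor_branch_length=len_don,
                acceptor_branch_length=len_acc,
                overlaps=overlaps,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Rate of displacement
# ---------------------------------------------------------------------------


@dataclass
class RatePoint:
    clade_id: str
    total_branch_length: float
    ogd_count: int
    independent: bool


def rate_points(
    tree: Tree,
    calls: Sequence[OGDCall],
    clades: Optional[Mapping[str, FrozenSet[str]]] = None,
) -> List[RatePoint]:
    """Evolutionary opportunity vs displacement count, per branch or named clade.

    Without ``clades``, every branch of the rooted tree yields a point
    (opportunity = total branch length inside its clade; count = calls whose
    recipient lies within the clade).  With ``clades`` (name -> leaf set),
    only those branches are used and flagged independent.
    """
    if not tree.is_rooted:
        raise ValueError("rate analysis requires a rooted tree")
    if clades is None:
        chosen = [(min(b.clade), b, False) for b in tree.branches()]
    else:
        chosen = []
        for name, leaves in clades.items():
            ref = BranchRef(frozenset(leaves))
            if not tree.has_branch(ref):
                raise KeyError(f"clade {name!r} does not match any branch of the tree")
            chosen.append((name, ref, True))
    out = []
    for name, branch, independent in chosen:
        count = sum(1 for c in calls if c.recipient.clade <= branch.clade)
        out.append(
            RatePoint(
                clade_id=str(name),
                total_branch_length=treecore.clade_total_length(tree, branch),
                ogd_count=count,
                independent=independent,
            )
        )
    return out


@dataclass
class RateLinearity:
    slope: float
    intercept: float
    fit_p: float  # slope t-test
    linearity_p: float  # quadratic-term F-test (lack-of-fit proxy)
    runs_p: float  # Wald-Wolfowitz runs test on residual signs
    degenerate: bool = False  # exact collinearity: runs test uninformative


def rate_linearity(points: Sequence[RatePoint]) -> RateLinearity:
    """Least-squares fit of count ~ opportunity, with linearity diagnostics."""
    if len(points) < 4:
        raise ValueError("need at least 4 rate points")
    x = np.array([p.total_branch_length for p in points], dtype=float)
    y = np.array([p.ogd_count for p in points], dtype=float)
    if np.all(x == x[0]):
        raise ValueError("all clade lengths identical; rate fit undefined")
    import statsmodels.api as sm

    linear = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = linear.params
    fit_p = float(linear.pvalues[1])
    quad = sm.OLS(y, sm.add_constant(np.column_stack([x, x**2]))).fit()
    # F-test of the quadratic term = two-sided t-test on its coefficient
    linearity_p = float(quad.pvalues[2]) if quad.df_resid > 0 else 1.0
    resid = np.asarray(linear.resid)[np.argsort(x, kind="stable")]  # runs along x
    degenerate = bool(np.allclose(resid, 0.0, atol=1e-10))
    if degenerate:
        runs_p = 1.0
    else:
        _runs, runs_p = runs_test(np.sign(resid)[np.abs(resid) > 1e-12].astype(int))
    return RateLinearity(
        slope=float(slope),
        intercept=float(intercept),
        fit_p=fit_p,
        linearity_p=linearity_p,
        runs_p=runs_p,
        degenerate=degenerate,
    )
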