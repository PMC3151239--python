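"""The displacement scan: placement evaluation, calling, filtering, grid exploration.

For every branch of the rooted combined tree and a given gene family, the
clade the branch defines is pruned and re-attached at every possible
position of the residual tree (its own original attachment included).
Each candidate tree's sitewise log-likelihood feeds a RELL bootstrap that
yields expected likelihood weights over the whole candidate set.  A
putative displacement is called when some placement *other than the
original* carries at least ``elw_cutoff`` of the weight (default 0.65)
and lies at least ``distance_cutoff`` substitutions/site (default 0.40)
from the original attachment -- the distance guard keeps mere
phylogenetic uncertainty from being mistaken for a transfer.  The branch
that was assessed is the recipient; the branch hosting the best placement
is the donor.  Two filters then drop uninterpretable calls: reciprocal
pairs (X->Y and Y->X in one family, direction unknowable) and transfers
whose donor is ancestral to their recipient.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import treecore
from .elw import expected_likelihood_weights
from .likelihood import AlignmentMatrix, PlacementEngine
from .substmodel import (
    RateModel,
    SubstitutionModel,
    discrete_gamma,
    empirical_frequencies,
    jtt_model,
    uniform_rates,
)
from .treecore import BranchRef, Tree, TreePoint, insertion_points, prune_clade

__all__ = [
    "ScanConfig",
    "CandidatePlacement",
    "PlacementEvaluation",
    "OGDCall",
    "evaluate_branch",
    "call_ogds",
    "filter_reciprocal",
    "filter_ancestral_donor",
    "scan_family",
    "parameter_grid",
    "FamilyScan",
]


def _default_elw_grid() -> List[float]:
    return [round(0.55 + 0.05 * i, 2) for i in range(10)]  # 0.55 .. 1.00


def _default_distance_grid() -> List[float]:
    return [round(0.1 * i, 1) for i in range(1, 11)]  # 0.1 .. 1.0


@dataclass
class ScanConfig:
    """All knobs of the displacement scan.

    ``elw_cutoff`` must exceed 0.5: since weights sum to 1, at most one
    candidate can pass, which guarantees a unique call per (family, branch).
    """

    elw_cutoff: float = 0.65
    distance_cutoff: float = 0.40
    elw_grid: List[float] = field(default_factory=_default_elw_grid)
    distance_grid: List[float] = field(default_factory=_default_distance_grid)
    n_replicates: int = 1000
    seed: int = 0
    branch_length_mode: str = "local"  # "local" | "none"
    gamma_alpha: Optional[float] = None  # None = single rate (program-default scans)
    gamma_ncat: int = 4
    frequencies: str = "empirical"  # "empirical" (+F) | "model"
    inclusive_distance: bool = True  # >= cutoff; False for strict >
    insertion_position: str = "midpoint"
    optimize_gap: float = 30.0  # only refit candidates within this logL gap of the best

    def __post_init__(self) -> None:
        if not 0.5 < self.elw_cutoff <= 1.0:
            raise ValueError("elw_cutoff must be in (0.5, 1]")
        if self.distance_cutoff < 0:
            raise ValueError("distance_cutoff must be >= 0")
        if not self.elw_grid or not self.distance_grid:
            raise ValueError("grids must be nonempty")
        if self.branch_length_mode not in ("local", "none"):
            raise ValueError("branch_length_mode must be 'local' or 'none'")
        if self.frequencies not in ("empirical", "model"):
            raise ValueError("frequencies must be 'empirical' or 'model'")

    def rate_model(self) -> RateModel:
        if self.gamma_alpha is None:
            return uniform_rates()
        return discrete_gamma(self.gamma_alpha, self.gamma_ncat)

    def substitution_model(self, aln: Optional[AlignmentMatrix]) -> SubstitutionModel:
        if self.frequencies == "model" or aln is None:
            return jtt_model("model")
        return jtt_model(empirical_frequencies(aln))

    @classmethod
    def from_yaml(cls, path) -> "ScanConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)


@dataclass
class CandidatePlacement:
    """One insertion point: where, how likely, how far from the original spot."""

    point: TreePoint  # on the residual tree
    donor_branch: Optional[BranchRef]  # combined-tree branch holding the point
    site_logl: np.ndarray
    log_likelihood: float
    distance: float  # residual-tree path length from the original attachment
    is_original: bool
    elw: float = np.nan


@dataclass
class PlacementEvaluation:
    """All candidate placements for one pruned branch of one family."""

    family: str
    pruned_branch: BranchRef
    candidates: List[CandidatePlacement]
    uninformative: bool = False

    def original(self) -> CandidatePlacement:
        return next(c for c in self.candidates if c.is_original)

    def best_non_original(self) -> Optional[CandidatePlacement]:
        non_orig = [c for c in self.candidates if not c.is_original]
        if not non_orig:
            return None
        return max(non_orig, key=lambda c: c.elw)

    @property
    def elw_values(self) -> np.ndarray:
        return np.array([c.elw for c in self.candidates])


@dataclass
class OGDCall:
    """A called displacement: family, recipient branch, donor branch, support."""

    family: str
    recipient: BranchRef
    donor: BranchRef
    elw: float
    distance: float
    filtered_reason: str = ""


# ---------------------------------------------------------------------------


def _branch_seed(base_seed: int, family: str, branch: BranchRef) -> int:
    """Stable per-(family, branch) RELL seed, independent of execution order."""
    key = f"{base_seed}:{family}:{','.join(sorted(branch.clade))}"
    return zlib.crc32(key.encode()) % (2**31)


def _map_point_to_original_branch(
    tree: Tree, pruned: treecore.PrunedTree, point: TreePoint
) -> Optional[BranchRef]:
    """Combined-tree branch on which an insertion point lies.

    Residual node ids are inherited from the combined tree, so a residual
    branch maps to the original edge with the same endpoints; a point on the
    merged branch maps to whichever of the two pre-merge edges contains it.
    Returns None for the exact original attachment point (not a donor).
    """
    res = pruned.residual
    prox, dist, length = res._resolve(point.branch)
    junction = pruned.attachment_point
    if point.branch == junction.branch:
        # both offsets are measured from the same proximal endpoint
        off_junction = junction.offset
        if abs(point.offset - off_junction) <= treecore.LENGTH_TOL:
            return None  # the original position itself
        if point.offset < off_junction:
            # between prox and the old junction node
            a, b = prox, _old_junction_node(tree, pruned)
        else:
            a, b = _old_junction_node(tree, pruned), dist
    else:
        a, b = prox, dist
    for clade, (p, d, _l) in tree._branches.items():
        if {p, d} == {a, b}:
            return BranchRef(clade)
    raise KeyError("insertion point does not map to a combined-tree branch")


def _old_junction_node(tree: Tree, pruned: treecore.PrunedTree) -> int:
    """Node of the combined tree where the pruned clade was attached."""
    prox, _dist, _l = tree._resolve(pruned.pruned_branch)
    return prox


def evaluate_branch(
    tree: Tree,
    branch: BranchRef,
    aln: AlignmentMatrix,
    config: ScanConfig,
    family: str = "family",
    model: Optional[SubstitutionModel] = None,
    rates: Optional[RateModel] = None,
) -> PlacementEvaluation:
    """Evaluate every placement of one branch's clade for one gene family."""
    model = model if model is not None else config.substitution_model(aln)
    rates = rates if rates is not None else config.rate_model()
    pruned = prune_clade(tree, branch)
    engine = PlacementEngine(pruned, aln, model, rates)
    points = insertion_points(pruned, config.insertion_position)
    res = pruned.residual

    candidates: List[CandidatePlacement] = []
    for point in points:
        prox, dist, length = res._resolve(point.branch)
        d1, d2 = point.offset, length - point.offset
        stem = pruned.subtree.stem_length
        site_logl = engine.site_logl((prox, dist), d1, d2, stem)
        is_original = (
            point.branch == pruned.attachment_point.branch
            and abs(point.offset - pruned.attachment_point.offset) <= treecore.LENGTH_TOL
        )
        distance = treecore.path_length(res, pruned.attachment_point, point)
        donor = _map_point_to_original_branch(tree, pruned, point)
        candidates.append(
            CandidatePlacement(
                point=point,
                donor_branch=donor,
                site_logl=site_logl,
                log_likelihood=float(site_logl.sum()),
                distance=0.0 if is_original else distance,
                is_original=is_original,
            )
        )

    if config.branch_length_mode == "local":
        best = max(c.log_likelihood for c in candidates)
        for cand in candidates:
            if best - cand.log_likelihood > config.optimize_gap:
                continue
            prox, dist, length = res._resolve(cand.point.branch)
            site_logl, _params = engine.optimize_local(
                (prox, dist),
                cand.point.offset,
                length - cand.point.offset,
                pruned.subtree.stem_length,
            )
            cand.site_logl = site_logl
            cand.log_likelihood = float(site_logl.sum())

    table = np.vstack([c.site_logl for c in candidates])
    result = expected_likelihood_weights(
        table,
        n_replicates=config.n_replicates,
        seed=_branch_seed(config.seed, family, branch),
    )
    for cand, w in zip(candidates, result.elw):
        cand.elw = float(w)

    informative = bool(aln.subset(sorted(tree.leaf_names)).variable_columns().any())
    return PlacementEvaluation(
        family=family,
        pruned_branch=branch,
        candidates=candidates,
        uninformative=not informative,
    )


def call_ogds(
    evaluations: Iterable[PlacementEvaluation],
    config: ScanConfig,
    elw_cutoff: Optional[float] = None,
    distance_cutoff: Optional[float] = None,
) -> List[OGDCall]:
    """Apply the ELW and path-length cutoffs; at most one call per evaluation."""
    elw_cut = config.elw_cutoff if elw_cutoff is None else elw_cutoff
    dist_cut = config.distance_cutoff if distance_cutoff is None else distance_cutoff
    calls: List[OGDCall] = []
    for ev in evaluations:
        best = ev.best_non_original()
        if best is None or best.donor_branch is None:
            continue
        if best.elw < elw_cut:
            continue
        far_enough = (
            best.distance >= dist_cut if config.inclusive_distance else best.distance > dist_cut
        )
        if not far_enough:
            continue
        calls.append(
            OGDCall(
                family=ev.family,
                recipient=ev.pruned_branch,
                donor=best.donor_branch,
                elw=best.elw,
                distance=best.distance,
            )
        )
    return calls


def filter_reciprocal(calls: Sequence[OGDCall]) -> List[OGDCall]:
    """Drop every pair of calls in one family that are each other's reverse."""
    keyed = {(c.family, c.recipient.clade, c.donor.clade) for c in calls}
    out = []
    for c in calls:
        if (c.family, c.donor.clade, c.recipient.clade) in keyed:
            continue  # its reverse is also called: direction unknowable
        out.append(c)
    return out


def filter_ancestral_donor(calls: Sequence[OGDCall], tree: Tree) -> List[OGDCall]:
    """Drop calls whose donor branch is root-ward of (ancestral to) the recipient."""
    if not tree.is_rooted:
        raise ValueError("ancestral-donor filter requires a rooted tree")
    return [
        c
        for c in calls
        if not treecore.is_ancestral(tree, c.donor, c.recipient)
    ]


@dataclass
class FamilyScan:
    family: str
    evaluations: List[PlacementEvaluation]
    calls: List[OGDCall]  # post-filter
    raw_calls: List[OGDCall]  # pre-filter


def scan_family(
    tree: Tree,
    aln: AlignmentMatrix,
    config: ScanConfig,
    family: str = "family",
    progress=None,
) -> FamilyScan:
    """Evaluate every prunable branch of the rooted combined tree for one family."""
    if not tree.is_rooted:
        raise ValueError("the combined tree must be rooted (root_between) before scanning")
    missing = tree.leaf_names - set(aln.labels)
    if missing:
        raise ValueError(f"family {family!r} lacks taxa: {sorted(missing)}")
    model = config.substitution_model(aln)
    rates = config.rate_model()
    evaluations = []
    for branch in treecore.enumerate_branches(tree):
        if len(tree.leaf_names - branch.clade) < 3:
            continue  # residual tree would be degenerate; branch not assessable
        ev = evaluate_branch(
            tree, branch, aln, config, family=family, model=model, rates=rates
        )
        evaluations.append(ev)
        if progress is not None:
            progress(family, branch)
    raw = call_ogds(evaluations, config)
    filtered = filter_ancestral_donor(filter_reciprocal(raw), tree)
    return FamilyScan(family=family, evaluations=evaluations, calls=filtered, raw_calls=raw)


def parameter_grid(
    scans: Sequence[FamilyScan],
    tree: Tree,
    config: ScanConfig,
    elw_grid: Optional[Sequence[float]] = None,
    distance_grid: Optional[Sequence[float]] = None,
) -> "GridResult":
    """Post-filter OGD counts over the (ELW cutoff) x (distance cutoff) grid."""
    elws = list(elw_grid if elw_grid is not None else config.elw_grid)
    dists = list(distance_grid if distance_grid is not None else config.distance_grid)
    counts = np.zeros((len(elws), len(dists)), dtype=int)
    for i, e in enumerate(elws):
        for j, d in enumerate(dists):
            total = 0
            for scan in scans:
                raw = call_ogds(scan.evaluations, config, elw_cutoff=e, distance_cutoff=d)
                kept = filter_ancestral_donor(filter_reciprocal(raw), tree)
                total += len(kept)
            counts[i, j] = total
    return GridResult(elw_grid=elws, distance_grid=dists, counts=counts)


@dataclass
class GridResult:
    elw_grid: List[float]
    distance_grid: List[float]
    counts: np.ndarray
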