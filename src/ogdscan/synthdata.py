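"""Synthetic fixtures with known ground truth for the displacement pipeline.

A pure-birth (Yule) species tree is simulated and scaled to a target total
branch length in substitutions/site.  A gene family either inherits the
species history unchanged (a "clean" family) or is perturbed by one or
more SPR moves -- the displacement model of transfer: the recipient
lineage's gene copy is detached and re-attached next to the donor, so the
gene stays single-copy while its history disagrees with the species tree.
Alignments are then evolved forward along the gene tree under the same
substitution model the scan uses.  Trait tables (GC%, genome size,
habitat observation counts) evolve by Brownian motion along the species
tree, so sister taxa are more similar than random pairs.

Every generator is deterministic given its seed; ``write_fixture`` emits a
byte-reproducible file set (Newick + FASTA + TSV + manifest).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import yaml

from . import treecore
from .factors import HABITAT_CATEGORIES
from .likelihood import AlignmentMatrix, write_fasta_alignment
from .substmodel import RateModel, SubstitutionModel, jtt_model, uniform_rates
from .treecore import (
    BranchRef,
    Tree,
    TreePoint,
    branch_midpoint,
    insertion_points,
    prune_clade,
    regraft,
    write_newick,
)

__all__ = [
    "TruthRecord",
    "simulate_tree",
    "inject_transfers",
    "evolve_alignment",
    "simulate_traits",
    "Fixture",
    "make_fixture",
    "write_fixture",
    "branches_adjacent",
    "score_recovery",
]

DEFAULT_TOTAL_LENGTH = 8.0  # substitutions/site summed over the tree


@dataclass
class TruthRecord:
    """An injected transfer: who moved, where to, and how far."""

    family: str
    recipient_clade: FrozenSet[str]
    donor_clade: FrozenSet[str]
    distance: float  # residual-tree path length realised by the SPR


# ---------------------------------------------------------------------------
# Species tree
# ---------------------------------------------------------------------------


def simulate_tree(
    n: int,
    birth_rate: float = 1.0,
    seed: int = 0,
    total_length: float = DEFAULT_TOTAL_LENGTH,
) -> Tree:
    """Yule species tree with ``n`` leaves, scaled to ``total_length``.

    The tree is ultrametric (clock-like) up to the global scaling and comes
    rooted at the original birth-process root.
    """
    if n < 4:
        raise ValueError("need at least 4 leaves")
    from dendropy.simulate import treesim

    rng = random.Random(seed)
    dtree = treesim.birth_death_tree(
        birth_rate=birth_rate,
        death_rate=0.0,
        num_extant_tips=n,
        rng=rng,
    )
    width = len(str(n))
    # the process stops exactly at the n-th speciation, leaving zero-length
    # pendant edges; extending every tip by one waiting time keeps the tree
    # ultrametric and all branches positive
    extra = rng.expovariate(birth_rate * n)
    for i, leaf in enumerate(dtree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"S{i:0{width}d}"
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    dtree.seed_node.edge.length = None  # not part of the unrooted shape
    total = sum(e.length or 0.0 for e in dtree.edges())
    factor = total_length / total
    for edge in dtree.edges():
        if edge.length is not None:
            edge.length *= factor
    newick = dtree.as_string(schema="newick", suppress_rooting=True).strip()
    return treecore.parse_newick(newick)


# ---------------------------------------------------------------------------
# Transfer injection
# ---------------------------------------------------------------------------


def _branch_for_leafset(tree: Tree, leaves: FrozenSet[str]) -> Optional[BranchRef]:
    """The tree's branch whose bipartition matches ``leaves`` (either side)."""
    comp = tree.leaf_names - leaves
    for ref in tree.branches():
        if ref.clade == leaves:
            return ref
        if ref.clade == comp:
            return ref
    return None


def _node_depths(tree: Tree) -> Dict[int, float]:
    rp = tree.root_point
    assert rp is not None
    u, v, off, _side = tree._root_edge
    du = tree.node_distances(u)
    dv = tree.node_distances(v)
    len_uv = tree.adj[u][v]
    return {
        node: min(off + du[node], (len_uv - off) + dv[node]) for node in tree.adj
    }


def _branch_time_span(tree: Tree, depths: Dict[int, float], branch: BranchRef):
    prox, dist, _l = tree._resolve(branch)
    a, b = depths[prox], depths[dist]
    return (min(a, b), max(a, b))


def inject_transfers(
    species: Tree,
    k: int,
    min_distance: float,
    seed: int = 0,
    require_temporal_overlap: bool = False,
    family: str = "family",
) -> Tuple[Tree, List[TruthRecord]]:
    """Apply ``k`` independent SPR transfers to a copy of the species tree.

    Each event detaches a recipient clade and re-attaches it at the midpoint
    of a donor branch at residual-tree path distance >= ``min_distance`` from
    the original attachment.  Events never touch overlapping neighbourhoods
    (their recipient and donor clades are disjoint across events).  With
    ``require_temporal_overlap`` the donor and recipient branches must
    coexist in time on the (clock-like) species tree, as a real transfer's
    partners must.
    """
    if not species.is_rooted:
        raise ValueError("inject_transfers needs the rooted species tree")
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = np.random.default_rng(seed)
    gene = species.copy()
    truths: List[TruthRecord] = []
    if k == 0:
        return gene, truths
    n = species.n_leaves
    branches = treecore.enumerate_branches(species)
    depths = _node_depths(species) if require_temporal_overlap else None
    root_clade = species.root_point.branch.clade if species.root_point else None
    used: set = set()

    for _event in range(k):
        recipients = [
            b
            for b in branches
            if len(b.clade) <= n - 3
            and not (b.clade & used)
            and (not require_temporal_overlap or b.clade != root_clade)
        ]
        order = rng.permutation(len(recipients))
        placed = False
        for ri in order:
            recip = recipients[ri]
            gene_ref = _branch_for_leafset(gene, recip.clade)
            if gene_ref is None or gene_ref.clade != recip.clade:
                continue  # bipartition lost or flipped by a previous event
            pruned = prune_clade(gene, gene_ref)
            res = pruned.residual
            donors = [
                d
                for d in branches
                if not (d.clade & (recip.clade | used))
                and d != recip
                and (not require_temporal_overlap or d.clade != root_clade)
            ]
            donor_order = rng.permutation(len(donors))
            for di in donor_order:
                donor = donors[di]
                rref = _branch_for_leafset(res, donor.clade)
                if rref is None:
                    continue
                point = TreePoint(rref, res.branch_length(rref) / 2.0)
                dist = treecore.path_length(res, pruned.attachment_point, point)
                if dist < min_distance:
                    continue
                if require_temporal_overlap:
                    s1 = _branch_time_span(species, depths, recip)
                    s2 = _branch_time_span(species, depths, donor)
                    if s1[0] > s2[1] - 1e-12 or s2[0] > s1[1] - 1e-12:
                        continue
                gene = regraft(pruned, point)
                truths.append(
                    TruthRecord(
                        family=family,
                        recipient_clade=recip.clade,
                        donor_clade=donor.clade,
                        distance=dist,
                    )
                )
                used |= recip.clade | donor.clade
                placed = True
                break
            if placed:
                break
        if not placed:
            raise ValueError(
                f"could not place transfer {_event + 1}/{k} at min distance "
                f"{min_distance}; try fewer events or a smaller distance"
            )
    return gene, truths


# ---------------------------------------------------------------------------
# Sequence evolution
# ---------------------------------------------------------------------------


def evolve_alignment(
    gene_tree: Tree,
    length: int,
    model: Optional[SubstitutionModel] = None,
    rates: Optional[RateModel] = None,
    seed: int = 0,
) -> AlignmentMatrix:
    """Forward-simulate an amino-acid alignment along ``gene_tree``.

    Root states are drawn from the model's stationary frequencies; each site
    draws a rate category uniformly; states then evolve branch by branch via
    the model's transition matrices.
    """
    if length < 1:
        raise ValueError("alignment length must be >= 1")
    model = model if model is not None else jtt_model("model")
    rates = rates if rates is not None else uniform_rates()
    rng = np.random.default_rng(seed)
    cats = rng.integers(0, rates.ncat, size=length)

    root = next(n for n in gene_tree.adj if n not in gene_tree.labels)
    parent: Dict[int, Optional[int]] = {root: None}
    order = [root]
    i = 0
    while i < len(order):
        node = order[i]
        i += 1
        for nbr in gene_tree.adj[node]:
            if nbr != parent[node]:
                parent[nbr] = node
                order.append(nbr)

    states: Dict[int, np.ndarray] = {
        root: rng.choice(20, size=length, p=model.pi)
    }
    for node in order[1:]:
        par = parent[node]
        blen = gene_tree.adj[par][node]
        out = np.empty(length, dtype=np.int8)
        for k, rate in enumerate(rates.rates):
            in_cat = np.flatnonzero(cats == k)
            if in_cat.size == 0:
                continue
            p = model.p_matrix(blen * rate)
            par_states = states[par][in_cat]
            for s in range(20):
                sites = in_cat[par_states == s]
                if sites.size:
                    out[sites] = rng.choice(20, size=sites.size, p=p[s])
        states[node] = out

    labels = sorted(gene_tree.leaf_names)
    mat = np.vstack([states[gene_tree.leaf_of[lab]] for lab in labels])
    return AlignmentMatrix(labels, mat.astype(np.int8))


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------


def simulate_traits(tree: Tree, seed: int = 0) -> pd.DataFrame:
    """Clade-correlated trait table: GC%, genome size (Mb), habitat counts.

    GC%% follows a bounded Brownian walk (reflected into [25, 75]); genome
    size is Brownian on the log scale around ~3 Mb; habitat category weights
    are Brownian logits turned into multinomial observation counts, with at
    least two observations per taxon.
    """
    rng = np.random.default_rng(seed)
    root = next(n for n in tree.adj if n not in tree.labels)
    parent: Dict[int, Optional[int]] = {root: None}
    order = [root]
    i = 0
    while i < len(order):
        node = order[i]
        i += 1
        for nbr in tree.adj[node]:
            if nbr != parent[node]:
                parent[nbr] = node
                order.append(nbr)

    gc: Dict[int, float] = {root: 50.0}
    log_mb: Dict[int, float] = {root: float(np.log(3.0))}
    logits: Dict[int, np.ndarray] = {root: np.zeros(6)}
    for node in order[1:]:
        par = parent[node]
        blen = max(tree.adj[par][node], 1e-6)
        sd = np.sqrt(blen)
        g = gc[par] + rng.normal(0.0, 10.0 * sd)
        while g < 25.0 or g > 75.0:  # reflect at the physical bounds
            g = 2 * 25.0 - g if g < 25.0 else 2 * 75.0 - g
        gc[node] = g
        log_mb[node] = log_mb[par] + rng.normal(0.0, 0.35 * sd)
        logits[node] = logits[par] + rng.normal(0.0, 1.5 * sd, size=6)

    rows = []
    for lab in sorted(tree.leaf_names):
        node = tree.leaf_of[lab]
        w = np.exp(logits[node] - logits[node].max())
        w = w / w.sum()
        nobs = 2 + rng.poisson(4)
        counts = rng.multinomial(nobs, w)
        rows.append(
            {
                "taxon": lab,
                "gc_percent": round(gc[node], 3),
                "genome_mb": round(float(np.exp(log_mb[node])), 4),
                **{cat: int(c) for cat, c in zip(HABITAT_CATEGORIES, counts)},
            }
        )
    return pd.DataFrame(rows).set_index("taxon")


# ---------------------------------------------------------------------------
# End-to-end fixtures
# ---------------------------------------------------------------------------


@dataclass
class Fixture:
    species: Tree
    families: Dict[str, AlignmentMatrix]
    gene_trees: Dict[str, Tree]
    truths: List[TruthRecord]
    traits: pd.DataFrame
    seed: int
    params: Dict[str, object] = field(default_factory=dict)


def make_fixture(
    n_taxa: int = 12,
    n_families: int = 5,
    n_transfers: int = 2,
    n_sites: int = 500,
    seed: int = 42,
    min_distance: float = 0.6,
    total_length: float = DEFAULT_TOTAL_LENGTH,
    require_temporal_overlap: bool = False,
) -> Fixture:
    """Generate the standard in-memory fixture.

    The first ``n_transfers`` families carry one injected transfer each
    (at residual distance >= ``min_distance``); the rest are clean.
    """
    species = simulate_tree(n_taxa, seed=seed, total_length=total_length)
    families: Dict[str, AlignmentMatrix] = {}
    gene_trees: Dict[str, Tree] = {}
    truths: List[TruthRecord] = []
    for fam_idx in range(n_families):
        name = f"fam{fam_idx:02d}"
        fam_seed = (seed * 1009 + 13 * fam_idx + 1) % (2**31)
        k = 1 if fam_idx < n_transfers else 0
        gene, fam_truths = inject_transfers(
            species,
            k,
            min_distance,
            seed=fam_seed,
            require_temporal_overlap=require_temporal_overlap,
            family=name,
        )
        aln = evolve_alignment(gene, n_sites, seed=(fam_seed + 7) % (2**31))
        families[name] = aln
        gene_trees[name] = gene
        truths.extend(fam_truths)
    traits = simulate_traits(species, seed=(seed * 2003 + 5) % (2**31))
    return Fixture(
        species=species,
        families=families,
        gene_trees=gene_trees,
        truths=truths,
        traits=traits,
        seed=seed,
        params={
            "n_taxa": n_taxa,
            "n_families": n_families,
            "n_transfers": n_transfers,
            "n_sites": n_sites,
            "min_distance": min_distance,
            "total_length": total_length,
            "require_temporal_overlap": require_temporal_overlap,
        },
    )


def write_fixture(outdir, **kwargs) -> Path:
    """Write a :func:`make_fixture` file set; byte-identical for equal seeds."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fix = make_fixture(**kwargs)
    (outdir / "combined.nwk").write_text(write_newick(fix.species) + "\n")
    for name, aln in sorted(fix.families.items()):
        write_fasta_alignment(aln, outdir / f"{name}.fasta")
    fix.traits.to_csv(outdir / "traits.tsv", sep="\t")
    with open(outdir / "truth.tsv", "w") as fh:
        fh.write("family\trecipient_leaves\tdonor_leaves\tdistance\n")
        for t in fix.truths:
            fh.write(
                f"{t.family}\t{','.join(sorted(t.recipient_clade))}\t"
                f"{','.join(sorted(t.donor_clade))}\t{t.distance:.9g}\n"
            )
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump({"seed": fix.seed, **fix.params}, fh, sort_keys=True)
    return outdir


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------


def branches_adjacent(tree: Tree, a: BranchRef, b: BranchRef) -> bool:
    """True when two branches share an endpoint on the tree."""
    pa, da, _ = tree._resolve(a)
    pb, db, _ = tree._resolve(b)
    return bool({pa, da} & {pb, db})


def score_recovery(species: Tree, truths: Sequence[TruthRecord], calls) -> Dict[str, float]:
    """Sensitivity and donor accuracy of calls against injected truth.

    A truth is recovered when some post-filter call in its family has exactly
    the recipient branch; the donor is accurate when it equals or is adjacent
    to the true donor branch.
    """
    recovered = 0
    donor_ok = 0
    for t in truths:
        hits = [
            c
            for c in calls
            if c.family == t.family and c.recipient.clade == t.recipient_clade
        ]
        if not hits:
            continue
        recovered += 1
        true_donor = _branch_for_leafset(species, t.donor_clade)
        call = hits[0]
        if true_donor is not None and (
            call.donor.clade in (true_donor.clade, species.leaf_names - true_donor.clade)
            or branches_adjacent(species, call.donor, true_donor)
        ):
            donor_ok += 1
    n = len(truths)
    return {
        "sensitivity": recovered / n if n else float("nan"),
        "donor_accuracy": donor_ok / recovered if recovered else float("nan"),
        "n_truths": n,
        "n_recovered": recovered,
    }
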