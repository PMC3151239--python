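"""Pruning likelihood vs exhaustive enumeration; engine and optimiser contracts."""

import itertools

import numpy as np
import pytest
from scipy.optimize import golden

from ogdscan import likelihood as lk
from ogdscan import substmodel as sm
from ogdscan import treecore as tc


def enumeration_oracle(tree, aln, model):
    """Sum the likelihood over every assignment of states to internal nodes.

    Edges are oriented away from the first internal node; a gap/ambiguous
    leaf contributes no edge factor (probability one over its states).
    Exponential in the internal node count -- usable only for <= 5 leaves.
    """
    internal = [n for n in tree.adj if n not in tree.labels]
    leaves = {n: aln.row(tree.labels[n]) for n in tree.labels}
    root = internal[0]
    parent = {root: None}
    order = [root]
    i = 0
    while i < len(order):
        node = order[i]
        i += 1
        for nbr in tree.adj[node]:
            if nbr != parent[node]:
                parent[nbr] = node
                order.append(nbr)
    edges = [(parent[v], v, tree.adj[parent[v]][v]) for v in order[1:]]
    pmats = {(u, v): model.p_matrix(l) for u, v, l in edges}
    out = np.zeros(aln.n_sites)
    for s in range(aln.n_sites):
        total = 0.0
        for assign in itertools.product(range(20), repeat=len(internal)):
            state = dict(zip(internal, assign))
            for n, row in leaves.items():
                state[n] = row[s]
            term = model.pi[state[root]]
            for u, v, _l in edges:
                if state[v] == lk.MISSING:
                    continue  # missing leaf: marginalised out
                term *= pmats[(u, v)][state[u], state[v]]
            total += term
        out[s] = total
    return np.log(out)


TREES = [
    "((A:0.05,B:0.05):0.1,C:0.2,D:0.02);",
    "((A:0.3,B:0.01):0.2,C:0.4,D:0.15);",
    "(A:0.1,B:0.2,(C:0.3,(D:0.12,E:0.21):0.08):0.4);",
    "((A:0.25,E:0.3):0.1,B:0.05,(C:0.2,D:0.2):0.15);",
]
SEQS = {"A": "ARL", "B": "AR-", "C": "LKN", "D": "ARN", "E": "GRX"}


class TestPruningOracle:
    @pytest.mark.parametrize("newick", TREES)
    def test_matches_exhaustive_enumeration(self, jtt, newick):
        tree = tc.parse_newick(newick)
        aln = lk.AlignmentMatrix.from_sequences(
            {lab: SEQS[lab] for lab in tree.leaf_names}
        )
        ours = lk.site_log_likelihoods(tree, aln, jtt)
        oracle = enumeration_oracle(tree, aln, jtt)
        assert np.abs(ours - oracle).max() < 1e-8

    def test_two_leaf_closed_form(self, jtt):
        # direct formula: sum_x pi_x P_xA(t1) P_xR(t2) for a single site
        tree = tc.parse_newick("((A:0.05,B:0.05):0.0,C:0.0,D:0.0);")
        aln = lk.AlignmentMatrix.from_sequences({"A": "R", "B": "R", "C": "X", "D": "X"})
        ours = lk.site_log_likelihoods(tree, aln, jtt)
        r = sm.AA_ORDER.index("R")
        p = sm.transition_probabilities(jtt, 0.1)
        expected = np.log(jtt.pi[r] * p[r, r])
        # C and D are missing; A-B separated by 0.1 total
        assert ours[0] == pytest.approx(expected, abs=1e-10)

    def test_rerooting_invariance(self, jtt):
        tree = tc.parse_newick(TREES[2])
        aln = lk.AlignmentMatrix.from_sequences(
            {lab: SEQS[lab] for lab in tree.leaf_names}
        )
        base = lk.site_log_likelihoods(tree, aln, jtt)
        for b in list(tc.enumerate_branches(tree))[:4]:
            rerooted = tc.root_between(tree, b, 0.42)
            again = lk.site_log_likelihoods(rerooted, aln, jtt)
            assert np.abs(again - base).max() < 1e-9

    def test_leaf_order_invariance(self, jtt):
        tree = tc.parse_newick(TREES[0])
        seqs = {lab: SEQS[lab] for lab in tree.leaf_names}
        a1 = lk.AlignmentMatrix.from_sequences(seqs)
        a2 = lk.AlignmentMatrix.from_sequences(dict(reversed(list(seqs.items()))))
        assert np.allclose(
            lk.site_log_likelihoods(tree, a1, jtt),
            lk.site_log_likelihoods(tree, a2, jtt),
        )

    def test_duplicated_site_doubles_contribution(self, jtt):
        tree = tc.parse_newick(TREES[0])
        a1 = lk.AlignmentMatrix.from_sequences({"A": "A", "B": "R", "C": "L", "D": "A"})
        a2 = lk.AlignmentMatrix.from_sequences({"A": "AA", "B": "RR", "C": "LL", "D": "AA"})
        s1 = lk.site_log_likelihoods(tree, a1, jtt)
        s2 = lk.site_log_likelihoods(tree, a2, jtt)
        assert lk.total_log_likelihood(s2) == pytest.approx(2 * s1[0], abs=1e-10)

    def test_all_gap_column_contributes_zero(self, jtt):
        tree = tc.parse_newick(TREES[0])
        aln = lk.AlignmentMatrix.from_sequences({"A": "A-", "B": "R-", "C": "L-", "D": "A-"})
        site = lk.site_log_likelihoods(tree, aln, jtt)
        assert site[1] == pytest.approx(0.0, abs=1e-12)
        assert aln.all_gap_columns().tolist() == [False, True]

    def test_missing_taxon_error_names_labels(self, jtt):
        tree = tc.parse_newick(TREES[0])
        aln = lk.AlignmentMatrix.from_sequences({"A": "A", "B": "R", "C": "L"})
        with pytest.raises(ValueError, match="D"):
            lk.site_log_likelihoods(tree, aln, jtt)

    def test_gamma_categories_average_site_likelihood(self, jtt):
        tree = tc.parse_newick(TREES[0])
        aln = lk.AlignmentMatrix.from_sequences({"A": "A", "B": "R", "C": "L", "D": "A"})
        rates = sm.discrete_gamma(0.8, 4)
        mixed = lk.site_log_likelihoods(tree, aln, jtt, rates)
        per_cat = [
            lk.site_log_likelihoods(
                tc.parse_newick(TREES[0]), aln, jtt, sm.RateModel(None, np.array([r]))
            )[0]
            for r in rates.rates
        ]
        expected = np.log(np.mean(np.exp(per_cat)))
        assert mixed[0] == pytest.approx(expected, abs=1e-9)


class TestTotals:
    def test_empty_and_single(self):
        assert lk.total_log_likelihood([]) == 0.0
        assert lk.total_log_likelihood([-3.2]) == -3.2

    def test_matches_fsum_oracle(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(-5, 3, size=1000)
        import math

        assert lk.total_log_likelihood(vals) == math.fsum(vals.tolist())

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            lk.total_log_likelihood([1.0, np.inf])


class TestPlacementEngine:
    def test_engine_equals_direct_likelihood_at_every_point(self, jtt):
        from ogdscan import synthdata as sd

        tree = sd.simulate_tree(7, seed=13)
        gene, _ = sd.inject_transfers(tree, 1, 0.5, seed=4)
        aln = sd.evolve_alignment(gene, 40, model=jtt, seed=8)
        branch = next(
            b for b in tc.enumerate_branches(tree) if len(b.clade) == 1
        )
        pruned = tc.prune_clade(tree, branch)
        engine = lk.PlacementEngine(pruned, aln, jtt)
        for point in tc.insertion_points(pruned):
            prox, dist, length = pruned.residual._resolve(point.branch)
            from_engine = engine.site_logl(
                (prox, dist), point.offset, length - point.offset,
                pruned.subtree.stem_length,
            )
            direct = lk.site_log_likelihoods(tc.regraft(pruned, point), aln, jtt)
            assert np.abs(from_engine - direct).max() < 1e-10

    def test_local_optimisation_is_monotone(self, jtt):
        from ogdscan import synthdata as sd

        tree = sd.simulate_tree(6, seed=3)
        aln = sd.evolve_alignment(tree, 60, model=jtt, seed=5)
        branch = next(b for b in tc.enumerate_branches(tree) if len(b.clade) == 1)
        pruned = tc.prune_clade(tree, branch)
        engine = lk.PlacementEngine(pruned, aln, jtt)
        for point in tc.insertion_points(pruned):
            prox, dist, length = pruned.residual._resolve(point.branch)
            before = engine.site_logl(
                (prox, dist), point.offset, length - point.offset,
                pruned.subtree.stem_length,
            ).sum()
            after, _ = engine.optimize_local(
                (prox, dist), point.offset, length - point.offset,
                pruned.subtree.stem_length,
            )
            assert after.sum() >= before - 1e-6


class TestBranchOptimisation:
    def test_two_taxon_matches_golden_section_oracle(self, jtt):
        from ogdscan import synthdata as sd

        # two effective taxa: a quartet with three zero branches collapses the
        # optimisation to the single separating branch
        tree = tc.parse_newick("((A:0.2,B:0.0):0.0,C:0.0,D:0.0);")
        rng = np.random.default_rng(11)
        # evolve at true distance 0.7 between A and the rest
        sim = tc.parse_newick("((A:0.7,B:0.0):0.0,C:0.0,D:0.0);")
        aln = sd.evolve_alignment(sim, 400, model=jtt, seed=11)

        def neg(t):
            work = tc.parse_newick(f"((A:{max(t, 1e-8)},B:0.0):0.0,C:0.0,D:0.0);")
            return -lk.total_log_likelihood(lk.site_log_likelihoods(work, aln, jtt))

        t_opt = golden(neg, brack=(0.05, 0.5, 3.0), tol=1e-6)
        res = lk.optimize_branch_lengths(
            tree, aln, jtt, scope="local",
            branches=[tc.BranchRef(frozenset({"A"}))],
        )
        fitted = res.tree.branch_length(tc.BranchRef(frozenset({"A"})))
        assert fitted == pytest.approx(t_opt, abs=1e-3)

    def test_full_scope_never_decreases_likelihood(self, jtt):
        from ogdscan import synthdata as sd

        tree = sd.simulate_tree(6, seed=9, total_length=4.0)
        aln = sd.evolve_alignment(tree, 80, model=jtt, seed=2)
        before = lk.total_log_likelihood(lk.site_log_likelihoods(tree, aln, jtt))
        res = lk.optimize_branch_lengths(tree, aln, jtt, scope="full")
        assert res.log_likelihood >= before - 1e-6
        after = lk.total_log_likelihood(lk.site_log_likelihoods(res.tree, aln, jtt))
        assert after == pytest.approx(res.log_likelihood, abs=1e-6)
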