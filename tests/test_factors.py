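"""Trait summaries, distances, statistical tests, dating, and the rate fit."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from ogdscan import factors as fx
from ogdscan import synthdata as sd
from ogdscan import treecore as tc
from ogdscan.scan import OGDCall


def _ref(*leaves):
    return tc.BranchRef(frozenset(leaves))


FIVE_TAXON = "(((A:1,B:1):1,C:2):0.5,(D:1,E:1):0.5);"


class TestAncestralMean:
    def test_clade_mean_and_leaf_value(self):
        t = tc.parse_newick(FIVE_TAXON)
        gc = {"A": 40.0, "B": 60.0, "C": 55.0, "D": 30.0, "E": 70.0}
        assert fx.ancestral_mean(t, _ref("A", "B"), gc) == pytest.approx(50.0)
        assert fx.ancestral_mean(t, _ref("C"), gc) == pytest.approx(55.0)

    def test_root_side_mean_matches_direct_summation(self):
        t = sd.simulate_tree(10, seed=2)
        rng = np.random.default_rng(0)
        gc = {l: float(rng.uniform(30, 70)) for l in t.leaf_names}
        big = max(tc.enumerate_branches(t), key=lambda b: len(b.clade))
        expected = sum(gc[l] for l in big.clade) / len(big.clade)
        assert fx.ancestral_mean(t, big, gc) == pytest.approx(expected, abs=1e-12)
        # mean is bracketed by the leaf extremes
        vals = [gc[l] for l in big.clade]
        assert min(vals) <= fx.ancestral_mean(t, big, gc) <= max(vals)

    def test_missing_trait_lists_taxa(self):
        t = tc.parse_newick(FIVE_TAXON)
        with pytest.raises(ValueError, match="B"):
            fx.ancestral_mean(t, _ref("A", "B"), {"A": 1.0})


class TestHabitat:
    def _table(self, rows):
        df = pd.DataFrame(rows, columns=fx.HABITAT_CATEGORIES)
        df.index = list("ABCDE")[: len(rows)]
        return df

    def test_single_taxon_profile(self):
        t = tc.parse_newick(FIVE_TAXON)
        table = self._table([[2, 0, 0, 0, 0, 0]] * 5)
        prof = fx.habitat_profile(t, _ref("A"), table)
        assert prof.tolist() == [1, 0, 0, 0, 0, 0]

    def test_two_taxon_profile_sums_counts(self):
        t = tc.parse_newick(FIVE_TAXON)
        table = self._table([[1, 0, 0, 0, 0, 0], [0, 1, 0, 0, 0, 0]] + [[1] * 6] * 3)
        prof = fx.habitat_profile(t, _ref("A", "B"), table)
        assert prof.tolist() == [0.5, 0.5, 0, 0, 0, 0]
        assert prof.sum() == pytest.approx(1.0)

    def test_zero_observations_rejected(self):
        t = tc.parse_newick(FIVE_TAXON)
        table = self._table([[0] * 6] * 5)
        with pytest.raises(ValueError):
            fx.habitat_profile(t, _ref("A"), table)

    def test_habitat_distance_bounds_and_symmetry(self):
        p = np.array([1.0, 0, 0, 0, 0, 0])
        q = np.array([0, 1.0, 0, 0, 0, 0])
        assert fx.habitat_distance(p, p) == 0.0
        assert fx.habitat_distance(p, q) == pytest.approx(math.sqrt(2))
        r = np.full(6, 1 / 6)
        assert fx.habitat_distance(p, r) == fx.habitat_distance(r, p)
        with pytest.raises(ValueError):
            fx.habitat_distance(p, np.array([0.5, 0, 0, 0, 0, 0]))


class TestDistances:
    def test_sister_leaf_midpoints(self):
        t = tc.parse_newick("((A:0.1,B:0.2):1,C:1,D:1);")
        call = OGDCall("f", _ref("A"), _ref("B"), 0.9, 1.0)
        assert fx.donor_acceptor_distance(t, call) == pytest.approx(0.15)
        rev = OGDCall("f", _ref("B"), _ref("A"), 0.9, 1.0)
        assert fx.donor_acceptor_distance(t, rev) == pytest.approx(0.15)

    def test_all_pairs_excludes_nested_and_matches_enumeration(self):
        t = tc.parse_newick("((A:1,B:1):0.5,(C:1,D:1):0.5);")
        dists = fx.all_pairs_distances(t)
        branches = tc.enumerate_branches(t)
        expected = [
            (a, b)
            for a, b in itertools.combinations(branches, 2)
            if not (a.clade < b.clade or b.clade < a.clade)
        ]
        assert len(dists) == len(expected)
        # C(5,2)=10 pairs minus the 2 nested pairs ({A,B} vs {A} and {B})
        assert len(dists) == 8
        assert np.all(dists >= 0)

    def test_short_range_calls_differ_from_all_pairs_null(self):
        """Calls restricted to nearby donors are detectably shorter than the
        all-pairs null distribution (the directional sanity the evolutionary-
        distance analysis rests on)."""
        t = sd.simulate_tree(14, seed=21)
        null = fx.all_pairs_distances(t)
        branches = tc.enumerate_branches(t)
        observed = []
        for a, b in itertools.combinations(branches, 2):
            if a.clade < b.clade or b.clade < a.clade:
                continue
            d = tc.path_length(
                t, tc.branch_midpoint(t, a), tc.branch_midpoint(t, b)
            )
            if d <= np.quantile(null, 0.2):
                observed.append(d)
        stat, p = fx.ks_two_sample(observed, null)
        assert stat > 0.5
        assert p < 1e-6
        assert np.mean(observed) < np.mean(null)

    def test_all_pairs_invariant_to_relabeling(self):
        t1 = tc.parse_newick("((A:1,B:2):0.5,(C:1,D:3):0.5);")
        t2 = tc.parse_newick("((D:1,C:2):0.5,(B:1,A:3):0.5);")
        assert sorted(fx.all_pairs_distances(t1)) == pytest.approx(
            sorted(fx.all_pairs_distances(t2))
        )


class TestStatisticalOracles:
    """The five tests against independent textbook-formula computations."""

    def _datasets(self, n=20):
        rng = np.random.default_rng(1234)
        for _ in range(n):
            nx, ny = rng.integers(5, 30), rng.integers(5, 30)
            yield rng.normal(0, 1, nx), rng.normal(rng.uniform(-1, 1), 1.3, ny)

    def test_ks_matches_ecdf_oracle(self):
        for x, y in self._datasets():
            d, p = fx.ks_two_sample(x, y)
            # oracle: sup |ECDF_x - ECDF_y| over all pooled points
            pooled = np.concatenate([x, y])
            dd = max(
                abs((x <= v).mean() - (y <= v).mean()) for v in pooled
            )
            assert d == pytest.approx(dd, abs=1e-6)
            en = math.sqrt(len(x) * len(y) / (len(x) + len(y)))
            p_oracle = sps.kstwobign.sf(en * dd)
            assert p == pytest.approx(p_oracle, abs=1e-2)

    def test_ks_degenerate_cases(self):
        d, _ = fx.ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0
        d, _ = fx.ks_two_sample([1, 2, 3], [10, 11, 12])
        assert d == 1.0

    def test_wilcoxon_exact_enumeration_example(self):
        w, p = fx.wilcoxon_rank_sum([1, 2, 3], [4, 5, 6])
        assert p == pytest.approx(0.1, abs=1e-12)  # 2/20 rank splits
        assert w == 0.0

    def test_wilcoxon_matches_normal_approximation_oracle(self):
        for x, y in self._datasets():
            w, p = fx.wilcoxon_rank_sum(x, y)
            nx, ny = len(x), len(y)
            if nx * ny <= 400:
                continue  # exact path covered elsewhere
            # oracle: U statistic + continuity-corrected normal approximation
            ranks = sps.rankdata(np.concatenate([x, y]))
            u1 = ranks[:nx].sum() - nx * (nx + 1) / 2
            mu = nx * ny / 2
            tie_term = 0.0
            _vals, counts = np.unique(np.concatenate([x, y]), return_counts=True)
            n = nx + ny
            sigma = math.sqrt(
                nx * ny / 12 * ((n + 1) - ((counts**3 - counts).sum()) / (n * (n - 1)))
            )
            z = (u1 - mu - 0.5 * np.sign(u1 - mu)) / sigma
            p_oracle = 2 * sps.norm.sf(abs(z))
            assert w == pytest.approx(u1, abs=1e-6)
            assert p == pytest.approx(min(1.0, p_oracle), abs=1e-4)

    def test_wilcoxon_symmetry_and_identity(self):
        x = [1.5, 2.5, 3.5, 9.0]
        y = [0.5, 4.5, 6.5, 7.5]
        w_xy, p_xy = fx.wilcoxon_rank_sum(x, y)
        w_yx, p_yx = fx.wilcoxon_rank_sum(y, x)
        assert p_xy == pytest.approx(p_yx, abs=1e-12)
        assert w_xy + w_yx == len(x) * len(y)
        _w, p_same = fx.wilcoxon_rank_sum(x, x)
        assert p_same > 0.9

    def test_pearson_matches_textbook_formula(self):
        for x, y in self._datasets():
            m = min(len(x), len(y))
            x, y = x[:m], y[:m]
            r, p = fx.pearson_correlation(x, y)
            xc, yc = x - x.mean(), y - y.mean()
            r_oracle = (xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum())
            assert r == pytest.approx(r_oracle, abs=1e-12)
            tstat = r_oracle * math.sqrt((m - 2) / (1 - r_oracle**2))
            assert p == pytest.approx(2 * sps.t.sf(abs(tstat), m - 2), abs=1e-4)

    def test_pearson_exact_lines(self):
        x = np.arange(10.0)
        assert fx.pearson_correlation(x, 2 * x)[0] == pytest.approx(1.0)
        assert fx.pearson_correlation(x, -x)[0] == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            fx.pearson_correlation(x, np.ones(10))

    def test_runs_test_against_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n = int(rng.integers(4, 13))
            signs = rng.choice([-1, 1], size=n)
            if len(set(signs.tolist())) < 2:
                continue
            runs, p = fx.runs_test(signs)
            # oracle: enumerate every arrangement of the same +/- multiset
            n1 = int((signs > 0).sum())
            obs_runs = 1 + int((np.diff(signs) != 0).sum())
            assert runs == obs_runs
            all_counts = []
            for positions in itertools.combinations(range(n), n1):
                seq = np.full(n, -1)
                seq[list(positions)] = 1
                all_counts.append(1 + int((np.diff(seq) != 0).sum()))
            all_counts = np.array(all_counts)
            lo = (all_counts <= obs_runs).mean()
            hi = (all_counts >= obs_runs).mean()
            p_oracle = min(1.0, 2 * min(lo, hi))
            assert p == pytest.approx(p_oracle, abs=1e-12)

    def test_runs_hand_counted_sequence(self):
        signs = [1, 1, -1, -1, 1, 1, -1, -1]
        runs, _p = fx.runs_test(signs)
        assert runs == 4


class TestDating:
    def _calls_on(self, tree, pairs):
        return [
            OGDCall("f", _ref(*r), _ref(*d), 0.9, 1.0) for d, r in pairs
        ]

    def test_clock_tree_cross_clade_intervals_overlap(self):
        t = sd.simulate_tree(12, seed=8)  # ultrametric by construction
        branches = tc.enumerate_branches(t)
        depths = sd._node_depths(t)
        rng = np.random.default_rng(3)
        calls = []
        for _ in range(60):
            a, b = rng.choice(len(branches), size=2, replace=False)
            ba, bb = branches[a], branches[b]
            if ba.clade <= bb.clade or bb.clade <= ba.clade:
                continue
            s1 = sd._branch_time_span(t, depths, ba)
            s2 = sd._branch_time_span(t, depths, bb)
            if s1[0] >= s2[1] or s2[0] >= s1[1]:
                continue  # no temporal overlap: not a possible transfer pair
            calls.append(OGDCall("f", ba, bb, 0.9, 1.0))
        assert len(calls) >= 10
        intervals = fx.dating_intervals(t, calls)
        assert all(iv.overlaps for iv in intervals)

    def test_disjoint_intervals_reported(self):
        # non-clock tree: donor shallow, acceptor deep on opposite root sides
        t = tc.parse_newick("(((A:0.1,B:0.1):2.0,C:2.1):0.5,(D:1.0,E:2.0):0.5);")
        call = OGDCall("f", _ref("A"), _ref("D"), 0.9, 1.0)
        iv = fx.dating_intervals(t, [call])[0]
        assert not iv.overlaps
        assert iv.donor_midpoint_distance != pytest.approx(
            iv.acceptor_midpoint_distance
        )

    def test_nested_pair_rejected(self):
        t = tc.parse_newick(FIVE_TAXON)
        call = OGDCall("f", _ref("A"), _ref("A", "B"), 0.9, 1.0)
        with pytest.raises(ValueError, match="nested"):
            fx.dating_intervals(t, [call])


class TestRate:
    def test_rate_points_match_membership_oracle(self):
        t = sd.simulate_tree(12, seed=4)
        branches = tc.enumerate_branches(t)
        rng = np.random.default_rng(9)
        calls = []
        for _ in range(15):
            r, d = rng.choice(len(branches), size=2, replace=False)
            calls.append(OGDCall("f", branches[r], branches[d], 0.9, 1.0))
        pts = fx.rate_points(t, calls)
        assert len(pts) == len(branches)
        for p, b in zip(pts, branches):
            assert p.ogd_count == sum(
                1 for c in calls if c.recipient.clade <= b.clade
            )
            assert p.total_branch_length == pytest.approx(
                tc.clade_total_length(t, b)
            )

    def test_named_clades_partition_counts(self):
        t = tc.parse_newick(FIVE_TAXON)
        calls = [
            OGDCall("f", _ref("A"), _ref("D"), 0.9, 1.0),
            OGDCall("f", _ref("B"), _ref("E"), 0.9, 1.0),
            OGDCall("f", _ref("D"), _ref("C"), 0.9, 1.0),
        ]
        clades = {"ab": frozenset("AB"), "de": frozenset("DE")}
        pts = fx.rate_points(t, calls, clades)
        counts = {p.clade_id: p.ogd_count for p in pts}
        assert counts == {"ab": 2, "de": 1}
        assert all(p.independent for p in pts)
        with pytest.raises(KeyError):
            fx.rate_points(t, calls, {"bad": frozenset("AD")})

    def test_collinear_points_degenerate_runs(self):
        pts = [
            fx.RatePoint(str(i), float(i), 2 * i, True) for i in range(1, 8)
        ]
        lin = fx.rate_linearity(pts)
        assert lin.degenerate
        assert lin.runs_p == 1.0
        assert lin.slope == pytest.approx(2.0)
        assert lin.fit_p < 1e-10

    def test_quadratic_data_fails_linearity(self):
        rng = np.random.default_rng(42)
        x = np.linspace(0, 4, 20)
        y = x**2 + rng.normal(0, 0.3, 20)
        pts = [
            fx.RatePoint(str(i), float(xi), float(yi), True)
            for i, (xi, yi) in enumerate(zip(x, y))
        ]
        lin = fx.rate_linearity(pts)
        assert lin.linearity_p < 0.05

    def test_linear_noisy_data_passes_linearity(self):
        rng = np.random.default_rng(7)
        x = np.linspace(1, 10, 15)
        y = 1.5 * x + rng.normal(0, 0.8, 15)
        lin = fx.rate_linearity(
            [fx.RatePoint(str(i), float(a), float(b), True) for i, (a, b) in enumerate(zip(x, y))]
        )
        assert lin.fit_p < 0.001
        assert lin.linearity_p > 0.05
        assert lin.runs_p > 0.05
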