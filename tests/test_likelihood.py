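"""Rate matrices, branch propagation, and the pruning likelihood."""

import numpy as np
import pytest
import scipy.linalg

from stratodec.geography import (
    Area,
    Geography,
    MODEL_SPECS,
    PaleoEvent,
    TimeSlice,
)
from stratodec.likelihood import (
    DECEngine,
    DECParameters,
    SlicePropagator,
    ZeroLikelihoodError,
    branch_transition_matrix,
    build_rate_matrix,
    dec_loglikelihood,
)
from stratodec.phylo import Phylogeny
from stratodec.states import enumerate_ranges

from conftest import (
    oracle_loglike,
    random_geography,
    random_tips,
    random_tree,
)


def uniform_geography(n_areas: int) -> Geography:
    return Geography(areas=[Area(f"A{i}", i) for i in range(n_areas)])


class TestRateMatrix:
    def test_single_area_two_state_chain(self):
        states = enumerate_ranges(1)
        Q = build_rate_matrix(DECParameters(0.5, 0.2), np.zeros((1, 1)), states)
        # null is absorbing; {A} -> null at the extinction rate
        np.testing.assert_allclose(Q[0], [0.0, 0.0])
        np.testing.assert_allclose(Q[1], [0.2, -0.2])

    def test_two_area_gain_rates_no_extinction(self):
        states = enumerate_ranges(2)
        idx = {m: i for i, m in enumerate(states)}
        Q = build_rate_matrix(DECParameters(1.0, 0.0), np.ones((2, 2)), states)
        assert Q[idx[0b01], idx[0b11]] == pytest.approx(1.0)
        assert Q[idx[0b10], idx[0b11]] == pytest.approx(1.0)
        # no loss transitions anywhere with e = 0
        assert Q[idx[0b11], idx[0b01]] == 0.0
        assert Q[idx[0b11], idx[0b10]] == 0.0
        assert Q[idx[0b01], idx[0]] == 0.0

    def test_dispersal_sums_source_multipliers(self):
        states = enumerate_ranges(3)
        idx = {m: i for i, m in enumerate(states)}
        mult = np.array([[0, 0, 0.3], [0, 0, 0.6], [0, 0, 0]])
        Q = build_rate_matrix(DECParameters(2.0, 0.0), mult, states)
        # from {A0,A1} into A2: d * (m[0][2] + m[1][2])
        assert Q[idx[0b011], idx[0b111]] == pytest.approx(2.0 * 0.9)

    def test_rows_sum_to_zero(self):
        rng = np.random.default_rng(0)
        states = enumerate_ranges(4)
        mult = rng.uniform(size=(4, 4))
        np.fill_diagonal(mult, 0)
        Q = build_rate_matrix(DECParameters(0.7, 0.31), mult, states)
        np.testing.assert_allclose(Q.sum(axis=1), 0.0, atol=1e-12)

    def test_negative_multiplier_rejected(self):
        with pytest.raises(ValueError):
            build_rate_matrix(
                DECParameters(1, 1), np.array([[0, -1], [1, 0]]), enumerate_ranges(2)
            )


class TestBranchTransition:
    def make_propagators(self, Qs):
        return [SlicePropagator(Q) for Q in Qs]

    def random_Q(self, seed, n_areas=2):
        rng = np.random.default_rng(seed)
        mult = rng.uniform(size=(n_areas, n_areas))
        np.fill_diagonal(mult, 0)
        return build_rate_matrix(
            DECParameters(rng.uniform(0.1, 1), rng.uniform(0.1, 1)),
            mult,
            enumerate_ranges(n_areas),
        )

    def test_single_slice_equals_expm(self):
        Q = self.random_Q(1)
        slices = [TimeSlice(0, 10)]
        P = branch_transition_matrix(1.0, 4.0, slices, self.make_propagators([Q]))
        np.testing.assert_allclose(P, scipy.linalg.expm(Q * 3.0), atol=1e-12)

    def test_identical_rates_semigroup_across_boundaries(self):
        Q = self.random_Q(2)
        slices = [TimeSlice(0, 2), TimeSlice(2, 5), TimeSlice(5, 7), TimeSlice(7, 12)]
        P = branch_transition_matrix(
            1.0, 9.0, slices, self.make_propagators([Q] * 4)
        )
        np.testing.assert_allclose(P, scipy.linalg.expm(Q * 8.0), atol=1e-10)

    def test_two_slice_product_old_to_young(self):
        Q_young, Q_old = self.random_Q(3), self.random_Q(4)
        slices = [TimeSlice(0, 35), TimeSlice(35, 60)]
        P = branch_transition_matrix(
            34.0, 36.0, slices, self.make_propagators([Q_young, Q_old])
        )
        expected = scipy.linalg.expm(Q_old * 1.0) @ scipy.linalg.expm(Q_young * 1.0)
        np.testing.assert_allclose(P, expected, atol=1e-11)

    def test_rows_stochastic(self):
        Qs = [self.random_Q(s, 3) for s in (5, 6, 7)]
        slices = [TimeSlice(0, 1), TimeSlice(1, 4), TimeSlice(4, 9)]
        P = branch_transition_matrix(0.0, 9.0, slices, self.make_propagators(Qs))
        np.testing.assert_allclose(P.sum(axis=1), 1.0, atol=1e-9)
        assert np.all(P >= 0)

    def test_uncovered_interval_rejected(self):
        Q = self.random_Q(8)
        with pytest.raises(ValueError, match="not covered"):
            branch_transition_matrix(
                0.0, 20.0, [TimeSlice(0, 10)], self.make_propagators([Q])
            )


class TestPruningLikelihood:
    def cherry(self, depth=1.0):
        return Phylogeny.from_newick(f"(a:{depth},b:{depth});")

    def test_identical_tips_no_rates_is_one_third(self):
        """With d=e=0 on 2 areas only the matching singleton root survives."""
        geo = uniform_geography(2)
        tips = {"a": 0b01, "b": 0b01}
        lnL = dec_loglikelihood(
            self.cherry(), tips, DECParameters(0, 0), MODEL_SPECS["C"], geo
        )
        assert lnL == pytest.approx(np.log(1.0 / 3.0), abs=1e-12)

    def test_single_area_likelihood_is_one(self):
        geo = uniform_geography(1)
        tree = Phylogeny.from_newick("((a:1,b:1):1,c:2);")
        tips = {t: 0b1 for t in "abc"}
        lnL = dec_loglikelihood(
            tree, tips, DECParameters(0.3, 0.0), MODEL_SPECS["C"], geo
        )
        assert lnL == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("case", range(10))
    def test_matches_brute_force_enumeration(self, case):
        """Pruning equals exhaustive joint enumeration on small instances."""
        rng = np.random.default_rng(100 + case)
        n_areas = int(rng.integers(2, 4))
        n_tips = int(rng.integers(2, 5))
        geo = random_geography(rng, n_areas, n_slices=2)
        tree = random_tree(rng, n_tips)
        tips = random_tips(rng, tree, n_areas)
        d, e = rng.uniform(0.01, 0.5, size=2)
        spec = MODEL_SPECS[rng.choice(["A", "C"])]
        lnL = dec_loglikelihood(tree, tips, DECParameters(d, e), spec, geo)
        assert lnL == pytest.approx(
            oracle_loglike(tree, tips, d, e, geo, spec), rel=1e-8
        )

    def test_stratification_neutrality(self):
        """Slice boundaries with identical multipliers leave ln L unchanged."""
        rng = np.random.default_rng(42)
        flat = uniform_geography(3)
        cut = Geography(
            areas=[Area(f"A{i}", i) for i in range(3)],
            events=[PaleoEvent("x", 2.5), PaleoEvent("y", 7.0)],
        )
        tree = random_tree(rng, 12)
        tips = random_tips(rng, tree, 3)
        p = DECParameters(0.08, 0.03)
        lnl_flat = dec_loglikelihood(tree, tips, p, MODEL_SPECS["C"], flat)
        lnl_cut = dec_loglikelihood(tree, tips, p, MODEL_SPECS["C"], cut)
        assert lnl_cut == pytest.approx(lnl_flat, abs=1e-10)

    def test_invariant_under_area_relabeling(self):
        rng = np.random.default_rng(5)
        n_areas = 3
        geo = random_geography(rng, n_areas)
        tree = random_tree(rng, 6)
        tips = random_tips(rng, tree, n_areas)
        p = DECParameters(0.1, 0.05)
        base = dec_loglikelihood(tree, tips, p, MODEL_SPECS["A"], geo)
        perm = [2, 0, 1]
        pa = np.argsort(perm)
        geo2 = Geography(
            areas=[Area(f"A{perm[i]}", int(pa[perm[i]])) for i in range(n_areas)],
            events=geo.events,
            distance_classes=geo.distance_classes[np.ix_(perm, perm)],
            tiers=geo.tiers,
        )
        tips2 = {
            lab: sum(
                1 << j for j in range(n_areas) if mask >> perm[j] & 1
            )
            for lab, mask in tips.items()
        }
        moved = dec_loglikelihood(tree, tips2, p, MODEL_SPECS["A"], geo2)
        assert moved == pytest.approx(base, rel=1e-12)

    def test_invariant_under_tip_reordering(self):
        rng = np.random.default_rng(6)
        geo = uniform_geography(2)
        tree = Phylogeny.from_newick("((a:1,b:1):1,(c:1.5,d:1.5):0.5);")
        tree2 = Phylogeny.from_newick("((d:1.5,c:1.5):0.5,(b:1,a:1):1);")
        tips = {t: int(rng.integers(1, 4)) for t in "abcd"}
        p = DECParameters(0.2, 0.1)
        l1 = dec_loglikelihood(tree, tips, p, MODEL_SPECS["C"], geo)
        l2 = dec_loglikelihood(tree2, tips, p, MODEL_SPECS["C"], geo)
        assert l2 == pytest.approx(l1, rel=1e-12)

    def test_infeasible_data_raise_zero_likelihood(self):
        """Two widespread sister tips cannot both inherit the full range."""
        geo = uniform_geography(2)
        tips = {"a": 0b11, "b": 0b11}
        with pytest.raises(ZeroLikelihoodError):
            dec_loglikelihood(
                self.cherry(), tips, DECParameters(0, 0), MODEL_SPECS["C"], geo
            )

    def test_unreachable_area_shifts_lnl_by_root_renormalisation(self):
        """An extra area nothing reaches only rescales the root prior (e=0)."""
        rng = np.random.default_rng(9)
        tree = random_tree(rng, 5)
        tips = random_tips(rng, tree, 2)
        p = DECParameters(0.15, 0.0)
        geo2 = uniform_geography(2)
        base = dec_loglikelihood(tree, tips, p, MODEL_SPECS["C"], geo2)
        # third area at distance class 2 with tier multiplier 0: unreachable
        dist = np.array([[0, 0, 2], [0, 0, 2], [2, 2, 0]])
        geo3 = Geography(
            areas=[Area(f"A{i}", i) for i in range(3)],
            distance_classes=dist,
            tiers={0: 1.0, 2: 0.0},
        )
        grown = dec_loglikelihood(tree, tips, p, MODEL_SPECS["A"], geo3)
        assert grown == pytest.approx(base + np.log(3.0 / 7.0), abs=1e-10)


class TestEngine:
    def test_missing_tip_range_rejected(self, five_area):
        tree = Phylogeny.from_newick("(a:1,b:1);")
        with pytest.raises(ValueError, match="no range"):
            DECEngine(tree, {"a": 1}, five_area, MODEL_SPECS["B"])

    def test_range_size_cap_shrinks_state_space(self, five_area):
        tree = Phylogeny.from_newick("(a:1,b:1);")
        tips = {"a": 1, "b": 2}
        eng = DECEngine(tree, tips, five_area, MODEL_SPECS["B"], max_range_size=2)
        assert eng.space.n_states == 1 + 5 + 10
        assert np.isfinite(eng.loglike(DECParameters(0.01, 0.01)))
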