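"""Ancestral range reconstruction: marginal probabilities and Sankoff parsimony."""

import numpy as np
import dendropy
import pytest

from stratodec.ancestral import (
    sankoff_parsimony,
    summarize_node,
    symmetric_difference_cost,
)
from stratodec.geography import Area, Geography, MODEL_SPECS
from stratodec.likelihood import DECParameters
from stratodec.model import DECModel
from stratodec.phylo import Phylogeny

from conftest import (
    oracle_marginals,
    oracle_sankoff_cost,
    oracle_states,
    random_geography,
    random_tips,
    random_tree,
)


def results_at(model: DECModel, d: float, e: float):
    """A DECResults carrying fixed rates, for reconstruction tests."""
    from stratodec.model import DECResults

    return DECResults(
        model=model,
        spec=model.spec,
        params=DECParameters(d, e),
        neg_ln_L=-model.loglike((d, e)),
        converged=True,
        n_iter=0,
        n_starts=0,
    )


class TestMarginal:
    def test_certain_root_when_tips_identical_and_static(self):
        geo = Geography(areas=[Area("X", 0), Area("Y", 1)])
        tree = Phylogeny.from_newick("(a:1,b:1);")
        model = DECModel(tree, {"a": 1, "b": 1}, geo, "C")
        recon = results_at(model, 0.0, 0.0).ancestral_ranges()
        root = tree.root
        p = recon.probabilities[root]
        assert p[recon.masks.index(0b01)] == pytest.approx(1.0)

    def test_vectors_sum_to_one_and_null_mass_zero(self, study_fixture, five_area):
        model = DECModel(
            study_fixture.tree, study_fixture.tip_ranges, five_area, "B"
        )
        recon = results_at(model, 0.004, 0.002).ancestral_ranges()
        for v in recon.nodes():
            p = recon.probabilities[v]
            assert p.sum() == pytest.approx(1.0, abs=1e-9)
            assert p[0] == 0.0
            assert np.all(p >= 0)

    @pytest.mark.parametrize("case", range(8))
    def test_matches_brute_force_posterior(self, case):
        rng = np.random.default_rng(300 + case)
        n_areas = 2
        geo = random_geography(rng, n_areas, n_slices=2)
        tree = random_tree(rng, 3)
        tips = random_tips(rng, tree, n_areas)
        d, e = rng.uniform(0.02, 0.4, size=2)
        model = DECModel(tree, tips, geo, "A")
        recon = results_at(model, d, e).ancestral_ranges()
        expected = oracle_marginals(tree, tips, d, e, geo, MODEL_SPECS["A"])
        assert oracle_states(n_areas) == recon.masks
        for v in recon.nodes():
            np.testing.assert_allclose(
                recon.probabilities[v], expected[v], rtol=1e-8, atol=1e-12
            )

    def test_root_marginal_equals_normalised_root_partials(self, five_area, study_fixture):
        model = DECModel(
            study_fixture.tree, study_fixture.tip_ranges, five_area, "B"
        )
        params = DECParameters(0.004, 0.002)
        recon = results_at(model, params.d, params.e).ancestral_ranges()
        _, partials, _ = model.engine._prune(params)
        direct = model.engine.root_prior * partials[model.tree.root]
        direct /= direct.sum()
        np.testing.assert_allclose(
            recon.probabilities[model.tree.root], direct, atol=1e-10
        )

    def test_refuses_nonconverged_fit_unless_forced(self, study_fixture, five_area):
        model = DECModel(
            study_fixture.tree, study_fixture.tip_ranges, five_area, "B"
        )
        res = results_at(model, 0.004, 0.002)
        res.converged = False
        with pytest.raises(ValueError, match="non-converged"):
            res.ancestral_ranges()
        assert res.ancestral_ranges(force=True).method == "marginal"


class TestSankoff:
    def test_three_tip_textbook_case(self):
        """Tips {SA},{SA},{GA}: the cherry's ancestor is {SA}; cost from the oracle.

        Under the symmetric-difference step cost, swapping the disjoint
        singletons {SA} and {GA} costs two (one loss plus one gain), and
        exhaustive enumeration puts the minimum total at 2 with the root
        tied between {SA}, {GA} and {SA,GA}.
        """
        tree = Phylogeny.from_newick("((t1:1,t2:1):1,t3:2);")
        tips = {"t1": 0b01, "t2": 0b01, "t3": 0b10}
        recon = sankoff_parsimony(tree, tips, 2, area_labels=["SA", "GA"])
        assert recon.total_cost == oracle_sankoff_cost(tree, tips, 2) == 2
        inner = [v for v in recon.nodes() if v != tree.root][0]
        assert recon.mpr_sets[inner] == {0b01}
        assert recon.mpr_sets[tree.root] == {0b01, 0b10, 0b11}

    def test_identical_tips_zero_cost_everywhere(self):
        tree = Phylogeny.from_newick("((a:1,b:1):1,(c:1.5,d:1.5):0.5);")
        tips = {t: 0b101 for t in "abcd"}
        recon = sankoff_parsimony(tree, tips, 3)
        assert recon.total_cost == 0
        for v in recon.nodes():
            assert recon.mpr_sets[v] == {0b101}

    @pytest.mark.parametrize("case", range(10))
    def test_total_cost_equals_exhaustive_minimum(self, case):
        rng = np.random.default_rng(500 + case)
        n_areas = int(rng.integers(2, 4))
        tree = random_tree(rng, int(rng.integers(3, 7)))
        tips = random_tips(rng, tree, n_areas)
        recon = sankoff_parsimony(tree, tips, n_areas)
        assert recon.total_cost == oracle_sankoff_cost(tree, tips, n_areas)
        for v in recon.nodes():
            assert recon.mpr_sets[v]

    @pytest.mark.parametrize("case", range(5))
    def test_cost_invariant_under_rerooting(self, case):
        rng = np.random.default_rng(700 + case)
        tree = random_tree(rng, 6)
        tips = random_tips(rng, tree, 3)
        base = sankoff_parsimony(tree, tips, 3).total_cost
        dt = dendropy.Tree.get(data=tree.to_newick(), schema="newick")
        edges = [e for e in dt.preorder_edge_iter()
                 if e.head_node.parent_node is not None
                 and not e.head_node.is_leaf()]
        edge = edges[int(rng.integers(len(edges)))]
        dt.reroot_at_edge(edge, update_bipartitions=False)
        for e in dt.preorder_edge_iter():  # parsimony ignores branch lengths
            if e.length is None:
                e.length = 1.0
        rerooted = Phylogeny.from_dendropy(dt, require_ultrametric=False)
        assert sankoff_parsimony(rerooted, tips, 3).total_cost == base

    def test_asymmetric_cost_rejected_by_default(self):
        tree = Phylogeny.from_newick("(a:1,b:1);")
        tips = {"a": 1, "b": 2}
        C = symmetric_difference_cost([1, 2, 3])
        C[0, 1] = 5
        with pytest.raises(ValueError, match="asymmetric"):
            sankoff_parsimony(tree, tips, 2, cost=C)
        out = sankoff_parsimony(tree, tips, 2, cost=C, allow_asymmetric=True)
        assert out.total_cost >= 0

    def test_agrees_with_marginal_on_unambiguous_data(self):
        geo = Geography(areas=[Area("X", 0), Area("Y", 1)])
        tree = Phylogeny.from_newick("((a:1,b:1):1,c:2);")
        tips = {t: 0b10 for t in "abc"}
        model = DECModel(tree, tips, geo, "C")
        marg = results_at(model, 0.0, 0.0).ancestral_ranges()
        pars = sankoff_parsimony(tree, tips, 2, area_labels=geo.labels)
        for v in marg.nodes():
            top = marg.masks[int(np.argmax(marg.probabilities[v]))]
            assert pars.mpr_sets[v] == {0b10}
            assert top == 0b10


class TestSummaries:
    def make_marginal(self):
        geo = Geography(areas=[Area("GA", 0), Area("SA", 1)])
        tree = Phylogeny.from_newick("(a:1,b:1);")
        model = DECModel(tree, {"a": 0b11, "b": 0b01}, geo, "C")
        return results_at(model, 0.2, 0.05).ancestral_ranges(), tree

    def test_dominant_range_resolved_with_joined_labels(self):
        recon, tree = self.make_marginal()
        recon.probabilities[tree.root] = np.array([0.0, 0.1, 0.1, 0.8])
        s = summarize_node(recon, tree.root, threshold=0.5)
        assert s.resolved
        assert s.labels == ["GA+SA"]
        assert s.top_mass == pytest.approx(0.8)

    def test_flat_posterior_unresolved(self):
        recon, tree = self.make_marginal()
        recon.probabilities[tree.root] = np.array([0.0, 1 / 3, 1 / 3, 1 / 3])
        s = summarize_node(recon, tree.root, threshold=0.5)
        assert not s.resolved
        assert s.top_mass == pytest.approx(1 / 3)

    def test_multi_state_mpr_set_unresolved(self):
        tree = Phylogeny.from_newick("(a:1,b:1);")
        recon = sankoff_parsimony(tree, {"a": 0b01, "b": 0b10}, 2)
        s = summarize_node(recon, tree.root)
        assert not s.resolved
        assert len(s.labels) >= 2

    def test_node_table_and_pie_export(self, study_fixture, five_area):
        model = DECModel(
            study_fixture.tree, study_fixture.tip_ranges, five_area, "B"
        )
        recon = results_at(model, 0.004, 0.002).ancestral_ranges()
        tab = recon.node_table()
        assert len(tab) == study_fixture.tree.n_tips - 1
        assert set(tab.columns) >= {"node", "method", "resolved", "support"}
        pies = recon.pie_data()
        some_node = next(iter(pies))
        assert abs(sum(pies[some_node].values()) - 1.0) < 1e-6
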