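import warnings

import dendropy
import numpy as np
import pytest
from dendropy.calculate import treecompare
from scipy.stats import spearmanr

import enphylo as ep
from enphylo import phylo_niche as pn
from enphylo.errors import InputError


def _tree(newick):
    return dendropy.Tree.get(data=newick, schema="newick")


def _table(**traits):
    table = pn.NicheTraitTable()
    for sp, v in traits.items():
        table.add(sp, np.asarray(v, dtype=float))
    return table


class TestImputation:
    def test_zero_distance_sister_copied_exactly(self):
        tree = _tree("((A:0.00000001,T:0.00000001):0.5,(B:0.5,C:0.5):0.5);")
        table = _table(A=[1.0, -2.0], B=[5.0, 5.0], C=[-4.0, 3.0])
        imputed, var = pn.impute_tip_traits(tree, table, "T")
        np.testing.assert_allclose(imputed, [1.0, -2.0], atol=1e-5)
        assert np.all(var >= 0)

    def test_star_tree_gives_arithmetic_mean(self):
        tree = _tree("(A:1,B:1,C:1,T:1);")
        table = _table(A=[0.0], B=[3.0], C=[6.0])
        imputed, _ = pn.impute_tip_traits(tree, table, "T")
        assert imputed[0] == pytest.approx(3.0)

    def test_target_not_in_tree_raises(self):
        tree = _tree("(A:1,B:1,C:1);")
        table = _table(A=[0.0], B=[1.0], C=[2.0])
        with pytest.raises(InputError):
            pn.impute_tip_traits(tree, table, "Z")

    def test_too_few_observed_raises(self):
        tree = _tree("(A:1,B:1,T:1);")
        table = _table(A=[0.0], B=[1.0])
        with pytest.raises(InputError):
            pn.impute_tip_traits(tree, table, "T")

    def test_bm_parameter_recovery(self):
        # simulate BM traits on 64-tip trees, mask 20% of tips, impute:
        # imputed vectors correlate with the true ones
        rs = []
        for seed in range(20):
            truth = ep.simulate_tree_and_niches(64, 5, bm_rate=1.0, seed=seed)
            species = truth.species
            rng = np.random.default_rng(seed)
            masked = list(rng.choice(species, size=13, replace=False))
            table = pn.NicheTraitTable()
            for sp in species:
                if sp not in masked:
                    table.add(sp, truth.niche_optima.loc[sp].to_numpy())
            for sp in masked:
                imputed, _ = pn.impute_tip_traits(truth.tree, table, sp)
                true = truth.niche_optima.loc[sp].to_numpy()
                rs.append(np.corrcoef(imputed, true)[0, 1])
        assert np.mean(rs) > 0.7


class TestPerturbTree:
    def _base(self):
        truth = ep.simulate_tree_and_niches(12, 1, seed=0)
        return truth.tree

    def test_same_seed_identical(self):
        tree = self._base()
        a = pn.perturb_tree(tree, seed=5).as_string(schema="newick")
        b = pn.perturb_tree(tree, seed=5).as_string(schema="newick")
        assert a == b

    def test_tip_set_preserved(self):
        tree = self._base()
        before = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
        out = pn.perturb_tree(tree, seed=3)
        after = {leaf.taxon.label for leaf in out.leaf_node_iter()}
        assert before == after

    def test_topology_changes_across_seeds(self):
        tree = self._base()
        changed = 0
        for seed in range(50):
            out = pn.perturb_tree(tree, seed=seed)
            rf = treecompare.symmetric_difference(tree, out)
            if rf > 0:
                changed += 1
        assert changed >= 1

    def test_tiny_tree_returned_unchanged(self):
        tree = _tree("(A:1,B:1,C:1);")
        with pytest.warns(UserWarning):
            out = pn.perturb_tree(tree, seed=0)
        assert {l.taxon.label for l in out.leaf_node_iter()} == {"A", "B", "C"}


class TestKnightCandidates:
    def _stack(self, n=10):
        return ep.EnvStack(["a"], np.ones((1, n, n)), 1.0, (0, 0),
                           np.zeros((n, n), dtype=bool))

    def test_interior_reference_has_eight(self):
        cand = pn.knight_candidates([(5, 5)], self._stack())
        assert len(cand) == 8
        assert (3, 4) in cand and (7, 6) in cand

    def test_corner_reference_clipped(self):
        cand = pn.knight_candidates([(0, 0)], self._stack())
        assert sorted(cand) == [(1, 2), (2, 1)]

    def test_union_deduplicated(self):
        # (0,0) and (4,0): candidate sets overlap in (2,1)
        cand = pn.knight_candidates([(0, 0), (4, 0)], self._stack())
        assert cand.count((2, 1)) == 1
        assert len(cand) == len(set(cand))

    def test_no_candidates_raises(self):
        mask = np.ones((5, 5), dtype=bool)
        mask[0, 0] = False
        stack = ep.EnvStack(["a"], np.ones((1, 5, 5)), 1.0, (0, 0), mask)
        with pytest.raises(InputError):
            pn.knight_candidates([(0, 0)], stack)


class TestAngleSimilarity:
    def _stack_with_vectors(self, vectors):
        """One row per cell; 3 layers carry each cell's vector."""
        X = np.asarray(vectors, dtype=float)
        n = X.shape[0]
        vals = X.T.reshape(X.shape[1], 1, n)
        return ep.EnvStack([f"v{i}" for i in range(X.shape[1])], vals, 1.0,
                           (0, 0), np.zeros((1, n), dtype=bool))

    def test_identical_vector_is_one(self):
        zs = self._stack_with_vectors([[1.0, 2.0, 3.0], [1.0, 2.0, 3.0]])
        assert pn.angle_similarity((0, 0), [(0, 1)], zs) == pytest.approx(1.0)

    def test_negated_vector_is_minus_one(self):
        zs = self._stack_with_vectors([[1.0, 2.0, 3.0], [-1.0, -2.0, -3.0]])
        assert pn.angle_similarity((0, 0), [(0, 1)], zs) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        zs = self._stack_with_vectors([[1.0, 0.0, 1.0], [1.0, 1.0, 0.0]])
        assert pn.angle_similarity((0, 0), [(0, 1)], zs) == pytest.approx(-0.5)

    def test_constant_vector_ranks_last(self):
        zs = self._stack_with_vectors([[2.0, 2.0, 2.0], [1.0, 0.0, 1.0]])
        with pytest.warns(UserWarning):
            sim = pn.angle_similarity((0, 0), [(0, 1)], zs)
        assert sim == float("-inf")


class TestSelectPseudoPresences:
    def test_counts_by_reference_number(self, small_std):
        _, _, zs = small_std
        for n_ref, n_pseudo in [(2, 3), (3, 2), (4, 1)]:
            refs = [(10 + 5 * i, 10) for i in range(n_ref)]
            got = pn.select_pseudo_presences(refs, zs)
            assert len(got) == n_pseudo
            assert not set(got) & set(refs)

    def test_five_references_need_no_extension(self, small_std):
        _, _, zs = small_std
        refs = [(5, 5), (6, 6), (7, 7), (8, 8), (9, 9)]
        assert pn.select_pseudo_presences(refs, zs) == []

    def test_single_reference_raises(self, small_std):
        _, _, zs = small_std
        with pytest.raises(InputError):
            pn.select_pseudo_presences([(5, 5)], zs)

    def test_selected_dominate_unselected(self, small_std):
        # brute force: every selected candidate scores at least as high as
        # every unselected one (with the distance tie-break)
        _, _, zs = small_std
        refs = [(12, 12), (14, 15), (16, 12), (13, 18)]
        chosen = pn.select_pseudo_presences(refs, zs)
        cand = pn.knight_candidates(refs, zs)
        sims = {c: pn.angle_similarity(c, refs, zs) for c in cand}
        worst_chosen = min(sims[c] for c in chosen)
        best_unchosen = max((sims[c] for c in cand if c not in chosen),
                            default=float("-inf"))
        assert worst_chosen >= best_unchosen - 1e-12

    def test_similarity_tie_broken_by_distance(self):
        # two layers varying only along rows: cells in the same row have
        # identical vectors, so knight candidates in symmetric rows tie
        nrows, ncols = 9, 9
        rowvals = np.linspace(-1, 1, nrows)
        v0 = np.tile(rowvals[:, None], (1, ncols))
        vals = np.stack([v0, -v0, 2 * v0])
        zs = ep.EnvStack(["a", "b", "c"], vals, 1.0, (0, 0),
                         np.zeros((nrows, ncols), dtype=bool))
        refs = [(4, 1), (4, 2), (4, 3), (4, 4)]
        chosen = pn.select_pseudo_presences(refs, zs)
        assert len(chosen) == 1
        # all candidates in rows 4±1 and 4±2 tie on similarity; the winner
        # must be one of the geometrically closest (distance sqrt(2))
        assert min(abs(chosen[0][0] - 4), abs(chosen[0][1] - 4)) <= 2
        best_d = min(np.hypot(c[0] - r[0], c[1] - r[1])
                     for c in pn.knight_candidates(refs, zs) for r in refs)
        got_d = min(np.hypot(chosen[0][0] - r[0], chosen[0][1] - r[1])
                    for r in refs)
        assert got_d == pytest.approx(best_d)


class TestFitEnphylo:
    @pytest.fixture(scope="class")
    def setup(self, default_fixture, default_std, default_donors):
        table = ep.build_trait_table(default_donors)
        return default_fixture, default_std, table

    def test_presence_set_is_five_for_rare(self, setup):
        fx, (bg, _, zs), table = setup
        sp = next(s for s, n in fx.truth.occurrence_counts.items() if n == 3)
        fit = ep.fit_enphylo(sp, fx.occurrences[sp].cell_ids, fx.truth.tree,
                             table, zs, bg.cell_ids, n_tree_reps=2, seed=1)
        assert len(fit.presence_cells) == 5
        assert not set(fit.pseudo_cells) & set(fit.reference_cells)

    def test_single_tree_uses_input_tree(self, setup):
        fx, (bg, _, zs), table = setup
        sp = next(s for s, n in fx.truth.occurrence_counts.items() if n == 4)
        fit = ep.fit_enphylo(sp, fx.occurrences[sp].cell_ids, fx.truth.tree,
                             table, zs, bg.cell_ids, n_tree_reps=1, seed=1)
        assert fit.chosen_tree_index == 0

    def test_deterministic_under_seed(self, setup):
        fx, (bg, _, zs), table = setup
        sp = next(s for s, n in fx.truth.occurrence_counts.items() if n == 2)
        fits = [
            ep.fit_enphylo(sp, fx.occurrences[sp].cell_ids, fx.truth.tree,
                           table, zs, bg.cell_ids, n_tree_reps=5, seed=42)
            for _ in range(2)
        ]
        assert fits[0].chosen_tree_index == fits[1].chosen_tree_index
        np.testing.assert_array_equal(fits[0].suitability,
                                      fits[1].suitability)

    def test_masked_rich_species_matches_full_fit(self, setup):
        # treat a data-rich species as rare by masking all but 3 cells: the
        # imputed-niche map should rank-correlate with the full-data ENFA map
        fx, (bg, _, zs), table = setup
        sp = max(fx.truth.occurrence_counts, key=fx.truth.occurrence_counts.get)
        cells = fx.occurrences[sp].cell_ids
        full = ep.fit_enfa(zs, cells, bg.cell_ids)
        full_map = ep.mahalanobis_suitability(full, zs)
        masked_table = pn.NicheTraitTable(s_axes=table.s_axes)
        for s, v in table.traits.items():
            if s != sp:
                masked_table.add(s, v)
        masked_table.donor_marg_var = [v for s, v in
                                       zip(table.traits, table.donor_marg_var)
                                       if s != sp]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = ep.fit_enphylo(sp, cells[:10], fx.truth.tree, masked_table,
                                 zs, bg.cell_ids, n_tree_reps=5, seed=9)
        valid = np.isfinite(full_map)
        rho = spearmanr(fit.suitability[valid], full_map[valid]).statistic
        assert rho > 0.5
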