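import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import enphylo as ep
from enphylo import ensemble as es
from enphylo.errors import ExcludedSpeciesError, InputError, ModelRejectedError


class TestTiers:
    @pytest.mark.parametrize("n,tier", [
        (2, "ENPHYLO"), (14, "ENPHYLO"), (15, "ESM"), (30, "ESM"),
        (31, "SDM"), (60, "SDM"),
    ])
    def test_boundaries(self, n, tier):
        assert ep.assign_tier("sp", n).tier == tier

    def test_single_cell_excluded(self):
        with pytest.raises(ExcludedSpeciesError):
            ep.assign_tier("sp", 1)

    def test_partition_exhaustive_and_exclusive(self):
        for n in range(2, 100):
            t = ep.assign_tier("sp", n).tier
            assert t in ("ENPHYLO", "ESM", "SDM")
            assert (t == "ENPHYLO") == (n < 15)
            assert (t == "ESM") == (15 <= n <= 30)
            assert (t == "SDM") == (n > 30)


def _auc_brute(pos, neg):
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def _tss_brute(pos, neg):
    best = -1.0
    for t in set(pos) | set(neg):
        sens = np.mean([p >= t for p in pos])
        spec = np.mean([n < t for n in neg])
        best = max(best, sens + spec - 1.0)
    return best


class TestAuc:
    def test_perfect_separation(self):
        assert ep.auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_three_of_four_pairs_concordant(self):
        assert ep.auc([0.8, 0.4], [0.6, 0.2]) == pytest.approx(0.75)

    def test_identical_distributions_centered_at_half(self):
        rng = np.random.default_rng(0)
        vals = [ep.auc(rng.random(50), rng.random(50)) for _ in range(50)]
        assert abs(np.mean(vals) - 0.5) < 0.05

    def test_empty_class_raises(self):
        with pytest.raises(InputError):
            ep.auc([], [0.5])

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]),
                    min_size=1, max_size=20),
           st.lists(st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]),
                    min_size=1, max_size=20))
    def test_matches_brute_force_pair_counting(self, pos, neg):
        assert ep.auc(pos, neg) == pytest.approx(_auc_brute(pos, neg))


class TestTss:
    def test_formula(self):
        # perfectly separated at best threshold: sens 1, spec 1
        assert ep.tss([0.9, 0.8], [0.1, 0.2]) == pytest.approx(1.0)

    def test_partial_overlap(self):
        assert ep.tss([0.8, 0.4], [0.6, 0.2]) == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1, width=16), min_size=1, max_size=15),
           st.lists(st.floats(0, 1, width=16), min_size=1, max_size=15))
    def test_matches_exhaustive_threshold_scan(self, pos, neg):
        assert ep.tss(pos, neg) == pytest.approx(_tss_brute(pos, neg))


class TestBoyce:
    def test_monotone_increasing_pe_ratio(self):
        # presence density proportional to score on a uniform background:
        # P/E rises monotonically with the window midpoint
        rng = np.random.default_rng(1)
        bg = rng.random(2000)
        pos = np.sqrt(rng.random(500))
        assert ep.boyce(pos, bg) > 0.9

    def test_monotone_decreasing_pe_ratio(self):
        rng = np.random.default_rng(1)
        bg = rng.random(2000)
        pos = 1.0 - np.sqrt(rng.random(500))
        assert ep.boyce(pos, bg) < -0.9

    def test_degenerate_identical_scores_undefined(self):
        with pytest.warns(UserWarning):
            out = ep.boyce(np.full(10, 0.5), np.full(100, 0.5))
        assert np.isnan(out)


class TestEnsembleAverage:
    class _Const:
        def __init__(self, v):
            self.v = v

        def score_cells(self, stack, cells):
            return np.full(len(cells), self.v)

    def _rec(self, auc_val):
        r = es.EvalRecord()
        r.auc_values = [auc_val]
        r.tss_values = [0.5]
        r.boyce_values = [0.5]
        return r

    def test_single_scorer_identity(self, flat_stack):
        w = ep.ensemble_average([(self._Const(0.3), self._rec(0.9))])
        got = w.score_cells(flat_stack, [(0, 0)])
        assert got[0] == pytest.approx(0.3)

    def test_equal_weights_plain_mean(self, flat_stack):
        w = ep.ensemble_average([(self._Const(0.2), self._rec(0.8)),
                                 (self._Const(0.6), self._rec(0.8))])
        assert w.score_cells(flat_stack, [(0, 0)])[0] == pytest.approx(0.4)

    def test_auc_weighting_formula(self, flat_stack):
        w = ep.ensemble_average([(self._Const(1.0), self._rec(0.8)),
                                 (self._Const(0.0), self._rec(0.9))])
        assert w.score_cells(flat_stack, [(0, 0)])[0] == \
            pytest.approx(0.8 / 1.7)

    def test_output_stays_in_unit_interval(self, flat_stack):
        rng = np.random.default_rng(3)
        members = [(self._Const(rng.random()), self._rec(0.7 + 0.3 * rng.random()))
                   for _ in range(5)]
        w = ep.ensemble_average(members)
        got = w.score_cells(flat_stack, [(0, 0), (1, 1)])
        assert np.all((got >= 0) & (got <= 1))

    def test_none_passing_rejected(self, flat_stack):
        with pytest.raises(ModelRejectedError):
            ep.ensemble_average([(self._Const(0.5), self._rec(0.5))])


def _toy_stack(X):
    n = X.shape[0]
    vals = X.T.reshape(X.shape[1], 1, n)
    return ep.EnvStack([f"v{i}" for i in range(X.shape[1])], vals, 1.0,
                       (0, 0), np.zeros((1, n), dtype=bool))


class TestLearners:
    @pytest.mark.parametrize("kind", es.LEARNER_KINDS)
    def test_null_model_auc_near_half(self, kind):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((400, 2))
        zs = _toy_stack(X)
        cells = zs.valid_cells()
        pres, bg = cells[:100], cells[100:300]
        test_p, test_b = cells[300:350], cells[350:400]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = ep.fit_learner(kind, pres, bg, zs, seed=0, n_trees=100)
        a = ep.auc(model.score_cells(zs, test_p), model.score_cells(zs, test_b))
        assert abs(a - 0.5) < 0.15

    @pytest.mark.parametrize("kind", es.LEARNER_KINDS)
    def test_separable_toy_auc_one(self, kind):
        rng = np.random.default_rng(5)
        Xp = rng.standard_normal((50, 2)) + 4.0
        Xb = rng.standard_normal((200, 2)) - 4.0
        zs = _toy_stack(np.vstack([Xp, Xb]))
        cells = zs.valid_cells()
        pres, bg = cells[:50], cells[50:]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = ep.fit_learner(kind, pres, bg, zs, seed=0, n_trees=100)
        a = ep.auc(model.score_cells(zs, pres), model.score_cells(zs, bg))
        assert a > 0.99

    def test_glm_recovers_interior_optimum(self):
        # unimodal response along layer 1: the quadratic logistic model's
        # fitted score peaks at the true optimum
        rng = np.random.default_rng(6)
        grid = np.linspace(-3, 3, 500)
        X = np.column_stack([grid, rng.standard_normal(500) * 0.1])
        zs = _toy_stack(X)
        cells = zs.valid_cells()
        p_true = np.exp(-0.5 * ((grid - 0.8) / 0.6) ** 2)
        pres = [c for c, p in zip(cells, p_true) if rng.random() < p]
        bg = list(rng.permutation(len(cells))[:300])
        bg = [cells[i] for i in bg]
        model = ep.fit_learner("GLM_QUAD", pres, bg, zs, seed=0)
        scores = model.score_cells(zs, cells)
        got = grid[int(np.argmax(scores))]
        assert abs(got - 0.8) < 2 * (grid[1] - grid[0]) * 50  # within ~0.6

    def test_rf_allows_single_layer(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((100, 1))
        zs = _toy_stack(X)
        cells = zs.valid_cells()
        model = ep.fit_learner("RF", cells[:20], cells[20:], zs, seed=0,
                               n_trees=50)
        assert model.score_cells(zs, cells[:5]).shape == (5,)

    def test_single_layer_rejected_for_glm(self):
        rng = np.random.default_rng(8)
        zs = _toy_stack(rng.standard_normal((100, 1)))
        cells = zs.valid_cells()
        with pytest.raises(InputError):
            ep.fit_learner("GLM_QUAD", cells[:20], cells[20:], zs)


class _PerfectScorer:
    """Scores 1 on a fixed presence set, 0 elsewhere."""

    def __init__(self, presence):
        self.presence = set(presence)

    def score_cells(self, stack, cells):
        return np.array([1.0 if c in self.presence else 0.0 for c in cells])


class TestBootstrapEvaluate:
    def _data(self, flat_stack):
        cells = flat_stack.valid_cells()
        return cells[:30], cells[30:130]

    def test_perfect_scorer_scores_one(self, flat_stack):
        pres, bg = self._data(flat_stack)
        fitter = lambda p, b, s: _PerfectScorer(pres)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = ep.bootstrap_evaluate(fitter, pres, bg, flat_stack, seed=0)
        assert len(rec.auc_values) == 10  # default replicate count
        assert all(a == 1.0 for a in rec.auc_values)
        assert all(t == 1.0 for t in rec.tss_values)
        assert rec.pass_flag

    def test_deterministic_under_seed(self, flat_stack):
        pres, bg = self._data(flat_stack)
        rng_holder = []

        def fitter(p, b, s):
            rng_holder.append(s)
            return _PerfectScorer(pres)

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = ep.bootstrap_evaluate(fitter, pres, bg, flat_stack, seed=3)
            b = ep.bootstrap_evaluate(fitter, pres, bg, flat_stack, seed=3)
        assert a.auc_values == b.auc_values
        assert a.tss_values == b.tss_values
        np.testing.assert_array_equal(a.boyce_values, b.boyce_values)

    def test_tiny_presence_set_skipped_under_default_rule(self, flat_stack):
        # 5 presences leave a single test presence: every replicate is
        # skipped under the default minimum of 2 test presences
        pres, bg = self._data(flat_stack)
        fitter = lambda p, b, s: _PerfectScorer(pres)
        with pytest.raises(InputError), warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ep.bootstrap_evaluate(fitter, pres[:5], bg, flat_stack, seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rec = ep.bootstrap_evaluate(fitter, pres[:5], bg, flat_stack,
                                        seed=0, min_test_presences=1)
        assert rec.auc_values


class TestEsm:
    def _species(self, rng, V, n_pres=20, n_bg=150):
        X = rng.standard_normal((n_pres + n_bg, V))
        X[:n_pres] += 1.5  # niche shift on every layer
        zs = _toy_stack(X)
        cells = zs.valid_cells()
        return zs, cells[:n_pres], cells[n_pres:]

    def test_two_layers_give_one_combination_per_learner(self):
        rng = np.random.default_rng(9)
        zs, pres, bg = self._species(rng, 2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scorer, records = ep.fit_esm(pres, bg, zs, ["GLM_QUAD"], seed=0,
                                         n_reps=5)
        assert len(records) == 1

    def test_five_layers_give_ten_combinations(self):
        rng = np.random.default_rng(10)
        zs, pres, bg = self._species(rng, 5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scorer, records = ep.fit_esm(pres, bg, zs, ["GLM_QUAD"], seed=0,
                                         n_reps=5)
        assert len(records) == 10

    def test_scores_within_unit_interval(self):
        rng = np.random.default_rng(11)
        zs, pres, bg = self._species(rng, 3)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            scorer, _ = ep.fit_esm(pres, bg, zs, ["GLM_QUAD"], seed=0,
                                   n_reps=5)
        got = scorer.score_cells(zs, bg[:20])
        assert np.all((got >= 0) & (got <= 1))
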