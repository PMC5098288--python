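"""Validation designs: metrics, CI machinery, pairing, plateau logic."""

import numpy as np
import pytest
from scipy import stats

import selftraingp as sg
from selftraingp.experiments import stopping_step


@pytest.fixture(scope="module")
def design():
    """A pool/test layout over a moderately heritable population."""
    params = sg.SimulationParams(n_animals=220, n_markers=150, n_qtl=50,
                                 heritability=0.5, seed=21)
    pop = sg.simulate_population(params)
    ids = pop.animal_ids
    return {
        "pop": pop,
        "G": pop.genotypes,
        "phen": pop.phenotype_series(),
        "pool": ids[:120],
        "unlabeled": ids[120:200],
        "test": ids[200:],
    }


class TestEvaluate:
    def test_perfect_predictions(self, design):
        pop = design["pop"]
        f = sg.train_base(design["G"], pop.true_rfi)

        class Identity:
            def predict(self, G):
                return design["phen"].reindex(list(G.animal_ids)).to_numpy()

        ident = Identity()
        m = sg.evaluate(ident, design["G"].subset_animals(design["test"]),
                        design["phen"])
        assert m.correlation == pytest.approx(1.0)
        assert m.mse == pytest.approx(0.0)

    def test_sign_flip_gives_minus_one(self, design):
        class Neg:
            def predict(self, G):
                return -design["phen"].reindex(list(G.animal_ids)).to_numpy()

        m = sg.evaluate(Neg(), design["G"].subset_animals(design["test"]),
                        design["phen"])
        assert m.correlation == pytest.approx(-1.0)

    def test_hand_computed_example(self):
        class Fixed:
            def predict(self, G):
                return np.array([1.0, 2.0, 3.0])

        G = sg.GenotypeMatrix(["a", "b", "c"], ["m"], [[0.0], [1.0], [2.0]])
        m = sg.evaluate(Fixed(), G, np.array([2.0, 4.0, 6.0]))
        assert m.correlation == pytest.approx(1.0)
        assert m.mse == pytest.approx(14 / 3)

    def test_constant_prediction_undefined_correlation_mse_kept(self):
        class Const:
            def predict(self, G):
                return np.zeros(G.n_animals)

        G = sg.GenotypeMatrix(["a", "b", "c"], ["m"], [[0.0], [1.0], [2.0]])
        m = sg.evaluate(Const(), G, np.array([1.0, 2.0, 4.0]))
        assert np.isnan(m.correlation)
        assert m.mse == pytest.approx(7.0)

    def test_too_few_test_animals(self, design):
        with pytest.raises(ValueError, match="at least 3"):
            sg.evaluate(None, design["G"].subset_animals(design["test"][:2]),
                        design["phen"])


class TestCiMachinery:
    def test_halfwidth_formula(self):
        values = np.array([1.0, 2.0, 3.0, 4.0])
        expected = stats.t.ppf(0.975, 3) * values.std(ddof=1) / 2.0
        assert sg.mean_ci_halfwidth(values) == pytest.approx(expected)

    def test_single_value_flagged_undefined(self):
        assert np.isnan(sg.mean_ci_halfwidth(np.array([1.0])))

    def test_normal_option_narrower_than_t(self):
        values = np.arange(5.0)
        assert (sg.mean_ci_halfwidth(values, normal=True)
                < sg.mean_ci_halfwidth(values))

    def test_empirical_coverage_near_nominal(self):
        # 2000 sets of 15 normals; the acceptance check repeats at 5000
        rng = np.random.default_rng(3)
        hits = 0
        trials = 2000
        for _ in range(trials):
            x = rng.normal(5.0, 2.0, size=15)
            hw = sg.mean_ci_halfwidth(x)
            hits += abs(x.mean() - 5.0) <= hw
        assert 0.93 <= hits / trials <= 0.97


class TestLearningCurve:
    def config(self, **kw):
        base = dict(labeled_sizes=(10, 40), n_replicates=6, seed=5)
        base.update(kw)
        return sg.ExperimentConfig(**base)

    def test_full_pool_size_has_zero_ci(self, design):
        config = self.config(labeled_sizes=(len(design["pool"]),),
                             n_replicates=4)
        [summary] = sg.learning_curve(design["G"], design["phen"],
                                      design["pool"], design["test"], config)
        assert np.ptp(summary.correlations) == 0.0
        assert summary.ci_correlation == 0.0

    def test_more_data_helps(self, design):
        config = self.config(labeled_sizes=(15, 100), n_replicates=12)
        lo, hi = sg.learning_curve(design["G"], design["phen"],
                                   design["pool"], design["test"], config)
        assert hi.mean_correlation > lo.mean_correlation

    def test_single_replicate_has_undefined_ci(self, design):
        config = self.config(labeled_sizes=(10,), n_replicates=1)
        [summary] = sg.learning_curve(design["G"], design["phen"],
                                      design["pool"], design["test"], config)
        assert summary.n_replicates == 1
        assert np.isnan(summary.ci_correlation)

    def test_size_exceeding_pool_errors(self, design):
        config = self.config(labeled_sizes=(10_000,))
        with pytest.raises(ValueError, match="exceeds pool"):
            sg.learning_curve(design["G"], design["phen"], design["pool"],
                              design["test"], config)

    def test_reproducible_bit_identically(self, design):
        config = self.config()
        a = sg.learning_curve(design["G"], design["phen"], design["pool"],
                              design["test"], config)
        b = sg.learning_curve(design["G"], design["phen"], design["pool"],
                              design["test"], config)
        for s1, s2 in zip(a, b):
            np.testing.assert_array_equal(s1.correlations, s2.correlations)


class TestRatioSweep:
    def test_zero_unlabeled_cell_has_exactly_zero_difference(self, design):
        config = sg.ExperimentConfig(sweep_labeled_sizes=(30,),
                                     unlabeled_sizes=(0,), n_replicates=4,
                                     seed=6)
        result = sg.ratio_sweep(design["G"], design["phen"], design["pool"],
                                design["unlabeled"], design["test"], config)
        cell = result.cells[(30, 0)]
        np.testing.assert_array_equal(cell.diff_correlations,
                                      np.zeros(4))
        assert cell.ci_diff_correlation == 0.0

    def test_pairing_mean_of_differences(self, design):
        config = sg.ExperimentConfig(sweep_labeled_sizes=(30,),
                                     unlabeled_sizes=(40,), n_replicates=5,
                                     seed=7)
        result = sg.ratio_sweep(design["G"], design["phen"], design["pool"],
                                design["unlabeled"], design["test"], config)
        cell = result.cells[(30, 40)]
        assert cell.mean_diff_correlation == pytest.approx(
            np.mean(cell.augmented.correlations - cell.base.correlations))

    def test_infeasible_cell_skipped_with_report(self, design):
        config = sg.ExperimentConfig(sweep_labeled_sizes=(30,),
                                     unlabeled_sizes=(40, 10_000),
                                     n_replicates=2, seed=8)
        result = sg.ratio_sweep(design["G"], design["phen"], design["pool"],
                                design["unlabeled"], design["test"], config)
        assert (30, 10_000) not in result.cells
        assert any(nl == 30 and nu == 10_000 for nl, nu, _ in result.skipped)

    def test_cells_reproducible(self, design):
        config = sg.ExperimentConfig(sweep_labeled_sizes=(25,),
                                     unlabeled_sizes=(30,), n_replicates=3,
                                     seed=9)
        args = (design["G"], design["phen"], design["pool"],
                design["unlabeled"], design["test"], config)
        a, b = sg.ratio_sweep(*args), sg.ratio_sweep(*args)
        np.testing.assert_array_equal(
            a.cells[(25, 30)].diff_correlations,
            b.cells[(25, 30)].diff_correlations)


class TestPlateau:
    def test_infinite_tolerance_stops_after_first_increment(self, design):
        config = sg.ExperimentConfig(n_replicates=3, plateau_increment=20,
                                     plateau_tolerance=np.inf, seed=10)
        results = sg.plateau_search(design["G"], design["phen"],
                                    design["pool"], design["unlabeled"],
                                    design["test"], config,
                                    labeled_sizes=(40,))
        res = results[40]
        assert all(r.stopped_at == 20 for r in res.replicates)
        np.testing.assert_allclose(res.ratios, 0.5)
        assert all(len(r.step_correlations) == 1 for r in res.replicates)

    def test_zero_tolerance_runs_to_pool_exhaustion(self, design):
        config = sg.ExperimentConfig(n_replicates=2, plateau_increment=30,
                                     plateau_tolerance=0.0, seed=11)
        results = sg.plateau_search(design["G"], design["phen"],
                                    design["pool"], design["unlabeled"],
                                    design["test"], config,
                                    labeled_sizes=(40,))
        for rep in results[40].replicates:
            assert rep.exhausted
            assert rep.step_sizes == [30, 60]  # pool of 80, increment 30
        assert results[40].n_exhausted == 2

    def test_increment_larger_than_pool_errors(self, design):
        config = sg.ExperimentConfig(n_replicates=1, plateau_increment=10_000)
        with pytest.raises(ValueError, match="increment"):
            sg.plateau_search(design["G"], design["phen"], design["pool"],
                              design["unlabeled"], design["test"], config,
                              labeled_sizes=(40,))

    def test_no_step_beyond_the_stopping_step(self, design):
        config = sg.ExperimentConfig(n_replicates=4, plateau_increment=20,
                                     plateau_tolerance=0.05, seed=12)
        results = sg.plateau_search(design["G"], design["phen"],
                                    design["pool"], design["unlabeled"],
                                    design["test"], config,
                                    labeled_sizes=(40,))
        for rep in results[40].replicates:
            if not rep.exhausted:
                # the stopping step is the last one evaluated
                assert rep.step_sizes[-1] == rep.stopped_at
                idx = stopping_step(rep.step_correlations,
                                    rep.baseline_correlation, 0.05)
                assert idx == len(rep.step_correlations) - 1

    def test_stopping_rule_on_fixed_traces(self):
        assert stopping_step([0.30, 0.31, 0.3105], 0.25, 0.01) == 2
        assert stopping_step([0.20], 0.25, 0.01) == 0
        assert stopping_step([0.30, 0.40], 0.25, 0.01) is None
        assert stopping_step([0.30, 0.29], 0.25, 0.0) is None
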