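import numpy as np
import pytest

from osteoscreen import synthetic
from osteoscreen.datasets import apply_scaling, fit_scaling
from osteoscreen.networks import NetworkSpec, forward
from osteoscreen.training import (GeneralizationReport, SplitPlan, TrainConfig,
                                  assess_generalization, random_split,
                                  rms_error, select_architecture,
                                  train, train_ensemble, tune_hyperparameters)

FF0 = NetworkSpec("feedforward", 0)


@pytest.fixture(scope="module")
def scaled_linear():
    ds = synthetic.generate_dataset(synthetic.linear_spec(120, seed=11))
    return apply_scaling(ds, fit_scaling(ds), clip=False)


class TestTrain:
    def test_zero_iterations_returns_initial_weights(self, scaled_linear):
        cfg = TrainConfig(0.5, 4, iterations=0, seed=1)
        a = train(FF0, scaled_linear, cfg)
        b = train(FF0, scaled_linear, TrainConfig(2.0, 1, 0, seed=1))
        assert np.array_equal(a.pack(), b.pack())  # lr/batch irrelevant at 0

    def test_deterministic_given_seed(self, scaled_linear):
        cfg = TrainConfig(0.5, 4, iterations=500, seed=3)
        a, b = train(FF0, scaled_linear, cfg), train(FF0, scaled_linear, cfg)
        assert np.array_equal(a.pack(), b.pack())

    def test_learning_curve_improves(self, scaled_linear):
        short = train(FF0, scaled_linear, TrainConfig(1.0, 1, 100, seed=0))
        long = train(FF0, scaled_linear, TrainConfig(1.0, 1, 20000, seed=0))
        assert rms_error(long, scaled_linear) < rms_error(short, scaled_linear)

    def test_training_rms_approaches_logistic_floor(self, scaled_linear):
        """Noiseless additive data: depth-0 training RMS falls below 0.05."""
        ws = train(FF0, scaled_linear, TrainConfig(1.0, 1, 20000, seed=0))
        assert rms_error(ws, scaled_linear) < 0.05

    def test_epoch_sampling_mode(self, scaled_linear):
        cfg = TrainConfig(0.5, 4, 240, seed=0, sampling="epoch")
        ws = train(FF0, scaled_linear, cfg)
        assert np.isfinite(ws.pack()).all()


class TestRms:
    def test_perfect_predictions_give_zero(self, scaled_linear):
        ws = train(FF0, scaled_linear, TrainConfig(0.5, 4, 0, seed=0))
        out = forward(ws, scaled_linear.X).output
        perfect = scaled_linear
        from dataclasses import replace
        perfect = replace(perfect, Y=out, mask=np.ones_like(out, bool))
        assert rms_error(ws, perfect) == 0.0

    def test_single_cell_hand_calculation(self, scaled_linear):
        """One pattern, one observed outcome, error 0.5 -> RMS 0.5."""
        from osteoscreen.datasets import Dataset
        ws = train(FF0, scaled_linear, TrainConfig(0.5, 4, 0, seed=0))
        x = scaled_linear.X[:1]
        out = forward(ws, x).output
        Y = np.full((1, 26), np.nan)
        mask = np.zeros((1, 26), bool)
        Y[0, 0], mask[0, 0] = out[0, 0] - 0.5, True
        ds = Dataset(x, Y, mask)
        assert rms_error(ws, ds) == pytest.approx(0.5)

    def test_matches_two_loop_accumulation(self, scaled_linear, rng):
        ws = train(FF0, scaled_linear, TrainConfig(0.5, 4, 200, seed=0))
        out = forward(ws, scaled_linear.X).output
        total, count = 0.0, 0
        for i in range(scaled_linear.n_patterns):
            for k in range(26):
                if scaled_linear.mask[i, k]:
                    total += (scaled_linear.Y[i, k] - out[i, k]) ** 2
                    count += 1
        assert rms_error(ws, scaled_linear) == pytest.approx(
            np.sqrt(total / count), abs=1e-12)



class TestAssessment:
    def test_splits_disjoint_and_sized(self, rng):
        plan = SplitPlan(30, 10, 1, seed=0)
        tr, te = random_split(50, plan, rng)
        assert len(tr) == 30 and len(te) == 10
        assert len(set(tr) & set(te)) == 0
        assert len(set(tr) | set(te)) == 40

    def test_single_repeat_report(self, linear_dataset):
        plan = SplitPlan(90, 30, n_repeats=1, seed=2)
        rep = assess_generalization(FF0, TrainConfig(1.0, 2, 500),
                                    linear_dataset, plan)
        assert len(rep.test_rms) == 1
        assert rep.mean == rep.test_rms[0]
        assert rep.std == 0.0

    def test_oversized_split_rejected(self, linear_dataset):
        plan = SplitPlan(175, 50, 1, seed=0)
        with pytest.raises(ValueError, match="split"):
            assess_generalization(FF0, TrainConfig(1.0, 2, 100),
                                  linear_dataset, plan)


class TestTuning:
    def test_singleton_grids_return_that_config(self, linear_dataset):
        plan = SplitPlan(90, 30, 1, seed=0)
        best, report = tune_hyperparameters(FF0, [0.5], [4], linear_dataset,
                                            plan, iterations=200)
        assert best.learning_rate == 0.5 and best.batch_size == 4
        assert len(report) == 1

    def test_independent_sweep_evaluation_count(self, linear_dataset):
        plan = SplitPlan(90, 30, 1, seed=0)
        lr_grid, batch_grid = [0.3, 1.0], [2, 4, 8]
        _, report = tune_hyperparameters(FF0, lr_grid, batch_grid,
                                         linear_dataset, plan, iterations=200,
                                         default_batch=2)
        assert len(report) == len(lr_grid) + len(batch_grid) - 1

    def test_absurd_learning_rate_not_selected(self, linear_dataset):
        plan = SplitPlan(90, 30, 2, seed=1)
        best, _ = tune_hyperparameters(FF0, [1.0, 100.0], [2], linear_dataset,
                                       plan, iterations=1500)
        assert best.learning_rate == 1.0

    def test_full_grid_mode(self, linear_dataset):
        plan = SplitPlan(90, 30, 1, seed=0)
        _, report = tune_hyperparameters(FF0, [0.5, 1.0], [2, 4],
                                         linear_dataset, plan, iterations=200,
                                         full_grid=True)
        assert len(report) == 4


class TestSelection:
    def test_identical_candidates_rank_stably(self, linear_dataset):
        plan = SplitPlan(90, 30, 1, seed=0)
        cfg = TrainConfig(1.0, 2, 300)
        reports = select_architecture([(FF0, cfg), (FF0, cfg)],
                                      linear_dataset, plan)
        assert reports[0].mean == reports[1].mean

    def test_ranked_ascending_by_mean_rms(self, linear_dataset):
        plan = SplitPlan(90, 30, 1, seed=0)
        cfg = TrainConfig(1.0, 2, 1000)
        specs = [NetworkSpec("feedforward", d) for d in (0, 2)]
        reports = select_architecture([(s, cfg) for s in specs],
                                      linear_dataset, plan)
        means = [r.mean for r in reports]
        assert means == sorted(means)

    def test_additive_data_keeps_simplest_network_competitive(self, linear_dataset):
        """No planted interactions: depth-0 within 1 sd of the best.

        The budget is long enough for every candidate to be near its
        converged error; in an under-trained regime the comparison
        would measure optimisation speed, not representational need.
        """
        plan = SplitPlan(90, 30, 3, seed=4)
        cfg = TrainConfig(1.0, 1, 15000)
        specs = [NetworkSpec("feedforward", d) for d in (0, 1, 2)]
        reports = select_architecture([(s, cfg) for s in specs],
                                      linear_dataset, plan)
        ff0_rep = next(r for r in reports if r.spec.hidden_layers == 0)
        best = reports[0]
        spread = max(best.std, 1e-3)
        assert ff0_rep.mean <= best.mean + spread


class TestEnsemble:
    def test_single_member_prediction_equals_member(self, linear_dataset):
        ens = train_ensemble(FF0, TrainConfig(1.0, 2, 300), linear_dataset,
                             1, master_seed=0)
        from osteoscreen.screening import predict_ensemble
        X = linear_dataset.X[:5]
        scaled_mean, _ = predict_ensemble(ens.members, X, ens.scaling)
        from osteoscreen.datasets import scale_inputs
        direct = forward(ens.members[0],
                         scale_inputs(X, ens.scaling)).output
        np.testing.assert_array_equal(scaled_mean, direct)

    def test_members_pairwise_distinct(self, linear_dataset):
        ens = train_ensemble(FF0, TrainConfig(1.0, 2, 300), linear_dataset,
                             3, master_seed=0)
        packed = [m.pack() for m in ens.members]
        for i in range(3):
            for j in range(i + 1, 3):
                assert not np.array_equal(packed[i], packed[j])

    def test_ensemble_mean_rms_bounded_by_worst_member(self, linear_dataset):
        ens = train_ensemble(FF0, TrainConfig(1.0, 2, 2000), linear_dataset,
                             3, master_seed=1)
        scaled = apply_scaling(linear_dataset, ens.scaling, clip=False)
        member_rms = [rms_error(m, scaled) for m in ens.members]
        mean_out = np.mean([forward(m, scaled.X).output
                            for m in ens.members], axis=0)
        diff = (mean_out - np.where(scaled.mask, scaled.Y, 0.0))[scaled.mask]
        ens_rms = float(np.sqrt(np.mean(diff ** 2)))
        assert ens_rms <= max(member_rms) + 1e-12
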