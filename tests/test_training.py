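from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import kinetree.training as training
from kinetree.errors import EmptyEnsembleError
from kinetree.training import (
    CONTINUE,
    CONVERGED,
    REJECTED,
    STATUS_COMPLETED,
    STATUS_REJECTED,
    Ensemble,
    TrainConfig,
    build_feature_dataset,
    check_termination,
    cross_validate,
    make_cv_folds,
    predict,
    r2_score,
    select_and_ensemble,
    split_dataset,
    split_indices,
    train_two_stage,
    tune_hyperparameters,
)


class TestSplits:
    def test_paper_design_sizes(self):
        tr, va, te = split_indices(340, seed=0)
        assert (len(tr), len(va), len(te)) == (204, 68, 68)

    def test_small_dataset_sizes(self):
        tr, va, te = split_indices(10, seed=3)
        assert (len(tr), len(va), len(te)) == (6, 2, 2)

    def test_reproducible_and_partition(self):
        a = split_indices(101, seed=9)
        b = split_indices(101, seed=9)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)
        union = np.concatenate(a)
        assert len(union) == 101 and len(set(union)) == 101

    def test_too_small_refused(self):
        with pytest.raises(ValueError, match="too small"):
            split_indices(4)

    def test_bad_fractions_refused(self):
        with pytest.raises(ValueError, match="sum to 1"):
            split_indices(100, fractions=(0.5, 0.2, 0.2))

    def test_dataset_split_is_partition(self, factorial_dataset):
        ds, _ = factorial_dataset
        tr, va, te = split_dataset(ds, seed=1)
        assert len(tr) + len(va) + len(te) == len(ds)
        keys = pd.concat(
            [d.reactions[["ligand_id", "substituent", "position"]] for d in (tr, va, te)]
        )
        assert not keys.duplicated().any()


class TestTerminationRule:
    cfg = TrainConfig()

    def test_short_window_continues(self):
        assert check_termination([1.0] * 10, self.cfg) == CONTINUE

    def test_monotone_decrease_continues(self):
        losses = list(np.linspace(10, 5, 11))  # mean |change| 0.5, no flips
        assert check_termination(losses, self.cfg) == CONTINUE

    def test_alternating_half_rejected(self):
        losses = [5 + 0.25 * (-1) ** i for i in range(11)]  # changes +-0.5
        assert check_termination(losses, self.cfg) == REJECTED

    def test_flat_converges(self):
        assert check_termination([3.0] * 11, self.cfg) == CONVERGED

    def test_small_alternation_not_rejected(self):
        # 100% flips but mean |change| below the 0.2 magnitude arm
        losses = [5 + 0.05 * (-1) ** i for i in range(11)]
        assert check_termination(losses, self.cfg) != REJECTED

    def test_pure_function_of_window(self):
        tail = [5 + 0.25 * (-1) ** i for i in range(11)]
        assert check_termination([99, 0, 42] + tail, self.cfg) == check_termination(
            tail, self.cfg
        )


class TestTrainTwoStage:
    def test_zero_epochs_returns_untrained_with_metrics(self, tiny_dataset):
        ds, _ = tiny_dataset
        tr, va, _ = split_dataset(ds, seed=0)
        res = train_two_stage(tr, va, TrainConfig(max_epochs=0, seed=1))
        assert res.termination_status == STATUS_COMPLETED
        assert res.loss_history == []
        assert np.isfinite(res.val_mae)

    def test_noiseless_toy_reaches_tight_energy_fit(self, tiny_dataset):
        ds, synth = tiny_dataset
        tr, va, _ = split_dataset(ds, seed=0)
        res = train_two_stage(
            tr, va, TrainConfig(learning_rate=0.005, max_epochs=1000, seed=3)
        )
        pred = predict(res.model, tr)
        mae_dG = float(np.mean(np.abs(pred["dG_total"] - tr.dG_obs)))
        assert mae_dG < 0.1
        assert res.val_r2 > 0.99

    def test_injected_oscillating_losses_reject_run(self, tiny_dataset, monkeypatch):
        ds, _ = tiny_dataset
        tr, va, _ = split_dataset(ds, seed=0)
        seq = iter(5 + 0.5 * (-1) ** np.arange(1000))

        def stub_step(model, d, idx, stage, adam):
            return float(next(seq))

        monkeypatch.setattr(training, "_train_step", stub_step)
        res = train_two_stage(tr, va, TrainConfig(max_epochs=40, seed=0))
        assert res.termination_status == STATUS_REJECTED

    def test_seed_determinism(self, tiny_dataset):
        ds, _ = tiny_dataset
        tr, va, _ = split_dataset(ds, seed=0)
        cfg = TrainConfig(max_epochs=30, seed=7)
        a = train_two_stage(tr, va, cfg)
        b = train_two_stage(tr, va, cfg)
        assert a.loss_history == b.loss_history
        assert a.val_r2 == b.val_r2


def _fake_result(val_r2, val_mae, status=STATUS_COMPLETED, model=None):
    return training.TrainRunResult(
        model=model,
        loss_history=[],
        termination_status=status,
        val_r2=val_r2,
        val_mae=val_mae,
        stage1_cutoff_reached=True,
        config=TrainConfig(),
    )


class TestSelection:
    def test_top_ten_by_validation_r2(self):
        results = [_fake_result(0.8 + 0.01 * i, 0.1) for i in range(15)]
        ens = select_and_ensemble(results)
        assert len(ens) == 10
        assert min(m.val_r2 for m in ens.members) == pytest.approx(0.85)

    def test_mae_arm_excludes(self):
        with pytest.raises(EmptyEnsembleError):
            select_and_ensemble([_fake_result(0.9, 2.0)])

    def test_rejected_runs_never_qualify(self):
        with pytest.raises(EmptyEnsembleError):
            select_and_ensemble([_fake_result(0.95, 0.1, status=STATUS_REJECTED)])

    def test_member_thresholds_asserted_on_construction(self):
        with pytest.raises(EmptyEnsembleError):
            Ensemble(members=[_fake_result(0.5, 0.1)])

    def test_identical_members_average_to_themselves(self, tiny_dataset):
        ds, _ = tiny_dataset
        tr, va, _ = split_dataset(ds, seed=0)
        res = train_two_stage(tr, va, TrainConfig(max_epochs=10, seed=2))
        member = _fake_result(0.9, 0.1, model=res.model)
        ens = Ensemble(members=[member, member, member])
        single = predict(res.model, va)
        avg = ens.predict(va)
        np.testing.assert_allclose(avg["k_pred"], single["k_pred"], rtol=1e-12)


class TestCrossValidation:
    def test_fold_bookkeeping(self):
        folds = make_cv_folds(340, 5, seed=0)
        sizes = np.bincount(folds)
        assert sizes.tolist() == [68] * 5
        assert np.array_equal(folds, make_cv_folds(340, 5, seed=0))

    def test_four_runs_fixed_test_fold(self, tiny_dataset):
        ds, _ = tiny_dataset
        table = cross_validate(ds, TrainConfig(max_epochs=0, seed=0), seed=0)
        assert len(table) == 4
        assert sorted(table["val_fold"]) == [0, 1, 2, 3]
        assert set(table["test_fold"]) == {4}


class TestTuning:
    def test_budget_one_returns_single_config(self, tiny_dataset):
        ds, _ = tiny_dataset
        tr, va, _ = split_dataset(ds, seed=0)
        best, log = tune_hyperparameters(
            tr, va, budget=1, seed=0, base_config=TrainConfig(max_epochs=0)
        )
        assert len(log) == 1
        assert best.learning_rate == log.iloc[0]["learning_rate"]

    def test_one_point_space_trains_once(self, tiny_dataset):
        ds, _ = tiny_dataset
        tr, va, _ = split_dataset(ds, seed=0)
        space = {"learning_rate": [0.002]}
        best, log = tune_hyperparameters(
            tr, va, space=space, budget=5, seed=0,
            base_config=TrainConfig(max_epochs=0),
        )
        assert len(log) == 1
        assert best.learning_rate == 0.002

    def test_zero_budget_rejected(self, tiny_dataset):
        ds, _ = tiny_dataset
        tr, va, _ = split_dataset(ds, seed=0)
        with pytest.raises(ValueError):
            tune_hyperparameters(tr, va, budget=0)


def test_r2_score_definition(rng):
    y = rng.normal(size=50)
    assert r2_score(y, y) == pytest.approx(1.0)
    assert r2_score(y, np.full(50, y.mean())) == pytest.approx(0.0)


def test_grid_validation():
    with pytest.raises(ValueError):
        TrainConfig(learning_rate=0.1).validate_grid()
    TrainConfig().validate_grid()


def test_feature_dataset_keeps_substrate_pathway(tiny_dataset):
    ds, synth = tiny_dataset
    table = pd.DataFrame(
        np.eye(len(ds.ligand_ids)), index=ds.ligand_ids
    )
    fds = build_feature_dataset(synth.reactions, table)
    np.testing.assert_array_equal(fds.hammett, ds.hammett)
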