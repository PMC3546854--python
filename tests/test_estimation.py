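"""R^2 indices, dataset assembly, blocking, MLP training and winner
selection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import r2_score

from wristemg.errors import DataError, ParameterError, PipelineError
from wristemg.estimation import (
    Dataset,
    ScenarioSpec,
    assemble_dataset,
    dof_r2,
    global_r2,
    make_blocks,
    run_cross_validation,
    select_winner,
    train_mlp,
)
from wristemg.features import FeatureMatrix, WindowSchedule
from wristemg.kinematics import JointAngleSeries


class TestR2Indices:
    def test_perfect_estimate_is_exactly_one(self, rng):
        y = rng.standard_normal((50, 3))
        assert global_r2(y, y) == 1.0

    def test_mean_predictor_is_exactly_zero(self, rng):
        y = rng.standard_normal((50, 3))
        est = np.broadcast_to(y.mean(axis=0), y.shape)
        assert global_r2(y, est) == 0.0
        assert dof_r2(y[:, 0], np.full(50, y[:, 0].mean())) == 0.0

    def test_hand_computed_four_point_example(self):
        assert dof_r2([0, 1, 2, 3], [0, 1, 2, 5]) == pytest.approx(0.2)

    def test_can_be_negative(self, rng):
        y = rng.standard_normal(30)
        assert dof_r2(y, -5 * y) < 0.0

    def test_pooled_equals_variance_weighted_per_dof(self, rng):
        """The multivariate index is the SST-weighted mean of the per-DoF
        indices — checked on 100 random datasets to 1e-12."""
        for _ in range(100):
            n, d = rng.integers(5, 40), rng.integers(1, 5)
            y = rng.standard_normal((n, d)) * rng.uniform(0.5, 20, d)
            est = y + rng.standard_normal((n, d))
            sst = ((y - y.mean(axis=0)) ** 2).sum(axis=0)
            weighted = sum(
                sst[i] / sst.sum() * dof_r2(y[:, i], est[:, i]) for i in range(d)
            )
            assert global_r2(y, est) == pytest.approx(weighted, abs=1e-12)

    def test_agrees_with_sklearn_variance_weighted(self, rng):
        y = rng.standard_normal((40, 3))
        est = y + 0.3 * rng.standard_normal((40, 3))
        assert global_r2(y, est) == pytest.approx(
            r2_score(y, est, multioutput="variance_weighted"), abs=1e-12
        )

    def test_constant_targets_rejected(self):
        with pytest.raises(DataError):
            dof_r2(np.ones(10), np.ones(10))

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(
        st.floats(min_value=0.1, max_value=50.0),
        st.floats(min_value=-100.0, max_value=100.0),
    )
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(0)
        y = rng.standard_normal((30, 2))
        est = y + 0.5 * rng.standard_normal((30, 2))
        base = global_r2(y, est)
        moved = global_r2(scale * y + shift, scale * est + shift)
        assert moved == pytest.approx(base, rel=1e-9)


class TestScenarios:
    @pytest.mark.parametrize(
        "name,contractions,dofs",
        [
            ("DoF12", (1, 2, 4, 5), (1, 2)),
            ("DoF13", (1, 3, 6, 7), (1, 3)),
            ("DoF23", (2, 3, 8, 9), (2, 3)),
            ("DoF123", tuple(range(1, 11)), (1, 2, 3)),
        ],
    )
    def test_contraction_subsets(self, name, contractions, dofs):
        s = ScenarioSpec.from_name(name)
        assert s.contractions == contractions
        assert s.target_dofs == dofs

    def test_unknown_scenario(self):
        with pytest.raises(ParameterError):
            ScenarioSpec.from_name("DoF1")


def _toy_features(n_windows, n_feat, rng, fs=1024.0):
    sched = WindowSchedule(0.100, 0.040, fs)
    centers = sched.window_centers(
        (n_windows - 1) * sched.n_step_samples + sched.n_window_samples
    )
    return FeatureMatrix(
        rng.standard_normal((n_windows, n_feat)),
        centers,
        [f"f{i}" for i in range(n_feat)],
        sched,
    )


def _toy_angles(duration, fs=1024.0):
    n = int(duration * fs)
    t = np.arange(n) / fs
    return JointAngleSeries(
        30 * np.sin(2 * np.pi * 0.5 * t),
        20 * np.sin(2 * np.pi * 0.7 * t),
        90 + 40 * np.sin(2 * np.pi * 0.3 * t),
        fs,
    )


class TestAssembly:
    def test_scenario_filters_contractions(self, rng):
        feats = _toy_features(200, 5, rng)
        angles = _toy_angles(feats.window_centers[-1] + 0.1)
        labels = np.repeat(np.arange(1, 11), 20)
        ds = assemble_dataset(
            feats, feats, angles, "ipsi", ScenarioSpec.from_name("DoF12"),
            labels,
        )
        assert set(ds.labels) == {1, 2, 4, 5}
        assert ds.n_rows == 80
        assert ds.X.shape[0] == ds.Y.shape[0]
        assert ds.Y.shape[1] == 2

    def test_laterality_selects_side(self, rng):
        f_left = _toy_features(100, 4, rng)
        f_right = _toy_features(100, 4, rng)
        angles = _toy_angles(f_left.window_centers[-1] + 0.1)
        labels = np.ones(100, dtype=int)
        contra = assemble_dataset(
            f_left, f_right, angles, "contra",
            ScenarioSpec.from_name("DoF12"), labels, kinematics_side="right",
        )
        ipsi = assemble_dataset(
            f_left, f_right, angles, "ipsi",
            ScenarioSpec.from_name("DoF12"), labels, kinematics_side="right",
        )
        assert np.array_equal(contra.X, f_left.values)
        assert np.array_equal(ipsi.X, f_right.values)

    def test_window_mean_target(self, rng):
        feats = _toy_features(50, 3, rng)
        angles = _toy_angles(feats.window_centers[-1] + 0.1)
        ds = assemble_dataset(
            feats, None, angles, "ipsi", ScenarioSpec.from_name("DoF123"),
            np.ones(50, dtype=int), kinematics_side="left",
        )
        # window means are attenuated relative to the centre sample but close
        centre = angles.as_matrix()[
            np.round(feats.window_centers * angles.fs).astype(int)
        ]
        assert np.abs(ds.Y - centre).max() < 1.0

    def test_timeline_mismatch_raises(self, rng):
        feats = _toy_features(100, 3, rng)
        angles = _toy_angles(1.0)  # far shorter than the feature span
        with pytest.raises(DataError):
            assemble_dataset(
                feats, None, angles, "ipsi",
                ScenarioSpec.from_name("DoF123"), np.ones(100, dtype=int),
                kinematics_side="left",
            )


class TestBlocks:
    def _dataset(self, labels, rng):
        labels = np.asarray(labels)
        n = labels.size
        return Dataset(
            rng.standard_normal((n, 3)), rng.standard_normal((n, 2)),
            np.arange(n, dtype=float), labels, (1, 2), ["a", "b", "c"],
            "DoF12", "contra",
        )

    def test_partition_property(self, rng):
        ds = self._dataset(np.repeat([1, 2, 4, 5], 25), rng)
        blocks = make_blocks(ds, 5)
        all_idx = np.sort(np.concatenate(blocks))
        assert np.array_equal(all_idx, np.arange(ds.n_rows))

    def test_blocks_contiguous_within_contraction(self, rng):
        ds = self._dataset(np.repeat([1, 2], 50), rng)
        for block in make_blocks(ds, 5):
            for cid in (1, 2):
                part = block[ds.labels[block] == cid]
                if part.size:
                    assert np.array_equal(part, np.arange(part[0], part[-1] + 1))

    def test_too_few_windows_raises(self, rng):
        ds = self._dataset(np.array([1, 1, 1]), rng)
        with pytest.raises(ParameterError):
            make_blocks(ds, 5)


class TestTrainMlp:
    def _split(self, n):
        idx = np.arange(n)
        return idx[: int(0.8 * n)], idx[int(0.8 * n):]

    def test_constant_target_fits_constant(self, rng):
        X = rng.standard_normal((200, 5))
        y = np.zeros(200)
        m = train_mlp(X, y, seed=0, split=self._split(200), max_epochs=50)
        assert np.abs(m.predict(X)).max() < 1.0

    def test_linear_target_reaches_high_r2(self, rng):
        X = rng.standard_normal((400, 5))
        y = 3.0 * X[:, 2] - 1.0
        tr, va = self._split(400)
        m = train_mlp(X, y, seed=1, split=(tr, va))
        assert dof_r2(y[va], m.predict(X[va])) > 0.99

    def test_same_seed_identical_weights(self, rng):
        X = rng.standard_normal((200, 4))
        y = X[:, 0] + 0.1 * rng.standard_normal(200)
        m1 = train_mlp(X, y, seed=7, split=self._split(200), max_epochs=30)
        m2 = train_mlp(X, y, seed=7, split=self._split(200), max_epochs=30)
        for w1, w2 in zip(m1.net.coefs_, m2.net.coefs_):
            assert np.array_equal(w1, w2)

    def test_different_seeds_differ(self, rng):
        X = rng.standard_normal((200, 4))
        y = X[:, 0]
        m1 = train_mlp(X, y, seed=1, split=self._split(200), max_epochs=10)
        m2 = train_mlp(X, y, seed=2, split=self._split(200), max_epochs=10)
        assert not np.array_equal(m1.net.coefs_[0], m2.net.coefs_[0])

    def test_too_few_rows(self, rng):
        X = rng.standard_normal((30, 4))
        with pytest.raises(ParameterError):
            train_mlp(X, X[:, 0], seed=0, split=(np.arange(20), np.arange(20, 30)))

    def test_model_serializes_to_json(self, rng):
        import json

        X = rng.standard_normal((100, 4))
        m = train_mlp(X, X[:, 0], seed=0, split=self._split(100), max_epochs=10)
        blob = json.dumps(m.to_dict())
        assert "weights" in blob and "x_mean" in blob


class TestWinnerSelection:
    def test_argmax_by_validation_r2(self, rng):
        X = rng.standard_normal((200, 3))
        y = 2.0 * X[:, 0]
        tr, va = np.arange(160), np.arange(160, 200)
        models = [
            train_mlp(X, y, seed=s, split=(tr, va), max_epochs=e)
            for s, e in [(0, 2), (1, 200), (2, 5)]
        ]
        scores = [dof_r2(y[va], m.predict(X[va])) for m in models]
        winner = select_winner(models, X[va], y[va])
        assert winner is models[int(np.argmax(scores))]

    def test_single_candidate_returned(self, rng):
        X = rng.standard_normal((100, 3))
        y = X[:, 0]
        tr, va = np.arange(80), np.arange(80, 100)
        m = train_mlp(X, y, seed=0, split=(tr, va), max_epochs=5)
        assert select_winner([m], X[va], y[va]) is m

    def test_no_candidates_is_pipeline_error(self):
        with pytest.raises(PipelineError):
            select_winner([], np.zeros((5, 2)), np.zeros(5))

    def test_selection_beats_median_on_held_out_data(self, rng):
        """Winner selection should help on average: over 20 repetitions the
        winner's held-out R^2 is at least the median restart's."""
        win, med = [], []
        for rep in range(20):
            r = np.random.default_rng(rep)
            X = r.standard_normal((240, 4))
            y = np.tanh(X[:, 0]) + 0.5 * X[:, 1] + 0.3 * r.standard_normal(240)
            tr, va, te = np.arange(140), np.arange(140, 190), np.arange(190, 240)
            models = [
                train_mlp(X, y, seed=s, split=(tr, va), max_epochs=40)
                for s in range(5)
            ]
            winner = select_winner(models, X[va], y[va])
            test_scores = [dof_r2(y[te], m.predict(X[te])) for m in models]
            win.append(dof_r2(y[te], winner.predict(X[te])))
            med.append(np.median(test_scores))
        assert np.mean(win) >= np.mean(med) - 1e-9


class TestCrossValidation:
    def _learnable_dataset(self, rng, n_per=60):
        labels = np.repeat([1, 2, 4, 5], n_per)
        n = labels.size
        X = rng.standard_normal((n, 6))
        Y = np.column_stack(
            [2 * X[:, 0] - X[:, 1], np.tanh(X[:, 2]) * 3]
        ) + 0.05 * rng.standard_normal((n, 2))
        return Dataset(
            X, Y, np.arange(n, dtype=float), labels, (1, 2),
            [f"f{i}" for i in range(6)], "DoF12", "contra",
        )

    def test_each_row_in_exactly_one_test_fold(self, rng):
        ds = self._learnable_dataset(rng)
        cv = run_cross_validation(ds, restarts=2, master_seed=0, max_epochs=20)
        seen = np.concatenate(
            [f.predictions["t"].unique() for f in cv.folds]
        )
        assert np.array_equal(np.sort(seen), ds.t)

    def test_learnable_mapping_recovered(self, rng):
        ds = self._learnable_dataset(rng)
        cv = run_cross_validation(ds, restarts=3, master_seed=1, max_epochs=150)
        assert cv.mean_r2 > 0.8
        assert set(cv.folds[0].r2_per_dof) == {1, 2}

    def test_report_structure(self, rng):
        ds = self._learnable_dataset(rng)
        cv = run_cross_validation(ds, restarts=2, master_seed=2, max_epochs=20)
        rep = cv.to_report()
        assert rep["n_folds"] == 5
        assert len(rep["r2_global_per_fold"]) == 5
        assert set(rep["r2_per_dof_mean"]) == {"1", "2"}
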