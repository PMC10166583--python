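"""Train/validation splitting, regression fitting, and panel-wide imputation."""

import numpy as np
import pytest

from flowimpute.fcsio import ChannelDescriptor, EventMatrix
from flowimpute.imputation import (
    XgbParams,
    derive_seed,
    fit_marker_model,
    impute_all,
    predict_model,
    split_events,
    surrogate_backbone_eval,
    validate_model,
)
from flowimpute.transforms import TransformSpec

FAST = XgbParams(n_estimators=100)
LINEAR = TransformSpec(kind="linear")


class TestSplitEvents:
    def test_half_split_of_20000_is_exact(self):
        s = split_events(20_000, 0.5, seed=0)
        assert s.train_idx.size == 10_000
        assert s.val_idx.size == 10_000

    def test_round_half_up_on_odd_n(self):
        # n=7, fraction=0.5 -> 3.5 rounds half-up to 4 training events
        s = split_events(7, 0.5, seed=1)
        assert s.train_idx.size == 4
        assert s.val_idx.size == 3

    def test_same_seed_reproduces_partition(self):
        a, b = split_events(999, 0.5, seed=5), split_events(999, 0.5, seed=5)
        np.testing.assert_array_equal(a.train_idx, b.train_idx)
        np.testing.assert_array_equal(a.val_idx, b.val_idx)

    def test_partition_is_disjoint_and_covering(self):
        s = split_events(1234, 0.3, seed=2)
        assert set(s.train_idx) & set(s.val_idx) == set()
        assert set(s.train_idx) | set(s.val_idx) == set(range(1234))

    @pytest.mark.parametrize("n,frac", [(1, 0.5), (5, 0.0), (5, 1.0)])
    def test_degenerate_inputs_rejected(self, n, frac):
        with pytest.raises(ValueError):
            split_events(n, frac, seed=0)

    def test_derived_seeds_are_stable_and_bounded(self):
        s1 = derive_seed(3, "file.fcs", "CD19")
        s2 = derive_seed(3, "file.fcs", "CD19")
        assert s1 == s2 and 0 <= s1 < 2**31
        assert derive_seed(3, "file.fcs", "CD20") != s1


class TestFitAndValidate:
    def test_exact_linear_target_learned(self):
        rng = np.random.default_rng(0)
        X = rng.uniform(0, 100, size=(5000, 4))
        y = 2.5 * X[:, 1] - 7.0
        s = split_events(5000, 0.5, seed=0)
        m = fit_marker_model(X[s.train_idx], y[s.train_idx], FAST, seed=0)
        pred = predict_model(m, X[s.val_idx])
        truth = y[s.val_idx]
        r2 = 1 - np.sum((pred - truth) ** 2) / np.sum((truth - truth.mean()) ** 2)
        assert r2 >= 0.99

    def test_constant_target_predicts_constant_with_warning(self):
        X = np.random.default_rng(1).uniform(size=(500, 3))
        with pytest.warns(UserWarning, match="zero variance"):
            m = fit_marker_model(X, np.full(500, 4.2), FAST, seed=0)
        np.testing.assert_allclose(predict_model(m, X), 4.2, atol=1e-6)

    def test_step_function_target_reaches_noise_floor(self):
        # two populations, switch-like marker: MSE <= 1.2 x injected noise var
        rng = np.random.default_rng(2)
        n = 8000
        pop = rng.integers(0, 2, n)
        X = rng.normal(loc=pop[:, None] * 8.0, scale=1.0, size=(n, 3))
        sigma = 0.5
        y = 10.0 * (X[:, 0] > 4.0) + rng.normal(0, sigma, n)
        s = split_events(n, 0.5, seed=0)
        m = fit_marker_model(X[s.train_idx], y[s.train_idx], FAST, seed=0)
        mse, _ = validate_model(m, X[s.val_idx], y[s.val_idx])
        assert mse <= 1.2 * sigma**2

    def test_validation_metrics_definitions(self):
        rng = np.random.default_rng(3)
        X = rng.uniform(size=(200, 2))
        y = X[:, 0]
        m = fit_marker_model(X, y, XgbParams(n_estimators=300), seed=0)
        # near-perfect fit: both metrics ~ 0
        mse, mae = validate_model(m, X, y)
        assert mse == pytest.approx(0, abs=1e-4)
        assert mae == pytest.approx(0, abs=1e-2)
        # constant offset: MSE = 1, MAE = 1 against y+1
        mse, mae = validate_model(m, X, y + 1.0)
        assert mse == pytest.approx(1.0, abs=1e-2)
        assert mae == pytest.approx(1.0, abs=1e-2)

    def test_metrics_equal_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        X = rng.uniform(size=(300, 2))
        y = rng.normal(size=300)
        m = fit_marker_model(X, y, XgbParams(n_estimators=20), seed=0)
        mse, mae = validate_model(m, X, y)
        pred = predict_model(m, X)
        # independent mean-of-squares accumulation
        acc_sq = acc_abs = 0.0
        for p, t in zip(pred, y):
            acc_sq += (p - t) ** 2
            acc_abs += abs(p - t)
        assert mse == pytest.approx(acc_sq / 300, rel=1e-12)
        assert mae == pytest.approx(acc_abs / 300, rel=1e-12)

    def test_row_mismatch_and_empty_validation_rejected(self):
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="row mismatch"):
            fit_marker_model(X, np.ones(9), FAST, seed=0)
        m = fit_marker_model(X, np.arange(10.0), FAST, seed=0)
        with pytest.raises(ValueError, match="empty validation"):
            validate_model(m, np.empty((0, 2)), np.empty(0))

    def test_no_leakage_between_train_and_validation(self):
        s = split_events(5000, 0.5, seed=9)
        assert np.intersect1d(s.train_idx, s.val_idx).size == 0


def _panel_files(n_files, n_events=2000, seed=0, markers_per_file=1):
    """Files with 4 backbone channels and exploratory columns = f(backbone)+noise."""
    rng = np.random.default_rng(seed)
    files, ann = [], {}
    truth = {}
    for j in range(n_files):
        bb = rng.normal(loc=[0, 5, 10, 20], scale=2.0, size=(n_events, 4))
        cols, chans = [bb], [
            ChannelDescriptor(f"BB{i + 1}", role="backbone") for i in range(4)
        ]
        pairs = []
        for k in range(markers_per_file):
            name = f"M{j + 1}_{k + 1}"
            signal = 3.0 * bb[:, k % 4]
            noisy = signal + rng.normal(0, signal.std() / 3, n_events)
            cols.append(noisy[:, None])
            chans.append(ChannelDescriptor(f"PE{k + 1}-A", role="infinity"))
            pairs.append((f"PE{k + 1}-A", name))
            truth[name] = signal
        fname = f"file{j + 1}.fcs"
        files.append(
            EventMatrix(np.hstack(cols), chans, source_path=fname)
        )
        ann[fname] = pairs
    return files, ann, truth


class TestImputeAll:
    def test_one_model_and_column_per_file(self):
        files, ann, _ = _panel_files(3)
        target = np.random.default_rng(5).normal(size=(100, 4))
        models, imputed, names = impute_all(
            files, ann, [f"BB{i + 1}" for i in range(4)], target,
            spec=LINEAR, hyperparams=FAST, min_events=100,
        )
        assert len(models) == 3
        assert imputed.shape == (100, 3)
        assert names == ["M1_1", "M2_1", "M3_1"]

    def test_multi_marker_file_yields_one_model_per_channel(self):
        files, ann, _ = _panel_files(1, markers_per_file=2)
        target = np.random.default_rng(5).normal(size=(50, 4))
        models, imputed, names = impute_all(
            files, ann, [f"BB{i + 1}" for i in range(4)], target,
            spec=LINEAR, hyperparams=FAST, min_events=100,
        )
        assert len(models) == 2 and imputed.shape[1] == 2
        assert names == ["M1_1", "M1_2"]

    def test_imputed_values_track_truth_at_snr_3(self):
        files, ann, _ = _panel_files(2, n_events=4000, seed=6)
        bb_names = [f"BB{i + 1}" for i in range(4)]
        # predict onto file 1's backbone; every marker's true signal there is
        # its known link applied to that backbone (3 x BB1 for these files)
        target_bb = files[0].data[:, :4]
        expected = 3.0 * target_bb[:, 0]
        _, imputed, names = impute_all(
            files, ann, bb_names, target_bb,
            spec=LINEAR, hyperparams=FAST, min_events=100,
        )
        for col, name in zip(imputed.T, names):
            r = np.corrcoef(col, expected)[0, 1]
            assert r >= 0.9, f"{name}: r={r:.3f}"

    def test_missing_annotated_channel_names_file(self):
        files, ann, _ = _panel_files(1)
        ann["file1.fcs"] = [("PE9-A", "M1_1")]
        with pytest.raises(KeyError, match="PE9-A"):
            impute_all(
                files, ann, [f"BB{i + 1}" for i in range(4)],
                np.ones((10, 4)), spec=LINEAR, hyperparams=FAST, min_events=100,
            )

    def test_duplicate_marker_names_suffixed_with_warning(self):
        files, ann, _ = _panel_files(2)
        ann["file2.fcs"] = [("PE1-A", "M1_1")]  # same name as file1's marker
        with pytest.warns(UserWarning, match="duplicate marker"):
            _, _, names = impute_all(
                files, ann, [f"BB{i + 1}" for i in range(4)],
                np.ones((10, 4)), spec=LINEAR, hyperparams=FAST, min_events=100,
            )
        assert names == ["M1_1", "M1_1.1"]

    def test_too_few_events_rejected(self):
        files, ann, _ = _panel_files(1, n_events=100)
        with pytest.raises(ValueError, match="min_events"):
            impute_all(
                files, ann, [f"BB{i + 1}" for i in range(4)],
                np.ones((10, 4)), spec=LINEAR, hyperparams=FAST,
            )

    def test_fixed_seed_reproduces_predictions(self):
        files, ann, _ = _panel_files(1, n_events=1000, seed=8)
        bb_names = [f"BB{i + 1}" for i in range(4)]
        target = files[0].data[:, :4]
        out1 = impute_all(files, ann, bb_names, target, spec=LINEAR,
                          hyperparams=FAST, run_seed=11, min_events=100)
        out2 = impute_all(files, ann, bb_names, target, spec=LINEAR,
                          hyperparams=FAST, run_seed=11, min_events=100)
        np.testing.assert_array_equal(out1[1], out2[1])
        np.testing.assert_array_equal(
            out1[0][0].split.train_idx, out2[0][0].split.train_idx
        )


class TestSurrogateBackbone:
    def _file(self, n=4000, seed=0, extra=None):
        rng = np.random.default_rng(seed)
        bb = rng.normal(loc=[0, 3, 6, 9, 12], scale=1.5, size=(n, 5))
        cols = [bb]
        chans = [ChannelDescriptor(f"S{i + 1}", role="backbone") for i in range(5)]
        for name, col in (extra or {}).items():
            cols.append(col[:, None])
            chans.append(ChannelDescriptor(name, role="backbone"))
        return EventMatrix(np.hstack(cols), chans, source_path="f.fcs")

    def test_duplicated_channel_gives_near_perfect_r(self):
        f = self._file(extra={"DUP": np.zeros(4000)})
        f.data[:, 5] = f.data[:, 0]  # leakage sanity check
        rep = surrogate_backbone_eval(
            f, [f"S{i + 1}" for i in range(5)], ["DUP"],
            spec=LINEAR, hyperparams=FAST,
        )
        assert rep["DUP"]["r"] > 0.999

    def test_independent_noise_channel_uncorrelated(self):
        rng = np.random.default_rng(3)
        noise = rng.normal(size=20_000)
        f = self._file(n=20_000, extra={"NOISE": noise})
        rep = surrogate_backbone_eval(
            f, [f"S{i + 1}" for i in range(5)], ["NOISE"],
            spec=LINEAR, hyperparams=FAST,
        )
        assert abs(rep["NOISE"]["r"]) < 0.05

    def test_overlapping_channel_sets_rejected(self):
        f = self._file()
        with pytest.raises(ValueError, match="overlap"):
            surrogate_backbone_eval(f, ["S1", "S2"], ["S2"], spec=LINEAR)


class TestZscoreArtifact:
    def test_per_file_zscore_perturbs_predictions_under_composition_shift(self):
        """Two files share the same marker biology but differ in population mix;
        per-file standardization then distorts what identical backbone values
        mean, so predictions for the same inputs diverge more than without it."""
        from scipy.stats import wilcoxon

        rng = np.random.default_rng(12)
        n = 4000

        def make_file(p_hi, fname):
            pop = rng.random(n) < p_hi
            bb = rng.normal(
                loc=np.where(pop[:, None], [8.0, 2.0], [2.0, 8.0]),
                scale=1.0, size=(n, 2),
            )
            signal = 2.0 * bb[:, 0]
            y = signal + rng.normal(0, signal.std() / 4, n)
            chans = [
                ChannelDescriptor("B1", role="backbone"),
                ChannelDescriptor("B2", role="backbone"),
                ChannelDescriptor("PE1-A", role="infinity"),
            ]
            return EventMatrix(
                np.hstack([bb, y[:, None]]), chans, source_path=fname
            )

        # identical biology, shifted composition (20% vs 80% high population)
        files = [make_file(0.2, "a.fcs"), make_file(0.8, "b.fcs")]
        ann = {"a.fcs": [("PE1-A", "Ma")], "b.fcs": [("PE1-A", "Mb")]}
        grid = np.column_stack(
            [np.linspace(0, 10, 300), np.linspace(10, 0, 300)]
        )

        def discrepancy(zscore):
            _, imputed, _ = impute_all(
                files, ann, ["B1", "B2"], grid, spec=LINEAR,
                hyperparams=FAST, run_seed=1, zscore=zscore, min_events=100,
            )
            return np.abs(imputed[:, 0] - imputed[:, 1])

        d_plain = discrepancy(False)
        d_z = discrepancy(True)
        assert d_z.mean() > 2.0 * d_plain.mean()
        assert wilcoxon(d_z, d_plain, alternative="greater").pvalue < 1e-6
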