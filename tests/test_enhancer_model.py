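import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

import _oracles
from relocus.enhancer_model import (
    EnhancerModel,
    EnhancerModelConfig,
    TrainingRegion,
    call_peaks,
    curate_training_set,
    evaluate_auroc,
    extract_features,
    fit_model,
    load_model,
    predict_track,
    sample_negative_intervals,
    save_model,
)
from relocus.io_formats import GenomicInterval, SignalTrack


def region(start, end, **flags):
    return TrainingRegion(GenomicInterval("chr1", start, end), **flags)


class TestCuration:
    def test_catalogue_minus_flags(self):
        catalogue = (
            [region(i * 1000, i * 1000 + 500) for i in range(84)]
            + [region(100_000 + i * 1000, 100_000 + i * 1000 + 500, misannotated=True) for i in range(17)]
            + [region(300_000 + i * 1000, 300_000 + i * 1000 + 500, outflow_tract=True) for i in range(25)]
        )
        retained, summary = curate_training_set(catalogue)
        assert summary == {
            "catalogued": 126,
            "misannotated": 17,
            "outflow_tract": 25,
            "retained": 84,
        }
        assert len(retained) == 84

    def test_no_flags_is_identity(self):
        catalogue = [region(0, 100), region(200, 300)]
        retained, _ = curate_training_set(catalogue)
        assert retained == catalogue

    def test_all_flagged_warns_and_returns_empty(self):
        catalogue = [region(0, 100, misannotated=True)]
        with pytest.warns(UserWarning, match="every"):
            retained, _ = curate_training_set(catalogue)
        assert retained == []


class TestFeatures:
    def test_constant_track_gives_constant_feature(self):
        track = SignalTrack.from_records([("chr1", 0, 10_000, 3.25)])
        intervals = [GenomicInterval("chr1", 100, 200), GenomicInterval("chr1", 5_000, 5_010)]
        features = extract_features({"t": track}, intervals)
        assert np.allclose(features["t"], 3.25)

    def test_half_covered_bin_averages_coverage(self):
        track = SignalTrack.from_records([("chr1", 0, 50, 2.0)])
        features = extract_features({"t": track}, [GenomicInterval("chr1", 0, 100)])
        assert features["t"].iloc[0] == pytest.approx(1.0)

    def test_missing_track_is_an_error(self):
        with pytest.raises(ValueError, match="not provided"):
            extract_features({}, [GenomicInterval("chr1", 0, 10)], ["atac"])

    def test_negatives_never_overlap_positives(self, rng):
        positives = [GenomicInterval("chr1", i * 10_000, i * 10_000 + 500) for i in range(10)]
        negatives = sample_negative_intervals(positives, {"chr1": 500_000}, 50, 500, rng)
        assert len(negatives) == 50
        for neg in negatives:
            assert not any(neg.overlaps(p) for p in positives)


def _noise_track(rng, length=50_000, res=50, amp=0.1):
    values = rng.uniform(0, amp, size=length // res)
    starts = np.arange(length // res) * res
    return SignalTrack({"chr1": (starts, starts + res, values)})


class TestFit:
    def test_perfectly_separating_track_dominates(self, rng):
        n = 400
        informative = np.concatenate([rng.uniform(2, 3, n // 2), rng.uniform(0, 0.5, n // 2)])
        noise = rng.uniform(0, 1, n)
        labels = np.array([1] * (n // 2) + [0] * (n // 2))
        features = pd.DataFrame({"signal": informative, "noise": noise})
        model = fit_model(features, labels, EnhancerModelConfig(seed=0))
        assert model.training_auroc >= 0.99
        assert abs(model.coefficients[0]) > abs(model.coefficients[1])

    def test_permuted_labels_give_chance_auroc(self, rng):
        n = 2000
        features = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        labels = rng.permutation([1] * 200 + [0] * (n - 200))
        model = fit_model(features, labels, EnhancerModelConfig(seed=0))
        assert 0.4 < model.training_auroc < 0.6

    def test_single_class_labels_rejected(self, rng):
        features = pd.DataFrame({"a": rng.normal(size=10)})
        with pytest.raises(ValueError, match="single class"):
            fit_model(features, np.ones(10, dtype=int))

    def test_deterministic_given_seed(self, rng):
        n = 200
        features = pd.DataFrame({"a": rng.normal(size=n), "b": rng.normal(size=n)})
        labels = np.array([1] * 50 + [0] * 150)
        m1 = fit_model(features, labels, EnhancerModelConfig(seed=3))
        m2 = fit_model(features, labels, EnhancerModelConfig(seed=3))
        assert np.array_equal(m1.coefficients, m2.coefficients)

    def test_model_tsv_roundtrip(self, tmp_path, rng):
        features = pd.DataFrame({"a": rng.normal(size=100), "b": rng.normal(size=100)})
        labels = np.array([1] * 30 + [0] * 70)
        model = fit_model(features, labels)
        path = tmp_path / "model.tsv"
        save_model(model, path)
        back = load_model(path)
        assert back.track_names == model.track_names
        assert np.array_equal(back.coefficients, model.coefficients)
        assert back.intercept == model.intercept


class TestPredict:
    def _manual_model(self):
        return EnhancerModel(
            track_names=("a", "b"),
            coefficients=np.array([1.5, -0.5]),
            intercept=-2.0,
            feature_means=np.zeros(2),
            feature_stds=np.ones(2),
        )

    def test_zero_signal_predicts_logistic_intercept(self):
        model = self._manual_model()
        tracks = {
            "a": SignalTrack({"chr1": (np.array([0]), np.array([100]), np.array([0.0]))}),
            "b": SignalTrack({"chr1": (np.array([0]), np.array([100]), np.array([0.0]))}),
        }
        prediction = predict_track(model, tracks, EnhancerModelConfig(bin_bp=10), {"chr1": 100})
        expected = 1.0 / (1.0 + np.exp(2.0))
        _, _, values = prediction.runs("chr1")
        assert np.allclose(values, expected)

    def test_hand_computed_logistic_at_one_bin(self):
        model = self._manual_model()
        tracks = {
            "a": SignalTrack.from_records([("chr1", 0, 10, 2.0)]),
            "b": SignalTrack.from_records([("chr1", 0, 10, 0.8)]),
        }
        prediction = predict_track(model, tracks, EnhancerModelConfig(bin_bp=10), {"chr1": 10})
        expected = 1.0 / (1.0 + np.exp(-(-2.0 + 1.5 * 2.0 - 0.5 * 0.8)))
        assert prediction.value_at("chr1", 5) == pytest.approx(expected, abs=1e-9)

    def test_predictions_lie_in_open_unit_interval(self, rng):
        model = self._manual_model()
        tracks = {"a": _noise_track(rng, amp=5.0), "b": _noise_track(rng, amp=5.0)}
        prediction = predict_track(model, tracks, EnhancerModelConfig(bin_bp=50))
        _, _, values = prediction.runs("chr1")
        assert np.all((values > 0) & (values < 1))


class TestCallPeaks:
    def _track(self, values, width=1):
        starts = np.arange(len(values)) * width
        return SignalTrack(
            {"chr1": (starts, starts + width, np.asarray(values, dtype=float))}
        )

    def test_threshold_base_breaks_run(self):
        track = self._track([0, 0, 0.06, 0.07, 0.05, 0.2, 0])
        peaks = call_peaks(track, EnhancerModelConfig(peak_threshold=0.05))
        spans = [(p.interval.start, p.interval.end) for p in peaks]
        assert spans == [(2, 4), (5, 6)]

    def test_all_below_threshold_gives_no_peaks(self):
        track = self._track([0.01, 0.04, 0.05])
        assert call_peaks(track, EnhancerModelConfig(peak_threshold=0.05)) == []

    def test_all_above_threshold_gives_single_spanning_peak(self):
        track = self._track([0.2, 0.3, 0.4])
        (peak,) = call_peaks(track, EnhancerModelConfig(peak_threshold=0.05))
        assert (peak.interval.start, peak.interval.end) == (0, 3)
        assert peak.max_value == pytest.approx(0.4)
        assert peak.mean_value == pytest.approx(0.3)

    def test_matches_per_base_bruteforce_on_random_tracks(self, rng):
        for _ in range(10):
            n = int(rng.integers(5, 60))
            values = np.round(rng.uniform(0, 0.12, size=n), 3)
            widths = rng.integers(1, 5, size=n)
            starts = np.concatenate([[0], np.cumsum(widths)[:-1]])
            track = SignalTrack({"chr1": (starts, starts + widths, values)})
            got = [
                (p.interval.chrom, p.interval.start, p.interval.end)
                for p in call_peaks(track, EnhancerModelConfig(peak_threshold=0.05))
            ]
            assert got == _oracles.peaks_bruteforce(track, 0.05)

    def test_peak_set_monotone_shrinking_in_threshold(self, rng):
        track = _noise_track(rng, amp=0.2)
        loose = call_peaks(track, EnhancerModelConfig(peak_threshold=0.05))
        tight = call_peaks(track, EnhancerModelConfig(peak_threshold=0.10))
        loose_bases = {
            (p.interval.chrom, b)
            for p in loose
            for b in range(p.interval.start, p.interval.end)
        }
        tight_bases = {
            (p.interval.chrom, b)
            for p in tight
            for b in range(p.interval.start, p.interval.end)
        }
        assert tight_bases <= loose_bases

    def test_idempotent_on_its_own_output(self, rng):
        track = _noise_track(rng, amp=0.2)
        peaks = call_peaks(track, EnhancerModelConfig(peak_threshold=0.05))
        rerun_track = SignalTrack.from_records(
            [
                (p.interval.chrom, p.interval.start, p.interval.end, p.max_value)
                for p in peaks
            ]
        )
        rerun = call_peaks(rerun_track, EnhancerModelConfig(peak_threshold=0.05))
        assert [(p.interval.start, p.interval.end) for p in rerun] == [
            (p.interval.start, p.interval.end) for p in peaks
        ]


class TestAuroc:
    def test_perfect_separation_is_one(self):
        assert evaluate_auroc([0.9, 0.4, 0.1], [1, 0, 0]) == 1.0

    def test_three_point_hand_case(self):
        assert evaluate_auroc([0.9, 0.4, 0.1], [0, 1, 0]) == 0.5

    def test_null_scores_near_half(self, rng):
        scores = rng.uniform(size=5000)
        labels = rng.integers(0, 2, size=5000)
        assert abs(evaluate_auroc(scores, labels) - 0.5) < 0.03

    def test_agrees_with_sklearn_and_pair_counting(self, rng):
        scores = np.round(rng.uniform(size=300), 2)  # rounding forces ties
        labels = rng.integers(0, 2, size=300)
        ours = evaluate_auroc(scores, labels)
        assert ours == pytest.approx(roc_auc_score(labels, scores))
        assert ours == pytest.approx(_oracles.auroc_by_pair_counting(scores, labels))


def test_multitrack_beats_best_single_track_on_held_out_data(pipeline_products):
    """Integrating tracks should not lose to the best single track (held out)."""
    products = pipeline_products
    features, labels = products["features"], products["labels"]
    rng = np.random.default_rng(7)
    order = rng.permutation(len(labels))
    n_train = int(0.6 * len(order))
    train, test = order[:n_train], order[n_train:]
    # guarantee both classes in both splits under this seed
    assert labels[train].sum() > 2 and labels[test].sum() > 2
    cfg = EnhancerModelConfig(seed=7)
    multi = fit_model(features.iloc[train], labels[train], cfg)
    multi_auroc = evaluate_auroc(
        multi.predict_proba(features.iloc[test].to_numpy()), labels[test]
    )
    single_aurocs = []
    for name in features.columns:
        single = fit_model(features.iloc[train][[name]], labels[train], cfg)
        single_aurocs.append(
            evaluate_auroc(
                single.predict_proba(features.iloc[test][[name]].to_numpy()),
                labels[test],
            )
        )
    assert multi_auroc >= max(single_aurocs) - 0.02


def test_uninformative_tracks_are_downweighted(pipeline_products):
    model = pipeline_products["model"]
    coefs = dict(zip(model.track_names, np.abs(model.coefficients)))
    informative = pipeline_products["bundle"].config.informative_tracks
    worst_informative = min(v for k, v in coefs.items() if k in informative)
    best_uninformative = max(v for k, v in coefs.items() if k not in informative)
    assert best_uninformative < worst_informative
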