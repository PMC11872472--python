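import numpy as np
import pytest

from qtshape.errors import ConfigurationError
from qtshape.kshape import ClusterModel
from qtshape.pipeline import (
    PipelineConfig,
    compare_to_truth,
    run_pipeline,
    truth_fiducials_for_templates,
)
from qtshape.template_qt import (
    Template,
    bazett,
    centroid_dtw_distances,
    compute_qt,
    exclude_outlier_beats,
    register_fiducials,
    select_templates,
    transfer_fiducials,
)
from qtshape.warping import WarpingPath, dtw


def model_for(X, labels, k):
    return ClusterModel(k=k, centroids=np.zeros((k, X.shape[1])), labels=np.asarray(labels))


class TestSelectTemplates:
    def test_member_equal_to_centroid_selected(self, rng):
        X = rng.normal(size=(5, 30))
        model = model_for(X, [0] * 5, k=1)
        model.centroids = X[3][None, :].copy()
        (t,) = select_templates(model, X)
        assert t.beat_index == 3

    def test_tie_breaks_to_lowest_index(self, rng):
        x = rng.normal(size=30)
        X = np.vstack([x, x, x])
        model = model_for(X, [0, 0, 0], k=1)
        model.centroids = x[None, :].copy()
        (t,) = select_templates(model, X)
        assert t.beat_index == 0

    def test_matches_brute_force_argmin(self, rng):
        X = rng.normal(size=(20, 25))
        model = model_for(X, [0] * 20, k=1)
        model.centroids = rng.normal(size=(1, 25))
        (t,) = select_templates(model, X)
        d = [dtw(model.centroids[0], X[i])[0] for i in range(20)]
        assert t.beat_index == int(np.argmin(d))

    def test_empty_cluster_skipped(self, rng):
        X = rng.normal(size=(4, 25))
        model = model_for(X, [0, 0, 0, 0], k=2)
        model.centroids = rng.normal(size=(2, 25))
        templates = select_templates(model, X)
        assert [t.cluster_id for t in templates] == [0]


class TestExcludeOutliers:
    def _run(self, distances, k=1):
        d = np.asarray(distances, dtype=float)
        model = model_for(np.zeros((d.size, 4)), [0] * d.size, k=k)
        exclude_outlier_beats(model, d)
        return model.excluded

    def test_linear_interpolation_percentile(self):
        # distances 1..10: 90th percentile = 9.1; only the 10 is excluded
        excl = self._run(np.arange(1.0, 11.0))
        assert excl.tolist() == [False] * 9 + [True]

    def test_all_equal_exempt(self):
        excl = self._run(np.full(8, 3.0))
        assert not excl.any()

    def test_five_member_cap(self):
        excl = self._run([1.0, 2.0, 3.0, 4.0, 100.0])
        assert excl.sum() == 1  # ceil(0.1 * 5) = 1
        assert excl[4]

    def test_per_cluster_screening(self, rng):
        d = np.concatenate([np.arange(1.0, 11.0), np.arange(101.0, 111.0)])
        labels = [0] * 10 + [1] * 10
        model = model_for(np.zeros((20, 4)), labels, k=2)
        exclude_outlier_beats(model, d)
        # each cluster loses exactly its own top decile
        assert model.excluded[:10].sum() == 1 and model.excluded[9]
        assert model.excluded[10:].sum() == 1 and model.excluded[19]


class TestRegisterFiducials:
    def test_attaches_and_computes_template_qt(self, rng):
        t = Template(cluster_id=0, beat_index=0, samples=rng.normal(size=400))
        register_fiducials([t], {0: (30, 130)})
        assert compute_qt(t.qrs_onset, t.t_end, fs=250.0) == pytest.approx(400.0)

    def test_missing_cluster_listed(self, rng):
        ts = [Template(cluster_id=i, beat_index=i, samples=rng.normal(size=50))
              for i in (0, 2)]
        with pytest.raises(ConfigurationError, match=r"\[2\]"):
            register_fiducials(ts, {0: (5, 20)})

    def test_inverted_fiducials_rejected(self, rng):
        t = Template(cluster_id=0, beat_index=0, samples=rng.normal(size=50))
        with pytest.raises(ValueError):
            register_fiducials([t], {0: (20, 5)})

    def test_twelve_templates_twelve_rows(self, rng):
        ts = [Template(cluster_id=i, beat_index=i, samples=rng.normal(size=400))
              for i in range(12)]
        register_fiducials(ts, {i: (30, 130) for i in range(12)})
        assert all(t.qrs_onset == 30 and t.t_end == 130 for t in ts)


class TestTransferFiducials:
    def _template(self, onset=3, t_end=7, L=10):
        t = Template(cluster_id=0, beat_index=0, samples=np.zeros(L))
        t.set_fiducials(onset, t_end)
        return t

    def test_diagonal_path_identity(self):
        t = self._template()
        path = WarpingPath(np.column_stack([np.arange(10), np.arange(10)]))
        assert transfer_fiducials(t, path) == (3, 7)

    def test_latest_point_for_onset(self):
        pairs = [(i, i) for i in range(4)] + [(3, 4), (3, 5)] + [
            (i, i + 2) for i in range(4, 10)
        ]
        t = self._template()
        onset, _ = transfer_fiducials(t, WarpingPath(np.array(pairs)))
        assert onset == 5

    def test_earliest_point_for_t_end(self):
        pairs = [(i, i) for i in range(8)] + [(7, 8), (8, 9), (9, 9)]
        t = self._template()
        _, t_end = transfer_fiducials(t, WarpingPath(np.array(pairs)))
        assert t_end == 7

    def test_unregistered_template_rejected(self):
        t = Template(cluster_id=0, beat_index=0, samples=np.zeros(10))
        path = WarpingPath(np.column_stack([np.arange(10), np.arange(10)]))
        with pytest.raises(ConfigurationError):
            transfer_fiducials(t, path)


class TestQtMath:
    @pytest.mark.parametrize(
        "onset,t_end,expected", [(30, 130, 400.0), (20, 140, 480.0)]
    )
    def test_compute_qt(self, onset, t_end, expected):
        assert compute_qt(onset, t_end, 250.0) == pytest.approx(expected)

    def test_non_positive_interval_invalid(self):
        assert np.isnan(compute_qt(30, 30, 250.0))

    @pytest.mark.parametrize(
        "qt,rr,expected", [(400.0, 1000.0, 400.0), (400.0, 640.0, 500.0),
                           (350.0, 1440.0, 291.67)]
    )
    def test_bazett(self, qt, rr, expected):
        assert bazett(qt, rr) == pytest.approx(expected, abs=0.01)

    def test_bazett_rejects_bad_rr(self):
        with pytest.raises(ValueError):
            bazett(400.0, 0.0)

    def test_bazett_monotone_in_rr(self):
        rrs = np.linspace(400, 2000, 30)
        vals = [bazett(400.0, rr) for rr in rrs]
        assert (np.diff(vals) < 0).all()


class TestEndToEnd:
    def test_template_beats_recover_registered_qt(self, small_record):
        record, truth = small_record
        config = PipelineConfig(k=2, n_init=2, max_iter=30, seed=3)
        state = run_pipeline(record, config, truth=truth)
        fs = record.fs
        by_row = {t.beat_index: t for t in state.templates}
        for row, t in by_row.items():
            beat = state.beats[state.positions[row]]
            m = [x for x in state.measurements if x.beat_index == beat.beat_index]
            assert len(m) == 1
            expected = (t.t_end - t.qrs_onset) / fs * 1000.0
            assert m[0].qt_ms == pytest.approx(expected, abs=1e-12)

    def test_zero_noise_exact_recovery(self, small_record):
        record, truth = small_record
        config = PipelineConfig(k=2, n_init=2, max_iter=30, seed=3)
        state = run_pipeline(record, config, truth=truth)
        df = compare_to_truth(state, truth)
        assert len(df) > 40
        assert (df["qt_error_ms"] == 0.0).all()

    def test_outlier_distances_computed_per_cluster(self, small_record):
        record, truth = small_record
        config = PipelineConfig(k=2, n_init=1, max_iter=10, seed=3)
        state = run_pipeline(record, config, truth=truth)
        d = state.distances
        assert np.isfinite(d[~state.model.excluded & ~np.isnan(d)]).all()
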