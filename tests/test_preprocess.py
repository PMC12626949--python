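"""Resampling, axis harmonisation, label consensus/transfer, windowing,
robust scaling — each against an independent brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from armuse.preprocess import (
    LabelTrack,
    RobustWindowScaler,
    annotator_agreement,
    apply_scaler,
    assemble_variant,
    consensus_labels,
    fit_scaler,
    harmonize_axes,
    resample_to_30hz,
    segment_and_window,
    transfer_labels,
)
from armuse.sensor_io import (
    FUNCTIONAL,
    NONFUNCTIONAL,
    UNKNOWN,
    AnnotationSet,
    ClockMap,
    RawTrace,
)


def _trace(a, rate=30, side="right", role="paretic"):
    a = np.asarray(a, dtype=float)
    return RawTrace(t=np.arange(len(a)) / rate, a=a, rate_hz=rate,
                    side=side, role=role)


class TestResample:
    def test_30hz_identity(self):
        tr = _trace(np.random.default_rng(0).normal(size=(90, 3)))
        out = resample_to_30hz(tr)
        np.testing.assert_array_equal(out.a, tr.a)

    def test_200hz_sinusoid_resampled_to_300_samples_within_1pct(self):
        rate, dur, f = 200, 10, 1.0
        t = np.arange(rate * dur) / rate
        a = np.zeros((len(t), 3))
        a[:, 0] = np.sin(2 * np.pi * f * t)
        out = resample_to_30hz(_trace(a, rate=rate))
        assert len(out) == 300
        expected = np.sin(2 * np.pi * f * out.t)
        # ignore filter edge effects at the ends
        sl = slice(15, -15)
        assert np.max(np.abs(out.a[sl, 0] - expected[sl])) < 0.01

    def test_50hz_sample_count(self):
        out = resample_to_30hz(_trace(np.zeros((500, 3)), rate=50))
        assert len(out) == 300

    def test_upsampling_rejected(self):
        with pytest.raises(ValueError, match="up-sample"):
            resample_to_30hz(_trace(np.zeros((10, 3)), rate=15))


class TestHarmonizeAxes:
    def test_right_trace_unchanged(self):
        tr = _trace([[1, 2, 3], [4, 5, 6]], side="right")
        np.testing.assert_array_equal(harmonize_axes(tr).a, tr.a)

    def test_left_trace_mirror_axis_negated(self):
        tr = _trace([[1.0, 5.0, 7.0], [2.0, 6.0, 8.0]], side="left")
        out = harmonize_axes(tr, mirror_axis="x")
        np.testing.assert_array_equal(out.a[:, 0], [-1.0, -2.0])
        np.testing.assert_array_equal(out.a[:, 1:], tr.a[:, 1:])

    def test_involution(self):
        tr = _trace(np.random.default_rng(1).normal(size=(30, 3)), side="left")
        twice = harmonize_axes(harmonize_axes(tr, "y"), "y")
        np.testing.assert_array_equal(twice.a, tr.a)

    def test_unknown_side_rejected(self):
        tr = _trace(np.zeros((3, 3)))
        tr.side = "up"
        with pytest.raises(ValueError, match="unknown side"):
            harmonize_axes(tr)


def _vote_oracle(column):
    """Brute-force mode with tie -> unknown."""
    vals, counts = np.unique(column, return_counts=True)
    best = counts.max()
    if (counts == best).sum() > 1 or best * 2 <= len(column):
        return UNKNOWN
    return vals[np.argmax(counts)]


class TestConsensus:
    @pytest.mark.parametrize("votes,expected", [
        ((FUNCTIONAL, FUNCTIONAL, NONFUNCTIONAL), FUNCTIONAL),
        ((FUNCTIONAL, NONFUNCTIONAL, UNKNOWN), UNKNOWN),
        ((UNKNOWN, UNKNOWN, FUNCTIONAL), UNKNOWN),
        ((NONFUNCTIONAL,) * 3, NONFUNCTIONAL),
    ])
    def test_majority_examples(self, votes, expected):
        ann = AnnotationSet(frame_rate_hz=30,
                            tracks={"p": np.array(votes).reshape(-1, 1)})
        assert consensus_labels(ann, "p").labels[0] == expected

    def test_matches_brute_force_mode_on_random_frames(self, rng):
        arr = rng.choice([FUNCTIONAL, NONFUNCTIONAL, UNKNOWN],
                         size=(3, 1000)).astype(np.int8)
        ann = AnnotationSet(frame_rate_hz=30, tracks={"p": arr})
        got = consensus_labels(ann, "p").labels
        want = np.array([_vote_oracle(arr[:, i]) for i in range(1000)])
        np.testing.assert_array_equal(got, want)

    @given(st.integers(1, 5), st.integers(1, 40), st.integers(0, 10_000))
    def test_consensus_equals_oracle_property(self, n_ann, n_frames, seed):
        arr = np.random.default_rng(seed).choice(
            [FUNCTIONAL, NONFUNCTIONAL, UNKNOWN],
            size=(n_ann, n_frames)).astype(np.int8)
        ann = AnnotationSet(frame_rate_hz=30, tracks={"p": arr})
        got = consensus_labels(ann, "p").labels
        want = np.array([_vote_oracle(arr[:, i]) for i in range(n_frames)])
        np.testing.assert_array_equal(got, want)


class TestAgreement:
    def test_identical_tracks_agree_100(self):
        arr = np.zeros((3, 50), dtype=np.int8)
        ann = AnnotationSet(frame_rate_hz=30, tracks={"p": arr})
        assert annotator_agreement(ann, "p") == 100.0

    def test_one_of_four_frames_differs(self):
        arr = np.zeros((2, 4), dtype=np.int8)
        arr[1, 0] = FUNCTIONAL
        ann = AnnotationSet(frame_rate_hz=30, tracks={"p": arr})
        assert annotator_agreement(ann, "p") == pytest.approx(75.0)

    def test_three_annotators_match_pairwise_brute_force(self, rng):
        arr = rng.choice([FUNCTIONAL, NONFUNCTIONAL, UNKNOWN],
                         size=(3, 200)).astype(np.int8)
        ann = AnnotationSet(frame_rate_hz=30, tracks={"p": arr})
        pairs = [(0, 1), (0, 2), (1, 2)]
        want = 100 * np.mean([np.mean(arr[i] == arr[j]) for i, j in pairs])
        assert annotator_agreement(ann, "p") == pytest.approx(want)

    def test_single_annotator_rejected(self):
        ann = AnnotationSet(frame_rate_hz=30,
                            tracks={"p": np.zeros((1, 5), dtype=np.int8)})
        with pytest.raises(ValueError, match="at least 2"):
            annotator_agreement(ann, "p")


class TestTransferLabels:
    def test_identity_map_same_rate_copies(self):
        labels = np.array([0, 0, 1, 1, -1, 0], dtype=np.int8)
        track = LabelTrack(rate_hz=30, labels=labels)
        out = transfer_labels(track, ClockMap(0.0, 1.0), 6)
        np.testing.assert_array_equal(out.labels, labels)

    def test_half_rate_frames_repeat_twice(self):
        track = LabelTrack(rate_hz=15, labels=np.array([0, 1, 0], dtype=np.int8))
        out = transfer_labels(track, ClockMap(0.0, 1.0), 6)
        np.testing.assert_array_equal(out.labels, [0, 0, 1, 1, 0, 0])

    def test_offset_map_shifts_by_30_samples_vs_brute_force(self, rng):
        labels = rng.choice([0, 1], size=300).astype(np.int8)
        track = LabelTrack(rate_hz=30, labels=labels)
        cm = ClockMap(offset_s=1.0, scale=1.0)
        out = transfer_labels(track, cm, 300)
        # brute-force per-sample lookup
        want = np.full(300, UNKNOWN, dtype=np.int8)
        for i in range(300):
            tv = (i / 30 - cm.offset_s) / cm.scale
            j = int(np.floor(tv * 30 + 1e-9))
            if 0 <= j < 300:
                want[i] = labels[j]
        np.testing.assert_array_equal(out.labels, want)
        np.testing.assert_array_equal(out.labels[30:], labels[:-30])
        assert np.all(out.labels[:30] == UNKNOWN)


def _window_oracle(labels, T=60):
    """Brute-force tiler: U-removal, run splitting, majority labels."""
    labels = np.asarray(labels)
    runs, cur = [], []
    for i, v in enumerate(labels):
        if v == UNKNOWN:
            if cur:
                runs.append(cur)
            cur = []
        else:
            cur.append(i)
    if cur:
        runs.append(cur)
    out = []
    for run in runs:
        for k in range(len(run) // T):
            seg = [labels[i] for i in run[k * T:(k + 1) * T]]
            nf = sum(v == FUNCTIONAL for v in seg)
            if 2 * nf == T:
                continue
            out.append((run[k * T], 1 if 2 * nf > T else 0))
    return out


class TestWindowing:
    def _run(self, labels):
        labels = np.asarray(labels, dtype=np.int8)
        a = np.arange(len(labels) * 3, dtype=float).reshape(-1, 3)
        ds = segment_and_window(_trace(a), LabelTrack(rate_hz=30, labels=labels))
        return ds, a

    def test_150_nonfunctional_samples_give_two_windows(self):
        ds, _ = self._run(np.zeros(150))
        assert len(ds) == 2
        assert np.all(ds.y == 0)

    def test_below_window_length_gives_nothing(self):
        ds, _ = self._run(np.zeros(59))
        assert len(ds) == 0

    def test_alternating_runs_with_unknown_gap(self):
        labels = np.concatenate([np.full(70, FUNCTIONAL),
                                 np.full(10, UNKNOWN),
                                 np.full(130, NONFUNCTIONAL)])
        ds, a = self._run(labels)
        assert len(ds) == 3
        assert ds.y.tolist() == [1, 0, 0]
        # windows restart at each run: first NF window starts at sample 80
        np.testing.assert_array_equal(ds.windows[1], a[80:140])

    def test_tied_windows_dropped(self):
        labels = np.concatenate([np.full(30, FUNCTIONAL),
                                 np.full(30, NONFUNCTIONAL)])
        ds, _ = self._run(labels)
        assert len(ds) == 0

    def test_no_unknown_reaches_dataset_and_counts_match_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(30, 400))
            labels = rng.choice([FUNCTIONAL, NONFUNCTIONAL, UNKNOWN],
                                size=n, p=[0.4, 0.4, 0.2])
            ds, a = self._run(labels)
            oracle = _window_oracle(labels)
            assert len(ds) == len(oracle)
            for (start, y), win, got_y in zip(oracle, ds.windows, ds.y):
                assert got_y == y
                np.testing.assert_array_equal(win, a[start:start + 60])

    @given(st.integers(0, 100_000), st.integers(60, 600))
    def test_window_count_formula_property(self, seed, n):
        labels = np.random.default_rng(seed).choice(
            [FUNCTIONAL, NONFUNCTIONAL, UNKNOWN], size=n, p=[0.35, 0.35, 0.3])
        ds, _ = self._run(labels)
        assert len(ds) == len(_window_oracle(labels))


class TestAssembleVariant:
    def _arm(self, labels, offset=0.0):
        labels = np.asarray(labels, dtype=np.int8)
        a = offset + np.random.default_rng(0).normal(size=(len(labels), 3))
        return _trace(a), LabelTrack(rate_hz=30, labels=labels)

    def test_identical_unknown_free_arms_give_equal_counts(self):
        labels = np.zeros(240, dtype=np.int8)
        p = self._arm(labels)
        n = self._arm(labels, offset=1.0)
        dp = assemble_variant(p, n, "paretic")
        dc = assemble_variant(p, n, "combined")
        assert len(dc) == len(dp)
        assert dc.n_channels == 6

    def test_extra_unknown_on_nonparetic_shrinks_combined(self):
        p_labels = np.zeros(300, dtype=np.int8)
        n_labels = p_labels.copy()
        n_labels[100:160] = UNKNOWN
        p = self._arm(p_labels)
        n = self._arm(n_labels)
        dp = assemble_variant(p, n, "paretic")
        dc = assemble_variant(p, n, "combined")
        assert len(dc) < len(dp)
        # oracle: single-arm tiler on the intersected valid mask
        merged = p_labels.copy()
        merged[n_labels == UNKNOWN] = UNKNOWN
        assert len(dc) == len(_window_oracle(merged))

    def test_combined_uses_paretic_labels(self):
        p = self._arm(np.full(120, FUNCTIONAL, dtype=np.int8))
        n = self._arm(np.full(120, NONFUNCTIONAL, dtype=np.int8))
        dc = assemble_variant(p, n, "combined")
        assert np.all(dc.y == 1)

    def test_timeline_mismatch_rejected(self):
        p = self._arm(np.zeros(120, dtype=np.int8))
        n = self._arm(np.zeros(60, dtype=np.int8))
        with pytest.raises(ValueError, match="common timeline"):
            assemble_variant(p, n, "combined")


class TestRobustScaler:
    def test_standard_channel_nearly_unchanged(self, rng):
        # median 0, IQR 1 by construction -> identity transform
        x = rng.normal(size=4000)
        x = (x - np.median(x)) / (np.percentile(x, 75) - np.percentile(x, 25))
        X = x.reshape(-1, 10, 1)
        out = RobustWindowScaler().fit(X).transform(X)
        np.testing.assert_allclose(out, X, atol=1e-12)

    def test_constant_channel_maps_to_zeros_with_warning(self):
        X = np.full((5, 4, 2), 3.0)
        X[..., 1] = np.random.default_rng(0).normal(size=(5, 4))
        with pytest.warns(RuntimeWarning, match="zero-IQR"):
            out = RobustWindowScaler().fit(X).transform(X)
        np.testing.assert_array_equal(out[..., 0], 0.0)

    def test_training_median_zero_iqr_one_and_quantile_oracle(self, rng):
        X = rng.normal(2.0, 5.0, size=(40, 60, 3)) ** 3
        scaler = RobustWindowScaler().fit(X)
        out = scaler.transform(X)
        for c in range(3):
            flat = out[..., c].ravel()
            assert np.median(flat) == pytest.approx(0.0, abs=1e-9)
            iqr = np.percentile(flat, 75) - np.percentile(flat, 25)
            assert iqr == pytest.approx(1.0, abs=1e-9)
            # independent quantile computation
            raw = X[..., c].ravel()
            q1, q2, q3 = np.percentile(raw, [25, 50, 75])
            np.testing.assert_allclose(out[..., c], (X[..., c] - q2) / (q3 - q1))

    def test_matches_sklearn_robust_scaler(self, rng):
        from sklearn.preprocessing import RobustScaler

        X = rng.normal(size=(30, 60, 3)) * [1.0, 10.0, 0.1] + [0, 5, -2]
        ours = RobustWindowScaler().fit(X).transform(X)
        flat = X.reshape(-1, 3)
        theirs = RobustScaler().fit(flat).transform(flat).reshape(X.shape)
        np.testing.assert_allclose(ours, theirs, atol=1e-9)

    def test_affine_relation(self, rng):
        X = rng.normal(size=(20, 60, 3))
        params = fit_scaler(X)
        np.testing.assert_allclose(apply_scaler(params, 2 * X),
                                   2 * apply_scaler(params, X)
                                   + params.median / params.iqr,
                                   atol=1e-9)

    def test_empty_fit_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            RobustWindowScaler().fit(np.empty((0, 60, 3)))
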