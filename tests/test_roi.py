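import numpy as np
import pytest

from boutonquant import roi as R
from boutonquant.errors import BoutonQuantError
from boutonquant.synth import GeneratorConfig, NoiseParams, RenderGeometry, generate_dataset


def _spot_image(centers, amp=200.0, sigma=1.5, shape=(64, 64), floor=100.0):
    ys, xs = np.mgrid[:shape[0], :shape[1]]
    img = np.full(shape, floor)
    for cx, cy in centers:
        img = img + amp * np.exp(-((xs - cx) ** 2 + (ys - cy) ** 2) / (2 * sigma ** 2))
    return img


class TestDetectPuncta:
    def test_blank_image_empty(self):
        assert R.detect_puncta(np.full((32, 32), 7.0)) == []

    def test_empty_image_error(self):
        with pytest.raises(BoutonQuantError):
            R.detect_puncta(np.empty((0, 0)))

    def test_recovers_spot_centers(self):
        centers = [(10, 12), (30, 40), (50, 20), (22, 52)]
        rois = R.detect_puncta(_spot_image(centers))
        assert len(rois) == len(centers)
        for cx, cy in centers:
            d = min(np.hypot(r.center[0] - cx, r.center[1] - cy) for r in rois)
            assert d <= 1.0

    def test_close_pair_suppressed_to_brighter(self):
        img = _spot_image([(30, 30)], amp=300.0) + _spot_image([(32, 31)], amp=150.0) - 100.0
        rois = R.detect_puncta(img, min_separation=6.0)
        assert len(rois) == 1
        assert np.hypot(rois[0].center[0] - 30, rois[0].center[1] - 30) <= 1.0

    def test_order_is_descending_intensity(self):
        img = _spot_image([(10, 10)], amp=100.0) + _spot_image([(40, 40)], amp=400.0) - 100.0
        rois = R.detect_puncta(img)
        assert rois[0].center == (40.0, 40.0)


class TestBackgroundPlacement:
    def test_first_candidate_in_empty_field(self):
        rois = [R.Roi("r0", (32.0, 32.0), 3.0)]
        updated, bgs, excluded = R.place_background_rois(rois, (64, 64))
        assert excluded == []
        assert len(bgs) == 1
        # first enumerated candidate: offset 2r+1 at angle 0 (+x direction)
        assert bgs[0].center == pytest.approx((39.0, 32.0))
        assert updated[0].partner == bgs[0].roi_id

    def test_border_terminal_placed_inward(self):
        rois = [R.Roi("r0", (3.0, 32.0), 3.0)]
        _, bgs, excluded = R.place_background_rois(rois, (64, 64))
        assert excluded == []
        (cx, cy) = bgs[0].center
        assert 3.0 <= cx <= 60.0 and 3.0 <= cy <= 60.0

    def test_impossible_placement_excluded(self):
        # 13x13 field: every ring candidate at offset >= 2r+1 leaves the bounds
        rois = [R.Roi("r0", (6.0, 6.0), 3.0)]
        _, bgs, excluded = R.place_background_rois(rois, (13, 13), max_offset=7.0)
        assert excluded == ["r0"]
        assert bgs == []


class TestExtractTrace:
    def test_uniform_stack(self):
        stack = np.full((5, 32, 32), 42.0)
        tr = R.extract_trace(stack, R.Roi("r0", (16.0, 16.0), 3.0), frame_rate=50.0)
        np.testing.assert_allclose(tr.values, 42.0)

    def test_linearity(self, rng):
        a = rng.uniform(0, 100, size=(4, 32, 32))
        b = rng.uniform(0, 100, size=(4, 32, 32))
        roi = R.Roi("r0", (10.0, 20.0), 3.0)
        ta = R.extract_trace(a, roi, 50.0).values
        tb = R.extract_trace(b, roi, 50.0).values
        tab = R.extract_trace(a + b, roi, 50.0).values
        np.testing.assert_allclose(tab, ta + tb, rtol=1e-12)

    def test_out_of_bounds_error(self):
        with pytest.raises(BoutonQuantError):
            R.extract_trace(np.zeros((2, 16, 16)), R.Roi("r0", (1.0, 1.0), 3.0), 50.0)


class TestBackgroundCorrect:
    def test_self_subtraction_zero(self):
        t = R.Trace(np.arange(10.0), 50.0, "a")
        out = R.background_correct(t, t)
        np.testing.assert_array_equal(out.values, 0.0)
        assert out.corrected

    def test_zero_background_identity(self):
        t = R.Trace(np.arange(10.0), 50.0, "a")
        z = R.Trace(np.zeros(10), 50.0, "b")
        np.testing.assert_array_equal(R.background_correct(t, z).values, t.values)

    def test_global_constant_removed_exactly(self, rng):
        sig = rng.uniform(0, 10, 20)
        bg = rng.uniform(0, 10, 20)
        c = 123.456
        out0 = R.background_correct(R.Trace(sig, 5.0), R.Trace(bg, 5.0)).values
        out1 = R.background_correct(R.Trace(sig + c, 5.0), R.Trace(bg + c, 5.0)).values
        np.testing.assert_allclose(out1, out0, atol=1e-12)

    def test_length_mismatch_error(self):
        with pytest.raises(BoutonQuantError):
            R.background_correct(R.Trace(np.zeros(5), 5.0), R.Trace(np.zeros(6), 5.0))


class TestAverageTrials:
    def test_identical_trials_idempotent(self):
        t = R.Trace(np.sin(np.arange(30.0)), 100.0)
        out = R.average_trials([t] * 15)
        np.testing.assert_allclose(out.values, t.values)

    def test_single_trial_unchanged(self):
        t = R.Trace(np.arange(5.0), 100.0)
        np.testing.assert_array_equal(R.average_trials([t]).values, t.values)

    def test_noise_reduction_follows_sqrt_n(self, rng):
        # Monte-Carlo: averaging 15 iid-noise trials shrinks SD by ~1/sqrt(15)
        sigma, n_trials, n_frames, n_rep = 2.0, 15, 200, 60
        resid_sd = []
        for _ in range(n_rep):
            trials = [R.Trace(rng.normal(0, sigma, n_frames), 100.0)
                      for _ in range(n_trials)]
            resid_sd.append(R.average_trials(trials).values.std())
        expected = sigma / np.sqrt(n_trials)
        assert np.mean(resid_sd) == pytest.approx(expected, rel=0.05)

    def test_empty_and_mismatched(self):
        with pytest.raises(BoutonQuantError):
            R.average_trials([])
        with pytest.raises(BoutonQuantError):
            R.average_trials([R.Trace(np.zeros(5), 5.0), R.Trace(np.zeros(6), 5.0)])


class TestRoundTripTables:
    def test_roi_table_round_trip(self):
        rois = [R.Roi("r0", (3.5, 4.5), 3.0, partner="r0_bg"),
                R.Roi("r0_bg", (10.0, 4.5), 3.0, kind="background")]
        back = R.rois_from_frame(R.rois_to_frame(rois))
        assert back[0].partner == "r0_bg"
        assert back[1].kind == "background"
        assert back[0].center == rois[0].center


@pytest.fixture(scope="module")
def movie_ds():
    cfg = GeneratorConfig(n_neurons=1, n_terminals=30, ca_e_mm=(2.0,), seed=23,
                          render=RenderGeometry(height=96, width=96))
    return generate_dataset(cfg)


class TestOnRenderedMovies:
    def _detect(self, ds, movie):
        lo, hi = ds.protocol.baseline_window
        ref = movie[lo:hi].astype(float).mean(axis=0)
        return ref, R.detect_puncta(ref)

    def test_detection_recall_and_fdr(self, movie_ds):
        rec = movie_ds.recordings[0]
        _, rois = self._detect(movie_ds, rec.movie)
        matched = R.match_rois_to_terminals(rois, rec.positions)
        recall = len(matched) / len(rec.positions)
        fdr = 1.0 - len(matched) / len(rois) if rois else 0.0
        assert recall >= 0.95
        assert fdr <= 0.05

    def test_background_trace_level(self, movie_ds):
        # mean background-ROI trace ~ rendered background + camera offset
        rec = movie_ds.recordings[0]
        ref, rois = self._detect(movie_ds, rec.movie)
        _, bgs, _ = R.place_background_rois(rois, ref.shape)
        geom = movie_ds.config.render
        levels = [R.extract_trace(rec.movie, b, movie_ds.protocol.frame_rate).values.mean()
                  for b in bgs[:10]]
        assert np.mean(levels) == pytest.approx(geom.background + geom.offset, rel=0.05)

    def test_corrected_deflection_proportional_to_truth(self):
        # noiseless render: extracted corrected dF tracks the generating trace
        cfg = GeneratorConfig(n_neurons=1, n_terminals=12, ca_e_mm=(2.0,), seed=29,
                              noise=NoiseParams(0.0, 0.0),
                              render=RenderGeometry(height=96, width=96))
        ds = generate_dataset(cfg)
        rec = ds.recordings[0]
        lo, hi = ds.protocol.baseline_window
        ref = rec.movie[lo:hi].astype(float).mean(axis=0)
        rois = R.detect_puncta(ref)
        rois, bgs, _ = R.place_background_rois(rois, ref.shape)
        bg_by_id = {b.roi_id: b for b in bgs}
        matched = R.match_rois_to_terminals(rois, rec.positions)
        xs, ys = [], []
        for r in rois:
            if r.roi_id not in matched or r.partner is None:
                continue
            j = matched[r.roi_id]
            t = R.extract_trace(rec.movie, r, ds.protocol.frame_rate)
            b = R.extract_trace(rec.movie, bg_by_id[r.partner], ds.protocol.frame_rate)
            corr = R.background_correct(t, b).values
            true = rec.clean[j]
            xs.append(true - true[:49].mean())
            ys.append(corr - corr[:49].mean())
        xs, ys = np.concatenate(xs), np.concatenate(ys)
        r2 = np.corrcoef(xs, ys)[0, 1] ** 2
        assert r2 > 0.999
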