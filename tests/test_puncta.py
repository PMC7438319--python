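"""Detector, segmentation and measurement contracts for fluorescent puncta."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from synapcount import puncta, synthgen


def gaussian_spot(shape=(64, 64), center=(32.0, 32.0), amp=200.0,
                  sx=2.0, sy=2.0, background=0.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]]
    img = amp * np.exp(-0.5 * (((xx - center[1]) / sx) ** 2 +
                               ((yy - center[0]) / sy) ** 2))
    return img + background


def brute_force_nld(image, scale, theta):
    """Direct second difference of the smoothed image, the oracle for the
    separable implementation."""
    from scipy import ndimage

    smooth = ndimage.gaussian_filter(image.astype(float), sigma=scale / 2.0,
                                     mode="nearest")
    dy, dx = scale * np.sin(theta), scale * np.cos(theta)
    out = np.zeros_like(smooth)
    h, w = smooth.shape
    for r in range(h):
        for c in range(w):
            def sample(y, x):
                y = min(max(y, 0.0), h - 1.0)
                x = min(max(x, 0.0), w - 1.0)
                y0, x0 = int(y), int(x)
                y1, x1 = min(y0 + 1, h - 1), min(x0 + 1, w - 1)
                fy, fx = y - y0, x - x0
                return ((1 - fy) * (1 - fx) * smooth[y0, x0]
                        + (1 - fy) * fx * smooth[y0, x1]
                        + fy * (1 - fx) * smooth[y1, x0]
                        + fy * fx * smooth[y1, x1])
            out[r, c] = smooth[r, c] - 0.5 * (sample(r + dy, c + dx)
                                              + sample(r - dy, c - dx))
    return out


class TestNldFeatures:
    def test_constant_image_gives_zero_features(self):
        f = puncta.nld_features(np.full((32, 32), 7.0))
        assert np.allclose(f, 0.0, atol=1e-9)

    def test_linear_ramp_gives_zero_features_in_interior(self):
        # margin > smoothing truncation (4 sigma = 8 px) + shift (4 px),
        # outside which edge padding bends the ramp
        yy, xx = np.mgrid[:64, :64]
        f = puncta.nld_features(3.0 * xx + 2.0 * yy)
        interior = f[:, 16:-16, 16:-16]
        assert np.abs(interior).max() < 1e-6

    def test_matches_brute_force_oracle_on_spot(self):
        img = gaussian_spot(shape=(40, 40), center=(20.0, 20.0))
        scale, theta = 2.5, 0.0
        oracle = brute_force_nld(img, scale, theta)
        f = puncta.nld_features(img, scales=(scale,), n_orientations=1)
        assert np.allclose(f[0][5:-5, 5:-5], oracle[5:-5, 5:-5], atol=1e-6)

    def test_spot_feature_peaks_at_center(self):
        img = gaussian_spot(center=(30.0, 34.0))
        f = puncta.nld_features(img)
        resp = puncta.spot_response(f)
        peak = np.unravel_index(np.argmax(resp), resp.shape)
        assert abs(peak[0] - 30) <= 1 and abs(peak[1] - 34) <= 1

    def test_scale_larger_than_image_rejected(self):
        with pytest.raises(ValueError):
            puncta.nld_features(np.zeros((16, 16)), scales=(10.0,))


class TestDetectCandidates:
    def test_zero_image_yields_no_candidates(self):
        assert puncta.detect_candidates(np.zeros((64, 64))) == []

    def test_threshold_above_global_max_yields_empty(self):
        img = gaussian_spot()
        assert puncta.detect_candidates(img, low_threshold=1e9) == []

    def test_candidate_recall_on_synthetic_field(self, default_field):
        spec, image, truth = default_field
        hits, total = 0, 0
        for ch in (1, 2):
            cands = puncta.detect_candidates(image[ch - 1], low_threshold=0)
            gt = truth[truth.channel == ch][["y_px", "x_px"]].to_numpy()
            d, _ = cKDTree([c.peak for c in cands]).query(gt)
            hits += (d <= 3).sum()
            total += len(gt)
        assert hits / total >= 0.99

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            puncta.detect_candidates(np.zeros((32, 32)), low_threshold=-1)


class TestClassifier:
    def test_heldout_discrimination(self, classifier):
        from sklearn.metrics import roc_auc_score

        spec = synthgen.PunctaFieldSpec(seed=202)
        image, truth = synthgen.make_puncta_field(spec)
        cands = puncta.detect_candidates(image[0], channel=1)
        gt = truth[truth.channel == 1][["y_px", "x_px"]].to_numpy()
        d, _ = cKDTree(gt).query([c.peak for c in cands])
        y = d <= 2.0
        X = np.stack([c.features for c in cands])
        scores = classifier.predict_proba(X)[:, 1]
        assert roc_auc_score(y, scores) >= 0.95

    def test_pure_noise_field_mostly_rejected(self, classifier):
        spec = synthgen.PunctaFieldSpec(density_ch1=0, density_ch2=0,
                                        coloc_fraction=0, seed=203)
        image, _ = synthgen.make_puncta_field(spec)
        cands = puncta.detect_candidates(image[0], channel=1)
        accepted = puncta.classify_candidates(cands, classifier)
        assert len(cands) > 0
        assert len(accepted) <= 0.02 * len(cands)

    def test_empty_candidate_list_passes_through(self, classifier):
        assert puncta.classify_candidates([], classifier) == []

    def test_single_class_training_rejected(self):
        img = gaussian_spot()
        cands = puncta.detect_candidates(img)
        with pytest.raises(ValueError):
            puncta.train_classifier(cands, [True] * len(cands))


class TestSegmentation:
    def test_ten_percent_rule_on_background_free_spot(self):
        img = gaussian_spot(amp=200.0)
        mask = puncta.segment_punctum(img, (32, 32), background=0.0)
        expected = img >= 20.0
        assert np.array_equal(mask, expected)

    def test_scale_invariance(self):
        img = gaussian_spot(amp=150.0, background=0.0)
        m1 = puncta.segment_punctum(img, (32, 32), background=0.0)
        m2 = puncta.segment_punctum(img * 37.5, (32, 32), background=0.0)
        assert np.array_equal(m1, m2)

    def test_peak_below_background_signals_empty_mask(self):
        img = np.full((32, 32), 100.0)
        mask = puncta.segment_punctum(img, (16, 16), background=150.0)
        assert not mask.any()

    def test_two_spots_three_sigma_apart_get_separate_masks(self):
        class AcceptAll:                # isolates segmentation from the
            def predict(self, X):       # learned classifier
                return np.ones(len(X), dtype=bool)

        sx = 2.0
        img = (gaussian_spot(shape=(64, 96), center=(32.0, 40.0), sx=sx)
               + gaussian_spot(shape=(64, 96), center=(32.0, 40.0 + 3 * sx),
                               amp=180.0, sx=sx))
        records = puncta.detect_puncta(img, AcceptAll())
        assert len(records) == 2
        for cy0, cx0 in ((32.0, 40.0), (32.0, 46.0)):
            m = [r for r in records
                 if np.hypot(r.centroid[0] - cy0, r.centroid[1] - cx0) < 2.0]
            assert len(m) == 1

    def test_segmented_area_tracks_truth_on_isolated_puncta(self):
        spec = synthgen.PunctaFieldSpec(density_ch1=10, density_ch2=0,
                                        coloc_fraction=0, seed=301)
        image, truth = synthgen.make_puncta_field(spec)
        gt = truth[truth.channel == 1]
        rel_errs = []
        for row in gt.itertuples():
            peak = (int(round(row.y_px)), int(round(row.x_px)))
            flat, shape = puncta.segment_punctum(image[0], peak,
                                                 return_indices=True)
            if flat.size == 0:
                continue
            area = flat.size * spec.pixel_size ** 2
            rel_errs.append(abs(area - row.area_nm2) / row.area_nm2)
        assert len(rel_errs) >= 0.95 * len(gt)
        assert np.median(rel_errs) <= 0.15


class TestMeasurement:
    def test_uniform_disc_is_round_and_symmetric(self):
        yy, xx = np.mgrid[:41, :41]
        mask = (yy - 20) ** 2 + (xx - 20) ** 2 <= 10 ** 2
        img = np.where(mask, 100.0, 0.0)
        rec = puncta.measure_punctum(img, mask, background=0.0)
        assert abs(rec.skewness) < 0.1
        assert rec.aspect_ratio == pytest.approx(1.0, abs=0.05)
        assert rec.circularity == pytest.approx(1.0, rel=0.10)

    def test_size_uses_pixel_area(self):
        mask = np.zeros((20, 20), dtype=bool)
        mask[5:15, 5:15] = True      # 100 pixels
        img = np.where(mask, 50.0, 0.0)
        rec = puncta.measure_punctum(img, mask, pixel_size=84.0,
                                     background=0.0)
        assert rec.size == pytest.approx(0.7056, abs=1e-9)

    def test_elliptical_mask_aspect_ratio(self):
        yy, xx = np.mgrid[:61, :61]
        mask = ((yy - 30) / 8.0) ** 2 + ((xx - 30) / 16.0) ** 2 <= 1.0
        img = np.where(mask, 80.0, 0.0)
        rec = puncta.measure_punctum(img, mask, background=0.0)
        assert rec.aspect_ratio == pytest.approx(2.0, rel=0.10)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            puncta.measure_punctum(np.zeros((8, 8)),
                                   np.zeros((8, 8), dtype=bool))

    def test_record_invariants_on_detected_field(self, classifier,
                                                 default_field):
        spec, image, _ = default_field
        records = puncta.detect_puncta(image[0], classifier,
                                       pixel_size=spec.pixel_size)
        assert records
        for r in records:
            assert r.aspect_ratio >= 1.0
            assert r.circularity <= 1.0 + 1e-9
            assert r.size == pytest.approx(
                r.n_pixels * spec.pixel_size ** 2 / 1e6)
            assert r.mean_intensity > 0


class TestDensityAndColocalization:
    def test_density_zero_records(self):
        assert puncta.puncta_density([], 100.0) == 0.0

    def test_density_arithmetic(self):
        d = puncta.puncta_density([None] * 1850, 43.008 ** 2)
        assert d == pytest.approx(100.017, abs=1e-3)

    def test_density_zero_area_rejected(self):
        with pytest.raises(ValueError):
            puncta.puncta_density([], 0.0)

    @staticmethod
    def _record(shape, pixels, channel=1):
        flat = np.sort(np.array([p[0] * shape[1] + p[1] for p in pixels]))
        ys, xs = np.divmod(flat, shape[1])
        return puncta.PunctumRecord(
            channel=channel, centroid=(float(ys.mean()), float(xs.mean())),
            mask=flat, image_shape=shape)

    def test_identical_sets_give_c_one(self):
        shape = (32, 32)
        recs = [self._record(shape, [(5, 5), (5, 6)]),
                self._record(shape, [(20, 20), (20, 21)])]
        res = puncta.colocalization(recs, recs)
        assert res.c == 1.0
        assert res.n_entities_total == 2

    def test_disjoint_sets_give_c_zero(self):
        shape = (32, 32)
        r1 = [self._record(shape, [(5, 5), (5, 6)])]
        r2 = [self._record(shape, [(25, 25), (25, 26)], channel=2)]
        res = puncta.colocalization(r1, r2)
        assert res.c == 0.0
        assert res.n_entities_total == 2

    def test_partial_overlap_entity_counting(self):
        # ch1 = {A, B}, ch2 = {A', C}; A and A' overlap -> entities
        # {AA', B, C} and c = 1/3
        shape = (48, 48)
        A = self._record(shape, [(10, 10), (10, 11), (11, 10)])
        B = self._record(shape, [(30, 30), (30, 31)])
        A2 = self._record(shape, [(10, 10), (10, 11), (9, 10)], channel=2)
        C = self._record(shape, [(40, 8), (40, 9)], channel=2)
        res = puncta.colocalization([A, B], [A2, C])
        assert res.n_entities_both_channels == 1
        assert res.n_entities_total == 3
        assert res.c == pytest.approx(1 / 3)
        assert res.pairing == [(0, 0)]

    def test_pairing_is_one_to_one(self, classifier, default_field):
        spec, image, _ = default_field
        r1, r2, summary = puncta.analyze_field(image, classifier,
                                               spec.area_um2,
                                               pixel_size=spec.pixel_size)
        res = puncta.colocalization(r1, r2)
        assert len({i for i, _ in res.pairing}) == len(res.pairing)
        assert len({j for _, j in res.pairing}) == len(res.pairing)
        assert res.n_entities_total == len(r1) + len(r2) - len(res.pairing)


class TestRecovery:
    """Detection-level recovery of the generator's ground truth."""

    def test_density_recovery_across_densities_and_seeds(self, classifier):
        # half-size fields keep 20 seeds per density tractable; recovery is
        # judged against the realized ground-truth count in each field
        for density in (20.0, 80.0, 140.0):
            rel = []
            for seed in range(20):
                spec = synthgen.PunctaFieldSpec(
                    field_width=21.504, field_height=21.504,
                    density_ch1=density, density_ch2=0, coloc_fraction=0,
                    seed=1000 + seed)
                image, truth = synthgen.make_puncta_field(spec)
                recs = puncta.detect_puncta(image[0], classifier,
                                            pixel_size=spec.pixel_size)
                true_n = (truth.channel == 1).sum()
                if true_n:
                    rel.append(abs(len(recs) - true_n) / true_n)
            assert np.mean(rel) <= 0.05

    def test_coloc_recovery(self, classifier):
        for frac in (0.0, 0.5, 0.66, 1.0):
            d1, d2 = (84.0, 84.0) if frac == 1.0 else (91.3103, 77.1788)
            spec = synthgen.PunctaFieldSpec(density_ch1=d1, density_ch2=d2,
                                            coloc_fraction=frac, seed=2100)
            image, _ = synthgen.make_puncta_field(spec)
            _, _, summary = puncta.analyze_field(image, classifier,
                                                 spec.area_um2)
            assert abs(summary["c"] - frac) <= 0.05
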