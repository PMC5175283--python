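"""Three-zone intensity binning, ROI sampling and per-zone quantification."""

import numpy as np
import pytest

import msiquant as mq
from msiquant.zonation import BACKGROUND, HIGH, LOW, MASKED, MID
from conftest import as_norm


class TestZoneMap:
    def test_four_level_example(self):
        img = as_norm(np.array([[10.0, 5.0, 1.0, 0.05]]))
        zm = mq.zone_map(img, background_threshold=0.1, robust_max=False)
        assert zm.labels.tolist() == [[HIGH, MID, LOW, BACKGROUND]]

    def test_tie_at_high_boundary_is_high(self):
        img = as_norm(np.array([[10.0, 7.5, 1.0]]))
        zm = mq.zone_map(img, background_threshold=0.1, robust_max=False)
        assert zm.labels[0, 1] == HIGH  # closed lower bound at 0.75*max

    def test_tie_at_low_boundary_is_mid(self):
        img = as_norm(np.array([[10.0, 2.5, 1.0]]))
        zm = mq.zone_map(img, background_threshold=0.1, robust_max=False)
        assert zm.labels[0, 1] == MID

    def test_masked_pixel_labelled_masked(self):
        mask = np.array([[True, False, True]])
        img = as_norm(np.array([[10.0, 3.0, 1.0]]), mask=mask)
        zm = mq.zone_map(img, 0.1, robust_max=False)
        assert zm.labels[0, 1] == MASKED

    def test_matches_bruteforce_classifier(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            values = rng.uniform(0, 10, (15, 15))
            img = as_norm(values)
            thr = rng.uniform(0.05, 1.0)
            zm = mq.zone_map(img, thr, robust_max=False)
            vmax = values.max()
            for r in range(15):
                for c in range(15):
                    v = values[r, c]
                    if v <= thr:
                        expected = BACKGROUND
                    elif v >= 0.75 * vmax:
                        expected = HIGH
                    elif v >= 0.25 * vmax:
                        expected = MID
                    else:
                        expected = LOW
                    assert zm.labels[r, c] == expected

    def test_partition_sums_to_valid_pixels(self):
        rng = np.random.default_rng(2)
        img = as_norm(rng.uniform(0, 5, (20, 20)))
        zm = mq.zone_map(img, 0.5)
        counts = zm.counts()
        assert (counts["high"] + counts["mid"] + counts["low"]
                + counts["background"]) == int(img.mask.sum())

    def test_all_background_errors(self):
        img = as_norm(np.full((3, 3), 0.01))
        with pytest.raises(ValueError, match="no signal"):
            mq.zone_map(img, background_threshold=0.5)

    def test_robust_max_ignores_single_hot_pixel(self):
        values = np.full((50, 50), 5.0)
        values[0, 0] = 1e6
        zm = mq.zone_map(as_norm(values), 0.1, robust_max=True)
        # with a robust section max the bulk of the section stays "high"
        assert (zm.labels == HIGH).sum() > 2000


def _banded_image(signals=(10.0, 5.0, 2.0), band_rows=20, cols=60):
    values = np.zeros((band_rows * 3, cols))
    values[:band_rows] = signals[0]
    values[band_rows:2 * band_rows] = signals[1]
    values[2 * band_rows:] = signals[2]
    return as_norm(values)


class TestSampleZoneRois:
    def test_solid_zones_give_disjoint_pure_rois(self):
        img = _banded_image()
        zm = mq.zone_map(img, 0.1, robust_max=False)
        rois = mq.sample_zone_rois(zm, n_per_zone=3, roi_pixels=25,
                                   purity=1.0, seed=4)
        for zone, zone_rois in rois.items():
            assert len(zone_rois) == 3
            taken = set()
            for roi in zone_rois:
                assert not taken & set(roi.coords)
                taken |= set(roi.coords)
                labels = zm.labels[roi.indices()]
                assert (labels == labels[0]).all()

    def test_deterministic_under_seed(self):
        img = _banded_image()
        zm = mq.zone_map(img, 0.1, robust_max=False)
        a = mq.sample_zone_rois(zm, 2, 25, 0.9, seed=11)
        b = mq.sample_zone_rois(zm, 2, 25, 0.9, seed=11)
        assert {z: [r.coords for r in rs] for z, rs in a.items()} == \
               {z: [r.coords for r in rs] for z, rs in b.items()}

    def test_purity_contract_on_speckled_zone(self):
        rng = np.random.default_rng(8)
        # speckled mid zone (85% mid, 15% low) over solid high/low bands
        values = np.where(rng.random((40, 40)) < 0.85, 4.0, 1.0)
        values[30:35] = 8.0
        values[35:] = 1.0
        zm = mq.zone_map(as_norm(values), 0.1, robust_max=False)
        rois = mq.sample_zone_rois(zm, n_per_zone=2, roi_pixels=25,
                                   purity=0.8, seed=3)
        for code, name in ((MID, "mid"), (LOW, "low")):
            for roi in rois.get(name, []):
                frac = (zm.labels[roi.indices()] == code).mean()
                assert frac >= 0.8

    def test_infeasible_zone_errors(self):
        # a 2-pixel "low" zone cannot host a pure 25-pixel ROI
        values = np.full((30, 30), 8.0)
        values[15:] = 4.0
        values[0, 0] = values[0, 1] = 1.0
        zm = mq.zone_map(as_norm(values), 0.1, robust_max=False)
        with pytest.raises(ValueError, match="low"):
            mq.sample_zone_rois(zm, 1, 25, purity=1.0, seed=0)


class TestZoneQuantify:
    def test_uniform_bands_identity_curve_folds(self, identity_curve):
        # zones assigned directly: uniform signals 8 / 4 / 2 with y = x
        img = _banded_image((8.0, 4.0, 2.0))
        shape = img.shape
        rois = {
            "high": [mq.make_circular_roi((10, 30), 25, shape)],
            "mid": [mq.make_circular_roi((30, 30), 25, shape)],
            "low": [mq.make_circular_roi((50, 30), 25, shape)],
        }
        rep = mq.zone_quantify(img, rois, identity_curve)
        assert rep.fold_high_vs_low == pytest.approx(4.0)
        assert rep.fold_high_vs_mid == pytest.approx(2.0)
        assert rep.folds_defined

    def test_single_roi_per_zone_sd_unavailable(self, identity_curve):
        img = _banded_image()
        zm = mq.zone_map(img, 0.1, robust_max=False)
        rois = mq.sample_zone_rois(zm, 1, 25, 1.0, seed=0)
        rep = mq.zone_quantify(img, rois, identity_curve)
        assert all(np.isnan(sd) for sd in rep.sd_amount.values())

    def test_nonpositive_zone_mean_undefined_folds(self):
        curve = mq.CalibrationCurve(1.0, 10.0, 1.0,
                                    [(1, 11), (2, 12), (3, 13)], (1.0, 3.0))
        img = _banded_image()
        zm = mq.zone_map(img, 0.1, robust_max=False)
        rois = mq.sample_zone_rois(zm, 2, 25, 1.0, seed=0)
        rep = mq.zone_quantify(img, rois, curve)  # low/mid amounts < 0
        assert not rep.folds_defined
        assert np.isnan(rep.fold_high_vs_low)

    @pytest.mark.parametrize("seed", range(5))
    def test_fold_recovery_on_designed_phantom(self, seed, threshold_model,
                                               calibration_curve):
        section = mq.make_zoned_phantom(seed=seed)
        truth = section.truth.zone_densities
        norm = mq.normalize(section.drug, section.istd)
        zm = mq.zone_map(norm, threshold_model.threshold)
        rois = mq.sample_zone_rois(zm, 3, 25, purity=1.0, seed=seed)
        rep = mq.zone_quantify(norm, rois, calibration_curve)
        assert rep.fold_high_vs_low == pytest.approx(
            truth["high"] / truth["low"], rel=0.10)
        assert rep.fold_high_vs_mid == pytest.approx(
            truth["high"] / truth["mid"], rel=0.10)


class TestHomogenateEquivalent:
    def test_uniform_section_equals_subroi(self, identity_curve):
        img = as_norm(np.full((20, 20), 6.0))
        whole = mq.whole_image_roi(img)
        sub = mq.make_circular_roi((10, 10), 25, (20, 20))
        bulk = mq.homogenate_equivalent(img, whole, identity_curve)
        assert bulk.amount_pmol_per_mm2 == pytest.approx(
            mq.quantify_roi(img, sub, identity_curve).amount_pmol_per_mm2)

    def test_empty_tissue_errors(self, identity_curve):
        img = as_norm(np.ones((4, 4)), mask=np.zeros((4, 4), bool))
        roi = mq.make_circular_roi((2, 2), 4, (4, 4))
        with pytest.raises(ValueError):
            mq.homogenate_equivalent(img, roi, identity_curve)

    def test_equal_bulk_different_heterogeneity(self, threshold_model,
                                                calibration_curve):
        uniform = mq.make_phantom(mq.PhantomConfig(
            archetype="homogeneous", density_viable=6.0, seed=3))[0]
        clustered = mq.make_phantom(mq.PhantomConfig(
            archetype="necrotic_core", density_viable=12.0,
            necrotic_fraction=0.5, seed=3))[0]
        bulk, pct = [], []
        for sec in (uniform, clustered):
            norm = mq.normalize(sec.drug, sec.istd)
            roi = mq.whole_image_roi(norm)
            bulk.append(mq.homogenate_equivalent(
                norm, roi, calibration_curve).amount_pmol_per_mm2)
            pct.append(mq.percent_positive(
                norm, threshold=threshold_model.threshold))
        assert abs(bulk[0] - bulk[1]) / bulk[0] < 0.01
        assert abs(pct[0] - pct[1]) > 15
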