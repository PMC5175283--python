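"""Ion-image extraction, grid I/O round-trips, and circular ROIs."""

import numpy as np
import pytest

import msiquant as mq
from msiquant import MSIFormatError, ROIError, extract_ion_image
from msiquant.msi_data import roi_from_json

SPECTRUM = (np.array([283.9, 284.2, 284.5, 289.2]),
            np.array([5.0, 10.0, 3.0, 7.0]))


class TestExtractIonImage:
    @pytest.mark.parametrize("mz,expected", [
        # closed window [283.95, 284.45]: 284.5 excluded, 283.9 excluded
        (284.2, 10.0 + 0.0),
        (289.2, 7.0),
    ])
    def test_closed_window_sum(self, mz, expected):
        img = extract_ion_image({(0, 0): SPECTRUM}, mz=mz, tol=0.25)
        assert img.values[0, 0] == expected

    def test_window_includes_peak_at_edge(self):
        # 283.95 is exactly at the lower closed bound
        img = extract_ion_image(
            {(0, 0): (np.array([283.95, 284.2]), np.array([5.0, 10.0]))},
            mz=284.2, tol=0.25)
        assert img.values[0, 0] == 15.0

    def test_missing_pixel_masked_and_matches_bruteforce(self):
        rng = np.random.default_rng(42)
        spectra = {}
        for coord in [(0, 0), (0, 1), (1, 1)]:  # (1, 0) missing
            mzs = rng.uniform(250, 300, 40)
            ints = rng.uniform(0, 20, 40)
            spectra[coord] = (mzs, ints)
        mz, tol = 284.2, 0.25
        img = extract_ion_image(spectra, mz=mz, tol=tol)
        assert img.shape == (2, 2)
        assert not img.mask[1, 0]
        for (r, c), (mzs, ints) in spectra.items():
            expected = sum(float(i) for m, i in zip(mzs, ints)
                           if mz - tol <= m <= mz + tol)
            assert img.values[r, c] == pytest.approx(expected, abs=1e-12)

    def test_additive_over_peak_partition(self):
        rng = np.random.default_rng(1)
        mzs = rng.uniform(280, 290, 60)
        ints = rng.uniform(0, 5, 60)
        whole = extract_ion_image({(0, 0): (mzs, ints)}, 284.2, 2.0)
        part_a = extract_ion_image({(0, 0): (mzs[:30], ints[:30])}, 284.2, 2.0)
        part_b = extract_ion_image({(0, 0): (mzs[30:], ints[30:])}, 284.2, 2.0)
        assert whole.values[0, 0] == pytest.approx(
            part_a.values[0, 0] + part_b.values[0, 0], rel=1e-12)

    def test_window_outside_acquired_range_names_range(self):
        with pytest.raises(ValueError, match=r"250.*300"):
            extract_ion_image({(0, 0): SPECTRUM}, mz=200.0, tol=0.25,
                              acquired_mz_range=(250.0, 300.0))

    def test_window_disjoint_from_observed_peaks_errors(self):
        with pytest.raises(ValueError, match="outside acquired"):
            extract_ion_image({(0, 0): SPECTRUM}, mz=250.0, tol=0.25)

    def test_duplicate_coordinates_error(self):
        triples = [((0, 0), *SPECTRUM), ((0, 0), *SPECTRUM)]
        with pytest.raises(ValueError, match="duplicate"):
            extract_ion_image(triples, mz=284.2, tol=0.25)


class TestCircularROI:
    def test_single_pixel(self):
        roi = mq.make_circular_roi((5, 5), 1, (11, 11))
        assert roi.coords == ((5, 5),)

    def test_unit_ring_lexicographic_ties(self):
        roi = mq.make_circular_roi((5, 5), 5, (20, 20))
        assert roi.coords == ((5, 5), (4, 5), (5, 4), (5, 6), (6, 5))

    def test_25_pixel_roi_area(self):
        roi = mq.make_circular_roi((10, 10), 25, (30, 30))
        assert roi.n_pixels == 25
        assert roi.area_mm2(100.0) == pytest.approx(0.25)

    def test_deterministic(self):
        a = mq.make_circular_roi((7, 3), 13, (25, 25))
        b = mq.make_circular_roi((7, 3), 13, (25, 25))
        assert a.coords == b.coords

    def test_too_many_pixels_errors(self):
        with pytest.raises(ROIError):
            mq.make_circular_roi((1, 1), 10, (3, 3))

    def test_roi_json_roundtrip(self):
        circle = roi_from_json({"kind": "circle", "center": [5, 5],
                                "n_pixels": 9}, (20, 20))
        assert circle.n_pixels == 9
        pixels = roi_from_json(circle.to_json(), (20, 20))
        assert pixels.coords == circle.coords


@pytest.fixture
def sample_image():
    rng = np.random.default_rng(3)
    values = rng.uniform(0, 100, (6, 5))
    mask = np.ones((6, 5), bool)
    mask[2, 2] = mask[5, 0] = False
    values[~mask] = 0
    return mq.IonImage(values, mask, pixel_size_um=100.0, target_mz=284.2,
                       mz_tolerance=0.25, label="roundtrip test")


class TestGridIO:
    def test_csv_roundtrip_identity(self, sample_image, tmp_path):
        path = mq.write_grid(sample_image, tmp_path / "img.csv")
        back = mq.read_grid(path)
        assert np.array_equal(back.values, sample_image.values)
        assert np.array_equal(back.mask, sample_image.mask)
        assert back.pixel_size_um == sample_image.pixel_size_um
        assert back.target_mz == sample_image.target_mz
        assert back.mz_tolerance == sample_image.mz_tolerance
        assert back.label == sample_image.label

    def test_csv_na_cell_is_masked(self, tmp_path):
        (tmp_path / "g.csv").write_text("#pixel_size_um=100\n1.5,NA\n2.0,3.0\n")
        img = mq.read_grid(tmp_path / "g.csv")
        assert not img.mask[0, 1]
        assert img.mask.sum() == 3

    def test_csv_ragged_rows_error(self, tmp_path):
        (tmp_path / "bad.csv").write_text("1,2,3\n4,5\n")
        with pytest.raises(MSIFormatError, match="ragged"):
            mq.read_grid(tmp_path / "bad.csv")

    def test_csv_bad_cell_error(self, tmp_path):
        (tmp_path / "bad.csv").write_text("1,x\n")
        with pytest.raises(MSIFormatError, match="bad cell"):
            mq.read_grid(tmp_path / "bad.csv")

    def test_imzml_roundtrip_identity(self, sample_image, tmp_path):
        path = mq.write_grid(sample_image, tmp_path / "img.imzml")
        assert (tmp_path / "img.ibd").exists()
        back = mq.read_grid(path)
        assert back.shape == sample_image.shape
        assert np.array_equal(back.mask, sample_image.mask)
        assert np.array_equal(back.values[back.mask],
                              sample_image.values[sample_image.mask])
        assert back.pixel_size_um == sample_image.pixel_size_um
        assert back.target_mz == sample_image.target_mz
        assert back.mz_tolerance == sample_image.mz_tolerance
        assert back.label == sample_image.label

    def test_processed_and_continuous_modes_agree(self, tmp_path):
        from pyimzml.ImzMLWriter import ImzMLWriter

        rng = np.random.default_rng(9)
        vals = rng.uniform(1, 50, (4, 4))
        drug = mq.IonImage(vals, None, 100.0, 284.2, 0.25)
        istd = mq.IonImage(vals * 0.3, None, 100.0, 289.2, 0.25)
        spectra = mq.images_to_spectra(drug, istd)
        for mode in ("processed", "continuous"):
            with ImzMLWriter(str(tmp_path / f"{mode}.imzML"), mode=mode,
                             intensity_dtype=np.float64) as writer:
                for (r, c), (mzs, ints) in sorted(spectra.items()):
                    writer.addSpectrum(mzs, ints, (c + 1, r + 1))
        a = mq.read_grid(tmp_path / "processed.imzML", mz=284.2, tol=0.25)
        b = mq.read_grid(tmp_path / "continuous.imzML", mz=284.2, tol=0.25)
        assert np.allclose(a.values, b.values)
        assert np.array_equal(a.mask, b.mask)

    def test_malformed_imzml_errors(self, tmp_path):
        (tmp_path / "bad.imzml").write_text("<not valid xml")
        with pytest.raises(MSIFormatError):
            mq.read_grid(tmp_path / "bad.imzml")

    def test_truncated_ibd_errors(self, sample_image, tmp_path):
        path = mq.write_grid(sample_image, tmp_path / "img.imzml")
        ibd = tmp_path / "img.ibd"
        ibd.write_bytes(ibd.read_bytes()[:20])
        with pytest.raises(MSIFormatError, match="imzML"):
            mq.read_grid(path)


class TestInvariants:
    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            mq.IonImage(np.array([[-1.0]]), None)

    def test_masked_negative_ok(self):
        img = mq.IonImage(np.array([[-1.0, 2.0]]),
                          np.array([[False, True]]))
        assert img.valid_values().tolist() == [2.0]

    def test_stack_group_validation(self):
        img = mq.IonImage(np.ones((2, 2)), None)
        with pytest.raises(ValueError):
            mq.SectionStack([(img, img)], group="mystery")
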