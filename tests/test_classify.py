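import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ssfm import (
    ClassBands,
    KOperator,
    LabelMap,
    NoiseModel,
    PhantomSpec,
    Region,
    apply_k,
    build_maps,
    classify_map,
    default_bands,
    default_calibration,
    export_scatter,
    intensity_vs_concentration,
    make_phantom,
    simulate_cube,
    summarize,
)
from ssfm.preprocess import PreprocessConfig


class TestDefaultBands:
    @pytest.mark.parametrize(
        "lam,label",
        [
            (550.0, "melanoma"),
            (553.0, "bcc"),       # closed-open: boundary belongs upward
            (563.0, "scc"),
            (570.0, "normal"),
            (581.0, "nevus"),
            (600.0, "unclassified"),
            (540.0, "unclassified"),
        ],
    )
    def test_interval_lookup(self, lam, label):
        assert default_bands().lookup(lam) == label

    def test_bands_cover_the_published_peak_window(self):
        bands = default_bands()
        assert bands.intervals[0][1] == 548.0
        assert bands.intervals[-1][2] == 588.0

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        edges=st.lists(
            st.floats(min_value=540.0, max_value=600.0),
            min_size=3,
            max_size=6,
            unique=True,
        )
    )
    def test_disjoint_bands_never_double_assign(self, edges):
        edges = sorted(edges)
        labels = [f"band{k}" for k in range(len(edges) - 1)]
        bands = ClassBands(
            tuple(
                (label, lo, hi)
                for label, lo, hi in zip(labels, edges, edges[1:])
            )
        )
        probes = np.linspace(538.0, 602.0, 257)
        for lam in probes:
            hits = [
                label
                for label, lo, hi in bands.intervals
                if lo <= lam < hi
            ]
            assert len(hits) <= 1
            expected = hits[0] if hits else "unclassified"
            assert bands.lookup(lam) == expected


class TestClassifyMap:
    def test_two_region_phantom_segmented_exactly(self, sharp_cfg):
        spec = PhantomSpec(
            background="normal", regions=(Region(5, 5, 25, 20, "melanoma"),)
        )
        truth_labels = make_phantom(spec)
        cube, _ = simulate_cube(truth_labels, seed=6)
        maps = build_maps(cube, sharp_cfg)
        predicted = classify_map(maps.wavelength_map)
        np.testing.assert_array_equal(predicted.labels, truth_labels.labels)

    def test_missing_pixels_stay_missing(self):
        lam = np.full((4, 4), 563.0)
        lam[2, 2] = np.nan
        labels = classify_map(lam)
        assert labels.labels[2, 2] == "missing"
        assert labels.labels[0, 0] == "scc"

    def test_spatial_median_corrects_isolated_pixel(self):
        lam = np.full((7, 7), 555.0)
        lam[3, 3] = 563.0  # lone SCC pixel inside a BCC field
        raw = classify_map(lam)
        assert raw.labels[3, 3] == "scc"
        filtered = classify_map(lam, spatial_median=True)
        assert filtered.labels[3, 3] == "bcc"
        assert np.all(filtered.labels != "scc")

    def test_accuracy_noise_free_is_total(self, uniform_cube, sharp_cfg):
        bands = default_bands()
        for label in ("melanoma", "bcc", "scc", "normal", "nevus"):
            cube, truth, _ = uniform_cube(label, seed=3, m=20, n=15)
            maps = build_maps(cube, sharp_cfg)
            predicted = classify_map(maps.wavelength_map)
            _, lo, hi = next(b for b in bands.intervals if b[0] == label)
            in_band = (truth.wavelength_map >= lo) & (truth.wavelength_map < hi)
            assert np.all(predicted.labels[in_band] == label)

    def test_accuracy_99_percent_away_from_band_edges(self, uniform_cube):
        """Rician noise at 2% amplitude misclassifies <1% of interior pixels."""
        bands = default_bands()
        total = correct = 0
        for label in ("melanoma", "bcc", "scc", "normal", "nevus"):
            amp = intensity_vs_concentration(
                {"melanoma": 2.0, "bcc": 8.0, "scc": 10.0, "normal": 16.0, "nevus": 12.0}[label]
            )
            sigma = 0.02 * amp
            cube, truth, _ = uniform_cube(
                label, seed=17, noise=NoiseModel("rician", sigma)
            )
            maps = build_maps(cube, PreprocessConfig(rician_sigma=sigma))
            predicted = classify_map(maps.wavelength_map)
            _, lo, hi = next(b for b in bands.intervals if b[0] == label)
            interior = (truth.wavelength_map >= lo + 0.5) & (
                truth.wavelength_map < hi - 0.5
            )
            total += int(interior.sum())
            correct += int((predicted.labels[interior] == label).sum())
        assert correct / total >= 0.99


class TestSummarize:
    def test_nevus_width_recovered_from_spread(self, uniform_cube, sharp_cfg):
        cube, _, labels = uniform_cube("nevus", seed=10)
        maps = build_maps(cube, sharp_cfg)
        summary = summarize(labels, maps)
        assert summary.stats["nevus"].count == 1800
        assert summary.stats["nevus"].width_nm == pytest.approx(14.8, rel=0.05)

    def test_modal_shift_of_melanoma_field(self, uniform_cube, sharp_cfg):
        cube, _, labels = uniform_cube("melanoma", seed=10)
        maps = build_maps(cube, sharp_cfg)
        summary = summarize(labels, maps)
        assert summary.stats["melanoma"].modal_shift_nm == pytest.approx(18.0, abs=0.2)

    def test_empty_class_marked_undefined(self, uniform_cube, sharp_cfg):
        cube, _, labels = uniform_cube("scc", seed=1, m=6, n=5)
        maps = build_maps(cube, sharp_cfg)
        summary = summarize(labels, maps)
        assert summary.stats["bcc"].count == 0
        assert np.isnan(summary.stats["bcc"].mean_lambda_nm)
        assert summary.stats["scc"].fraction == pytest.approx(1.0)

    def test_fractions_sum_to_one(self, sharp_cfg):
        spec = PhantomSpec(
            background="normal",
            regions=(Region(0, 0, 30, 30, "scc"), Region(30, 0, 60, 15, "bcc")),
        )
        labels = make_phantom(spec)
        cube, _ = simulate_cube(labels, seed=9)
        maps = build_maps(cube, sharp_cfg)
        predicted = classify_map(maps.wavelength_map)
        summary = summarize(predicted, maps)
        assert sum(s.fraction for s in summary.stats.values()) == pytest.approx(1.0)

    def test_class_concentration_is_table_lookup(self, uniform_cube, sharp_cfg):
        cube, _, labels = uniform_cube("nevus", seed=1, m=6, n=5)
        maps = build_maps(cube, sharp_cfg)
        summary = summarize(labels, maps)
        assert summary.stats["nevus"].typ_conc_uM == 12.0


class TestExportScatter:
    def test_default_phantom_has_1800_rows_and_conservation(
        self, uniform_cube, sharp_cfg
    ):
        cube, _, _ = uniform_cube("normal", seed=13)
        maps = build_maps(cube, sharp_cfg)
        maps = apply_k(maps, KOperator(kind="table", table=default_calibration()))
        predicted = classify_map(maps.wavelength_map)
        frame = export_scatter(predicted, maps)
        assert len(frame) == 1800
        np.testing.assert_allclose(frame["lambda_nm"] - frame["shift_nm"], 532.0)
        summary = summarize(predicted, maps)
        for label, group in frame.groupby("label"):
            assert summary.stats[label].count == len(group)

    def test_missing_pixels_excluded(self):
        lam = np.full((4, 4), 563.0)
        lam[0, 0] = np.nan
        from ssfm import PixelMaps

        maps = PixelMaps(
            intensity_map=np.ones((4, 4)),
            wavelength_map=lam,
            shift_map=lam - 532.0,
        )
        labels = classify_map(lam)
        frame = export_scatter(labels, maps)
        assert len(frame) == 15
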