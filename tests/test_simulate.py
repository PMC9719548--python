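import numpy as np
import pytest
from scipy import stats

from ssfm import (
    KAPPA_UM,
    ConfigError,
    CoverageError,
    NoiseModel,
    PhantomSpec,
    RangeError,
    Region,
    WavelengthGrid,
    class_by_label,
    default_class_table,
    intensity_vs_concentration,
    make_phantom,
    simulate_cube,
    wavelength_vs_concentration,
)


class TestDefaultClassTable:
    @pytest.mark.parametrize(
        "label,center,spread,conc",
        [
            ("melanoma", 550.0, 2.0, 2.0),
            ("bcc", 555.0, 4.0, 8.0),
            ("scc", 563.0, 3.3, 10.0),
            ("normal", 570.0, 4.1, 16.0),
            ("nevus", 581.0, 14.8, 12.0),
        ],
    )
    def test_printed_class_parameters(self, label, center, spread, conc):
        params = class_by_label()[label]
        assert params.center_nm == center
        assert params.spread_nm == spread
        assert params.typ_conc_uM == conc

    def test_bands_bracket_centers(self):
        for params in default_class_table():
            assert params.band_lo_nm < params.center_nm < params.band_hi_nm


class TestIntensityCurve:
    def test_no_fluorophore_no_signal(self):
        assert intensity_vs_concentration(0.0) == 0.0

    def test_quench_constant_makes_10_and_40_emit_identically(self):
        i10 = intensity_vs_concentration(10.0)
        i40 = intensity_vs_concentration(40.0)
        assert i10 == pytest.approx(i40, rel=1e-14)

    def test_brute_force_argmax_is_the_quench_constant(self):
        c = np.arange(0.0, 200.0, 1e-3)
        best = c[np.argmax(intensity_vs_concentration(c))]
        assert best == pytest.approx(KAPPA_UM, abs=1e-3)

    def test_negative_concentration_rejected(self):
        with pytest.raises(RangeError):
            intensity_vs_concentration(-1.0)


class TestWavelengthCurve:
    def test_anchor_values(self, calibration):
        assert wavelength_vs_concentration(2.0, calibration) == pytest.approx(550.0)
        assert wavelength_vs_concentration(10.0, calibration) == pytest.approx(563.0)

    def test_monotone_in_concentration(self, calibration):
        rng = np.random.default_rng(11)
        c = rng.uniform(2.0, 16.0, size=(1000, 2))
        lo, hi = c.min(axis=1), c.max(axis=1)
        lam_lo = wavelength_vs_concentration(lo, calibration)
        lam_hi = wavelength_vs_concentration(hi, calibration)
        assert np.all(lam_lo <= lam_hi)

    def test_outside_span_rejected(self, calibration):
        with pytest.raises(RangeError):
            wavelength_vs_concentration(40.0, calibration)


class TestMakePhantom:
    def test_region_area_arithmetic(self):
        spec = PhantomSpec(
            background="normal",
            regions=(Region(10, 10, 20, 20, "melanoma"),),
        )
        labels = make_phantom(spec)
        counts = labels.counts()
        assert counts["melanoma"] == 100
        assert counts["normal"] == 1700

    def test_empty_region_list_uniform(self):
        labels = make_phantom(PhantomSpec(m=5, n=4, background="bcc"))
        assert labels.counts() == {"bcc": 20}

    def test_overlap_takes_later_label(self):
        spec = PhantomSpec(
            m=10,
            n=10,
            background="normal",
            regions=(
                Region(0, 0, 6, 6, "bcc"),
                Region(3, 3, 8, 8, "scc"),
            ),
        )
        labels = make_phantom(spec)
        assert labels.labels[4, 4] == "scc"
        assert labels.labels[1, 1] == "bcc"

    def test_region_outside_grid_rejected(self):
        spec = PhantomSpec(
            m=10, n=10, regions=(Region(5, 5, 12, 8, "scc"),)
        )
        with pytest.raises(ConfigError):
            make_phantom(spec)


class TestSimulateCube:
    def test_same_seed_identical_cubes(self, uniform_cube):
        cube_a, _, _ = uniform_cube("scc", seed=5, noise=NoiseModel("rician", 0.05))
        cube_b, _, _ = uniform_cube("scc", seed=5, noise=NoiseModel("rician", 0.05))
        np.testing.assert_array_equal(cube_a.data, cube_b.data)

    def test_different_seed_differs(self, uniform_cube):
        cube_a, _, _ = uniform_cube("scc", seed=5)
        cube_b, _, _ = uniform_cube("scc", seed=6)
        assert not np.array_equal(cube_a.data, cube_b.data)

    def test_noise_free_argmax_near_true_peak(self, uniform_cube, grid):
        cube, truth, _ = uniform_cube("melanoma", seed=3)
        lam_argmax = grid.values[np.argmax(cube.data, axis=-1)]
        assert np.all(np.abs(lam_argmax - truth.wavelength_map) <= grid.step)

    def test_dichroic_cutoff_zeroes_response(self, uniform_cube, grid):
        cube, _, _ = uniform_cube("melanoma", seed=3)
        assert np.all(cube.data[:, :, grid.values <= 535.0] == 0.0)

    def test_rician_noise_bias_matches_rice_mean(self, uniform_cube, grid):
        """Mean of the noisy peak channel shows the Rician positive bias."""
        amp = intensity_vs_concentration(10.0)
        sigma = 0.05 * amp
        cube, truth, _ = uniform_cube(
            "scc", seed=9, noise=NoiseModel("rician", sigma), spread_nm=0.0
        )
        k = np.argmin(np.abs(grid.values - 563.0))
        observed = cube.data[:, :, k].mean()
        clean = amp * np.exp(-((grid.values[k] - 563.0) ** 2) / (2 * 6.0**2))
        expected = stats.rice.mean(b=clean / sigma, scale=sigma)
        assert observed > clean
        assert observed == pytest.approx(expected, rel=0.01)

    def test_classes_spectrally_separated_noise_free(self, uniform_cube):
        ranges = {}
        for label in ("melanoma", "bcc", "scc", "normal", "nevus"):
            _, truth, _ = uniform_cube(label, seed=1)
            ranges[label] = (
                truth.wavelength_map.min(),
                truth.wavelength_map.max(),
            )
        ordered = [ranges[l] for l in ("melanoma", "bcc", "scc", "normal", "nevus")]
        for (_, hi), (lo, _) in zip(ordered, ordered[1:]):
            assert hi <= lo + 1e-9

    def test_grid_must_cover_emission_band(self):
        labels = make_phantom(PhantomSpec(m=4, n=4, background="scc"))
        narrow = WavelengthGrid(np.linspace(545.0, 580.0, 64))
        with pytest.raises(CoverageError):
            simulate_cube(labels, grid=narrow, seed=0)

    def test_unknown_label_rejected(self):
        labels = make_phantom(PhantomSpec(m=4, n=4, background="stroma"))
        with pytest.raises(ConfigError):
            simulate_cube(labels, seed=0)
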