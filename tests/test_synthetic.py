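"""Synthetic generators: closed-form intensity law, determinism, and the
distributional properties downstream statistics rely on."""

import numpy as np
import pytest
from scipy import ndimage

from sopquant import (
    DivisionPopulationSpec,
    GeometryError,
    SyntheticCellSpec,
    crescent_law,
    division_angle,
    generate_cell_image,
    generate_contingency,
    generate_division_population,
    generate_population_profiles,
    generate_profile,
    segregation_ratio,
)


def ring_centerline_values(spec, image, n=360):
    """Bilinear image values on the analytic ellipse centerline, with their
    angular positions (y-down frame, measured from the +x axis)."""
    cx, cy = spec.center
    A, B = spec.semi_axes
    th = np.linspace(-np.pi, np.pi, n, endpoint=False)
    t = np.arctan2(np.sin(th) * A / B, np.cos(th))
    x = cx + A * np.cos(t)
    y = cy + B * np.sin(t)
    theta = np.arctan2(y - cy, x - cx)
    vals = ndimage.map_coordinates(image, [y, x], order=1)
    return theta, vals


class TestCellImage:
    def test_uniform_ring_at_kappa_zero(self):
        spec = SyntheticCellSpec(crescent_kappa=0.0, crescent_amplitude=150.0, noise_sd=0.0)
        image, _ = generate_cell_image(spec)
        _, vals = ring_centerline_values(spec, image)
        expected = spec.cortex_baseline + spec.crescent_amplitude
        assert np.allclose(vals, expected, rtol=0.02)

    def test_zero_amplitude_ring_is_baseline(self):
        spec = SyntheticCellSpec(crescent_amplitude=0.0, noise_sd=0.0)
        image, _ = generate_cell_image(spec)
        _, vals = ring_centerline_values(spec, image)
        assert np.allclose(vals, spec.cortex_baseline, rtol=0.02)

    def test_crescent_peaks_at_center_and_dips_at_antipode(self):
        spec = SyntheticCellSpec(
            crescent_kappa=4.0, crescent_amplitude=200.0,
            crescent_center_angle=30.0, noise_sd=0.0,
        )
        image, _ = generate_cell_image(spec)
        theta, vals = ring_centerline_values(spec, image)
        peak_theta = np.degrees(theta[np.argmax(vals)])
        trough_theta = np.degrees(theta[np.argmin(vals)])
        assert abs(peak_theta - 30.0) < 3.0
        assert abs(abs(trough_theta - 30.0) - 180.0) < 3.0
        # closed-form values at the two extremes
        mu = np.deg2rad(30.0)
        assert vals.max() == pytest.approx(
            crescent_law(np.array([mu]), 4, 200, 300, center_angle_deg=30.0)[0], rel=0.02
        )
        assert vals.min() == pytest.approx(
            crescent_law(np.array([mu + np.pi]), 4, 200, 300, center_angle_deg=30.0)[0], rel=0.02
        )

    def test_ring_centerline_matches_closed_form_everywhere(self):
        spec = SyntheticCellSpec(crescent_kappa=4.0, crescent_amplitude=200.0, noise_sd=0.0)
        image, _ = generate_cell_image(spec)
        theta, vals = ring_centerline_values(spec, image)
        law = crescent_law(theta, 4.0, 200.0, spec.cortex_baseline)
        assert np.max(np.abs(vals - law) / law) <= 0.02

    def test_interior_and_exterior_levels(self):
        spec = SyntheticCellSpec(noise_sd=0.0)
        image, mask = generate_cell_image(spec)
        assert image[int(spec.center[1]), int(spec.center[0])] == pytest.approx(spec.cytoplasm_level)
        assert image[2, 2] == pytest.approx(spec.background_level)
        assert mask[int(spec.center[1]), int(spec.center[0])]
        assert not mask[2, 2]

    def test_seed_determinism_and_nonnegativity(self):
        spec = SyntheticCellSpec(noise_sd=50.0, background_level=5.0, seed=11)
        img1, _ = generate_cell_image(spec)
        img2, _ = generate_cell_image(spec)
        assert np.array_equal(img1, img2)
        assert img1.min() >= 0.0
        img3, _ = generate_cell_image(SyntheticCellSpec(noise_sd=50.0, background_level=5.0, seed=12))
        assert not np.array_equal(img1, img3)

    def test_ring_outside_image_rejected(self):
        with pytest.raises(GeometryError):
            generate_cell_image(SyntheticCellSpec(image_size=(64, 64), center=(60.0, 32.0)))

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"semi_axes": (7.0, 7.0), "ring_width": 4.0},  # < 2*ring_width
            {"crescent_kappa": -1.0},
            {"noise_sd": -1.0},
            {"crescent_center_angle": 200.0},
        ],
    )
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SyntheticCellSpec(**kwargs)


class TestProfileGenerator:
    def test_uniform_limit(self):
        prof = generate_profile(36, 0.0, 1.0, 1.0, 0.0, seed=0)
        assert np.allclose(prof.values, 2.0)

    def test_unimodal_peak_at_crescent_center(self):
        prof = generate_profile(36, 2.0, 1.0, 0.5, 0.0, seed=0, crescent_center_angle=90.0)
        k = np.arange(1, 37)
        theta = 2 * np.pi * k / 36
        expected = crescent_law(theta, 2.0, 1.0, 0.5, 90.0)
        assert np.allclose(prof.values, expected)
        # peak at the sample closest to the center; strictly unimodal around it
        peak = np.argmax(prof.values)
        assert np.degrees(theta[peak]) == pytest.approx(90.0, abs=360 / 36)
        rolled = np.roll(prof.values, -peak)  # descending away from the peak on both sides
        assert np.all(np.diff(rolled[:18]) < 0)

    def test_seed_determinism(self):
        p1 = generate_profile(50, 2.0, 1.0, 0.5, 0.3, seed=42)
        p2 = generate_profile(50, 2.0, 1.0, 0.5, 0.3, seed=42)
        assert np.array_equal(p1.values, p2.values)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            generate_profile(2, 0.0, 1.0, 1.0, 0.0, seed=0)


class TestDivisionPopulation:
    def test_zero_dispersion_gives_constant_angles(self):
        spec = DivisionPopulationSpec(n_cells=20, angle_mean=25.0, angle_sd=0.0, seed=1)
        records = generate_division_population(spec)
        assert len(records) == 20
        assert all(division_angle(r) == pytest.approx(25.0, abs=0.01) for r in records)

    def test_segregation_ratio_matches_beta_mean(self):
        """Empirical mean ratio at n = 1e4 against the Beta(a,b) mean a/(a+b)."""
        a, b = 2.0, 8.0
        spec = DivisionPopulationSpec(n_cells=10_000, segregation_shape=(a, b), seed=5)
        records = generate_division_population(spec)
        ratios = [segregation_ratio(r) for r in records]
        assert np.mean(ratios) == pytest.approx(a / (a + b), abs=3 * 0.12 / 100)

    def test_extreme_asymmetry(self):
        spec = DivisionPopulationSpec(n_cells=2000, segregation_shape=(1.0, 200.0), seed=6)
        ratios = [segregation_ratio(r) for r in generate_division_population(spec)]
        assert np.mean(ratios) == pytest.approx(1.0 / 201.0, abs=0.002)

    def test_angle_sd_distinguishes_tight_from_broad(self):
        """Sample SDs at n = 60 recover 35 vs 68 degrees within +-20%."""
        rng = np.random.default_rng(0)
        for target in (35.0, 68.0):
            sds = []
            for _ in range(50):
                spec = DivisionPopulationSpec(n_cells=60, angle_sd=target, seed=int(rng.integers(2**31)))
                angles = [division_angle(r) for r in generate_division_population(spec)]
                sds.append(np.std(angles, ddof=1))
            assert abs(np.mean(sds) - target) / target < 0.2

    def test_population_profiles_reflect_polarization_kappa(self):
        from sopquant import polarization_coefficient

        tight = DivisionPopulationSpec(n_cells=30, polarization_kappa=4.0, seed=2)
        loose = DivisionPopulationSpec(n_cells=30, polarization_kappa=0.0, seed=2)
        p_tight = np.mean([polarization_coefficient(p).P for p in generate_population_profiles(tight)])
        p_loose = np.mean([polarization_coefficient(p).P for p in generate_population_profiles(loose)])
        assert p_tight > 0.5 > p_loose

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            DivisionPopulationSpec(n_cells=0)
        with pytest.raises(ValueError):
            DivisionPopulationSpec(angle_sd=-1.0)
        with pytest.raises(ValueError):
            DivisionPopulationSpec(segregation_shape=(0.0, 1.0))


class TestContingencyGenerator:
    def test_identical_probabilities_converge(self):
        probs = [0.5, 0.3, 0.2]
        table = generate_contingency([probs, probs], [100_000, 100_000], seed=9)
        fracs = table.counts / table.counts.sum(axis=1, keepdims=True)
        assert np.max(np.abs(fracs - probs)) < 0.01

    def test_zero_count_row(self):
        table = generate_contingency([[0.5, 0.5], [0.5, 0.5]], [0, 10], seed=0)
        assert table.counts[0].sum() == 0

    def test_seed_determinism(self):
        t1 = generate_contingency([[0.7, 0.3], [0.2, 0.8]], [50, 50], seed=4)
        t2 = generate_contingency([[0.7, 0.3], [0.2, 0.8]], [50, 50], seed=4)
        assert np.array_equal(t1.counts, t2.counts)

    @pytest.mark.parametrize(
        "probs,ns",
        [
            ([[0.5, 0.6]], [10]),          # does not sum to 1
            ([[0.5, 0.5], [-0.1, 1.1]], [10, 10]),  # negative probability
            ([[0.5, 0.5], [0.5, 0.5]], [10, -1]),   # negative count
        ],
    )
    def test_invalid_inputs_rejected(self, probs, ns):
        with pytest.raises(ValueError):
            generate_contingency(probs, ns, seed=0)
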