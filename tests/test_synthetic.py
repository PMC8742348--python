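"""Synthetic generators: photon traces, ACF fixtures, nucleus images."""

import numpy as np
import pytest

from nucleodyn.synthetic import (
    NucleusShapeSpec,
    TraceSimConfig,
    ellipsoid_surface_area,
    ellipsoid_volume,
    generate_acf_curves,
    generate_nucleus_image,
    simulate_trace,
    sphericity_of,
)
from nucleodyn.fcs_fit import evaluate_acf_model


def _fast_config(**kw) -> TraceSimConfig:
    base = dict(
        diffusion_coefficient=20.0,
        w_r=0.25,
        omega=2.0,
        n_molecules=3.0,
        brightness=1e5,
        bin_width=2e-4,
        duration=1.0,
        seed=0,
    )
    base.update(kw)
    return TraceSimConfig(**base)


class TestSimulateTrace:
    def test_no_emission_gives_all_zero_trace(self):
        trace, _ = simulate_trace(_fast_config(brightness=0.0, background_rate=0.0))
        assert trace.counts.sum() == 0

    def test_same_seed_bit_identical(self):
        a, _ = simulate_trace(_fast_config(seed=42))
        b, _ = simulate_trace(_fast_config(seed=42))
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_different_seed_differs(self):
        a, _ = simulate_trace(_fast_config(seed=1))
        b, _ = simulate_trace(_fast_config(seed=2))
        assert not np.array_equal(a.counts, b.counts)

    def test_counts_are_nonnegative_integers(self):
        trace, _ = simulate_trace(_fast_config(binding_classes=((2.0, 1.0),)))
        assert np.issubdtype(trace.counts.dtype, np.integer)
        assert trace.counts.min() >= 0

    def test_mean_count_rate_matches_gaussian_volume_average(self):
        # closed form: uniform emitters at concentration N / V_eff seen
        # through the 3-D Gaussian profile give <rate> = eps * N / 2^{3/2}
        cfg = _fast_config(brightness=2e5, duration=1.0)
        rates = []
        for seed in range(10):
            trace, _ = simulate_trace(cfg.__class__(**{**cfg.__dict__, "seed": seed}))
            rates.append(trace.counts.mean() / trace.bin_width)
        expected = cfg.brightness * cfg.n_molecules / 2.0**1.5
        se = np.std(rates, ddof=1) / np.sqrt(len(rates))
        assert abs(np.mean(rates) - expected) < 3 * se

    def test_total_counts_scale_linearly_with_brightness(self):
        lo, _ = simulate_trace(_fast_config(brightness=5e4, seed=3))
        hi, _ = simulate_trace(_fast_config(brightness=1e5, seed=3))
        assert hi.counts.sum() == pytest.approx(2 * lo.counts.sum(), rel=0.05)

    def test_ground_truth_params_follow_kinetics(self):
        cfg = _fast_config(binding_classes=((4.0, 10.0), (0.5, 1.0)))
        _, truth = simulate_trace(cfg)
        # detailed balance: f_j proportional to k_on/k_off
        assert truth.f_short == pytest.approx(0.4 / 1.9)
        assert truth.f_long == pytest.approx(0.5 / 1.9)
        assert truth.f_diff == pytest.approx(1.0 / 1.9)
        assert truth.tau_short == pytest.approx(0.1)
        assert truth.tau_long == pytest.approx(1.0)
        assert truth.tau_diff == pytest.approx(0.25**2 / (4 * 20.0))

    @pytest.mark.parametrize(
        "kw",
        [
            dict(duration=0.01),  # < 100 bins
            dict(binding_classes=((1.0, 3.0), (1.0, 2.0), (1.0, 1.0))),
            dict(binding_classes=((1.0, 1.0), (1.0, 2.0))),  # wrong order
            dict(bin_width=-1e-4),
        ],
    )
    def test_invalid_configs_rejected(self, kw):
        with pytest.raises(ValueError):
            _fast_config(**kw)


class TestGenerateAcfCurves:
    def test_zero_noise_reproduces_model_exactly(self, two_population_params, lag_grid):
        curve = generate_acf_curves(two_population_params, lag_grid, 0.0, 1, 0)[0]
        np.testing.assert_array_equal(
            curve.g, evaluate_acf_model(two_population_params, lag_grid)
        )

    def test_mean_of_noisy_curves_converges_to_model(
        self, two_population_params, lag_grid
    ):
        # CLT: mean of 1000 replicates within 4 SE of the noiseless curve
        sd = 0.02
        curves = generate_acf_curves(two_population_params, lag_grid, sd, 1000, seed=8)
        stack = np.vstack([c.g for c in curves])
        model = evaluate_acf_model(two_population_params, lag_grid)
        se = sd / np.sqrt(1000)
        assert np.all(np.abs(stack.mean(axis=0) - model) < 4 * se)

    def test_same_seed_identical_curve_set(self, two_population_params, lag_grid):
        a = generate_acf_curves(two_population_params, lag_grid, 0.01, 3, seed=5)
        b = generate_acf_curves(two_population_params, lag_grid, 0.01, 3, seed=5)
        for ca, cb in zip(a, b):
            np.testing.assert_array_equal(ca.g, cb.g)

    def test_invalid_inputs_rejected(self, two_population_params):
        with pytest.raises(ValueError):
            generate_acf_curves(two_population_params, [], 0.0, 1, 0)
        with pytest.raises(ValueError):
            generate_acf_curves(two_population_params, [1e-3, 1e-2], -0.1, 1, 0)


class TestNucleusGroundTruth:
    def test_sphere_volume_closed_form(self):
        # 4/3 pi 5^3 = 523.5988 um^3
        assert ellipsoid_volume(5, 5, 5) == pytest.approx(523.5988, abs=1e-3)

    def test_sphere_sphericity_is_one(self):
        a = ellipsoid_surface_area(5, 5, 5)
        assert sphericity_of(ellipsoid_volume(5, 5, 5), a) == pytest.approx(1.0, rel=1e-12)

    def test_prolate_spheroid_sphericity(self):
        # closed-form prolate area 2 pi a^2 (1 + (c/(a e)) arcsin e)
        v = ellipsoid_volume(5, 5, 10)
        a = ellipsoid_surface_area(5, 5, 10)
        assert sphericity_of(v, a) == pytest.approx(0.9287, abs=5e-4)

    def test_triaxial_area_between_bounding_spheroids(self):
        a_tri = ellipsoid_surface_area(3, 4, 5)
        assert ellipsoid_surface_area(3, 3, 5) < a_tri < ellipsoid_surface_area(4, 4, 5)

    def test_generated_record_matches_closed_form(self):
        spec = NucleusShapeSpec(semi_axes=(5, 5, 5), seed=0)
        _, truth = generate_nucleus_image(spec)
        assert truth.volume == pytest.approx(523.5988, abs=1e-3)
        assert truth.sphericity == pytest.approx(1.0, rel=1e-12)

    def test_deformed_truth_from_mesh_is_consistent(self):
        # perturbed solid: mesh-integrated truth must be close to the
        # unperturbed ellipsoid for small amplitude, with psi <= 1
        spec = NucleusShapeSpec(semi_axes=(5, 5, 5), deformation_amplitude=0.05, seed=2)
        _, truth = generate_nucleus_image(spec)
        assert truth.volume == pytest.approx(523.6, rel=0.1)
        assert truth.sphericity < 1.0


class TestGenerateNucleusImage:
    def test_same_seed_bit_identical(self):
        spec = NucleusShapeSpec(seed=11)
        a, _ = generate_nucleus_image(spec)
        b, _ = generate_nucleus_image(spec)
        np.testing.assert_array_equal(a.data, b.data)

    def test_voxel_volume_converges_with_resolution(self):
        # noiseless occupancy volume approaches the analytic value as the
        # grid refines: error at 0.2 um must be below error at 0.4 um
        errors = []
        for v in (0.4, 0.2):
            spec = NucleusShapeSpec(
                semi_axes=(4, 4, 4),
                voxel_size=(v, v, v),
                psf_sigma=1e-3,
                noise_model="none",
                seed=1,
            )
            img, truth = generate_nucleus_image(spec)
            measured = (img.data > (spec.background + spec.peak_intensity) / 2).sum() * v**3
            errors.append(abs(measured - truth.volume) / truth.volume)
        assert errors[1] < errors[0]
        assert errors[1] < 0.02

    def test_peak_must_exceed_background(self):
        with pytest.raises(ValueError):
            NucleusShapeSpec(semi_axes=(5, 5, 5), peak_intensity=5.0)

    def test_solid_must_fit_in_explicit_extent(self):
        spec = NucleusShapeSpec(semi_axes=(5, 5, 5), grid_shape=(10, 10, 10))
        with pytest.raises(ValueError, match="does not fit"):
            generate_nucleus_image(spec)
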