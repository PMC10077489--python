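"""Tests for the synthetic ground-truth generators."""
import dataclasses

import numpy as np
import pytest

from glxquant import synthetic, tem
from glxquant.synthetic import (
    CohortSpec,
    DecayTruth,
    GroupSpec,
    LoopTruth,
    TEMTruth,
    make_cohort,
    make_decay_trace,
    make_loop_image,
    make_tem_annotation,
    render_ring_image,
    ring_radial_profile,
)

from conftest import numeric_ring_profile


class TestLoopTruthValidation:
    def test_offset_exceeding_radius_rejected(self):
        with pytest.raises(ValueError):
            LoopTruth(radius_membrane=1.0, glx_offset=1.5)

    def test_negative_pixel_size_rejected(self):
        with pytest.raises(ValueError):
            LoopTruth(pixel_size=-0.05)

    def test_bad_noise_model_rejected(self):
        with pytest.raises(ValueError):
            LoopTruth(noise_model="salt_and_pepper")


class TestMakeLoopImage:
    def test_coincident_rings_are_proportional(self):
        """glx_offset = 0, no noise: the channels differ only by per-channel
        intensity scaling."""
        truth = LoopTruth(glx_offset=0.0, noise_model="none")
        pair, _ = make_loop_image(truth)
        g = (pair.glx - truth.background[0]) / truth.peak_intensity[0]
        m = (pair.membrane - truth.background[1]) / truth.peak_intensity[1]
        np.testing.assert_allclose(g, m, atol=1e-9)

    def test_radial_maximum_at_ring_radius(self, default_loop, default_truth):
        """Peak position vs an independent dense numerical convolution of
        the ideal circle with the PSF, within half a pixel."""
        pair, resolved = default_loop
        half_px = default_truth.pixel_size / 2
        for radius, channel in (
            (default_truth.glx_radius, pair.glx),
            (default_truth.radius_membrane, pair.membrane),
        ):
            rs = np.linspace(radius - 0.3, radius + 0.3, 1201)
            oracle = numeric_ring_profile(rs, radius, default_truth.psf_sigma)
            r_oracle = rs[np.argmax(oracle)]
            assert abs(r_oracle - radius) < half_px
            # peak of the rendered image along a horizontal ray, with
            # parabolic sub-pixel refinement of the discrete argmax
            cx, cy = resolved.center
            ps = default_truth.pixel_size
            row = int(cy / ps)
            xs = (np.arange(channel.shape[1]) + 0.5) * ps
            right = np.flatnonzero(xs > cx)
            vals = channel[row, right]
            i = int(np.argmax(vals))
            y0, y1, y2 = vals[i - 1], vals[i], vals[i + 1]
            delta = 0.5 * (y0 - y2) / (y0 - 2 * y1 + y2)
            r_img = xs[right][i] + delta * ps - cx
            assert abs(r_img - radius) < half_px

    def test_determinism_bit_identical(self):
        truth = LoopTruth(noise_model="gaussian", noise_magnitude=0.05, seed=42)
        pair1, _ = make_loop_image(truth)
        pair2, _ = make_loop_image(truth)
        assert np.array_equal(pair1.glx, pair2.glx)
        assert np.array_equal(pair1.membrane, pair2.membrane)

    def test_field_of_view_too_small(self):
        with pytest.raises(ValueError, match="field of view too small"):
            make_loop_image(LoopTruth(radius_membrane=5.0, fov_um=8.0))

    def test_noise_never_leaves_negative_intensities(self):
        truth = LoopTruth(
            noise_model="gaussian", noise_magnitude=0.5, seed=3,
            background=(0.0, 0.0),
        )
        pair, _ = make_loop_image(truth)
        assert pair.glx.min() >= 0
        assert pair.membrane.min() >= 0

    def test_poisson_noise_deterministic(self):
        truth = LoopTruth(noise_model="poisson", seed=11)
        pair1, _ = make_loop_image(truth)
        pair2, _ = make_loop_image(truth)
        assert np.array_equal(pair1.glx, pair2.glx)

    def test_abluminal_flag_moves_glx_ring_outside(self):
        truth = LoopTruth(glx_side="abluminal", glx_offset=0.3)
        assert truth.glx_radius == pytest.approx(5.3)

    def test_zero_psf_and_ring_width_rejected(self):
        with pytest.raises(ValueError):
            make_loop_image(LoopTruth(psf_sigma=0.0, ring_width=0.0))


class TestRingRenderingInvariants:
    @pytest.mark.parametrize("sigma", [0.08, 0.2])
    def test_flux_conservation(self, sigma):
        """Pixel sum x pixel area equals the unblurred ring circumference."""
        ps = 0.05
        n = 300
        img = render_ring_image((n, n), (n * ps / 2, n * ps / 2), 5.0, sigma, ps)
        total = img.sum() * ps**2
        assert total == pytest.approx(2 * np.pi * 5.0, rel=1e-4)

    def test_radial_symmetry_under_rotation(self, default_loop):
        """The loop centre sits at the grid centre, so a 90-degree rotation
        maps pixel centres onto pixel centres exactly."""
        pair, _ = default_loop
        np.testing.assert_allclose(pair.glx, np.rot90(pair.glx), atol=1e-9)
        np.testing.assert_allclose(pair.membrane, np.rot90(pair.membrane), atol=1e-9)

    def test_profile_matches_numeric_convolution(self):
        rs = np.linspace(4.0, 6.0, 41)
        analytic = ring_radial_profile(rs, 5.0, 0.1)
        oracle = numeric_ring_profile(rs, 5.0, 0.1)
        np.testing.assert_allclose(analytic, oracle, rtol=1e-6)


def _small_loop_defaults():
    # small frame keeps cohort tests fast
    return LoopTruth(radius_membrane=2.0, pixel_size=0.1, glx_offset=0.3)


class TestMakeCohort:
    def test_counts(self, tmp_path):
        spec = CohortSpec(
            groups=(
                GroupSpec("a", 0.2, 0.0, 2),
                GroupSpec("b", 0.4, 0.0, 2),
            ),
            glomeruli_per_subject=2,
            loops_per_glomerulus=3,
            loop_defaults=_small_loop_defaults(),
            seed=0,
        )
        manifest = make_cohort(spec, tmp_path)
        assert len(manifest) == 24
        assert all((tmp_path / p).exists() for p in manifest["path"])
        assert (tmp_path / "manifest.csv").exists()
        assert (tmp_path / "seeds.csv").exists()

    def test_zero_between_subject_sd_gives_equal_offsets(self, tmp_path):
        spec = CohortSpec(
            groups=(GroupSpec("a", 0.25, 0.0, 3),),
            glomeruli_per_subject=1,
            loops_per_glomerulus=2,
            loop_defaults=_small_loop_defaults(),
            seed=1,
        )
        manifest = make_cohort(spec, tmp_path)
        assert manifest["true_offset_um"].nunique() == 1
        assert manifest["true_offset_um"].iloc[0] == pytest.approx(0.25)

    def test_group_means_within_three_standard_errors(self, tmp_path):
        """Oracle: SE = between-subject SD / sqrt(n_subjects)."""
        sd, n = 0.05, 30
        spec = CohortSpec(
            groups=(GroupSpec("lo", 0.2, sd, n), GroupSpec("hi", 0.4, sd, n)),
            glomeruli_per_subject=1,
            loops_per_glomerulus=1,
            loop_defaults=_small_loop_defaults(),
            seed=2,
        )
        manifest = make_cohort(spec, tmp_path)
        se = sd / np.sqrt(n)
        by_subject = manifest.drop_duplicates("subject_id")
        for label, target in (("lo", 0.2), ("hi", 0.4)):
            mean = by_subject.loc[by_subject["group"] == label, "true_offset_um"].mean()
            assert abs(mean - target) < 3 * se


class TestMakeTemAnnotation:
    def test_all_zero_thickness_fully_uncovered(self):
        truth = TEMTruth(n_intersections=10, thickness_mean=0.0, thickness_sd=0.0)
        _, achieved = make_tem_annotation(truth)
        assert achieved.achieved_uncovered_fraction == 1.0

    def test_target_fraction_exact_by_construction(self):
        truth = TEMTruth(n_intersections=20, fraction_uncovered_target=0.35, seed=5)
        annotation, achieved = make_tem_annotation(truth)
        assert achieved.achieved_uncovered_fraction == pytest.approx(0.35)
        assert (tem.thicknesses(annotation) <= 10.0).sum() == 7

    def test_thickness_mean_within_sampling_error(self):
        truth = TEMTruth(
            n_intersections=1000, thickness_mean=200.0, thickness_sd=50.0, seed=6
        )
        annotation, _ = make_tem_annotation(truth)
        th = tem.thicknesses(annotation)
        assert abs(th.mean() - 200.0) < 3 * 50.0 / np.sqrt(1000)

    def test_separations_realize_thickness(self):
        truth = TEMTruth(n_intersections=50, seed=7)
        annotation, achieved = make_tem_annotation(truth)
        th = tem.thicknesses(annotation)
        assert np.mean(th <= truth.uncovered_max) == pytest.approx(
            achieved.achieved_uncovered_fraction
        )


class TestMakeDecayTrace:
    def test_zero_permeability_constant_trace(self):
        trace = make_decay_trace(DecayTruth(ps_true=0.0, noise_sd=0.0))
        np.testing.assert_allclose(trace.intensities, 1000.0)

    def test_closed_form_value_at_60s(self):
        """k = 2*0.025/5 = 0.01 /s; I(60) = I_inf + (I0-I_inf)*e^-0.6."""
        truth = DecayTruth(
            ps_true=0.025, radius=5.0, i0=1000.0, i_inf=100.0, noise_sd=0.0
        )
        trace = make_decay_trace(truth)
        idx = np.argmin(np.abs(trace.times - 60.0))
        expected = 100.0 + 900.0 * np.exp(-0.6)
        assert trace.intensities[idx] == pytest.approx(expected, rel=1e-12)

    def test_noisy_trace_deterministic(self):
        truth = DecayTruth(noise_sd=5.0, seed=9)
        t1 = make_decay_trace(truth)
        t2 = make_decay_trace(truth)
        assert np.array_equal(t1.intensities, t2.intensities)

    def test_short_duration_rejected(self):
        with pytest.raises(ValueError):
            DecayTruth(duration=30.0)
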