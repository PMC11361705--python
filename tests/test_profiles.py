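"""Projection, line profiles, half-maximum diameters, quotients, signal stats."""

from __future__ import annotations

import warnings

import numpy as np
import pytest

from stavquant.profiles import (
    GranuleMeasurement,
    Projection,
    count_peaks,
    detect_granules,
    diameter_at_half_max,
    extract_profile,
    max_signal_stats,
    measure_granule,
    pooled_summary,
    project,
    quantify_stack,
    summarise_replicates,
)
from stavquant.scene import OpticsSpec

from conftest import PX, make_sphere_stack, padded_profile
from oracles import student_t_unpaired, two_sided_p_df4


def make_projection(arrays: dict[str, np.ndarray], px: float = PX) -> Projection:
    channels = tuple(arrays)
    data = np.stack([np.asarray(arrays[c], dtype=float) for c in channels])
    return Projection(data=data, channels=channels, pixel_size_xy=px, method="sum")


class TestProject:
    def test_sum_projection_of_constant_slices(self):
        stack, _, _, _ = make_sphere_stack(3, shape=(10, 32, 32))
        stack.data[:] = 1.0
        proj = project(stack, "sum")
        assert np.all(proj.data == 10.0)

    def test_max_projection(self):
        stack, _, _, _ = make_sphere_stack(3, shape=(8, 32, 32))
        proj = project(stack, "max")
        assert np.array_equal(proj.data, stack.data.max(axis=1))

    def test_sum_projection_conserves_total(self):
        stack, _, _, _ = make_sphere_stack(4, shape=(12, 32, 32))
        proj = project(stack, "sum")
        assert proj.data.sum() == pytest.approx(stack.data.sum(), rel=1e-12)

    def test_unknown_method_rejected(self):
        stack, _, _, _ = make_sphere_stack(3, shape=(8, 32, 32))
        with pytest.raises(ValueError, match="method"):
            project(stack, "median")


class TestDetectGranules:
    def test_single_granule_found_within_one_pixel(self):
        optics = OpticsSpec(psf_sigma_xy=100.0, psf_sigma_z=250.0, background=5.0, read_noise_sd=1.0)
        stack, center_px, _, _ = make_sphere_stack(5, optics=optics, shape=(16, 64, 64), noise=True)
        found = detect_granules(project(stack, "sum"), "strep")
        assert len(found) == 1
        dy = found[0]["center_px"][0] - center_px[0]
        dx = found[0]["center_px"][1] - center_px[1]
        assert np.hypot(dy, dx) < 1.0

    def test_blank_image_gives_empty_list(self):
        proj = make_projection({"strep": np.zeros((32, 32))})
        assert detect_granules(proj, "strep") == []

    def test_larger_granule_listed_first(self):
        img = np.zeros((64, 64))
        img[10:16, 10:16] = 50.0  # small, dim
        img[40:52, 40:52] = 100.0  # large, bright
        found = detect_granules(make_projection({"strep": img}), "strep", min_area_px=4)
        assert len(found) == 2
        assert found[0]["center_px"][0] > 30  # the brighter/larger one first


class TestExtractProfile:
    def test_constant_image_gives_constant_profile(self):
        proj = make_projection({"c": np.full((48, 48), 3.25)})
        prof = extract_profile(proj, (23.5, 23.5), 30.0, 20.0, channel="c")
        assert np.allclose(prof.intensities, 3.25)
        assert prof.positions[0] == 0.0
        assert np.all(np.diff(prof.positions) > 0)

    def test_rotational_symmetry_of_isotropic_disk(self):
        optics = OpticsSpec(psf_sigma_xy=100.0, psf_sigma_z=250.0, background=0.0, read_noise_sd=0.0)
        stack, center_px, _, _ = make_sphere_stack(6, optics=optics, shape=(24, 64, 64))
        proj = project(stack, "sum")
        p0 = extract_profile(proj, center_px, 0.0, 30.0, channel="strep")
        p90 = extract_profile(proj, center_px, 90.0, 30.0, channel="strep")
        rms = np.sqrt(np.mean((p0.intensities - p90.intensities) ** 2))
        assert rms < 0.01 * p0.intensities.max()

    def test_profile_matches_dense_projection_oracle(self):
        """Rendered + extracted profile vs analytic 10x-oversampled projection."""
        from oracles import projected_sphere_image

        r_px, sigma_px = 6.0, 1.5
        optics = OpticsSpec(psf_sigma_xy=sigma_px * PX, psf_sigma_z=250.0,
                            background=0.0, read_noise_sd=0.0)
        stack, center_px, _, _ = make_sphere_stack(r_px, optics=optics, shape=(24, 64, 64))
        proj = project(stack, "sum")
        prof = extract_profile(proj, center_px, 0.0, 30.0, channel="strep", width_px=1)

        img, step = projected_sphere_image(r_px, sigma_px, oversample=10)
        mid = img.shape[0] // 2
        x_oracle = (np.arange(img.shape[1]) - mid) * step
        x_prof = prof.positions / PX - (prof.positions[-1] / PX) / 2
        oracle = np.interp(x_prof, x_oracle, img[mid])
        # both normalised to unit peak: rendering scales by amplitude and z-step
        a = prof.intensities / prof.intensities.max()
        b = oracle / oracle.max()
        rms = np.sqrt(np.mean((a - b) ** 2))
        assert rms < 0.02

    def test_segment_leaving_image_rejected(self):
        proj = make_projection({"c": np.zeros((32, 32))})
        with pytest.raises(ValueError, match="exits the image"):
            extract_profile(proj, (16.0, 16.0), 0.0, 100.0, channel="c")


class TestDiameterAtHalfMax:
    def test_triangle_profile_worked_example(self):
        """[0,50,100,50,0] at unit spacing: level 50, crossings 1 and 3."""
        prof, _ = padded_profile([0, 50, 100, 50, 0])
        d, flag = diameter_at_half_max(prof)
        assert flag is None
        assert d == pytest.approx(2.0)

    def test_double_peak_outer_width(self):
        """[0,100,40,100,0]: outermost crossings at 0.5 and 3.5, width 3."""
        prof, _ = padded_profile([0, 100, 40, 100, 0])
        d, flag = diameter_at_half_max(prof)
        assert flag is None
        assert d == pytest.approx(3.0)

    def test_projected_sphere_closed_form(self):
        """Half-max chord of a projected uniform sphere is sqrt(3) * r."""
        r_px = 10.0
        stack, center_px, _, _ = make_sphere_stack(r_px, shape=(48, 96, 96))
        proj = project(stack, "sum")
        prof = extract_profile(proj, center_px, 0.0, 5 * r_px, channel="strep", width_px=1)
        d, _ = diameter_at_half_max(prof)
        assert d / PX == pytest.approx(np.sqrt(3.0) * r_px, rel=0.01)

    def test_profile_still_rising_at_edge_flagged_unbounded(self):
        """A granule clipped by the segment end has no defined diameter."""
        from stavquant.profiles import LineProfile

        clipped = LineProfile(
            positions=np.arange(8.0),
            intensities=np.array([0, 5, 10, 20, 40, 60, 80, 100.0]),
            channel="c",
            start_px=(0, 0),
            end_px=(0, 7),
            width_px=1,
        )
        d, flag = diameter_at_half_max(clipped)
        assert d is None and flag == "unbounded"

    def test_baseline_from_lowest_decile_ignores_offset(self):
        """Adding a flat pedestal must not change the measured width."""
        prof, _ = padded_profile([0, 50, 100, 50, 0])
        lifted, _ = padded_profile([0, 50, 100, 50, 0])
        lifted.intensities = lifted.intensities + 40.0
        d0, _ = diameter_at_half_max(prof)
        d1, _ = diameter_at_half_max(lifted)
        assert d1 == pytest.approx(d0)


class TestCountPeaks:
    def test_single_peak(self):
        prof, _ = padded_profile([0, 50, 100, 50, 0])
        assert count_peaks(prof) == 1

    def test_double_peak_with_prominence(self):
        prof, _ = padded_profile([0, 100, 40, 100, 0])
        assert count_peaks(prof, min_prominence_fraction=0.3) == 2

    def test_shell_profile_double_volume_single(self):
        optics = OpticsSpec(psf_sigma_xy=65.0, psf_sigma_z=200.0, background=0.0, read_noise_sd=0.0)
        for mode, frac, expected in (("shell", 0.2, 2), ("volume", 1.0, 1)):
            stack, center_px, _, _ = make_sphere_stack(
                8, mode=mode, shell_fraction=frac, optics=optics, shape=(32, 64, 64)
            )
            proj = project(stack, "sum")
            prof = extract_profile(proj, center_px, 0.0, 40.0, channel="strep", width_px=1)
            assert count_peaks(prof) == expected

    def test_invalid_prominence_rejected(self):
        prof, _ = padded_profile([0, 50, 100, 50, 0])
        with pytest.raises(ValueError):
            count_peaks(prof, min_prominence_fraction=1.5)


class TestMeasureGranule:
    def _two_channel_projection(self):
        """Shell-labelled HA and volume-labelled strep on identical geometry."""
        optics = OpticsSpec(psf_sigma_xy=80.0, psf_sigma_z=200.0, background=0.0, read_noise_sd=0.0)
        sh, center_px, _, _ = make_sphere_stack(
            7, mode="shell", shell_fraction=0.25, optics=optics, shape=(28, 64, 64), channel="HA"
        )
        vol, _, _, _ = make_sphere_stack(7, optics=optics, shape=(28, 64, 64), channel="strep")
        data = np.concatenate([sh.data, vol.data])
        return Projection(
            data=data.sum(axis=1), channels=("HA", "strep"), pixel_size_xy=PX, method="sum"
        ), center_px

    def test_identical_channels_give_quotient_one(self):
        stack, center_px, _, _ = make_sphere_stack(6, shape=(24, 64, 64), channel="strep")
        proj = project(stack, "sum")
        dup = Projection(
            data=np.concatenate([proj.data, proj.data]),
            channels=("HA", "strep"),
            pixel_size_xy=PX,
            method="sum",
        )
        m = measure_granule(dup, center_px, "HA", "strep", length_px=36.0)
        assert m.quotient == pytest.approx(1.0)

    def test_shell_channel_measures_wider(self):
        proj, center_px = self._two_channel_projection()
        m = measure_granule(proj, center_px, "HA", "strep", length_px=40.0, width_px=1)
        assert m.quotient is not None and m.quotient > 1.0

    def test_swapping_stain_assignment_inverts_quotient_exactly(self):
        proj, center_px = self._two_channel_projection()
        m = measure_granule(proj, center_px, "HA", "strep", length_px=40.0)
        m_swap = measure_granule(proj, center_px, "strep", "HA", length_px=40.0)
        assert m_swap.quotient == pytest.approx(1.0 / m.quotient, rel=1e-12)

    def test_flagged_diameter_propagates_to_undefined_quotient(self):
        proj = make_projection({"HA": np.zeros((48, 48)), "strep": np.full((48, 48), 5.0)})
        proj.data[0, 20:28, 20:28] = 100.0  # HA has a granule; strep is flat (unbounded)
        m = measure_granule(proj, (23.5, 23.5), "HA", "strep", length_px=30.0)
        assert m.quotient is None
        assert any("strep" in f for f in m.flags)

    def test_quantify_stack_detects_and_measures(self):
        optics = OpticsSpec(psf_sigma_xy=80.0, psf_sigma_z=200.0, background=4.0, read_noise_sd=1.0)
        sh, _, _, _ = make_sphere_stack(
            6, mode="shell", shell_fraction=0.25, optics=optics, shape=(24, 64, 64),
            channel="HA", noise=True, seed=4
        )
        vol, _, _, _ = make_sphere_stack(
            6, optics=optics, shape=(24, 64, 64), channel="strep", noise=True, seed=4
        )
        from stavquant.scene import ImageStack

        stack = ImageStack(
            data=np.concatenate([sh.data, vol.data]),
            channels=("HA", "strep"),
            z_step=140.0,
            pixel_size_xy=PX,
        )
        m = quantify_stack(stack)
        assert m is not None
        assert m.quotient is not None and m.quotient > 1.0


class TestReplicateSummaries:
    @staticmethod
    def _measurement(q, rep, peaks=None):
        return GranuleMeasurement(
            granule_id=f"g{q}", replicate=rep, diameters_nm={"HA": q, "strep": 1.0},
            quotient=q, peak_counts=peaks or {"HA": 1, "strep": 1},
        )

    def test_mean_and_sample_sd(self):
        ms = [self._measurement(q, 0) for q in (1.2, 1.4, 1.6)]
        (s,) = summarise_replicates(ms)
        assert s.mean_quotient == pytest.approx(1.4)
        assert s.sd_quotient == pytest.approx(0.2)
        assert s.n_granules == 3

    def test_single_quotient_has_undefined_sd(self):
        (s,) = summarise_replicates([self._measurement(1.3, 0)])
        assert s.sd_quotient is None

    def test_replicate_without_quotients_excluded_with_warning(self):
        bad = GranuleMeasurement(
            granule_id="g", replicate=1, diameters_nm={"HA": None, "strep": 2.0},
            quotient=None, peak_counts={"HA": 1, "strep": 1}, flags=["HA:unbounded"],
        )
        with pytest.warns(UserWarning, match="no defined quotients"):
            summaries = summarise_replicates([self._measurement(1.2, 0), bad])
        assert [s.replicate for s in summaries] == [0]

    def test_double_peak_fraction(self):
        ms = [
            self._measurement(1.2, 0, {"HA": 2, "strep": 1}),
            self._measurement(1.3, 0, {"HA": 1, "strep": 1}),
        ]
        (s,) = summarise_replicates(ms)
        assert s.double_peak_fraction["HA"] == pytest.approx(0.5)
        assert s.double_peak_fraction["strep"] == 0.0

    def test_pooled_summary(self):
        ms = [self._measurement(q, r) for r, q in ((0, 1.2), (0, 1.4), (1, 1.6))]
        mean, sd, n = pooled_summary(ms)
        assert mean == pytest.approx(1.4)
        assert n == 3


class TestMaxSignalStats:
    @staticmethod
    def _projections(values):
        return [
            Projection(data=np.full((1, 8, 8), v), channels=("signal",),
                       pixel_size_xy=PX, method="sum")
            for v in values
        ]

    def test_doubled_group_gives_fold_change_two(self):
        a = self._projections([20.0, 24.0, 22.0])
        b = self._projections([10.0, 12.0, 11.0])
        s = max_signal_stats(a, b)
        assert s.fold_change == pytest.approx(2.0)

    def test_identical_groups_fold_one_p_one(self):
        a = self._projections([10.0, 12.0, 11.0])
        s = max_signal_stats(a, a)
        assert s.fold_change == pytest.approx(1.0)
        assert s.p_value == pytest.approx(1.0)

    def test_t_statistic_matches_closed_form_oracle(self):
        """Student t and two-sided p for [10,12,11] vs [5,6,7], df=4."""
        a = self._projections([10.0, 12.0, 11.0])
        b = self._projections([5.0, 6.0, 7.0])
        s = max_signal_stats(a, b)
        t_oracle, df = student_t_unpaired([10, 12, 11], [5, 6, 7])
        assert df == 4
        assert s.t_statistic == pytest.approx(t_oracle, abs=1e-12)
        assert s.p_value == pytest.approx(two_sided_p_df4(t_oracle), abs=1e-12)

    def test_empty_mask_excluded_with_warning(self):
        a = self._projections([10.0, 12.0, 11.0])
        b = self._projections([5.0, 6.0, 7.0])
        masks_a = [np.ones((8, 8), bool), np.ones((8, 8), bool), np.zeros((8, 8), bool)]
        with pytest.warns(UserWarning, match="empty mask"):
            s = max_signal_stats(a, b, masks_a=masks_a)
        assert s.n_a == 2 and s.n_b == 3

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            max_signal_stats(self._projections([1.0]), self._projections([1.0, 2.0]))
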