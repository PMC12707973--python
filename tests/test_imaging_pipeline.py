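"""Stack correction, per-pixel SO2 mapping, dynamics, and annuli."""

import numpy as np
import pytest

from tdhsi.imaging_pipeline import (CalibrationError, OxygenTimeSeries,
                                    SO2Map, SpectralStack, annulus_profile,
                                    background_spectrum, corrected_ratio,
                                    delta_so2, hypoxia_metrics, map_so2,
                                    read_stack, write_stack)
from tdhsi.spectra import BloodSpec, WavelengthGrid
from tdhsi.synthetic import PhantomSpec, generate_stack


def _uniform_stack(grid, value=100.0, shape=(8, 8)):
    nb = len(grid)
    data = np.full(shape + (nb,), value)
    return SpectralStack(data, grid.centers, np.full(nb, 200.0),
                         np.full(nb, 5.0), pixel_size=0.05)


@pytest.fixture(scope="module")
def phantom(grid):
    spec = PhantomSpec(blood=BloodSpec(so2=0.98), noise_sigma=0.01)
    stack, truth = generate_stack(spec, (48, 48), grid, seed=7,
                                  mode="transmissive")
    bg_roi = ~truth["vessel_mask"].copy()
    bg_roi[:, 12:36] = False  # stay clear of the vessel
    return stack, truth, bg_roi


class TestCorrectedRatio:
    def test_stack_equal_to_background_gives_unit_ratio(self, grid):
        stack = _uniform_stack(grid)
        bg = np.full(len(grid), 100.0)
        ratio = corrected_ratio(stack, bg)
        np.testing.assert_allclose(ratio, 1.0, rtol=1e-12)

    def test_perfect_reference_no_noise(self, grid):
        nb = len(grid)
        data = np.full((4, 4, nb), 200.0)
        stack = SpectralStack(data, grid.centers, np.full(nb, 200.0),
                              np.zeros(nb), 0.05)
        num = (stack.data - 0.0) / (200.0 - 0.0)
        np.testing.assert_allclose(num, 1.0)

    def test_reference_below_dark_names_band(self, grid):
        nb = len(grid)
        ref = np.full(nb, 200.0)
        ref[3] = 1.0  # below the dark level at 530 nm
        stack = SpectralStack(np.full((4, 4, nb), 50.0), grid.centers, ref,
                              np.full(nb, 5.0), 0.05)
        with pytest.raises(CalibrationError, match="530"):
            corrected_ratio(stack, np.full(nb, 50.0))

    def test_vessel_dips_at_high_contrast_band(self, grid, phantom):
        stack, truth, bg_roi = phantom
        ratio = corrected_ratio(stack, background_spectrum(stack, bg_roi))
        i550 = int(np.where(grid.centers == 550.0)[0][0])
        centre = ratio[2, stack.shape[1] // 2, i550]
        assert centre < 0.1  # strong hemoglobin absorption at 550 nm


class TestMapSO2:
    def test_uniform_stack_fully_rejected(self, grid):
        stack = _uniform_stack(grid)
        bg_roi = np.zeros((8, 8), dtype=bool)
        bg_roi[:2] = True
        result = map_so2(stack, background_roi=bg_roi)
        assert not result.accepted_mask.any()
        assert (result.reject_reason[~result.accepted_mask] != "").all()

    def test_phantom_recovery_on_shallow_vessel(self, grid, phantom):
        stack, truth, bg_roi = phantom
        result = map_so2(stack, background_roi=bg_roi)
        shallow = truth["vessel_mask"] & (truth["depth_mm"] <= 1.0)
        acc = result.accepted_mask & shallow
        assert acc.sum() > 0.5 * shallow.sum()
        err = np.median(np.abs(result.so2[acc] - truth["so2"]))
        assert err < 0.02

    def test_transposition_equivariance(self, grid, phantom):
        stack, truth, bg_roi = phantom
        small = SpectralStack(stack.data[:10], stack.wavelengths,
                              stack.reference, stack.dark, stack.pixel_size,
                              stack.mode)
        swapped = SpectralStack(np.swapaxes(small.data, 0, 1),
                                stack.wavelengths, stack.reference,
                                stack.dark, stack.pixel_size, stack.mode)
        bg = background_spectrum(stack, bg_roi)
        a = map_so2(small, background=bg)
        b = map_so2(swapped, background=bg)
        np.testing.assert_array_equal(a.so2, b.so2.T)
        np.testing.assert_array_equal(a.accepted_mask, b.accepted_mask.T)

    def test_fine_vessel_resolved_in_count_profile(self, grid):
        # 48 um capillary: accepted-pixel count across the vessel must
        # show >3:1 contrast over the avascular background
        spec = PhantomSpec(vessel_diameter_mm=0.048,
                           depth_range_mm=(0.02, 0.15),
                           blood=BloodSpec(so2=0.98), noise_sigma=0.005)
        stack, truth = generate_stack(spec, (32, 48), grid, seed=3,
                                      mode="transmissive")
        bg_roi = ~truth["vessel_mask"].copy()
        bg_roi[:, 12:36] = False
        result = map_so2(stack, background_roi=bg_roi)
        profile = result.accepted_mask.sum(axis=0)
        on_vessel = profile[truth["vessel_mask"].any(axis=0)].max()
        off_vessel = profile[~truth["vessel_mask"].any(axis=0)].max()
        assert on_vessel > 3 * max(off_vessel, 1)


class TestDynamics:
    def _series(self, values, times=None, baseline=(0.0, 4.0)):
        values = np.asarray(values, dtype=float)
        if times is None:
            times = np.arange(values.size, dtype=float)
        return OxygenTimeSeries(times, values, baseline)

    def test_flat_series_zero_change(self):
        s = self._series(np.full(10, 0.8))
        np.testing.assert_allclose(delta_so2(s), 0.0)
        assert hypoxia_metrics(s, 5.0) == (0.0, 0.0)

    def test_halved_signal_gives_minus_half(self):
        vals = np.full(10, 0.8)
        vals[6:] = 0.4
        d = delta_so2(self._series(vals))
        np.testing.assert_allclose(d[6:], -0.5)

    def test_scale_invariance(self):
        vals = 0.8 + 0.1 * np.sin(np.arange(12))
        d1 = delta_so2(self._series(vals))
        d2 = delta_so2(self._series(3.7 * vals))
        np.testing.assert_allclose(d1, d2, rtol=1e-12)

    def test_trapezoid_dip_recovers_exactly(self):
        # baseline 0.8 for t in [0,4]; dip to 0.48 (-40%); linear return
        # crossing baseline exactly at t = 9.0 => recovery 4.0 min after
        # onset at t = 5.0
        t = np.arange(0.0, 13.0)
        v = np.full(t.size, 0.8)
        v[6] = 0.48
        v[7] = 0.48
        v[8] = 0.64
        # linear from (8, 0.64) through (9, 0.8): crosses baseline at 9.0
        peak, rec = hypoxia_metrics(
            OxygenTimeSeries(t, v, (0.0, 4.0)), 5.0)
        assert peak == pytest.approx(0.4, abs=1e-12)
        assert rec == pytest.approx(4.0, abs=1e-9)

    def test_never_recovering_series_signalled(self):
        t = np.arange(0.0, 8.0)
        v = np.full(t.size, 0.8)
        v[5:] = 0.5
        peak, rec = hypoxia_metrics(OxygenTimeSeries(t, v, (0.0, 3.0)), 4.0)
        assert peak == pytest.approx(0.375)
        assert rec is None

    def test_zero_baseline_signalled(self):
        s = OxygenTimeSeries(np.arange(5.0), np.zeros(5), (0.0, 2.0))
        with pytest.raises(ValueError):
            delta_so2(s)


def _accepted_map(so2):
    so2 = np.asarray(so2, dtype=float)
    return SO2Map(so2, np.isfinite(so2), np.full_like(so2, 1.0),
                  np.full(so2.shape, "", dtype=object))


class TestAnnulusProfile:
    def test_uniform_map_all_rings_equal(self):
        m = _accepted_map(np.full((201, 201), 0.8))
        prof = annulus_profile(m, (100.0, 100.0), pixel_size=0.05)
        assert prof.mean_so2.size == 9
        np.testing.assert_allclose(prof.mean_so2, 0.8)
        np.testing.assert_allclose(np.diff(prof.ring_edges), 0.5)

    def test_linear_radial_gradient_matches_area_weighted_integral(self):
        # so2(r) = 0.5 + 0.05 r (mm): exact ring mean is
        # 0.5 + 0.05 * (2/3) (r1^3 - r0^3) / (r1^2 - r0^2)
        n, px = 401, 0.025
        c = (n - 1) / 2.0
        rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        r_mm = np.hypot(rr - c, cc - c) * px
        m = _accepted_map(0.5 + 0.05 * r_mm)
        prof = annulus_profile(m, (c, c), pixel_size=px)
        edges = prof.ring_edges
        for i in range(9):
            r0, r1 = edges[i], edges[i + 1]
            exact = 0.5 + 0.05 * (2.0 / 3.0) * (r1**3 - r0**3) / (r1**2 - r0**2)
            assert prof.mean_so2[i] == pytest.approx(exact, abs=0.005)
        assert prof.tumor_rings.tolist() == [0, 1, 2, 3, 4, 5]
        assert prof.adjacent_rings.tolist() == [6, 7, 8]

    def test_rotation_invariance_of_ring_means(self):
        n, px = 201, 0.05
        c = (n - 1) / 2.0
        rr, cc = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
        r_mm = np.hypot(rr - c, cc - c) * px
        base = 0.5 + 0.05 * r_mm
        p1 = annulus_profile(_accepted_map(base), (c, c), px)
        p2 = annulus_profile(_accepted_map(np.rot90(base)), (c, c), px)
        np.testing.assert_allclose(p1.mean_so2, p2.mean_so2, atol=0.01)

    def test_empty_ring_flagged(self):
        so2 = np.full((201, 201), np.nan)
        so2[100, 100] = 0.7  # only the innermost ring has a pixel
        prof = annulus_profile(_accepted_map(so2), (100.0, 100.0), 0.05)
        assert np.isfinite(prof.mean_so2[0])
        assert np.isnan(prof.mean_so2[1:]).all()
        assert prof.pixel_counts[1:].sum() == 0

    def test_center_too_close_to_edge(self):
        m = _accepted_map(np.full((40, 40), 0.5))
        with pytest.raises(ValueError):
            annulus_profile(m, (5.0, 20.0), pixel_size=0.1)


class TestStackIO:
    def test_tiff_sidecar_round_trip(self, grid, tmp_path, rng):
        nb = len(grid)
        data = rng.uniform(10, 100, (6, 5, nb))
        stack = SpectralStack(data, grid.centers, np.full(nb, 120.0),
                              np.full(nb, 2.0), 0.02, "reflective")
        write_stack(stack, tmp_path / "s")
        back = read_stack(tmp_path / "s")
        np.testing.assert_allclose(back.data, data, rtol=1e-6)
        np.testing.assert_allclose(back.wavelengths, grid.centers)
        assert back.mode == "reflective"
        assert back.pixel_size == pytest.approx(0.02)

    def test_stack_validation(self, grid):
        nb = len(grid)
        with pytest.raises(ValueError):
            SpectralStack(np.ones((4, 4, nb)), grid.centers,
                          np.ones(nb - 1), np.zeros(nb), 0.05)
        with pytest.raises(ValueError):
            SpectralStack(-np.ones((4, 4, nb)), grid.centers, np.ones(nb),
                          np.zeros(nb), 0.05)
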