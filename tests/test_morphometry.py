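"""Morphometry engine against closed-form Gaussian-pit oracles."""

import numpy as np
import pytest

from foveage import AScanProfile, synth_ilm_profile
from foveage.morphometry import (EdgeOutsideScanError, NoPitError,
                                 central_foveal_thickness, detect_foveal_bulge,
                                 detect_pit_edges, detect_pit_floor,
                                 measure_profile, mean_pit_slope, pit_depth,
                                 pit_diameter, profile_derivative,
                                 smooth_profile, threshold_sensitivity)
from foveage.profiles import ProfileError
from foveage.synthetic import synth_ez_profile

from conftest import (oracle_cft, oracle_depth, oracle_diameter,
                      oracle_edges, oracle_max_slope, oracle_mean_slope)


def vprofile(slope=0.14, extent=1000.0, step=5.0, floor_t=200.0):
    x = np.arange(-extent, extent + step / 2, step)
    return AScanProfile(x, floor_t + slope * np.abs(x))


class TestSmoothing:
    def test_polynomial_reproduction(self):
        x = np.arange(-500, 501, 5.0)
        prof = AScanProfile(x, 200 + 0.01 * x)
        out = smooth_profile(prof, window=55, polyorder=2)
        assert np.max(np.abs(out.t - prof.t)) < 1e-9

    def test_noise_reduction(self, gaussian_pit):
        truth = gaussian_pit(noise=0).t
        rms_raw, rms_smooth = [], []
        for s in range(30):
            noisy = gaussian_pit(noise=2.0, seed=s)
            rms_raw.append(np.sqrt(np.mean((noisy.t - truth) ** 2)))
            rms_smooth.append(np.sqrt(np.mean(
                (smooth_profile(noisy).t - truth) ** 2)))
        assert np.mean(rms_smooth) < np.mean(rms_raw)

    def test_window_preconditions(self):
        x = np.arange(0, 255, 5.0)   # 51 points
        prof = AScanProfile(x, np.full(51, 250.0))
        smooth_profile(prof, window=25, polyorder=2)    # 5 samples: fine
        with pytest.raises(ValueError):
            smooth_profile(prof, window=300, polyorder=2)  # > profile length
        with pytest.raises(ValueError):
            smooth_profile(prof, window=5, polyorder=2)    # < polyorder + 2


class TestDerivative:
    def test_linear_exact(self):
        x = np.arange(0, 1001, 5.0)
        d = profile_derivative(AScanProfile(x, 100 + 0.25 * x))
        assert np.allclose(d, 0.25, atol=1e-12)

    def test_constant_zero(self):
        x = np.arange(-500, 501, 5.0)
        d = profile_derivative(AScanProfile(x, np.full(x.size, 250.0)))
        assert np.allclose(d, 0.0, atol=1e-12)

    def test_gaussian_max_matches_oracle(self, noiseless_pit):
        d = profile_derivative(noiseless_pit)
        assert np.max(np.abs(d)) == pytest.approx(
            oracle_max_slope(120, 330), rel=1e-3)
        assert abs(noiseless_pit.x[np.argmax(np.abs(d))]) == pytest.approx(
            330, abs=5)


class TestFloor:
    def test_gaussian_floor(self, noiseless_pit):
        fx, ft = detect_pit_floor(noiseless_pit)
        assert fx == 0.0
        assert ft == pytest.approx(160.0, abs=1e-9)

    def test_translation_equivariance(self):
        x = np.arange(-2500, 2501, 5.0)
        t = 280 - 120 * np.exp(-(x - 40.0) ** 2 / (2 * 330**2))
        fx, _ = detect_pit_floor(AScanProfile(x, t))
        assert fx == 40.0

    def test_monotone_profile_rejected(self):
        x = np.arange(0, 1001, 5.0)
        with pytest.raises(NoPitError):
            detect_pit_floor(AScanProfile(x, 200 + 0.05 * x))


class TestEdges:
    @pytest.mark.parametrize("fraction", [0.4, 0.5, 0.6])
    def test_oracle_agreement(self, noiseless_pit, fraction):
        el, er = detect_pit_edges(noiseless_pit, fraction)
        expected = oracle_edges(330, fraction)
        assert er == pytest.approx(expected, rel=0.005)
        assert el == pytest.approx(-expected, rel=0.005)

    def test_symmetry(self, noiseless_pit):
        el, er = detect_pit_edges(noiseless_pit, 0.5)
        assert abs(el) == pytest.approx(er, abs=1e-6)

    def test_fraction_ordering(self, noiseless_pit):
        edges = {f: detect_pit_edges(noiseless_pit, f)[1]
                 for f in (0.4, 0.5, 0.6)}
        assert edges[0.4] > edges[0.5] > edges[0.6]

    def test_edge_outside_scan(self):
        # pit width comparable to the scan: derivative never decays enough
        rng = np.random.default_rng(0)
        prof = synth_ilm_profile(280, 120, 2000, 0, 2500, 5, rng)
        with pytest.raises(EdgeOutsideScanError):
            detect_pit_edges(prof, 0.01)


class TestDepthDiameterSlope:
    def test_depth_oracle(self, noiseless_pit):
        floor = detect_pit_floor(noiseless_pit)
        edges = detect_pit_edges(noiseless_pit, 0.5)
        d = pit_depth(noiseless_pit, edges, floor)
        assert d == pytest.approx(oracle_depth(120, 0.5), rel=0.005)

    def test_depth_trapezoid_exact(self):
        # flat-bottomed pit: plateau 160 µm (|x| <= 100), edges at 260 µm
        x = np.arange(-1000, 1001, 5.0)
        t = np.where(np.abs(x) <= 100, 160.0,
                     np.where(np.abs(x) >= 260, 260.0,
                              160.0 + (np.abs(x) - 100) * 100.0 / 160.0))
        prof = AScanProfile(x, t)
        d = pit_depth(prof, (-260.0, 260.0), (0.0, 160.0))
        assert d == pytest.approx(100.0, abs=1e-9)

    def test_depth_vertical_offset_invariant(self, noiseless_pit):
        floor = detect_pit_floor(noiseless_pit)
        edges = detect_pit_edges(noiseless_pit, 0.5)
        d0 = pit_depth(noiseless_pit, edges, floor)
        shifted = noiseless_pit.with_values(noiseless_pit.t + 50.0)
        d1 = pit_depth(shifted, edges, (floor[0], floor[1] + 50.0))
        assert d1 == pytest.approx(d0, abs=1e-9)

    def test_diameter_oracle_and_scaling(self, gaussian_pit):
        for sigma in (250.0, 330.0, 450.0):
            prof = gaussian_pit(sigma=sigma)
            edges = detect_pit_edges(prof, 0.5)
            assert pit_diameter(edges) == pytest.approx(
                oracle_diameter(sigma, 0.5), rel=0.005)

    def test_slope_oracle(self, noiseless_pit):
        floor = detect_pit_floor(noiseless_pit)
        edges = detect_pit_edges(noiseless_pit, 0.5)
        s = mean_pit_slope(noiseless_pit, edges, floor)
        assert s == pytest.approx(oracle_mean_slope(120, 330, 0.5), rel=0.02)

    def test_slope_constant_wall(self):
        prof = vprofile(slope=0.14)
        s = mean_pit_slope(prof, (-600.0, 600.0), (0.0, 200.0))
        assert s == pytest.approx(np.degrees(np.arctan(0.14)), abs=0.15)

    def test_slope_mirror_symmetric(self, noiseless_pit):
        floor = detect_pit_floor(noiseless_pit)
        edges = detect_pit_edges(noiseless_pit, 0.5)
        mirrored = AScanProfile(noiseless_pit.x, noiseless_pit.t[::-1])
        s0 = mean_pit_slope(noiseless_pit, edges, floor)
        s1 = mean_pit_slope(mirrored, (-edges[1], -edges[0]),
                            (-floor[0], floor[1]))
        assert s1 == pytest.approx(s0, abs=1e-9)

    def test_slope_chord_method(self, noiseless_pit):
        floor = detect_pit_floor(noiseless_pit)
        edges = detect_pit_edges(noiseless_pit, 0.5)
        chord = mean_pit_slope(noiseless_pit, edges, floor, method="chord")
        expected = np.degrees(np.arctan(oracle_depth(120, 0.5)
                                        / oracle_edges(330, 0.5)))
        assert chord == pytest.approx(expected, rel=0.01)


class TestCFT:
    def test_constant_profile(self):
        x = np.arange(-600, 601, 5.0)
        assert central_foveal_thickness(
            AScanProfile(x, np.full(x.size, 250.0)), 0.0) == 250.0

    def test_gaussian_oracle(self, noiseless_pit):
        assert central_foveal_thickness(noiseless_pit, 0.0) == pytest.approx(
            oracle_cft(280, 120, 330), rel=0.005)

    def test_incomplete_coverage(self):
        x = np.arange(-400, 401, 5.0)
        with pytest.raises(ValueError):
            central_foveal_thickness(AScanProfile(x, np.full(x.size, 250.0)),
                                     0.0)


class TestFullMeasureInvariances:
    def test_lateral_translation(self, noiseless_pit):
        g0 = measure_profile(noiseless_pit)
        x = noiseless_pit.x
        t = 280 - 120 * np.exp(-(x - 40.0) ** 2 / (2 * 330**2))
        g1 = measure_profile(AScanProfile(x, t))
        assert g1.floor_x == pytest.approx(40.0, abs=2.5)
        assert g1.pit_depth == pytest.approx(g0.pit_depth, rel=1e-3)
        assert g1.pit_diameter == pytest.approx(g0.pit_diameter, rel=1e-3)
        assert g1.mean_slope == pytest.approx(g0.mean_slope, rel=1e-3)
        assert g1.cft == pytest.approx(g0.cft, rel=1e-3)

    def test_vertical_offset(self, noiseless_pit):
        g0 = measure_profile(noiseless_pit)
        g1 = measure_profile(noiseless_pit.with_values(noiseless_pit.t + 50))
        assert g1.pit_depth == pytest.approx(g0.pit_depth, abs=1e-6)
        assert g1.pit_diameter == pytest.approx(g0.pit_diameter, abs=1e-6)
        assert g1.mean_slope == pytest.approx(g0.mean_slope, abs=1e-6)
        assert g1.cft == pytest.approx(g0.cft + 50, abs=1e-6)

    def test_oracle_grid(self, gaussian_pit):
        """Closed-form agreement over a grid of pit shapes (< 0.5%)."""
        for amp in (60.0, 110.0, 160.0):
            for sigma in (250.0, 330.0, 450.0):
                g = measure_profile(gaussian_pit(amp=amp, sigma=sigma))
                assert g.pit_depth == pytest.approx(
                    oracle_depth(amp, 0.5), rel=0.005)
                assert g.pit_diameter == pytest.approx(
                    oracle_diameter(sigma, 0.5), rel=0.005)

    def test_noise_robustness(self, gaussian_pit):
        """Parameter bias vs noiseless truth < 2% at noise SD 2 µm."""
        truth = measure_profile(gaussian_pit(noise=0))
        acc = {k: [] for k in ("cft", "pit_depth", "pit_diameter",
                               "mean_slope")}
        for s in range(150):
            g = measure_profile(gaussian_pit(noise=2.0, seed=s))
            for k in acc:
                acc[k].append(getattr(g, k))
        for k, vals in acc.items():
            bias = abs(np.mean(vals) - getattr(truth, k)) / getattr(truth, k)
            assert bias < 0.02, f"{k} bias {bias:.3%}"


class TestBulgeDetector:
    def test_present_noiseless(self):
        grid = np.arange(-1000, 1001, 5.0)
        ez = synth_ez_profile(True, 10.0, 100.0, 0.0, grid,
                              np.random.default_rng(0))
        assert detect_foveal_bulge(ez) is True

    def test_flat_noiseless(self):
        grid = np.arange(-1000, 1001, 5.0)
        ez = synth_ez_profile(False, 10.0, 100.0, 0.0, grid,
                              np.random.default_rng(0))
        assert detect_foveal_bulge(ez) is False

    def test_monte_carlo_detection(self):
        """Bulge height 10 µm at noise SD 1 µm: detected in >= 99/100."""
        grid = np.arange(-1000, 1001, 5.0)
        hits = sum(detect_foveal_bulge(synth_ez_profile(
            True, 10.0, 100.0, 1.0, grid, np.random.default_rng(s)))
            for s in range(100))
        assert hits >= 99

    def test_coverage_error(self):
        grid = np.arange(-500, 501, 5.0)
        ez = synth_ez_profile(True, 10.0, 100.0, 0.0, grid,
                              np.random.default_rng(0))
        with pytest.raises(ValueError):
            detect_foveal_bulge(ez)


class TestThresholdSensitivity:
    def test_ordering_and_magnitude(self, noiseless_pit):
        rep = threshold_sensitivity(noiseless_pit)
        assert rep.complete
        g = rep.geometries
        assert g[0.4].pit_diameter > g[0.5].pit_diameter > g[0.6].pit_diameter
        assert g[0.4].pit_depth > g[0.5].pit_depth > g[0.6].pit_depth
        # depth difference between extreme thresholds stays moderate
        assert rep.relative_differences[(0.4, 0.6)]["pit_depth"] < 10.0

    def test_identical_fractions_zero_difference(self, noiseless_pit):
        rep = threshold_sensitivity(noiseless_pit, fractions=(0.5, 0.5))
        for diffs in rep.relative_differences.values():
            assert all(v == 0.0 for v in diffs.values())

    def test_partial_failure_flagged(self, gaussian_pit):
        # scan truncated at 1200 µm: the 0.2% threshold crossing lies
        # beyond the grid while the 50% crossing is comfortably inside
        truncated = gaussian_pit(extent=1200.0)
        rep = threshold_sensitivity(truncated, fractions=(0.002, 0.5))
        assert 0.002 in rep.failures and 0.5 in rep.geometries
        assert not rep.complete


class TestProfileContainer:
    def test_invariants(self):
        with pytest.raises(ProfileError):
            AScanProfile(np.arange(10.0), np.ones(10))          # too short
        x = np.arange(-500, 501, 5.0)
        with pytest.raises(ProfileError):
            AScanProfile(x, np.zeros(x.size))                   # non-positive
        bad = x.copy()
        bad[10] += 1.0
        with pytest.raises(ProfileError):
            AScanProfile(bad, np.ones(x.size))                  # non-uniform
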