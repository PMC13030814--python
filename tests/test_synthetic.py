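"""Synthetic cohort generator: determinism, structure, calibration."""

import numpy as np
import pytest

from foveage import (CohortConfig, cohort_to_frame, generate_cohort,
                     phenoage, sample_biomarkers, synth_ez_profile,
                     synth_ilm_profile)
from foveage.synthetic import ConfigurationError, calibrate_bulge_intercept


def small_cfg(**kw):
    kw.setdefault("n_participants", 40)
    kw.setdefault("seed", 1)
    return CohortConfig(**kw)


class TestConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortConfig(n_participants=1)
        with pytest.raises(ConfigurationError):
            CohortConfig(age_min=50, age_max=40)
        with pytest.raises(ConfigurationError):
            CohortConfig(bulge_or_per_year=0.0)
        with pytest.raises(ConfigurationError):
            CohortConfig(profile_extent=100.0)   # < 3 pit widths


class TestIlmProfile:
    def test_closed_form_values(self):
        rng = np.random.default_rng(0)
        prof = synth_ilm_profile(280, 120, 330, 0, 2500, 5, rng)
        assert prof.t[prof.x == 0][0] == pytest.approx(160.0)
        assert prof.t[0] == pytest.approx(280.0, abs=0.01)   # far tail
        at_sigma = prof.t[prof.x == 330][0]
        assert at_sigma == pytest.approx(280 - 120 * np.exp(-0.5), abs=1e-9)

    def test_rim_must_exceed_amplitude(self):
        with pytest.raises(ValueError):
            synth_ilm_profile(100, 120, 330, 0, 2500, 5,
                              np.random.default_rng(0))

    def test_noise_level(self):
        draws = np.array([synth_ilm_profile(
            280, 120, 330, 2.0, 500, 5, np.random.default_rng(s)).t
            for s in range(400)])
        per_point_sd = draws.std(axis=0)
        assert np.mean(per_point_sd) == pytest.approx(2.0, rel=0.05)


class TestEzProfile:
    def test_elevation_height(self):
        grid = np.arange(-1000, 1001, 5.0)
        ez = synth_ez_profile(True, 10.0, 100.0, 0.0, grid,
                              np.random.default_rng(0))
        peak = ez.t[grid == 0][0]
        annulus = ez.t[(np.abs(grid) >= 400) & (np.abs(grid) <= 600)].mean()
        assert peak - annulus == pytest.approx(10.0, abs=0.01)
        # averaged over the central ±50 µm the elevation is slightly lower
        center = ez.t[np.abs(grid) <= 50].mean()
        assert center - annulus == pytest.approx(10.0, abs=0.5)

    def test_flat_when_absent(self):
        grid = np.arange(-1000, 1001, 5.0)
        ez = synth_ez_profile(False, 10.0, 100.0, 0.0, grid,
                              np.random.default_rng(0))
        assert np.all(ez.t == 0.0)

    def test_negative_height_rejected(self):
        with pytest.raises(ValueError):
            synth_ez_profile(True, -1.0, 100.0, 0.0,
                             np.arange(-700, 701, 5.0),
                             np.random.default_rng(0))


class TestCohortStructure:
    def test_counts_and_pairing(self):
        cfg = CohortConfig(seed=1)
        parts, eyes = generate_cohort(cfg, include_profiles=False,
                                      include_biomarkers=False)
        assert len(parts) == 154 and len(eyes) == 308
        df = cohort_to_frame(parts, eyes)
        per = df.groupby("participant_id")["laterality"].apply(
            lambda s: sorted(s))
        assert all(v == ["left", "right"] for v in per)

    def test_seeded_determinism(self):
        cfg = small_cfg()
        d1 = cohort_to_frame(*generate_cohort(cfg))
        d2 = cohort_to_frame(*generate_cohort(cfg))
        assert d1.equals(d2)

    def test_ages_within_range(self):
        cfg = small_cfg(age_min=30, age_max=40)
        parts, _ = generate_cohort(cfg, include_profiles=False,
                                   include_biomarkers=False)
        ages = np.array([p.chron_age for p in parts])
        assert ages.min() >= 30 and ages.max() <= 40

    def test_inter_eye_correlation(self):
        d = cohort_to_frame(*generate_cohort(
            CohortConfig(seed=3, n_participants=500),
            include_profiles=False, include_biomarkers=False))
        for col in ("true_amp_um", "true_sigma_um", "true_rim_um"):
            w = d.pivot(index="participant_id", columns="laterality",
                        values=col)
            r = np.corrcoef(w["right"], w["left"])[0, 1]
            assert r > 0.8, f"{col}: inter-eye r = {r:.3f}"


class TestBulgeGeneration:
    def test_null_or_gives_no_age_association(self):
        cfg = CohortConfig(seed=2, n_participants=2000,
                           bulge_or_per_year=1.0)
        d = cohort_to_frame(*generate_cohort(cfg, include_profiles=False,
                                             include_biomarkers=False))
        r = np.corrcoef(d["chron_age"], d["bulge_truth"].astype(float))[0, 1]
        assert abs(r) < 0.05

    def test_marginal_prevalence_calibration(self):
        cfg = CohortConfig(seed=4, n_participants=3000)
        d = cohort_to_frame(*generate_cohort(cfg, include_profiles=False,
                                             include_biomarkers=False))
        assert d["bulge_truth"].mean() == pytest.approx(0.685, abs=0.02)

    def test_intercept_calibration_solver(self):
        ages = np.linspace(22, 89, 200)
        alpha = calibrate_bulge_intercept(np.log(0.949), ages, 1.0, 0.685)
        # recompute the implied marginal prevalence by brute-force MC
        rng = np.random.default_rng(0)
        a = rng.choice(ages, 200_000)
        u = rng.normal(0, 1.0, a.size)
        p = 1 / (1 + np.exp(-(alpha + np.log(0.949) * a + u)))
        assert p.mean() == pytest.approx(0.685, abs=0.005)

    def test_geometry_age_independent(self):
        """Regression of generated pit amplitude on age: slope CI covers 0
        in the bulk of seeds (geometry is age-independent by design)."""
        from scipy import stats
        cover = 0
        for s in range(40):
            parts, _ = generate_cohort(
                CohortConfig(seed=100 + s, n_participants=400),
                include_profiles=False, include_biomarkers=False)
            ages = np.array([p.chron_age for p in parts])
            amp = np.array([p.true_pit_params[1] for p in parts])
            res = stats.linregress(ages, amp)
            cover += abs(res.slope) < 1.96 * res.stderr
        assert cover >= 34   # ~95% coverage, 40 seeds


class TestBiomarkers:
    def test_phenoage_correlation_and_accel(self):
        rng = np.random.default_rng(1)
        ages = rng.uniform(22, 89, 2000)
        pheno = np.array([phenoage(sample_biomarkers(a, rng=rng), a).phenoage
                          for a in ages])
        r = np.corrcoef(ages, pheno)[0, 1]
        accel = pheno - ages
        assert r == pytest.approx(0.92, abs=0.02)
        assert accel.mean() == pytest.approx(-3.6, abs=0.6)
        assert accel.std() == pytest.approx(7.8, rel=0.1)

    def test_degenerate_accel(self):
        rng = np.random.default_rng(2)
        panel = sample_biomarkers(60.0, 0.0, 0.0, rng)
        assert phenoage(panel, 60.0).phenoage == pytest.approx(60.0,
                                                               abs=1e-6)

    def test_panels_physiological(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            p = sample_biomarkers(rng.uniform(22, 89), rng=rng)
            assert 2.5 <= p.glucose <= 25.0
            assert 30.0 <= p.albumin <= 55.0
            assert 0 < p.lymphocyte_pct <= 100
            assert p.crp > 0
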