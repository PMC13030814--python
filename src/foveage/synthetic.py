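"""Seeded synthetic cohorts with the statistical structure of a healthy
adult OCT-plus-blood-panel study.

The generator emulates a cross-sectional cohort of paired eyes:

* ages uniform over the study range (default 22–89 y);
* foveal pit geometry independent of age by construction, with substantial
  between-participant variance and strong within-participant (inter-eye)
  correlation, realized as shared per-participant true parameters plus a
  small per-eye jitter;
* ILM thickness profiles following a single-Gaussian pit deficit
  T(x) = rim - amp * exp(-x^2 / (2 sigma^2)) + noise, which has closed-form
  derivatives and hence exact morphometry oracles;
* foveal bulge presence from a random-intercept logistic model
  logit(p) = alpha + ln(OR_per_year) * age + u_i, with alpha calibrated
  numerically so the marginal cohort prevalence hits a target (default
  0.685); the driving "age" may be chronological age or PhenoAge;
* biomarker panels constructed by drawing a target
  PhenoAge = age + Normal(accel_mean, accel_sd) and solving the PhenoAge
  linear predictor for glucose, with the other biomarkers from
  age-indexed reference distributions and a small configurable fraction
  of acute-phase CRP values (> 10 mg/L) to exercise the exclusion filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .profiles import AScanProfile
from .phenoage import (BiomarkerPanel, PhenoAgeCoefficients, _coeffs,
                       linear_predictor, phenoage, xb_for_phenoage)

__all__ = ["CohortConfig", "Participant", "EyeRecord", "generate_cohort",
           "synth_ilm_profile", "synth_ez_profile", "sample_biomarkers",
           "calibrate_bulge_intercept", "cohort_to_frame"]


class ConfigurationError(ValueError):
    """Invalid cohort configuration."""


@dataclass
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Geometry defaults are calibrated in closed form to healthy-adult
    reference medians: at the 50% derivative threshold a Gaussian-deficit
    pit has depth = 0.8434 * amplitude and diameter = 3.843 * sigma, so
    amplitude 113 µm and width 326 µm give a median pit depth near 95 µm
    and a median diameter near 1253 µm; the between-participant SDs match
    the reference interquartile ranges.
    """

    n_participants: int = 154
    age_min: float = 22.0
    age_max: float = 89.0
    seed: int = 0
    # pit geometry (between-participant distribution of true parameters)
    pit_depth_mean: float = 113.0     # Gaussian-deficit amplitude, µm
    pit_depth_sd: float = 25.0
    pit_sigma_mean: float = 326.0     # Gaussian-deficit width, µm
    pit_sigma_sd: float = 70.0
    rim_thickness_mean: float = 280.0
    rim_thickness_sd: float = 15.0
    inter_eye_sd: float = 5.0         # per-eye jitter on rim/amplitude, µm
    profile_noise_sd: float = 2.0
    profile_extent: float = 2500.0    # half-width of the scan, µm
    profile_step: float = 5.0
    # foveal bulge logistic model
    bulge_or_per_year: float = 0.949
    bulge_ref_prevalence: float = 0.685   # target marginal prevalence
    bulge_random_intercept_sd: float = 1.0
    ez_bulge_height: float = 10.0
    ez_bulge_sigma: float = 100.0
    ez_noise_sd: float = 1.0
    # biomarkers
    phenoage_accel_mean: float = -3.6
    phenoage_accel_sd: float = 7.8
    crp_high_frac: float = 0.02       # fraction with acute-phase CRP > 10 mg/L

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ConfigurationError("n_participants must be >= 2")
        if not self.age_min < self.age_max:
            raise ConfigurationError("age_min must be < age_max")
        sds = (self.pit_depth_sd, self.pit_sigma_sd, self.rim_thickness_sd,
               self.inter_eye_sd, self.profile_noise_sd,
               self.bulge_random_intercept_sd, self.ez_noise_sd,
               self.phenoage_accel_sd)
        if any(s < 0 for s in sds):
            raise ConfigurationError("standard deviations must be >= 0")
        if self.bulge_or_per_year <= 0:
            raise ConfigurationError("bulge_or_per_year must be > 0")
        if self.profile_step <= 0:
            raise ConfigurationError("profile_step must be > 0")
        if self.profile_extent < 3 * self.pit_sigma_mean:
            raise ConfigurationError(
                "profile_extent must cover >= 3 pit widths")
        if not 0 <= self.crp_high_frac < 1:
            raise ConfigurationError("crp_high_frac must be in [0, 1)")
        if not 0 < self.bulge_ref_prevalence < 1:
            raise ConfigurationError("bulge_ref_prevalence must be in (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Participant:
    id: str
    chron_age: float
    random_intercept_bulge: float       # logits
    true_pit_params: tuple[float, float, float]  # (rim, amplitude, sigma) µm
    biomarkers: BiomarkerPanel | None = None
    phenoage: float | None = None
    phenoage_accel: float | None = None


@dataclass
class EyeRecord:
    participant_id: str
    laterality: Literal["right", "left"]
    bulge_truth: bool
    eye_pit_params: tuple[float, float, float]
    ilm_profile: AScanProfile | None = None
    ez_profile: AScanProfile | None = None


def synth_ilm_profile(rim_thickness: float, pit_depth_amp: float,
                      pit_sigma: float, noise_sd: float, extent: float,
                      step: float, rng: np.random.Generator) -> AScanProfile:
    """Gaussian-deficit ILM thickness profile on a uniform grid.

    T(x) = rim - amp * exp(-x^2 / (2 sigma^2)) + Normal(0, noise_sd).
    """
    if pit_depth_amp <= 0 or pit_sigma <= 0:
        raise ValueError("pit amplitude and width must be > 0")
    if rim_thickness <= pit_depth_amp:
        raise ValueError("rim thickness must exceed pit amplitude "
                         "(thickness at the floor would be non-positive)")
    x = np.arange(-extent, extent + step / 2, step)
    t = rim_thickness - pit_depth_amp * np.exp(-x**2 / (2 * pit_sigma**2))
    if noise_sd > 0:
        t = t + rng.normal(0.0, noise_sd, size=x.size)
    return AScanProfile(x, t)


def synth_ez_profile(bulge_present: bool, bulge_height: float,
                     bulge_sigma: float, noise_sd: float,
                     grid: np.ndarray, rng: np.random.Generator) -> AScanProfile:
    """EZ height profile: central Gaussian elevation if the bulge is
    present, flat baseline otherwise."""
    if bulge_height < 0:
        raise ValueError("bulge_height must be >= 0")
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    t = np.zeros_like(grid)
    if bulge_present:
        t = t + bulge_height * np.exp(-grid**2 / (2 * bulge_sigma**2))
    if noise_sd > 0:
        t = t + rng.normal(0.0, noise_sd, size=grid.size)
    return AScanProfile(grid, t, require_positive=False)


# age-indexed reference distributions for the non-glucose biomarkers:
# (intercept at age 0, per-year slope, residual SD, accel loading per 1 SD
# of PhenoAgeAccel), centered on adult reference intervals.  The loadings
# co-move the panel with biological-age acceleration so that glucose only
# absorbs the residual of the PhenoAge target, keeping it physiological.
_BIOMARKER_REFS = {
    "albumin": (47.5, -0.05, 2.5, -1.5),      # g/L
    "creatinine": (62.0, 0.20, 10.0, 6.0),    # µmol/L
    "lymphocyte_pct": (36.5, -0.05, 6.0, -3.0),
    "mcv": (87.5, 0.03, 4.0, 1.5),            # fL
    "rdw": (12.5, 0.010, 0.7, 0.7),           # %
    "alp": (65.0, 0.10, 14.0, 10.0),          # U/L
    "wbc": (6.2, 0.0, 1.2, 0.8),              # 10⁹/L
}
# plausibility clips (keep panels physiological and PhenoAge-invertible)
_BIOMARKER_BOUNDS = {
    "albumin": (30.0, 55.0), "creatinine": (35.0, 140.0),
    "lymphocyte_pct": (8.0, 60.0), "mcv": (72.0, 102.0),
    "rdw": (10.5, 17.0), "alp": (25.0, 160.0), "wbc": (2.5, 12.0),
}
_GLUCOSE_BOUNDS = (2.5, 25.0)   # mmol/L
_CRP_BOUNDS = (0.05, 10.0)      # mg/L, non-acute branch


def sample_biomarkers(chron_age: float, accel_mean: float = -3.6,
                      accel_sd: float = 7.8,
                      rng: np.random.Generator | None = None,
                      crp_high_frac: float = 0.02,
                      coeffs: PhenoAgeCoefficients | None = None,
                      max_retries: int = 50) -> BiomarkerPanel:
    """Draw a biomarker panel whose PhenoAge is exactly
    chron_age + Normal(accel_mean, accel_sd).

    Eight biomarkers come from age-indexed reference normals that co-vary
    with the drawn acceleration (CRP from a lognormal with an acute-phase
    contamination fraction); glucose is then solved from the PhenoAge
    linear predictor so the panel hits the drawn target exactly.  If the
    solved glucose falls outside physiological bounds, it is pinned at
    the bound and CRP re-solved to keep the target exact; failing that,
    everything (including the target) is redrawn, with a retry cap.
    """
    if rng is None:
        rng = np.random.default_rng()
    c = _coeffs(coeffs)
    for _ in range(max_retries):
        accel = (accel_mean if accel_sd == 0
                 else rng.normal(accel_mean, accel_sd))
        target = chron_age + accel
        xb_target = xb_for_phenoage(target, c)
        z_accel = 0.0 if accel_sd == 0 else (accel - accel_mean) / accel_sd
        vals = {}
        for name, (b0, b1, sd, load) in _BIOMARKER_REFS.items():
            lo, hi = _BIOMARKER_BOUNDS[name]
            draw = b0 + b1 * chron_age + load * z_accel + rng.normal(0.0, sd)
            vals[name] = float(np.clip(draw, lo, hi))
        acute = rng.uniform() < crp_high_frac
        if acute:
            crp = float(rng.uniform(10.5, 30.0))
        else:
            crp = float(np.clip(rng.lognormal(
                math.log(1.0) + 0.008 * (chron_age - 50.0), 0.9),
                *_CRP_BOUNDS))
        rest_no_crp = (c.intercept
                       + c.albumin * vals["albumin"]
                       + c.creatinine * vals["creatinine"]
                       + c.lymphocyte_pct * vals["lymphocyte_pct"]
                       + c.mcv * vals["mcv"]
                       + c.rdw * vals["rdw"]
                       + c.alp * vals["alp"]
                       + c.wbc * vals["wbc"]
                       + c.chron_age * chron_age)
        glucose = (xb_target - rest_no_crp
                   - c.log_crp_mg_dl * math.log(crp / 10.0)) / c.glucose
        if not _GLUCOSE_BOUNDS[0] <= glucose <= _GLUCOSE_BOUNDS[1]:
            if acute:
                continue
            # pin glucose at the violated bound, re-solve CRP exactly
            glucose = float(np.clip(glucose, *_GLUCOSE_BOUNDS))
            log_crp = (xb_target - rest_no_crp
                       - c.glucose * glucose) / c.log_crp_mg_dl
            crp = 10.0 * math.exp(log_crp)
            if not _CRP_BOUNDS[0] <= crp <= _CRP_BOUNDS[1]:
                continue
        return BiomarkerPanel(albumin=vals["albumin"],
                              creatinine=vals["creatinine"],
                              glucose=float(glucose), crp=crp,
                              lymphocyte_pct=vals["lymphocyte_pct"],
                              mcv=vals["mcv"], rdw=vals["rdw"],
                              alp=vals["alp"], wbc=vals["wbc"])
    raise RuntimeError(
        f"could not construct a physiological panel at age "
        f"{chron_age:.1f} y after {max_retries} tries")


_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite_e.hermegauss(40)
_GH_WEIGHTS = _GH_WEIGHTS / _GH_WEIGHTS.sum()


def _marginal_prevalence(alpha: float, slope: float, age_samples: np.ndarray,
                         intercept_sd: float) -> float:
    """E[expit(alpha + slope*age + u)] over the age distribution and
    u ~ Normal(0, intercept_sd), by probabilists'-Hermite quadrature."""
    eta = alpha + slope * age_samples[:, None] + intercept_sd * _GH_NODES[None, :]
    return float((expit(eta) @ _GH_WEIGHTS).mean())


def calibrate_bulge_intercept(slope: float, age_samples: np.ndarray,
                              intercept_sd: float,
                              target_prevalence: float) -> float:
    """Solve for the logistic intercept giving the target marginal
    prevalence under the supplied age distribution."""
    def f(alpha: float) -> float:
        return _marginal_prevalence(alpha, slope, age_samples,
                                    intercept_sd) - target_prevalence
    return brentq(f, -40.0, 40.0, xtol=1e-10)


def generate_cohort(config: CohortConfig, include_profiles: bool = True,
                    include_biomarkers: bool = True,
                    bulge_age_variable: Literal["chronological", "phenoage"]
                    = "chronological",
                    ) -> tuple[list[Participant], list[EyeRecord]]:
    """Generate one cohort: participants with paired-eye records.

    ``bulge_age_variable`` selects which age drives the bulge logistic
    model (PhenoAge requires biomarkers).  Profiles and biomarkers can be
    switched off for fast model-recovery simulations.  Fully reproducible
    from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_participants
    if bulge_age_variable == "phenoage" and not include_biomarkers:
        raise ConfigurationError(
            "PhenoAge-driven bulge generation needs biomarkers")

    ages = rng.uniform(config.age_min, config.age_max, size=n)

    # true per-participant geometry, independent of age by construction
    rim = np.clip(rng.normal(config.rim_thickness_mean,
                             config.rim_thickness_sd, n), 230.0, 340.0)
    amp = np.clip(rng.normal(config.pit_depth_mean, config.pit_depth_sd, n),
                  40.0, 200.0)
    sig = np.clip(rng.normal(config.pit_sigma_mean, config.pit_sigma_sd, n),
                  180.0, 520.0)
    amp = np.minimum(amp, rim - 30.0)   # keep the floor physically positive

    participants: list[Participant] = []
    pheno_ages = np.empty(n)
    for i in range(n):
        pid = f"P{i + 1:04d}"
        p = Participant(
            id=pid, chron_age=float(ages[i]),
            random_intercept_bulge=float(
                rng.normal(0.0, config.bulge_random_intercept_sd)),
            true_pit_params=(float(rim[i]), float(amp[i]), float(sig[i])),
        )
        if include_biomarkers:
            p.biomarkers = sample_biomarkers(
                p.chron_age, config.phenoage_accel_mean,
                config.phenoage_accel_sd, rng, config.crp_high_frac)
            res = phenoage(p.biomarkers, p.chron_age)
            p.phenoage = res.phenoage
            p.phenoage_accel = res.phenoage_accel
            pheno_ages[i] = res.phenoage
        participants.append(p)

    # bulge logistic model: intercept calibrated to the marginal prevalence
    slope = math.log(config.bulge_or_per_year)
    if bulge_age_variable == "phenoage":
        driving_age = pheno_ages
        calib_ages = pheno_ages
    else:
        driving_age = ages
        calib_ages = np.linspace(config.age_min, config.age_max, 241)
    alpha = calibrate_bulge_intercept(
        slope, np.asarray(calib_ages, float),
        config.bulge_random_intercept_sd, config.bulge_ref_prevalence)

    grid = np.arange(-config.profile_extent,
                     config.profile_extent + config.profile_step / 2,
                     config.profile_step)
    eyes: list[EyeRecord] = []
    for i, p in enumerate(participants):
        eta = alpha + slope * driving_age[i] + p.random_intercept_bulge
        pr = expit(eta)
        for lat in ("right", "left"):
            e_rim = p.true_pit_params[0] + rng.normal(0.0, config.inter_eye_sd)
            e_amp = p.true_pit_params[1] + rng.normal(0.0, config.inter_eye_sd)
            e_sig = p.true_pit_params[2] + rng.normal(0.0, 2 * config.inter_eye_sd)
            e_amp = min(max(e_amp, 30.0), e_rim - 20.0)
            bulge = bool(rng.uniform() < pr)
            rec = EyeRecord(participant_id=p.id, laterality=lat,
                            bulge_truth=bulge,
                            eye_pit_params=(float(e_rim), float(e_amp),
                                            float(e_sig)))
            if include_profiles:
                rec.ilm_profile = synth_ilm_profile(
                    e_rim, e_amp, e_sig, config.profile_noise_sd,
                    config.profile_extent, config.profile_step, rng)
                rec.ez_profile = synth_ez_profile(
                    bulge, config.ez_bulge_height, config.ez_bulge_sigma,
                    config.ez_noise_sd, grid, rng)
            eyes.append(rec)
    return participants, eyes


def cohort_to_frame(participants: list[Participant],
                    eyes: list[EyeRecord]) -> pd.DataFrame:
    """Eye-level table: ids, ages, biomarkers, bulge truth and the
    noiseless true geometry parameters per eye."""
    pmap = {p.id: p for p in participants}
    rows = []
    for e in eyes:
        p = pmap[e.participant_id]
        row = {
            "participant_id": p.id, "laterality": e.laterality,
            "chron_age": p.chron_age, "phenoage": p.phenoage,
            "phenoage_accel": p.phenoage_accel,
            "bulge_truth": e.bulge_truth,
            "true_rim_um": e.eye_pit_params[0],
            "true_amp_um": e.eye_pit_params[1],
            "true_sigma_um": e.eye_pit_params[2],
        }
        if p.biomarkers is not None:
            row.update(vars(p.biomarkers))
        rows.append(row)
    return pd.DataFrame(rows)
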