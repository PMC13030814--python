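"""PhenoAge biological age from nine blood biomarkers plus chronological age.

PhenoAge maps a weighted combination of routine clinical-laboratory
biomarkers (albumin, creatinine, glucose, C-reactive protein, lymphocyte
percentage, mean red-cell volume, red-cell distribution width, alkaline
phosphatase, leukocyte count) and chronological age onto the age scale via
a Gompertz mortality model: the linear predictor xb gives a 120-month
mortality risk M = 1 - exp(-exp(xb) * (exp(120*g) - 1) / g), which is then
converted to years through the published log-log inverse mapping.
PhenoAgeAccel = PhenoAge - chronological age; positive values indicate
accelerated biological aging.

The regression constants ship in a versioned, checksummed JSON file; the
module refuses to run if the file has been altered.  CRP is stored in
mg/L (the scale of the acute-inflammation exclusion threshold) and enters
the linear predictor as ln(CRP in mg/dL) = ln(mg_L / 10).
"""

from __future__ import annotations

import hashlib
import json
import math
import warnings
from dataclasses import dataclass, fields
from importlib import resources
from typing import Iterable

import pandas as pd

__all__ = [
    "BiomarkerPanel", "PhenoAgeCoefficients", "PhenoAgeResult",
    "load_coefficients", "phenoage", "phenoage_accel",
    "xb_for_phenoage", "crp_exclusion_filter", "CRP_EXCLUSION_MG_L",
]

#: CRP level (mg/L) above which a panel is treated as acute-phase
CRP_EXCLUSION_MG_L = 10.0

#: sha256 of the shipped constants file; guards against silent edits
_COEFFS_SHA256 = "a47376bd0c3879704435c5c6508005b3f8d2f7410aa40f5c4b9c5075fcc39d74"

_RISK_EPS = 1e-12


@dataclass(frozen=True)
class BiomarkerPanel:
    """The nine PhenoAge inputs, in the units of the constants file."""

    albumin: float          # g/L
    creatinine: float       # µmol/L
    glucose: float          # mmol/L
    crp: float              # mg/L
    lymphocyte_pct: float   # %
    mcv: float              # fL
    rdw: float              # %
    alp: float              # U/L
    wbc: float              # 10⁹ cells/L

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if not (v > 0 and math.isfinite(v)):
                raise ValueError(f"biomarker {f.name} must be positive, got {v}")
        if self.lymphocyte_pct > 100:
            raise ValueError("lymphocyte_pct must be in (0, 100]")


@dataclass(frozen=True)
class PhenoAgeCoefficients:
    intercept: float
    albumin: float
    creatinine: float
    glucose: float
    log_crp_mg_dl: float
    lymphocyte_pct: float
    mcv: float
    rdw: float
    alp: float
    wbc: float
    chron_age: float
    gamma: float
    horizon_months: float
    offset_years: float
    rate_per_year: float
    scale: float
    version: str = "unversioned"

    @property
    def gompertz_factor(self) -> float:
        """(exp(horizon * gamma) - 1) / gamma, the cumulative-hazard factor."""
        return (math.exp(self.horizon_months * self.gamma) - 1.0) / self.gamma


@dataclass(frozen=True)
class PhenoAgeResult:
    xb: float               # linear predictor
    mortality_risk: float   # 120-month mortality probability
    phenoage: float         # years
    phenoage_accel: float   # years


def load_coefficients(verify_checksum: bool = True) -> PhenoAgeCoefficients:
    """Load the shipped constants, verifying the file checksum."""
    ref = resources.files("foveage") / "data" / "phenoage_coefficients.json"
    raw = ref.read_bytes()
    if verify_checksum:
        digest = hashlib.sha256(raw).hexdigest()
        if digest != _COEFFS_SHA256:
            raise RuntimeError(
                "phenoage_coefficients.json checksum mismatch "
                f"({digest}); refusing to compute PhenoAge from altered constants")
    doc = json.loads(raw)
    lp = doc["linear_predictor"]
    return PhenoAgeCoefficients(
        intercept=lp["intercept"], albumin=lp["albumin"],
        creatinine=lp["creatinine"], glucose=lp["glucose"],
        log_crp_mg_dl=lp["log_crp_mg_dl"], lymphocyte_pct=lp["lymphocyte_pct"],
        mcv=lp["mcv"], rdw=lp["rdw"], alp=lp["alp"], wbc=lp["wbc"],
        chron_age=lp["chron_age"],
        gamma=doc["gompertz"]["gamma"],
        horizon_months=doc["gompertz"]["horizon_months"],
        offset_years=doc["age_mapping"]["offset_years"],
        rate_per_year=doc["age_mapping"]["rate_per_year"],
        scale=doc["age_mapping"]["scale"],
        version=doc.get("version", "unversioned"),
    )


_DEFAULT_COEFFS: PhenoAgeCoefficients | None = None


def _coeffs(coeffs: PhenoAgeCoefficients | None) -> PhenoAgeCoefficients:
    global _DEFAULT_COEFFS
    if coeffs is not None:
        return coeffs
    if _DEFAULT_COEFFS is None:
        _DEFAULT_COEFFS = load_coefficients()
    return _DEFAULT_COEFFS


def linear_predictor(panel: BiomarkerPanel, chron_age: float,
                     coeffs: PhenoAgeCoefficients | None = None) -> float:
    """xb = intercept + sum(w_i * x_i) + w_age * age, CRP as ln(mg/dL)."""
    c = _coeffs(coeffs)
    return (c.intercept
            + c.albumin * panel.albumin
            + c.creatinine * panel.creatinine
            + c.glucose * panel.glucose
            + c.log_crp_mg_dl * math.log(panel.crp / 10.0)
            + c.lymphocyte_pct * panel.lymphocyte_pct
            + c.mcv * panel.mcv
            + c.rdw * panel.rdw
            + c.alp * panel.alp
            + c.wbc * panel.wbc
            + c.chron_age * chron_age)


def phenoage(panel: BiomarkerPanel, chron_age: float,
             coeffs: PhenoAgeCoefficients | None = None) -> PhenoAgeResult:
    """Compute PhenoAge (years) and PhenoAgeAccel for one participant."""
    c = _coeffs(coeffs)
    xb = linear_predictor(panel, chron_age, c)
    risk = 1.0 - math.exp(-math.exp(xb) * c.gompertz_factor)
    if not (_RISK_EPS < risk < 1.0 - _RISK_EPS):
        warnings.warn("mortality risk clamped before log-log inversion",
                      RuntimeWarning, stacklevel=2)
        risk = min(max(risk, _RISK_EPS), 1.0 - _RISK_EPS)
    pheno = c.offset_years + math.log(-c.scale * math.log1p(-risk)) / c.rate_per_year
    return PhenoAgeResult(xb=xb, mortality_risk=risk, phenoage=pheno,
                          phenoage_accel=phenoage_accel(pheno, chron_age))


def phenoage_accel(phenoage_years: float, chron_age: float) -> float:
    """PhenoAgeAccel = PhenoAge - chronological age (years)."""
    if not (math.isfinite(phenoage_years) and math.isfinite(chron_age)):
        raise ValueError("ages must be finite")
    return phenoage_years - chron_age


def xb_for_phenoage(target_phenoage: float,
                    coeffs: PhenoAgeCoefficients | None = None) -> float:
    """Invert the age mapping: the linear predictor that yields a given
    PhenoAge.  Closed form: xb = rate*(P - offset) - ln(scale * gompertz)."""
    c = _coeffs(coeffs)
    return (c.rate_per_year * (target_phenoage - c.offset_years)
            - math.log(c.scale * c.gompertz_factor))


def crp_exclusion_filter(rows: pd.DataFrame,
                         threshold: float = CRP_EXCLUSION_MG_L,
                         crp_column: str = "crp",
                         id_column: str = "participant_id",
                         ) -> tuple[pd.DataFrame, list]:
    """Drop rows whose CRP strictly exceeds the acute-inflammation threshold.

    "Exceeding" is strict: crp == threshold is retained.  Returns the
    retained rows and the sorted unique ids of excluded rows.
    """
    if crp_column not in rows.columns:
        raise ValueError(f"missing CRP column {crp_column!r}")
    crp = rows[crp_column]
    if crp.isna().any():
        bad = rows.loc[crp.isna(), id_column].tolist() \
            if id_column in rows.columns else rows.index[crp.isna()].tolist()
        raise ValueError(f"missing CRP for ids {bad}")
    mask = crp > threshold
    excluded_rows = rows.loc[mask]
    excluded = (sorted(excluded_rows[id_column].unique().tolist())
                if id_column in rows.columns else excluded_rows.index.tolist())
    return rows.loc[~mask].copy(), excluded


def panels_to_frame(panels: Iterable[BiomarkerPanel]) -> pd.DataFrame:
    return pd.DataFrame([vars(p) for p in panels])
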