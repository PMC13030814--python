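"""Age-trend modeling of eye-level foveal parameters.

For each outcome and age type (chronological or biological/PhenoAge),
three candidate fixed-effect structures are fitted on identical rows with
a participant random intercept, all by maximum likelihood so the AICs are
comparable:

* constant — intercept only (no age dependence);
* linear — a fixed linear age term;
* spline — a thin-plate-style penalized truncated-power spline on age,
  with basis dimension k in {5, 10, 15, 20} and the best k chosen by AIC.

The lowest AIC wins overall.  The significance of the linear age
association is always read from the linear candidate's Wald test,
regardless of which structure wins, and p-values are adjusted across the
whole parameter-by-age-type family with Benjamini–Hochberg.  Population
predictions (random effects excluded) run over ages 17–92 in 1-year steps
with 95% confidence intervals for the mean and wider 95% prediction
intervals folding in the random-intercept (and, for Gaussian outcomes,
residual) variance; predictions are then averaged within four age groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit
from statsmodels.stats.multitest import multipletests

from .lmm import fit_gaussian_lmm
from .glmm import fit_binomial_glmm

__all__ = [
    "ModelSpec", "FitResult", "PredictionCurve", "GroupSummary",
    "fit_candidate", "fit_all_candidates", "select_model", "bh_adjust",
    "predict_population", "group_average", "odds_ratio_per_year",
    "spearman_rho", "AGE_GRID", "AGE_GROUPS", "SPLINE_K_GRID",
]

AGE_GRID = np.arange(17, 93)                       # years, 76 points
AGE_GROUPS = ((17, 44), (45, 59), (60, 74), (75, 92))
SPLINE_K_GRID = (5, 10, 15, 20)
_Z95 = stats.norm.ppf(0.975)

_AGE_COLUMNS = {"chronological": "chron_age", "biological": "phenoage"}


@dataclass(frozen=True)
class ModelSpec:
    outcome: str
    family: str                      # {"gaussian", "binomial"}
    form: str                        # {"constant", "linear", "spline"}
    age_type: str = "chronological"  # {"chronological", "biological"}
    spline_k: int | None = None

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.form not in ("constant", "linear", "spline"):
            raise ValueError(f"unknown form {self.form!r}")
        if self.age_type not in _AGE_COLUMNS:
            raise ValueError(f"unknown age_type {self.age_type!r}")
        if (self.spline_k is None) != (self.form != "spline"):
            raise ValueError("spline_k must be given iff form == 'spline'")
        if self.spline_k is not None and self.spline_k < 4:
            raise ValueError("spline_k must be >= 4")


@dataclass
class _Design:
    """Reproducible fixed-effect design: rebuildable at prediction ages."""

    form: str
    age_center: float
    age_scale: float
    knots: np.ndarray = field(default_factory=lambda: np.empty(0))

    def fixed(self, ages: np.ndarray) -> np.ndarray:
        a = (np.asarray(ages, float) - self.age_center) / self.age_scale
        if self.form == "constant":
            return np.ones((a.size, 1))
        return np.column_stack([np.ones(a.size), a])

    def spline(self, ages: np.ndarray) -> np.ndarray:
        a = (np.asarray(ages, float) - self.age_center) / self.age_scale
        k = (self.knots - self.age_center) / self.age_scale
        return np.maximum(a[:, None] - k[None, :], 0.0) ** 3


@dataclass
class FitResult:
    spec: ModelSpec
    beta: np.ndarray
    cov_beta: np.ndarray
    spline_beta: np.ndarray | None    # posterior means of penalized coefs
    design: _Design
    aic: float
    loglik: float
    wald_p_linear: float | None       # linear form only
    edf: float | None                 # spline form only
    sd_patient: float
    sd_resid: float | None            # gaussian only
    n_obs: int
    n_participants: int
    converged: bool

    @property
    def n_fixed(self) -> int:
        return int(self.beta.size)


def _prepare(data: pd.DataFrame, spec: ModelSpec
             ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    age_col = _AGE_COLUMNS[spec.age_type]
    for col in (spec.outcome, age_col, "participant_id"):
        if col not in data.columns:
            raise ValueError(f"data lacks column {col!r}")
    sub = data[[spec.outcome, age_col, "participant_id"]].dropna()
    y = sub[spec.outcome].to_numpy(float)
    ages = sub[age_col].to_numpy(float)
    groups = pd.Categorical(sub["participant_id"]).codes
    if np.ptp(y) == 0:
        raise ValueError(f"outcome {spec.outcome!r} is degenerate")
    return y, ages, np.asarray(groups)


def _make_design(spec: ModelSpec, ages: np.ndarray) -> _Design:
    center = float(ages.mean())
    scale = max(float(ages.std()), 1e-9)
    knots = np.empty(0)
    if spec.form == "spline":
        q = np.linspace(0, 1, spec.spline_k)[1:-1]   # k-2 interior knots
        knots = np.quantile(ages, q)
    return _Design(spec.form, center, scale, knots)


def fit_candidate(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit one candidate model on the eye-level table.

    Gaussian outcomes use the profiled-ML random-intercept LMM (the spline
    smooth enters as a penalized variance component); binomial outcomes use
    the Gauss–Hermite random-intercept logit (spline basis unpenalized).
    """
    y, ages, groups = _prepare(data, spec)
    design = _make_design(spec, ages)
    X = design.fixed(ages)

    if spec.family == "gaussian":
        Zs = design.spline(ages) if spec.form == "spline" else None
        f = fit_gaussian_lmm(y, X, groups, Zs)
        beta, cov = f.beta, f.cov_beta
        # posterior means of the penalized coefficients, for predictions
        spline_beta = None
        if Zs is not None and f.sd_spline and f.sd_spline > 0:
            r_s = (f.sd_spline / f.sigma_resid) ** 2
            resid = y - X @ beta
            M = Zs.T @ Zs + np.eye(Zs.shape[1]) / r_s
            spline_beta = np.linalg.solve(M, Zs.T @ resid)
        elif Zs is not None:
            spline_beta = np.zeros(Zs.shape[1])
        aic, loglik, sd_pat, sd_res = f.aic, f.loglik, f.sd_patient, f.sigma_resid
        edf = f.edf_smooth if spec.form == "spline" else None
        converged, n_groups = f.converged, f.n_groups
    else:
        if spec.form == "spline":
            X = np.hstack([X, design.spline(ages)])
        f = fit_binomial_glmm(y, X, groups)
        beta, cov, spline_beta = f.beta, f.cov_beta, None
        aic, loglik, sd_pat, sd_res = f.aic, f.loglik, f.sd_patient, None
        edf = float(X.shape[1] - 1) if spec.form == "spline" else None
        converged, n_groups = f.converged, f.n_groups
        if spec.form == "spline":
            spline_beta = beta[2:]
            beta, cov = beta, cov     # kept whole; design.spline rebuilds

    wald_p = None
    if spec.form == "linear":
        se = float(np.sqrt(cov[1, 1]))
        z = beta[1] / se if se > 0 else np.inf
        wald_p = float(2 * stats.norm.sf(abs(z)))

    return FitResult(
        spec=spec, beta=np.asarray(beta, float),
        cov_beta=np.asarray(cov, float), spline_beta=spline_beta,
        design=design, aic=float(aic), loglik=float(loglik),
        wald_p_linear=wald_p, edf=edf, sd_patient=float(sd_pat),
        sd_resid=(float(sd_res) if sd_res is not None else None),
        n_obs=y.size, n_participants=int(n_groups), converged=converged)


def fit_all_candidates(data: pd.DataFrame, outcome: str, family: str,
                       age_type: str = "chronological",
                       spline_ks: tuple[int, ...] = SPLINE_K_GRID,
                       ) -> list[FitResult]:
    """Fit the constant, linear, and spline (all k) candidates."""
    fits = [
        fit_candidate(data, ModelSpec(outcome, family, "constant", age_type)),
        fit_candidate(data, ModelSpec(outcome, family, "linear", age_type)),
    ]
    for k in spline_ks:
        fits.append(fit_candidate(
            data, ModelSpec(outcome, family, "spline", age_type, spline_k=k)))
    return fits


def select_model(fits: list[FitResult]) -> FitResult:
    """Lowest-AIC selection: the best spline k is chosen first among the
    spline candidates, then compared against constant and linear.  Ties
    (dAIC < 1e-6) go to the model with fewer fixed parameters."""
    ok = [f for f in fits if f.converged and np.isfinite(f.aic)]
    if len(ok) < 2:
        raise ValueError("need >= 2 converged fits to select a model")
    splines = [f for f in ok if f.spec.form == "spline"]
    others = [f for f in ok if f.spec.form != "spline"]
    pool = list(others)
    if splines:
        pool.append(min(splines, key=lambda f: (f.aic, f.n_fixed)))
    pool.sort(key=lambda f: (f.aic, f.n_fixed))
    best = pool[0]
    for f in pool[1:]:
        if abs(f.aic - best.aic) < 1e-6 and f.n_fixed < best.n_fixed:
            best = f
    return best


def bh_adjust(pvals, labels=None) -> np.ndarray:
    """Benjamini–Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass
class PredictionCurve:
    ages: np.ndarray
    fit: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    pi_low: np.ndarray
    pi_high: np.ndarray
    family: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "age": self.ages, "fit": self.fit,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "pi_low": self.pi_low, "pi_high": self.pi_high})


def predict_population(fit: FitResult, ages: np.ndarray | None = None,
                       extrapolate: bool = False) -> PredictionCurve:
    """Population-level predictions (random effects excluded).

    CI: mean prediction ± 1.96 SE of the fixed-effect predictor.  PI for
    Gaussian outcomes additionally folds in the participant and residual
    variance on the response scale; for binomial outcomes both intervals
    are built on the logit scale (the PI inflated by the random-intercept
    SD) and inverse-transformed.
    """
    ages = AGE_GRID if ages is None else np.asarray(ages, float)
    if not extrapolate and (ages.min() < 17 or ages.max() > 92):
        raise ValueError("ages outside [17, 92]; pass extrapolate=True")

    if fit.spec.family == "binomial" and fit.spec.form == "spline":
        X = np.hstack([fit.design.fixed(ages), fit.design.spline(ages)])
        eta = X @ fit.beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov_beta, X))
    else:
        X = fit.design.fixed(ages)
        eta = X @ fit.beta
        se = np.sqrt(np.einsum("ij,jk,ik->i", X, fit.cov_beta, X))
        if fit.spec.form == "spline" and fit.spline_beta is not None:
            eta = eta + fit.design.spline(ages) @ fit.spline_beta

    if fit.spec.family == "gaussian":
        pi_sd = np.sqrt(se**2 + fit.sd_patient**2 + (fit.sd_resid or 0.0)**2)
        return PredictionCurve(
            ages, eta, eta - _Z95 * se, eta + _Z95 * se,
            eta - _Z95 * pi_sd, eta + _Z95 * pi_sd, "gaussian")
    wide = np.sqrt(se**2 + fit.sd_patient**2)
    return PredictionCurve(
        ages, expit(eta), expit(eta - _Z95 * se), expit(eta + _Z95 * se),
        expit(eta - _Z95 * wide), expit(eta + _Z95 * wide), "binomial")


@dataclass
class GroupSummary:
    table: pd.DataFrame    # one row per age group

    def __str__(self) -> str:
        return self.table.to_string(index=False)


def group_average(curve: PredictionCurve,
                  data_ages: np.ndarray | None = None) -> GroupSummary:
    """Average the prediction curve within the four age groups; per-group
    n counts eyes whose age falls in the group."""
    data_ages = np.asarray([] if data_ages is None else data_ages, float)
    rows = []
    for lo, hi in AGE_GROUPS:
        sel = (curve.ages >= lo) & (curve.ages <= hi)
        n_obs = int(((data_ages >= lo) & (data_ages < hi + 1)).sum())
        if not sel.any():
            rows.append({"group": f"{lo}-{hi}", "n": n_obs, "fit": np.nan,
                         "ci_low": np.nan, "ci_high": np.nan,
                         "pi_low": np.nan, "pi_high": np.nan})
            continue
        rows.append({
            "group": f"{lo}-{hi}", "n": n_obs,
            "fit": float(curve.fit[sel].mean()),
            "ci_low": float(curve.ci_low[sel].mean()),
            "ci_high": float(curve.ci_high[sel].mean()),
            "pi_low": float(curve.pi_low[sel].mean()),
            "pi_high": float(curve.pi_high[sel].mean()),
        })
    return GroupSummary(pd.DataFrame(rows))


def odds_ratio_per_year(fit: FitResult) -> tuple[float, float, float]:
    """Per-year odds ratio with 95% Wald CI from a binomial linear fit."""
    if fit.spec.family != "binomial" or fit.spec.form != "linear":
        raise ValueError("odds ratio requires a binomial linear fit")
    slope = fit.beta[1] / fit.design.age_scale       # per raw year
    se = float(np.sqrt(fit.cov_beta[1, 1])) / fit.design.age_scale
    return (float(np.exp(slope)), float(np.exp(slope - _Z95 * se)),
            float(np.exp(slope + _Z95 * se)))


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), two-sided p."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired vectors with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Spearman correlation undefined for constant input")
    rs, p = stats.spearmanr(x, y)
    return float(rs), float(p)
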