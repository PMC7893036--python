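"""Model fitting, AICc multimodel inference and reporting.

Candidate fixed-effect structures follow the analysis design: a global
model (season + species + season:species), then season-only and
species-only reductions, all with crossed random intercepts for animal
and date.  Reference levels are drought (season) and gemsbok (species).

Candidates are compared by AICc with Akaike weights; models within
ΔAICc < 2 of the best form the plausible set.  Coefficients are
reported on an explicit per-response scale:

* ``identity`` — the model (response) scale, e.g. °C;
* ``log`` — the model was fit to log(response); estimates stay on the
  log scale and seasonal contrasts exponentiate;
* ``response-rate`` — Poisson estimates exponentiated: the intercept is
  a daily rate, other terms rate ratios, CIs multiplicative;
* ``response-proportion`` — binomial (logit) fits re-expressed as
  proportion-scale cell effects: the intercept is the reference-cell
  proportion and each effect the additive change in proportion, with
  delta-method CIs, so cell means reconstruct by simple addition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as scipy_stats

from .config import RESPONSES, PlantedCoefficients
from .glmm import GLMMResult, fit_gaussian, fit_glmm_laplace

__all__ = [
    "ModelSpec",
    "MixedModelFit",
    "fit_mixed",
    "fit_candidates",
    "aicc",
    "akaike_weights",
    "build_selection_table",
    "conditional_r2",
    "nakagawa_r2",
    "marginal_means",
    "seasonal_contrast",
    "FIXED_STRUCTURES",
]

_Z95 = 1.959963984540054

FIXED_STRUCTURES = {
    "global": ["intercept", "season", "species", "interaction"],
    "season": ["intercept", "season"],
    "species": ["intercept", "species"],
    "null": ["intercept"],
}

_COMPLETE_FLAG = {
    "t_min": "complete_temp",
    "t_max": "complete_temp",
    "t_amplitude": "complete_temp",
    "cool_hours": "complete_microclimate",
    "cumulative_cool_use": "complete_microclimate",
    "travel_hours": "complete_travel",
    "total_activity_24h": "complete_activity",
    "heat_activity_proportion": "complete_activity",
}


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: response, family, fixed structure, reporting scale."""

    response: str
    family: str = "gaussian"  # gaussian | binomial | poisson
    fixed: str = "global"  # key of FIXED_STRUCTURES
    scale: str = "identity"  # reporting scale tag (see module docstring)
    weights: str | None = None  # column of per-row binomial weights
    variance_by_cell: bool = False  # per species-season residual variances (Gaussian)
    ar1: bool = False  # AR(1) residuals over days within animal (Gaussian)
    reml: bool = True  # Gaussian: REML coefficients/CIs; AICc always uses ML loglik

    def __post_init__(self) -> None:
        if self.family not in ("gaussian", "binomial", "poisson"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.fixed not in FIXED_STRUCTURES:
            raise ValueError(f"unknown fixed structure {self.fixed!r}")
        if (self.variance_by_cell or self.ar1) and self.family != "gaussian":
            raise ValueError("variance structures apply to Gaussian fits only")

    @classmethod
    def for_response(cls, response: str, fixed: str = "global", **kw) -> "ModelSpec":
        """Default family/scale for one of the pipeline's eight responses."""
        family, scale = RESPONSES[response]
        if response == "heat_activity_proportion":
            kw.setdefault("weights", "total_activity_24h")
        if response in ("t_min", "t_max", "t_amplitude"):
            kw.setdefault("variance_by_cell", True)
        return cls(response, family=family, fixed=fixed, scale=scale, **kw)


@dataclass
class MixedModelFit:
    """Fitted-model summary on the spec's reporting scale."""

    spec: ModelSpec
    coefficients: pd.DataFrame  # term, estimate, ci_low, ci_high (reporting scale)
    loglik: float
    k: int
    n_obs: int
    n_animals: int
    n_dates: int
    variance_components: dict
    family: str
    link: str
    converged: bool
    message: str = ""
    result: GLMMResult = field(default=None, repr=False)

    @property
    def estimates(self) -> dict[str, float]:
        return dict(zip(self.coefficients["term"], self.coefficients["estimate"]))

    def coefficient_table(self) -> PlantedCoefficients | None:
        """Reporting-scale coefficient table for contrast helpers (global fits)."""
        if self.spec.fixed != "global":
            return None
        e = self.estimates
        return PlantedCoefficients(
            e["intercept"], e["season"], e["species"], e["interaction"], self.spec.scale
        )


def _design(data: pd.DataFrame, fixed: str) -> tuple[np.ndarray, list[str]]:
    terms = FIXED_STRUCTURES[fixed]
    season = (data["season"] == "non-drought").to_numpy(float)
    species = (data["species"] == "wildebeest").to_numpy(float)
    cols = {"intercept": np.ones(len(data)), "season": season, "species": species,
            "interaction": season * species}
    X = np.column_stack([cols[t] for t in terms])
    return X, terms


def _prepare(spec: ModelSpec, data: pd.DataFrame) -> pd.DataFrame:
    flag = _COMPLETE_FLAG.get(spec.response)
    d = data.copy()
    if flag is not None and flag in d.columns:
        d = d[d[flag]]
    d = d.dropna(subset=[spec.response])
    if spec.weights is not None:
        d = d.dropna(subset=[spec.weights])
        d = d[d[spec.weights] > 0]
    if d.empty:
        raise ValueError(f"no complete observations for response {spec.response!r}")
    seasons = set(d["season"])
    if seasons != {"drought", "non-drought"}:
        raise ValueError(
            f"response {spec.response!r}: data must contain both seasons, found {sorted(seasons)}"
        )
    per_species = d.groupby("species")["animal_id"].nunique()
    if "species" in FIXED_STRUCTURES[spec.fixed] or spec.fixed == "global":
        for sp in ("gemsbok", "wildebeest"):
            if per_species.get(sp, 0) < 2:
                raise ValueError(f"need >= 2 animals per species, {sp} has {per_species.get(sp, 0)}")
    return d


def fit_mixed(spec: ModelSpec, data: pd.DataFrame) -> MixedModelFit:
    """Fit one GLMM to the daily-metrics table.

    Gaussian responses use exact ML (REML on request) with the optional
    species-season variance structure; binomial/Poisson use a Laplace
    approximation.  Non-convergence is flagged on the returned fit, not
    silently ignored.
    """
    d = _prepare(spec, data)
    X, terms = _design(d, spec.fixed)
    y = d[spec.response].to_numpy(float)

    if spec.family == "gaussian":
        if spec.scale == "log":
            if np.any(y <= 0):
                keep = y > 0
                d, X, y = d[keep], X[keep], y[keep]
            y = np.log(y)
        groups = None
        gnames = None
        if spec.variance_by_cell:
            cell = d["species"].astype(str) + "/" + d["season"].astype(str)
            codes, uniq = pd.factorize(cell)
            groups, gnames = codes, list(uniq)
        day_index = None
        if spec.ar1:
            day_index = pd.to_datetime(d["date"]).map(pd.Timestamp.toordinal).to_numpy()
        res = fit_gaussian(
            y, X, terms, d["animal_id"].to_numpy(), d["date"].astype(str).to_numpy(),
            residual_groups=groups, group_names=gnames, ar1=spec.ar1,
            day_index=day_index, reml=spec.reml,
        )
    else:
        if spec.family == "binomial":
            if np.any((y < 0) | (y > 1)):
                raise ValueError("binomial response must be proportions in [0, 1]")
            pw = d[spec.weights].to_numpy(float) if spec.weights else None
        else:
            if np.any(y < 0) or np.any(np.abs(y - np.round(y)) > 1e-9):
                raise ValueError("poisson response must be non-negative integer counts")
            pw = None
        res = fit_glmm_laplace(
            y, X, terms, d["animal_id"].to_numpy(), d["date"].astype(str).to_numpy(),
            spec.family, prior_weights=pw,
        )

    coefs = _report_coefficients(res, spec, terms)
    vc = {"animal": res.vc_animal, "date": res.vc_date, "residual": res.vc_residual}
    if res.ar1_rho is not None:
        vc["ar1_rho"] = res.ar1_rho
    return MixedModelFit(
        spec=spec, coefficients=coefs, loglik=res.loglik, k=res.k,
        n_obs=res.n_obs, n_animals=res.n_animals, n_dates=res.n_dates,
        variance_components=vc, family=res.family, link=res.link,
        converged=res.converged, message=res.message, result=res,
    )


def _cell_vector(terms: Sequence[str], species: str, season: str) -> np.ndarray:
    c = []
    for t in terms:
        if t == "intercept":
            c.append(1.0)
        elif t == "season":
            c.append(1.0 if season == "non-drought" else 0.0)
        elif t == "species":
            c.append(1.0 if species == "wildebeest" else 0.0)
        elif t == "interaction":
            c.append(1.0 if (season == "non-drought" and species == "wildebeest") else 0.0)
    return np.array(c)


def _critical_value(res: GLMMResult, spec: ModelSpec, term: str) -> float:
    """95% critical value for one term's Wald interval.

    Gaussian fits use t quantiles with containment degrees of freedom:
    terms constant within animals (intercept, species) are tested against
    the animal stratum, the season term against the date stratum, and the
    interaction against the residual stratum.  With only ~10 animals the
    animal-stratum correction matters; GLMM (Laplace) fits keep the
    conventional normal quantile.
    """
    if spec.family != "gaussian":
        return _Z95
    if term in ("intercept", "species"):
        df = max(res.n_animals - (2 if "species" in res.fe_names else 1), 2)
    elif term == "season":
        df = max(res.n_dates - 2, 2)
    else:
        df = max(res.n_obs - res.k, 2)
    return float(scipy_stats.t.ppf(0.975, df))


def _report_coefficients(res: GLMMResult, spec: ModelSpec, terms) -> pd.DataFrame:
    beta, se = res.beta, res.se
    if spec.scale in ("identity", "log"):
        crit = np.array([_critical_value(res, spec, t) for t in terms])
        est, lo, hi = beta, beta - crit * se, beta + crit * se
    elif spec.scale == "response-rate":
        est = np.exp(beta)
        lo, hi = np.exp(beta - _Z95 * se), np.exp(beta + _Z95 * se)
    elif spec.scale == "response-proportion":
        # express logit-scale fit as additive proportion-scale cell effects
        def invlogit(x):
            return 1.0 / (1.0 + np.exp(-x))

        cells = {
            (sp, se_): _cell_vector(terms, sp, se_)
            for sp in ("gemsbok", "wildebeest")
            for se_ in ("drought", "non-drought")
        }
        # contrast of cell proportions for each reported term
        contrasts = {
            "intercept": [(1.0, ("gemsbok", "drought"))],
            "season": [(1.0, ("gemsbok", "non-drought")), (-1.0, ("gemsbok", "drought"))],
            "species": [(1.0, ("wildebeest", "drought")), (-1.0, ("gemsbok", "drought"))],
            "interaction": [
                (1.0, ("wildebeest", "non-drought")),
                (-1.0, ("wildebeest", "drought")),
                (-1.0, ("gemsbok", "non-drought")),
                (1.0, ("gemsbok", "drought")),
            ],
        }
        est, lo, hi = [], [], []
        for t in terms:
            val, grad = 0.0, np.zeros(len(beta))
            for sign, cell in contrasts[t]:
                c = cells[cell]
                p = invlogit(float(c @ beta))
                val += sign * p
                grad += sign * p * (1.0 - p) * c
            sd = math.sqrt(max(float(grad @ res.cov_beta @ grad), 0.0))
            est.append(val)
            lo.append(val - _Z95 * sd)
            hi.append(val + _Z95 * sd)
        est, lo, hi = np.array(est), np.array(lo), np.array(hi)
    else:  # pragma: no cover
        raise ValueError(f"unknown scale {spec.scale!r}")
    return pd.DataFrame({"term": list(terms), "estimate": est, "ci_low": lo, "ci_high": hi})


# ---------------------------------------------------------------------------
# Information criteria


def aicc(fit, k: int | None = None, n: int | None = None) -> float:
    """Small-sample corrected AIC: −2ℓ + 2k + 2k(k+1)/(n−k−1).

    Accepts a fitted model or a raw log-likelihood with explicit k and n.
    Undefined (raises) when n ≤ k + 1.
    """
    if isinstance(fit, MixedModelFit):
        loglik, k, n = fit.loglik, fit.k, fit.n_obs
    else:
        loglik = float(fit)
        if k is None or n is None:
            raise TypeError("aicc(loglik, k=..., n=...) requires k and n")
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n} <= k+1={k + 1}")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1.0) / (n - k - 1.0)


def akaike_weights(aiccs: Sequence[float]) -> pd.DataFrame:
    """ΔAICc, Akaike weights and the ΔAICc < 2 plausibility flag."""
    a = np.asarray(list(aiccs), dtype=float)
    if a.size == 0:
        raise ValueError("need at least one candidate model")
    delta = a - a.min()
    rel = np.exp(-0.5 * delta)
    w = rel / rel.sum()
    return pd.DataFrame({"aicc": a, "delta_aicc": delta, "weight": w, "plausible": delta < 2.0})


def nakagawa_r2(var_fixed: float, var_random: float, var_residual: float) -> float:
    """Conditional R²: (fixed + random) / (fixed + random + residual) variance."""
    total = var_fixed + var_random + var_residual
    if total <= 0:
        raise ValueError("conditional R² undefined when all variance components are zero")
    return (var_fixed + var_random) / total


def conditional_r2(fit: MixedModelFit) -> float:
    """Nakagawa–Schielzeth conditional R² of a mixed-model fit.

    The fixed-effect variance is the variance of the fitted fixed linear
    predictor; the residual variance is family-appropriate: the Gaussian
    residual variance (mean across strata under the variance structure),
    π²/3 for the binomial logit, and the lognormal approximation
    ln(1 + 1/λ̄) for the Poisson log link, with λ̄ the mean fitted rate.
    """
    res = fit.result
    var_f = float(np.var(res.fitted_fixed))
    var_r = fit.variance_components["animal"] + fit.variance_components["date"]
    if fit.family == "gaussian":
        resid = fit.variance_components["residual"]
        var_e = float(np.mean(list(resid.values()))) if isinstance(resid, dict) else float(resid)
    elif fit.family == "binomial":
        var_e = math.pi**2 / 3.0
    else:  # poisson, log link
        lam = float(np.mean(np.exp(res.fitted_fixed)))
        var_e = math.log1p(1.0 / lam)
    return nakagawa_r2(var_f, var_r, var_e)


def build_selection_table(fits: Mapping[str, MixedModelFit]) -> pd.DataFrame:
    """Per-candidate AICc, ΔAICc, weight, plausibility and conditional R²."""
    names = list(fits)
    table = akaike_weights([aicc(fits[m]) for m in names])
    table.insert(0, "model", names)
    table["k"] = [fits[m].k for m in names]
    table["loglik"] = [fits[m].loglik for m in names]
    table["conditional_r2"] = [conditional_r2(fits[m]) for m in names]
    table["converged"] = [fits[m].converged for m in names]
    return table.sort_values("delta_aicc").reset_index(drop=True)


def fit_candidates(
    response: str,
    data: pd.DataFrame,
    candidates: Sequence[str] = ("global", "season", "species"),
    **spec_kw,
) -> dict[str, MixedModelFit]:
    """Fit the candidate set for one response (global, season-only, species-only)."""
    return {
        c: fit_mixed(ModelSpec.for_response(response, fixed=c, **spec_kw), data)
        for c in candidates
    }


# ---------------------------------------------------------------------------
# Marginal means & contrasts


def marginal_means(fit: MixedModelFit, grid: Sequence[tuple[str, str]] | None = None) -> pd.DataFrame:
    """Model-based cell means on the response scale with 95% CIs.

    Predictions are at the random-effect centre (typical animal and
    date); CIs transform the Wald interval of the cell linear predictor
    through the inverse link.  For log-scale Gaussian fits the cell
    prediction is exp(linear predictor) — the model-scale median.
    """
    res = fit.result
    terms = list(fit.coefficients["term"])
    if grid is None:
        grid = [(sp, se) for sp in ("gemsbok", "wildebeest") for se in ("drought", "non-drought")]
        if "species" not in terms:
            grid = [("gemsbok", se) for se in ("drought", "non-drought")]
        if "season" not in terms:
            grid = [(sp, "drought") for sp in ("gemsbok", "wildebeest")]
    rows = []
    for sp, se_ in grid:
        if sp == "wildebeest" and "species" not in terms:
            raise ValueError("species level requested but absent from the fitted model")
        if se_ == "non-drought" and "season" not in terms:
            raise ValueError("season level requested but absent from the fitted model")
        c = _cell_vector(terms, sp, se_)
        eta = float(c @ res.beta)
        sd = math.sqrt(max(float(c @ res.cov_beta @ c), 0.0))
        lo, hi = eta - _Z95 * sd, eta + _Z95 * sd
        if fit.link == "log" or fit.spec.scale in ("log", "response-rate"):
            mean, lo, hi = math.exp(eta), math.exp(lo), math.exp(hi)
        elif fit.link == "logit":
            mean, lo, hi = (1 / (1 + math.exp(-v)) for v in (eta, lo, hi))
        else:
            mean = eta
        rows.append({"species": sp, "season": se_, "mean": mean, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def _coef(coefficients, name: str) -> float:
    if isinstance(coefficients, PlantedCoefficients):
        return getattr(coefficients, name)
    if isinstance(coefficients, Mapping):
        return float(coefficients[name])
    raise TypeError("coefficients must be a PlantedCoefficients or a mapping")


def _scale_of(coefficients, scale: str | None) -> str:
    if scale is not None:
        return scale
    if isinstance(coefficients, PlantedCoefficients):
        return coefficients.scale
    if isinstance(coefficients, Mapping) and "scale" in coefficients:
        return str(coefficients["scale"])
    raise ValueError("coefficient table carries no scale tag")


def seasonal_contrast(
    coefficients,
    species: str,
    direction: str = "drought-minus-non-drought",
    scale: str | None = None,
) -> float:
    """Within-species seasonal change on the response scale.

    With drought as the reference level, the drought-minus-non-drought
    change is −β_season for gemsbok and −(β_season + β_interaction) for
    wildebeest; on the log / rate scale the change is multiplicative and
    returned as a fractional change (e.g. −0.362 for −36.2%); on the
    proportion scale it is additive on proportions.
    """
    if species not in ("gemsbok", "wildebeest"):
        raise ValueError(f"unknown species {species!r}")
    if direction not in ("drought-minus-non-drought", "non-drought-minus-drought"):
        raise ValueError(f"unknown direction {direction!r}")
    tag = _scale_of(coefficients, scale)

    b_season = _coef(coefficients, "season")
    b_inter = _coef(coefficients, "interaction")
    if tag == "response-rate":  # stored as rate ratios: log for the linear predictor
        b_season, b_inter = math.log(b_season), math.log(b_inter)

    lin = b_season + (b_inter if species == "wildebeest" else 0.0)
    if direction == "drought-minus-non-drought":
        lin = -lin
    if tag in ("log", "response-rate"):
        return math.exp(lin) - 1.0
    if tag in ("identity", "response-proportion"):
        return lin
    raise ValueError(f"unknown scale tag {tag!r}")
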