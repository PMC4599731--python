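"""Binomial GLMs of apparent survival with AICc-based multi-model inference.

Two candidate-model families relate movement covariates at the upstream
curtain to apparent survival at the downstream curtain:

* the **entry** set, over every smolt detected upstream: initial receiver
  position (``P_initial``), Julian day of first detection (``Julian``),
  natal ``Population``, plus ``FL`` and release ``Year`` for steelhead, with
  ``Population:Julian`` and ``Population:P_initial`` interactions;
* the **lateral** set, over smolts with at least two upstream detection
  sequences: first lateral displacement (``Dx12``), the time between the
  first two sequences (``Duration``), ``Population``, plus ``FL``/``Year``
  for steelhead, with ``Population:Dx12`` and ``Population:Duration``.

Continuous predictors are standardized to mean 0, SD 0.5 by subtracting the
mean and dividing by twice the sample SD, which puts their coefficients on
the scale of a binary predictor's.  Every marginality-respecting subset of
the full term list is fitted by maximum likelihood, ranked by AICc, and the
models within 2 AICc units of the best are combined by zero-substitution
("full") model averaging with Burnham-Anderson unconditional standard
errors; conditional (subset) averages are carried alongside.

The fitting surface follows the statsmodels convention: build a
:class:`SurvivalModel` from a route-record table, call :meth:`~SurvivalModel.fit`,
and read the ranking table, averaged coefficients, and ``summary()`` off the
returned :class:`SurvivalResults`.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .routes import JUAN_DE_FUCA

__all__ = [
    "standardize",
    "aicc",
    "all_subsets",
    "rank_models",
    "model_average",
    "pseudo_r2",
    "ModelFit",
    "SurvivalModel",
    "SurvivalResults",
]

Z_CRIT = 1.959963984540054  # two-sided 95% normal quantile


def standardize(values: np.ndarray) -> tuple[np.ndarray, float, float]:
    """Center and scale by twice the sample SD: z = (x - mean) / (2 * sd).

    Returns (z, mean, sd).  Raises for constant input.
    """
    x = np.asarray(values, dtype=float)
    if len(x) < 2:
        raise ValueError("standardize requires n >= 2")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd == 0.0:
        raise ValueError("cannot standardize a constant variable")
    return (x - mean) / (2.0 * sd), mean, sd


def aicc(loglik: float, k: int, n: int) -> float:
    """Small-sample corrected Akaike information criterion."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (n - k - 1 <= 0)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def _parents(term: str) -> tuple[str, ...]:
    return tuple(term.split(":")) if ":" in term else ()


def all_subsets(mains: list[str], interactions: list[str]) -> list[tuple[str, ...]]:
    """Every subset of terms (incl. empty = intercept-only) in which each
    interaction's parent main effects are present; ordered by term count,
    then lexicographically."""
    for term in interactions:
        for p in _parents(term):
            if p not in mains:
                raise ValueError(f"interaction {term!r} lacks parent {p!r} among mains")
    models = []
    for r_main in range(len(mains) + 1):
        for main_sub in itertools.combinations(sorted(mains), r_main):
            eligible = [t for t in interactions if all(p in main_sub for p in _parents(t))]
            for r_int in range(len(eligible) + 1):
                for int_sub in itertools.combinations(sorted(eligible), r_int):
                    models.append(tuple(sorted(main_sub + int_sub)))
    models = sorted(set(models), key=lambda t: (len(t), t))
    return models


def pseudo_r2(loglik: float, loglik_null: float, k: int) -> tuple[float, float]:
    """McFadden pseudo-R2 and its parameter-penalized adjustment."""
    if loglik_null == 0.0:
        raise ValueError("null log-likelihood of zero; pseudo-R2 undefined")
    r2 = 1.0 - loglik / loglik_null
    adj = 1.0 - (loglik - k) / loglik_null
    return r2, adj


@dataclass
class ModelFit:
    """One fitted candidate logistic model with AICc bookkeeping."""

    terms: tuple[str, ...]
    params: pd.Series
    bse: pd.Series
    loglik: float
    k: int
    n: int
    aicc: float
    r2: float
    adj_r2: float
    converged: bool = True
    separation: bool = False
    delta_aicc: float = np.nan
    weight: float = np.nan

    @property
    def label(self) -> str:
        return " + ".join(self.terms) if self.terms else "(intercept)"


def rank_models(fits: list[ModelFit]) -> list[ModelFit]:
    """Attach ΔAICc and Akaike weights; returns fits sorted by AICc."""
    usable = [f for f in fits if f.converged and not f.separation]
    if not usable:
        raise ValueError("no converged candidate models to rank")
    best = min(f.aicc for f in usable)
    rel = np.array([np.exp(-(f.aicc - best) / 2.0) for f in usable])
    total = rel.sum()
    for f, r in zip(usable, rel):
        f.delta_aicc = f.aicc - best
        f.weight = float(r / total)
    return sorted(usable, key=lambda f: f.aicc)


def model_average(fits: list[ModelFit], delta_max: float = 2.0) -> pd.DataFrame:
    """Average coefficients over the ΔAICc <= delta_max candidate set.

    Weights are renormalized within the set.  The primary ("full") average
    substitutes zero for a coefficient in models that exclude its term; the
    unconditional SE follows Burnham & Anderson,
    ``SE = sum_i w_i * sqrt(se_i^2 + (b_i - b_bar)^2)``.  Conditional
    (models-containing-the-term-only) averages are emitted as secondary
    columns.  95% CIs are Wald intervals on the unconditional SE.
    """
    ranked = rank_models(list(fits))
    chosen = [f for f in ranked if f.delta_aicc <= delta_max]
    w = np.array([f.weight for f in chosen])
    w = w / w.sum()
    columns: list[str] = []
    for f in chosen:
        for c in f.params.index:
            if c not in columns:
                columns.append(c)
    rows = []
    for col in columns:
        betas = np.array([float(f.params.get(col, 0.0)) for f in chosen])
        ses = np.array([float(f.bse.get(col, 0.0)) for f in chosen])
        present = np.array([col in f.params.index for f in chosen])
        b_full = float(np.sum(w * betas))
        se_full = float(np.sum(w * np.sqrt(ses**2 + (betas - b_full) ** 2)))
        w_c = w[present] / w[present].sum()
        b_c = float(np.sum(w_c * betas[present]))
        se_c = float(np.sum(w_c * np.sqrt(ses[present] ** 2 + (betas[present] - b_c) ** 2)))
        rows.append(
            {
                "term": col,
                "coef": b_full,
                "se": se_full,
                "ci_lower": b_full - Z_CRIT * se_full,
                "ci_upper": b_full + Z_CRIT * se_full,
                "coef_conditional": b_c,
                "se_conditional": se_c,
                "n_models": int(present.sum()),
            }
        )
    return pd.DataFrame(rows).set_index("term")


# ---------------------------------------------------------------------------
# design construction


@dataclass
class _Design:
    """Prepared response, per-term design blocks and standardization scalers."""

    y: np.ndarray
    blocks: dict[str, pd.DataFrame]
    mains: list[str]
    interactions: list[str]
    scalers: dict[str, tuple[float, float]]
    data: pd.DataFrame
    pop_levels: list[str] = field(default_factory=list)


ENTRY, LATERAL = "entry", "lateral"

_VAR_SOURCES = {
    "P_initial": "p_initial",
    "Julian": "julian_day",
    "FL": "fork_length_mm",
    "Dx12": "dx12_km",
    "Duration": "duration12_h",
}


def _prepare_design(records: pd.DataFrame, species: str, model_set: str) -> _Design:
    if model_set not in (ENTRY, LATERAL):
        raise ValueError(f"model_set must be 'entry' or 'lateral', got {model_set!r}")
    sub = records[(records["species"] == species) & (records["route"] != JUAN_DE_FUCA)].copy()
    if model_set == ENTRY:
        sub = sub.dropna(subset=["p_initial", "julian_day"])
        continuous = ["P_initial", "Julian"]
        focal = ["Julian", "P_initial"]
    else:
        sub = sub.dropna(subset=["dx12_km", "duration12_h"])
        if species == "steelhead":
            # too few multi-sequence Seymour fish to estimate population terms
            sub = sub[sub["population"] != "Seymour"]
        continuous = ["Dx12", "Duration"]
        focal = ["Dx12", "Duration"]
    if species == "steelhead":
        continuous = continuous + ["FL"]

    # populations represented by a single fish cannot carry a dummy
    pop_counts = sub["population"].value_counts()
    thin = pop_counts[pop_counts < 2].index.tolist()
    if thin:
        warnings.warn(f"dropping population(s) with < 2 records: {thin}", stacklevel=3)
        sub = sub[~sub["population"].isin(thin)]
    if len(sub) == 0:
        raise ValueError(f"no usable {species} records for the {model_set} model set")

    y = sub["survived_qcs"].astype(int).to_numpy()
    blocks: dict[str, pd.DataFrame] = {}
    scalers: dict[str, tuple[float, float]] = {}
    mains: list[str] = []

    for name in continuous:
        z, mean, sd = standardize(sub[_VAR_SOURCES[name]].to_numpy(dtype=float))
        blocks[name] = pd.DataFrame({name: z}, index=sub.index)
        scalers[name] = (mean, sd)
        mains.append(name)

    pop_levels = sorted(sub["population"].unique())  # first level is the reference
    interactions: list[str] = []
    if len(pop_levels) >= 2:
        dummies = pd.DataFrame(
            {
                f"Population[{lvl}]": (sub["population"] == lvl).astype(float)
                for lvl in pop_levels[1:]
            },
            index=sub.index,
        )
        blocks["Population"] = dummies
        mains.append("Population")
        for v in focal:
            iname = f"Population:{v}"
            icols = dummies.mul(blocks[v][v], axis=0)
            icols.columns = [f"{c}:{v}" for c in dummies.columns]
            blocks[iname] = icols
            interactions.append(iname)
    if species == "steelhead":
        years = sorted(sub["release_year"].unique())
        if len(years) >= 2:
            blocks["Year"] = pd.DataFrame(
                {f"Year[{yr}]": (sub["release_year"] == yr).astype(float) for yr in years[1:]},
                index=sub.index,
            )
            mains.append("Year")
    return _Design(y, blocks, mains, interactions, scalers, sub, pop_levels)


def _fit_glm(y: np.ndarray, X: pd.DataFrame) -> tuple[pd.Series, pd.Series, float, bool, bool]:
    """(params, bse, loglik, converged, separation) for one logistic fit."""
    model = sm.GLM(y, X, family=sm.families.Binomial())
    separation = False
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(tol=1e-8, maxiter=200)
        params, bse, llf = res.params, res.bse, float(res.llf)
        converged = bool(res.converged)
    except Exception:  # perfect separation or singular design
        return pd.Series(dtype=float), pd.Series(dtype=float), -np.inf, False, True
    if np.max(np.abs(params.to_numpy())) > 15.0 or np.max(bse.to_numpy()) > 1e2:
        separation = True
    if not np.isfinite(llf):
        converged = False
    return params, bse, llf, converged, separation


class SurvivalModel:
    """Apparent-survival logistic model family for one species.

    Parameters
    ----------
    records : pandas.DataFrame
        Route records (one row per detected smolt) as produced by
        :func:`smoltroutes.routes.build_route_records`.
    species : str
        ``"sockeye"`` or ``"steelhead"``; determines which terms enter the
        full model (sockeye omits ``FL`` and ``Year``, collinear with
        population).
    model_set : str
        ``"entry"`` (all detected smolts) or ``"lateral"`` (smolts with at
        least two upstream detection sequences).
    """

    def __init__(self, records: pd.DataFrame, species: str, model_set: str = ENTRY):
        self.species = species
        self.model_set = model_set
        self.design = _prepare_design(records, species, model_set)

    @classmethod
    def from_route_records(cls, records: pd.DataFrame, species: str, model_set: str = ENTRY):
        return cls(records, species, model_set)

    @property
    def nobs(self) -> int:
        return len(self.design.y)

    def candidate_specs(self) -> list[tuple[str, ...]]:
        return all_subsets(self.design.mains, self.design.interactions)

    def _design_matrix(self, terms: tuple[str, ...]) -> pd.DataFrame:
        parts = [pd.DataFrame({"Intercept": np.ones(self.nobs)}, index=self.design.data.index)]
        for t in terms:
            parts.append(self.design.blocks[t])
        return pd.concat(parts, axis=1)

    def fit_one(self, terms: tuple[str, ...], loglik_null: float | None = None) -> ModelFit:
        """Fit a single candidate model by maximum likelihood."""
        X = self._design_matrix(tuple(terms))
        n = self.nobs
        params, bse, llf, converged, separation = _fit_glm(self.design.y, X)
        k = X.shape[1]
        if loglik_null is None:
            p0 = self.design.y.mean()
            loglik_null = float(n * (p0 * np.log(p0) + (1 - p0) * np.log(1 - p0))) if 0 < p0 < 1 else 0.0
        if converged and not separation and loglik_null != 0.0:
            r2, adj = pseudo_r2(llf, loglik_null, k)
        else:
            r2 = adj = np.nan
        a = aicc(llf, k, n) if np.isfinite(llf) else np.inf
        return ModelFit(tuple(terms), params, bse, llf, k, n, a, r2, adj, converged, separation)

    def fit(self, delta_max: float = 2.0) -> "SurvivalResults":
        """Fit every marginality-valid candidate model, rank by AICc, and
        average the ΔAICc <= ``delta_max`` set."""
        p0 = self.design.y.mean()
        if p0 in (0.0, 1.0):
            raise ValueError("response is constant; survival model is degenerate")
        n = self.nobs
        loglik_null = float(n * (p0 * np.log(p0) + (1 - p0) * np.log(1 - p0)))
        fits = [self.fit_one(spec, loglik_null) for spec in self.candidate_specs()]
        flagged = [f for f in fits if f.separation or not f.converged]
        if flagged:
            warnings.warn(
                f"{len(flagged)} candidate model(s) flagged (separation/non-convergence) "
                "and excluded from averaging",
                stacklevel=2,
            )
        ranked = rank_models(fits)
        averaged = model_average(ranked, delta_max=delta_max)
        return SurvivalResults(self, ranked, averaged, delta_max)


class SurvivalResults:
    """Fitted candidate set: ranking table, averaged coefficients, predictions."""

    def __init__(self, model: SurvivalModel, fits: list[ModelFit], averaged: pd.DataFrame, delta_max: float):
        self.model = model
        self.fits = fits
        self.averaged = averaged
        self.delta_max = delta_max

    @property
    def ranking(self) -> pd.DataFrame:
        rows = [
            {
                "model": f.label,
                "r2": f.r2,
                "adj_r2": f.adj_r2,
                "loglik": f.loglik,
                "k": f.k,
                "aicc": f.aicc,
                "delta_aicc": f.delta_aicc,
                "weight": f.weight,
            }
            for f in self.fits
        ]
        return pd.DataFrame(rows)

    @property
    def best(self) -> ModelFit:
        return self.fits[0]

    def significant_terms(self) -> list[str]:
        """Averaged design columns whose 95% CI excludes zero (intercept aside)."""
        av = self.averaged
        keep = (av["ci_lower"] > 0) | (av["ci_upper"] < 0)
        return [t for t in av.index[keep] if t != "Intercept"]

    def predict(
        self,
        variable: str,
        grid: np.ndarray | None = None,
        by_population: bool = True,
        n_points: int = 50,
    ) -> pd.DataFrame:
        """Averaged-model survival probability along one continuous variable.

        The grid is in the variable's raw units and is truncated to the
        observed range (per population when population terms are present);
        all other covariates sit at their means (standardized zero).
        """
        design = self.model.design
        if variable not in design.scalers:
            raise ValueError(f"unknown continuous variable {variable!r}")
        mean, sd = design.scalers[variable]
        raw = design.data[_VAR_SOURCES[variable]].to_numpy(dtype=float)
        av = self.averaged["coef"]
        has_pop = any(c.startswith("Population[") for c in av.index)
        pops = design.pop_levels if (by_population and has_pop) else [None]
        rows = []
        for pop in pops:
            if pop is None:
                obs = raw
            else:
                obs = design.data.loc[design.data["population"] == pop, _VAR_SOURCES[variable]].to_numpy(float)
                if len(obs) == 0:
                    continue
            lo, hi = float(np.min(obs)), float(np.max(obs))
            g = np.linspace(lo, hi, n_points) if grid is None else np.asarray(grid, dtype=float)
            clipped = np.clip(g, lo, hi)
            if grid is not None and not np.array_equal(clipped, g):
                warnings.warn(f"prediction grid truncated to observed range [{lo}, {hi}]", stacklevel=2)
            z = (clipped - mean) / (2.0 * sd)
            eta = np.full_like(z, float(av.get("Intercept", 0.0)))
            eta += z * float(av.get(variable, 0.0))
            if pop is not None and pop != design.pop_levels[0]:
                eta += float(av.get(f"Population[{pop}]", 0.0))
                eta += z * float(av.get(f"Population[{pop}]:{variable}", 0.0))
            prob = 1.0 / (1.0 + np.exp(-eta))
            for gv, pv in zip(clipped, prob):
                rows.append({"population": pop or "(all)", "value": gv, "prob_survival": pv})
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Plain-text summary: candidate ranking and averaged coefficients."""
        lines = [
            f"Apparent-survival GLMs ({self.model.species}, {self.model.model_set} set)",
            f"n = {self.model.nobs} smolts, {len(self.fits)} converged candidate models, "
            f"{sum(f.delta_aicc <= self.delta_max for f in self.fits)} within ΔAICc <= {self.delta_max:g}",
            "",
            "Top models:",
        ]
        top = self.ranking.head(8)
        lines.append(
            top.to_string(
                index=False,
                float_format=lambda v: f"{v:.3f}",
                columns=["model", "r2", "adj_r2", "loglik", "aicc", "delta_aicc", "weight"],
            )
        )
        lines += ["", f"Model-averaged coefficients (full average, ΔAICc <= {self.delta_max:g}):"]
        av = self.averaged[["coef", "se", "ci_lower", "ci_upper", "n_models"]]
        lines.append(av.to_string(float_format=lambda v: f"{v:.3f}"))
        sig = self.significant_terms()
        lines += ["", "95% CI excludes zero: " + (", ".join(sig) if sig else "(none)")]
        return "\n".join(lines)
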