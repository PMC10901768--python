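"""Departure-date regressions: GLMs with a wintering-origin interaction
and backward likelihood-ratio model selection.

Each response (arrival date, migration speed, number of stopovers, total
stopover duration) is modelled against departure date with wintering
origin (GB vs Europe) as a factor in interaction, one model per season.
Gaussian family throughout except a log-link Poisson for the stopover
count. Selection starts from the full model and removes terms backward
— interaction first, then main effects, never a main effect whose
interaction survives — testing each removal with a deviance-based F test
(Gaussian; exact partial F for the linear model) or a chi-square
likelihood-ratio test (Poisson).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as sps

GAUSSIAN = "GAUSSIAN"
POISSON = "POISSON"

RESPONSES = ("arrival_date", "migration_speed", "n_stopovers", "total_stopover_duration")

__all__ = [
    "RegressionDesign", "ModelFit", "fit_glm", "select_model",
    "fit_departure_models", "GAUSSIAN", "POISSON",
]


@dataclass(frozen=True)
class RegressionDesign:
    """One response ~ departure_date * origin design for one season."""

    response: str
    season: str = "SPRING"
    family: str = GAUSSIAN
    interaction: bool = True

    def __post_init__(self) -> None:
        if self.family == POISSON and self.response != "n_stopovers":
            raise ValueError("Poisson family is reserved for the stopover count")

    @property
    def formula(self) -> str:
        rhs = "departure_date * origin" if self.interaction else "departure_date + origin"
        return f"{self.response} ~ {rhs}"


@dataclass
class ModelFit:
    """A fitted GLM plus the backward-selection trace that produced it."""

    design: RegressionDesign
    result: object                       # statsmodels GLMResults
    terms: tuple[str, ...]
    trace: list[dict] = field(default_factory=list)

    @property
    def coefficients(self) -> pd.DataFrame:
        r = self.result
        return pd.DataFrame({"beta": r.params, "se": r.bse, "p": r.pvalues})

    @property
    def deviance(self) -> float:
        return float(self.result.deviance)

    def summary_rows(self) -> list[dict]:
        rows = []
        for name in self.result.params.index:
            rows.append({
                "response": self.design.response, "season": self.design.season,
                "family": self.design.family, "term": name,
                "beta": float(self.result.params[name]),
                "se": float(self.result.bse[name]),
                "p": float(self.result.pvalues[name]),
            })
        return rows


def _family(design: RegressionDesign):
    if design.family == POISSON:
        return sm.families.Poisson()
    return sm.families.Gaussian()


def _fit(formula: str, data: pd.DataFrame, design: RegressionDesign):
    model = smf.glm(formula, data=data, family=_family(design))
    try:
        return model.fit()
    except ValueError:
        # IRLS cannot start from a zero-deviance guess (e.g. a constant
        # response); seed it with the least-squares solution instead
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            start = smf.ols(formula, data=data).fit().params.values
            return model.fit(start_params=start)


def fit_glm(design: RegressionDesign, data: pd.DataFrame) -> ModelFit:
    """Maximum-likelihood fit of the (full, by default) design.

    ``data`` needs columns ``departure_date`` (numeric day of year),
    ``origin`` (categorical GB/EUROPE) and the response. Requires at
    least two observations per origin level when the interaction is in
    the model.
    """
    data = data.dropna(subset=[design.response, "departure_date", "origin"])
    if design.interaction:
        counts = data["origin"].value_counts()
        if len(counts) < 2 or counts.min() < 2:
            raise ValueError("interaction model needs >=2 observations per origin level")
    res = _fit(design.formula, data, design)
    terms = ("departure_date", "origin", "departure_date:origin") if design.interaction \
        else ("departure_date", "origin")
    return ModelFit(design, res, terms)


def _drop_test(full_res, red_res, family: str) -> tuple[str, float, float]:
    """Test the term(s) dropped between nested fits.

    Gaussian: deviance-based F with dispersion from the larger model.
    Poisson: chi-square likelihood-ratio test.
    Returns (test_name, statistic, p).
    """
    df_diff = full_res.df_model - red_res.df_model
    if df_diff <= 0:
        return ("none", 0.0, 1.0)
    if family == GAUSSIAN:
        scale = full_res.deviance / full_res.df_resid
        f = (red_res.deviance - full_res.deviance) / df_diff / scale
        p = sps.f.sf(f, df_diff, full_res.df_resid)
        return ("F", float(f), float(p))
    lr = 2.0 * (full_res.llf - red_res.llf)
    p = sps.chi2.sf(lr, df_diff)
    return ("LRT", float(lr), float(p))


def _formula_for(response: str, terms: tuple[str, ...]) -> str:
    return f"{response} ~ {' + '.join(terms) if terms else '1'}"


def select_model(full: ModelFit, data: pd.DataFrame, alpha: float = 0.05) -> ModelFit:
    """Backward elimination from the full model by nested LRTs at ``alpha``.

    The interaction is tested first; main effects are only candidates
    once no interaction involving them remains (marginality). The least
    significant droppable term goes at each step until every remaining
    term is significant; an intercept-only model is a legal outcome.
    """
    design = full.design
    data = data.dropna(subset=[design.response, "departure_date", "origin"])
    terms = list(full.terms)
    current = full.result
    trace: list[dict] = []

    while terms:
        has_int = "departure_date:origin" in terms
        candidates = ["departure_date:origin"] if has_int else list(terms)
        best = None
        for term in candidates:
            reduced_terms = tuple(t for t in terms if t != term)
            red = _fit(_formula_for(design.response, reduced_terms), data, design)
            test, stat, p = _drop_test(current, red, design.family)
            if best is None or p > best[2]:
                best = (term, stat, p, red, test)
        term, stat, p, red, test = best
        trace.append({"dropped": term, "test": test, "stat": stat, "p": p,
                      "kept": p < alpha})
        if p < alpha:
            break
        terms.remove(term)
        current = red

    return ModelFit(design, current, tuple(terms), trace)


def fit_departure_models(data: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Fit and select all four responses per season; returns the summary table.

    ``data`` is the per-journey metrics table with columns season, origin,
    departure_date and the responses; seasons with too few observations
    for the interaction model are skipped with a note row.
    """
    rows = []
    for season, grp in data.groupby("season"):
        for response in RESPONSES:
            if response not in grp.columns:
                continue
            family = POISSON if response == "n_stopovers" else GAUSSIAN
            design = RegressionDesign(response, season=season, family=family)
            sub = grp.dropna(subset=[response, "departure_date", "origin"])
            counts = sub["origin"].value_counts()
            if len(counts) < 2 or counts.min() < 2:
                rows.append({"response": response, "season": season,
                             "family": family, "term": "SKIPPED:insufficient data",
                             "beta": np.nan, "se": np.nan, "p": np.nan})
                continue
            fit = select_model(fit_glm(design, sub), sub, alpha=alpha)
            rows.extend(fit.summary_rows())
    return pd.DataFrame(rows)
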