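"""Linear models with F tests and binomial GLMs of background-choice data.

``fit_lm`` fits ordinary least squares on (optionally log10) responses with
categorical predictors and reports per-term F tests (Type II marginal sums
of squares by default, Type I sequential by option).  ``fit_binomial_glm``
fits a logit-link GLM by IRLS and reports Wald z per coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.anova import anova_lm

COLOURS = frozenset({"brown", "green"})
BLINDFOLD_LEVELS = frozenset({"control", "painted"})

#: |coefficient| beyond which a logit fit is flagged as (quasi-)separated.
SEPARATION_BOUND = 15.0


@dataclass
class ChoiceTrial:
    """One background-choice observation."""

    larva_id: str
    larval_colour: str
    blindfold: str
    arena: str  # diagonal | horizontal
    dowel_position: str  # brown_far | green_far | none
    chosen_colour: str
    matching_success: int = field(init=False)

    def __post_init__(self) -> None:
        self.matching_success = encode_matching(self.larval_colour, self.chosen_colour)
        if self.blindfold not in BLINDFOLD_LEVELS:
            raise ValueError(f"unknown blindfold status {self.blindfold!r}")


@dataclass
class ModelFit:
    """Fitted-model summary: per-term statistics plus bookkeeping."""

    family: str  # gaussian_lm | binomial_glm
    terms: pd.DataFrame
    n_obs: int
    df_resid: int
    separation_flag: bool = False
    diagnostics: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        matches = [t for t in self.terms.index if name in t]
        if not matches:
            raise KeyError(f"no model term matching {name!r}; have {list(self.terms.index)}")
        return self.terms.loc[matches[0]]


def encode_matching(larval_colour: str, chosen_colour: str) -> int:
    """1 if the chosen background colour equals the larva's own colour."""
    for value in (larval_colour, chosen_colour):
        if value not in COLOURS:
            raise ValueError(f"unknown colour label {value!r}; expected one of {sorted(COLOURS)}")
    return int(larval_colour == chosen_colour)


def trials_to_frame(trials: list[ChoiceTrial]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "larva_id": [t.larva_id for t in trials],
            "larval_colour": [t.larval_colour for t in trials],
            "blindfold": [t.blindfold for t in trials],
            "arena": [t.arena for t in trials],
            "dowel_position": [t.dowel_position for t in trials],
            "chosen_colour": [t.chosen_colour for t in trials],
            "matching_success": [t.matching_success for t in trials],
        }
    )


def _qq_data(residuals: np.ndarray) -> dict:
    (theoretical, ordered), (slope, intercept, _) = scipy.stats.probplot(residuals)
    return {
        "theoretical_quantiles": theoretical,
        "ordered_residuals": ordered,
        "slope": slope,
        "intercept": intercept,
    }


def fit_lm(
    data: pd.DataFrame,
    response: str,
    factors: list[str],
    log10: bool = False,
    anova_type: int = 2,
) -> ModelFit:
    """OLS with categorical factors and per-term F tests.

    Parameters
    ----------
    data : one row per observation; ``response`` numeric, factors categorical.
    log10 : model log10 of the response (all values must be > 0).
    anova_type : 2 for marginal (default) or 1 for sequential sums of squares.
    """
    if anova_type not in (1, 2):
        raise ValueError("anova_type must be 1 or 2")
    df = data.copy()
    y = df[response].astype(float)
    if log10:
        bad = df.index[y <= 0].tolist()
        if bad:
            raise ValueError(
                f"log10 requested but response {response!r} is non-positive for rows: {bad}"
            )
        df["_y"] = np.log10(y)
    else:
        df["_y"] = y
    formula = "_y ~ " + " + ".join(f"C({f})" for f in factors)
    fit = smf.ols(formula, data=df).fit()
    notes: list[str] = []
    if fit.ssr <= 1e-12 * max(1.0, float(fit.centered_tss)):
        # zero-residual degenerate fit: F is unbounded
        warnings.warn("perfect fit (zero residual): F statistics are infinite", stacklevel=2)
        notes.append("perfect fit: infinite F")
        terms = pd.DataFrame(
            {
                "df1": [fit.df_model / max(len(factors), 1)] * len(factors),
                "df2": [fit.df_resid] * len(factors),
                "F": [np.inf] * len(factors),
                "p_value": [0.0] * len(factors),
            },
            index=[f"C({f})" for f in factors],
        )
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            table = anova_lm(fit, typ=anova_type)
        table = table.drop(index=[i for i in table.index if i.strip() == "Residual"])
        terms = pd.DataFrame(
            {
                "df1": table["df"].astype(float),
                "df2": float(fit.df_resid),
                "F": table["F"].astype(float),
                "p_value": table["PR(>F)"].astype(float),
            }
        )
    terms["estimate"] = np.nan
    terms["se"] = np.nan
    return ModelFit(
        family="gaussian_lm",
        terms=terms,
        n_obs=int(fit.nobs),
        df_resid=int(fit.df_resid),
        diagnostics={"qq": _qq_data(fit.resid.to_numpy()), "coefficients": fit.params},
        notes=notes,
    )


def fit_binomial_glm(
    trials: list[ChoiceTrial] | pd.DataFrame,
    predictors: list[str] | None = None,
) -> ModelFit:
    """Logit-link binomial GLM of matching success, fitted by IRLS.

    Wald z statistics per coefficient; coefficients with magnitude above
    :data:`SEPARATION_BOUND` raise the separation flag (not an error).
    Convergence: |change in deviance| < 1e-8, at most 50 iterations.
    """
    df = trials if isinstance(trials, pd.DataFrame) else trials_to_frame(trials)
    if len(df) < 10:
        raise ValueError(f"need at least 10 trials, got {len(df)}")
    predictors = predictors or []
    allowed = {"larval_colour", "blindfold", "dowel_position"}
    unknown = set(predictors) - allowed
    if unknown:
        raise ValueError(f"unknown predictors {sorted(unknown)}; allowed: {sorted(allowed)}")
    if predictors:
        formula = "matching_success ~ " + " + ".join(f"C({p})" for p in predictors)
    else:
        formula = "matching_success ~ 1"
    model = smf.glm(formula, data=df, family=sm.families.Binomial())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(maxiter=50, tol=1e-8)
    params = fit.params
    separated = bool(np.any(np.abs(params) > SEPARATION_BOUND))
    terms = pd.DataFrame(
        {
            "estimate": params,
            "se": fit.bse,
            "z": fit.tvalues,
            "p_value": fit.pvalues,
        }
    )
    return ModelFit(
        family="binomial_glm",
        terms=terms,
        n_obs=int(fit.nobs),
        df_resid=int(fit.df_resid),
        separation_flag=separated,
        diagnostics={
            "deviance": float(fit.deviance),
            # statsmodels seeds its history with inf and the starting-value
            # deviance; only entries from the first IRLS iterate are real
            "deviance_history": list(fit.fit_history.get("deviance", []))[2:],
        },
        notes=["separation suspected: |coefficient| > 15"] if separated else [],
    )
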