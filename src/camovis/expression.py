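"""RT-qPCR relative quantification and downstream expression statistics.

Relative expression of a target gene against the reference is
``(E_ref ^ Cp_ref) / (E_target ^ Cp_target)`` with amplification
efficiency E idealised to 2.  The dermal proportion of a sample is
``sum(dermal tissues) / (head + sum(dermal tissues))``, analysed with a
logit-link beta regression (constant precision) fitted by Newton
iterations on the exact log-likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, psi
from statsmodels.tools.numdiff import approx_hess

from .behaviour import ModelFit

GENES = ("Arr-1", "RDB", "UVA", "BlA", "BlB", "MelA", "MelB", "LW1", "LW2")
REFERENCE_GENE = "spectrin"
STAGES = ("larva", "adult")
HEAD_TISSUE = "head"
DERMAL_TISSUES = ("thorax", "abdomen", "claspers_or_genitalia")

#: Replicate Cp spread above this many cycles is flagged as unreliable.
CP_SD_FLAG = 0.5

#: Proportions exactly at 0 or 1 are nudged inside the open interval.
BOUNDARY_NUDGE = 1e-6

DEFAULT_EFFICIENCY = 2.0


@dataclass
class QpcrRecord:
    sample_id: str
    stage: str
    tissue: str
    gene: str
    cp_values: tuple[float, ...]

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")
        if len(self.cp_values) > 3:
            raise ValueError("at most 3 replicate Cp values")
        for cp in self.cp_values:
            if np.isnan(cp):
                continue  # unusable replicate, dropped at collapse time
            if not (0 < cp <= 45):
                raise ValueError(f"Cp {cp} outside (0, 45]")


@dataclass
class ExpressionRatio:
    sample_id: str
    stage: str
    tissue: str
    gene: str
    ratio: float

    def __post_init__(self) -> None:
        if self.ratio <= 0:
            raise ValueError("expression ratio must be > 0")


@dataclass
class DermalProportion:
    sample_id: str
    stage: str
    gene: str
    proportion: float

    def __post_init__(self) -> None:
        if not (0 < self.proportion < 1):
            raise ValueError("dermal proportion must lie strictly inside (0, 1)")


def relative_expression(
    cp_ref: float,
    cp_target: float,
    e_ref: float = DEFAULT_EFFICIENCY,
    e_target: float = DEFAULT_EFFICIENCY,
) -> float:
    """(E_ref ^ Cp_ref) / (E_target ^ Cp_target)."""
    for cp in (cp_ref, cp_target):
        if not (0 < cp <= 45):
            raise ValueError(f"Cp {cp} outside (0, 45]")
    for e in (e_ref, e_target):
        if not (1 < e <= 2):
            raise ValueError(f"efficiency {e} outside (1, 2]")
    return (e_ref**cp_ref) / (e_target**cp_target)


def collapse_triplicates(record: QpcrRecord) -> tuple[float, float, bool]:
    """Mean replicate Cp, replicate SD, and an SD > 0.5 cycle flag.

    A single replicate yields SD 0 with the flag raised (spread unknowable).
    """
    cps = np.asarray(record.cp_values, dtype=float)
    cps = cps[~np.isnan(cps)]
    if cps.size == 0:
        raise ValueError(f"no usable Cp replicates for {record.sample_id}/{record.gene}")
    mean = float(cps.mean())
    if cps.size == 1:
        return mean, 0.0, True
    sd = float(cps.std(ddof=1))
    return mean, sd, sd > CP_SD_FLAG


def dermal_proportion(head: float, body_parts: dict[str, float]) -> float:
    """sum(dermal) / (head + sum(dermal)), nudged inside (0, 1)."""
    missing = [t for t in DERMAL_TISSUES if t not in body_parts]
    if missing:
        raise ValueError(f"missing dermal tissue ratio(s): {missing}")
    if head <= 0 or any(v <= 0 for v in body_parts.values()):
        raise ValueError("expression ratios must be strictly positive")
    body = sum(body_parts[t] for t in DERMAL_TISSUES)
    p = body / (head + body)
    return float(np.clip(p, BOUNDARY_NUDGE, 1 - BOUNDARY_NUDGE))


# --------------------------------------------------------------------------
# beta regression: logit mean submodel, constant precision phi


#: Bound on log(phi): degenerate (zero-spread) data push phi to infinity;
#: the fit then converges at this cap instead of overflowing.
GAMMA_MAX = 25.0


def _beta_loglik(y: np.ndarray, mu: np.ndarray, phi: float) -> float:
    a = mu * phi
    b = (1 - mu) * phi
    return float(
        np.sum(
            gammaln(phi) - gammaln(a) - gammaln(b)
            + (a - 1) * np.log(y) + (b - 1) * np.log1p(-y)
        )
    )


def _beta_grad(y: np.ndarray, X: np.ndarray, beta: np.ndarray, gamma: float) -> np.ndarray:
    phi = np.exp(min(gamma, GAMMA_MAX))
    mu = 1.0 / (1.0 + np.exp(-X @ beta))
    ystar = np.log(y) - np.log1p(-y)
    mustar = psi(mu * phi) - psi((1 - mu) * phi)
    g_beta = X.T @ (phi * (ystar - mustar) * mu * (1 - mu))
    g_phi = np.sum(
        psi(phi) - mu * psi(mu * phi) - (1 - mu) * psi((1 - mu) * phi)
        + mu * np.log(y) + (1 - mu) * np.log1p(-y)
    )
    return np.append(g_beta, g_phi * phi)  # chain rule for gamma = log(phi)


def _fit_beta_ml(
    y: np.ndarray, X: np.ndarray, max_iter: int = 200, tol: float = 1e-10
) -> tuple[np.ndarray, np.ndarray, float, list[float]]:
    """Newton iterations on (beta, log phi); returns params, SEs, loglik, trace."""
    # moment-based starting values
    logit_y = np.log(y) - np.log1p(-y)
    beta0, *_ = np.linalg.lstsq(X, logit_y, rcond=None)
    mu0 = 1.0 / (1.0 + np.exp(-X @ beta0))
    resid_var = max(np.var(y - mu0, ddof=X.shape[1]), 1e-6)
    phi0 = max(np.mean(mu0 * (1 - mu0)) / resid_var - 1.0, 1.0)
    theta = np.append(beta0, min(np.log(phi0), GAMMA_MAX))

    def ll(t: np.ndarray) -> float:
        mu = 1.0 / (1.0 + np.exp(-X @ t[:-1]))
        mu = np.clip(mu, 1e-12, 1 - 1e-12)
        return _beta_loglik(y, mu, np.exp(min(t[-1], GAMMA_MAX)))

    trace = [ll(theta)]
    for _ in range(max_iter):
        grad = _beta_grad(y, X, theta[:-1], theta[-1])
        hess = approx_hess(theta, ll)
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = -grad  # fall back to gradient ascent
        new = theta - step  # Newton on the (concave near optimum) loglik
        # damp until the likelihood does not decrease
        damp = 1.0
        while ll(new) < trace[-1] - 1e-12 and damp > 1e-8:
            damp /= 2.0
            new = theta - damp * step
        new[-1] = min(new[-1], GAMMA_MAX)
        theta = new
        trace.append(ll(theta))
        if abs(trace[-1] - trace[-2]) < tol:
            break
    else:
        raise RuntimeError(
            f"beta regression did not converge in {max_iter} iterations; "
            f"log-likelihood trace: {trace}"
        )
    hess = approx_hess(theta, ll)
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return theta, se, trace[-1], trace


def beta_regression(
    proportions: list[DermalProportion] | pd.DataFrame,
    predictor: str = "stage",
    include_predictor: bool = True,
) -> ModelFit:
    """Beta regression of proportions on a two-level predictor.

    Mean submodel logit(mu) = b0 + b1 * level, constant precision phi.
    Maximum likelihood by damped Newton iterations; Wald z for each
    coefficient.  Set ``include_predictor=False`` for the intercept-only
    reduction.
    """
    if isinstance(proportions, pd.DataFrame):
        df = proportions
        y = df["proportion"].to_numpy(dtype=float)
        levels = df[predictor].astype(str).to_numpy()
    else:
        y = np.array([p.proportion for p in proportions])
        levels = np.array([getattr(p, predictor) for p in proportions])
    if len(y) < 6:
        raise ValueError("need at least 6 proportions")
    if np.any(y <= 0) or np.any(y >= 1):
        raise ValueError("proportions must lie strictly inside (0, 1)")
    names = ["intercept"]
    if include_predictor:
        uniq = sorted(set(levels))
        if len(uniq) != 2:
            raise ValueError(f"predictor must have exactly 2 levels, got {uniq}")
        X = np.column_stack([np.ones_like(y), (levels == uniq[1]).astype(float)])
        names.append(f"{predictor}[{uniq[1]}]")
    else:
        X = np.ones((len(y), 1))
    theta, se, loglik, trace = _fit_beta_ml(y, X)
    k = X.shape[1]
    est = np.append(theta[:k], np.exp(theta[k]))
    ses = np.append(se[:k], np.nan)  # phi SE on the log scale, not reported
    z = np.append(theta[:k] / se[:k], np.nan)
    import scipy.stats

    p = np.append(2 * scipy.stats.norm.sf(np.abs(theta[:k] / se[:k])), np.nan)
    terms = pd.DataFrame(
        {"estimate": est, "se": ses, "z": z, "p_value": p},
        index=names + ["phi"],
    )
    return ModelFit(
        family="beta_regression",
        terms=terms,
        n_obs=len(y),
        df_resid=len(y) - k - 1,
        diagnostics={"loglik": loglik, "trace": trace},
    )


def stage_contrast(expressions: pd.DataFrame, value: str = "ratio") -> ModelFit:
    """Two-level linear model of log10 expression on stage.

    Sign convention: the stage coefficient is mean(larva) - mean(adult)
    (adult is the reference level).  Returns the t statistic for stage.
    """
    import statsmodels.formula.api as smf

    df = expressions.copy()
    vals = df[value].astype(float)
    if (vals <= 0).any():
        raise ValueError("expression values must be > 0 for log10")
    df["_y"] = np.log10(vals)
    fit = smf.ols("_y ~ C(stage, Treatment(reference='adult'))", data=df).fit()
    stage_term = [t for t in fit.params.index if t != "Intercept"][0]
    terms = pd.DataFrame(
        {
            "estimate": fit.params,
            "se": fit.bse,
            "t": fit.tvalues,
            "p_value": fit.pvalues,
        }
    ).rename(index={stage_term: "stage[larva]"})
    return ModelFit(
        family="gaussian_lm",
        terms=terms,
        n_obs=int(fit.nobs),
        df_resid=int(fit.df_resid),
    )


# --------------------------------------------------------------------------
# table-level helpers used by the pipeline


def expression_table(qpcr: pd.DataFrame, efficiency: float = DEFAULT_EFFICIENCY) -> pd.DataFrame:
    """Long Cp table -> per (sample, tissue, gene) relative-expression ratios.

    Expects columns sample, stage, tissue, gene, rep, cp; the reference
    gene must be present for every (sample, tissue).
    """
    mean_cp = (
        qpcr.groupby(["sample", "stage", "tissue", "gene"], sort=False)["cp"]
        .mean()
        .reset_index()
    )
    ref = mean_cp[mean_cp["gene"] == REFERENCE_GENE].rename(columns={"cp": "cp_ref"})
    targets = mean_cp[mean_cp["gene"] != REFERENCE_GENE]
    merged = targets.merge(
        ref[["sample", "tissue", "cp_ref"]], on=["sample", "tissue"], how="left"
    )
    if merged["cp_ref"].isna().any():
        bad = merged.loc[merged["cp_ref"].isna(), ["sample", "tissue"]].drop_duplicates()
        raise ValueError(f"reference gene missing for: {bad.to_dict('records')}")
    merged["ratio"] = [
        relative_expression(row.cp_ref, row.cp, efficiency, efficiency)
        for row in merged.itertuples()
    ]
    return merged[["sample", "stage", "tissue", "gene", "ratio"]]


def dermal_proportion_table(ratios: pd.DataFrame) -> pd.DataFrame:
    """Per (sample, gene) dermal proportion from a ratio table."""
    rows = []
    for (sample, stage, gene), grp in ratios.groupby(["sample", "stage", "gene"], sort=False):
        by_tissue = dict(zip(grp["tissue"], grp["ratio"]))
        if HEAD_TISSUE not in by_tissue:
            raise ValueError(f"missing head tissue for sample {sample}, gene {gene}")
        p = dermal_proportion(
            by_tissue[HEAD_TISSUE], {t: by_tissue[t] for t in DERMAL_TISSUES if t in by_tissue}
        )
        rows.append({"sample": sample, "stage": stage, "gene": gene, "proportion": p})
    return pd.DataFrame(rows)
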