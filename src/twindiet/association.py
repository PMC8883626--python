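"""Mixed-effect association of eating behaviours with intake and anthropometry.

Outcomes (weight, BMI, energy, energy-adjusted macronutrients and fibre) are
regressed on a behaviour (breakfast consumer status or eating-window length)
with age and total energy as fixed covariates and random intercepts for
family and zygosity (crossed, since zygosity is not nested in family).
Fits use maximum likelihood so the behaviour term can be tested against the
null model by a likelihood-ratio chi-square.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "LMMFit",
    "fit_random_intercept_lmm",
    "lrt_vs_null",
    "behaviour_association_table",
]


@dataclass
class LMMFit:
    outcome: str
    fixed_effects: pd.DataFrame  # name, estimate, se, ci_low, ci_high
    random_variances: dict[str, float]
    residual_variance: float
    loglik: float
    n_obs: int
    n_params: int
    formula: str
    converged: bool = True
    extras: dict = field(default_factory=dict)


def fit_random_intercept_lmm(
    data: pd.DataFrame,
    outcome: str,
    fixed: list[str],
    groups: list[str] = ("family_id", "zygosity"),
) -> LMMFit:
    """Gaussian LMM with independent (crossed) random intercepts per grouping factor.

    Fitted by maximum likelihood (not REML) via variance components on a
    single overall group, which accommodates crossed factors.  Rows with
    missing outcome or covariates are dropped (listwise).  A grouping factor
    with no between-group variance simply gets variance ~0, not an error.
    """
    cols = [outcome, *fixed, *groups]
    work = data[cols].dropna().copy()
    if len(work) < len(fixed) + 3:
        raise ValueError("too few complete rows")
    work["_one"] = 1
    for g in groups:
        if work[g].nunique() < 2:
            raise ValueError(f"grouping factor {g!r} needs >= 2 levels")

    rhs = " + ".join(fixed) if fixed else "1"
    formula = f"{outcome} ~ {rhs}"
    vc = {g: f"0 + C({g})" for g in groups}
    model = smf.mixedlm(formula, data=work, groups="_one", vc_formula=vc, re_formula="0")
    # rank check on the fixed design
    X = model.exog
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient fixed-effects design")
    # boundary fits (a variance component at 0) are legitimate here, so the
    # optimizer's boundary/Hessian warnings are expected noise; gradient
    # methods occasionally stall near the boundary, so keep the best
    # likelihood across optimizers
    res = None
    with np.errstate(all="ignore"), warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        for method in ("bfgs", "lbfgs"):
            try:
                cand = model.fit(reml=False, method=method, maxiter=500, disp=False)
            except Exception:
                continue
            if np.isfinite(cand.llf) and (res is None or cand.llf > res.llf + 1e-9):
                res = cand
        if res is None or not res.converged:
            try:
                cand = model.fit(reml=False, method="powell", maxiter=2000, disp=False)
                if np.isfinite(cand.llf) and (res is None or cand.llf > res.llf + 1e-9):
                    res = cand
            except Exception:
                pass
    if res is None:
        raise RuntimeError("mixed-model fit failed with every optimizer")

    fe_rows = []
    for name in model.exog_names:
        est = res.fe_params[name]
        se = res.bse_fe[name]
        fe_rows.append(
            {
                "name": name,
                "estimate": float(est),
                "se": float(se),
                "ci_low": float(est - 1.96 * se),
                "ci_high": float(est + 1.96 * se),
            }
        )
    rvar = {g: float(max(res.vcomp[i], 0.0)) for i, g in enumerate(groups)}
    k = X.shape[1] + len(groups) + 1  # betas + variance components + residual
    return LMMFit(
        outcome=outcome,
        fixed_effects=pd.DataFrame(fe_rows),
        random_variances=rvar,
        residual_variance=float(res.scale),
        loglik=float(res.llf),
        n_obs=len(work),
        n_params=k,
        formula=formula,
        converged=bool(res.converged),
    )


def lrt_vs_null(full: LMMFit, null: LMMFit) -> float:
    """Likelihood-ratio p-value for the terms the full model adds to the null."""
    if full.n_obs != null.n_obs or full.outcome != null.outcome:
        raise ValueError("models must be fitted on the same data and outcome")
    df = full.n_params - null.n_params
    if df <= 0:
        # identical formulas: zero deviance by construction
        if full.formula == null.formula:
            return 1.0
        raise ValueError("null model is not nested in the full model")
    lr = max(0.0, 2.0 * (full.loglik - null.loglik))
    p = float(stats.chi2.sf(lr, df))
    return max(p, 1e-15) if p < 1e-15 else p


_DEFAULT_OUTCOMES = (
    "weight_kg",
    "bmi",
    "energy_kcal",
    "ea_protein_g",
    "ea_carbohydrate_g",
    "ea_fat_g",
    "ea_fibre_g",
)


def behaviour_association_table(
    data: pd.DataFrame,
    behaviour: str,
    outcomes: tuple[str, ...] = _DEFAULT_OUTCOMES,
    covariates: tuple[str, ...] = ("age", "energy_kcal"),
    groups: tuple[str, ...] = ("family_id", "zygosity"),
) -> pd.DataFrame:
    """Per-outcome behaviour effect: group means, effect size (+-SE), CI, LRT p.

    ``behaviour`` is a boolean (breakfast consumer) or continuous (eating
    window) column.  Energy is dropped from the covariates when it is itself
    the outcome.  Degenerate splits (an empty behaviour group) are flagged
    rather than fitted.
    """
    rows = []
    is_binary = data[behaviour].dropna().isin([0, 1, True, False]).all()
    for outcome in outcomes:
        covs = [c for c in covariates if c != outcome]
        row: dict = {"outcome": outcome, "behaviour": behaviour}
        if is_binary:
            g1 = data.loc[data[behaviour].astype(bool), outcome].dropna()
            g0 = data.loc[~data[behaviour].astype(bool), outcome].dropna()
            if len(g0) == 0 or len(g1) == 0:
                row.update({"flag": "degenerate_group", "p": np.nan})
                rows.append(row)
                continue
            row.update(
                {
                    "mean_consumer": g1.mean(),
                    "sd_consumer": g1.std(ddof=1),
                    "mean_skipper": g0.mean(),
                    "sd_skipper": g0.std(ddof=1),
                }
            )
        else:
            row.update({"mean": data[outcome].mean(), "sd": data[outcome].std(ddof=1)})
        work = data.copy()
        work["_beh"] = work[behaviour].astype(float)
        full = fit_random_intercept_lmm(work, outcome, ["_beh", *covs], list(groups))
        null = fit_random_intercept_lmm(work, outcome, list(covs), list(groups))
        beh = full.fixed_effects.set_index("name").loc["_beh"]
        row.update(
            {
                "effect": beh["estimate"],
                "se": beh["se"],
                "ci_low": beh["ci_low"],
                "ci_high": beh["ci_high"],
                "p": lrt_vs_null(full, null),
                "n": full.n_obs,
                "flag": "",
            }
        )
        rows.append(row)
    return pd.DataFrame(rows)
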