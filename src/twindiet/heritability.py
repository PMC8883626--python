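"""Univariate twin variance decomposition (ACE / AE / CE / E) by maximum likelihood.

The classical biometric model: a trait's variance is split into additive
genetic (A), common-environment (C) and unique-environment/error (E)
components.  Twin pairs are bivariate normal with common mean mu, variance
V = A + C + E, and covariance A + C for MZ pairs or 0.5*A + C for DZ pairs
(additive effects correlate fully in MZ twins and 0.5 in DZ twins; common
environment contributes equally to both).  Components are kept non-negative
by optimizing their square roots.  Model choice follows the lowest AIC,
with ties broken toward the more parsimonious model.

Traits are covariate-adjusted (age, sex, BMI) by OLS residualization and
re-standardized before fitting, so reported proportions (h2 = A/V etc.) are
on the standardized scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "ACEFit",
    "adjust_covariates",
    "build_twin_pairs",
    "fit_twin_model",
    "bootstrap_h2_ci",
    "falconer_h2",
    "select_model",
]

_MODEL_COMPONENTS = {"ACE": "ACE", "AE": "AE", "CE": "CE", "E": "E"}


@dataclass
class ACEFit:
    model: str
    varA: float
    varC: float
    varE: float
    loglik: float
    aic: float
    n_mz: int
    n_dz: int
    data_checksum: float
    ci_h2: tuple[float, float] | None = None

    @property
    def total_var(self) -> float:
        return self.varA + self.varC + self.varE

    @property
    def h2(self) -> float:
        return self.varA / self.total_var

    @property
    def c2(self) -> float:
        return self.varC / self.total_var

    @property
    def e2(self) -> float:
        return self.varE / self.total_var

    @property
    def n_params(self) -> int:
        return 1 + len(_MODEL_COMPONENTS[self.model])  # mean + free components


def adjust_covariates(trait, covariates: pd.DataFrame) -> np.ndarray:
    """OLS-residualize a trait on intercept + covariates, re-standardized.

    Sex-like string columns are coded 0/1.  Raises on a rank-deficient
    (collinear) design.
    """
    y = np.asarray(trait, dtype=float)
    X = [np.ones(len(y))]
    for col in covariates.columns:
        v = covariates[col]
        if v.dtype.kind not in "fi":
            codes, _ = pd.factorize(v, sort=True)
            X.append(codes.astype(float))
        else:
            X.append(v.to_numpy(dtype=float))
    X = np.column_stack(X)
    if len(y) < X.shape[1] + 2:
        raise ValueError("too few observations for covariate adjustment")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear covariates: design matrix is rank deficient")
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    sd = resid.std(ddof=1)
    if sd < 1e-12:
        raise ValueError("trait is fully explained by covariates; nothing to decompose")
    return resid / sd


def build_twin_pairs(
    participants: pd.DataFrame, trait: pd.Series, trait_name: str = "trait"
) -> pd.DataFrame:
    """Complete twin pairs (trait_1, trait_2, zygosity) from a per-participant trait.

    ``trait`` is indexed by participant_id.  Families without both twins
    measured are dropped; twins are ordered by participant id.
    """
    df = participants[["participant_id", "family_id", "zygosity"]].copy()
    df["value"] = df["participant_id"].map(trait)
    df = df.dropna(subset=["value"]).sort_values("participant_id")
    rows = []
    for fam, grp in df.groupby("family_id", sort=True):
        if len(grp) != 2:
            continue
        rows.append(
            {
                "family_id": fam,
                "zygosity": grp["zygosity"].iloc[0],
                "trait_1": grp["value"].iloc[0],
                "trait_2": grp["value"].iloc[1],
                "trait_name": trait_name,
            }
        )
    return pd.DataFrame(rows)


def _pair_arrays(pairs: pd.DataFrame) -> dict[str, np.ndarray]:
    out = {}
    for zyg in ("MZ", "DZ"):
        grp = pairs[pairs["zygosity"] == zyg]
        out[zyg] = grp[["trait_1", "trait_2"]].to_numpy(dtype=float)
    return out


def _loglik(mu: float, vA: float, vC: float, vE: float, arrays: dict[str, np.ndarray]) -> float:
    """Sum of bivariate-normal log densities over MZ and DZ pairs."""
    total = 0.0
    v = vA + vC + vE
    for zyg, data in arrays.items():
        if len(data) == 0:
            continue
        c = vA + vC if zyg == "MZ" else 0.5 * vA + vC
        det = v * v - c * c
        if det <= 1e-12 or v <= 1e-12:
            return -np.inf
        d1 = data[:, 0] - mu
        d2 = data[:, 1] - mu
        quad = (v * (d1**2 + d2**2) - 2.0 * c * d1 * d2) / det
        total += np.sum(-np.log(2 * np.pi) - 0.5 * np.log(det) - 0.5 * quad)
    return float(total)


def fit_twin_model(pairs: pd.DataFrame, model: str = "ACE") -> ACEFit:
    """Maximum-likelihood fit of one twin model.

    Non-negativity is enforced by optimizing square roots of the variance
    components; several moment-informed starts guard against local optima.
    Requires pairs of both zygosities (A and C are not separable otherwise).
    """
    if model not in _MODEL_COMPONENTS:
        raise ValueError(f"model must be one of {sorted(_MODEL_COMPONENTS)}")
    arrays = _pair_arrays(pairs)
    n_mz, n_dz = len(arrays["MZ"]), len(arrays["DZ"])
    if model != "E" and (n_mz < 2 or n_dz < 2):
        raise ValueError("need at least 2 pairs of each zygosity")

    flat = np.concatenate([arrays["MZ"].ravel(), arrays["DZ"].ravel()])
    mu0, var0 = float(flat.mean()), float(flat.var(ddof=1))
    r_mz = _pair_corr(arrays["MZ"])
    r_dz = _pair_corr(arrays["DZ"])
    a2_0 = float(np.clip(2 * (r_mz - r_dz), 0.05, 0.85))
    c2_0 = float(np.clip(2 * r_dz - r_mz, 0.05, 0.85 - a2_0 + 0.05))

    comps = _MODEL_COMPONENTS[model]

    def unpack(theta: np.ndarray) -> tuple[float, float, float, float]:
        mu = theta[0]
        vals = {"A": 0.0, "C": 0.0, "E": 0.0}
        for i, comp in enumerate(comps):
            vals[comp] = theta[1 + i] ** 2
        return mu, vals["A"], vals["C"], vals["E"]

    def nll(theta: np.ndarray) -> float:
        return -_loglik(*unpack(theta), arrays)

    starts = []
    for a2s, c2s in ((a2_0, c2_0), (0.3, 0.2), (0.6, 0.05), (0.05, 0.05)):
        shares = {"A": a2s, "C": c2s, "E": max(1.0 - a2s - c2s, 0.05)}
        starts.append(
            np.array([mu0] + [np.sqrt(max(shares[c], 1e-4) * var0) for c in comps])
        )

    best = None
    for x0 in starts:
        res = optimize.minimize(
            nll, x0, method="Nelder-Mead",
            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000, "adaptive": True},
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError(f"{model} fit failed to converge: {best}")

    mu, vA, vC, vE = unpack(best.x)
    ll = -best.fun
    k = 1 + len(comps)
    return ACEFit(
        model=model,
        varA=vA,
        varC=vC,
        varE=vE,
        loglik=ll,
        aic=2 * k - 2 * ll,
        n_mz=n_mz,
        n_dz=n_dz,
        data_checksum=float(np.sum(flat)),
    )


def _pair_corr(data: np.ndarray) -> float:
    if len(data) < 3:
        return 0.0
    # intraclass-style: symmetrize by double entry
    x = np.concatenate([data[:, 0], data[:, 1]])
    y = np.concatenate([data[:, 1], data[:, 0]])
    return float(np.corrcoef(x, y)[0, 1])


def bootstrap_h2_ci(
    pairs: pd.DataFrame,
    model: str = "AE",
    n_boot: int = 500,
    seed: int = 0,
    alpha: float = 0.05,
) -> tuple[float, float]:
    """Percentile bootstrap CI for h2, resampling pairs within zygosity."""
    rng = np.random.default_rng(seed)
    mz = pairs[pairs["zygosity"] == "MZ"]
    dz = pairs[pairs["zygosity"] == "DZ"]
    h2s = []
    for _ in range(n_boot):
        bs = pd.concat(
            [
                mz.sample(len(mz), replace=True, random_state=rng.integers(2**31)),
                dz.sample(len(dz), replace=True, random_state=rng.integers(2**31)),
            ],
            ignore_index=True,
        )
        try:
            h2s.append(fit_twin_model(bs, model).h2)
        except (ValueError, RuntimeError):
            continue
    lo, hi = np.quantile(h2s, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


def falconer_h2(r_mz: float, r_dz: float) -> tuple[float, bool]:
    """Falconer's moment estimate 2*(rMZ - rDZ), clipped to [0, 1].

    Returns (estimate, clipped_flag).
    """
    for r in (r_mz, r_dz):
        if not -1.0 <= r <= 1.0:
            raise ValueError("correlations must lie in [-1, 1]")
    raw = 2.0 * (r_mz - r_dz)
    clipped = not 0.0 <= raw <= 1.0
    return float(np.clip(raw, 0.0, 1.0)), clipped


def select_model(fits: list[ACEFit]) -> ACEFit:
    """Lowest-AIC fit; exact ties go to the model with fewer parameters.

    All fits must come from the same pair data (checked via pair counts and
    a trait checksum).
    """
    if len(fits) < 2:
        raise ValueError("need at least two fits to select among")
    ref = fits[0]
    for f in fits[1:]:
        if (f.n_mz, f.n_dz) != (ref.n_mz, ref.n_dz) or not np.isclose(
            f.data_checksum, ref.data_checksum
        ):
            raise ValueError("fits were computed on different data")
    return min(fits, key=lambda f: (round(f.aic, 9), f.n_params))
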