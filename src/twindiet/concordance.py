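"""Agreement between acute (EFR) and habitual (FFQ) dietary assessments.

Three complementary views: per-nutrient Spearman rank correlation,
Bland-Altman mean difference with 95% limits of agreement, and Procrustes
rotational agreement between principal-coordinate configurations of the two
nutrient matrices, with a Monte-Carlo permutation test (999 permutations by
default; p-values follow the add-one rule and therefore bottom out at
1/(n_perm + 1) = 0.001).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "PairedProfiles",
    "ProcrustesResult",
    "BlandAltman",
    "pair_closest",
    "spearman_matrix",
    "bland_altman",
    "pcoa",
    "procrustes_test",
    "nutrient_configuration",
]


@dataclass
class PairedProfiles:
    participant_ids: list
    efr: pd.DataFrame  # rows aligned with ffq
    ffq: pd.DataFrame
    days_between: np.ndarray


@dataclass
class ProcrustesResult:
    m2: float
    rotation: np.ndarray
    n_perm: int
    p_value: float


@dataclass
class BlandAltman:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    averages: np.ndarray
    differences: np.ndarray


def pair_closest(
    efrs: pd.DataFrame,
    ffqs: pd.DataFrame,
    efr_date: str = "record_date",
    ffq_date: str = "ffq_date",
) -> PairedProfiles:
    """Retain one EFR and one FFQ per participant, minimizing |date difference|.

    Ties are broken toward the earliest EFR date, then the earliest FFQ date.
    Participants present in only one table are omitted.
    """
    efrs = efrs.assign(_d=pd.to_datetime(efrs[efr_date]))
    ffqs = ffqs.assign(_d=pd.to_datetime(ffqs[ffq_date]))
    shared = sorted(set(efrs["participant_id"]) & set(ffqs["participant_id"]))
    e_rows, f_rows, days = [], [], []
    for pid in shared:
        e = efrs[efrs["participant_id"] == pid]
        f = ffqs[ffqs["participant_id"] == pid]
        best = None
        for _, er in e.sort_values("_d").iterrows():
            for _, fr in f.sort_values("_d").iterrows():
                gap = abs((er["_d"] - fr["_d"]).days)
                if best is None or gap < best[0]:
                    best = (gap, er, fr)
        gap, er, fr = best
        e_rows.append(er.drop("_d"))
        f_rows.append(fr.drop("_d"))
        days.append(gap)
    return PairedProfiles(
        participant_ids=shared,
        efr=pd.DataFrame(e_rows).reset_index(drop=True),
        ffq=pd.DataFrame(f_rows).reset_index(drop=True),
        days_between=np.array(days),
    )


def spearman_matrix(paired: PairedProfiles, nutrient_cols: list[str]) -> pd.DataFrame:
    """Tie-corrected Spearman rho and two-sided p per nutrient (pairwise-complete)."""
    rows = []
    for col in nutrient_cols:
        x = pd.to_numeric(paired.efr[col], errors="coerce")
        y = pd.to_numeric(paired.ffq[col], errors="coerce")
        ok = x.notna() & y.notna()
        if ok.sum() < 4 or x[ok].nunique() < 2 or y[ok].nunique() < 2:
            rows.append({"nutrient": col, "rho": np.nan, "p": np.nan, "n": int(ok.sum())})
            continue
        rho, p = stats.spearmanr(x[ok], y[ok])
        rows.append({"nutrient": col, "rho": rho, "p": p, "n": int(ok.sum())})
    return pd.DataFrame(rows)


def bland_altman(x, y) -> BlandAltman:
    """Bland-Altman agreement of two aligned measurements (x - y convention)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must be the same length")
    if len(x) < 2:
        raise ValueError("need at least two pairs")
    d = x - y
    mean_diff = d.mean()
    sd_diff = d.std(ddof=1)
    return BlandAltman(
        mean_diff=float(mean_diff),
        sd_diff=float(sd_diff),
        loa_low=float(mean_diff - 1.96 * sd_diff),
        loa_high=float(mean_diff + 1.96 * sd_diff),
        averages=(x + y) / 2.0,
        differences=d,
    )


def pcoa(dist: np.ndarray, k: int | None = None, tol: float = 1e-8) -> np.ndarray:
    """Classical principal-coordinates embedding of a distance matrix.

    Double-centers -0.5 * D^2, eigendecomposes, and returns coordinates on
    the axes with positive eigenvalues (descending), or the first ``k``.
    With Euclidean input this reproduces the centered data's principal
    components up to sign.
    """
    D = np.asarray(dist, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh(B)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > tol * max(vals.max(), 1.0)
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    if k is not None:
        if coords.shape[1] >= k:
            coords = coords[:, :k]
        else:
            coords = np.pad(coords, ((0, 0), (0, k - coords.shape[1])))
    return coords


def _center_scale(M: np.ndarray) -> np.ndarray:
    M = M - M.mean(axis=0)
    ss = np.sqrt((M**2).sum())
    if ss == 0:
        raise ValueError("configuration has zero spread")
    return M / ss


def _m2(Xc: np.ndarray, Yc: np.ndarray) -> tuple[float, np.ndarray]:
    # both centered + unit sum of squares; optimal rotation from the SVD
    U, s, Vt = np.linalg.svd(Yc.T @ Xc)
    return float(max(0.0, 1.0 - s.sum() ** 2)), (U @ Vt)


def procrustes_test(
    X: np.ndarray,
    Y: np.ndarray,
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
) -> ProcrustesResult:
    """Procrustes m2 with a Monte-Carlo permutation test (protest-style).

    Both configurations are centered and scaled to unit sum of squares;
    m2 = 1 - (sum of singular values of Y'X)^2, i.e. the minimized residual
    sum of squares after optimal rotation and uniform scaling.  The null
    distribution permutes the rows of Y; the add-one rule keeps
    p >= 1/(n_perm + 1).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if X.shape[0] != Y.shape[0]:
        raise ValueError("configurations must have the same number of rows")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 rows")
    # pad the narrower configuration with zero columns (shape-compatible rotation)
    width = max(X.shape[1], Y.shape[1])
    X = np.pad(X, ((0, 0), (0, width - X.shape[1])))
    Y = np.pad(Y, ((0, 0), (0, width - Y.shape[1])))

    Xc, Yc = _center_scale(X), _center_scale(Y)
    m2_obs, rotation = _m2(Xc, Yc)

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = X.shape[0]
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        m2_perm, _ = _m2(Xc, Yc[perm])
        if m2_perm <= m2_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return ProcrustesResult(m2=m2_obs, rotation=rotation, n_perm=n_perm, p_value=p)


def nutrient_configuration(matrix: pd.DataFrame | np.ndarray, k: int | None = None) -> np.ndarray:
    """Z-score nutrient columns, take Euclidean distances, embed by PCoA."""
    M = np.asarray(matrix, dtype=float)
    sd = M.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    Z = (M - M.mean(axis=0)) / sd
    return pcoa(squareform(pdist(Z)), k=k)
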