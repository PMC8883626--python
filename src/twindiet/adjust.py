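"""Residual energy adjustment (Willett method) and nutrient summaries.

A nutrient is regressed on total energy within each processing batch by
ordinary least squares; the adjusted value is the residual plus the fitted
value at the batch's mean energy.  This removes the linear association with
total intake while preserving the batch mean exactly.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["energy_residual_adjust", "adjust_profile_table", "summarize_nutrients"]


def energy_residual_adjust(
    values: np.ndarray | pd.Series,
    energy: np.ndarray | pd.Series,
    group: np.ndarray | pd.Series | None = None,
) -> np.ndarray:
    """Energy-adjusted nutrient values via the residual method, per group.

    adjusted_i = residual_i + (intercept + slope * mean(energy_group)).
    Requires >= 3 units and non-constant energy within every group.
    """
    values = np.asarray(values, dtype=float)
    energy = np.asarray(energy, dtype=float)
    if values.shape != energy.shape:
        raise ValueError("values and energy must be aligned")
    group = np.zeros(len(values)) if group is None else np.asarray(group)

    out = np.empty_like(values)
    for g in np.unique(group):
        idx = group == g
        e, v = energy[idx], values[idx]
        if idx.sum() < 3:
            raise ValueError(f"group {g!r}: need at least 3 units for adjustment")
        if np.ptp(e) == 0:
            raise ValueError(f"group {g!r}: energy is constant, slope undefined")
        X = np.column_stack([np.ones(len(e)), e])
        beta, *_ = np.linalg.lstsq(X, v, rcond=None)
        fitted = X @ beta
        out[idx] = (v - fitted) + (beta[0] + beta[1] * e.mean())
    return out


def adjust_profile_table(
    profiles: pd.DataFrame,
    nutrient_cols: list[str],
    energy_col: str = "energy_kcal",
    batch_col: str = "batch",
) -> pd.DataFrame:
    """Add ``ea_``-prefixed energy-adjusted columns to a wide nutrient table."""
    out = profiles.copy()
    for col in nutrient_cols:
        out[f"ea_{col}"] = energy_residual_adjust(
            profiles[col], profiles[energy_col], profiles[batch_col]
        )
    return out


def summarize_nutrients(profiles: pd.DataFrame, cols: list[str] | None = None) -> pd.DataFrame:
    """Mean, SD (n-1), median, min, max per nutrient column.

    With a single profile the SD is reported as 0 by convention.
    """
    if len(profiles) == 0:
        raise ValueError("no profiles to summarize")
    cols = cols or [c for c in profiles.columns if profiles[c].dtype.kind in "fi"]
    rows = []
    for c in cols:
        v = profiles[c].dropna()
        rows.append(
            {
                "nutrient": c,
                "mean": v.mean(),
                "sd": v.std(ddof=1) if len(v) > 1 else 0.0,
                "median": v.median(),
                "min": v.min(),
                "max": v.max(),
                "n": len(v),
            }
        )
    return pd.DataFrame(rows)
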