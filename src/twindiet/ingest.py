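"""EFR/FFQ ingestion: quality scoring, exclusion cascades, food-key merging.

Reporting quality is scored structurally per record on three fields —
portion size, food description, meal timing — each 0 (no information on
any entry), 1 (incomplete / present on only some entries) or 2 (complete
on every entry), summed to a 0-6 total with >= 5 deemed acceptable.

Records are excluded per processing batch by a cascade: energy floor
(500 kcal), age floor (18 y), missing demographics, basal-metabolic-rate /
energy ratio beyond mean +- 2 SD (Harris-Benedict BMR), and macronutrient
outliers beyond mean +- 2 SD.  Each excluded record carries the first
failing rule as its reason.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "QualityScore",
    "ExclusionReport",
    "parse_clock_time",
    "field_state",
    "score_quality",
    "score_quality_table",
    "harris_benedict_bmr",
    "apply_efr_exclusions",
    "apply_ffq_exclusions",
    "aggregate_food_key",
]

# original Harris-Benedict (1919) coefficients: intercept, weight, height, age
_HB_COEF = {
    "F": (655.0955, 9.5634, 1.8496, 4.6756),
    "M": (66.4730, 13.7516, 5.0033, 6.7550),
}

MACRO_COLUMNS = ["protein_g", "carbohydrate_g", "fat_g"]


def harris_benedict_bmr(sex: str, weight_kg: float, height_cm: float, age_y: float) -> float:
    """Basal metabolic rate (kcal/day), original Harris-Benedict equation."""
    if sex not in _HB_COEF:
        raise ValueError(f"sex must be 'M' or 'F', got {sex!r}")
    if min(weight_kg, height_cm, age_y) <= 0:
        raise ValueError("weight, height and age must be positive")
    b0, bw, bh, ba = _HB_COEF[sex]
    return b0 + bw * weight_kg + bh * height_cm - ba * age_y


# ---------------------------------------------------------------------------
# clock-time parsing and structural field states

_TIME_24 = re.compile(r"^\s*([01]?\d|2[0-3])[:.h]([0-5]\d)\s*$")
_TIME_12 = re.compile(r"^\s*(1[0-2]|0?[1-9])[:.]([0-5]\d)\s*(am|pm|a\.m\.|p\.m\.)\s*$", re.I)


def parse_clock_time(text) -> float | None:
    """Minutes since midnight from 'HH:MM' or 'H:MM am/pm'; None if unparseable."""
    if text is None or (isinstance(text, float) and np.isnan(text)):
        return None
    s = str(text).strip()
    if not s:
        return None
    m = _TIME_24.match(s)
    if m:
        return int(m.group(1)) * 60 + int(m.group(2))
    m = _TIME_12.match(s)
    if m:
        h = int(m.group(1)) % 12
        if m.group(3).lower().startswith("p"):
            h += 12
        return h * 60 + int(m.group(2))
    return None


_QUANTITY_WORDS = {
    "cup", "cups", "slice", "slices", "tsp", "tbsp", "teaspoon", "tablespoon",
    "glass", "mug", "bowl", "handful", "portion", "serving", "half", "quarter",
    "ml", "g", "kg", "oz", "pint", "can", "bottle", "pot", "bag", "piece", "pieces",
}


def field_state(value, kind: str) -> int:
    """Structural completeness of one entry field: 0 missing, 1 partial, 2 complete.

    Portions are complete only if they carry a quantity token (a digit or a
    measure word); times only if they parse as a clock time; descriptions if
    they are more than a single truncated word.
    """
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return 0
    s = str(value).strip()
    if not s:
        return 0
    if kind == "timing":
        return 2 if parse_clock_time(s) is not None else 1
    if kind == "portion":
        tokens = {t.strip(".,()").lower() for t in s.split()}
        has_qty = bool(re.search(r"\d", s)) or bool(tokens & _QUANTITY_WORDS)
        return 2 if has_qty else 1
    if kind == "description":
        words = re.findall(r"[A-Za-z]+", s)
        return 2 if len(words) >= 2 or (len(words) == 1 and len(words[0]) >= 8) else 1
    raise ValueError(f"unknown field kind {kind!r}")


@dataclass(frozen=True)
class QualityScore:
    portion: int
    description: int
    timing: int

    @property
    def total(self) -> int:
        return self.portion + self.description + self.timing

    @property
    def acceptable(self) -> bool:
        return self.total >= 5


def _component(states: list[int]) -> int:
    if all(s == 0 for s in states):
        return 0
    if all(s == 2 for s in states):
        return 2
    return 1


def score_quality(entries: pd.DataFrame) -> QualityScore:
    """Score one record's entries (rows of one ``record_id``)."""
    if len(entries) == 0:
        raise ValueError("cannot score an empty record")
    return QualityScore(
        portion=_component([field_state(v, "portion") for v in entries["portion_text"]]),
        description=_component([field_state(v, "description") for v in entries["description"]]),
        timing=_component([field_state(v, "timing") for v in entries["meal_time"]]),
    )


def score_quality_table(entries: pd.DataFrame) -> pd.DataFrame:
    """Quality components, total and acceptability for every record."""
    rows = []
    for rid, grp in entries.groupby("record_id", sort=True):
        q = score_quality(grp)
        rows.append(
            {
                "record_id": rid,
                "portion": q.portion,
                "description": q.description,
                "timing": q.timing,
                "total": q.total,
                "acceptable": q.acceptable,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# exclusion cascades


@dataclass
class ExclusionReport:
    kept: list
    excluded: pd.DataFrame  # columns: unit_id, reason
    thresholds: dict = field(default_factory=dict)

    @property
    def counts(self) -> pd.Series:
        if len(self.excluded) == 0:
            return pd.Series(dtype=int)
        return self.excluded["reason"].value_counts()


def _two_sd_band(values: pd.Series, mult: float = 2.0) -> tuple[float, float]:
    m, s = values.mean(), values.std(ddof=1)
    return m - mult * s, m + mult * s


def apply_efr_exclusions(
    entries: pd.DataFrame,
    participants: pd.DataFrame,
    energy_floor: float = 500.0,
    age_floor: float = 18.0,
    sd_mult: float = 2.0,
    recompute_thresholds: bool = True,
    frozen_thresholds: dict | None = None,
) -> ExclusionReport:
    """Per-batch record exclusion cascade.

    Rules, in order: (1) total energy < ``energy_floor``; (2) participant age
    < ``age_floor``; missing demographics (height/weight/age/sex needed for
    the BMR screen); (3) BMR/energy ratio beyond ``sd_mult`` SD of its batch
    mean; (4) any of protein/carbohydrate/fat beyond ``sd_mult`` SD of the
    batch mean.  When ``recompute_thresholds`` (default), each SD band is
    computed on the records surviving the earlier rules within the batch.
    Passing ``frozen_thresholds`` (a previous report's ``thresholds``) reuses
    those bands verbatim, making the cascade idempotent on its kept set.
    """
    if entries.empty:
        raise ValueError("no records to screen")
    totals = (
        entries.groupby(["record_id", "participant_id", "batch"], sort=True)[
            ["energy_kcal", *MACRO_COLUMNS]
        ]
        .sum()
        .reset_index()
    )
    unknown = set(totals["participant_id"]) - set(participants["participant_id"])
    if unknown:
        raise KeyError(f"records reference unknown participants: {sorted(unknown)[:5]}")
    df = totals.merge(participants, on="participant_id", how="left")

    excluded: list[tuple[str, str]] = []
    thresholds: dict = {}

    def drop(mask: pd.Series, reason: str, frame: pd.DataFrame) -> pd.DataFrame:
        for rid in frame.loc[mask, "record_id"]:
            excluded.append((rid, reason))
        return frame.loc[~mask]

    df = drop(df["energy_kcal"] < energy_floor, "energy_floor", df)
    df = drop(df["age"] < age_floor, "age_floor", df)
    demo_missing = df[["height_cm", "weight_kg", "age", "sex"]].isna().any(axis=1)
    df = drop(demo_missing, "missing_demographics", df)

    df = df.assign(
        bmr=[
            harris_benedict_bmr(s, w, h, a)
            for s, w, h, a in zip(df["sex"], df["weight_kg"], df["height_cm"], df["age"])
        ]
    )
    df = df.assign(bmr_ratio=df["bmr"] / df["energy_kcal"])

    def band(batch, name: str, values: pd.Series) -> tuple[float, float]:
        if frozen_thresholds is not None:
            return frozen_thresholds[(batch, name)]
        m, s = values.mean(), values.std(ddof=1)
        return m - sd_mult * s, m + sd_mult * s

    kept_parts = []
    for batch, grp in df.groupby("batch", sort=True):
        if grp.empty:
            raise ValueError(f"batch {batch} has no surviving records")
        lo, hi = band(batch, "bmr_ratio", grp["bmr_ratio"])
        thresholds[(batch, "bmr_ratio")] = (lo, hi)
        grp = drop((grp["bmr_ratio"] < lo) | (grp["bmr_ratio"] > hi), "bmr_ratio_outlier", grp)
        base = grp if recompute_thresholds else df[df["batch"] == batch]
        bad = pd.Series(False, index=grp.index)
        for col in MACRO_COLUMNS:
            lo, hi = band(batch, col, base[col])
            thresholds[(batch, col)] = (lo, hi)
            bad |= (grp[col] < lo) | (grp[col] > hi)
        grp = drop(bad, "macro_outlier", grp)
        kept_parts.append(grp)
    kept = pd.concat(kept_parts) if kept_parts else df.iloc[:0]

    return ExclusionReport(
        kept=sorted(kept["record_id"].tolist()),
        excluded=pd.DataFrame(excluded, columns=["unit_id", "reason"]),
        thresholds=thresholds,
    )


def apply_ffq_exclusions(
    ffqs: pd.DataFrame,
    participants: pd.DataFrame,
    kept_efr_participants: set,
    incomplete_cap: int = 10,
    sd_mult: float = 2.0,
) -> ExclusionReport:
    """FFQ exclusion cascade: BMR/energy ratio +- 2 SD per batch, >= 10
    incomplete items, and no surviving EFR for the participant."""
    if ffqs.empty:
        raise ValueError("no FFQs to screen")
    unknown = set(ffqs["participant_id"]) - set(participants["participant_id"])
    if unknown:
        raise KeyError(f"FFQs reference unknown participants: {sorted(unknown)[:5]}")
    df = ffqs.merge(participants, on="participant_id", how="left")
    df = df.assign(
        bmr=[
            harris_benedict_bmr(s, w, h, a)
            for s, w, h, a in zip(df["sex"], df["weight_kg"], df["height_cm"], df["age"])
        ]
    )
    df = df.assign(bmr_ratio=df["bmr"] / df["energy_kcal"])

    excluded: list[tuple[str, str]] = []
    thresholds: dict = {}
    kept_parts = []
    for batch, grp in df.groupby("batch", sort=True):
        lo, hi = _two_sd_band(grp["bmr_ratio"], sd_mult)
        thresholds[(batch, "bmr_ratio")] = (lo, hi)
        out = (grp["bmr_ratio"] < lo) | (grp["bmr_ratio"] > hi)
        for fid in grp.loc[out, "ffq_id"]:
            excluded.append((fid, "bmr_ratio_outlier"))
        grp = grp.loc[~out]
        inc = grp["n_incomplete_items"] >= incomplete_cap
        for fid in grp.loc[inc, "ffq_id"]:
            excluded.append((fid, "incomplete_items"))
        grp = grp.loc[~inc]
        no_efr = ~grp["participant_id"].isin(kept_efr_participants)
        for fid in grp.loc[no_efr, "ffq_id"]:
            excluded.append((fid, "no_matched_efr"))
        kept_parts.append(grp.loc[~no_efr])
    kept = pd.concat(kept_parts)

    return ExclusionReport(
        kept=sorted(kept["ffq_id"].tolist()),
        excluded=pd.DataFrame(excluded, columns=["unit_id", "reason"]),
        thresholds=thresholds,
    )


# ---------------------------------------------------------------------------
# food-key aggregation


def aggregate_food_key(
    variants: pd.DataFrame,
    key_map: dict[str, str],
    nutrient_cols: list[str] | None = None,
    tol: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse variant item descriptions onto canonical food-key items.

    ``variants`` has one row per raw description with nutrient columns (NaN =
    value not in the source database).  Per canonical id: the variant with
    the most complete nutrients wins; among equally complete variants each
    nutrient is averaged only where the values agree within ``tol`` relative
    difference (|a - b| / mean <= tol); disagreeing nutrients are left NaN
    and reported for manual review.

    Returns (canonical nutrient table, review table of flagged nutrients).
    """
    nutrient_cols = nutrient_cols or [
        c for c in variants.columns if c not in ("description",)
    ]
    unmapped = [d for d in variants["description"] if d not in key_map]
    if unmapped:
        raise KeyError(f"descriptions missing from the food key: {unmapped}")

    rows, flags = [], []
    work = variants.assign(_key=[key_map[d] for d in variants["description"]])
    for key, grp in work.groupby("_key", sort=True):
        completeness = grp[nutrient_cols].notna().sum(axis=1)
        best = grp.loc[completeness == completeness.max()]
        if len(best) == 1:
            merged = best.iloc[0][nutrient_cols]
        else:
            merged = {}
            for col in nutrient_cols:
                vals = best[col].dropna().to_numpy(dtype=float)
                if len(vals) == 0:
                    merged[col] = np.nan
                    continue
                centre = vals.mean()
                spread = (vals.max() - vals.min()) / centre if centre != 0 else 0.0
                if spread <= tol:
                    merged[col] = centre
                else:
                    merged[col] = np.nan
                    flags.append({"food_key_id": key, "nutrient": col, "values": vals.tolist()})
            merged = pd.Series(merged)
        rows.append({"food_key_id": key, **{c: merged[c] for c in nutrient_cols}})

    return pd.DataFrame(rows), pd.DataFrame(flags, columns=["food_key_id", "nutrient", "values"])


def relabel_entries(entries: pd.DataFrame, key_map: dict[str, str]) -> pd.DataFrame:
    """Rewrite entry descriptions to canonical food-key ids (record count unchanged)."""
    missing = sorted(set(entries["description"]) - set(key_map))
    if missing:
        raise KeyError(f"descriptions missing from the food key: {missing[:10]}")
    return entries.assign(food_key_id=[key_map[d] for d in entries["description"]])
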