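"""End-to-end pipeline: ingest -> quality -> exclusions -> behaviours ->
energy adjustment -> concordance -> co-occurrence -> heritability ->
association, with per-stage CSV outputs and a flow-count log.

Every stage is a pure function of (inputs, config, seed); running the same
configuration twice produces identical outputs.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import adjust, association, behaviours, concordance, cooccurrence, heritability, ingest
from .foods import NUTRIENT_COLUMNS
from .simulate import CohortConfig, SyntheticCohort, generate_cohort

log = logging.getLogger("twindiet")

__all__ = ["PipelineConfig", "run_pipeline"]

_MACROS = ["protein_g", "carbohydrate_g", "fat_g", "fibre_g"]


@dataclass
class PipelineConfig:
    energy_floor: float = 500.0
    age_floor: float = 18.0
    sd_mult: float = 2.0
    window_floor_h: float = 4.0
    breakfast_start_min: int = 360
    breakfast_end_min: int = 660
    breakfast_kcal_floor: float = 100.0
    n_perm: int = 999
    n_boot: int = 0  # bootstrap CI resamples for the selected twin model (0 = skip)
    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)

    def __post_init__(self) -> None:
        if min(self.energy_floor, self.age_floor, self.sd_mult, self.window_floor_h) <= 0:
            raise ValueError("thresholds must be positive")
        if self.breakfast_start_min >= self.breakfast_end_min:
            raise ValueError("breakfast window start must precede its end")


def _participant_trait(summaries: pd.DataFrame, col: str) -> pd.Series:
    """One value per participant (first record, records sorted by id)."""
    first = summaries.sort_values("record_id").groupby("participant_id", sort=True).first()
    return first[col]


def _heritability_stage(
    participants: pd.DataFrame, trait: pd.Series, name: str, n_boot: int, seed: int
) -> dict:
    merged = participants.set_index("participant_id").join(trait.rename("raw"), how="inner")
    merged = merged.dropna(subset=["raw", "age", "sex", "bmi"])
    adjusted = heritability.adjust_covariates(
        merged["raw"], merged[["age", "sex", "bmi"]]
    )
    pairs = heritability.build_twin_pairs(
        participants, pd.Series(adjusted, index=merged.index), trait_name=name
    )
    fits = [heritability.fit_twin_model(pairs, m) for m in ("ACE", "AE", "CE", "E")]
    best = heritability.select_model(fits)
    out = {
        "trait": name,
        "n_mz_pairs": best.n_mz,
        "n_dz_pairs": best.n_dz,
        "model_of_best_fit": best.model,
        "h2": best.h2,
        "c2": best.c2,
        "e2": best.e2,
        "aic": {f.model: f.aic for f in fits},
    }
    if n_boot > 0:
        out["h2_ci"] = heritability.bootstrap_h2_ci(pairs, best.model, n_boot=n_boot, seed=seed)
    return out


def run_pipeline(
    config: PipelineConfig | None = None,
    cohort: SyntheticCohort | None = None,
    outdir: str | Path | None = None,
) -> dict:
    """Run every stage on a synthetic (or supplied) cohort; return a report bundle.

    The bundle maps stage names to DataFrames/dicts; when ``outdir`` is given
    each table is also written as CSV plus a ``summary.json`` of flow counts
    and headline statistics.
    """
    cfg = config or PipelineConfig()
    if cohort is None:
        cohort = generate_cohort(cfg.cohort, seed=cfg.seed)
    bundle: dict = {"config": cfg}
    flow: dict[str, int] = {
        "participants": len(cohort.participants),
        "efr_records": cohort.efr_entries["record_id"].nunique(),
        "ffqs": len(cohort.ffq_table),
    }

    # --- quality -----------------------------------------------------------
    quality = ingest.score_quality_table(cohort.efr_entries)
    bundle["quality"] = quality
    flow["quality_acceptable"] = int(quality["acceptable"].sum())

    # --- exclusion cascade -------------------------------------------------
    efr_report = ingest.apply_efr_exclusions(
        cohort.efr_entries,
        cohort.participants,
        energy_floor=cfg.energy_floor,
        age_floor=cfg.age_floor,
        sd_mult=cfg.sd_mult,
    )
    bundle["efr_exclusions"] = efr_report
    kept_entries = cohort.efr_entries[cohort.efr_entries["record_id"].isin(efr_report.kept)]
    flow["efr_kept"] = len(efr_report.kept)
    for reason, count in efr_report.counts.items():
        flow[f"efr_excluded_{reason}"] = int(count)
    if kept_entries.empty:
        log.warning("all records excluded; downstream stages skipped")
        bundle["flow"] = flow
        _write(bundle, outdir)
        return bundle

    kept_participants = set(kept_entries["participant_id"])
    ffq_report = ingest.apply_ffq_exclusions(
        cohort.ffq_table, cohort.participants, kept_participants, sd_mult=cfg.sd_mult
    )
    bundle["ffq_exclusions"] = ffq_report
    kept_ffq = cohort.ffq_table[cohort.ffq_table["ffq_id"].isin(ffq_report.kept)]
    flow["ffq_kept"] = len(ffq_report.kept)

    # --- behaviours --------------------------------------------------------
    beh = behaviours.behaviour_table(kept_entries)
    beh = behaviours.filter_implausible_windows(beh, cfg.window_floor_h)
    bundle["behaviours"] = beh
    flow["behaviour_records"] = len(beh)

    # --- record totals + residual energy adjustment ------------------------
    totals = (
        kept_entries.groupby(["record_id", "participant_id", "batch"], sort=True)[
            NUTRIENT_COLUMNS
        ]
        .sum()
        .reset_index()
    )
    totals = adjust.adjust_profile_table(totals, _MACROS)
    bundle["efr_totals"] = totals
    bundle["nutrient_summary"] = adjust.summarize_nutrients(
        totals, ["energy_kcal", *_MACROS]
    )

    # --- concordance -------------------------------------------------------
    efr_dated = totals.merge(
        kept_entries[["record_id", "record_date"]].drop_duplicates(), on="record_id"
    )
    kept_ffq = adjust.adjust_profile_table(kept_ffq, _MACROS)
    paired = concordance.pair_closest(efr_dated, kept_ffq)
    ea_cols = [f"ea_{c}" for c in _MACROS]
    bundle["spearman"] = concordance.spearman_matrix(paired, ea_cols)
    bundle["bland_altman"] = {
        c: concordance.bland_altman(paired.efr[c], paired.ffq[c]) for c in ea_cols
    }
    X = concordance.nutrient_configuration(paired.efr[["energy_kcal", *ea_cols]])
    Y = concordance.nutrient_configuration(paired.ffq[["energy_kcal", *ea_cols]])
    k = min(X.shape[1], Y.shape[1])
    bundle["procrustes"] = concordance.procrustes_test(
        X[:, :k], Y[:, :k], n_perm=cfg.n_perm, seed=cfg.seed
    )
    flow["paired_efr_ffq"] = len(paired.participant_ids)

    # --- co-occurrence -----------------------------------------------------
    bundle["cooccurrence_all_day"] = cooccurrence.build_cooccurrence(
        kept_entries, "all_day_no_beverages"
    )
    bundle["cooccurrence_breakfast"] = cooccurrence.build_cooccurrence(kept_entries, "breakfast")
    bundle["word_frequencies"] = cooccurrence.word_frequencies(kept_entries["description"])
    bundle["phrase_frequencies"] = cooccurrence.phrase_frequencies(kept_entries)

    # --- heritability of behaviours ----------------------------------------
    herit = []
    if len(beh) >= 8:
        herit.append(
            _heritability_stage(
                cohort.participants,
                _participant_trait(beh, "eating_window"),
                "eating_window",
                cfg.n_boot,
                cfg.seed,
            )
        )
        herit.append(
            _heritability_stage(
                cohort.participants,
                _participant_trait(beh, "breakfast_consumer").astype(float),
                "breakfast_consumer",
                cfg.n_boot,
                cfg.seed,
            )
        )
    bundle["heritability"] = herit

    # --- behaviour associations --------------------------------------------
    assoc_data = (
        beh.merge(totals, on=["record_id", "participant_id"])
        .merge(cohort.participants, on="participant_id")
        .sort_values("record_id")
        .groupby("participant_id", sort=True)
        .first()
        .reset_index()
    )
    assoc = []
    for behaviour_col in ("breakfast_consumer", "eating_window"):
        try:
            assoc.append(
                association.behaviour_association_table(assoc_data, behaviour_col)
            )
        except ValueError as err:
            log.warning("association for %s skipped: %s", behaviour_col, err)
    bundle["associations"] = pd.concat(assoc, ignore_index=True) if assoc else pd.DataFrame()

    bundle["flow"] = flow
    _write(bundle, outdir)
    return bundle


def _write(bundle: dict, outdir: str | Path | None) -> None:
    if outdir is None:
        return
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, obj in bundle.items():
        if isinstance(obj, pd.DataFrame) and not obj.empty:
            obj.to_csv(out / f"{name}.csv", index=False)
    if "efr_exclusions" in bundle:
        bundle["efr_exclusions"].excluded.to_csv(out / "efr_excluded.csv", index=False)
    if "ffq_exclusions" in bundle:
        bundle["ffq_exclusions"].excluded.to_csv(out / "ffq_excluded.csv", index=False)
    for key in ("cooccurrence_all_day", "cooccurrence_breakfast"):
        if key in bundle:
            bundle[key].edges.to_csv(out / f"{key}_edges.csv", index=False)

    summary: dict = {"flow": bundle.get("flow", {})}
    if "procrustes" in bundle:
        pr = bundle["procrustes"]
        summary["procrustes"] = {"m2": pr.m2, "p_value": pr.p_value, "n_perm": pr.n_perm}
    if bundle.get("heritability"):
        summary["heritability"] = [
            {k: v for k, v in h.items() if k != "aic"} for h in bundle["heritability"]
        ]
    if "config" in bundle:
        cfgd = asdict(bundle["config"])
        cfgd["cohort"].pop("completeness_probs", None)
        cfgd["cohort"].pop("trait_specs", None)
        summary["config"] = cfgd
    (out / "summary.json").write_text(json.dumps(summary, indent=2, default=_json_default))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, (np.ndarray, tuple, set)):
        return list(o)
    return str(o)
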