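"""Synthetic twin cohort generator.

Produces a fully synthetic cohort — participants with MZ/DZ family
structure, one-day timestamped estimated food records (EFRs) and FFQ
nutrient profiles — whose generating parameters are known, so every
downstream stage (quality scoring, exclusions, behaviour derivation,
concordance, networks, heritability) can be tested without real data.

Latent traits follow the classical biometric twin model: a trait is a sum
of additive-genetic (A), common-environment (C) and unique-environment (E)
standard-normal latents scaled by sqrt(a2), sqrt(c2), sqrt(e2).  MZ twins
share A fully; DZ twins share half of A (correlation 0.5); both share C.
Expected within-pair correlations are therefore a2 + c2 (MZ) and
0.5*a2 + c2 (DZ).

Defaults emulate the study conditions this package targets: ~88% female,
mean age ~59 y, mean BMI ~26, EFR energy ~1847 (SD 550) kcal, eating
window mean ~8.5 h (SD 2.6) with heritability 0.33, breakfast-consumer
prevalence ~0.88 with liability heritability 0.11.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .foods import BY_KEY, NUTRIENT_COLUMNS, FoodItem, items_for_slot

__all__ = [
    "TraitSpec",
    "CohortConfig",
    "SyntheticCohort",
    "generate_twin_trait",
    "generate_cohort",
]


@dataclass(frozen=True)
class TraitSpec:
    """ACE variance shares for one latent trait; e2 is the remainder."""

    name: str
    a2: float
    c2: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.a2 <= 1.0 and 0.0 <= self.c2 <= 1.0):
            raise ValueError(f"{self.name}: variance shares must lie in [0, 1]")
        if self.a2 + self.c2 > 1.0 + 1e-12:
            raise ValueError(f"{self.name}: a2 + c2 = {self.a2 + self.c2:.3f} exceeds 1")

    @property
    def e2(self) -> float:
        return 1.0 - self.a2 - self.c2


# field-completeness probabilities: (complete, incomplete, missing)
_DEFAULT_COMPLETENESS = {
    "portion": (0.55, 0.45, 0.0),
    "description": (0.84, 0.16, 0.0),
    "timing": (0.97, 0.03, 0.0),
}


@dataclass
class CohortConfig:
    n_mz_pairs: int = 100
    n_dz_pairs: int = 70
    prop_female: float = 0.88
    age_mean: float = 58.65
    age_sd: float = 14.07
    bmi_mean: float = 25.94
    bmi_sd: float = 4.98
    energy_mean: float = 1847.42
    energy_sd: float = 550.18
    window_mean_h: float = 8.46
    window_sd_h: float = 2.60
    breakfast_prevalence: float = 0.88
    window_a2: float = 0.33
    breakfast_a2: float = 0.11
    energy_a2: float = 0.13
    energy_c2: float = 0.10
    trait_specs: list[TraitSpec] = field(default_factory=list)
    efr_ffq_rho: float = 0.40
    ffq_coverage: float = 0.85
    multi_record_prob: float = 0.065
    completeness_probs: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(_DEFAULT_COMPLETENESS)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mz_pairs < 1 or self.n_dz_pairs < 1:
            raise ValueError("need at least one pair of each zygosity")
        for name in ("prop_female", "breakfast_prevalence", "ffq_coverage", "efr_ffq_rho"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        for fld, probs in self.completeness_probs.items():
            if len(probs) != 3 or abs(sum(probs) - 1.0) > 1e-9 or min(probs) < 0:
                raise ValueError(f"completeness_probs[{fld!r}] must be 3 probabilities summing to 1")
        # validates a2 + c2 <= 1 for the built-in traits
        TraitSpec("eating_window", self.window_a2)
        TraitSpec("breakfast_liability", self.breakfast_a2)
        TraitSpec("energy", self.energy_a2, self.energy_c2)


@dataclass
class SyntheticCohort:
    participants: pd.DataFrame
    efr_entries: pd.DataFrame
    ffq_table: pd.DataFrame
    latent: pd.DataFrame  # per-participant latent traits (generator truth)
    truth: CohortConfig

    def write_csv(self, outdir) -> None:
        from pathlib import Path

        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.participants.to_csv(out / "participants.csv", index=False)
        self.efr_entries.to_csv(out / "efr_entries.csv", index=False)
        self.ffq_table.to_csv(out / "ffq.csv", index=False)
        self.latent.to_csv(out / "latent_truth.csv", index=False)


def generate_twin_trait(
    n_mz: int,
    n_dz: int,
    a2: float,
    c2: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Simulate one standardized ACE trait for MZ and DZ twin pairs.

    Returns a frame with one row per pair: ``family_id``, ``zygosity``,
    ``trait_1``, ``trait_2``.  The trait has population mean 0 and variance 1;
    within-pair correlation is a2 + c2 for MZ pairs and 0.5*a2 + c2 for DZ.
    """
    spec = TraitSpec("trait", a2, c2)
    if n_mz < 1 or n_dz < 1:
        raise ValueError("need at least one pair of each zygosity")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    def _pairs(n: int, zyg: str) -> pd.DataFrame:
        a_shared = rng.standard_normal(n)
        c_shared = rng.standard_normal(n)
        if zyg == "MZ":
            a1 = a2_lat = a_shared
        else:
            # half the additive variance shared -> r_A = 0.5
            a1 = np.sqrt(0.5) * a_shared + np.sqrt(0.5) * rng.standard_normal(n)
            a2_lat = np.sqrt(0.5) * a_shared + np.sqrt(0.5) * rng.standard_normal(n)
        e1, e2 = rng.standard_normal(n), rng.standard_normal(n)
        sa, sc, se = np.sqrt(spec.a2), np.sqrt(spec.c2), np.sqrt(spec.e2)
        return pd.DataFrame(
            {
                "zygosity": zyg,
                "trait_1": sa * a1 + sc * c_shared + se * e1,
                "trait_2": sa * a2_lat + sc * c_shared + se * e2,
            }
        )

    out = pd.concat([_pairs(n_mz, "MZ"), _pairs(n_dz, "DZ")], ignore_index=True)
    out.insert(0, "family_id", [f"F{i:05d}" for i in range(len(out))])
    return out


# ---------------------------------------------------------------------------
# cohort assembly


def _draw_traits(cfg: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    """One standardized ACE trait column per spec, long by participant."""
    specs = [
        TraitSpec("eating_window", cfg.window_a2),
        TraitSpec("breakfast_liability", cfg.breakfast_a2),
        TraitSpec("energy", cfg.energy_a2, cfg.energy_c2),
        *cfg.trait_specs,
    ]
    frames = {}
    for spec in specs:
        wide = generate_twin_trait(cfg.n_mz_pairs, cfg.n_dz_pairs, spec.a2, spec.c2, seed=rng)
        frames[spec.name] = np.concatenate([wide["trait_1"].to_numpy(), wide["trait_2"].to_numpy()])
    n_fam = cfg.n_mz_pairs + cfg.n_dz_pairs
    fam = [f"F{i:05d}" for i in range(n_fam)]
    zyg = ["MZ"] * cfg.n_mz_pairs + ["DZ"] * cfg.n_dz_pairs
    long = pd.DataFrame(
        {
            "participant_id": [f"P{i:05d}-{t}" for t in (1, 2) for i in range(n_fam)],
            "family_id": fam * 2,
            "zygosity": zyg * 2,
            **frames,
        }
    )
    return long.sort_values("participant_id", ignore_index=True)


def _fmt_time(minutes: float) -> str:
    m = int(round(minutes)) % 1440
    return f"{m // 60:02d}:{m % 60:02d}"


def _record_field_states(rng: np.random.Generator, probs, n_entries: int) -> np.ndarray:
    """Per-entry states (2 complete, 1 partial, 0 missing) for one field of one record.

    Completeness probabilities are record-level: 'complete' means every entry
    carries the field in full, 'incomplete' a mix of complete and partial
    entries, 'missing' no entry carries it — matching how reporting quality
    is judged on whole records.
    """
    state = rng.choice(3, p=probs)
    if state == 0:
        return np.full(n_entries, 2)
    if state == 2:
        return np.zeros(n_entries, dtype=int)
    per_entry = np.where(rng.random(n_entries) < 0.6, 2, 1)
    if (per_entry == 2).all():
        per_entry[rng.integers(n_entries)] = 1
    return per_entry


_PARTIAL_PORTIONS = ["some", "a bit", "small amount", "a few"]


def _menu_for_record(
    cfg: CohortConfig,
    rng: np.random.Generator,
    window_h: float,
    consumer: bool,
) -> list[tuple[float, FoodItem]]:
    """Draw (time-in-minutes, item) pairs for one record.

    First and last intake bracket the eating window exactly.  Consumers
    start between 06:00 and 10:30 with a multi-item breakfast; skippers'
    first intake falls after 11:00 (the window includes drinks, so no
    earlier token drink is drawn).
    """
    if consumer:
        first_h = float(np.clip(rng.normal(7.7, 0.7), 6.1, 10.4))
    else:
        first_h = float(np.clip(rng.normal(11.8, 0.6), 11.05, 13.5))
    last_h = min(first_h + window_h, 23.9)
    first_m, last_m = first_h * 60, last_h * 60

    def pick(slot: str, exclude: set[str] = frozenset()) -> FoodItem:
        pool = [it for it in items_for_slot(slot) if it.key_id not in exclude]
        return pool[rng.integers(len(pool))]

    entries: list[tuple[float, FoodItem]] = []

    # --- first occasion
    if consumer:
        drink = BY_KEY["tea_black"] if rng.random() < 0.6 else BY_KEY["coffee_instant"]
        entries.append((first_m, drink))
        if rng.random() < 0.8:
            entries.append((first_m, BY_KEY["milk_semi"]))
        n_food = 2 + int(rng.random() < 0.4)
        chosen: set[str] = set()
        for _ in range(n_food):
            it = pick("breakfast", exclude=chosen)
            chosen.add(it.key_id)
            entries.append((first_m + rng.uniform(0, 10), it))
    else:
        entries.append((first_m, pick("lunch")))

    # --- midday occasion (only if it fits inside the window)
    lunch_m = rng.normal(13.1, 0.5) * 60
    if first_m + 45 < lunch_m < last_m - 45:
        salad = rng.random() < 0.35
        if salad:
            for key in ("tomato_raw", "lettuce_raw"):
                entries.append((lunch_m, BY_KEY[key]))
            if rng.random() < 0.6:
                entries.append((lunch_m, BY_KEY["cucumber_raw"]))
            entries.append((lunch_m, BY_KEY["bread_roll"]))
        else:
            chosen = set()
            for _ in range(2):
                it = pick("lunch", exclude=chosen)
                chosen.add(it.key_id)
                entries.append((lunch_m + rng.uniform(0, 10), it))

    # --- afternoon snack (often tea + milk: the dominant co-occurring pair)
    snack_m = rng.normal(16.0, 0.8) * 60
    if first_m + 30 < snack_m < last_m - 30 and rng.random() < 0.75:
        entries.append((snack_m, BY_KEY["tea_black"]))
        if rng.random() < 0.85:
            entries.append((snack_m, BY_KEY["milk_semi"]))
        if rng.random() < 0.5:
            entries.append((snack_m + 2, pick("snack")))

    # --- last occasion (dinner)
    chosen = set()
    for _ in range(2 + int(rng.random() < 0.5)):
        it = pick("dinner", exclude=chosen)
        chosen.add(it.key_id)
        entries.append((last_m - rng.uniform(0, 10), it))
    if rng.random() < 0.25:
        entries.append((last_m, BY_KEY["wine_red" if rng.random() < 0.5 else "wine_white"]))

    # pin the window ends exactly
    times = np.array([t for t, _ in entries])
    entries[int(np.argmin(times))] = (first_m, entries[int(np.argmin(times))][1])
    times = np.array([t for t, _ in entries])
    entries[int(np.argmax(times))] = (last_m, entries[int(np.argmax(times))][1])
    return [(float(np.clip(t, first_m, last_m)), it) for t, it in entries]


def _record_rows(
    cfg: CohortConfig,
    rng: np.random.Generator,
    pid: str,
    record_id: str,
    window_h: float,
    consumer: bool,
    target_energy: float,
) -> list[dict]:
    menu = _menu_for_record(cfg, rng, window_h, consumer)
    raw_energy = sum(it.energy_kcal for _, it in menu)
    scale = target_energy / raw_energy if raw_energy > 0 else 1.0

    batch = 1 if rng.random() < 0.6 else 2
    year = rng.choice([2013, 2014]) if batch == 1 else rng.choice([2016, 2017])
    date = pd.Timestamp(int(year), int(rng.integers(1, 13)), int(rng.integers(1, 29)))

    states = {
        fld: _record_field_states(rng, cfg.completeness_probs[fld], len(menu))
        for fld in ("timing", "description", "portion")
    }
    rows = []
    for j, (t, it) in enumerate(menu):
        time_txt = {
            2: _fmt_time(t),
            1: str(rng.choice(["morning", "afternoon", "evening"])),
            0: "",
        }[int(states["timing"][j])]
        desc_txt = {2: it.description, 1: it.description.split(",")[0][:4], 0: ""}[
            int(states["description"][j])
        ]
        portion_txt = {2: it.portion_text, 1: str(rng.choice(_PARTIAL_PORTIONS)), 0: ""}[
            int(states["portion"][j])
        ]
        row = {
            "participant_id": pid,
            "record_id": record_id,
            "record_date": date.date().isoformat(),
            "batch": batch,
            "typical_day": bool(rng.random() < 0.8),
            "meal_time": time_txt,
            "description": desc_txt,
            "food_key_id": it.key_id,
            "portion_text": portion_txt,
        }
        for col in NUTRIENT_COLUMNS:
            row[col] = round(getattr(it, col) * scale, 3)
        rows.append(row)
    return rows


def generate_cohort(config: CohortConfig | None = None, seed: int | None = None) -> SyntheticCohort:
    """Generate participants, EFR entries and FFQ profiles for one cohort.

    Deterministic given ``config.seed`` (or the ``seed`` override).
    """
    cfg = config or CohortConfig()
    if seed is not None:
        cfg = CohortConfig(**{**cfg.__dict__, "seed": seed})
    rng = np.random.default_rng(cfg.seed)

    latent = _draw_traits(cfg, rng)
    n = len(latent)

    # demographics: twins share age and family; MZ share sex
    n_fam = cfg.n_mz_pairs + cfg.n_dz_pairs
    fam_age = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, n_fam), 18.1, 90.0)
    fam_female_mz = rng.random(n_fam) < cfg.prop_female
    sex, age = [], []
    for i, row in latent.iterrows():
        fam_idx = int(row["family_id"][1:])
        age.append(round(fam_age[fam_idx] + rng.uniform(-0.05, 0.05), 2))
        if row["zygosity"] == "MZ":
            sex.append("F" if fam_female_mz[fam_idx] else "M")
        else:
            sex.append("F" if rng.random() < cfg.prop_female else "M")
    height = np.where(
        np.array(sex) == "F", rng.normal(163.0, 6.0, n), rng.normal(177.0, 7.0, n)
    ).round(1)
    bmi = np.clip(rng.normal(cfg.bmi_mean, cfg.bmi_sd, n), 16.0, 55.0).round(2)
    weight = (bmi * (height / 100.0) ** 2).round(2)

    participants = pd.DataFrame(
        {
            "participant_id": latent["participant_id"],
            "family_id": latent["family_id"],
            "zygosity": latent["zygosity"],
            "sex": sex,
            "age": age,
            "height_cm": height,
            "weight_kg": weight,
            "bmi": bmi,
        }
    )

    # observable traits from the latents
    window_h = np.clip(
        cfg.window_mean_h + cfg.window_sd_h * latent["eating_window"].to_numpy(), 4.2, 15.5
    )
    thresh = stats.norm.ppf(cfg.breakfast_prevalence)
    consumer = latent["breakfast_liability"].to_numpy() < thresh
    target_energy = np.clip(
        cfg.energy_mean + cfg.energy_sd * latent["energy"].to_numpy(), 520.0, 4400.0
    )
    latent = latent.assign(
        window_hours=window_h, breakfast_consumer=consumer, target_energy=target_energy
    )

    entry_rows: list[dict] = []
    for i, pid in enumerate(latent["participant_id"]):
        n_rec = 1 + int(rng.random() < cfg.multi_record_prob)
        for r in range(n_rec):
            entry_rows.extend(
                _record_rows(
                    cfg, rng, pid, f"R-{pid}-{r}", window_h[i], bool(consumer[i]), target_energy[i]
                )
            )
    efr_entries = pd.DataFrame(entry_rows)

    # FFQ: rank-correlated noisy transform of each participant's EFR totals
    totals = efr_entries.groupby("participant_id", sort=True)[NUTRIENT_COLUMNS].mean()
    has_ffq = rng.random(len(totals)) < cfg.ffq_coverage
    ffq_rows = []
    rho = cfg.efr_ffq_rho
    z = (totals - totals.mean()) / totals.std(ddof=1)
    for j, (pid, zrow) in enumerate(z.iterrows()):
        if not has_ffq[j]:
            continue
        noise = rng.standard_normal(len(NUTRIENT_COLUMNS))
        mixed = rho * zrow.to_numpy() + np.sqrt(1 - rho**2) * noise
        vals = totals.mean().to_numpy() + totals.std(ddof=1).to_numpy() * mixed
        vals = np.clip(vals, 0.05 * totals.mean().to_numpy(), None)
        incomplete = int(rng.poisson(12) if rng.random() < 0.05 else rng.poisson(2.5))
        row = {
            "participant_id": pid,
            "ffq_id": f"Q-{pid}",
            "ffq_date": pd.Timestamp(2014 + int(rng.integers(0, 2)), int(rng.integers(1, 13)), int(rng.integers(1, 29))).date().isoformat(),
            "batch": int(rng.integers(1, 4)),
            "n_incomplete_items": incomplete,
        }
        row.update({c: round(v, 3) for c, v in zip(NUTRIENT_COLUMNS, vals)})
        ffq_rows.append(row)
    ffq_table = pd.DataFrame(ffq_rows)

    return SyntheticCohort(participants, efr_entries, ffq_table, latent, cfg)
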