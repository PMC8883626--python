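import numpy as np
import pandas as pd
import pytest

from twindiet.simulate import CohortConfig, generate_cohort


def make_entries(record_specs):
    """Build an EFR entry table from a compact spec.

    record_specs: list of (record_id, participant_id, batch, entries) where
    entries is a list of dicts with any of meal_time, description,
    food_key_id, portion_text, energy_kcal and macro overrides.
    """
    rows = []
    for rid, pid, batch, entries in record_specs:
        for e in entries:
            row = {
                "participant_id": pid,
                "record_id": rid,
                "record_date": e.get("record_date", "2016-05-01"),
                "batch": batch,
                "typical_day": True,
                "meal_time": e.get("meal_time", "08:00"),
                "description": e.get("description", "Tea, black, infusion, average"),
                "food_key_id": e.get("food_key_id", "tea_black"),
                "portion_text": e.get("portion_text", "1 mug (260 ml)"),
                "energy_kcal": e.get("energy_kcal", 100.0),
                "protein_g": e.get("protein_g", 10.0),
                "carbohydrate_g": e.get("carbohydrate_g", 20.0),
                "fat_g": e.get("fat_g", 5.0),
                "fibre_g": e.get("fibre_g", 2.0),
            }
            rows.append(row)
    return pd.DataFrame(rows)


def make_participants(specs):
    """specs: list of (participant_id, age, sex) or dicts with overrides."""
    rows = []
    for i, s in enumerate(specs):
        if isinstance(s, dict):
            row = {
                "participant_id": s["participant_id"],
                "family_id": s.get("family_id", f"F{i:03d}"),
                "zygosity": s.get("zygosity", "MZ"),
                "sex": s.get("sex", "F"),
                "age": s.get("age", 30.0),
                "height_cm": s.get("height_cm", 165.0),
                "weight_kg": s.get("weight_kg", 60.0),
                "bmi": s.get("bmi", 22.0),
            }
        else:
            pid, age, sex = s
            row = {
                "participant_id": pid,
                "family_id": f"F{i:03d}",
                "zygosity": "MZ",
                "sex": sex,
                "age": age,
                "height_cm": 165.0,
                "weight_kg": 60.0,
                "bmi": 22.0,
            }
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_cohort():
    """A modest synthetic cohort shared across tests (read-only)."""
    return generate_cohort(CohortConfig(n_mz_pairs=60, n_dz_pairs=40, seed=42))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
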