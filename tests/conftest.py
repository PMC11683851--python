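import numpy as np
import pandas as pd
import pytest

from pewsval.records import (
    CAP_REFILL_LEVELS, CONSCIOUSNESS_LEVELS, HIV_LEVELS, PATIENT_FIELDS,
)
from pewsval.registry import default_registry
from pewsval.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def cohort():
    """Small default-condition synthetic cohort shared across tests."""
    return generate_cohort(CohortConfig(n_children=800, seed=7))


@pytest.fixture()
def normal_patient():
    """A well child: every warning sign absent, vitals unremarkable."""
    return {
        "child_id": "well", "site": "site_1", "age_months": 12,
        "muac_cm": 13.5, "oedema": False, "waz": -0.5,
        "temperature_c": 36.8, "heart_rate": 120, "resp_rate": 35,
        "spo2_pct": 98, "cap_refill": "lt2s", "consciousness": "alert",
        "convulsions": False, "deep_breathing": False,
        "chest_indrawing": False, "wheeze": False, "stridor": False,
        "prostration": False, "unable_to_drink": False,
        "vomits_everything": False, "refusal_to_feed": False,
        "hiv_status": "negative", "diarrhoea": False,
        "pneumonia_lrti": False, "malaria": False, "severe_anaemia": False,
    }


@pytest.fixture()
def worst_patient():
    """A maximally deranged child: every item's predicate true."""
    return {
        "child_id": "worst", "site": "site_1", "age_months": 10,
        "muac_cm": 10.0, "oedema": True, "waz": -4.0,
        "temperature_c": 40.0, "heart_rate": 220, "resp_rate": 90,
        "spo2_pct": 80, "cap_refill": "gt3s", "consciousness": "unresponsive",
        "convulsions": True, "deep_breathing": True,
        "chest_indrawing": True, "wheeze": True, "stridor": True,
        "prostration": True, "unable_to_drink": True,
        "vomits_everything": True, "refusal_to_feed": True,
        "hiv_status": "positive", "diarrhoea": True,
        "pneumonia_lrti": True, "malaria": True, "severe_anaemia": True,
    }


def random_patient_frame(n: int, seed: int, missing_rate: float = 0.0) -> pd.DataFrame:
    """Random valid admission records for property tests."""
    rng = np.random.default_rng(seed)
    df = pd.DataFrame({
        "child_id": [f"r{i}" for i in range(n)],
        "site": rng.choice([f"site_{k}" for k in range(1, 10)], n),
        "age_months": rng.integers(2, 24, n).astype(float),
        "muac_cm": np.round(rng.uniform(8.0, 16.0, n), 1),
        "oedema": rng.random(n) < 0.15,
        "waz": np.round(rng.uniform(-6, 2, n), 2),
        "temperature_c": np.round(rng.uniform(34.0, 41.5, n), 1),
        "heart_rate": np.round(rng.uniform(60, 230, n)),
        "resp_rate": np.round(rng.uniform(15, 120, n)),
        "spo2_pct": np.round(rng.uniform(55, 100, n)),
        "cap_refill": rng.choice(list(CAP_REFILL_LEVELS), n),
        "consciousness": rng.choice(list(CONSCIOUSNESS_LEVELS), n),
        "hiv_status": rng.choice(list(HIV_LEVELS), n),
    })
    for b in ("convulsions", "deep_breathing", "chest_indrawing", "wheeze",
              "stridor", "prostration", "unable_to_drink",
              "vomits_everything", "refusal_to_feed", "diarrhoea",
              "pneumonia_lrti", "malaria", "severe_anaemia"):
        df[b] = rng.random(n) < 0.5
    if missing_rate > 0:
        for col in ("temperature_c", "heart_rate", "resp_rate", "spo2_pct",
                    "waz", "cap_refill", "muac_cm"):
            mask = rng.random(n) < missing_rate
            df.loc[mask, col] = np.nan if df[col].dtype != object else None
    return df
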