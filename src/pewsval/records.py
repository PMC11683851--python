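"""Admission-record schema and cohort table I/O.

The canonical in-memory container is a :class:`pandas.DataFrame` with one
row per admitted child and the column names below.  Missing values are
plain NaN/NA (empty cells in CSV).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

#: name -> kind; kind drives CSV parsing and validation.
PATIENT_FIELDS: dict[str, str] = {
    "child_id": "id",
    "site": "category",
    "age_months": "number",
    "muac_cm": "number",
    "oedema": "bool",
    "waz": "number",
    "temperature_c": "number",
    "heart_rate": "number",
    "resp_rate": "number",
    "spo2_pct": "number",
    "cap_refill": "category",
    "consciousness": "category",
    "convulsions": "bool",
    "deep_breathing": "bool",
    "chest_indrawing": "bool",
    "wheeze": "bool",
    "stridor": "bool",
    "prostration": "bool",
    "unable_to_drink": "bool",
    "vomits_everything": "bool",
    "refusal_to_feed": "bool",
    "hiv_status": "category",
    "diarrhoea": "bool",
    "pneumonia_lrti": "bool",
    "malaria": "bool",
    "severe_anaemia": "bool",
    "stratum": "category",
    "pop_weight": "number",
    "died_inpatient": "bool",
    "day_of_death": "number",
    "day_of_discharge": "number",
}

CAP_REFILL_LEVELS = ("lt2s", "s2to3", "gt3s")
CONSCIOUSNESS_LEVELS = ("alert", "verbal", "pain", "unresponsive")
HIV_LEVELS = ("positive", "negative", "unknown")
STRATA = ("none", "moderate", "severe")

#: syndrome flag columns usable as disease-restriction filters
SYNDROMES = ("diarrhoea", "pneumonia_lrti", "malaria", "severe_anaemia")

#: age bands (months, half-open [lo, hi)) used in the age sensitivity analysis
AGE_BANDS = ((2, 6), (6, 12), (12, 18), (18, 24))

_BOOL_MAP = {
    "true": True, "false": False, "1": True, "0": False,
    "yes": True, "no": False, "t": True, "f": False,
}


def _coerce_bool(s: pd.Series) -> pd.Series:
    if s.dtype == bool:
        return s.astype("boolean")
    out = s.astype("string").str.strip().str.lower().map(_BOOL_MAP)
    return out.astype("boolean")


def validate_cohort(df: pd.DataFrame, require_outcome: bool = True) -> pd.DataFrame:
    """Validate a cohort table against the record schema and invariants.

    Returns the (coerced) frame; raises ``ValueError`` on a violation.
    """
    missing_cols = [c for c in PATIENT_FIELDS if c not in df.columns]
    # outcome/weight columns are optional for scoring-only use
    optional = {"pop_weight", "died_inpatient", "day_of_death", "day_of_discharge",
                "stratum"}
    if not require_outcome:
        missing_cols = [c for c in missing_cols if c not in optional]
    if missing_cols:
        raise ValueError(f"cohort table is missing required columns: {missing_cols}")

    df = df.copy()
    for col, kind in PATIENT_FIELDS.items():
        if col not in df.columns:
            continue
        if kind == "bool":
            df[col] = _coerce_bool(df[col])
        elif kind == "number":
            df[col] = pd.to_numeric(df[col], errors="coerce")

    age = df["age_months"]
    if ((age < 2) | (age > 23)).any():
        raise ValueError("age_months outside the 2-23 month admission window")
    if (df["muac_cm"] <= 0).any():
        raise ValueError("muac_cm must be positive")
    spo2 = df["spo2_pct"].dropna()
    if ((spo2 < 0) | (spo2 > 100)).any():
        raise ValueError("spo2_pct outside [0, 100]")
    for col, levels in (("cap_refill", CAP_REFILL_LEVELS),
                        ("consciousness", CONSCIOUSNESS_LEVELS),
                        ("hiv_status", HIV_LEVELS)):
        bad = set(df[col].dropna().unique()) - set(levels)
        if bad:
            raise ValueError(f"{col} has unknown levels {sorted(bad)}")
    if "pop_weight" in df.columns and df["pop_weight"].notna().any():
        if (df["pop_weight"].dropna() <= 0).any():
            raise ValueError("pop_weight must be positive")
    if "died_inpatient" in df.columns and df["died_inpatient"].notna().any():
        died = df["died_inpatient"].fillna(False).astype(bool)
        if df.loc[died, "day_of_death"].isna().any():
            raise ValueError("died_inpatient set but day_of_death absent")
        completed = died | df["day_of_discharge"].notna()
        if (~completed).any() and df["day_of_death"].isna().all():
            pass  # in-progress records allowed only when explicitly scoring-only
    return df


def read_cohort(path, require_outcome: bool = True) -> pd.DataFrame:
    """Read a per-child admission CSV (empty cells = missing) and validate it."""
    df = pd.read_csv(path, comment="#", dtype={"child_id": str, "site": str})
    return validate_cohort(df, require_outcome=require_outcome)


def write_cohort(df: pd.DataFrame, path, header_lines: Iterable[str] = ()) -> None:
    """Write a cohort CSV, optionally preceded by '# ' metadata lines."""
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, index=False)


def age_band_label(age_months: float) -> str:
    for lo, hi in AGE_BANDS:
        if lo <= age_months < hi:
            return f"{lo}-{hi}m"
    if age_months == AGE_BANDS[-1][1]:
        return f"{AGE_BANDS[-1][0]}-{AGE_BANDS[-1][1]}m"
    raise ValueError(f"age {age_months} months outside 2-24m bands")


def age_band_column(df: pd.DataFrame) -> pd.Series:
    """Vectorised age-band labels for the age sensitivity analysis."""
    bins = [b[0] for b in AGE_BANDS] + [AGE_BANDS[-1][1]]
    labels = [f"{lo}-{hi}m" for lo, hi in AGE_BANDS]
    return pd.cut(df["age_months"], bins=bins, labels=labels,
                  right=False, include_lowest=True).astype(str)
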