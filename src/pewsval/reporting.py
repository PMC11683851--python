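"""Publication-shaped report tables.

Everything is CSV-first: the main weighted report mirrors the shape of a
per-score operating-point table (range, cutoff, AUC with CI, sensitivity,
specificity, weighted confusion counts, PPV/NPV, likelihood ratios,
deaths), with companion per-stratum, per-site, per-age-band, disease-
restricted and fixed-horizon reports and per-cutoff Youden scan tables.
Plots, if wanted, are renderings of these CSVs; no analysis depends on
graphics.

All randomness (bootstrap CIs) fans out deterministically from one base
seed, so re-running with the same cohort, definitions and configuration
reproduces every file byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from pewsval.records import AGE_BANDS, PATIENT_FIELDS, STRATA
from pewsval.registry import ScoreDefinition, score_frame
from pewsval.metrics import (
    confusion_at_cutoff, metrics_from_counts, validate_score,
    youden_optimal_cutoff,
)

__all__ = [
    "build_main_report", "build_subgroup_reports", "build_horizon_reports",
    "build_target_population_report", "cutoff_scan", "round_for_display",
    "write_report", "derive_seed", "config_hash",
]

REPORT_COLUMNS = [
    "score", "range", "subgroup", "horizon", "weighted", "evaluable", "reason",
    "cutoff", "cutoff_source", "auc", "ci_low", "ci_high", "band",
    "sensitivity", "specificity", "tp", "fp", "tn", "fn",
    "ppv_pct", "npv_pct", "lr_pos", "lr_neg", "deaths", "n_children",
]

DEFAULT_HORIZONS = (2, 5, 7, 30)


def derive_seed(base_seed: int, *tags) -> int:
    """Deterministic per-task sub-seed from one base seed."""
    h = hashlib.sha256(repr((base_seed,) + tags).encode()).digest()
    return int.from_bytes(h[:4], "big") % (2 ** 31)


def config_hash(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _rows_to_frame(rows: list[dict]) -> pd.DataFrame:
    df = pd.DataFrame(rows)
    for col in REPORT_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    return df[REPORT_COLUMNS]


def build_main_report(registry: Mapping[str, ScoreDefinition],
                      cohort: pd.DataFrame, weighted: bool = True,
                      n_boot: int = 2000, seed: int = 0,
                      subgroup: Optional[Mapping[str, object]] = None,
                      horizon: Optional[int] = None) -> pd.DataFrame:
    """One row per registered score, sorted by descending AUC.

    The full-cohort report is population-weighted; every row shares the
    same weighted deaths (tp+fn) and survivors (tn+fp) denominators.
    """
    rows = []
    for i, definition in enumerate(registry.values()):
        rows.append(validate_score(
            definition, cohort, weighted=weighted, subgroup=subgroup,
            horizon=horizon, n_boot=n_boot,
            seed=derive_seed(seed, definition.name, subgroup and tuple(
                sorted(subgroup.items())), horizon)))
    df = _rows_to_frame(rows)
    return df.sort_values(["evaluable", "auc"], ascending=[False, False],
                          kind="mergesort").reset_index(drop=True)


def build_subgroup_reports(registry, cohort, by: str, n_boot: int = 2000,
                           seed: int = 0) -> dict[str, pd.DataFrame]:
    """Per-level reports for one stratifier.

    ``by`` is one of ``stratum``, ``site``, ``age`` or ``syndrome``.
    Stratum, site and age analyses are unweighted (each level is its own
    reference population); syndrome restrictions inherit the full-cohort
    population weights.
    """
    if by == "stratum":
        levels = [s for s in STRATA if (cohort["stratum"] == s).any()]
        key, weighted = "stratum", False
    elif by == "site":
        levels = sorted(cohort["site"].dropna().unique())
        key, weighted = "site", False
    elif by == "age":
        levels = [f"{lo}-{hi}m" for lo, hi in AGE_BANDS]
        key, weighted = "age_band", False
    elif by == "syndrome":
        levels = ["diarrhoea", "pneumonia_lrti", "malaria", "severe_anaemia"]
        key, weighted = "syndrome", True
    else:
        raise ValueError(f"unknown stratifier {by!r}")
    out = {}
    for level in levels:
        out[str(level)] = build_main_report(
            registry, cohort, weighted=weighted, n_boot=n_boot, seed=seed,
            subgroup={key: level})
    return out


def build_horizon_reports(registry, cohort,
                          horizons: Sequence[int] = DEFAULT_HORIZONS,
                          n_boot: int = 2000, seed: int = 0,
                          weighted: bool = True) -> dict[int, pd.DataFrame]:
    """Fixed-horizon mortality reports (death by day h instead of inpatient)."""
    return {int(h): build_main_report(registry, cohort, weighted=weighted,
                                      n_boot=n_boot, seed=seed, horizon=int(h))
            for h in horizons}


def build_target_population_report(registry, cohort, n_boot: int = 2000,
                                   seed: int = 0) -> pd.DataFrame:
    """Disease-restricted rows for scores designed for a specific syndrome.

    Each such score (e.g. a malaria score, or respiratory-severity indices
    designed for lower respiratory tract infection) is re-evaluated in the
    population it was designed for, inheriting the full-cohort weights;
    applicability restrictions (e.g. HIV-negative only) are enforced here.
    """
    rows = []
    for definition in registry.values():
        if definition.target_population is None:
            continue
        rows.append(validate_score(
            definition, cohort, weighted=True,
            subgroup={"syndrome": definition.target_population},
            restrict_to_applicable=True, n_boot=n_boot,
            seed=derive_seed(seed, definition.name, "target_population")))
    return _rows_to_frame(rows) if rows else pd.DataFrame(columns=REPORT_COLUMNS)


def cutoff_scan(definition: ScoreDefinition, cohort: pd.DataFrame,
                weighted: bool = True) -> pd.DataFrame:
    """Per-cutoff J/sensitivity/specificity over the score's full range.

    Returns range_max + 2 candidate rows (cutoffs range_min .. range_max+1)
    with the Youden-optimal cutoff flagged (lowest cutoff on ties).
    """
    sf = score_frame(definition, cohort)
    keep = sf["total_points"].notna()
    df, sf = cohort[keep], sf[keep]
    scores = sf["total_points"].to_numpy()
    outcomes = df["died_inpatient"].fillna(False).to_numpy(dtype=bool)
    weights = df["pop_weight"].to_numpy(dtype=float) if weighted else None
    res = youden_optimal_cutoff(scores, outcomes, weights,
                                definition.range_min, definition.range_max)
    table = res.table.copy()
    table.insert(0, "score", definition.name)
    table["optimal"] = table["cutoff"] == res.cutoff
    return table


_DISPLAY_ROUNDING = {
    "auc": 2, "ci_low": 2, "ci_high": 2,
    "sensitivity": 2, "specificity": 2,
    "ppv_pct": 2, "npv_pct": 2, "lr_pos": 2, "lr_neg": 2,
    "tp": 0, "fp": 0, "tn": 0, "fn": 0, "deaths": 0,
}


def round_for_display(report: pd.DataFrame) -> pd.DataFrame:
    """Display rounding (2 dp metrics, integer counts); analysis stays exact."""
    out = report.copy()
    for col, nd in _DISPLAY_ROUNDING.items():
        if col in out.columns:
            out[col] = out[col].round(nd)
    return out


def write_report(report: pd.DataFrame, path,
                 header_lines: Iterable[str] = ()) -> None:
    """Write a report CSV preceded by '# ' metadata lines (seed etc.)."""
    with open(path, "w", newline="") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        report.to_csv(fh, index=False)


DATA_DICTIONARY = {
    "child_id": "opaque child identifier",
    "site": "enrolment site (site_1 .. site_9)",
    "age_months": "age in months, 2-23",
    "muac_cm": "mid-upper arm circumference, cm",
    "oedema": "bipedal nutritional oedema (kwashiorkor)",
    "waz": "weight-for-age Z-score",
    "temperature_c": "axillary temperature, deg C",
    "heart_rate": "heart rate, beats/min",
    "resp_rate": "respiratory rate, breaths/min",
    "spo2_pct": "oxygen saturation, %",
    "cap_refill": "capillary refill time: lt2s / s2to3 / gt3s",
    "consciousness": "AVPU level: alert / verbal / pain / unresponsive",
    "convulsions": "convulsions during this illness",
    "deep_breathing": "deep (acidotic) breathing",
    "chest_indrawing": "lower chest wall indrawing",
    "wheeze": "audible wheeze",
    "stridor": "stridor in a calm child",
    "prostration": "unable to sit unsupported / breastfeed",
    "unable_to_drink": "unable to drink or breastfeed",
    "vomits_everything": "vomits everything",
    "refusal_to_feed": "refusal to feed",
    "hiv_status": "positive / negative / unknown",
    "diarrhoea": "admission syndrome: diarrhoea",
    "pneumonia_lrti": "admission syndrome: severe pneumonia / LRTI",
    "malaria": "admission syndrome: malaria",
    "severe_anaemia": "admission syndrome: severe anaemia",
    "stratum": "nutritional stratum: none / moderate / severe",
    "pop_weight": "population weight (target share / sample share)",
    "died_inpatient": "died during admission",
    "day_of_death": "day of death since admission (if died)",
    "day_of_discharge": "day of discharge alive (if discharged)",
    "latent_severity": "simulator-only latent severity diagnostic",
}


def data_dictionary_frame() -> pd.DataFrame:
    rows = [(name, PATIENT_FIELDS.get(name, "number"), desc)
            for name, desc in DATA_DICTIONARY.items()]
    return pd.DataFrame(rows, columns=["column", "kind", "description"])
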