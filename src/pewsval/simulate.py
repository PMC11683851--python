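"""Synthetic stratified admission cohorts.

Emulates the sampling design of a multi-site paediatric acute-illness
cohort: children aged 2-23 months enrolled 2:1:2 across three nutritional
strata (no / moderate / severe wasting-or-kwashiorkor, defined by MUAC,
age and oedema), deliberate over-recruitment of malnourished children
undone at analysis time by population weights, stratum in-hospital
mortality of 3.5% / 8.1% / 20.4%, and deaths concentrated in the first
48 hours of admission.

The statistical model is a single latent severity per child (standard
normal plus a site shift).  Death is Bernoulli on the logistic scale with
a per-stratum intercept calibrated so the marginal stratum mortality
equals the configured rate for any severity effect size; every clinical
sign is Bernoulli with logit-linear dependence on severity, and the
continuous vitals are severity-shifted (truncated) normals.  Higher
severity therefore raises both the probability of death and every score,
which is what makes the scores discriminative on simulated data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from pewsval.records import PATIENT_FIELDS, STRATA, validate_cohort

_SCHEMA_ORDER = list(PATIENT_FIELDS)

__all__ = [
    "CohortConfig", "assign_stratum", "compute_population_weights",
    "generate_cohort", "outcome_at_horizon",
]


@dataclass(frozen=True)
class CohortConfig:
    """Simulator parameters.

    Defaults reproduce the emulated study conditions: n = 3101 children,
    9 sites, exact 2:1:2 enrolment over strata, stratum mortality
    (0.035, 0.081, 0.204), syndrome prevalences 55/21/14/14%.  The target
    population proportions behind the weights default to 0.80/0.10/0.10 —
    a plausible general admitted population, chosen because the real
    weighting targets are not published.
    """

    n_children: int = 3101
    n_sites: int = 9
    enrolment_ratio: tuple[float, float, float] = (2.0, 1.0, 2.0)
    stratum_mortality: tuple[float, float, float] = (0.035, 0.081, 0.204)
    target_population_proportions: tuple[float, float, float] = (0.80, 0.10, 0.10)
    syndrome_prevalences: Mapping[str, float] = field(default_factory=lambda: {
        "diarrhoea": 0.55, "pneumonia_lrti": 0.21,
        "malaria": 0.14, "severe_anaemia": 0.14,
    })
    severity_effect: float = 1.0
    site_effects: Optional[Sequence[float]] = None
    missingness_rate: float = 0.02
    exact_quota: bool = True
    seed: int = 0

    def validate(self) -> "CohortConfig":
        if self.n_children <= 0:
            raise ValueError("n_children must be positive")
        if self.n_sites <= 0:
            raise ValueError("n_sites must be positive")
        if any(r <= 0 for r in self.enrolment_ratio):
            raise ValueError("enrolment_ratio entries must be positive")
        if any(not 0.0 <= m <= 1.0 for m in self.stratum_mortality):
            raise ValueError("stratum_mortality outside [0, 1]")
        if abs(sum(self.target_population_proportions) - 1.0) > 1e-9:
            raise ValueError("target_population_proportions must sum to 1")
        if any(not 0.0 <= p <= 1.0 for p in self.syndrome_prevalences.values()):
            raise ValueError("syndrome prevalences outside [0, 1]")
        if not 0.0 <= self.missingness_rate < 1.0:
            raise ValueError("missingness_rate outside [0, 1)")
        if self.severity_effect < 0:
            raise ValueError("severity_effect must be nonnegative")
        if self.site_effects is not None and len(self.site_effects) != self.n_sites:
            raise ValueError("site_effects length must equal n_sites")
        return self

    def resolved_site_effects(self) -> np.ndarray:
        if self.site_effects is not None:
            return np.asarray(self.site_effects, dtype=float)
        # modest spread so site sensitivity analyses show real variation
        return np.linspace(-0.5, 0.5, self.n_sites)


# ---------------------------------------------------------------------------
# stratum / weight logic (shared with real data)


def _muac_thresholds(age_months: float) -> tuple[float, float]:
    """(moderate_lower, no_wasting_lower) MUAC thresholds in cm."""
    return (11.0, 12.0) if age_months < 6 else (11.5, 12.5)


def assign_stratum(muac_cm: float, age_months: float, oedema: bool) -> str:
    """Nutritional stratum from MUAC, age and oedema.

    Oedema (kwashiorkor) is 'severe' regardless of MUAC.  Otherwise, for
    age >= 6 months: none if MUAC >= 12.5 cm, moderate if 11.5 <= MUAC
    < 12.5, severe if MUAC < 11.5; for age < 6 months the thresholds are
    12.0 and 11.0 cm.  Interval edges are half-open so the three
    categories partition the MUAC axis.
    """
    if muac_cm <= 0:
        raise ValueError("muac_cm must be positive")
    if oedema:
        return "severe"
    lo, hi = _muac_thresholds(age_months)
    if muac_cm >= hi:
        return "none"
    if muac_cm >= lo:
        return "moderate"
    return "severe"


def _assign_stratum_vec(muac: np.ndarray, age: np.ndarray,
                        oedema: np.ndarray) -> np.ndarray:
    lo = np.where(age < 6, 11.0, 11.5)
    hi = np.where(age < 6, 12.0, 12.5)
    out = np.where(muac >= hi, "none", np.where(muac >= lo, "moderate", "severe"))
    out = np.where(oedema, "severe", out)
    return out.astype(object)


def compute_population_weights(strata: Sequence[str],
                               target_proportions: Sequence[float]) -> np.ndarray:
    """Per-child population weights: target share / sample share by stratum.

    The weighted stratum shares reproduce the target exactly and the mean
    weight is 1 (weights sum to n).
    """
    strata = np.asarray(strata, dtype=object)
    target = np.asarray(target_proportions, dtype=float)
    n = len(strata)
    weights = np.empty(n, dtype=float)
    for s, t in zip(STRATA, target):
        mask = strata == s
        n_s = int(mask.sum())
        if n_s == 0:
            if t > 0:
                raise ValueError(f"stratum {s!r} empty but target share {t} > 0")
            continue
        weights[mask] = t / (n_s / n)
    return weights


# ---------------------------------------------------------------------------
# generation


def _quota_counts(n: int, ratio: Sequence[float]) -> np.ndarray:
    """Largest-remainder allocation of n children to the strata."""
    ratio = np.asarray(ratio, dtype=float)
    share = ratio / ratio.sum()
    exact = share * n
    counts = np.floor(exact).astype(int)
    rem = n - counts.sum()
    order = np.argsort(-(exact - counts))
    counts[order[:rem]] += 1
    return counts


def _calibrated_intercept(target: float, z: np.ndarray, beta: float) -> float:
    """Solve a so that mean(expit(a + beta*z)) == target over this stratum."""
    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf
    if beta == 0.0 or len(z) == 0:
        return float(logit(target))
    f = lambda a: float(np.mean(expit(a + beta * z))) - target
    return brentq(f, -40.0, 40.0, xtol=1e-12)


def _muac_grid(lo: float, hi: float) -> np.ndarray:
    """0.1 cm grid covering [lo, hi) — keeps stratum round-trips exact."""
    return np.round(np.arange(round(lo * 10), round(hi * 10)) / 10.0, 1)


_SIGN_MODEL = {
    # sign: (baseline prevalence, logit slope on severity)
    "convulsions": (0.06, 0.8),
    "deep_breathing": (0.12, 1.0),
    "chest_indrawing": (0.18, 0.9),
    "wheeze": (0.10, 0.3),
    "stridor": (0.02, 0.5),
    "prostration": (0.10, 1.1),
    "unable_to_drink": (0.15, 1.0),
    "vomits_everything": (0.10, 0.6),
    "refusal_to_feed": (0.18, 0.9),
}

_MISSABLE = ("temperature_c", "heart_rate", "resp_rate", "spo2_pct",
             "waz", "cap_refill")


def generate_cohort(config: CohortConfig) -> pd.DataFrame:
    """Generate one synthetic cohort; fully reproducible from config.seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_children

    # -- strata and enrolment
    if config.exact_quota:
        counts = _quota_counts(n, config.enrolment_ratio)
        stratum = np.repeat(np.array(STRATA, dtype=object), counts)
        rng.shuffle(stratum)
    else:
        ratio = np.asarray(config.enrolment_ratio, float)
        stratum = rng.choice(np.array(STRATA, dtype=object), size=n,
                             p=ratio / ratio.sum())

    age = rng.integers(2, 24, size=n).astype(float)
    oedema = np.zeros(n, dtype=bool)
    severe = stratum == "severe"
    oedema[severe] = rng.random(severe.sum()) < 0.30

    # -- MUAC drawn inside the assigned stratum's interval (0.1 cm grid)
    muac = np.empty(n, dtype=float)
    lo = np.where(age < 6, 11.0, 11.5)
    hi = np.where(age < 6, 12.0, 12.5)
    for i in range(n):
        if oedema[i]:
            grid = _muac_grid(10.0, 14.0)
        elif stratum[i] == "none":
            grid = _muac_grid(hi[i], hi[i] + 2.5)
        elif stratum[i] == "moderate":
            grid = _muac_grid(lo[i], hi[i])
        else:
            grid = _muac_grid(lo[i] - 2.5, lo[i])
        muac[i] = grid[rng.integers(len(grid))]

    # -- latent severity: standard normal plus a site shift
    site_idx = rng.integers(0, config.n_sites, size=n)
    site_eff = config.resolved_site_effects()
    z = rng.standard_normal(n) + site_eff[site_idx]

    # -- death, calibrated per stratum so marginal mortality hits the target
    beta = config.severity_effect
    p_death = np.empty(n, dtype=float)
    for s, m in zip(STRATA, config.stratum_mortality):
        mask = stratum == s
        a = _calibrated_intercept(m, z[mask], beta)
        p_death[mask] = expit(a + beta * z[mask])
    died = rng.random(n) < p_death

    # -- event times: deaths front-loaded (~70% within 48 h) with sicker
    #    children dying earlier, survivors discharged after a short stay
    p_geo = np.clip(0.45 + 0.12 * z, 0.10, 0.95)
    day_of_death = np.where(
        died, np.minimum(rng.geometric(p_geo), 60), np.nan)
    day_of_discharge = np.where(died, np.nan, 2 + rng.poisson(4.0, size=n))

    # -- clinical signs: logit-linear in severity
    cols: dict[str, np.ndarray] = {}
    for sign, (base, slope) in _SIGN_MODEL.items():
        cols[sign] = rng.random(n) < expit(logit(base) + slope * z)

    # ordinal fields via a noisy latent copy of severity
    c_lat = z + rng.standard_normal(n)
    consciousness = np.select(
        [c_lat < 1.5, c_lat < 2.2, c_lat < 2.9],
        ["alert", "verbal", "pain"], default="unresponsive").astype(object)
    r_lat = z + rng.standard_normal(n)
    cap_refill = np.select(
        [r_lat < 1.8, r_lat < 2.6],
        ["lt2s", "s2to3"], default="gt3s").astype(object)

    # -- vitals: severity-shifted truncated normals
    temperature = np.clip(37.2 + 0.25 * z + rng.normal(0, 0.8, n), 34.0, 41.5)
    heart_rate = np.clip(
        128 - 8 * (age >= 12) + 9 * z + rng.normal(0, 16, n), 60, 230)
    resp_rate = np.clip(
        38 + 6 * (age < 12) + 7 * z + rng.normal(0, 9, n), 15, 120)
    spo2 = np.clip(97 - 1.8 * z + rng.normal(0, 2.5, n), 55, 100)

    # -- weight-for-age: strongly stratum-dependent, mildly severity-linked
    waz_mean = np.select([stratum == "none", stratum == "moderate"],
                         [-0.7, -2.1], default=-3.2)
    waz = np.clip(waz_mean - 0.15 * z + rng.normal(0, 0.7, n), -6.0, 3.0)

    hiv = rng.choice(np.array(["positive", "negative", "unknown"], dtype=object),
                     size=n, p=[0.06, 0.88, 0.06])

    df = pd.DataFrame({
        "child_id": [f"C{i:05d}" for i in range(n)],
        "site": [f"site_{k + 1}" for k in site_idx],
        "age_months": age,
        "muac_cm": muac,
        "oedema": oedema,
        "waz": np.round(waz, 2),
        "temperature_c": np.round(temperature, 1),
        "heart_rate": np.round(heart_rate, 0),
        "resp_rate": np.round(resp_rate, 0),
        "spo2_pct": np.round(spo2, 0),
        "cap_refill": cap_refill,
        "consciousness": consciousness,
        **{k: v for k, v in cols.items()},
        "hiv_status": hiv,
        **{syn: rng.random(n) < p
           for syn, p in config.syndrome_prevalences.items()},
        "stratum": stratum,
        "died_inpatient": died,
        "day_of_death": day_of_death,
        "day_of_discharge": day_of_discharge,
        "latent_severity": np.round(z, 4),  # simulator-only diagnostic
    })

    # -- missingness on measured fields only (never outcomes or design vars)
    if config.missingness_rate > 0:
        for colname in _MISSABLE:
            mask = rng.random(n) < config.missingness_rate
            if df[colname].dtype == object:
                df.loc[mask, colname] = None
            else:
                df.loc[mask, colname] = np.nan

    df["pop_weight"] = compute_population_weights(
        df["stratum"].to_numpy(), config.target_population_proportions)
    # column order: schema columns first, diagnostics last
    ordered = [c for c in _SCHEMA_ORDER if c in df.columns] + ["latent_severity"]
    df = df[ordered]
    return validate_cohort(df)


def outcome_at_horizon(record, horizon_days: int,
                       include_post_discharge: bool = True) -> bool:
    """Death by a fixed day since admission (fixed-horizon mortality).

    ``record`` is a mapping/row with ``day_of_death`` / ``day_of_discharge``.
    With ``include_post_discharge=False``, a death after discharge (day of
    death beyond day of discharge) does not count.
    """
    if horizon_days <= 0:
        raise ValueError("horizon_days must be positive")
    dd = record.get("day_of_death") if hasattr(record, "get") else record["day_of_death"]
    dc = record.get("day_of_discharge") if hasattr(record, "get") else record["day_of_discharge"]
    dd_missing = dd is None or (isinstance(dd, float) and np.isnan(dd))
    dc_missing = dc is None or (isinstance(dc, float) and np.isnan(dc))
    if dd_missing and dc_missing:
        raise ValueError("record has neither day_of_death nor day_of_discharge")
    if dd_missing:
        return False
    if not include_post_discharge and not dc_missing and dd > dc:
        return False
    return bool(dd <= horizon_days)


def horizon_outcome_column(df: pd.DataFrame, horizon_days: int,
                           include_post_discharge: bool = True) -> np.ndarray:
    """Vectorised :func:`outcome_at_horizon` over a cohort table."""
    if horizon_days <= 0:
        raise ValueError("horizon_days must be positive")
    dd = pd.to_numeric(df["day_of_death"], errors="coerce")
    dc = pd.to_numeric(df["day_of_discharge"], errors="coerce")
    if (dd.isna() & dc.isna()).any():
        raise ValueError("records with neither event day present")
    out = dd.notna() & (dd <= horizon_days)
    if not include_post_discharge:
        out &= ~(dc.notna() & dd.notna() & (dd > dc))
    return out.to_numpy(dtype=bool)
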