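"""Score one admitted child with every registered early warning score.

Builds a single admission record for a 10-month-old with severe wasting,
deep breathing and reduced consciousness, evaluates all 11 registered
score variants and prints each total next to its range and risk cutoff.
A total at or above the cutoff flags the child as at increased risk of
inpatient death under that score.
"""

from pewsval import default_registry, evaluate_score

child = {
    "child_id": "demo-001", "site": "site_3", "age_months": 10,
    "muac_cm": 11.2, "oedema": False, "waz": -3.4,
    "temperature_c": 38.1, "heart_rate": 172, "resp_rate": 62,
    "spo2_pct": 88, "cap_refill": "s2to3", "consciousness": "pain",
    "convulsions": False, "deep_breathing": True, "chest_indrawing": True,
    "wheeze": False, "stridor": False, "prostration": True,
    "unable_to_drink": True, "vomits_everything": False,
    "refusal_to_feed": True, "hiv_status": "negative",
    "diarrhoea": True, "pneumonia_lrti": True, "malaria": False,
    "severe_anaemia": False,
}

registry = default_registry()
print(f"{'score':22s} {'total':>5s} {'range':>7s} {'cutoff':>6s}  flag")
for definition in registry.values():
    res = evaluate_score(definition, child)
    cutoff = definition.predefined_cutoff
    flag = ""
    if cutoff is not None:
        flag = "HIGH RISK" if res.total_points >= cutoff else "low risk"
    elif not res.applicable:
        flag = "(not applicable)"
    rng = f"{definition.range_min}-{definition.range_max}"
    print(f"{definition.name:22s} {res.total_points:5d} {rng:>7s} "
          f"{'' if cutoff is None else cutoff:>6}  {flag}")
print("\nScores without a printed cutoff (PEDIA early/late, RISC, "
      "RISC-Malawi) get a Youden-optimal one at validation time.")
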