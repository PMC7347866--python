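"""Score bedside nurse observations with the aggregated PEW table.

Two observation sets for a two-year-old: one unremarkable, one with
tachypnoea, distress, desaturation and supplemental oxygen.  Scores run
0-26; a total of 9 or more triggers a request for intensive-care review.
"""

from rapidindex import PewsObservation, PewsScoringTable, compute_pews

table = PewsScoringTable()
age_months = 27

normal = PewsObservation(
    timestamp=0,
    respiratory_rate=25,
    respiratory_distress=0,
    spo2=98,
    inspired_oxygen=0.21,
    heart_rate=110,
    systolic_bp=95,
    capillary_refill_seconds=1.5,
)
unwell = PewsObservation(
    timestamp=60,
    respiratory_rate=52,
    respiratory_distress=2,
    spo2=88,
    inspired_oxygen=0.45,
    heart_rate=175,
    systolic_bp=62,
    capillary_refill_seconds=3.5,
)

for label, obs in (("normal", normal), ("unwell", unwell)):
    score = compute_pews(obs, table, age_months)
    flag = "ALERT (PICU review)" if score >= table.alert_threshold else "no alert"
    print(f"{label:7s} PEW score {score:2d}/26 -> {flag}")

# The normal set scores 0; the unwell set accumulates subscores across
# several parameters and crosses the >=9 review threshold.
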