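"""Estimate weighted per-protocol cumulative incidence and contrasts.

The full pipeline: generate claims, build the cohort, censor at protocol
deviation, weight, and estimate cumulative incidence of colon cancer (with
death as a competing event) on the age time scale, by HIV status, under the
2-year and 10-year screening protocols.
"""

from screenpp import (GeneratorParams, PerProtocolAnalysis, ProtocolSpec,
                      WeightModelSpec, build_cohort, build_person_intervals,
                      generate_population)

data = generate_population(GeneratorParams(n_beneficiaries=60000, seed=5))
cohort, _ = build_cohort(data.demographics, data.enrollment, data.claims,
                         control_fraction=0.25, sampling_seed=6)
print(f"analyzed cohort: {len(cohort)} ({int(cohort['exposed'].sum())} with HIV)")

for k in (2, 10):
    spec = ProtocolSpec(cadence_years=k)
    intervals = build_person_intervals(cohort, data.claims, spec)
    est = PerProtocolAnalysis(intervals, WeightModelSpec()).estimate(
        full_output=True)
    print(f"\nscreening every {k} years -- weighted risk of colon cancer (%):")
    print("  age   with HIV   without HIV      RD (pp)     RR")
    for _, row in est["contrast"].table.iterrows():
        print(f"  {row['age']:4.0f}   {100 * row['risk_exposed']:8.2f}   "
              f"{100 * row['risk_unexposed']:11.2f}   "
              f"{100 * row['rd']:10.2f}   {row['rr']:5.2f}")
# RD < 0 / RR < 1 reflect the generator's lower colon-cancer hazard under
# HIV; the curves answer "what if everyone followed the protocol and nobody
# disenrolled", which is what the censoring-plus-weighting construction
# estimates.
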