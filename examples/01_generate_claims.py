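"""Generate a synthetic Medicaid-style claims dataset and look inside it.

The generator produces three observable tables (demographics, enrollment
spans, dated claims) plus a separate hidden-truth table that records the true
event months -- the analysis pipeline never reads the truth table, but tests
and oracles do.
"""

from screenpp import GeneratorParams, generate_population, write_dataset

params = GeneratorParams(n_beneficiaries=5000, seed=1)
data = generate_population(params)

print(f"beneficiaries: {len(data.demographics)}")
print(f"enrollment spans: {len(data.enrollment)}")
print(f"claims: {len(data.claims)}")
print("\nclaims by category:")
print(data.claims["category"].value_counts().to_string())
print("\nhidden truth (first rows, never used by the pipeline):")
print(data.truth.head(3).to_string(index=False))

paths = write_dataset(data, "scratch/example_claims")
print(f"\nwrote {sorted(p.name for p in paths.values())} to {paths['claims'].parent}")
# The claim counts show the raw material of a claims emulation: endoscopies,
# comorbidity markers, death claims, and sparse cancer diagnosis claims.
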