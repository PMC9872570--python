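"""Flatten FHIR R4 bundles into the one-row-per-patient clinical table.

Emits FHIR bundles for a small simulated cohort, parses them back, links
every resource to its patient via the MRN, and shows the resulting
table. Anything not mapped to a flat column survives verbatim in a
JSON-string column, so no clinical content is silently dropped.
"""
from vcfhir import cohort_sim, fhir_flatten

cohort = cohort_sim.simulate_cohort(8, seed=3)
bundles = [cohort_sim.emit_fhir(p) for p in cohort]
table = fhir_flatten.flatten_bundles(bundles)

print(table[["mrn", "gender", "age", "survived", "condition_1", "medication_1"]])
print(f"\ncolumns: {list(table.columns)}")

# 'survived' is derived from the presence of deceasedDateTime; ages are
# computed at the latest event date in the cohort. One row per MRN.
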