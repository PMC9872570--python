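"""Simulate a breast-cancer cohort and look at its survival structure.

Every patient is an adult woman who receives one of two anthracyclines;
survival is 90% when the drug matches her pharmacogenomic variant status
(no variant + Doxorubicin, or variant + Epirubicin) and 50% otherwise.
"""
from collections import defaultdict

from vcfhir import default_module, simulate_cohort

cohort = simulate_cohort(n=2000, module=default_module(), seed=42)

cells = defaultdict(lambda: [0, 0])
for p in cohort:
    cells[(p.carrier, p.drug)][0] += p.survived
    cells[(p.carrier, p.drug)][1] += 1

print(f"{'carrier':8} {'drug':12} {'n':>5} {'survival':>9}")
for (carrier, drug), (surv, n) in sorted(cells.items()):
    print(f"{str(carrier):8} {drug:12} {n:5d} {100 * surv / n:8.1f}%")

# The two matched cells should sit near 90%, the mismatched cells near
# 50% — the planted effect that the downstream z-test study recovers.
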