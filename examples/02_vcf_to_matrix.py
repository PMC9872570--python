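"""Build the patient x variant-feature matrix from per-patient VCFs.

Writes a small simulated cohort's VCFs (10% of background calls are
missing, as in real non-GVCF inputs), then runs the full chain: read,
split multi-allelics, normalize, merge, LD-prune, impute missing calls
as average-quality reference calls, and transpose.
"""
import tempfile
from pathlib import Path

from vcfhir import cohort_sim, variant_matrix

with tempfile.TemporaryDirectory() as d:
    out = Path(d)
    cohort_sim.write_cohort(out, n=20, seed=7, missing_rate=0.1, n_background_sites=50)
    matrix = variant_matrix.vcfs_to_matrix(sorted((out / "vcf").glob("*.vcf")))
    variant_matrix.write_tsv(matrix, out / "matrix.tsv")

    print(f"patients: {len(matrix.patients)}")
    print(f"variants kept after LD pruning: {len(matrix.site_keys)}")
    print(f"feature columns (4 per variant): {matrix.data.shape[1]}")
    n_imputed = int(matrix.imputed.to_numpy().sum())
    print(f"imputed calls: {n_imputed} "
          f"({100 * n_imputed / matrix.imputed.size:.1f}% of the table)")
    key = matrix.site_keys[0]
    print(f"\nfirst variant {key}, first 3 patients:")
    print(matrix.data[[f"{key}:GT", f"{key}:DP", f"{key}:PL"]].head(3))

# Each retained variant contributes GT/AF/DP/PL columns; imputed entries
# are homozygous-reference calls at the patient's average depth/quality.
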