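# Methods

This note records the models, conventions and design choices behind
`vcfhir`, in the order data flows through the pipeline.

## Genomic processing

**Coordinates and representation.** All coordinates are 1-based
inclusive, matching VCF. Alleles are strings over {A, C, G, T, N}. A
site is identified by the key (chrom, pos, ref, alt) after splitting and
normalization, so the same physical variant from different patients
merges to one column.

**Multi-allelic splitting.** A record with m alternate alleles becomes m
biallelic records, each carrying its own per-alt AF. Genotype allele
indexes equal to the focal alt become 1; indexes pointing at any *other*
alt become 0. This recode is lossy for genuinely multi-allelic genotypes
(e.g. 1/2), which is logged; it mirrors the behavior of common splitters
and keeps every variant at a fixed column width, which is the reason for
splitting in the first place. Total alt-allele count is conserved across
the output records for every genotype.

**Normalization.** Left alignment follows the standard iterative
algorithm: while the alleles share a trailing base, truncate it; if an
allele empties, prepend the reference base at pos − 1 and decrement pos;
finally trim shared leading bases while both alleles keep length ≥ 2.
The result is parsimonious, leftmost, idempotent, and edit-equivalent to
the input (applying either edit to the reference yields the same
sequence). Two boundary conventions: at the contig start there is no
base to prepend, so the shared trailing base is kept (the conventional
representation for a pos-1 indel); and without a reference sequence the
procedure degrades to parsimony trimming only, with a warning, since
left-shifting requires sequence context. A REF allele that disagrees
with the supplied reference raises a consistency error rather than
silently normalizing a corrupt record.

**LD pruning.** Variants are pruned on the squared Pearson correlation
of alt-allele dosage vectors (0/1/2; phase ignored — the simplest
covariance-faithful coding). A window of `window` variants slides in
steps of `step`; within a window, any retained pair with r² ≥ threshold
loses its *later* member (position order), making the output
deterministic. Zero-variance dosage vectors are defined to have r² = 0
against any partner (and are logged): a monomorphic column carries no
linkage information and pruning it on an undefined correlation would be
arbitrary. Windows never span a chromosome boundary. Defaults r² = 0.5,
window = 50, step = 5 are conventional pairwise-pruning settings and are
overridable everywhere they appear.

**Merging and imputation.** The merged call table is the union of sites
over patients; a patient without a call at a site holds an explicit
missing call. Because the inputs are VCFs rather than GVCFs, a missing
entry says nothing about the genotype — the pipeline adopts the
assumption that uncalled positions are reference calls of average
quality and depth *for that patient*: GT = 0/0, DP = round(mean DP over
the patient's called sites), PL = [0, g, 2g] with g = round(mean
genotype quality), where genotype quality is the second-smallest PL
entry. The linear PL ramp is the shape a hom-ref call of quality g
takes; "average quality" is operationalized as the mean GQ, which is
documented rather than uniquely forced. Imputed calls are flagged, and
the flags survive the TSV round trip in a companion column. A patient
with zero called sites cannot be imputed and is reported by name.
Degenerate partial calls (genotype present but DP or PL missing) are
filled from the same per-patient means and flagged.

**Matrix layout.** The patient-major matrix has exactly four columns per
variant — `<chrom>:<pos>:<ref>><alt>:{GT, AF, DP, PL}`. GT columns hold
genotype strings verbatim ("0/1"), which keeps the TSV round trip
bit-faithful; the numeric dosage view used by the analyses is a
documented mapping (count of non-reference alleles) available via
`dosage_frame()` / `encode_features`. AF repeats the site-level allele
frequency down the column; when the input VCFs carry no AF, it is
recomputed as the cohort alt-allele frequency after merging (logged).

## Clinical flattening

Supported resources are Patient, Condition, MedicationRequest and
Observation — the set the downstream applications consume; other types
are counted and skipped. The MRN is the Patient identifier whose type
coding is "MR", falling back to `Patient.id` (logged) since synthetic
bundles vary. Subject references of the forms `Patient/<id>` and
`urn:uuid:<id>` are resolved against the bundle's Patient entries; a
resource whose subject cannot be resolved is an error, not a silent
drop.

Repeated resources become indexed columns (`condition_1…k`,
`medication_1…m`) ordered by (onset/authored date, code) — bounded
column growth at desk scale, rather than one boolean column per possible
code. The flattener *consumes* exactly the leaves it maps; everything
else in a resource (display texts, units, severities, extensions) is
preserved verbatim as a JSON string in a companion `*_json` column, so
every value in a bundle is findable in exactly one cell or one JSON
column. `survived` is false iff `deceasedDateTime` is present or
`deceasedBoolean` is true. Ages are computed at a reference date
defaulting to the latest date seen in the cohort's mapped fields.

## Cohort simulator

The simulator emulates a state-machine disease module: demographic
filter (female, ages 30–90 uniform), condition onset, a 50/50 medication
branch (Doxorubicin/Epirubicin), and a survival outcome drawn from a
(carrier × drug) table — 0.9 for the two matched cells, 0.5 for the
mismatched cells, against an untreated baseline of 0.5. Carrier
prevalence is 0.5, with heterozygous/homozygous genotypes split evenly
among carriers. Balanced 50/50 branches maximize the power of the
four-cell study and are configurable (including an optional untreated
arm, off by default). The condition and drug codes are fixture-defined
placeholders, not asserted real SNOMED/RxNorm bindings.

Dates are fixed relative to a simulation date (2022-01-01): birthDate is
the simulation date minus age in years, and all clinical events fall
later in 2022, so the age recovered by the flattener equals the
simulated age exactly.

Each patient's randomness comes from an independent stream keyed by
(seed, patient index), so cohorts are reproducible, order-invariant, and
prefix-stable: growing a cohort never rewrites existing patients.

Emitted VCFs always contain the PGx site (genotype encodes carrier
status); background sites get genotypes drawn from per-site allele
frequencies (dosage ~ Binomial(2, AF)), DP ~ Poisson(30), and a
quality-consistent PL triple. Each background call is omitted from the
file with probability `missing_rate`, mimicking the silence of non-GVCF
inputs and exercising the imputation stage. What the simulator does
*not* emulate: linkage structure between background sites (draws are
independent, so LD pruning on simulated data removes only chance
correlations), sequencing error, longitudinal encounters, and real
terminology bindings. Passing tests therefore demonstrate the
pipeline's correctness and the recoverability of a planted effect — not
calibration against real long-read data.

The Gaussian-mixture feature generator places component centers at the
vertices of a regular simplex with edge length `separation` (randomly
rotated), so "center spacing" means the same distance between every pair
of components — the geometry under which elbow selection and cluster
recovery are well-posed.

## Clustering and validity indices

Inertia is defined as the **mean** squared distance from each point to
its assigned centroid. The common sum-based definition differs by the
factor n, which cancels in cluster assignments and in the elbow
argument, so the choice affects only the reported scale. The elbow is
formalized as the k maximizing the discrete second difference
inertia(k−1) − 2·inertia(k) + inertia(k+1) — the simplest reproducible
reading of "the bend toward horizontal"; a curve with no positive
curvature triggers a warning but still returns a selection.

k-means++ (greedy seeding, Lloyd iterations, best of n_init restarts),
DBSCAN and RBF-affinity spectral clustering are delegated to
scikit-learn behind the module's interface; the three validity indices
are implemented directly from their formulas and cross-checked in the
test suite against both brute-force transcriptions and scikit-learn's
implementations to 1e-9:

- Davies–Bouldin: (1/k) Σᵢ maxⱼ≠ᵢ (Sᵢ + Sⱼ)/Mᵢⱼ, S = mean distance to
  centroid, M = centroid distance; 0 for zero scatter; coincident
  centroids make a pair undefined (error).
- Calinski–Harabasz: [BSS/(k−1)] / [WSS/(n−k)]; zero within-group
  scatter returns +∞ with a logged flag rather than an exception.
- Silhouette: mean of (b − a)/max(a, b); singleton clusters score 0.

For DBSCAN output, indices are computed over non-noise points only, with
the noise fraction reported alongside. Distances are Euclidean
throughout; the spectral affinity width gamma defaults to 1.0 on
standardized features.

## Pharmacogenomic study

Each (carrier × drug) cell is tested one-sided against the untreated
survival rate p₀ = 0.5 with the one-sample proportion z-test, no
continuity correction, at α = 0.01 by default. The four tests are
reported without multiple-testing correction — they are four separate
planned comparisons against a fixed baseline, not a family of post-hoc
contrasts. Carrier status is derived from the PGx genotype column of the
*genomic* matrix (dosage ≥ 1), keeping the genomic data causal for the
study rather than leaking through a clinical field. Cells with n = 0 are
flagged untestable; cells where n·p₀ < 5 carry a normal-approximation
warning but still return a result.

Sampling variation matters at these scales: a 10 000-patient cohort
yields ≈ 2 500 patients per cell, so observed cell survival has a
standard error of 0.6–1.0 percentage points and fluctuates around the
planted 90%/50% parameters within exact binomial bounds — the test suite
checks recovery against those bounds.

## Pipeline and determinism

The orchestrator replaces every cloud service in the workflow (FHIR
server, sync agent, warehouse) with local files — infrastructure, not
method. Configs are validated strictly (unknown keys rejected, all
violations reported at once, defaults materialized and logged). Every
stage records its parameters, row/column counts and output SHA-256
digests in a run manifest; with a fixed seed, re-running a config
reproduces identical digests for all stages. All randomness descends
from the single config seed.

Default problem sizes (200-patient cohorts with ~100 background sites in
the pipeline default; up to 10 000 patients in the parameter-recovery
checks) keep every analysis interactive on a laptop while leaving the
statistical conclusions comfortably powered.

## Known limitations

- The multi-allelic genotype recode is lossy for non-focal alt alleles
  (logged but not reversible from the matrix).
- Imputation assumes missingness means "confidently reference", which is
  optimistic for low-coverage regions; GVCF input would remove the
  assumption entirely and is the natural extension.
- FHIR support covers the four resource types the analyses consume, JSON
  encoding only; no server, bulk export, or genomics resources.
- The simulator's background variants are linkage-free and
  error-free; clustering structure in simulated cohorts comes from the
  clinical features and the PGx site, not from realistic population
  structure.
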