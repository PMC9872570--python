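"""Synthetic cohort generator: state-machine clinical module + paired VCFs.

Emulates a Synthea-style disease module for a breast-cancer cohort of
adult women (ages 30-90): every patient receives a breast-cancer
condition, is prescribed one of two anthracyclines (Doxorubicin or
Epirubicin), and survives with a probability determined by the
combination of drug and carrier status at one pharmacogenomic (PGx)
variant. Survival is 90% when drug and genotype match (no variant +
Doxorubicin, or variant + Epirubicin) and stays at the untreated
baseline of 50% otherwise.

Each simulated patient yields a FHIR R4 bundle (clinical truth) and a
single-sample VCF whose PGx-site genotype encodes carrier status, plus
background variants with randomly missing calls to exercise the
imputation stage. A Gaussian-mixture feature generator is included as a
ground-truthed fixture for the clustering application.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np

from .variant_matrix import Site, _chrom_sort_key

logger = logging.getLogger(__name__)

DOXORUBICIN = "Doxorubicin"
EPIRUBICIN = "Epirubicin"
UNTREATED = "none"

# Placeholder codes for the synthetic module; not asserted as real
# SNOMED/RxNorm bindings.
BREAST_CANCER_CODE = "254837009"
BREAST_CANCER_DISPLAY = "Malignant neoplasm of breast"

# Default PGx site: a biallelic SNP standing in for the study variant.
PGX_SITE = Site(chrom="chr17", pos=43100000, ref="A", alt="G", af=0.5)

SIMULATION_DATE = date(2022, 1, 1)
_ONSET = "2022-02-01T00:00:00Z"
_AUTHORED = "2022-02-15T00:00:00Z"
_DECEASED = "2022-06-30T00:00:00Z"


class ModuleValidationError(ValueError):
    """Module transition/survival probabilities violate an invariant."""


@dataclass
class ModuleSpec:
    """State-machine module: demographic filter, drug branch, outcome.

    ``survival_table`` maps (carrier, drug) to the probability of
    surviving; the drug branch and carrier prevalence are Bernoulli
    splits. ``age_range`` is inclusive.
    """

    carrier_prob: float = 0.5
    drug_probs: dict[str, float] = field(
        default_factory=lambda: {DOXORUBICIN: 0.5, EPIRUBICIN: 0.5}
    )
    survival_table: dict[tuple[bool, str], float] = field(default_factory=dict)
    untreated_survival: float = 0.5
    age_range: tuple[int, int] = (30, 90)
    untreated_arm: bool = False

    def validate(self) -> None:
        if not 0.0 <= self.carrier_prob <= 1.0:
            raise ModuleValidationError("carrier_prob must be in [0,1]")
        if abs(sum(self.drug_probs.values()) - 1.0) > 1e-9:
            raise ModuleValidationError("drug branch probabilities must sum to 1")
        for cell, p in self.survival_table.items():
            if not 0.0 <= p <= 1.0:
                raise ModuleValidationError(f"survival probability {cell} out of [0,1]")
        if not 0.0 <= self.untreated_survival <= 1.0:
            raise ModuleValidationError("untreated_survival must be in [0,1]")
        lo, hi = self.age_range
        if lo > hi or lo < 0:
            raise ModuleValidationError("invalid age_range")

    def survival_prob(self, carrier: bool, drug: str) -> float:
        if drug == UNTREATED:
            return self.untreated_survival
        return self.survival_table[(carrier, drug)]

    @classmethod
    def from_config(cls, doc: dict) -> "ModuleSpec":
        """Build from a JSON/YAML config mirroring the module structure."""
        table = {
            (bool(entry["carrier"]), str(entry["drug"])): float(entry["survival"])
            for entry in doc.get("survival_table", [])
        }
        spec = cls(
            carrier_prob=float(doc.get("carrier_prob", 0.5)),
            drug_probs={str(k): float(v) for k, v in doc.get(
                "drug_probs", {DOXORUBICIN: 0.5, EPIRUBICIN: 0.5}).items()},
            survival_table=table or default_module().survival_table,
            untreated_survival=float(doc.get("untreated_survival", 0.5)),
            age_range=tuple(doc.get("age_range", (30, 90))),  # type: ignore[arg-type]
            untreated_arm=bool(doc.get("untreated_arm", False)),
        )
        spec.validate()
        return spec


def default_module() -> ModuleSpec:
    """The default breast-cancer module.

    Matched drug/genotype cells survive at 90%; mismatched cells stay at
    the untreated 50% baseline. Carrier prevalence and the drug branch
    are balanced 50/50.
    """
    spec = ModuleSpec(
        survival_table={
            (False, DOXORUBICIN): 0.9,
            (True, EPIRUBICIN): 0.9,
            (True, DOXORUBICIN): 0.5,
            (False, EPIRUBICIN): 0.5,
        },
    )
    spec.validate()
    return spec


@dataclass
class SimPatient:
    """Ground-truth simulator state for one patient."""

    mrn: str
    index: int
    sex: str
    age: int
    carrier: bool
    genotype: tuple[int, int]
    drug: str
    survived: bool

    def __post_init__(self) -> None:
        if self.sex != "female":
            raise ValueError("cohort is exclusively female")
        if self.carrier != (sum(self.genotype) >= 1):
            raise ValueError("carrier flag inconsistent with genotype")


def _patient_rng(seed: int, index: int, stream: int = 0) -> np.random.Generator:
    """Independent per-patient stream: cohort content is invariant to
    generation order and cohort size."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index, stream)))


def simulate_cohort(n: int, module: ModuleSpec | None = None, seed: int = 0) -> list[SimPatient]:
    """Draw ``n`` patients through the state machine, reproducibly."""
    if n < 1:
        raise ValueError("n must be >= 1")
    module = module or default_module()
    module.validate()
    lo, hi = module.age_range
    drugs = sorted(module.drug_probs)
    probs = [module.drug_probs[d] for d in drugs]
    patients = []
    for i in range(n):
        rng = _patient_rng(seed, i)
        age = int(rng.integers(lo, hi + 1))
        carrier = bool(rng.random() < module.carrier_prob)
        if carrier:
            genotype = (0, 1) if rng.random() < 0.5 else (1, 1)
        else:
            genotype = (0, 0)
        if module.untreated_arm and rng.random() < 1.0 / (len(drugs) + 1):
            drug = UNTREATED
        else:
            drug = str(rng.choice(drugs, p=probs))
        survived = bool(rng.random() < module.survival_prob(carrier, drug))
        patients.append(
            SimPatient(
                mrn=f"P{i:06d}", index=i, sex="female", age=age,
                carrier=carrier, genotype=genotype, drug=drug, survived=survived,
            )
        )
    return patients


# ---------------------------------------------------------------------------
# FHIR emission
# ---------------------------------------------------------------------------

def emit_fhir(patient: SimPatient, sim_date: date = SIMULATION_DATE) -> dict:
    """Emit one FHIR R4 Bundle for a simulated patient.

    birthDate is ``sim_date`` minus the patient's age in years, so age is
    recoverable at any reference date later in the simulation year.
    Non-survivors carry deceasedDateTime.
    """
    birth = date(sim_date.year - patient.age, sim_date.month, sim_date.day)
    pat: dict = {
        "resourceType": "Patient",
        "id": patient.mrn,
        "identifier": [
            {
                "type": {"coding": [{"system": "http://terminology.hl7.org/CodeSystem/v2-0203", "code": "MR"}]},
                "value": patient.mrn,
            }
        ],
        "gender": patient.sex,
        "birthDate": birth.isoformat(),
    }
    if not patient.survived:
        pat["deceasedDateTime"] = _DECEASED
    entries = [
        {"fullUrl": f"urn:uuid:{patient.mrn}", "resource": pat},
        {
            "resource": {
                "resourceType": "Condition",
                "subject": {"reference": f"urn:uuid:{patient.mrn}"},
                "code": {
                    "coding": [{"system": "http://snomed.info/sct", "code": BREAST_CANCER_CODE,
                                "display": BREAST_CANCER_DISPLAY}],
                    "text": BREAST_CANCER_DISPLAY,
                },
                "onsetDateTime": _ONSET,
            }
        },
    ]
    if patient.drug != UNTREATED:
        entries.append(
            {
                "resource": {
                    "resourceType": "MedicationRequest",
                    "subject": {"reference": f"urn:uuid:{patient.mrn}"},
                    "medicationCodeableConcept": {"text": patient.drug},
                    "authoredOn": _AUTHORED,
                }
            }
        )
    return {"resourceType": "Bundle", "type": "collection", "entry": entries}


# ---------------------------------------------------------------------------
# VCF emission
# ---------------------------------------------------------------------------

def make_background_sites(n_sites: int, seed: int = 0, chrom: str = "chr1") -> list[Site]:
    """Random biallelic background SNPs with allele frequencies ~ U(0.05, 0.95)."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(2**20,)))
    bases = "ACGT"
    sites = []
    positions = np.sort(rng.choice(np.arange(10_000, 10_000_000), size=n_sites, replace=False))
    for pos in positions:
        ref = bases[rng.integers(4)]
        alt = bases[(bases.index(ref) + int(rng.integers(1, 4))) % 4]
        af = float(np.round(rng.uniform(0.05, 0.95), 4))
        sites.append(Site(chrom=chrom, pos=int(pos), ref=ref, alt=alt, af=af))
    return sites


_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele Frequency">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read Depth">
##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled Genotype Likelihoods">
##contig=<ID=chr1>
##contig=<ID=chr17>
"""


def _format_call(gt: tuple[int, int], rng: np.random.Generator) -> str:
    dp = max(1, int(rng.poisson(30)))
    q = int(rng.integers(30, 61))
    if gt == (0, 0):
        pl = (0, q, 2 * q)
    elif gt == (1, 1):
        pl = (2 * q, q, 0)
    else:
        pl = (q, 0, q)
    return f"{gt[0]}/{gt[1]}:{dp}:{','.join(map(str, pl))}"


def emit_vcf(
    patient: SimPatient,
    background_sites: list[Site],
    missing_rate: float = 0.1,
    seed: int = 0,
    pgx_site: Site = PGX_SITE,
) -> str:
    """Emit a single-sample VCF 4.2 document for one patient.

    The PGx site is always present and its genotype encodes carrier
    status. Background genotypes are drawn from each site's allele
    frequency; each background call is independently omitted from the
    file with probability ``missing_rate`` (a VCF, unlike a GVCF, says
    nothing about uncalled positions — this is what the downstream
    imputation stage repairs).
    """
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be in [0,1]")
    rng = _patient_rng(seed, patient.index, stream=1)
    sites = sorted(
        [*background_sites, pgx_site],
        key=lambda s: (_chrom_sort_key(s.chrom), s.pos),
    )
    lines = [_VCF_HEADER + f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{patient.mrn}"]
    for site in sites:
        is_pgx = (site.chrom, site.pos) == (pgx_site.chrom, pgx_site.pos)
        if is_pgx:
            gt = tuple(sorted(patient.genotype))
        else:
            dosage = int(rng.binomial(2, site.af))
            gt = {0: (0, 0), 1: (0, 1), 2: (1, 1)}[dosage]
            if rng.random() < missing_rate:
                continue  # call missing: site absent from this patient's VCF
        call = _format_call(gt, rng)
        lines.append(
            f"{site.chrom}\t{site.pos}\t.\t{site.ref}\t{site.alt}\t50\tPASS\t"
            f"AF={site.af}\tGT:DP:PL\t{call}"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Cohort writer (used by the pipeline and CLI)
# ---------------------------------------------------------------------------

def write_cohort(
    out_dir: str | Path,
    n: int,
    seed: int = 0,
    module: ModuleSpec | None = None,
    missing_rate: float = 0.1,
    n_background_sites: int = 100,
    pgx_site: Site = PGX_SITE,
) -> list[SimPatient]:
    """Simulate and write ``fhir/<mrn>.json``, ``vcf/<mrn>.vcf`` and truth.tsv."""
    out = Path(out_dir)
    (out / "fhir").mkdir(parents=True, exist_ok=True)
    (out / "vcf").mkdir(parents=True, exist_ok=True)
    cohort = simulate_cohort(n, module=module, seed=seed)
    sites = make_background_sites(n_background_sites, seed=seed)
    truth_lines = ["mrn\tage\tcarrier\tdrug\tsurvived"]
    for p in cohort:
        (out / "fhir" / f"{p.mrn}.json").write_text(json.dumps(emit_fhir(p), indent=1))
        (out / "vcf" / f"{p.mrn}.vcf").write_text(
            emit_vcf(p, sites, missing_rate=missing_rate, seed=seed, pgx_site=pgx_site)
        )
        truth_lines.append(f"{p.mrn}\t{p.age}\t{p.carrier}\t{p.drug}\t{p.survived}")
    (out / "truth.tsv").write_text("\n".join(truth_lines) + "\n")
    logger.info("wrote cohort of %d patients to %s", n, out)
    return cohort


# ---------------------------------------------------------------------------
# Clustering fixture
# ---------------------------------------------------------------------------

def gaussian_mixture_features(
    n: int, k: int, separation: float = 10.0, sigma: float = 1.0,
    n_features: int = 2, seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Labeled draws from ``k`` spherical Gaussian components.

    Component centers are equally spaced: the vertices of a regular
    (k-1)-simplex with edge length ``separation``, randomly rotated
    (requires ``n_features >= k - 1``). Returns (X, true_labels) for
    cluster-recovery tests.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if separation <= 0:
        raise ValueError("separation must be > 0")
    if n_features < k - 1:
        raise ValueError("equal center spacing needs n_features >= k - 1")
    rng = np.random.default_rng(seed)
    # regular simplex: centered identity rows have pairwise distance sqrt(2)
    centered = np.eye(k) - 1.0 / k
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    coords = (u * s)[:, : max(k - 1, 1)] * (separation / np.sqrt(2.0))
    centers = np.zeros((k, n_features))
    centers[:, : coords.shape[1]] = coords if k > 1 else 0.0
    q, _ = np.linalg.qr(rng.normal(size=(n_features, n_features)))
    centers = centers @ q.T
    labels = rng.integers(k, size=n)
    X = centers[labels] + rng.normal(scale=sigma, size=(n, n_features))
    return X, labels
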