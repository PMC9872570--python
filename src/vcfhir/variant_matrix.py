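"""Turn per-patient VCFs into a clean patient x variant-feature matrix.

The stages mirror a standard small-variant post-processing chain: read
VCF 4.2, split multi-allelic sites into biallelic records, left-align and
trim indels against the reference, prune variants in high linkage
disequilibrium, merge all patients into one site-major call table, impute
missing entries as average-quality reference calls, and finally transpose
into a patient-major feature matrix (four columns per variant: GT, AF,
DP, PL) suitable for merging with clinical data.
"""
from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

logger = logging.getLogger(__name__)

_ALLELE_RE = re.compile(r"^[ACGTN]+$")


class VcfParseError(ValueError):
    """Malformed VCF header or data line."""


class ReferenceMismatchError(ValueError):
    """REF allele disagrees with the reference sequence at its position."""


class DuplicateSampleError(ValueError):
    """The same patient id appears in more than one input VCF."""


class CannotImputeError(ValueError):
    """A patient has zero called sites, so per-patient averages are undefined."""


class MatrixFormatError(ValueError):
    """TSV column layout does not match the expected matrix schema."""


@dataclass
class SampleCall:
    """One sample's call at one site.

    ``gt`` is a pair of allele indexes (``(0, 1)`` for ``0/1``) or ``None``
    when the genotype is missing. ``pl`` is the phred-scaled genotype
    likelihood triple for a biallelic site. ``imputed`` marks calls filled
    in by :func:`impute_missing`.
    """

    gt: tuple[int, int] | None
    dp: int | None = None
    pl: tuple[int, int, int] | None = None
    imputed: bool = False

    @property
    def is_missing(self) -> bool:
        return self.gt is None

    @property
    def dosage(self) -> int:
        """Alt-allele count (0/1/2); missing genotypes have no dosage."""
        if self.gt is None:
            raise ValueError("missing genotype has no dosage")
        return sum(1 for a in self.gt if a >= 1)

    def gt_string(self) -> str:
        if self.gt is None:
            return "./."
        return f"{self.gt[0]}/{self.gt[1]}"

    @property
    def gq(self) -> int | None:
        """Genotype quality: second-smallest PL entry."""
        if self.pl is None:
            return None
        return sorted(self.pl)[1]


MISSING_CALL = SampleCall(gt=None, dp=None, pl=None, imputed=False)


@dataclass
class VariantRecord:
    """One VCF site with per-sample calls (1-based coordinates)."""

    chrom: str
    pos: int
    ref: str
    alts: list[str]
    af: list[float] | None = None
    calls: dict[str, SampleCall] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        for allele in [self.ref, *self.alts]:
            if not allele or not _ALLELE_RE.match(allele):
                raise ValueError(f"invalid allele {allele!r}")
        if self.af is not None and len(self.af) != len(self.alts):
            raise ValueError(
                f"AF count {len(self.af)} != alt count {len(self.alts)}"
            )

    @property
    def is_biallelic(self) -> bool:
        return len(self.alts) == 1

    def site_key(self) -> str:
        if not self.is_biallelic:
            raise ValueError("site key defined for biallelic records only")
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alts[0]}"


# ---------------------------------------------------------------------------
# VCF input
# ---------------------------------------------------------------------------

def _call_from_pysam(sample) -> SampleCall:
    gt = sample.get("GT")
    if gt is None or all(a is None for a in gt):
        gt_out = None
    elif any(a is None for a in gt):
        gt_out = None  # half-missing treated as missing
    else:
        gt_out = (int(gt[0]), int(gt[1]))
    dp = sample.get("DP")
    pl = sample.get("PL")
    if pl is not None:
        pl = tuple(int(x) for x in pl if x is not None)
        pl = pl if len(pl) == 3 else None
    return SampleCall(gt=gt_out, dp=None if dp is None else int(dp), pl=pl)


def read_vcf(path: str | Path) -> list[VariantRecord]:
    """Read a VCF 4.2 file into :class:`VariantRecord` objects.

    Missing FORMAT values stay missing (never zero-filled). Malformed
    headers or data lines raise :class:`VcfParseError` naming the line.
    """
    path = str(path)
    try:
        vf = pysam.VariantFile(path)
    except Exception as exc:  # pysam raises ValueError/OSError variants
        raise VcfParseError(f"{path}: malformed VCF header: {exc}") from exc
    n_header = len(str(vf.header).splitlines())
    records: list[VariantRecord] = []
    it = iter(vf)
    i = 0
    while True:
        line_no = n_header + i + 1
        try:
            rec = next(it)
        except StopIteration:
            break
        except Exception as exc:
            raise VcfParseError(f"{path}: malformed data line {line_no}: {exc}") from exc
        try:
            af = rec.info.get("AF")
            if af is not None:
                af = [float(x) for x in (af if isinstance(af, tuple) else (af,))]
            calls = {name: _call_from_pysam(rec.samples[name]) for name in rec.samples}
            records.append(
                VariantRecord(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alts=list(rec.alts or ()),
                    af=af,
                    calls=calls,
                )
            )
        except ValueError as exc:
            raise VcfParseError(f"{path}: malformed data line {line_no}: {exc}") from exc
        i += 1
    return records


# ---------------------------------------------------------------------------
# Multi-allelic splitting
# ---------------------------------------------------------------------------

def split_multiallelic(record: VariantRecord) -> list[VariantRecord]:
    """Split a multi-allelic record into one biallelic record per alt.

    Genotype allele indexes pointing at the focal alt become 1; indexes
    pointing at any other alt become 0 (a lossy recode, logged). The
    per-alt AF travels with its record. Biallelic input is returned as-is.
    """
    if not record.alts:
        raise ValueError("record has no alt alleles")
    if record.is_biallelic:
        return [record]
    out: list[VariantRecord] = []
    for j, alt in enumerate(record.alts):
        focal = j + 1
        calls: dict[str, SampleCall] = {}
        recoded = False
        for sample, call in record.calls.items():
            if call.gt is None:
                calls[sample] = replace(call)
                continue
            new_gt = tuple(1 if a == focal else 0 for a in call.gt)
            if any(a not in (0, focal) for a in call.gt):
                recoded = True
            calls[sample] = replace(call, gt=(new_gt[0], new_gt[1]))
        if recoded:
            logger.info(
                "lossy genotype recode at %s:%d while splitting alt %s",
                record.chrom, record.pos, alt,
            )
        out.append(
            VariantRecord(
                chrom=record.chrom,
                pos=record.pos,
                ref=record.ref,
                alts=[alt],
                af=None if record.af is None else [record.af[j]],
                calls=calls,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Normalization (parsimony + left alignment)
# ---------------------------------------------------------------------------

def _ref_base(reference: Mapping[str, str], chrom: str, pos: int) -> str:
    """1-based single-base access working for dict-of-str and pyfaidx.Fasta."""
    seq = reference[chrom]
    return str(seq[pos - 1 : pos]).upper()


def normalize(
    record: VariantRecord, reference: Mapping[str, str] | None
) -> VariantRecord:
    """Left-align and trim a biallelic variant to its canonical form.

    Iteratively truncates a shared trailing base; when an allele empties,
    prepends the preceding reference base and decrements ``pos``; finally
    trims shared leading bases while both alleles keep length >= 2. The
    result is parsimonious, leftmost, and idempotent, and applying it to
    the reference yields the same alternate sequence as the input edit.

    Without a reference, degrades to parsimony trimming only (left
    alignment needs sequence context); a warning is logged.
    """
    if not record.is_biallelic:
        raise ValueError("normalize requires a biallelic record")
    pos, ref, alt = record.pos, record.ref, record.alts[0]
    if reference is not None:
        observed = str(reference[record.chrom][pos - 1 : pos - 1 + len(ref)]).upper()
        if observed != ref:
            raise ReferenceMismatchError(
                f"{record.chrom}:{pos} REF {ref} != reference {observed}"
            )
        # vt-style: truncate shared trailing base; extend left when emptied
        while True:
            if len(ref) == 1 and len(alt) == 1:
                break
            if ref[-1] != alt[-1]:
                break
            if (len(ref) == 1 or len(alt) == 1) and pos == 1:
                break  # at the contig start there is no base to prepend
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                pos -= 1
                b = _ref_base(reference, record.chrom, pos)
                ref, alt = b + ref, b + alt
    else:
        logger.debug(
            "no reference supplied: %s:%d normalized by parsimony trimming only",
            record.chrom, record.pos,
        )
        while len(ref) >= 2 and len(alt) >= 2 and ref[-1] == alt[-1]:
            ref, alt = ref[:-1], alt[:-1]
    # parsimony: trim shared leading bases while both alleles keep length >= 2
    while len(ref) >= 2 and len(alt) >= 2 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    if (pos, ref, alt) == (record.pos, record.ref, record.alts[0]):
        return record
    return replace(record, pos=pos, ref=ref, alts=[alt])


def apply_edit(sequence: str, pos: int, ref: str, alt: str) -> str:
    """Apply a single REF>ALT edit to a contig sequence (1-based pos)."""
    start = pos - 1
    if sequence[start : start + len(ref)] != ref:
        raise ReferenceMismatchError(f"edit REF {ref} absent at pos {pos}")
    return sequence[:start] + alt + sequence[start + len(ref):]


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _r2(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        return 0.0  # zero-variance dosage vector: r^2 defined as 0
    r = float(np.corrcoef(a, b)[0, 1])
    return r * r


def ld_prune(
    genotypes: np.ndarray,
    r2_threshold: float = 0.5,
    window: int = 50,
    step: int = 5,
    chroms: Sequence[str] | None = None,
) -> list[int]:
    """Windowed pairwise LD pruning on a variant x patient dosage matrix.

    Slides a ``window``-variant window in increments of ``step``; within
    each window any retained pair with squared Pearson correlation of
    dosage vectors >= ``r2_threshold`` loses its later member (position
    order is the tie-break, so output is deterministic). Variants with
    zero dosage variance correlate 0 with everything (logged). When
    ``chroms`` is given, windows never span a chromosome boundary.
    """
    X = np.asarray(genotypes, dtype=float)
    n = X.shape[0]
    if not 0.0 <= r2_threshold <= 1.0:
        raise ValueError("r2_threshold must be in [0, 1]")
    if chroms is not None and len(chroms) != n:
        raise ValueError("chroms length must match variant count")
    removed = np.zeros(n, dtype=bool)
    zero_var = [i for i in range(n) if X[i].std() == 0.0]
    if zero_var:
        logger.info("%d zero-variance dosage vectors (r^2 taken as 0)", len(zero_var))
    for start in range(0, max(n - 1, 1), step):
        stop = min(start + window, n)
        idx = [i for i in range(start, stop) if not removed[i]]
        for ai in range(len(idx)):
            a = idx[ai]
            if removed[a]:
                continue
            for b in idx[ai + 1:]:
                if removed[b]:
                    continue
                if chroms is not None and chroms[a] != chroms[b]:
                    continue
                if _r2(X[a], X[b]) >= r2_threshold:
                    removed[b] = True
        if stop == n:
            break
    return [i for i in range(n) if not removed[i]]


# ---------------------------------------------------------------------------
# Merging, imputation, transposition
# ---------------------------------------------------------------------------

@dataclass
class Site:
    chrom: str
    pos: int
    ref: str
    alt: str
    af: float | None = None

    @property
    def key(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def _chrom_sort_key(chrom: str) -> tuple:
    m = re.match(r"^(chr)?(\d+|[XYM]|MT)$", chrom)
    if m:
        tok = m.group(2)
        order = {"X": 23, "Y": 24, "M": 25, "MT": 25}
        return (0, order.get(tok, 0) or int(tok), chrom)
    return (1, 0, chrom)


@dataclass
class CallTable:
    """Site-major merged call table: sites x patients."""

    sites: list[Site]
    patients: list[str]
    calls: list[dict[str, SampleCall]]  # aligned with sites; one entry per patient

    def missing_count(self) -> int:
        return sum(
            1 for row in self.calls for p in self.patients if row[p].is_missing
        )

    def has_missing(self) -> bool:
        return self.missing_count() > 0


def merge_samples(tables: list[list[VariantRecord]]) -> CallTable:
    """Merge per-patient biallelic record lists into one call table.

    The site key is (chrom, pos, ref, alt); the site set is the union over
    patients and patients without a call at a site hold an explicit
    missing :class:`SampleCall`. Duplicate patient ids across inputs raise
    :class:`DuplicateSampleError`. Missing per-site AF is recomputed as
    the cohort alt-allele frequency (logged).
    """
    patients: list[str] = []
    for records in tables:
        for rec in records:
            for sample in rec.calls:
                if sample not in patients:
                    patients.append(sample)
                break  # sample set is constant within one patient's VCF
    seen: set[str] = set()
    for records in tables:
        names = {s for rec in records for s in rec.calls}
        dup = names & seen
        if dup:
            raise DuplicateSampleError(f"duplicate patient id(s): {sorted(dup)}")
        seen |= names

    by_key: dict[tuple, Site] = {}
    calls_by_key: dict[tuple, dict[str, SampleCall]] = {}
    for records in tables:
        for rec in records:
            if not rec.is_biallelic:
                raise ValueError("merge_samples requires biallelic records")
            key = (rec.chrom, rec.pos, rec.ref, rec.alts[0])
            if key not in by_key:
                af = None if rec.af is None else rec.af[0]
                by_key[key] = Site(rec.chrom, rec.pos, rec.ref, rec.alts[0], af)
                calls_by_key[key] = {}
            elif by_key[key].af is None and rec.af is not None:
                by_key[key].af = rec.af[0]
            calls_by_key[key].update(rec.calls)

    ordered = sorted(by_key, key=lambda k: (_chrom_sort_key(k[0]), k[1], k[2], k[3]))
    sites, call_rows = [], []
    for key in ordered:
        site = by_key[key]
        row = {p: calls_by_key[key].get(p, replace(MISSING_CALL)) for p in patients}
        if site.af is None:
            called = [row[p] for p in patients if not row[p].is_missing]
            if called:
                site.af = sum(c.dosage for c in called) / (2 * len(called))
                logger.info("AF for %s recomputed from cohort genotypes", site.key)
        sites.append(site)
        call_rows.append(row)
    return CallTable(sites=sites, patients=patients, calls=call_rows)


def impute_missing(table: CallTable) -> CallTable:
    """Replace missing calls with average-quality reference calls.

    Input VCFs (unlike GVCFs) carry no information for non-variant
    positions, so every missing entry is assumed to be a homozygous
    reference call of that patient's average depth and quality:
    GT=0/0, DP = round(mean called DP), PL = [0, g, 2g] with g =
    round(mean genotype quality), GQ being the second-smallest PL entry.
    """
    mean_dp: dict[str, float] = {}
    mean_gq: dict[str, float] = {}
    for p in table.patients:
        dps = [row[p].dp for row in table.calls if not row[p].is_missing and row[p].dp is not None]
        gqs = [row[p].gq for row in table.calls if not row[p].is_missing and row[p].gq is not None]
        n_called = sum(1 for row in table.calls if not row[p].is_missing)
        if n_called == 0:
            raise CannotImputeError(f"patient {p} has zero called sites")
        mean_dp[p] = float(np.mean(dps)) if dps else 0.0
        mean_gq[p] = float(np.mean(gqs)) if gqs else 0.0

    new_rows: list[dict[str, SampleCall]] = []
    for row in table.calls:
        new_row: dict[str, SampleCall] = {}
        for p, call in row.items():
            if call.is_missing:
                g = int(round(mean_gq[p]))
                new_row[p] = SampleCall(
                    gt=(0, 0),
                    dp=int(round(mean_dp[p])),
                    pl=(0, g, 2 * g),
                    imputed=True,
                )
            else:
                dp = call.dp
                pl = call.pl
                imputed = call.imputed
                if dp is None:  # called genotype with missing depth: degenerate input
                    dp, imputed = int(round(mean_dp[p])), True
                if pl is None:
                    g = int(round(mean_gq[p]))
                    pl = (0, g, 2 * g) if call.gt == (0, 0) else (0, 0, 0)
                    imputed = True
                new_row[p] = SampleCall(gt=call.gt, dp=dp, pl=pl, imputed=imputed)
        new_rows.append(new_row)
    return CallTable(sites=list(table.sites), patients=list(table.patients), calls=new_rows)


FEATURE_FIELDS = ("GT", "AF", "DP", "PL")


@dataclass
class PatientGenomicMatrix:
    """Patient-major feature matrix: 4 columns (GT, AF, DP, PL) per variant.

    GT columns hold genotype strings ("0/1"), AF floats, DP ints, PL the
    likelihood triple as "a,b,c". ``imputed`` is a parallel patients x
    site-key boolean frame flagging imputed calls.
    """

    data: pd.DataFrame  # index: patient ids; columns: "<sitekey>:<field>"
    imputed: pd.DataFrame  # index: patient ids; columns: site keys; bool

    @property
    def patients(self) -> list[str]:
        return list(self.data.index)

    @property
    def site_keys(self) -> list[str]:
        return [c[:-3] for c in self.data.columns if c.endswith(":GT")]

    def dosage(self, patient: str, site_key: str) -> int:
        gt = self.data.loc[patient, f"{site_key}:GT"]
        return sum(1 for a in gt.split("/") if a != "." and int(a) >= 1)

    def dosage_frame(self) -> pd.DataFrame:
        """Patients x sites alt-allele-count matrix (numeric view of GT)."""
        cols = {}
        for key in self.site_keys:
            cols[key] = self.data[f"{key}:GT"].map(
                lambda s: sum(1 for a in s.split("/") if a != "." and int(a) >= 1)
            )
        return pd.DataFrame(cols, index=self.data.index)


def to_patient_matrix(table: CallTable) -> PatientGenomicMatrix:
    """Transpose a fully imputed call table into a patient-major matrix."""
    if table.has_missing():
        raise ValueError("call table still contains missing calls; impute first")
    columns: dict[str, list] = {}
    flag_cols: dict[str, list[bool]] = {}
    for site, row in zip(table.sites, table.calls):
        key = site.key
        columns[f"{key}:GT"] = [row[p].gt_string() for p in table.patients]
        columns[f"{key}:AF"] = [site.af if site.af is not None else float("nan")] * len(table.patients)
        columns[f"{key}:DP"] = [row[p].dp for p in table.patients]
        columns[f"{key}:PL"] = [",".join(map(str, row[p].pl)) for p in table.patients]
        flag_cols[key] = [row[p].imputed for p in table.patients]
    data = pd.DataFrame(columns, index=pd.Index(table.patients, name="patient"))
    flags = pd.DataFrame(flag_cols, index=data.index)
    return PatientGenomicMatrix(data=data, imputed=flags)


def from_patient_matrix(matrix: PatientGenomicMatrix) -> CallTable:
    """Inverse of :func:`to_patient_matrix` (lossless on shared fields)."""
    patients = matrix.patients
    sites: list[Site] = []
    calls: list[dict[str, SampleCall]] = []
    for key in matrix.site_keys:
        chrom, pos, edit = key.split(":")
        ref, alt = edit.split(">")
        af = float(matrix.data[f"{key}:AF"].iloc[0])
        sites.append(Site(chrom, int(pos), ref, alt, af))
        row = {}
        for p in patients:
            gt = tuple(int(a) for a in matrix.data.loc[p, f"{key}:GT"].split("/"))
            pl = tuple(int(x) for x in matrix.data.loc[p, f"{key}:PL"].split(","))
            row[p] = SampleCall(
                gt=(gt[0], gt[1]),
                dp=int(matrix.data.loc[p, f"{key}:DP"]),
                pl=(pl[0], pl[1], pl[2]),
                imputed=bool(matrix.imputed.loc[p, key]),
            )
        calls.append(row)
    order = sorted(
        range(len(sites)),
        key=lambda i: (_chrom_sort_key(sites[i].chrom), sites[i].pos, sites[i].ref, sites[i].alt),
    )
    return CallTable(
        sites=[sites[i] for i in order],
        patients=patients,
        calls=[calls[i] for i in order],
    )


# ---------------------------------------------------------------------------
# TSV round trip
# ---------------------------------------------------------------------------

IMPUTED_COLUMN = "imputed_sites"


def write_tsv(matrix: PatientGenomicMatrix, path: str | Path) -> None:
    """Write the matrix as TSV; imputed flags go to a companion column."""
    df = matrix.data.copy()
    df[IMPUTED_COLUMN] = [
        ";".join(k for k in matrix.imputed.columns if matrix.imputed.loc[p, k])
        for p in matrix.patients
    ]
    df.to_csv(path, sep="\t", index=True, index_label="patient")


def read_tsv(path: str | Path) -> PatientGenomicMatrix:
    """Read a matrix written by :func:`write_tsv` (exact round trip)."""
    try:
        df = pd.read_csv(
            path, sep="\t", index_col="patient", dtype=str,
            keep_default_na=False, on_bad_lines="error",
        )
    except (pd.errors.ParserError, ValueError, KeyError) as exc:
        raise MatrixFormatError(f"{path}: {exc}") from exc
    if IMPUTED_COLUMN not in df.columns:
        raise MatrixFormatError(f"{path}: missing {IMPUTED_COLUMN!r} column")
    expected = {f for c in df.columns if c != IMPUTED_COLUMN for f in (c.rsplit(":", 1)[-1],)}
    if not expected <= set(FEATURE_FIELDS):
        raise MatrixFormatError(f"{path}: unexpected feature columns {expected - set(FEATURE_FIELDS)}")
    imputed_raw = df.pop(IMPUTED_COLUMN)
    site_keys = [c[:-3] for c in df.columns if c.endswith(":GT")]
    for key in site_keys:
        for f in FEATURE_FIELDS:
            if f"{key}:{f}" not in df.columns:
                raise MatrixFormatError(f"{path}: variant {key} lacks {f} column")
        df[f"{key}:AF"] = df[f"{key}:AF"].astype(float)
        df[f"{key}:DP"] = df[f"{key}:DP"].astype(int)
    flags = pd.DataFrame(False, index=df.index, columns=site_keys)
    for p, raw in imputed_raw.items():
        for key in filter(None, raw.split(";")):
            flags.loc[p, key] = True
    df.index.name = "patient"
    return PatientGenomicMatrix(data=df, imputed=flags)


# ---------------------------------------------------------------------------
# One-call pipeline over a set of per-patient VCFs
# ---------------------------------------------------------------------------

def vcfs_to_matrix(
    paths: Iterable[str | Path],
    reference: Mapping[str, str] | None = None,
    r2_threshold: float = 0.5,
    window: int = 50,
    step: int = 5,
) -> PatientGenomicMatrix:
    """Full chain: read, split, normalize, merge, LD-prune, impute, transpose."""
    if reference is None:
        logger.warning(
            "no reference supplied: normalization degrades to parsimony trimming"
        )
    tables = []
    for p in paths:
        records = []
        for rec in read_vcf(p):
            for bi in split_multiallelic(rec):
                records.append(normalize(bi, reference))
        tables.append(records)
    merged = merge_samples(tables)
    # dosage matrix for pruning: missing treated as 0 alt alleles
    dosages = np.array(
        [
            [0 if row[p].is_missing else row[p].dosage for p in merged.patients]
            for row in merged.calls
        ],
        dtype=float,
    )
    keep = ld_prune(
        dosages, r2_threshold, window, step,
        chroms=[s.chrom for s in merged.sites],
    )
    pruned = CallTable(
        sites=[merged.sites[i] for i in keep],
        patients=merged.patients,
        calls=[merged.calls[i] for i in keep],
    )
    logger.info("LD pruning kept %d of %d sites", len(keep), len(merged.sites))
    return to_patient_matrix(impute_missing(pruned))
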