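"""Flatten FHIR R4 JSON bundles into a one-row-per-patient table.

Clinical data for one patient is spread over several FHIR resources
(Patient, Condition, MedicationRequest, Observation) inside a Bundle.
This module links them via the patient's Medical Record Number (MRN),
flattens the pieces the downstream applications consume into fixed
columns, keeps anything unmapped verbatim as a JSON-string column, and
round-trips the result through Parquet (or CSV).
"""
from __future__ import annotations

import copy
import json
import logging
from collections import Counter
from dataclasses import dataclass
from datetime import date, datetime
from pathlib import Path

import pandas as pd

logger = logging.getLogger(__name__)

SUPPORTED_RESOURCE_TYPES = {"Patient", "Condition", "MedicationRequest", "Observation"}

DEMOGRAPHIC_COLUMNS = ["mrn", "gender", "birth_date", "age", "survived", "deceased_datetime"]


class BundleParseError(ValueError):
    """Bundle entry is structurally invalid (e.g. missing resourceType)."""


class OrphanResourceError(ValueError):
    """A non-Patient resource's subject cannot be resolved to a Patient."""


class PatientCardinalityError(ValueError):
    """Zero or multiple Patient resources where exactly one is required."""


class DuplicatePatientError(ValueError):
    """The same MRN appears in more than one bundle."""


class TableFormatError(ValueError):
    """Columnar file does not match the clinical-table schema."""


@dataclass
class FhirResource:
    """One supported resource, tagged with the owning patient's MRN."""

    resource_type: str
    raw: dict
    subject_mrn: str

    def __post_init__(self) -> None:
        if self.raw.get("resourceType") != self.resource_type:
            raise ValueError("resource_type does not match JSON resourceType")
        if self.resource_type != "Patient" and not self.subject_mrn:
            raise ValueError("non-Patient resource requires a subject MRN")


@dataclass
class BundleReport:
    resources: list[FhirResource]
    skipped: Counter  # resourceType -> count of unsupported entries


def patient_mrn(patient: dict) -> str:
    """MRN = identifier whose type coding is "MR"; falls back to Patient.id."""
    for ident in patient.get("identifier", []):
        for coding in ident.get("type", {}).get("coding", []):
            if coding.get("code") == "MR":
                return str(ident.get("value", ""))
    pid = str(patient.get("id", ""))
    if pid:
        logger.info("Patient lacks an MR identifier; using Patient.id %s", pid)
    return pid


def _subject_ref(resource: dict) -> str | None:
    return resource.get("subject", {}).get("reference")


def parse_bundle_report(bundle: dict) -> BundleReport:
    """Parse one Bundle, resolving subjects to the bundle's Patient MRN.

    Subject references of the forms ``Patient/<id>`` and ``urn:uuid:<id>``
    are resolved against the bundle's Patient entries (fullUrl or id).
    Unsupported resource types are counted and skipped.
    """
    entries = bundle.get("entry", [])
    # first pass: patients, keyed by every name a subject reference may use
    ref_to_mrn: dict[str, str] = {}
    for i, entry in enumerate(entries):
        res = entry.get("resource", {})
        rtype = res.get("resourceType")
        if rtype is None:
            raise BundleParseError(f"bundle entry {i} missing resourceType")
        if rtype != "Patient":
            continue
        mrn = patient_mrn(res)
        if entry.get("fullUrl"):
            ref_to_mrn[entry["fullUrl"]] = mrn
        if res.get("id"):
            ref_to_mrn[f"Patient/{res['id']}"] = mrn
            ref_to_mrn[f"urn:uuid:{res['id']}"] = mrn

    resources: list[FhirResource] = []
    skipped: Counter = Counter()
    for i, entry in enumerate(entries):
        res = entry.get("resource", {})
        rtype = res["resourceType"]
        if rtype not in SUPPORTED_RESOURCE_TYPES:
            skipped[rtype] += 1
            continue
        if rtype == "Patient":
            resources.append(FhirResource("Patient", res, patient_mrn(res)))
            continue
        ref = _subject_ref(res)
        mrn = ref_to_mrn.get(ref or "")
        if mrn is None:
            raise OrphanResourceError(
                f"bundle entry {i} ({rtype}) subject {ref!r} does not resolve to a Patient"
            )
        resources.append(FhirResource(rtype, res, mrn))
    if skipped:
        logger.info("skipped unsupported resources: %s", dict(skipped))
    return BundleReport(resources=resources, skipped=skipped)


def parse_bundle(bundle: dict) -> list[FhirResource]:
    return parse_bundle_report(bundle).resources


# ---------------------------------------------------------------------------
# Flattening
# ---------------------------------------------------------------------------

def _pop_path(obj: dict, *path):
    """Remove and return a nested value; leaves siblings in place."""
    node = obj
    for key in path[:-1]:
        if not isinstance(node, dict) or key not in node:
            return None
        node = node[key]
    if isinstance(node, dict):
        return node.pop(path[-1], None)
    return None


def _prune_empty(node):
    if isinstance(node, dict):
        return {k: p for k, v in node.items() if (p := _prune_empty(v)) not in ({}, [], None)}
    if isinstance(node, list):
        return [p for v in node if (p := _prune_empty(v)) not in ({}, [], None)]
    return node


def _primary_code(codeable: dict | None) -> str | None:
    if not codeable:
        return None
    for coding in codeable.get("coding", []):
        if coding.get("code"):
            return str(coding["code"])
    return codeable.get("text")


def _consume_code(node: dict, key: str = "code") -> str | None:
    """Pop the primary code leaf out of a CodeableConcept, in place.

    Only the consumed leaf (and its structural ``system``) is removed;
    sibling leaves such as display/text survive into the leftover JSON.
    """
    cc = node.get(key)
    if not cc:
        return None
    for coding in cc.get("coding", []):
        if coding.get("code"):
            val = str(coding.pop("code"))
            coding.pop("system", None)
            return val
    if cc.get("text") is not None:
        return str(cc.pop("text"))
    return None


# keys that identify/link a resource rather than carry clinical content
_STRUCTURAL_KEYS = {"resourceType", "id", "subject"}


def _leftover_json(working: dict) -> str | None:
    """Serialize whatever flattening did not consume, as a JSON string."""
    rest = {k: v for k, v in working.items() if k not in _STRUCTURAL_KEYS}
    rest = _prune_empty(rest)
    return json.dumps(rest, sort_keys=True) if rest else None


def extract_patient_row(resources: list[FhirResource]) -> dict:
    """Flatten all of one patient's resources into a single row dict.

    Demographics come from the Patient; each Condition contributes its
    primary code and onset, each MedicationRequest its code/text, each
    Observation a code/value pair. Repeated resources are indexed in
    (date, code) order. Unmapped nested structure is preserved verbatim
    in ``*_json`` columns.
    """
    patients = [r for r in resources if r.resource_type == "Patient"]
    if len(patients) != 1:
        raise PatientCardinalityError(
            f"expected exactly one Patient resource, found {len(patients)}"
        )
    pat = copy.deepcopy(patients[0].raw)
    deceased_dt = pat.pop("deceasedDateTime", None)
    deceased = deceased_dt is not None or pat.pop("deceasedBoolean", False) is True
    row: dict = {
        "mrn": patients[0].subject_mrn,
        "gender": pat.pop("gender", None),
        "birth_date": pat.pop("birthDate", None),
        "survived": not deceased,
        "deceased_datetime": deceased_dt,
    }
    pat.pop("identifier", None)  # wholly consumed by the MRN mapping
    leftover = _leftover_json(pat)
    if leftover:
        row["patient_json"] = leftover

    conditions = sorted(
        (copy.deepcopy(r.raw) for r in resources if r.resource_type == "Condition"),
        key=lambda c: (c.get("onsetDateTime") or "", _primary_code(c.get("code")) or ""),
    )
    for i, cond in enumerate(conditions, 1):
        row[f"condition_{i}"] = _consume_code(cond)
        onset = cond.pop("onsetDateTime", None)
        if onset:
            row[f"condition_{i}_onset"] = onset
        leftover = _leftover_json(cond)
        if leftover:
            row[f"condition_{i}_json"] = leftover

    meds = sorted(
        (copy.deepcopy(r.raw) for r in resources if r.resource_type == "MedicationRequest"),
        key=lambda m: (
            m.get("authoredOn") or "",
            m.get("medicationCodeableConcept", {}).get("text")
            or _primary_code(m.get("medicationCodeableConcept")) or "",
        ),
    )
    for i, med in enumerate(meds, 1):
        concept = med.get("medicationCodeableConcept", {})
        if concept.get("text") is not None:
            row[f"medication_{i}"] = str(concept.pop("text"))
        else:
            row[f"medication_{i}"] = _consume_code(med, "medicationCodeableConcept")
        authored = med.pop("authoredOn", None)
        if authored:
            row[f"medication_{i}_authored"] = authored
        leftover = _leftover_json(med)
        if leftover:
            row[f"medication_{i}_json"] = leftover

    observations = sorted(
        (copy.deepcopy(r.raw) for r in resources if r.resource_type == "Observation"),
        key=lambda o: (o.get("effectiveDateTime") or "", _primary_code(o.get("code")) or ""),
    )
    obs_seen: Counter = Counter()
    for obs in observations:
        code = _consume_code(obs) or "unknown"
        obs_seen[code] += 1
        col = f"observation_{code}" if obs_seen[code] == 1 else f"observation_{code}_{obs_seen[code]}"
        if "valueQuantity" in obs:
            row[col] = obs["valueQuantity"].pop("value", None)
        elif "valueString" in obs:
            row[col] = obs.pop("valueString")
        elif "valueBoolean" in obs:
            row[col] = obs.pop("valueBoolean")
        leftover = _leftover_json(obs)
        if leftover:
            row[f"{col}_json"] = leftover
    return row


def _parse_date(value) -> date | None:
    if not isinstance(value, str):
        return None
    try:
        return datetime.fromisoformat(value.replace("Z", "+00:00")).date()
    except ValueError:
        try:
            return date.fromisoformat(value[:10])
        except ValueError:
            return None


def _age_at(birth: date, ref: date) -> int:
    years = ref.year - birth.year
    if (ref.month, ref.day) < (birth.month, birth.day):
        years -= 1
    return years


def flatten_to_table(
    resources: list[FhirResource], reference_date: date | None = None
) -> pd.DataFrame:
    """Build the clinical table: one row per MRN, union of columns.

    ``age`` is computed at ``reference_date`` (default: the latest date
    appearing anywhere in the cohort's mapped fields). Column order is
    deterministic: demographics first, then condition/medication/
    observation columns sorted by name.
    """
    by_mrn: dict[str, list[FhirResource]] = {}
    for res in resources:
        by_mrn.setdefault(res.subject_mrn, []).append(res)
    for mrn, group in by_mrn.items():
        n_pat = sum(1 for r in group if r.resource_type == "Patient")
        if n_pat > 1:
            raise DuplicatePatientError(f"MRN {mrn} has {n_pat} Patient resources")
    rows = [extract_patient_row(group) for group in by_mrn.values()]
    df = pd.DataFrame(rows) if rows else pd.DataFrame(columns=DEMOGRAPHIC_COLUMNS)
    if rows:
        df = df.sort_values("mrn", kind="stable").reset_index(drop=True)

    if reference_date is None:
        dates = [
            d
            for row in rows
            for v in row.values()
            if (d := _parse_date(v)) is not None
        ]
        reference_date = max(dates) if dates else date.today()
    ages = []
    for _, r in df.iterrows():
        birth = _parse_date(r.get("birth_date"))
        ages.append(_age_at(birth, reference_date) if birth else None)
    df["age"] = pd.Series(ages, index=df.index, dtype="Int64") if len(df) else pd.Series(dtype="Int64")

    front = [c for c in DEMOGRAPHIC_COLUMNS if c in df.columns]
    rest = sorted(c for c in df.columns if c not in front)
    return df[front + rest]


def flatten_bundles(
    bundles: list[dict], reference_date: date | None = None
) -> pd.DataFrame:
    resources: list[FhirResource] = []
    for b in bundles:
        resources.extend(parse_bundle(b))
    return flatten_to_table(resources, reference_date=reference_date)


def load_bundle_dir(path: str | Path) -> list[dict]:
    """Read every ``*.json`` bundle under a directory (sorted, stable)."""
    files = sorted(Path(path).glob("*.json"))
    return [json.loads(f.read_text()) for f in files]


# ---------------------------------------------------------------------------
# Columnar round trip
# ---------------------------------------------------------------------------

def write_columnar(table: pd.DataFrame, path: str | Path) -> None:
    """Write the clinical table as Parquet (or CSV for ``.csv`` paths)."""
    path = Path(path)
    if path.suffix == ".csv":
        table.to_csv(path, index=False)
    else:
        table.to_parquet(path, index=False)


def read_columnar(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        if path.suffix == ".csv":
            df = pd.read_csv(path, keep_default_na=False, na_values=[""])
        else:
            df = pd.read_parquet(path)
    except Exception as exc:
        raise TableFormatError(f"{path}: unreadable columnar file: {exc}") from exc
    if "mrn" not in df.columns:
        raise TableFormatError(f"{path}: schema mismatch, no 'mrn' column")
    return df
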