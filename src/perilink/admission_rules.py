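"""Identification of birth admissions and code-derived clinical variables.

Infant birth admissions and maternal delivery admissions are identified from
hospital records alone — independently of the birth registration — using
ICD-10-AM diagnosis and ACHI procedure code lists shipped in
``vocab/tables.yml``, plus administrative fields (age, birthweight, source
of referral, admission order). Cross-record date/hospital constraints are
enforced separately so that a candidate link can be vetoed even when both
records are individually plausible.

Code matching is hierarchical and case-insensitive: a list entry ``O24``
matches ``O24.1``; dotted ranges such as ``O60.1-O60.3`` expand to their
members. Records whose codes support neither reading are classified
``unclassifiable`` explicitly, never silently defaulted.
"""

from __future__ import annotations

import datetime as dt
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "CodeList",
    "Vocabulary",
    "load_vocabulary",
    "normalize_code",
    "identify_infant_birth_admission",
    "identify_maternal_delivery_admission",
    "check_link_constraints",
    "derive_variables",
    "classify_plurality_stillbirth",
    "classify_admissions",
]

log = logging.getLogger(__name__)

_CODE_RE = re.compile(r"^[A-Z0-9]+$")


def normalize_code(code: str) -> str:
    """Uppercase and strip the dot: ``o24.4`` -> ``O244``."""
    return str(code).strip().upper().replace(".", "")


def _expand_entry(entry: str) -> list[str]:
    """Expand one vocabulary entry into normalized prefixes.

    ``O80-O84`` -> O80..O84; ``O60.1-O60.3`` -> O601..O603;
    ``90467-90470`` -> the four codes; plain entries normalize as-is.
    """
    entry = str(entry).strip().upper()
    if "-" not in entry:
        return [normalize_code(entry)]
    lo, hi = (normalize_code(p) for p in entry.split("-", 1))
    m_lo = re.match(r"^([A-Z]*)(\d+)$", lo)
    m_hi = re.match(r"^([A-Z]*)(\d+)$", hi)
    if not m_lo or not m_hi or m_lo.group(1) != m_hi.group(1) or len(
        m_lo.group(2)
    ) != len(m_hi.group(2)):
        raise ValueError(f"malformed code range: {entry!r}")
    alpha, width = m_lo.group(1), len(m_lo.group(2))
    a, b = int(m_lo.group(2)), int(m_hi.group(2))
    if a > b:
        raise ValueError(f"range start exceeds end: {entry!r}")
    return [f"{alpha}{i:0{width}d}" for i in range(a, b + 1)]


@dataclass(frozen=True)
class CodeList:
    """A named set of diagnosis/procedure code prefixes with range support."""

    name: str
    diagnosis_codes: tuple[str, ...] = ()
    procedure_codes: tuple[str, ...] = ()
    table_label: str | None = None
    _diag_prefixes: tuple[str, ...] = field(init=False, repr=False, default=())
    _proc_prefixes: tuple[str, ...] = field(init=False, repr=False, default=())

    def __post_init__(self) -> None:
        diag = tuple(p for e in self.diagnosis_codes for p in _expand_entry(e))
        proc = tuple(p for e in self.procedure_codes for p in _expand_entry(e))
        object.__setattr__(self, "_diag_prefixes", diag)
        object.__setattr__(self, "_proc_prefixes", proc)

    def matches_diagnosis(self, code: str) -> bool:
        c = normalize_code(code)
        return bool(c) and any(c.startswith(p) for p in self._diag_prefixes)

    def matches_procedure(self, code: str) -> bool:
        c = normalize_code(code)
        return bool(c) and any(c.startswith(p) for p in self._proc_prefixes)

    def matches_record(self, diagnoses: Iterable[str], procedures: Iterable[str] = ()) -> bool:
        return any(self.matches_diagnosis(c) for c in _clean(diagnoses)) or any(
            self.matches_procedure(c) for c in _clean(procedures)
        )

    def pattern(self, kind: str) -> str | None:
        """Regex over a space-joined normalized code string (vectorized path)."""
        prefixes = self._diag_prefixes if kind == "diagnosis" else self._proc_prefixes
        if not prefixes:
            return None
        alts = "|".join(re.escape(p) for p in prefixes)
        return rf"(?:^| )(?:{alts})"


def _clean(codes: Iterable[str]) -> list[str]:
    out = []
    for c in codes:
        n = normalize_code(c)
        if not n:
            continue
        if not _CODE_RE.match(n):
            log.warning("ignoring malformed code %r", c)
            continue
        out.append(n)
    return out


@dataclass(frozen=True)
class Vocabulary:
    infant_birth: dict[str, CodeList]
    maternal_delivery: dict[str, CodeList]
    variables: dict[str, CodeList]
    classification: dict[str, CodeList]


def _parse_section(section: Mapping) -> dict[str, CodeList]:
    out = {}
    for name, spec in section.items():
        out[name] = CodeList(
            name=name,
            diagnosis_codes=tuple(str(c) for c in spec.get("diagnosis", [])),
            procedure_codes=tuple(str(c) for c in spec.get("procedure", [])),
            table_label=spec.get("table_label"),
        )
    return out


def load_vocabulary(path: str | None = None) -> Vocabulary:
    """Load the bundled (or a user-supplied) YAML code vocabulary."""
    if path is None:
        text = resources.files("perilink").joinpath("vocab/tables.yml").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    raw = yaml.safe_load(text)
    return Vocabulary(
        infant_birth=_parse_section(raw["infant_birth_admission"]),
        maternal_delivery=_parse_section(raw["maternal_delivery_admission"]),
        variables=_parse_section(raw["variables"]),
        classification=_parse_section(raw["classification"]),
    )


# ---------------------------------------------------------------------------
# per-record rules


def _codes_of(rec: Mapping, col: str) -> list[str]:
    raw = rec.get(col, "") if hasattr(rec, "get") else rec[col]
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return []
    if isinstance(raw, str):
        return _clean(raw.split())
    return _clean(raw)


def identify_infant_birth_admission(rec: Mapping, vocab: Vocabulary) -> bool:
    """True iff *rec* is an infant's birth admission.

    Requires an age of 0-1 days, the record being the infant's first
    admission, and any of: a liveborn Z38 code, a born-in-hospital source
    of referral, or a recorded birthweight together with a perinatal-period
    P code.
    """
    age = rec.get("age_days")
    try:
        age_ok = int(age) in (0, 1)
    except (TypeError, ValueError):
        age_ok = False
    if not age_ok:
        return False
    try:
        if int(rec.get("admission_order", 1)) != 1:
            return False
    except (TypeError, ValueError):
        pass
    diags = _codes_of(rec, "diagnosis_codes")
    if vocab.infant_birth["liveborn"].matches_record(diags):
        return True
    if str(rec.get("source_of_referral", "")).strip().lower() == "born in hospital":
        return True
    bw = rec.get("birthweight_g")
    has_bw = bw not in (None, "") and not (isinstance(bw, float) and np.isnan(bw))
    return has_bw and vocab.infant_birth["perinatal_condition"].matches_record(diags)


def identify_maternal_delivery_admission(rec: Mapping, vocab: Vocabulary) -> bool:
    """True iff any delivery-related diagnosis or procedure code is present."""
    diags = _codes_of(rec, "diagnosis_codes")
    procs = _codes_of(rec, "procedure_codes")
    return any(cl.matches_record(diags, procs) for cl in vocab.maternal_delivery.values())


def _date(value) -> dt.date | None:
    try:
        return dt.date.fromisoformat(str(value))
    except (TypeError, ValueError):
        return None


def check_link_constraints(birth: Mapping, rec: Mapping, role: str) -> bool:
    """Cross-record date and hospital constraints for a candidate link.

    Infant: admission within +/-1 calendar day of the date of birth and
    matching hospital of birth. Mother: date of birth inside the admission-
    to-separation interval and matching hospital. Missing dates fail with a
    logged reason.
    """
    if role not in ("mother", "infant"):
        raise ValueError(f"role must be 'mother' or 'infant', got {role!r}")
    hosp_b = str(birth.get("hospital_code", "")).strip().upper()
    hosp_r = str(rec.get("hospital_code", "")).strip().upper()
    if not hosp_b or hosp_b != hosp_r:
        return False
    birth_date = _date(birth.get("i_dob") or birth.get("dob"))
    adm = _date(rec.get("admission_date"))
    if birth_date is None or adm is None:
        log.info("link constraint failed: missing date")
        return False
    if role == "infant":
        return abs((adm - birth_date).days) <= 1
    sep = _date(rec.get("separation_date"))
    if sep is None:
        log.info("link constraint failed: missing separation date")
        return False
    return adm <= birth_date <= sep


def derive_variables(rec: Mapping, vocab: Vocabulary) -> dict[str, bool]:
    """Clinical variable flags derived from a record's codes; absent -> False."""
    diags = _codes_of(rec, "diagnosis_codes")
    procs = _codes_of(rec, "procedure_codes")
    return {
        name: cl.matches_record(diags, procs) for name, cl in vocab.variables.items()
    }


def classify_plurality_stillbirth(rec: Mapping, vocab: Vocabulary) -> tuple[str, str]:
    """Plurality and live/stillbirth status from diagnosis codes.

    Conflicting (both singleton and multiple) or absent evidence yields
    ``unclassifiable``; a stillbirth outcome code overrides the livebirth
    reading implied by other delivery codes.
    """
    diags = _codes_of(rec, "diagnosis_codes")
    single = vocab.classification["singleton"].matches_record(diags)
    multi = vocab.classification["multiple"].matches_record(diags)
    still = vocab.classification["stillbirth"].matches_record(diags)
    if single and not multi:
        plurality = "singleton"
    elif multi and not single:
        plurality = "multiple"
    else:
        plurality = "unclassifiable"
    if still:
        status = "stillbirth"
    elif single or multi:
        status = "livebirth"
    else:
        status = "unclassifiable"
    return plurality, status


# ---------------------------------------------------------------------------
# vectorized frame path


def _norm_code_series(s: pd.Series) -> pd.Series:
    return (
        s.fillna("")
        .astype(str)
        .str.upper()
        .str.replace(".", "", regex=False)
        .str.replace(r"\s+", " ", regex=True)
        .str.strip()
    )


def classify_admissions(records: pd.DataFrame, vocab: Vocabulary) -> pd.DataFrame:
    """Vectorized classification of a hospital-record frame.

    Returns a frame indexed like *records* with boolean columns
    ``is_infant_birth_admission`` / ``is_maternal_delivery_admission``,
    string columns ``plurality_class`` / ``birth_status`` and one boolean
    column per derived clinical variable. A record flagged as an infant
    birth admission is never simultaneously flagged maternal.
    """
    def col(name: str, default) -> pd.Series:
        if name in records.columns:
            return records[name]
        return pd.Series(default, index=records.index)

    diag = _norm_code_series(col("diagnosis_codes", ""))
    proc = _norm_code_series(col("procedure_codes", ""))

    def match(cl: CodeList) -> pd.Series:
        hit = pd.Series(False, index=records.index)
        p = cl.pattern("diagnosis")
        if p:
            hit |= diag.str.contains(p, regex=True)
        p = cl.pattern("procedure")
        if p:
            hit |= proc.str.contains(p, regex=True)
        return hit

    age = pd.to_numeric(col("age_days", np.nan), errors="coerce")
    order = pd.to_numeric(col("admission_order", 1), errors="coerce").fillna(1)
    bw = pd.to_numeric(col("birthweight_g", np.nan), errors="coerce")
    sor = col("source_of_referral", "").fillna("").astype(str).str.strip().str.lower()
    infant = (
        age.isin([0, 1])
        & (order == 1)
        & (
            match(vocab.infant_birth["liveborn"])
            | (sor == "born in hospital")
            | (bw.notna() & match(vocab.infant_birth["perinatal_condition"]))
        )
    )
    maternal = pd.Series(False, index=records.index)
    for cl in vocab.maternal_delivery.values():
        maternal |= match(cl)
    maternal &= ~infant  # a record cannot be both

    single = match(vocab.classification["singleton"])
    multi = match(vocab.classification["multiple"])
    still = match(vocab.classification["stillbirth"])
    plurality = np.select(
        [single & ~multi, multi & ~single], ["singleton", "multiple"], "unclassifiable"
    )
    status = np.select(
        [still, single | multi], ["stillbirth", "livebirth"], "unclassifiable"
    )

    out = pd.DataFrame(
        {
            "is_infant_birth_admission": infant,
            "is_maternal_delivery_admission": maternal,
            "plurality_class": plurality,
            "birth_status": status,
        },
        index=records.index,
    )
    for name, cl in vocab.variables.items():
        out[name] = match(cl)
    return out
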