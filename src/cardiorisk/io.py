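"""Ingest of cardiotoxicity-rank tables and pharmacology annotations.

Reads delimited (CSV/TSV) or spreadsheet-exported drug tables whose
columns are mapped onto the record fields through configuration,
normalizes trade-name/salt-form entries down to generic names, and
consolidates duplicates so every drug appears exactly once.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import pandas as pd

from .targets import TargetClass
from .units import Quantity

logger = logging.getLogger(__name__)

__all__ = [
    "Concern",
    "Severity",
    "ToxicityType",
    "Mode",
    "DrugRecord",
    "TargetAnnotation",
    "DrugEntry",
    "ConsolidationResult",
    "MergeResult",
    "IngestConfigError",
    "InputError",
    "DEFAULT_SALT_SUFFIXES",
    "normalize_drug_name",
    "parse_dictrank_table",
    "consolidate_records",
    "merge_annotations",
]


class IngestConfigError(ValueError):
    """The table cannot be mapped onto the expected columns."""


class InputError(ValueError):
    """The input data itself is unusable (empty file, empty name, ...)."""


class Concern(str, Enum):
    """Cardiotoxicity concern category, ordered most severe first."""

    MOST = "most"
    LESS = "less"
    NO = "no"
    AMBIGUOUS = "ambiguous"


#: resolution order when duplicate rows disagree: keep the worse label
CONCERN_SEVERITY_ORDER: tuple[Concern, ...] = (
    Concern.MOST,
    Concern.LESS,
    Concern.AMBIGUOUS,
    Concern.NO,
)


class Severity(str, Enum):
    SEVERE = "severe"
    MODERATE = "moderate"
    MILD = "mild"
    NONE = "none"


SEVERITY_ORDER: tuple[Severity, ...] = (
    Severity.SEVERE,
    Severity.MODERATE,
    Severity.MILD,
    Severity.NONE,
)


class ToxicityType(str, Enum):
    ARRHYTHMIA = "arrhythmia"
    HEART_DAMAGE = "heart_damage"
    MIXED = "mixed"
    NONE = "none"


class Mode(str, Enum):
    AGONIST = "agonist"
    ANTAGONIST_OR_INHIBITOR = "antagonist_or_inhibitor"


# Salt, ester and formulation tokens stripped from the tail of raw drug
# names. Editable configuration; this default list covers the common
# pharmaceutical counter-ions plus radiolabel formulation tags.
DEFAULT_SALT_SUFFIXES: tuple[str, ...] = (
    "acetate",
    "besylate",
    "bitartrate",
    "bromide",
    "calcium",
    "carbonate",
    "chloride",
    "citrate",
    "dihydrate",
    "disodium",
    "fumarate",
    "hcl",
    "hydrobromide",
    "hydrochloride",
    "lactate",
    "maleate",
    "mesylate",
    "monohydrate",
    "nitrate",
    "phosphate",
    "potassium",
    "sodium",
    "succinate",
    "sulfate",
    "sulphate",
    "tartrate",
    "tosylate",
    "18f",
)


@dataclass(frozen=True)
class DrugRecord:
    """One row of a cardiotoxicity-rank table, normalized."""

    raw_name: str
    generic_name: str
    concern: Concern
    severity: Severity = Severity.NONE
    toxicity_type: ToxicityType = ToxicityType.NONE
    keywords: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not self.generic_name:
            raise InputError("generic_name must be non-empty")


@dataclass(frozen=True)
class TargetAnnotation:
    """A drug's plausible risk target with raw pharmacology values."""

    generic_name: str
    target_name: str
    target_class: TargetClass
    mode: Mode = Mode.ANTAGONIST_OR_INHIBITOR
    affinity_values: tuple[Quantity, ...] = ()
    ppb: float | None = None          # bound fraction in [0, 1]
    cmax: Quantity | None = None      # total Cmax
    molecular_weight: float | None = None  # g/mol

    def __post_init__(self) -> None:
        if self.ppb is not None and not (0.0 <= self.ppb <= 1.0):
            raise InputError(f"ppb must lie in [0, 1], got {self.ppb}")


@dataclass
class DrugEntry:
    """A drug joined with its annotations (possibly none)."""

    record: DrugRecord
    annotations: list[TargetAnnotation] = field(default_factory=list)

    @property
    def annotated(self) -> bool:
        return bool(self.annotations)


@dataclass
class ConsolidationResult:
    records: list[DrugRecord]
    conflicts: list[str] = field(default_factory=list)


@dataclass
class MergeResult:
    entries: list[DrugEntry]
    unmatched_annotations: list[str] = field(default_factory=list)


def normalize_drug_name(
    raw_name: str, suffix_list: tuple[str, ...] = DEFAULT_SALT_SUFFIXES
) -> str:
    """Lowercase, trim, and strip salt/ester/formulation tokens from the tail.

    Idempotent: normalizing an already-normalized name is a no-op.

    Raises
    ------
    InputError
        If the name is empty or consists only of suffix tokens.
    """
    if not raw_name or not raw_name.strip():
        raise InputError("drug name must be non-empty")
    tokens = raw_name.strip().lower().split()
    suffixes = {s.lower() for s in suffix_list}
    while len(tokens) > 1 and tokens[-1] in suffixes:
        tokens.pop()
    name = " ".join(tokens)
    if not name:
        raise InputError(f"name {raw_name!r} reduces to nothing after suffix stripping")
    return name


# --- table parsing -----------------------------------------------------

#: default mapping from record fields to header names (case-insensitive)
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "name": "Drug Name",
    "concern": "DICT Concern",
    "severity": "Severity",
    "toxicity_type": "Toxicity Type",
    "keywords": "Keywords",
}

_CONCERN_SYNONYMS: dict[str, Concern] = {}
for _c in Concern:
    for variant in (
        _c.value,
        f"{_c.value} concern",
        f"{_c.value}-concern",
        f"{_c.value}_concern",
        f"{_c.value} dict concern",
    ):
        _CONCERN_SYNONYMS[variant] = _c


def _normalize_label(text: str) -> str:
    return re.sub(r"\s+", " ", str(text).strip().lower())


def parse_concern(label: str) -> Concern | None:
    """Map a concern label in any common dialect onto the enum, else None."""
    key = _normalize_label(label).replace("-", " ").replace("_", " ")
    key = re.sub(r"\s+", " ", key)
    return _CONCERN_SYNONYMS.get(key) or _CONCERN_SYNONYMS.get(key.replace(" concern", ""))


def _parse_severity(label: str) -> Severity:
    key = _normalize_label(label)
    for s in Severity:
        if s.value == key:
            return s
    return Severity.NONE


def _parse_toxicity(label: str) -> ToxicityType:
    key = _normalize_label(label).replace(" ", "_")
    for t in ToxicityType:
        if t.value == key:
            return t
    return ToxicityType.NONE


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"no such file: {path}")
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        return pd.read_excel(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    return pd.read_csv(path, sep=sep)


def parse_dictrank_table(
    path: str | Path,
    column_map: dict[str, str] | None = None,
    suffix_list: tuple[str, ...] = DEFAULT_SALT_SUFFIXES,
) -> tuple[list[DrugRecord], list[str]]:
    """Read a concern-ranked drug table into records.

    Returns ``(records, skipped)`` where ``skipped`` lists rows whose
    concern label could not be mapped — they are reported, never silently
    dropped.

    Raises
    ------
    IngestConfigError
        If a mandatory column (name, concern) is absent, naming it.
    InputError
        If the file is missing or has no data rows.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    df = _read_table(path)
    if df.empty:
        raise InputError(f"empty table: {path}")

    lower_cols = {str(c).strip().lower(): c for c in df.columns}

    def col(field_name: str, required: bool) -> str | None:
        wanted = cmap[field_name].strip().lower()
        if wanted in lower_cols:
            return lower_cols[wanted]
        if required:
            raise IngestConfigError(
                f"mandatory column {cmap[field_name]!r} (field {field_name!r}) not found"
            )
        return None

    name_col = col("name", required=True)
    concern_col = col("concern", required=True)
    severity_col = col("severity", required=False)
    tox_col = col("toxicity_type", required=False)
    kw_col = col("keywords", required=False)

    records: list[DrugRecord] = []
    skipped: list[str] = []
    for _, row in df.iterrows():
        raw_name = str(row[name_col])
        concern = parse_concern(str(row[concern_col]))
        if concern is None:
            skipped.append(f"{raw_name}: unmappable concern {row[concern_col]!r}")
            continue
        keywords: tuple[str, ...] = ()
        if kw_col is not None and pd.notna(row[kw_col]):
            keywords = tuple(
                k.strip() for k in str(row[kw_col]).split(";") if k.strip()
            )
        records.append(
            DrugRecord(
                raw_name=raw_name,
                generic_name=normalize_drug_name(raw_name, suffix_list),
                concern=concern,
                severity=_parse_severity(str(row[severity_col])) if severity_col else Severity.NONE,
                toxicity_type=_parse_toxicity(str(row[tox_col])) if tox_col else ToxicityType.NONE,
                keywords=keywords,
            )
        )
    for msg in skipped:
        logger.warning("skipped row: %s", msg)
    return records, skipped


def consolidate_records(records: list[DrugRecord]) -> ConsolidationResult:
    """Collapse duplicate generic names into one record each.

    When duplicates disagree, the worse concern (most > less > ambiguous
    > no) and the worse severity are retained — safety screening should
    not understate risk — and the conflict is recorded for audit.
    Keywords are unioned. Output order follows first appearance.
    """
    by_name: dict[str, DrugRecord] = {}
    conflicts: list[str] = []
    for rec in records:
        existing = by_name.get(rec.generic_name)
        if existing is None:
            by_name[rec.generic_name] = rec
            continue
        merged = existing
        if rec.concern is not existing.concern:
            worse = min(existing.concern, rec.concern, key=CONCERN_SEVERITY_ORDER.index)
            conflicts.append(
                f"{rec.generic_name}: concern {existing.concern.value} vs "
                f"{rec.concern.value}; kept {worse.value}"
            )
            merged = replace(merged, concern=worse)
        if rec.severity is not existing.severity:
            worse_sev = min(existing.severity, rec.severity, key=SEVERITY_ORDER.index)
            conflicts.append(
                f"{rec.generic_name}: severity {existing.severity.value} vs "
                f"{rec.severity.value}; kept {worse_sev.value}"
            )
            merged = replace(merged, severity=worse_sev)
        merged = replace(
            merged,
            keywords=tuple(dict.fromkeys(existing.keywords + rec.keywords)),
        )
        by_name[rec.generic_name] = merged
    for msg in conflicts:
        logger.info("consolidation conflict: %s", msg)
    return ConsolidationResult(records=list(by_name.values()), conflicts=conflicts)


def merge_annotations(
    drugs: list[DrugRecord], annotations: list[TargetAnnotation]
) -> MergeResult:
    """Left-join annotations onto drugs by generic name.

    Drugs without any annotation come back with an empty annotation list
    (explicitly unannotated); annotations whose drug is unknown are
    reported in ``unmatched_annotations``.

    Raises
    ------
    InputError
        If two annotations share the same (drug, target) key.
    """
    seen: set[tuple[str, str]] = set()
    by_drug: dict[str, list[TargetAnnotation]] = {}
    for ann in annotations:
        key = (ann.generic_name, ann.target_name)
        if key in seen:
            raise InputError(f"duplicate annotation for drug/target {key}")
        seen.add(key)
        by_drug.setdefault(ann.generic_name, []).append(ann)

    known = {d.generic_name for d in drugs}
    unmatched = sorted(
        {ann.generic_name for ann in annotations if ann.generic_name not in known}
    )
    for name in unmatched:
        logger.warning("annotation for unknown drug: %s", name)

    entries = [DrugEntry(record=d, annotations=by_drug.get(d.generic_name, [])) for d in drugs]
    return MergeResult(entries=entries, unmatched_annotations=unmatched)
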