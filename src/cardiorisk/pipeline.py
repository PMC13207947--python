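"""Glue from raw tables to classified, engagement-scored drugs.

ingest -> normalize/consolidate -> harmonize units -> assign panels ->
evaluate engagement. Each step lives in its own module; this one wires
them together for scripts, the CLI and end-to-end tests.
"""

from __future__ import annotations

import pandas as pd

from .engagement import PharmProfile, evaluate_profile
from .io import (
    DrugEntry,
    DrugRecord,
    Mode,
    TargetAnnotation,
    consolidate_records,
    merge_annotations,
)
from .summary import ClassifiedDrug
from .targets import (
    DEFAULT_CORRECTIONS,
    DEFAULT_QT_KEYWORDS,
    TargetClass,
    assign_panel,
)
from .units import aggregate_values, parse_quantity, to_nanomolar

__all__ = [
    "annotations_from_frame",
    "profile_from_entry",
    "classify_entries",
    "run_pipeline",
]


def annotations_from_frame(df: pd.DataFrame) -> list[TargetAnnotation]:
    """Build annotations from a table with one row per (drug, target).

    Expected columns: generic_name, target_name, target_class, mode,
    affinity (semicolon-separated quantity strings), ppb,
    cmax (quantity string), molecular_weight. Empty cells mean missing.
    """
    annotations: list[TargetAnnotation] = []
    for _, row in df.iterrows():
        aff_cell = row.get("affinity")
        affinities = ()
        if pd.notna(aff_cell) and str(aff_cell).strip():
            affinities = tuple(
                parse_quantity(part) for part in str(aff_cell).split(";") if part.strip()
            )
        ppb_cell = row.get("ppb")
        ppb = float(ppb_cell) if pd.notna(ppb_cell) and str(ppb_cell).strip() != "" else None
        cmax_cell = row.get("cmax")
        cmax = (
            parse_quantity(str(cmax_cell))
            if pd.notna(cmax_cell) and str(cmax_cell).strip()
            else None
        )
        mw_cell = row.get("molecular_weight")
        mw = float(mw_cell) if pd.notna(mw_cell) and str(mw_cell).strip() != "" else None
        mode_cell = str(row.get("mode", Mode.ANTAGONIST_OR_INHIBITOR.value))
        annotations.append(
            TargetAnnotation(
                generic_name=str(row["generic_name"]).strip().lower(),
                target_name=str(row["target_name"]),
                target_class=TargetClass.from_label(str(row["target_class"])),
                mode=Mode(mode_cell) if mode_cell in Mode._value2member_map_ else Mode.ANTAGONIST_OR_INHIBITOR,
                affinity_values=affinities,
                ppb=ppb,
                cmax=cmax,
                molecular_weight=mw,
            )
        )
    return annotations


def profile_from_entry(entry: DrugEntry) -> PharmProfile | None:
    """Harmonize a drug's annotations into a single pharmacology profile.

    All affinity values across the drug's annotations are converted to
    nM (through the molecular weight when reported in mass-per-volume
    units) and aggregated by median; likewise Cmax and protein binding.
    Returns None for unannotated drugs.
    """
    if not entry.annotations:
        return None
    affinities: list[float] = []
    cmaxes: list[float] = []
    ppbs: list[float] = []
    for ann in entry.annotations:
        for q in ann.affinity_values:
            affinities.append(to_nanomolar(q, ann.molecular_weight))
        if ann.cmax is not None:
            cmaxes.append(to_nanomolar(ann.cmax, ann.molecular_weight))
        if ann.ppb is not None:
            ppbs.append(ann.ppb)
    return PharmProfile(
        generic_name=entry.record.generic_name,
        affinity_nM=aggregate_values(affinities),
        ppb=aggregate_values(ppbs) if ppbs else None,
        cmax_total_nM=aggregate_values(cmaxes),
    )


def classify_entries(
    entries: list[DrugEntry],
    corrections: dict[str, TargetClass] | None = None,
    qt_keywords: tuple[str, ...] = DEFAULT_QT_KEYWORDS,
) -> list[ClassifiedDrug]:
    """Assign panels and evaluate engagement for joined drug entries."""
    if corrections is None:
        corrections = DEFAULT_CORRECTIONS
    classified: list[ClassifiedDrug] = []
    for entry in entries:
        assignment = assign_panel(
            entry.record.generic_name,
            [a.target_class for a in entry.annotations],
            keywords=entry.record.keywords,
            corrections=corrections,
            qt_keywords=qt_keywords,
        )
        profile = profile_from_entry(entry)
        result = None
        if profile is not None and profile.affinity_nM is not None:
            result = evaluate_profile(profile)
        classified.append(
            ClassifiedDrug(
                record=entry.record,
                assignment=assignment,
                profile=profile,
                result=result,
            )
        )
    return classified


def run_pipeline(
    records: list[DrugRecord],
    annotations: list[TargetAnnotation],
    corrections: dict[str, TargetClass] | None = None,
) -> list[ClassifiedDrug]:
    """Consolidate, join and classify; the full analysis path."""
    consolidated = consolidate_records(records)
    merged = merge_annotations(consolidated.records, annotations)
    return classify_entries(merged.entries, corrections=corrections)
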