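"""Tiered concern-vs-risk-target summaries and the sensitivity analysis.

The central question these summaries answer: how often are drugs of each
cardiotoxicity concern category associated with one of the key
cardiovascular risk-target classes, and does that association persist as
broad therapeutic classes are peeled away (tiers 1-3)? A companion
frequency table relates safety-event severity to the exposure margin
log10(Cmax,u / affinity) among most-concern drugs. The analysis is
deliberately descriptive — counts and percentages, no inference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .engagement import EngagementResult, PharmProfile, evaluate_profile
from .io import Concern, DrugRecord, Severity
from .targets import PanelAssignment, tier_membership

__all__ = [
    "ClassifiedDrug",
    "TierSummary",
    "SeverityMarginTable",
    "ImputationReport",
    "contingency",
    "severity_margin_table",
    "sensitivity_run",
    "DEFAULT_LOG10_BINS",
    "IMPUTED_FU",
]

#: fraction unbound assumed when protein binding is unreported
IMPUTED_FU: float = 0.5

#: log10(margin) bin edges: integer powers of 10 from 1e-4 to 1e2
DEFAULT_LOG10_BINS: tuple[float, ...] = tuple(float(x) for x in range(-4, 3))


@dataclass
class ClassifiedDrug:
    """A drug with its concern label, panel assignment and pharmacology."""

    record: DrugRecord
    assignment: PanelAssignment
    profile: PharmProfile | None = None
    result: EngagementResult | None = None

    @property
    def margin(self) -> float | None:
        return None if self.result is None else self.result.margin


@dataclass
class TierSummary:
    """Concern x mapped/unmapped contingency counts for one tier."""

    tier: int
    counts: dict[Concern, tuple[int, int]]  # concern -> (mapped, unmapped)

    def percent_mapped(self, concern: Concern) -> int | None:
        """100 x mapped / (mapped + unmapped), nearest integer percent."""
        mapped, unmapped = self.counts.get(concern, (0, 0))
        total = mapped + unmapped
        if total == 0:
            return None
        return round(100 * mapped / total)

    def total(self, concern: Concern) -> int:
        mapped, unmapped = self.counts.get(concern, (0, 0))
        return mapped + unmapped


@dataclass
class SeverityMarginTable:
    """Histogram of log10 exposure margins per severity level."""

    bin_edges: tuple[float, ...]
    counts: dict[Severity, list[int]]
    mean_log10_margin: dict[Severity, float]

    @property
    def n_drugs(self) -> int:
        return sum(sum(row) for row in self.counts.values())


@dataclass
class ImputationReport:
    imputed_ppb: list[str] = field(default_factory=list)
    excluded_cmax: list[str] = field(default_factory=list)
    curve_only: list[str] = field(default_factory=list)


def contingency(entries: list[ClassifiedDrug], tier: int) -> TierSummary:
    """Count mapped vs unmapped drugs per concern category at one tier."""
    counts: dict[Concern, tuple[int, int]] = {c: (0, 0) for c in Concern}
    for entry in entries:
        mapped, unmapped = counts[entry.record.concern]
        if tier_membership(entry.assignment, tier):
            counts[entry.record.concern] = (mapped + 1, unmapped)
        else:
            counts[entry.record.concern] = (mapped, unmapped + 1)
    return TierSummary(tier=tier, counts=counts)


def severity_margin_table(
    entries: list[ClassifiedDrug],
    bin_edges: tuple[float, ...] = DEFAULT_LOG10_BINS,
) -> SeverityMarginTable:
    """Bin log10(Cmax,u / affinity) by severity.

    Only entries carrying a margin contribute; values beyond the outer
    edges are clamped into the first/last bin so every drug is counted.
    Also reports the mean log10 margin per severity, the summary used to
    compare how close to (or past) the affinity the typical exposure of
    each severity group sits.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing with >= 2 values")
    counts: dict[Severity, list[int]] = {}
    means: dict[Severity, float] = {}
    by_sev: dict[Severity, list[float]] = {}
    for entry in entries:
        if entry.margin is None or entry.margin <= 0:
            continue
        by_sev.setdefault(entry.record.severity, []).append(math.log10(entry.margin))
    for sev, logs in by_sev.items():
        clamped = np.clip(logs, edges[0], np.nextafter(edges[-1], -np.inf))
        hist, _ = np.histogram(clamped, bins=edges)
        counts[sev] = hist.tolist()
        means[sev] = float(np.mean(logs))
    return SeverityMarginTable(
        bin_edges=tuple(edges.tolist()), counts=counts, mean_log10_margin=means
    )


def sensitivity_run(
    entries: list[ClassifiedDrug],
    tiers: tuple[int, ...] = (1, 2, 3),
) -> tuple[dict[int, TierSummary], ImputationReport, list[ClassifiedDrug]]:
    """Re-run the summaries with every drug included, imputing what must be.

    Missing protein binding is replaced by a fraction unbound of 0.5.
    Drugs without Cmax keep their concentration-response curve but are
    excluded from margin/engagement statistics; drugs without affinity
    are carried as curve-only placeholders. Classification counts are
    untouched by the imputation — it affects exposure metrics only.

    Returns the per-tier summaries, the report naming every imputed or
    excluded drug, and the imputed entries themselves.
    """
    report = ImputationReport()
    imputed: list[ClassifiedDrug] = []
    for entry in entries:
        prof = entry.profile
        new = ClassifiedDrug(
            record=entry.record,
            assignment=entry.assignment,
            profile=prof,
            result=entry.result,
        )
        if prof is not None and prof.affinity_nM is not None:
            if prof.ppb is None:
                prof = replace(prof, ppb=1.0 - IMPUTED_FU)
                report.imputed_ppb.append(entry.record.generic_name)
                new.profile = prof
                new.result = evaluate_profile(prof)
            if prof.cmax_total_nM is None:
                report.excluded_cmax.append(entry.record.generic_name)
                if new.result is None:
                    new.result = evaluate_profile(prof)
        else:
            report.curve_only.append(entry.record.generic_name)
        imputed.append(new)
    summaries = {t: contingency(imputed, t) for t in tiers}
    return summaries, report, imputed
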