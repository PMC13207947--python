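"""Benchmarking a candidate against reference drugs, and panel figures.

A new molecule with in vitro affinity, expected clinical exposure and
plasma protein binding can be placed among marketed drugs sharing its
target class: the candidate is ranked by predicted target engagement at
the unbound peak concentration, and flagged when its free exposure
reaches the affinity (margin >= 1, i.e. more than half-maximal
engagement at the clinical peak).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .engagement import CurveGrid, PharmProfile, evaluate_profile
from .io import Concern, Severity
from .summary import ClassifiedDrug
from .targets import TargetClass

logger = logging.getLogger(__name__)

__all__ = ["ReferenceRow", "BenchmarkReport", "benchmark_candidate", "render_panels"]


@dataclass(frozen=True)
class ReferenceRow:
    generic_name: str
    concern: Concern
    severity: Severity
    engagement_at_cmaxu: float
    margin: float


@dataclass
class BenchmarkReport:
    candidate: PharmProfile
    target_class: TargetClass
    references: list[ReferenceRow]
    candidate_engagement: float
    candidate_margin: float
    candidate_rank: int
    exceeds_affinity_flag: bool
    warnings: list[str] = field(default_factory=list)


def benchmark_candidate(
    candidate: PharmProfile,
    target_class: TargetClass,
    reference_set: list[ClassifiedDrug],
) -> BenchmarkReport:
    """Rank a complete-data candidate among same-class reference drugs.

    Rank 1 is the highest engagement at Cmax,u. Ties are broken by larger
    margin, then by name order, so the ranking is deterministic and does
    not depend on the order references arrive in.
    """
    if not candidate.complete:
        raise ValueError("candidate must have affinity, ppb and Cmax")
    cand_result = evaluate_profile(candidate)
    assert cand_result.engagement_at_cmaxu is not None and cand_result.margin is not None

    rows: list[ReferenceRow] = []
    for entry in reference_set:
        if entry.assignment.panel is not target_class:
            continue
        if entry.result is None or entry.result.engagement_at_cmaxu is None:
            continue
        rows.append(
            ReferenceRow(
                generic_name=entry.record.generic_name,
                concern=entry.record.concern,
                severity=entry.record.severity,
                engagement_at_cmaxu=entry.result.engagement_at_cmaxu,
                margin=entry.result.margin,
            )
        )

    warnings: list[str] = []
    if not rows:
        warnings.append(f"no reference drugs with complete data in class {target_class.value}")

    ranked = sorted(
        [(r.engagement_at_cmaxu, r.margin, r.generic_name) for r in rows]
        + [(cand_result.engagement_at_cmaxu, cand_result.margin, candidate.generic_name)],
        key=lambda t: (-t[0], -t[1], t[2]),
    )
    rank = 1 + next(
        i for i, t in enumerate(ranked) if t[2] == candidate.generic_name
    )
    return BenchmarkReport(
        candidate=candidate,
        target_class=target_class,
        references=sorted(rows, key=lambda r: (-r.engagement_at_cmaxu, -r.margin, r.generic_name)),
        candidate_engagement=cand_result.engagement_at_cmaxu,
        candidate_margin=cand_result.margin,
        candidate_rank=rank,
        exceeds_affinity_flag=cand_result.margin >= 1.0,
        warnings=warnings,
    )


_CONCERN_COLORS = {
    Concern.MOST: "#c0392b",
    Concern.LESS: "#e67e22",
    Concern.AMBIGUOUS: "#7f8c8d",
    Concern.NO: "#27ae60",
}

_SEVERITY_MARKERS = {
    Severity.SEVERE: "o",
    Severity.MODERATE: "s",
    Severity.MILD: "^",
    Severity.NONE: "D",
}


def _plot_panel(
    ax: plt.Axes, entries: list[ClassifiedDrug], grid: CurveGrid, title: str
) -> list[tuple[str, float, float]]:
    """Draw one panel; return the (name, x, y) marker positions drawn."""
    markers: list[tuple[str, float, float]] = []
    no_affinity = [e for e in entries if e.profile is None or e.profile.affinity_nM is None]
    with_affinity = [e for e in entries if e not in no_affinity]
    for entry in with_affinity:
        result = entry.result or evaluate_profile(entry.profile, grid)
        xs = [c for c, _ in result.curve]
        ys = [y for _, y in result.curve]
        color = _CONCERN_COLORS[entry.record.concern]
        ax.plot(xs, ys, color=color, lw=1.0, alpha=0.8, label=entry.record.generic_name)
        if result.engagement_at_cmaxu is not None:
            x = entry.profile.cmax_unbound_nM
            y = result.engagement_at_cmaxu
            ax.scatter(
                [x], [y],
                color=color,
                marker=_SEVERITY_MARKERS[entry.record.severity],
                zorder=3,
                s=36,
            )
            markers.append((entry.record.generic_name, float(x), float(y)))
    # drugs with unknown affinity: flat lines at spread-out heights
    n = len(no_affinity)
    for i, entry in enumerate(no_affinity):
        y = 0.05 + (0.9 * i / max(n - 1, 1) if n > 1 else 0.45)
        ax.axhline(y, color=_CONCERN_COLORS[entry.record.concern], ls="--", lw=0.8)
    ax.set_xscale("log")
    ax.set_ylim(-0.02, 1.02)
    ax.set_xlabel("free concentration (nM)")
    ax.set_ylabel("fractional target engagement")
    ax.set_title(title)
    return markers


def render_panels(
    entries: list[ClassifiedDrug],
    out_dir: str | Path,
    grid: CurveGrid = CurveGrid(),
    fmt: str = "png",
) -> dict[str, dict]:
    """Write one figure per target-class panel; return what was drawn.

    Curves are colored by concern and the marker at (Cmax,u, engagement)
    is shaped by severity. Drugs whose panel is ``other`` are split into
    four figures by concern category. Drugs missing Cmax get a curve
    without a marker; drugs missing affinity are drawn as horizontal
    dashed lines. Empty panels are skipped with a log entry.

    Returns a mapping panel-name -> {"path": file, "markers": [(name, x, y)]}.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    by_panel: dict[TargetClass, list[ClassifiedDrug]] = {}
    for entry in entries:
        by_panel.setdefault(entry.assignment.panel, []).append(entry)

    rendered: dict[str, dict] = {}

    def render_one(name: str, panel_entries: list[ClassifiedDrug], title: str) -> None:
        if not panel_entries:
            logger.info("panel %s empty; skipped", name)
            return
        fig, ax = plt.subplots(figsize=(6, 4))
        markers = _plot_panel(ax, panel_entries, grid, title)
        path = out_dir / f"{name}.{fmt}"
        fig.tight_layout()
        fig.savefig(path, dpi=100)
        plt.close(fig)
        rendered[name] = {"path": path, "markers": markers}

    for panel, panel_entries in sorted(by_panel.items(), key=lambda kv: kv[0].value):
        if panel is TargetClass.OTHER:
            for concern in Concern:
                subset = [e for e in panel_entries if e.record.concern is concern]
                render_one(
                    f"other_{concern.value}_concern",
                    subset,
                    f"Other targets — {concern.value} concern",
                )
        else:
            safe = panel.value.replace("/", "-").replace(" ", "_")
            render_one(safe, panel_entries, panel.value)
    return rendered
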