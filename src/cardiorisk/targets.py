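"""Cardiovascular risk-target taxonomy, panel assignment and tier membership.

Eighteen target classes (receptors, ion channels, enzymes, transporters)
are treated as key cardiovascular risk targets; hERG takes priority when a
drug maps to several mechanisms or carries QT-prolongation / Torsades de
Pointes keywords. Broad therapeutic classes (antibacterials, statins, ...)
and a second exclusion set (antineoplastics, GABA, VEGFR/EGFR,
anticoagulants) are peeled off in successively stricter tiers when
summarizing how concern categories distribute over the risk targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

__all__ = [
    "TargetClass",
    "KEY_RISK_CLASSES",
    "BROAD_THERAPEUTIC_CLASSES",
    "TIER3_EXCLUSIONS",
    "DEFAULT_QT_KEYWORDS",
    "DEFAULT_CORRECTIONS",
    "AssignmentRule",
    "PanelAssignment",
    "assign_panel",
    "tier_membership",
]


class TargetClass(str, Enum):
    """Every panel a drug can be counted under."""

    # the 18 key cardiovascular risk classes
    HERG = "hERG"
    ADRENERGIC = "adrenergic receptor"
    DOPAMINE = "dopamine receptor"
    SEROTONIN = "serotonin receptor"
    ANDROGEN = "androgen receptor"
    SEX_HORMONE = "sex hormone receptor"
    OPIOID = "opioid receptor"
    COX = "cyclooxygenase"
    SODIUM_CHANNEL = "sodium channel"
    CALCIUM_CHANNEL = "calcium channel"
    MUSCARINIC = "muscarinic receptor"
    GLUCOCORTICOID = "glucocorticoid receptor"
    PDE = "phosphodiesterase"
    TOPOISOMERASE = "topoisomerase"
    ACE = "ACE"
    AT1 = "AT1 receptor"
    MONOAMINE_TRANSPORTER = "monoamine transporter"
    ACHE = "acetylcholinesterase"
    # broad therapeutic classes, excluded at tier 2
    ANTIBACTERIAL = "antibacterial"
    ANTIVIRAL = "antiviral"
    ANTIFUNGAL = "antifungal"
    ANTIPARASITIC = "antiparasitic"
    ANTIDIABETIC = "antidiabetic"
    ANTIHISTAMINE = "antihistamine"
    STATIN = "statin"
    # additionally excluded at tier 3
    ANTINEOPLASTIC = "antineoplastic"
    GABA = "GABA"
    VEGFR_EGFR = "VEGFR/EGFR"
    ANTICOAGULANT = "anticoagulant-antiplatelet"
    # catch-alls
    OTHER = "other"
    NO_TARGET = "no pharmacological target"

    @classmethod
    def from_label(cls, label: str) -> "TargetClass":
        """Resolve a free-text class label case-insensitively."""
        key = label.strip().lower()
        for member in cls:
            if member.value.lower() == key:
                return member
        raise ValueError(f"unknown target class label {label!r}")


KEY_RISK_CLASSES: frozenset[TargetClass] = frozenset(
    {
        TargetClass.HERG,
        TargetClass.ADRENERGIC,
        TargetClass.DOPAMINE,
        TargetClass.SEROTONIN,
        TargetClass.ANDROGEN,
        TargetClass.SEX_HORMONE,
        TargetClass.OPIOID,
        TargetClass.COX,
        TargetClass.SODIUM_CHANNEL,
        TargetClass.CALCIUM_CHANNEL,
        TargetClass.MUSCARINIC,
        TargetClass.GLUCOCORTICOID,
        TargetClass.PDE,
        TargetClass.TOPOISOMERASE,
        TargetClass.ACE,
        TargetClass.AT1,
        TargetClass.MONOAMINE_TRANSPORTER,
        TargetClass.ACHE,
    }
)

BROAD_THERAPEUTIC_CLASSES: frozenset[TargetClass] = frozenset(
    {
        TargetClass.ANTIBACTERIAL,
        TargetClass.ANTIVIRAL,
        TargetClass.ANTIFUNGAL,
        TargetClass.ANTIPARASITIC,
        TargetClass.ANTIDIABETIC,
        TargetClass.ANTIHISTAMINE,
        TargetClass.STATIN,
    }
)

TIER3_EXCLUSIONS: frozenset[TargetClass] = frozenset(
    {
        TargetClass.ANTINEOPLASTIC,
        TargetClass.GABA,
        TargetClass.VEGFR_EGFR,
        TargetClass.ANTICOAGULANT,
    }
)

_UNMAPPED: frozenset[TargetClass] = frozenset({TargetClass.OTHER, TargetClass.NO_TARGET})

# Keyword stems that pull a drug into the hERG panel regardless of its
# annotated mechanism; matched case-insensitively as substrings.
DEFAULT_QT_KEYWORDS: tuple[str, ...] = ("qt", "torsade")

# Known curation fixes: the therapeutic target listed in the raw
# annotation is not the mechanism behind the safety signal.
DEFAULT_CORRECTIONS: dict[str, TargetClass] = {
    "moxifloxacin": TargetClass.HERG,
    "probenecid": TargetClass.OTHER,
}


class AssignmentRule(str, Enum):
    MANUAL_CORRECTION = "manual_correction"
    HERG_PRIORITY = "herg_priority"
    DIRECT = "direct"


@dataclass(frozen=True)
class PanelAssignment:
    """The panel a drug is plotted and counted under, plus why."""

    generic_name: str
    panel: TargetClass
    rule: AssignmentRule

    def __post_init__(self) -> None:
        if self.rule is AssignmentRule.HERG_PRIORITY and self.panel is not TargetClass.HERG:
            raise ValueError("herg_priority rule implies the hERG panel")


def _matches_qt(keywords: Iterable[str], terms: tuple[str, ...]) -> bool:
    for kw in keywords:
        low = kw.lower()
        if any(term in low for term in terms):
            return True
    return False


def assign_panel(
    generic_name: str,
    target_classes: list[TargetClass],
    keywords: Iterable[str] = (),
    corrections: dict[str, TargetClass] | None = None,
    qt_keywords: tuple[str, ...] = DEFAULT_QT_KEYWORDS,
) -> PanelAssignment:
    """Assign a drug to exactly one display/counting panel.

    Precedence: a manual-correction entry wins outright; then the hERG
    priority rule (annotated hERG class, or any QT/Torsades keyword);
    then the first annotated class; a drug with no annotated class falls
    into the no-pharmacological-target panel.
    """
    if corrections is None:
        corrections = DEFAULT_CORRECTIONS
    name = generic_name.strip().lower()
    if name in corrections:
        return PanelAssignment(name, corrections[name], AssignmentRule.MANUAL_CORRECTION)
    if TargetClass.HERG in target_classes or _matches_qt(keywords, qt_keywords):
        return PanelAssignment(name, TargetClass.HERG, AssignmentRule.HERG_PRIORITY)
    if target_classes:
        return PanelAssignment(name, target_classes[0], AssignmentRule.DIRECT)
    return PanelAssignment(name, TargetClass.NO_TARGET, AssignmentRule.DIRECT)


def tier_membership(assignment: PanelAssignment, tier: int) -> bool:
    """Whether a panel counts as mapped to a risk target at a given tier.

    Tier 1 maps every named class (only ``other`` and ``no pharmacological
    target`` are unmapped). Tier 2 additionally unmaps the broad
    therapeutic classes; tier 3 further unmaps antineoplastics,
    GABA-acting drugs, VEGFR/EGFR inhibitors and anticoagulants. Mapping
    is monotone: tier 3 ⊆ tier 2 ⊆ tier 1.
    """
    if tier not in (1, 2, 3):
        raise ValueError(f"tier must be 1, 2 or 3, got {tier}")
    panel = assignment.panel
    if panel in _UNMAPPED:
        return False
    if tier >= 2 and panel in BROAD_THERAPEUTIC_CLASSES:
        return False
    if tier == 3 and panel in TIER3_EXCLUSIONS:
        return False
    return True
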