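"""Synthetic cardiotoxicity-rank datasets with known ground truth.

Emulates the statistical structure the analysis assumes — four concern
categories with fixed marginals, class-conditional assignment to the 18
key risk-target classes (hERG over-represented among most-concern
drugs), lognormal affinities and exposures, Beta-distributed plasma
protein binding, element-wise missingness at the observed availability
rates, and trade-name/salt-form duplicate rows — so every pipeline stage
can be tested end to end with no downloads. Severity is coupled to the
exposure margin so the severity-vs-margin trend is recoverable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .io import Concern, DrugRecord, Severity
from .summary import ClassifiedDrug
from .targets import (
    KEY_RISK_CLASSES,
    AssignmentRule,
    PanelAssignment,
    TargetClass,
)

__all__ = ["SyntheticConfig", "SyntheticDataset", "generate", "fixture_from_counts"]

_CONCERNS: tuple[Concern, ...] = (Concern.MOST, Concern.LESS, Concern.AMBIGUOUS, Concern.NO)

# deterministic ordering of the 18 key classes for sampling
_KEY_CLASSES: tuple[TargetClass, ...] = tuple(
    sorted(KEY_RISK_CLASSES, key=lambda c: c.value)
)

_GENERIC_KEYWORDS = ("hypertension", "tachycardia", "palpitations", "edema")


class SyntheticConfig(BaseModel):
    """Generator settings; the defaults are the study conditions."""

    n_per_concern: dict[Concern, int] = Field(
        default_factory=lambda: {
            Concern.MOST: 327,
            Concern.LESS: 507,
            Concern.AMBIGUOUS: 105,
            Concern.NO: 328,
        }
    )
    p_mapped_per_concern: dict[Concern, float] = Field(
        default_factory=lambda: {
            Concern.MOST: 0.84,
            Concern.LESS: 0.66,
            Concern.AMBIGUOUS: 0.54,
            Concern.NO: 0.44,
        }
    )
    #: probability a mapped most-concern drug is hERG; chosen so hERG is
    #: ~20% of the whole most-concern category (0.20 / 0.84)
    herg_weight: float = 0.20 / 0.84
    #: fraction of unmapped drugs with no pharmacological target at all
    p_no_target: float = 0.05
    affinity_logmean: float = math.log(100.0)  # nM
    affinity_logsd: float = 1.5
    cmax_logmean: float = math.log(300.0)  # nM
    cmax_logsd: float = 1.2
    ppb_alpha: float = 5.0
    ppb_beta: float = 2.0
    availability_ppb: float = 0.811
    availability_affinity: float = 0.738
    availability_cmax: float = 0.535
    duplicate_rate: float = 0.04
    #: logistic slope of P(severe) on log10(margin)
    severity_margin_coupling: float = 1.0
    seed: int = 0

    @field_validator(
        "herg_weight",
        "p_no_target",
        "availability_ppb",
        "availability_affinity",
        "availability_cmax",
        "duplicate_rate",
    )
    @classmethod
    def _check_prob(cls, v: float) -> float:
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"probability out of [0, 1]: {v}")
        return v

    @field_validator("p_mapped_per_concern")
    @classmethod
    def _check_probs(cls, v: dict[Concern, float]) -> dict[Concern, float]:
        for p in v.values():
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability out of [0, 1]: {p}")
        return v

    @field_validator("n_per_concern")
    @classmethod
    def _check_counts(cls, v: dict[Concern, int]) -> dict[Concern, int]:
        for n in v.values():
            if n < 0:
                raise ValueError(f"counts must be nonnegative, got {n}")
        return v


@dataclass
class SyntheticDataset:
    """Generated tables: raw rank table, annotations, and ground truth."""

    dictrank: pd.DataFrame
    annotations: pd.DataFrame
    truth: pd.DataFrame


def _sample_severity(
    rng: np.random.Generator, concern: Concern, log10_margin: float, coupling: float
) -> Severity:
    if concern is Concern.NO:
        return Severity.NONE
    p_severe = 1.0 / (1.0 + math.exp(-coupling * log10_margin))
    u = rng.random()
    if u < p_severe:
        return Severity.SEVERE
    # split the rest between moderate and mild, mild favored at low margin
    if rng.random() < 0.5:
        return Severity.MODERATE
    return Severity.MILD


def _affinity_strings(rng: np.random.Generator, affinity_nM: float, mw: float) -> str:
    """Render 1-3 noisy affinity values in mixed units around the truth.

    Values are jittered multiplicatively so the median in nM recovers a
    value near the truth; unit choice exercises the harmonization path.
    """
    n = int(rng.integers(1, 4))
    jitter = np.exp(rng.normal(0.0, 0.1, size=n))
    # keep the middle value exact so the median is exactly recoverable
    jitter[n // 2] = 1.0
    parts = []
    for j in jitter:
        v = affinity_nM * float(j)
        style = rng.integers(0, 3)
        if style == 0:
            parts.append(f"{v:.6g} nM")
        elif style == 1:
            parts.append(f"{v / 1e3:.6g} µM")
        else:  # ng/mL via molecular weight: mg/L = nM * MW / 1e6
            parts.append(f"{v * mw / 1e3:.6g} ng/mL")
    return "; ".join(parts)


def generate(config: SyntheticConfig) -> SyntheticDataset:
    """Generate the three tables; identical config + seed is bit-identical."""
    rng = np.random.default_rng(config.seed)

    key_classes = list(_KEY_CLASSES)
    other_key = [c for c in key_classes if c is not TargetClass.HERG]
    w_other = (1.0 - config.herg_weight) / len(other_key)
    class_probs = [
        config.herg_weight if c is TargetClass.HERG else w_other for c in key_classes
    ]

    dict_rows: list[dict] = []
    ann_rows: list[dict] = []
    truth_rows: list[dict] = []

    idx = 0
    for concern in _CONCERNS:
        n = config.n_per_concern.get(concern, 0)
        p_mapped = config.p_mapped_per_concern.get(concern, 0.0)
        for _ in range(n):
            idx += 1
            name = f"drug-{idx:05d}"
            mapped = bool(rng.random() < p_mapped)
            if mapped:
                tclass = key_classes[int(rng.choice(len(key_classes), p=class_probs))]
            elif rng.random() < config.p_no_target:
                tclass = TargetClass.NO_TARGET
            else:
                tclass = TargetClass.OTHER

            affinity = float(np.exp(rng.normal(config.affinity_logmean, config.affinity_logsd)))
            cmax = float(np.exp(rng.normal(config.cmax_logmean, config.cmax_logsd)))
            ppb = float(rng.beta(config.ppb_alpha, config.ppb_beta))
            mw = float(rng.uniform(200.0, 600.0))
            margin = cmax * (1.0 - ppb) / affinity
            severity = _sample_severity(
                rng, concern, math.log10(margin), config.severity_margin_coupling
            )

            keywords: list[str] = []
            if tclass is TargetClass.HERG:
                keywords.append("QT prolongation")
                if rng.random() < 0.3:
                    keywords.append("Torsades de Pointes")
            elif concern is not Concern.NO:
                keywords.append(str(rng.choice(_GENERIC_KEYWORDS)))

            mask_aff = bool(rng.random() >= config.availability_affinity)
            mask_ppb = bool(rng.random() >= config.availability_ppb)
            mask_cmax = bool(rng.random() >= config.availability_cmax)

            dict_rows.append(
                {
                    "Drug Name": name.capitalize(),
                    "DICT Concern": f"{concern.value.capitalize()} concern",
                    "Severity": severity.value if severity is not Severity.NONE else "",
                    "Toxicity Type": "",
                    "Keywords": "; ".join(keywords),
                }
            )
            if tclass is not TargetClass.NO_TARGET:
                ann_rows.append(
                    {
                        "generic_name": name,
                        "target_name": f"{tclass.value} target",
                        "target_class": tclass.value,
                        "mode": "antagonist_or_inhibitor",
                        "affinity": "" if mask_aff else _affinity_strings(rng, affinity, mw),
                        "ppb": "" if mask_ppb else round(ppb, 6),
                        "cmax": "" if mask_cmax else f"{cmax:.6g} nM",
                        "molecular_weight": round(mw, 2),
                    }
                )
            truth_rows.append(
                {
                    "generic_name": name,
                    "concern": concern.value,
                    "severity": severity.value,
                    "true_class": tclass.value,
                    "mapped_tier1": tclass not in (TargetClass.OTHER, TargetClass.NO_TARGET),
                    "true_affinity_nM": affinity,
                    "true_cmax_nM": cmax,
                    "true_ppb": ppb,
                    "true_margin": margin,
                    "masked_affinity": mask_aff,
                    "masked_ppb": mask_ppb,
                    "masked_cmax": mask_cmax,
                }
            )

    # salt-form duplicate rows: same drug re-listed under an alias
    n_dup = int(round(config.duplicate_rate * len(truth_rows)))
    if n_dup > 0:
        dup_idx = rng.choice(len(dict_rows), size=n_dup, replace=False)
        for i in sorted(int(j) for j in dup_idx):
            alias = dict(dict_rows[i])
            alias["Drug Name"] = dict_rows[i]["Drug Name"] + " Hydrochloride"
            dict_rows.append(alias)

    return SyntheticDataset(
        dictrank=pd.DataFrame(dict_rows),
        annotations=pd.DataFrame(ann_rows),
        truth=pd.DataFrame(truth_rows),
    )


def replica_rank_table(
    unique_per_concern: dict[Concern, int],
    raw_per_concern: dict[Concern, int],
) -> pd.DataFrame:
    """Synthetic rank table with a prescribed duplicate structure.

    Builds, deterministically and with no pharmacology, a table whose raw
    row counts per concern equal ``raw_per_concern`` and whose unique
    generic names per concern equal ``unique_per_concern``; the excess
    rows are salt-form aliases of already-listed drugs. A synthetic
    stand-in for distribution-scale ingestion tests when the real public
    download is out of reach.
    """
    rows: list[dict] = []
    for concern in _CONCERNS:
        n_unique = unique_per_concern.get(concern, 0)
        n_raw = raw_per_concern.get(concern, 0)
        if n_raw < n_unique:
            raise ValueError(f"raw count below unique count for {concern.value}")
        label = f"{concern.value.capitalize()} concern"
        names = [f"{concern.value}-drug-{i:05d}" for i in range(n_unique)]
        for name in names:
            rows.append({"Drug Name": name.capitalize(), "DICT Concern": label})
        for i in range(n_raw - n_unique):  # salt-form aliases of the first drugs
            rows.append(
                {"Drug Name": names[i].capitalize() + " Hydrochloride", "DICT Concern": label}
            )
    return pd.DataFrame(rows)


def fixture_from_counts(
    counts: dict[Concern, tuple[int, int]]
) -> list[ClassifiedDrug]:
    """Deterministic classified-drug list realizing a contingency table.

    Emits exactly the requested number of mapped and unmapped drugs per
    concern with placeholder pharmacology. Mapped drugs sit in the hERG
    panel (mapped at every tier); unmapped drugs sit in ``other``. The
    contingency of the result reproduces ``counts`` exactly, so summary
    operations can be tested against published tallies.
    """
    entries: list[ClassifiedDrug] = []
    i = 0
    for concern, (mapped, unmapped) in counts.items():
        if mapped < 0 or unmapped < 0:
            raise ValueError("counts must be nonnegative")
        for flag, count in ((True, mapped), (False, unmapped)):
            panel = TargetClass.HERG if flag else TargetClass.OTHER
            for _ in range(count):
                i += 1
                name = f"fixture-{i:05d}"
                record = DrugRecord(
                    raw_name=name, generic_name=name, concern=concern
                )
                assignment = PanelAssignment(name, panel, AssignmentRule.DIRECT)
                entries.append(
                    ClassifiedDrug(record=record, assignment=assignment, profile=None)
                )
    return entries
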