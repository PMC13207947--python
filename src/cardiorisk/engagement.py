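"""Fractional target engagement under the hyperbolic Emax model.

Engagement of a target at free drug concentration C is

    E(C) = Emax * C / (EC50 + C)

with Emax fixed at 1 (full engagement) and the Hill coefficient
implicitly 1. The pharmacologically active exposure is the unbound peak
plasma concentration

    Cmax,u = Cmax * (1 - ppb)

where ppb is the fraction bound to plasma proteins. The safety margin is
the ratio Cmax,u / EC50; margin >= 1 is algebraically equivalent to
engagement >= 0.5 at the clinical peak. Agonist EC50 and
antagonist/inhibitor IC50 enter the model identically; the mode of
action is metadata only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PharmProfile",
    "EngagementResult",
    "CurveGrid",
    "fractional_engagement",
    "unbound_cmax",
    "evaluate_profile",
]


def fractional_engagement(c: float, affinity: float, e_max: float = 1.0) -> float:
    """Fraction of target engaged at free concentration ``c`` (nM).

    Exactly 0 at c = 0; approaches ``e_max`` as c grows. ``affinity`` is
    the EC50/IC50 in nM.
    """
    if affinity <= 0:
        raise ValueError(f"affinity must be positive, got {affinity}")
    if c < 0:
        raise ValueError(f"concentration must be nonnegative, got {c}")
    if not (0 < e_max <= 1):
        raise ValueError(f"e_max must lie in (0, 1], got {e_max}")
    return e_max * c / (affinity + c)


def unbound_cmax(cmax_total: float, ppb: float) -> float:
    """Unbound peak concentration: total Cmax scaled by the free fraction."""
    if not (0.0 <= ppb <= 1.0):
        raise ValueError(f"plasma protein binding must lie in [0, 1], got {ppb}")
    if cmax_total < 0:
        raise ValueError(f"Cmax must be nonnegative, got {cmax_total}")
    return cmax_total * (1.0 - ppb)


@dataclass(frozen=True)
class PharmProfile:
    """Harmonized per-drug pharmacology, all concentrations in nM."""

    generic_name: str
    affinity_nM: float | None = None
    ppb: float | None = None
    cmax_total_nM: float | None = None
    e_max: float = 1.0

    def __post_init__(self) -> None:
        if self.ppb is not None and not (0.0 <= self.ppb <= 1.0):
            raise ValueError(f"ppb must lie in [0, 1], got {self.ppb}")
        if self.affinity_nM is not None and self.affinity_nM <= 0:
            raise ValueError("affinity must be positive")

    @property
    def fu(self) -> float | None:
        """Fraction unbound, 1 - ppb."""
        return None if self.ppb is None else 1.0 - self.ppb

    @property
    def cmax_unbound_nM(self) -> float | None:
        if self.cmax_total_nM is None or self.ppb is None:
            return None
        return unbound_cmax(self.cmax_total_nM, self.ppb)

    @property
    def complete(self) -> bool:
        return (
            self.affinity_nM is not None
            and self.ppb is not None
            and self.cmax_total_nM is not None
        )


@dataclass(frozen=True)
class CurveGrid:
    """Log-spaced concentration grid, in multiples of the affinity.

    Defaults span 10^-2 x affinity to 10^4 x affinity over 200 points,
    which covers engagement from ~1% to ~99.99%.
    """

    low_factor: float = 1e-2
    high_factor: float = 1e4
    n_points: int = 200

    def concentrations(self, affinity: float) -> np.ndarray:
        return np.logspace(
            math.log10(affinity * self.low_factor),
            math.log10(affinity * self.high_factor),
            self.n_points,
        )


@dataclass
class EngagementResult:
    """Engagement curve plus the point metrics at the clinical peak."""

    generic_name: str
    curve: list[tuple[float, float]] = field(default_factory=list)
    engagement_at_cmaxu: float | None = None
    margin: float | None = None

    @property
    def log10_margin(self) -> float | None:
        return None if self.margin is None or self.margin <= 0 else math.log10(self.margin)

    @property
    def exceeds_affinity(self) -> bool | None:
        """True iff Cmax,u >= affinity, i.e. margin >= 1, i.e. engagement >= 0.5."""
        return None if self.margin is None else self.margin >= 1.0


def evaluate_profile(p: PharmProfile, grid: CurveGrid = CurveGrid()) -> EngagementResult:
    """Build the concentration-response curve and peak-exposure metrics.

    The curve is always produced when an affinity is known. The
    engagement at Cmax,u and the margin require both Cmax and protein
    binding; when either is missing they stay missing rather than being
    guessed.
    """
    if p.affinity_nM is None:
        raise ValueError(f"{p.generic_name}: cannot evaluate without an affinity")
    conc = grid.concentrations(p.affinity_nM)
    curve = [(float(c), fractional_engagement(float(c), p.affinity_nM, p.e_max)) for c in conc]
    result = EngagementResult(generic_name=p.generic_name, curve=curve)
    cmax_u = p.cmax_unbound_nM
    if cmax_u is not None:
        result.engagement_at_cmaxu = fractional_engagement(cmax_u, p.affinity_nM, p.e_max)
        result.margin = cmax_u / p.affinity_nM
    return result
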