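"""Aggregation of bubble records into venous/arterial loads and risk tiers.

Venous bubbles are filtered by the lung; arterial bubbles reach the
brain and spinal cord.  Three arterialization pathways are modelled as
configurable fractions/counts: a patent foramen ovale (PFO) shunting a
fraction of the venous load, intrapulmonary arteriovenous anastomoses
(IPAVA) shunting another fraction, and bubbles forming directly in
distal arteries where local flow reduction lets tissue gas load the
blood (the arterial-tree trigger).  Arterial delivery splits 8:1
between brain and spinal cord.

The tier boundaries are implementation defaults for an ordinal summary;
no quantitative DCI probability is produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .arterial_tree import ArteryTree, TensionQuery, tree_tension_profile
from .bubble_dynamics import BubbleRecord

PATHWAYS = ("PFO", "IPAVA", "distal")

#: Brain receives eight times the arterial blood directed to the spinal cord.
DEFAULT_BRAIN_SPINAL_SPLIT = 8.0


@dataclass(frozen=True)
class LoadSummary:
    """Bubble loads per unit time over an observation window."""

    window_min: float
    venous_count_per_h: float
    venous_volume_mm3_per_h: float
    arterial_per_h: dict[str, float] = field(
        default_factory=lambda: {p: 0.0 for p in PATHWAYS}
    )
    brain_spinal_split: float = DEFAULT_BRAIN_SPINAL_SPLIT

    def __post_init__(self) -> None:
        if self.window_min <= 0:
            raise ValueError("window_min must be positive")
        if self.venous_count_per_h < 0 or self.venous_volume_mm3_per_h < 0:
            raise ValueError("loads must be non-negative")
        if set(self.arterial_per_h) != set(PATHWAYS):
            raise ValueError(f"arterial pathways must be exactly {PATHWAYS}")
        if any(v < 0 for v in self.arterial_per_h.values()):
            raise ValueError("arterial loads must be non-negative")

    @property
    def arterial_total_per_h(self) -> float:
        return float(sum(self.arterial_per_h.values()))

    @property
    def brain_fraction(self) -> float:
        """Fraction of arterial bubbles delivered to the brain."""
        s = self.brain_spinal_split
        return s / (s + 1.0)


def summarize_loads(records: list[BubbleRecord], window_min: float) -> LoadSummary:
    """Convert detachment records within a window into per-hour loads."""
    if window_min <= 0:
        raise ValueError("window_min must be positive")
    hours = window_min / 60.0
    count = len(records)
    volume = float(sum(r.volume_mm3 for r in records))
    return LoadSummary(
        window_min=window_min,
        venous_count_per_h=count / hours,
        venous_volume_mm3_per_h=volume / hours,
    )


def arterialize(
    summary: LoadSummary,
    pfo_fraction: float = 0.0,
    ipava_fraction: float = 0.0,
    distal_events: int = 0,
) -> LoadSummary:
    """Route venous bubbles to the arterial side through the three pathways.

    PFO and IPAVA shunt fixed fractions of the venous count; distal
    events are bubbles formed in the arteries themselves (counted over
    the same window).
    """
    for name, f in (("pfo_fraction", pfo_fraction), ("ipava_fraction", ipava_fraction)):
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if pfo_fraction + ipava_fraction > 1.0:
        raise ValueError("shunt fractions must sum to at most 1")
    if distal_events < 0:
        raise ValueError("distal_events must be non-negative")
    hours = summary.window_min / 60.0
    return replace(
        summary,
        arterial_per_h={
            "PFO": summary.venous_count_per_h * pfo_fraction,
            "IPAVA": summary.venous_count_per_h * ipava_fraction,
            "distal": distal_events / hours,
        },
    )


def distal_formation_events(
    query: TensionQuery,
    tree: ArteryTree,
    ambient_kpa: float,
    threshold_kpa: float = 10.0,
    n_points_per_segment: int = 20,
) -> int:
    """Count flow-restricted tree segments primed for local bubble formation.

    A segment triggers when its flow scale is below 1 (a local flow
    reduction, e.g. the spinal arterial bed after decompression) and the
    blood tension anywhere along it exceeds ambient pressure by more than
    ``threshold_kpa``.
    """
    profile = tree_tension_profile(query, tree, n_points_per_segment)
    events = 0
    for seg in tree.segments:
        if tree.flow_scale(seg.name) >= 1.0:
            continue
        seg_tension = profile.loc[profile["segment"] == seg.name, "tension_kpa"]
        if float(seg_tension.max()) > ambient_kpa + threshold_kpa:
            events += 1
    return events


#: (low->moderate, moderate->high) boundaries on the combined load score.
DEFAULT_TIER_THRESHOLDS = (1.0, 20.0)


def risk_tier(
    summary: LoadSummary,
    sensitivity_b: float = 0.0,
    thresholds: tuple[float, float] = DEFAULT_TIER_THRESHOLDS,
) -> str:
    """Ordinal risk tier from the load summary and subject sensitivity.

    Score = (venous/h + 10 * arterial/h) * (1 + b/50): arterial bubbles
    weigh ten times venous ones, and heavy bubblers (large ``b``) scale
    the whole score up, so the tier is monotone in every load and in the
    sensitivity.
    """
    if sensitivity_b < 0:
        raise ValueError("sensitivity_b must be non-negative")
    lo, hi = thresholds
    if not 0 < lo < hi:
        raise ValueError("thresholds must be increasing and positive")
    score = (
        summary.venous_count_per_h + 10.0 * summary.arterial_total_per_h
    ) * (1.0 + sensitivity_b / 50.0)
    if score < lo:
        return "low"
    if score < hi:
        return "moderate"
    return "high"
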