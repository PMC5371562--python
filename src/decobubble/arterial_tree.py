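"""Steady-state inert-gas loading of blood along an arterial path.

After decompression the tissues surrounding an artery can hold a much
higher inert-gas tension than the blood leaving the heart.  Gas then
diffuses through the vessel wall into the flowing blood.  For a single
segment with internal radius ``r``, wall thickness ``W`` (the
intima-media diffusion barrier), volumetric flow ``V`` and diffusion
coefficient ``D``, the blood tension at distance ``x`` from the entrance
obeys

    Px = PT - (PT - P0) * exp(-(2 pi r D / (W V)) * x)

where ``P0`` is the entrance tension and ``PT`` the surrounding-tissue
tension.  Because flow drops and walls thin toward the periphery, the
exponent grows along the tree and distal segments load gas fastest;
a local flow reduction amplifies the effect in proportion.

Segments are stored in the conventional clinical units (cm, mL/s, mm)
and converted to SI in one place, :meth:`ArterySegment.transfer_exponent`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from importlib import resources
from math import exp, pi

import numpy as np
import pandas as pd
from scipy.optimize import brentq

#: Default inert-gas (nitrogen) diffusion coefficient in the vessel wall,
#: m^2/s.  Calibrated once, within the physically plausible aqueous-tissue
#: range 1--3e-9 m^2/s, so that the packaged brain path at full flow loads
#: the blood by 1.0% of its entrance tension (see docs/methods.md); frozen
#: thereafter.
DEFAULT_DIFFUSIVITY_M2_S = 1.1331e-9


@dataclass(frozen=True)
class ArterySegment:
    """One artery segment: geometry and flow in clinical units."""

    name: str
    length_cm: float
    radius_cm: float
    flow_ml_s: float
    wall_mm: float

    def __post_init__(self) -> None:
        for f in ("length_cm", "radius_cm", "flow_ml_s", "wall_mm"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{self.name}: {f} must be positive")

    def transfer_exponent(
        self,
        diffusivity_m2_s: float,
        flow_scale: float = 1.0,
        distance_cm: float | None = None,
    ) -> float:
        """Dimensionless exponent (2 pi r D / (W V)) * x at ``distance_cm``.

        This is the single clinical-units -> SI conversion boundary.
        """
        if flow_scale <= 0:
            raise ValueError(f"{self.name}: flow_scale must be positive")
        x_m = (self.length_cm if distance_cm is None else distance_cm) / 100.0
        r_m = self.radius_cm / 100.0
        w_m = self.wall_mm / 1000.0
        v_m3_s = self.flow_ml_s * flow_scale * 1e-6
        return 2.0 * pi * r_m * diffusivity_m2_s * x_m / (w_m * v_m3_s)


@dataclass(frozen=True)
class ArteryTree:
    """An ordered root-to-leaf chain of segments with per-segment flow scales."""

    segments: tuple[ArterySegment, ...]
    flow_scales: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("tree must contain at least one segment")
        for name, s in self.flow_scales.items():
            if s <= 0:
                raise ValueError(f"flow_scale for {name} must be positive")

    def flow_scale(self, name: str) -> float:
        return self.flow_scales.get(name, 1.0)

    def with_flow_scale(self, name: str, scale: float) -> "ArteryTree":
        if name not in {s.name for s in self.segments}:
            raise KeyError(f"unknown segment {name!r}")
        scales = dict(self.flow_scales)
        scales[name] = scale
        return replace(self, flow_scales=scales)

    def segment(self, name: str) -> ArterySegment:
        for s in self.segments:
            if s.name == name:
                return s
        raise KeyError(f"unknown segment {name!r}")


@dataclass(frozen=True)
class TensionQuery:
    """Boundary conditions for a tension computation.

    ``entrance_kpa`` (P0) is the blood tension entering the root segment,
    ``tissue_kpa`` (PT) the tension in the surrounding tissue, and
    ``diffusivity_m2_s`` the wall diffusion coefficient D.
    """

    entrance_kpa: float
    tissue_kpa: float
    diffusivity_m2_s: float = DEFAULT_DIFFUSIVITY_M2_S

    def __post_init__(self) -> None:
        if self.entrance_kpa < 0 or self.tissue_kpa < 0:
            raise ValueError("tensions must be non-negative")
        if self.diffusivity_m2_s <= 0:
            raise ValueError("diffusivity must be positive")


def segment_exit_tension(
    query: TensionQuery,
    segment: ArterySegment,
    flow_scale: float = 1.0,
    distance_cm: float | None = None,
) -> float:
    """Blood tension at ``distance_cm`` (default: segment exit)."""
    k = segment.transfer_exponent(query.diffusivity_m2_s, flow_scale, distance_cm)
    return query.tissue_kpa - (query.tissue_kpa - query.entrance_kpa) * exp(-k)


def tree_tension_profile(
    query: TensionQuery, tree: ArteryTree, n_points_per_segment: int = 20
) -> pd.DataFrame:
    """Tension along the whole path; each segment's exit feeds the next.

    Returns a DataFrame with columns ``distance_cm`` (cumulative),
    ``tension_kpa`` and ``segment``.
    """
    if n_points_per_segment < 2:
        raise ValueError("n_points_per_segment must be at least 2")
    rows: list[tuple[float, float, str]] = [
        (0.0, query.entrance_kpa, tree.segments[0].name)
    ]
    p_in = query.entrance_kpa
    offset = 0.0
    for seg in tree.segments:
        q = replace(query, entrance_kpa=p_in)
        scale = tree.flow_scale(seg.name)
        for x in np.linspace(0.0, seg.length_cm, n_points_per_segment)[1:]:
            rows.append(
                (offset + x, segment_exit_tension(q, seg, scale, x), seg.name)
            )
        p_in = rows[-1][1]
        offset += seg.length_cm
    return pd.DataFrame(rows, columns=["distance_cm", "tension_kpa", "segment"])


def path_exit_tension(query: TensionQuery, tree: ArteryTree) -> float:
    """Exit tension of the last segment (exact chained closed form)."""
    p = query.entrance_kpa
    for seg in tree.segments:
        q = replace(query, entrance_kpa=p)
        p = segment_exit_tension(q, seg, tree.flow_scale(seg.name))
    return p


def relative_rise_pct(query: TensionQuery, tree: ArteryTree) -> float:
    """Relative tension rise at the path end, 100 * (Px - P0) / P0."""
    px = path_exit_tension(query, tree)
    return 100.0 * (px - query.entrance_kpa) / query.entrance_kpa


def flow_reduction_scan(
    query: TensionQuery,
    tree: ArteryTree,
    segment_name: str,
    scales: list[float],
) -> pd.DataFrame:
    """Exit tension and % rise for a range of flow scales in one segment.

    Less flow means longer residence and more gas loading, so the % rise
    is strictly decreasing in the flow scale.
    """
    tree.segment(segment_name)  # raises KeyError on unknown name
    rows = []
    for s in scales:
        scaled = tree.with_flow_scale(segment_name, s)
        exit_kpa = path_exit_tension(query, scaled)
        rise = 100.0 * (exit_kpa - query.entrance_kpa) / query.entrance_kpa
        rows.append((s, exit_kpa, rise))
    return pd.DataFrame(rows, columns=["flow_scale", "exit_kpa", "rise_pct"])


def calibrate_diffusivity(
    tree: ArteryTree,
    entrance_kpa: float = 101.0,
    tissue_kpa: float = 500.0,
    target_rise_pct: float = 1.0,
    bounds: tuple[float, float] = (1e-10, 1e-8),
) -> float:
    """Solve for the D that produces ``target_rise_pct`` at the path end."""

    def f(d: float) -> float:
        q = TensionQuery(entrance_kpa, tissue_kpa, d)
        return relative_rise_pct(q, tree) - target_rise_pct

    return float(brentq(f, *bounds, xtol=1e-16, rtol=1e-14))


def tree_from_dict(payload: dict) -> ArteryTree:
    """Build a tree from the JSON layout used on disk (see io module)."""
    segs = []
    scales: dict[str, float] = {}
    for s in payload["segments"]:
        segs.append(
            ArterySegment(
                name=s["name"],
                length_cm=s["length_cm"],
                radius_cm=s["radius_cm"],
                flow_ml_s=s["flow_ml_s"],
                wall_mm=s["wall_mm"],
            )
        )
        if "flow_scale" in s and s["flow_scale"] != 1.0:
            scales[s["name"]] = s["flow_scale"]
    return ArteryTree(tuple(segs), scales)


def tree_to_dict(tree: ArteryTree) -> dict:
    return {
        "segments": [
            {
                "name": s.name,
                "length_cm": s.length_cm,
                "radius_cm": s.radius_cm,
                "flow_ml_s": s.flow_ml_s,
                "wall_mm": s.wall_mm,
                "flow_scale": tree.flow_scale(s.name),
            }
            for s in tree.segments
        ]
    }


def default_brain_path() -> ArteryTree:
    """The packaged aorta-to-anterior-cerebral-artery path.

    Segment dimensions are representative human values assembled from the
    vascular-anatomy literature (synthetic defaults, editable via JSON):
    aorta, common carotid, internal carotid, anterior cerebral (A2).
    """
    text = (
        resources.files("decobubble")
        .joinpath("data/brain_arterial_path.json")
        .read_text()
    )
    return tree_from_dict(json.loads(text))
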