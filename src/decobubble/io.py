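"""Readers and writers for profiles, trees, records and run configuration.

CSV files are comma-separated, UTF-8, "." decimal, with a mandatory
header row; every file written here carries a metadata comment/field
with the package version and a hash of the generating configuration.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .arterial_tree import ArteryTree, tree_from_dict, tree_to_dict
from .bubble_dynamics import BubbleRecord
from .gas_kinetics import DiveProfile, depth_to_ambient_kpa

PROFILE_COLUMNS = ("time_s", "ambient_kpa", "inert_fraction")
RECORD_COLUMNS = (
    "site_id",
    "vessel",
    "t_detach_min",
    "diameter_mm",
    "volume_mm3",
    "force_n",
    "sequence",
)


def config_hash(config: object) -> str:
    """Short stable hash of any JSON-serialisable configuration object."""
    payload = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _metadata_line(config: object | None) -> str:
    return f"# decobubble={__version__} config={config_hash(config or {})}"


def _require_columns(df: pd.DataFrame, required: tuple[str, ...], path: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {', '.join(missing)}")


def write_profile(
    profile: DiveProfile, path: str | Path, config: object | None = None
) -> None:
    df = pd.DataFrame(
        {
            "time_s": profile.times_s,
            "ambient_kpa": profile.ambient_kpa,
            "inert_fraction": profile.inert_fraction,
        }
    )
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_metadata_line(config) + "\n")
        df.to_csv(fh, index=False)


def read_profile(path: str | Path) -> DiveProfile:
    """Read a dive-profile CSV.

    Accepts either an ``ambient_kpa`` column or a ``depth_msw`` column
    (converted as 101.325 + 10.0897 * depth).  Column names are
    case-insensitive.
    """
    df = pd.read_csv(path, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    if "ambient_kpa" not in df.columns and "depth_msw" in df.columns:
        df["ambient_kpa"] = depth_to_ambient_kpa(df["depth_msw"].to_numpy())
    _require_columns(df, PROFILE_COLUMNS, str(path))
    return DiveProfile(
        df["time_s"].to_numpy(float),
        df["ambient_kpa"].to_numpy(float),
        df["inert_fraction"].to_numpy(float),
    )


def write_records(
    records: list[BubbleRecord], path: str | Path, config: object | None = None
) -> None:
    df = pd.DataFrame([asdict(r) for r in records], columns=RECORD_COLUMNS)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_metadata_line(config) + "\n")
        df.to_csv(fh, index=False)


def read_records(path: str | Path) -> list[BubbleRecord]:
    df = pd.read_csv(path, comment="#")
    df.columns = [c.strip().lower() for c in df.columns]
    _require_columns(df, RECORD_COLUMNS, str(path))
    return [
        BubbleRecord(
            site_id=str(r.site_id),
            vessel=str(r.vessel),
            t_detach_min=float(r.t_detach_min),
            diameter_mm=float(r.diameter_mm),
            volume_mm3=float(r.volume_mm3),
            force_n=float(r.force_n),
            sequence=int(r.sequence),
        )
        for r in df.itertuples()
    ]


def write_tree(
    tree: ArteryTree, path: str | Path, config: object | None = None
) -> None:
    payload = tree_to_dict(tree)
    payload["meta"] = {"decobubble": __version__, "config": config_hash(config or {})}
    Path(path).write_text(json.dumps(payload, indent=2), encoding="utf-8")


def read_tree(path: str | Path) -> ArteryTree:
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    if "segments" not in payload:
        raise ValueError(f"{path}: missing field 'segments'")
    for i, seg in enumerate(payload["segments"]):
        for f in ("name", "length_cm", "radius_cm", "flow_ml_s", "wall_mm"):
            if f not in seg:
                raise ValueError(f"{path}: segment {i}: missing field {f!r}")
    return tree_from_dict(payload)


@dataclass
class RunConfig:
    """Top-level configuration for a seeded simulation run."""

    seed: int = 0
    dt_s: float = 15.0
    duration_min: float = 120.0
    profile_path: str | None = None
    tree_path: str | None = None
    subjects_path: str | None = None
    overrides: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))
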