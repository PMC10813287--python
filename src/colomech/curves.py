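"""Stress-strain curve container and its on-disk text format.

A curve is stored as a comma-delimited text file with header
``strain,stress_pa`` (comment lines starting with ``#`` and CRLF endings are
tolerated) plus an optional JSON sidecar ``<file>.meta.json`` carrying the
orientation, stress kind and specimen geometry.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .mechanics import LoadingAxis

__all__ = ["StressStrainCurve", "read_curve", "write_curve"]


@dataclasses.dataclass
class StressStrainCurve:
    """Sampled engineering-strain / stress pairs for one specimen pull.

    Attributes
    ----------
    strain : ndarray
        Engineering strain (dimensionless), non-negative, increasing.
    stress : ndarray
        Stress in Pa; ``stress_kind`` says whether engineering or true.
    orientation : LoadingAxis
        Circumferential (1) or longitudinal (2).
    stress_kind : str
        ``"engineering"`` or ``"true"``.
    geometry : dict | None
        Optional specimen geometry metadata (mm).
    """

    strain: np.ndarray
    stress: np.ndarray
    orientation: LoadingAxis
    stress_kind: str = "engineering"
    geometry: dict | None = None

    def __post_init__(self) -> None:
        self.strain = np.asarray(self.strain, dtype=float)
        self.stress = np.asarray(self.stress, dtype=float)
        if self.strain.shape != self.stress.shape or self.strain.ndim != 1:
            raise ValueError("strain and stress must be equal-length 1-D arrays")
        self.orientation = LoadingAxis.coerce(self.orientation)

    def __len__(self) -> int:
        return self.strain.size


def read_curve(path: str | Path) -> StressStrainCurve:
    """Read a ``strain,stress_pa`` file and its sidecar if present."""
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    expected = ["strain", "stress_pa"]
    if list(df.columns)[:2] != expected:
        raise ValueError(f"{path}: expected columns {expected}, got {list(df.columns)}")
    meta_path = path.with_suffix(path.suffix + ".meta.json")
    orientation = LoadingAxis.CIRCUMFERENTIAL
    stress_kind = "engineering"
    geometry = None
    if meta_path.exists():
        meta = json.loads(meta_path.read_text())
        orientation = LoadingAxis.coerce(meta.get("orientation", orientation))
        stress_kind = meta.get("stress_kind", stress_kind)
        geometry = meta.get("geometry")
    return StressStrainCurve(
        strain=df["strain"].to_numpy(),
        stress=df["stress_pa"].to_numpy(),
        orientation=orientation,
        stress_kind=stress_kind,
        geometry=geometry,
    )


def write_curve(curve: StressStrainCurve, path: str | Path, *, provenance: dict | None = None) -> None:
    """Write the curve and a JSON sidecar with orientation/geometry metadata."""
    path = Path(path)
    df = pd.DataFrame({"strain": curve.strain, "stress_pa": curve.stress})
    df.to_csv(path, index=False)
    meta = {
        "orientation": int(curve.orientation),
        "stress_kind": curve.stress_kind,
        "geometry": curve.geometry,
    }
    if provenance:
        meta["provenance"] = provenance
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps(meta, indent=2) + "\n"
    )
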