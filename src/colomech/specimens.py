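"""Shared specimen-level data types: geometry, test protocol, load records."""

from __future__ import annotations

import dataclasses

import numpy as np

from .mechanics import LoadingAxis

__all__ = ["SpecimenGeometry", "TestProtocol", "LoadRecord"]


@dataclasses.dataclass
class SpecimenGeometry:
    """Rectangular tensile-specimen dimensions (mm).

    Pre-conditioning gauge length and width come from the die cut; repeated
    sub-failure load cycles leave the specimen longer and narrower, so the
    post-conditioning length and minimum width are the reference dimensions
    for stress and strain.
    """

    gauge_length: float
    width: float
    thickness: float
    orientation: LoadingAxis
    post_conditioning_length: float
    post_conditioning_width: float

    def __post_init__(self) -> None:
        self.orientation = LoadingAxis.coerce(self.orientation)
        for f in ("gauge_length", "width", "thickness",
                  "post_conditioning_length", "post_conditioning_width"):
            if not getattr(self, f) > 0:
                raise ValueError(f"{f} must be positive")
        if not self.post_conditioning_length > self.gauge_length:
            raise ValueError(
                "post-conditioning length must exceed the pre-conditioning gauge length"
            )

    @property
    def cross_section_m2(self) -> float:
        """Post-conditioning cross-section (minimum width x thickness), m^2."""
        return self.post_conditioning_width * self.thickness * 1e-6


@dataclasses.dataclass(frozen=True)
class TestProtocol:
    """Uniaxial test protocol: preconditioning then a monotone pull.

    Defaults: four triangular preconditioning cycles to 7% strain at a
    crosshead rate of 0.05 mm/s, load sampled at 30 Hz, video at 60 fps.
    """

    preconditioning_cycles: int = 4
    preconditioning_strain: float = 0.07
    displacement_rate: float = 0.05  # mm/s
    load_sample_rate: float = 30.0  # Hz
    frame_rate: float = 60.0  # Hz

    def __post_init__(self) -> None:
        if self.preconditioning_cycles < 0:
            raise ValueError("preconditioning_cycles must be >= 0")
        for f in ("preconditioning_strain", "displacement_rate",
                  "load_sample_rate", "frame_rate"):
            if not getattr(self, f) > 0:
                raise ValueError(f"{f} must be positive")


@dataclasses.dataclass
class LoadRecord:
    """Sampled load-cell record: time (s), force (N), displacement (mm)."""

    time: np.ndarray
    force: np.ndarray
    displacement: np.ndarray
    sample_rate: float
    onset_index: int | None = None
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        if not (self.time.shape == self.force.shape == self.displacement.shape):
            raise ValueError("time, force and displacement must have equal length")
        if self.time.ndim != 1 or self.time.size == 0:
            raise ValueError("record must contain at least one sample")
        if self.time.size > 1 and np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if not self.sample_rate > 0:
            raise ValueError("sample_rate must be positive")

    def __len__(self) -> int:
        return self.time.size

    def replace(self, **kwargs) -> "LoadRecord":
        return dataclasses.replace(self, **kwargs)
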