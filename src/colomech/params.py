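"""Material parameters of the anisotropic hyperelastic colorectal-tissue model.

The model combines a three-term Yeoh isotropic matrix with two in-plane fiber
families, each described by a polynomial in its squared-stretch pseudo-invariant
(powers 2..4) and an undeformed orientation angle measured from the
circumferential axis.  Eleven coefficients in total: a1..a3 (Pa), c2..c4 (Pa),
e2..e4 (Pa), beta1 and beta2 (degrees).
"""

from __future__ import annotations

import dataclasses
import json
import math
from importlib import resources
from pathlib import Path

__all__ = [
    "MaterialParameters",
    "canonicalize",
    "load_parameters",
    "save_parameters",
    "published_parameters",
]

# fixed polynomial orders: isotropic sum i=1..3, fiber sums j,k=2..4
N_ISO = 3
M_FIBER = 4


@dataclasses.dataclass(frozen=True)
class MaterialParameters:
    """The 11 coefficients of the fiber-reinforced Yeoh model.

    Parameters
    ----------
    a1, a2, a3 : float
        Yeoh isotropic coefficients, Pa.
    c2, c3, c4 : float
        Polynomial coefficients of fiber family 1, Pa.
    e2, e3, e4 : float
        Polynomial coefficients of fiber family 2, Pa.
    beta1, beta2 : float
        Undeformed fiber angles in degrees, measured from the circumferential
        axis in the circumferential-longitudinal plane.
    """

    a1: float
    a2: float
    a3: float
    c2: float
    c3: float
    c4: float
    e2: float
    e3: float
    e4: float
    beta1: float
    beta2: float

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if not math.isfinite(value):
                raise ValueError(f"parameter {name!r} must be finite, got {value!r}")

    @property
    def iso(self) -> tuple[float, float, float]:
        """Yeoh coefficients (a1, a2, a3) in Pa."""
        return (self.a1, self.a2, self.a3)

    @property
    def fiber1(self) -> tuple[float, float, float]:
        """Family-1 coefficients (c2, c3, c4) in Pa."""
        return (self.c2, self.c3, self.c4)

    @property
    def fiber2(self) -> tuple[float, float, float]:
        """Family-2 coefficients (e2, e3, e4) in Pa."""
        return (self.e2, self.e3, self.e4)

    def as_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    def as_array(self) -> list[float]:
        """Flat coefficient vector in field order (used by the optimizer)."""
        return [getattr(self, f.name) for f in dataclasses.fields(self)]

    @classmethod
    def from_array(cls, values) -> "MaterialParameters":
        names = [f.name for f in dataclasses.fields(cls)]
        if len(values) != len(names):
            raise ValueError(f"expected {len(names)} values, got {len(values)}")
        return cls(**{n: float(v) for n, v in zip(names, values)})


def canonicalize(params: MaterialParameters) -> MaterialParameters:
    """Remove the fiber-family labelling degeneracy.

    Angles are wrapped into [0, 180) -- the fiber direction vector enters the
    model only through its dyadic square, so beta and beta+180 are the same
    fiber -- and the two families are reordered so that beta1 <= beta2.  The
    stress response is invariant under this relabelling.
    """
    b1 = params.beta1 % 180.0
    b2 = params.beta2 % 180.0
    fam1 = (params.c2, params.c3, params.c4, b1)
    fam2 = (params.e2, params.e3, params.e4, b2)
    if b2 < b1:
        fam1, fam2 = fam2, fam1
    return MaterialParameters(
        a1=params.a1, a2=params.a2, a3=params.a3,
        c2=fam1[0], c3=fam1[1], c4=fam1[2],
        e2=fam2[0], e3=fam2[1], e4=fam2[2],
        beta1=fam1[3], beta2=fam2[3],
    )


_JSON_KEYS = {
    "a1", "a2", "a3", "c2", "c3", "c4", "e2", "e3", "e4",
    "beta1_deg", "beta2_deg",
}


def load_parameters(path: str | Path) -> MaterialParameters:
    """Read a parameter JSON file (keys a1..e4 in Pa, beta1_deg/beta2_deg)."""
    with open(path) as fh:
        raw = json.load(fh)
    return _from_json_dict(raw, source=str(path))


def _from_json_dict(raw: dict, source: str = "<dict>") -> MaterialParameters:
    unknown = set(raw) - _JSON_KEYS
    missing = _JSON_KEYS - set(raw)
    if unknown or missing:
        raise ValueError(
            f"bad parameter file {source}: unknown keys {sorted(unknown)}, "
            f"missing keys {sorted(missing)}"
        )
    kwargs = {k: float(v) for k, v in raw.items() if not k.startswith("beta")}
    return MaterialParameters(
        beta1=float(raw["beta1_deg"]), beta2=float(raw["beta2_deg"]), **kwargs
    )


def save_parameters(params: MaterialParameters, path: str | Path) -> None:
    d = params.as_dict()
    d["beta1_deg"] = d.pop("beta1")
    d["beta2_deg"] = d.pop("beta2")
    with open(path, "w") as fh:
        json.dump(d, fh, indent=2)
        fh.write("\n")


def published_parameters() -> MaterialParameters:
    """The published fitted coefficient set for porcine colorectal tissue.

    The balanced Pareto solution of the source study's calibration: fibers
    nearly aligned with the circumferential (beta1 ~ 0.79 deg) and longitudinal
    (beta2 ~ 90.1 deg) axes.
    """
    ref = resources.files("colomech.data").joinpath("table3.json")
    return _from_json_dict(json.loads(ref.read_text()), source="table3.json")
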