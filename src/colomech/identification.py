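"""Two-objective evolutionary identification of the model coefficients.

The fit minimizes a pair of normalized errors, one per loading direction::

    E = sum_l (sigma_exp_l - sigma_model_l)^2 / sum_l sigma_exp_l^2

(Ec over circumferential samples, Et over longitudinal samples) with an
NSGA-II genetic algorithm over the eleven coefficients.  The result is a
Pareto front of non-dominated (Ec, Et) trade-offs; the "balanced" member is
the minimax one, i.e. it minimizes max(Ec, Et).

Two aggregation modes handle multiple specimens per direction: pooling every
sampled point (default) or averaging the specimen curves onto a common strain
grid first.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from . import moo
from .curves import StressStrainCurve
from .mechanics import LoadingAxis, StressKind, uniaxial_stress_array
from .params import MaterialParameters, canonicalize

__all__ = [
    "ObjectivePair",
    "ParetoSolution",
    "FitConfig",
    "normalized_error",
    "evaluate_objectives",
    "run_moo",
    "select_balanced",
    "bounds_around",
    "HyperelasticCurveFitter",
]

_COEFF_NAMES = ("a1", "a2", "a3", "c2", "c3", "c4", "e2", "e3", "e4")
_PARAM_NAMES = _COEFF_NAMES + ("beta1", "beta2")


@dataclasses.dataclass(frozen=True)
class ObjectivePair:
    """Normalized circumferential (Ec) and longitudinal (Et) errors."""

    Ec: float
    Et: float

    def max(self) -> float:
        return max(self.Ec, self.Et)


@dataclasses.dataclass(frozen=True)
class ParetoSolution:
    params: MaterialParameters
    objectives: ObjectivePair


def _default_bounds() -> dict[str, tuple[float, float]]:
    b: dict[str, tuple[float, float]] = {n: (-1e7, 1e7) for n in _COEFF_NAMES}
    b["beta1"] = (0.0, 180.0)
    b["beta2"] = (0.0, 180.0)
    return b


@dataclasses.dataclass
class FitConfig:
    """Configuration of the evolutionary fit.

    Parameters
    ----------
    population_size, generations : int
        NSGA-II size; defaults converge on the synthetic recovery task.
    bounds : dict
        Per-parameter (low, high); coefficients in Pa, angles in degrees.
    seed : int
        Seed of the GA's random generator.
    stress_kind : str
        Which stress measure the objectives compare ("engineering" or "true").
    aggregation : str
        "pooled-points" (default) or "mean-curve".
    """

    population_size: int = 200
    generations: int = 300
    bounds: dict[str, tuple[float, float]] = dataclasses.field(
        default_factory=_default_bounds
    )
    seed: int = 0
    stress_kind: str = "engineering"
    aggregation: str = "pooled-points"

    def __post_init__(self) -> None:
        if self.population_size < 10:
            raise ValueError("population size must be >= 10")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if self.aggregation not in ("pooled-points", "mean-curve"):
            raise ValueError(f"unknown aggregation mode {self.aggregation!r}")
        StressKind(self.stress_kind)
        unknown = set(self.bounds) - set(_PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown bound keys {sorted(unknown)}")
        full = _default_bounds()
        full.update({k: (float(v[0]), float(v[1])) for k, v in self.bounds.items()})
        for name, (lo, hi) in full.items():
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"bounds for {name} must be finite with low < high")
        self.bounds = full

    def bounds_array(self) -> np.ndarray:
        return np.array([self.bounds[n] for n in _PARAM_NAMES], dtype=float)

    @classmethod
    def from_json(cls, path: str | Path) -> "FitConfig":
        raw = json.loads(Path(path).read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown FitConfig keys {sorted(unknown)}")
        if "bounds" in raw:
            raw["bounds"] = {k: tuple(v) for k, v in raw["bounds"].items()}
        return cls(**raw)


def bounds_around(
    params: MaterialParameters, low_factor: float = 0.1, high_factor: float = 10.0
) -> dict[str, tuple[float, float]]:
    """Sign-preserving multiplicative bounds around a coefficient set.

    Each coefficient's interval spans |value| x [low_factor, high_factor] on
    its own side of zero; angles span [0, 180).  Useful for recovery studies
    where the truth is known.
    """
    b: dict[str, tuple[float, float]] = {}
    d = params.as_dict()
    for name in _COEFF_NAMES:
        v = d[name]
        lo, hi = sorted((v * low_factor, v * high_factor))
        b[name] = (lo, hi)
    b["beta1"] = (0.0, 180.0)
    b["beta2"] = (0.0, 180.0)
    return b


def normalized_error(model_stresses, experimental_stresses) -> float:
    """Sum of squared residuals normalized by the experimental sum of squares."""
    m = np.asarray(model_stresses, dtype=float)
    e = np.asarray(experimental_stresses, dtype=float)
    if m.shape != e.shape or m.ndim != 1 or m.size == 0:
        raise ValueError("stress arrays must be equal-length non-empty 1-D arrays")
    denom = float(np.sum(e * e))
    if denom == 0.0:
        raise ValueError("experimental stresses are all zero: normalization degenerate")
    return float(np.sum((e - m) ** 2) / denom)


def _pool_points(
    curves: Sequence[StressStrainCurve], aggregation: str
) -> tuple[np.ndarray, np.ndarray]:
    """Reduce a curve set to one (strain, stress) point set per direction."""
    if not curves:
        raise ValueError("need at least one curve per direction")
    if aggregation == "pooled-points":
        eps = np.concatenate([c.strain for c in curves])
        sig = np.concatenate([c.stress for c in curves])
        return eps, sig
    # mean-curve: interpolate each specimen onto a common grid and average
    lo = max(float(c.strain[0]) for c in curves)
    hi = min(float(c.strain[-1]) for c in curves)
    if not hi > lo:
        raise ValueError("curves have no overlapping strain range to average over")
    n = max(len(c) for c in curves)
    grid = np.linspace(lo, hi, n)
    stack = np.vstack([np.interp(grid, c.strain, c.stress) for c in curves])
    return grid, stack.mean(axis=0)


def evaluate_objectives(
    params: MaterialParameters,
    circ_curves: Sequence[StressStrainCurve],
    long_curves: Sequence[StressStrainCurve],
    config: FitConfig | None = None,
) -> ObjectivePair:
    """(Ec, Et) of one parameter set against the two curve sets."""
    config = config or FitConfig()
    out = []
    for curves, axis in (
        (circ_curves, LoadingAxis.CIRCUMFERENTIAL),
        (long_curves, LoadingAxis.LONGITUDINAL),
    ):
        eps, sig = _pool_points(curves, config.aggregation)
        model = uniaxial_stress_array(params, eps, axis, config.stress_kind)
        out.append(normalized_error(model, sig))
    return ObjectivePair(Ec=out[0], Et=out[1])


def _make_objective(circ_pts, long_pts, stress_kind):
    eps_c, sig_c = circ_pts
    eps_l, sig_l = long_pts
    den_c = float(np.sum(sig_c**2))
    den_l = float(np.sum(sig_l**2))
    if den_c == 0.0 or den_l == 0.0:
        raise ValueError("experimental stresses are all zero in one direction")

    def objective(X: np.ndarray) -> np.ndarray:
        F = np.empty((X.shape[0], 2))
        for i, row in enumerate(X):
            p = MaterialParameters.from_array(row)
            mc = uniaxial_stress_array(p, eps_c, LoadingAxis.CIRCUMFERENTIAL, stress_kind)
            ml = uniaxial_stress_array(p, eps_l, LoadingAxis.LONGITUDINAL, stress_kind)
            F[i, 0] = np.sum((sig_c - mc) ** 2) / den_c
            F[i, 1] = np.sum((sig_l - ml) ** 2) / den_l
        return F

    return objective


def _fit_points(circ_pts, long_pts, config: FitConfig, callback=None):
    objective = _make_objective(circ_pts, long_pts, config.stress_kind)
    X, F = moo.nsga2(
        objective,
        config.bounds_array(),
        pop_size=config.population_size,
        generations=config.generations,
        seed=config.seed,
        callback=callback,
    )
    front = [
        ParetoSolution(
            params=MaterialParameters.from_array(x),
            objectives=ObjectivePair(Ec=float(f[0]), Et=float(f[1])),
        )
        for x, f in zip(X, F)
    ]
    front.sort(key=lambda s: (s.objectives.Ec, s.objectives.Et))
    return front


def run_moo(
    circ_curves: Sequence[StressStrainCurve],
    long_curves: Sequence[StressStrainCurve],
    config: FitConfig | None = None,
    callback=None,
) -> list[ParetoSolution]:
    """Generate the Pareto front of (Ec, Et); deterministic per config.seed."""
    config = config or FitConfig()
    circ_pts = _pool_points(circ_curves, config.aggregation)
    long_pts = _pool_points(long_curves, config.aggregation)
    return _fit_points(circ_pts, long_pts, config, callback)


def select_balanced(front: Sequence[ParetoSolution]) -> ParetoSolution:
    """Minimax member of the front: smallest max(Ec, Et).

    Ties are broken by smaller Ec + Et, then by input order.
    """
    if not front:
        raise ValueError("cannot select from an empty Pareto front")
    best = front[0]
    for sol in front[1:]:
        a, b = sol.objectives, best.objectives
        if (a.max(), a.Ec + a.Et) < (b.max(), b.Ec + b.Et):
            best = sol
    return best


class HyperelasticCurveFitter(BaseEstimator, RegressorMixin):
    """Scikit-learn style estimator wrapping the two-objective GA fit.

    ``X`` is an ``(n, 2)`` array of ``[engineering_strain, axis]`` rows with
    axis 1 = circumferential, 2 = longitudinal; ``y`` holds the measured
    stresses in Pa.  :meth:`fit` runs NSGA-II on the pooled points of each
    direction, stores the Pareto front and the canonicalized balanced
    solution, and :meth:`predict` evaluates that solution.

    Attributes
    ----------
    params_ : MaterialParameters
        Canonicalized balanced (minimax) Pareto solution.
    pareto_front_ : list of ParetoSolution
        Final non-dominated set, sorted by Ec.
    objectives_ : ObjectivePair
        (Ec, Et) of the balanced solution.
    """

    def __init__(
        self,
        population_size: int = 200,
        generations: int = 300,
        bounds: dict | None = None,
        stress_kind: str = "engineering",
        random_state: int = 0,
    ):
        self.population_size = population_size
        self.generations = generations
        self.bounds = bounds
        self.stress_kind = stress_kind
        self.random_state = random_state

    def _config(self) -> FitConfig:
        return FitConfig(
            population_size=self.population_size,
            generations=self.generations,
            bounds=dict(self.bounds) if self.bounds else _default_bounds(),
            seed=self.random_state,
            stress_kind=self.stress_kind,
        )

    @staticmethod
    def _split(X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n, 2) array of [strain, axis]")
        axes = X[:, 1].astype(int)
        if not np.all((axes == 1) | (axes == 2)):
            raise ValueError("axis column must contain only 1 or 2")
        mc, ml = axes == 1, axes == 2
        if y is None:
            return X[:, 0], mc, ml
        y = np.asarray(y, dtype=float)
        if y.shape != (X.shape[0],):
            raise ValueError("y must be a 1-D array matching X")
        return X[:, 0], mc, ml, y

    def fit(self, X, y):
        eps, mc, ml, y = self._split(X, y)
        if not mc.any() or not ml.any():
            raise ValueError("need samples on both loading axes to fit")
        config = self._config()
        front = _fit_points((eps[mc], y[mc]), (eps[ml], y[ml]), config)
        balanced = select_balanced(front)
        self.pareto_front_ = front
        self.params_ = canonicalize(balanced.params)
        self.objectives_ = balanced.objectives
        self.n_features_in_ = 2
        return self

    def predict(self, X):
        if not hasattr(self, "params_"):
            raise AttributeError("estimator is not fitted yet; call fit first")
        eps, mc, ml = self._split(X)
        out = np.empty(eps.shape)
        for mask, axis in ((mc, LoadingAxis.CIRCUMFERENTIAL), (ml, LoadingAxis.LONGITUDINAL)):
            if mask.any():
                out[mask] = uniaxial_stress_array(
                    self.params_, eps[mask], axis, self.stress_kind
                )
        return out
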