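"""Synthetic specimens, stress-strain curves and load histories.

Emulates the study conditions of the uniaxial colorectal-tissue experiment:
specimen geometry statistics per orientation (die-cut 20 mm gauge length;
width/thickness and post-conditioning dimensions drawn from the reported
per-orientation means and standard deviations), the preconditioning protocol
(four triangular cycles to 7% strain at 0.05 mm/s, load sampled at 30 Hz),
and model-generated stress-strain curves with multiplicative Gaussian noise.

Every sampler takes an explicit integer seed; there is no global random
state.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .curves import StressStrainCurve
from .mechanics import LoadingAxis, StressKind, predict_curve, uniaxial_stress_array
from .params import MaterialParameters
from .specimens import LoadRecord, SpecimenGeometry, TestProtocol

__all__ = [
    "GEOMETRY_STATS",
    "sample_geometry",
    "mean_geometry",
    "generate_curves",
    "generate_load_history",
]

# Per-orientation geometry statistics (mean, SD) in mm: die-cut gauge length
# is exact; width, thickness and the post-conditioning dimensions vary
# between specimens.
GEOMETRY_STATS = {
    LoadingAxis.CIRCUMFERENTIAL: {
        "gauge_length": (20.0, 0.0),
        "width": (10.1, 1.7),
        "thickness": (1.0, 0.2),
        "post_conditioning_length": (29.0, 2.6),
        "post_conditioning_width": (8.9, 2.0),
    },
    LoadingAxis.LONGITUDINAL: {
        "gauge_length": (20.0, 0.0),
        "width": (8.6, 1.6),
        "thickness": (1.1, 0.3),
        "post_conditioning_length": (29.8, 2.2),
        "post_conditioning_width": (8.0, 2.1),
    },
}


def _truncated_normal(rng, mean, sd, n, lower=None, upper=None):
    """Normal(mean, sd) truncated at +-3 SD and at a positivity floor."""
    if sd == 0.0:
        return np.full(n, mean)
    lo = max(mean - 3.0 * sd, 0.0 if lower is None else lower)
    hi = mean + 3.0 * sd if upper is None else upper
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=n, random_state=rng)


def sample_geometry(orientation, n: int, seed: int) -> list[SpecimenGeometry]:
    """Draw ``n`` independent specimen geometries for one orientation."""
    axis = LoadingAxis.coerce(orientation)
    if n < 1:
        raise ValueError("n must be >= 1")
    s = GEOMETRY_STATS[axis]
    rng = np.random.default_rng(seed)
    gauge = _truncated_normal(rng, *s["gauge_length"], n)
    width = _truncated_normal(rng, *s["width"], n)
    thick = _truncated_normal(rng, *s["thickness"], n)
    # post-conditioning length must exceed the gauge length
    post_len = _truncated_normal(
        rng, *s["post_conditioning_length"], n, lower=s["gauge_length"][0] * 1.001
    )
    post_w = _truncated_normal(rng, *s["post_conditioning_width"], n)
    return [
        SpecimenGeometry(
            gauge_length=float(gauge[i]),
            width=float(width[i]),
            thickness=float(thick[i]),
            orientation=axis,
            post_conditioning_length=float(post_len[i]),
            post_conditioning_width=float(post_w[i]),
        )
        for i in range(n)
    ]


def mean_geometry(orientation) -> SpecimenGeometry:
    """The average specimen of one orientation (no sampling)."""
    axis = LoadingAxis.coerce(orientation)
    s = GEOMETRY_STATS[axis]
    return SpecimenGeometry(
        gauge_length=s["gauge_length"][0],
        width=s["width"][0],
        thickness=s["thickness"][0],
        orientation=axis,
        post_conditioning_length=s["post_conditioning_length"][0],
        post_conditioning_width=s["post_conditioning_width"][0],
    )


def generate_curves(
    params: MaterialParameters,
    orientation,
    n_specimens: int,
    strain_max: float = 0.2,
    n_points: int = 50,
    noise_cv: float = 0.0,
    seed: int = 0,
    stress_kind: StressKind | str = StressKind.ENGINEERING,
) -> list[StressStrainCurve]:
    """Model stress-strain curves with multiplicative Gaussian noise.

    Each curve is the model prediction times ``1 + eps`` with
    ``eps ~ Normal(0, noise_cv)`` independently per point; negative stresses
    are clipped to zero.  ``noise_cv = 0`` returns exact model curves.
    """
    axis = LoadingAxis.coerce(orientation)
    if not strain_max > 0:
        raise ValueError("strain_max must be positive")
    if noise_cv < 0:
        raise ValueError("noise_cv must be >= 0")
    grid = np.linspace(0.0, strain_max, n_points)
    clean = predict_curve(params, grid, axis, stress_kind)
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_specimens):
        if noise_cv > 0:
            factor = 1.0 + rng.normal(0.0, noise_cv, size=grid.size)
            stress = np.maximum(clean.stress * factor, 0.0)
        else:
            stress = clean.stress.copy()
        out.append(
            StressStrainCurve(
                strain=grid.copy(),
                stress=stress,
                orientation=axis,
                stress_kind=clean.stress_kind,
            )
        )
    return out


def generate_load_history(
    geometry: SpecimenGeometry,
    protocol: TestProtocol,
    params: MaterialParameters,
    strain_max: float = 0.25,
) -> LoadRecord:
    """Noise-free load record: preconditioning cycles then a monotone ramp.

    The displacement trace holds ``protocol.preconditioning_cycles``
    triangular cycles to ``preconditioning_strain x gauge_length`` followed
    by a ramp to ``strain_max x post_conditioning_length``, all at the
    protocol displacement rate and sampled at the load sample rate.  Force is
    the model engineering stress times the post-conditioning cross-section;
    during the ramp the stretch is referred to the post-conditioning length
    (the onset of that ramp is the post-conditioning reference state, stored
    as ``metadata["onset_index"]``).
    """
    rate = protocol.displacement_rate
    dt = 1.0 / protocol.load_sample_rate
    d_pre = protocol.preconditioning_strain * geometry.gauge_length
    d_max = strain_max * geometry.post_conditioning_length

    # build the displacement profile from segment breakpoints
    knots_t = [0.0]
    knots_d = [0.0]
    t = 0.0
    for _ in range(protocol.preconditioning_cycles):
        t += d_pre / rate
        knots_t.append(t)
        knots_d.append(d_pre)
        t += d_pre / rate
        knots_t.append(t)
        knots_d.append(0.0)
    t_onset = t
    t += d_max / rate
    knots_t.append(t)
    knots_d.append(d_max)

    time = np.arange(0.0, t + dt / 2, dt)
    disp = np.interp(time, knots_t, knots_d)
    onset_index = int(np.searchsorted(time, t_onset, side="left"))

    area = geometry.cross_section_m2
    force = np.empty_like(disp)
    pre = slice(0, onset_index)
    post = slice(onset_index, None)
    # preconditioning phase strains the original gauge length
    force[pre] = area * uniaxial_stress_array(
        params, disp[pre] / geometry.gauge_length, geometry.orientation
    )
    force[post] = area * uniaxial_stress_array(
        params,
        (disp[post] - disp[onset_index]) / geometry.post_conditioning_length,
        geometry.orientation,
    )
    return LoadRecord(
        time=time,
        force=force,
        displacement=disp,
        sample_rate=protocol.load_sample_rate,
        metadata={"onset_index": onset_index, "strain_max": strain_max},
    )
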