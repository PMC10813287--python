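"""Raw tensile-record processing: smooth, slope-filter, find the onset of the
post-conditioning pull, and normalize to an engineering stress-strain curve.

Pipeline (matching how the rig data are reduced):

1. local 4th-order polynomial (Savitzky-Golay) smoothing of the force signal
   to suppress stepper-motor stepping artifacts;
2. numerical slope of the load followed by a zero-phase 5th-order Butterworth
   low-pass (cutoff as a fraction of Nyquist -- the sampling rate is only
   30 S/s, so the cutoff is a normalized configuration parameter);
3. onset detection: the start of the sustained positive-slope run that
   follows the final preconditioning unloading; time and load are zeroed
   there;
4. engineering strain and stress from the post-conditioning length and the
   minimum specimen width at onset, truncated at 20% strain by default.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import signal

from .curves import StressStrainCurve
from .errors import OnsetNotFoundError
from .specimens import LoadRecord, SpecimenGeometry, TestProtocol

__all__ = [
    "ProcessedCurve",
    "smooth_load",
    "slope_filter",
    "detect_onset",
    "engineering_curve",
    "process_record",
]

DEFAULT_SMOOTH_WINDOW = 31
DEFAULT_CUTOFF = 0.5  # fraction of Nyquist
DEFAULT_HOLD = 5
DEFAULT_STRAIN_LIMIT = 0.2


@dataclasses.dataclass
class ProcessedCurve(StressStrainCurve):
    """A stress-strain curve with processing provenance attached."""

    provenance: dict = dataclasses.field(default_factory=dict)


def smooth_load(record: LoadRecord, window: int = DEFAULT_SMOOTH_WINDOW) -> LoadRecord:
    """Sliding local least-squares quartic fit of the force signal.

    Exactly reproduces any global polynomial of degree <= 4; attenuates
    higher-frequency stepper noise.
    """
    if window % 2 == 0 or window <= 5 or window > len(record):
        raise ValueError(
            f"window must be odd, > 5 and <= record length, got {window}"
        )
    smoothed = signal.savgol_filter(record.force, window, polyorder=4)
    return record.replace(force=smoothed)


def slope_filter(
    record: LoadRecord, cutoff: float = DEFAULT_CUTOFF, order: int = 5
) -> np.ndarray:
    """Force slope (N/s): numerical derivative + zero-phase Butterworth low-pass.

    ``cutoff`` is a fraction of the Nyquist frequency in (0, 1).  Zero-phase
    (forward-backward) filtering keeps onset timing unshifted; DC gain is 1,
    so a linear ramp passes with its slope intact.
    """
    if len(record) == 0:
        raise ValueError("empty record")
    if not 0.0 < cutoff < 1.0:
        raise ValueError(f"cutoff must be in (0, 1) as a fraction of Nyquist, got {cutoff}")
    slope = np.gradient(record.force, record.time)
    padlen = 3 * (order + 1)
    if len(record) <= padlen:
        return slope
    b, a = signal.butter(order, cutoff)
    return signal.filtfilt(b, a, slope)


def _positive_runs(above: np.ndarray, hold: int) -> list[tuple[int, int]]:
    """[start, stop) spans where ``above`` holds for >= hold samples."""
    idx = np.flatnonzero(np.diff(np.concatenate(([0], above.view(np.int8), [0]))))
    runs = []
    for start, stop in zip(idx[::2], idx[1::2]):
        if stop - start >= hold:
            runs.append((int(start), int(stop)))
    return runs


def detect_onset(
    record: LoadRecord,
    protocol: TestProtocol | None = None,
    slope_threshold: float | None = None,
    hold: int = DEFAULT_HOLD,
    cutoff: float = DEFAULT_CUTOFF,
) -> int:
    """Index where the post-conditioning pull begins.

    Loading phases appear as sustained positive-slope runs in the filtered
    load slope: one per preconditioning cycle plus the final ramp.  The onset
    is the first index after the last preconditioning unloading where the
    slope stays above ``slope_threshold`` for at least ``hold`` samples, i.e.
    the start of run number ``preconditioning_cycles``.

    ``slope_threshold`` defaults to 10% of the peak filtered slope.
    """
    protocol = protocol or TestProtocol()
    slope = slope_filter(record, cutoff=cutoff)
    if slope_threshold is None:
        peak = float(np.max(slope))
        if peak <= 0:
            raise OnsetNotFoundError("load slope never positive; no loading phase found")
        slope_threshold = 0.1 * peak
    runs = _positive_runs(slope > slope_threshold, hold)
    if len(runs) < protocol.preconditioning_cycles + 1:
        raise OnsetNotFoundError(
            f"found {len(runs)} sustained loading phases, need "
            f"{protocol.preconditioning_cycles + 1} (cycles + final pull)"
        )
    onset = runs[protocol.preconditioning_cycles][0]
    record.onset_index = onset
    return onset


def engineering_curve(
    record: LoadRecord,
    geometry: SpecimenGeometry,
    reference_width: float | None = None,
    strain_limit: float | None = DEFAULT_STRAIN_LIMIT,
) -> ProcessedCurve:
    """Engineering stress-strain curve referred to the onset state.

    Strain is displacement past onset over the post-conditioning length;
    stress is force past onset over (minimum width at onset x thickness).
    Force in N and dimensions in mm give stress in Pa.  The curve passes
    through the origin exactly and is truncated at ``strain_limit``
    (damage territory beyond ~20% strain is excluded by default).
    """
    if record.onset_index is None:
        raise ValueError("record has no onset; run detect_onset first")
    if reference_width is None:
        reference_width = geometry.post_conditioning_width
    if not (reference_width > 0 and geometry.thickness > 0):
        raise ValueError("reference width and thickness must be positive")
    i0 = record.onset_index
    area_m2 = reference_width * geometry.thickness * 1e-6
    strain = (record.displacement[i0:] - record.displacement[i0]) / geometry.post_conditioning_length
    stress = (record.force[i0:] - record.force[i0]) / area_m2
    if strain_limit is not None:
        keep = strain <= strain_limit
        strain, stress = strain[keep], stress[keep]
    return ProcessedCurve(
        strain=strain,
        stress=stress,
        orientation=geometry.orientation,
        stress_kind="engineering",
        geometry={
            "post_conditioning_length_mm": geometry.post_conditioning_length,
            "reference_width_mm": reference_width,
            "thickness_mm": geometry.thickness,
        },
        provenance={
            "onset_index": int(i0),
            "strain_limit": strain_limit,
            "reference_width_source": (
                "explicit" if reference_width != geometry.post_conditioning_width else "geometry"
            ),
        },
    )


def process_record(
    record: LoadRecord,
    geometry: SpecimenGeometry,
    protocol: TestProtocol | None = None,
    reference_width: float | None = None,
    smooth_window: int | None = DEFAULT_SMOOTH_WINDOW,
    cutoff: float = DEFAULT_CUTOFF,
    slope_threshold: float | None = None,
    hold: int = DEFAULT_HOLD,
    strain_limit: float | None = DEFAULT_STRAIN_LIMIT,
) -> ProcessedCurve:
    """Full pipeline: smooth -> onset -> engineering curve."""
    work = record
    if smooth_window is not None and len(record) >= smooth_window:
        work = smooth_load(record, smooth_window)
    onset = detect_onset(work, protocol, slope_threshold, hold, cutoff)
    work.onset_index = onset
    curve = engineering_curve(work, geometry, reference_width, strain_limit)
    curve.provenance.update(
        {"smooth_window": smooth_window, "slope_cutoff": cutoff, "hold": hold}
    )
    return curve
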