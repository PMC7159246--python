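"""Extraction of mechanical properties from force-displacement-time traces.

Seven per-specimen scalars are derived from each ramp-to-failure test:
ultimate force/stress and strain at the maximum load, stiffness and elastic
modulus as the maximum gradient of sliding-window least-squares fits of
``force = a + b * displacement``, work to failure as the trapezoidal integral
of force over displacement, and relative stress relaxation as the fractional
drop in peak cyclic force from the first to the last tested cycle.

By default the stiffness/work analysis range is the ramp phase only (from the
start of the ramp to the ultimate point); ``range_mode="from_preload_end"``
extends it back to the end of the preload dwell, which includes the cyclic
block.
"""

from __future__ import annotations

from typing import Literal, Optional

import numpy as np
from scipy.signal import find_peaks

from .core import (
    PHASE_CYCLIC,
    PHASE_PRELOAD,
    PHASE_RAMP,
    LoadingProtocol,
    LoadTrace,
    MechanicalProperties,
    PhaseSegmentation,
    Specimen,
)

RangeMode = Literal["ramp_only", "from_preload_end"]


class SegmentationError(ValueError):
    """Raised when a trace cannot be segmented into the protocol's phases."""


def _cycle_minima(displacement: np.ndarray, lo: int, hi: int, protocol: LoadingProtocol
                  ) -> np.ndarray:
    """Indices of displacement minima (cycle starts) within [lo, hi)."""
    block = displacement[lo:hi]
    if block.size < 3:
        return np.array([], dtype=int)
    min_dist = max(1, int(0.7 * protocol.sampling_rate / protocol.cycle_frequency))
    minima, _ = find_peaks(-block, distance=min_dist)
    return minima + lo


def segment_phases(trace: LoadTrace, protocol: LoadingProtocol) -> PhaseSegmentation:
    """Locate the preload/cyclic/ramp boundaries of a trace.

    If the trace carries phase labels, block boundaries are read from them
    verbatim; otherwise they are inferred from the protocol timing
    (preload duration, cycle count / frequency) relative to the first
    timestamp.  Within the cyclic block, individual cycles are delimited by
    successive displacement minima.
    """
    n = len(trace)
    if trace.phase is not None:
        codes = np.asarray(trace.phase)
        preload_end = int(np.searchsorted(codes, PHASE_PRELOAD, side="right"))
        ramp_start = int(np.searchsorted(codes, PHASE_CYCLIC, side="right"))
        inferred = False
    else:
        t0 = trace.time[0]
        preload_end = int(np.searchsorted(trace.time, t0 + protocol.preload_duration))
        if preload_end >= n:
            raise SegmentationError(
                "trace is shorter than the preload phase "
                f"({trace.time[-1] - t0:.2f} s < {protocol.preload_duration} s)"
            )
        cyc_duration = protocol.cycle_count / protocol.cycle_frequency
        ramp_start = int(
            np.searchsorted(trace.time, t0 + protocol.preload_duration + cyc_duration)
        )
        ramp_start = min(ramp_start, n)
        inferred = True

    if preload_end == ramp_start:
        return PhaseSegmentation(preload_end, [], ramp_start)

    minima = _cycle_minima(trace.displacement, preload_end, ramp_start, protocol)
    # The cyclic block starts and ends at displacement minima that sit on the
    # block edges, where find_peaks cannot fire; add them explicitly.
    bounds = [preload_end] + [int(m) for m in minima if m > preload_end] + [ramp_start]
    bounds = sorted(set(bounds))
    cycles = list(zip(bounds[:-1], bounds[1:]))
    if inferred and protocol.cycle_count and len(cycles) < protocol.cycle_count:
        raise SegmentationError(
            f"detected {len(cycles)} cycles but the protocol specifies "
            f"{protocol.cycle_count}"
        )
    return PhaseSegmentation(preload_end, cycles, ramp_start)


def ultimate_point(trace: LoadTrace) -> tuple[float, float, int]:
    """(force, displacement, index) at the global force maximum.

    Ties are broken by the earliest index.
    """
    if len(trace) == 0:
        raise ValueError("empty trace")
    idx = int(np.argmax(trace.force))
    return float(trace.force[idx]), float(trace.displacement[idx]), idx


def ultimate_stress(force: float, csa: float) -> float:
    """Engineering stress [MPa] = force [N] / cross-sectional area [mm^2]."""
    if csa <= 0:
        raise ValueError(f"csa must be positive, got {csa!r}")
    return force / csa


def strain_at_failure(displacement_at_ultimate: float, gauge_length: float) -> float:
    """Clamp-to-clamp strain at the ultimate point."""
    if gauge_length <= 0:
        raise ValueError(f"gauge_length must be positive, got {gauge_length!r}")
    return displacement_at_ultimate / gauge_length


def _analysis_range(
    trace: LoadTrace,
    seg: PhaseSegmentation,
    range_mode: RangeMode,
    ultimate_index: Optional[int] = None,
) -> tuple[int, int]:
    """Inclusive (start, stop) sample range for stiffness/work analysis."""
    if ultimate_index is None:
        _, _, ultimate_index = ultimate_point(trace)
    start = seg.ramp_start if range_mode == "ramp_only" else seg.preload_end
    if range_mode not in ("ramp_only", "from_preload_end"):
        raise ValueError(f"unknown range_mode {range_mode!r}")
    if start > ultimate_index:
        raise ValueError("analysis range is empty (ultimate point precedes range start)")
    return start, ultimate_index


def default_window(range_length: int) -> int:
    """Sliding-window width: at least 5 samples, else 10% of the range."""
    return max(5, int(round(0.1 * range_length)))


def stiffness_max_gradient(
    trace: LoadTrace,
    seg: PhaseSegmentation,
    window: Optional[int] = None,
    range_mode: RangeMode = "ramp_only",
    ultimate_index: Optional[int] = None,
) -> float:
    """Maximum slope b over sliding-window OLS fits ``force = a + b*displacement``.

    A window of fixed width slides with stride 1 over the analysis range; in
    each position an ordinary-least-squares line is fitted and the maximum
    slope across windows is returned.  Windows with (numerically) zero
    displacement variance are skipped; if every window is degenerate an error
    is raised.
    """
    a, b = _analysis_range(trace, seg, range_mode, ultimate_index)
    x = trace.displacement[a:b + 1].astype(float)
    y = trace.force[a:b + 1].astype(float)
    n = x.size
    if window is None:
        window = default_window(n)
    w = int(window)
    if w < 3:
        raise ValueError(f"window must span at least 3 samples, got {w}")
    if n < w:
        raise ValueError(f"analysis range ({n} samples) is shorter than the window ({w})")

    # Centering guards the cumulative-sum formulation against cancellation.
    x = x - x.mean()
    y = y - y.mean()
    cx = np.concatenate(([0.0], np.cumsum(x)))
    cy = np.concatenate(([0.0], np.cumsum(y)))
    cxx = np.concatenate(([0.0], np.cumsum(x * x)))
    cxy = np.concatenate(([0.0], np.cumsum(x * y)))
    sx = cx[w:] - cx[:-w]
    sy = cy[w:] - cy[:-w]
    sxx = cxx[w:] - cxx[:-w]
    sxy = cxy[w:] - cxy[:-w]
    denom = w * sxx - sx * sx
    num = w * sxy - sx * sy
    scale = np.maximum(sxx, 1e-300)
    valid = denom > 1e-12 * w * scale
    if not np.any(valid):
        raise ValueError("zero displacement variance within every window")
    return float(np.max(num[valid] / denom[valid]))


def elastic_modulus(stiffness: float, csa: float, gauge_length: float) -> float:
    """Geometry-normalized stiffness [MPa] = k * L / A."""
    if csa <= 0 or gauge_length <= 0:
        raise ValueError("csa and gauge_length must be positive")
    return stiffness * gauge_length / csa


def work_to_failure(
    trace: LoadTrace,
    seg: PhaseSegmentation,
    range_mode: RangeMode = "ramp_only",
    ultimate_index: Optional[int] = None,
) -> float:
    """Trapezoidal integral of force over displacement up to the ultimate
    point, in mJ (1 N*mm = 1 mJ).  Displacement is used as recorded."""
    a, b = _analysis_range(trace, seg, range_mode, ultimate_index)
    if b == a:
        return 0.0
    return float(
        np.trapezoid(trace.force[a:b + 1], trace.displacement[a:b + 1])
    )


def relative_stress_relaxation(trace: LoadTrace, seg: PhaseSegmentation) -> float:
    """(Fpeak_last - Fpeak_first) / Fpeak_first over the detected cycles.

    Peak force is the maximum within each cycle window; the value is negative
    when cyclic peak force relaxes.
    """
    if len(seg.cycle_boundaries) < 2:
        raise ValueError(
            f"need at least 2 detected cycles, got {len(seg.cycle_boundaries)}"
        )
    first_lo, first_hi = seg.cycle_boundaries[0]
    last_lo, last_hi = seg.cycle_boundaries[-1]
    f_first = float(np.max(trace.force[first_lo:first_hi + 1]))
    f_last = float(np.max(trace.force[last_lo:last_hi + 1]))
    if f_first <= 0:
        raise ValueError("first-cycle peak force must be positive")
    return (f_last - f_first) / f_first


def extract_all(
    trace: LoadTrace,
    specimen: Specimen,
    protocol: LoadingProtocol = LoadingProtocol(),
    window: Optional[int] = None,
    range_mode: RangeMode = "ramp_only",
) -> MechanicalProperties:
    """Extract all seven mechanical properties of one specimen.

    Ultimate stress and elastic modulus are recomputed from the same ultimate
    point and stiffness, so the unit identities
    ``ultimate_stress * csa == ultimate_force`` and
    ``elastic_modulus * csa / gauge_length == stiffness`` hold exactly.
    """
    seg = segment_phases(trace, protocol)
    uf, ud, uidx = ultimate_point(trace)
    k = stiffness_max_gradient(trace, seg, window, range_mode, ultimate_index=uidx)
    return MechanicalProperties(
        ultimate_force=uf,
        ultimate_stress=ultimate_stress(uf, specimen.csa),
        stiffness=k,
        elastic_modulus=elastic_modulus(k, specimen.csa, specimen.gauge_length),
        work_to_failure=work_to_failure(trace, seg, range_mode, ultimate_index=uidx),
        strain_at_failure=strain_at_failure(ud, specimen.gauge_length),
        relative_stress_relaxation=relative_stress_relaxation(trace, seg),
        csa=specimen.csa,
    )
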