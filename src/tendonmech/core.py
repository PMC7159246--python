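"""Shared domain types for the tendon augmentation analysis pipeline.

The experiment this package models is an ex vivo tensile study on bovine
superficial digital flexor tendons: specimens are preloaded, cycled between
0 and 5% strain, then ramp-loaded to failure while force, displacement and
time are logged.  Four experimental arms are compared: healthy and
enzymatically degenerated tendons, each with and without an intratendinous
genipin (a collagen crosslinker) injection.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

#: Closed set of group labels: healthy control, healthy genipin-treated,
#: degenerated control, degenerated genipin-treated.
GROUPS: tuple[str, ...] = ("C", "GP", "Col", "ColGP")

#: Integer phase codes used in trace arrays (compact alternative to strings).
PHASE_PRELOAD, PHASE_CYCLIC, PHASE_RAMP = 0, 1, 2
PHASE_NAMES = {PHASE_PRELOAD: "preload", PHASE_CYCLIC: "cyclic", PHASE_RAMP: "ramp"}
PHASE_CODES = {v: k for k, v in PHASE_NAMES.items()}


@dataclass(frozen=True)
class LoadingProtocol:
    """Parameters of the tensile-testing protocol.

    Defaults reproduce the study protocol: 0.1 MPa preload held for one
    minute, 500 cycles of 0-5% strain at ~1 Hz, ramp to failure at 15%
    strain/s, 100 Hz sampling, 45 mm clamp-to-clamp gauge length.
    """

    preload_stress: float = 0.1       # MPa
    preload_duration: float = 60.0    # s
    cycle_count: int = 500
    cycle_strain_amplitude: float = 0.05   # dimensionless strain
    cycle_frequency: float = 1.0      # Hz
    ramp_strain_rate: float = 0.15    # 1/s
    sampling_rate: float = 100.0      # Hz
    gauge_length: float = 45.0        # mm

    def __post_init__(self) -> None:
        positive = {
            "preload_stress": self.preload_stress,
            "preload_duration": self.preload_duration,
            "cycle_strain_amplitude": self.cycle_strain_amplitude,
            "cycle_frequency": self.cycle_frequency,
            "ramp_strain_rate": self.ramp_strain_rate,
            "sampling_rate": self.sampling_rate,
            "gauge_length": self.gauge_length,
        }
        for name, value in positive.items():
            if not np.isfinite(value) or value <= 0:
                raise ValueError(f"{name} must be strictly positive, got {value!r}")
        if self.cycle_count < 0:
            raise ValueError(f"cycle_count must be >= 0, got {self.cycle_count}")
        if self.sampling_rate < 2 * self.cycle_frequency:
            raise ValueError(
                "sampling_rate must be at least twice cycle_frequency "
                f"({self.sampling_rate} < 2 * {self.cycle_frequency})"
            )


@dataclass
class LoadTrace:
    """One synchronized force-displacement-time record of a tensile test.

    ``phase`` is optional; when present it holds integer codes
    (:data:`PHASE_PRELOAD`, :data:`PHASE_CYCLIC`, :data:`PHASE_RAMP`) in
    contiguous preload -> cyclic -> ramp blocks.
    """

    time: np.ndarray          # s, strictly increasing
    force: np.ndarray         # N
    displacement: np.ndarray  # mm (clamp to clamp)
    phase: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.displacement = np.asarray(self.displacement, dtype=float)
        n = self.time.size
        if n < 2:
            raise ValueError("trace must contain at least 2 samples")
        if self.force.size != n or self.displacement.size != n:
            raise ValueError("time, force and displacement must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.phase is not None:
            self.phase = np.asarray(self.phase)
            if self.phase.size != n:
                raise ValueError("phase must have the same length as time")
            codes = self.phase
            if np.any(np.diff(codes) < 0):
                raise ValueError("phase blocks must appear in preload->cyclic->ramp order")

    def __len__(self) -> int:
        return self.time.size


@dataclass(frozen=True)
class Specimen:
    """Identity and geometry of one tendon half."""

    id: str
    group: str
    csa: float                  # mm^2, mid-substance cross-sectional area
    gauge_length: float = 45.0  # mm

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}; expected one of {GROUPS}")
        if not np.isfinite(self.csa) or self.csa <= 0:
            raise ValueError(f"csa must be positive, got {self.csa!r}")
        if self.gauge_length <= 0:
            raise ValueError("gauge_length must be positive")


@dataclass
class PhaseSegmentation:
    """Sample-index boundaries of the three loading phases.

    ``cycle_boundaries`` holds (start, end) index pairs, one per detected
    cycle, ordered and contained in ``[preload_end, ramp_start]``.
    """

    preload_end: int
    cycle_boundaries: list[tuple[int, int]] = field(default_factory=list)
    ramp_start: int = 0

    def __post_init__(self) -> None:
        if self.preload_end > self.ramp_start:
            raise ValueError("preload_end must not exceed ramp_start")
        prev_end = self.preload_end
        for start, end in self.cycle_boundaries:
            if not (self.preload_end <= start < end <= self.ramp_start):
                raise ValueError("cycle boundaries must lie within the cyclic block")
            if start < prev_end:
                raise ValueError("cycle boundaries must be ordered and non-overlapping")
            prev_end = end


@dataclass
class MechanicalProperties:
    """The seven per-specimen scalars extracted from a ramp-to-failure test."""

    ultimate_force: float               # N
    ultimate_stress: float              # MPa
    stiffness: float                    # N/mm (max sliding-window OLS gradient)
    elastic_modulus: float              # MPa
    work_to_failure: float              # mJ (= N*mm)
    strain_at_failure: float            # dimensionless
    relative_stress_relaxation: float   # dimensionless, <= 0 when force relaxes
    csa: float                          # mm^2

    #: CSV column order used by the external interfaces.
    FIELDS = (
        "ultimate_force_N",
        "ultimate_stress_MPa",
        "stiffness_N_mm",
        "elastic_modulus_MPa",
        "work_to_failure_mJ",
        "strain_at_failure",
        "relative_stress_relaxation",
        "csa_mm2",
    )

    def as_row(self) -> dict[str, float]:
        return {
            "ultimate_force_N": self.ultimate_force,
            "ultimate_stress_MPa": self.ultimate_stress,
            "stiffness_N_mm": self.stiffness,
            "elastic_modulus_MPa": self.elastic_modulus,
            "work_to_failure_mJ": self.work_to_failure,
            "strain_at_failure": self.strain_at_failure,
            "relative_stress_relaxation": self.relative_stress_relaxation,
            "csa_mm2": self.csa,
        }


def as_grouped(values: Sequence[float] | np.ndarray) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.size and not np.all(np.isfinite(arr)):
        raise ValueError("values must all be finite")
    return arr
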