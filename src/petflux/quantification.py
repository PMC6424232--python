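"""Static-scan quantification: calibration, SUV, ROI statistics, and the
single-time-point net-clearance estimate.

The static estimator inverts the graphical uptake relation at one time
point: with a known effective distribution volume ``V0``, the tissue
concentration at scan time ``T`` and the plasma curve integral give

    Ki = (C_bone(T) - V0 * Cp(T)) / int_0^T Cp dt
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import ndimage

from petflux.errors import CalibrationError, DomainError, EmptyRoiError

__all__ = [
    "WellCounterCalibration",
    "RoiMeasurement",
    "LesionMeasurement",
    "calibrate",
    "decay_correct",
    "segment_lesion",
    "suv",
    "static_ki",
    "FLUORINE18_HALF_LIFE_MIN",
]

logger = logging.getLogger(__name__)

#: physical half-life of 18F, minutes
FLUORINE18_HALF_LIFE_MIN = 109.77

#: 26-connectivity structuring element for 3-D component labelling
_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class WellCounterCalibration:
    """Scanner/well-counter cross-calibration.

    ``conversion_factor`` is counts·s⁻¹ per kBq/mL.  When replicate phantom
    counts and the phantom's true concentration are supplied, the factor is
    their mean divided by the truth.
    """

    conversion_factor: float
    phantom_truth: float | None = None
    replicate_counts: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if not self.conversion_factor > 0:
            raise CalibrationError(
                f"conversion factor must be > 0, got {self.conversion_factor}"
            )

    @classmethod
    def from_replicates(
        cls, replicate_counts: Sequence[float], phantom_truth: float
    ) -> "WellCounterCalibration":
        if phantom_truth <= 0:
            raise CalibrationError("phantom truth concentration must be > 0")
        counts = tuple(float(c) for c in replicate_counts)
        if not counts:
            raise CalibrationError("at least one replicate count is required")
        return cls(
            conversion_factor=float(np.mean(counts)) / phantom_truth,
            phantom_truth=phantom_truth,
            replicate_counts=counts,
        )


@dataclass(frozen=True)
class RoiMeasurement:
    """Voxel statistics of a segmented region of interest."""

    voxel_values: np.ndarray
    voxel_volume: float  # mL per voxel
    indices: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None

    def __post_init__(self) -> None:
        values = np.asarray(self.voxel_values, dtype=float).ravel()
        object.__setattr__(self, "voxel_values", values)
        if values.size == 0:
            raise EmptyRoiError("ROI contains no voxels")
        if np.any(values < 0):
            raise ValueError("voxel values must be >= 0")
        if self.voxel_volume <= 0:
            raise ValueError("voxel volume must be > 0")

    @property
    def max(self) -> float:
        return float(np.max(self.voxel_values))

    @property
    def mean(self) -> float:
        return float(np.mean(self.voxel_values))

    @property
    def volume(self) -> float:
        """ROI volume in cm^3 (== mL)."""
        return float(self.voxel_values.size * self.voxel_volume)


@dataclass
class LesionMeasurement:
    """One lesion's static-scan quantities at one visit."""

    C_bone_T: float  # kBq/mL at scan time T
    SUV_max: float  # g/mL
    SUV_mean: float  # g/mL
    volume: float  # cm^3
    K_i: float = float("nan")  # mL min^-1 mL^-1
    T: float = 60.0  # minutes post-injection

    def __post_init__(self) -> None:
        if self.SUV_max < self.SUV_mean - 1e-12:
            raise ValueError("SUV_max must be >= SUV_mean")


def calibrate(counts_per_s: float, cal: WellCounterCalibration) -> float:
    """Convert a well-counter count rate to activity concentration (kBq/mL)."""
    if counts_per_s < 0:
        raise DomainError("count rate must be >= 0")
    return counts_per_s / cal.conversion_factor


def decay_correct(
    value: float, elapsed: float, half_life: float = FLUORINE18_HALF_LIFE_MIN
) -> float:
    """Correct an activity concentration back to a reference time.

    Multiplies by ``2**(elapsed / half_life)`` — the measured value decayed
    for ``elapsed`` minutes since the reference time.
    """
    if half_life <= 0:
        raise DomainError("half-life must be > 0")
    return value * 2.0 ** (elapsed / half_life)


def _hill_climb(image: np.ndarray, seed: tuple[int, int, int]) -> tuple[int, int, int]:
    """Ascend from seed to a local maximum over the 26-neighbourhood."""
    shape = image.shape
    current = tuple(int(i) for i in seed)
    while True:
        lo = [max(c - 1, 0) for c in current]
        hi = [min(c + 2, s) for c, s in zip(current, shape)]
        window = image[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]]
        local = np.unravel_index(int(np.argmax(window)), window.shape)
        candidate = tuple(l + o for l, o in zip(lo, local))
        if image[candidate] <= image[current]:
            return current
        current = candidate


def segment_lesion(
    image: np.ndarray,
    seed_voxel: tuple[int, int, int],
    voxel_volume: float = 1.0,
    threshold_fraction: float = 0.40,
) -> RoiMeasurement:
    """Threshold-based lesion segmentation around a seed voxel.

    Hill-climbs from the seed to the local maximum, keeps voxels at or above
    ``threshold_fraction`` of that maximum, and returns the 26-connected
    component containing the peak.

    Raises
    ------
    EmptyRoiError
        If the seed sits on zero background.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 3:
        raise ValueError("image must be a 3-D array")
    seed = tuple(int(i) for i in seed_voxel)
    if image[seed] <= 0:
        raise EmptyRoiError(f"seed voxel {seed} lies on zero background")
    peak = _hill_climb(image, seed)
    peak_value = image[peak]
    mask = image >= threshold_fraction * peak_value
    labels, _ = ndimage.label(mask, structure=_STRUCT_26)
    component = labels == labels[peak]
    indices = np.nonzero(component)
    return RoiMeasurement(
        voxel_values=image[component], voxel_volume=voxel_volume, indices=indices
    )


def suv(concentration: float, injected_activity: float, body_weight: float) -> float:
    """Standardized uptake value normalized to body weight (g/mL).

    ``concentration`` in kBq/mL, ``injected_activity`` in MBq, ``body_weight``
    in kg; tissue density is taken as 1 g/mL.
    """
    if injected_activity <= 0:
        raise DomainError("injected activity must be > 0")
    if body_weight <= 0:
        raise DomainError("body weight must be > 0")
    return concentration * (body_weight * 1000.0) / (injected_activity * 1000.0)


def static_ki(
    C_bone_T: float,
    cp_T: float,
    integral_cp: float,
    V0: float,
    clip_negative: bool = True,
) -> float:
    """Single-time-point net clearance estimate (mL min^-1 mL^-1).

    Parameters
    ----------
    C_bone_T : float
        Tissue activity concentration at scan time, kBq/mL.
    cp_T : float
        Plasma concentration at scan time, kBq/mL.
    integral_cp : float
        Integral of the plasma curve from 0 to scan time, kBq·min/mL.
    V0 : float
        Effective distribution volume (graphical intercept), unitless.
    clip_negative : bool
        When True (default), negative estimates are clipped to 0 with a
        logged warning.
    """
    if integral_cp <= 0:
        raise DomainError("integral of the plasma curve must be > 0")
    if V0 < 0:
        raise DomainError("V0 must be >= 0")
    ki = (C_bone_T - V0 * cp_T) / integral_cp
    if ki < 0 and clip_negative:
        logger.warning("negative Ki estimate %.4g clipped to 0", ki)
        return 0.0
    return ki
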