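"""Forward two-tissue compartment model for bone-seeking tracers.

The model has a reversible free compartment exchanging with plasma
(``K1``/``k2``) and a bound compartment fed by ``k3`` with optional efflux
``k4``::

    plasma --K1--> free --k3--> bound
           <--k2--      <--k4--

The macro parameter ``K1*k3/(k2+k3)`` is the net plasma clearance to the
bound compartment.  :func:`simulate_tissue_curve` solves the linear system
by convolving the plasma input with the analytic bi-exponential impulse
response; the convolution is exact for piecewise-linear inputs, which makes
it directly comparable to a brute-force ODE integrator.
:func:`patlak_fit` provides the graphical slope/intercept estimate used as
the dynamic reference for the static estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import signal

from petflux.errors import (
    CoverageError,
    DegenerateModelError,
    DivisionError,
    InsufficientDataError,
)

__all__ = [
    "RateConstants",
    "TimeActivityCurve",
    "macro_flux",
    "simulate_tissue_curve",
    "patlak_fit",
]

#: default internal grid spacing (minutes) for forward simulation
DEFAULT_GRID_STEP = 0.1


@dataclass(frozen=True)
class RateConstants:
    """Kinetic rate constants of the two-tissue fluoride model.

    Parameters
    ----------
    K1 : float
        Plasma-to-tissue clearance, mL min^-1 mL^-1.
    k2 : float
        Tissue-to-plasma rate, min^-1.
    k3 : float
        Binding (mineralization) rate, min^-1.
    k4 : float
        Efflux from the bound compartment, min^-1 (default 0).
    """

    K1: float
    k2: float
    k3: float
    k4: float = 0.0

    def __post_init__(self) -> None:
        for name in ("K1", "k2", "k3", "k4"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class TimeActivityCurve:
    """Activity concentration (kBq/mL) sampled at strictly increasing times (min)."""

    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if times.shape != values.shape:
            raise ValueError("times and values must have equal length")
        if times.size == 0:
            raise ValueError("curve must contain at least one sample")
        if times[0] < 0:
            raise ValueError("first time must be >= 0")
        if times.size > 1 and not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if np.any(values < 0):
            raise ValueError("activity concentrations must be >= 0")

    def __len__(self) -> int:
        return int(self.times.size)

    def interp(self, t: np.ndarray | float) -> np.ndarray | float:
        """Linear interpolation at ``t`` (no extrapolation)."""
        t_arr = np.asarray(t, dtype=float)
        if np.any(t_arr < self.times[0]) or np.any(t_arr > self.times[-1]):
            raise CoverageError(
                f"requested times outside [{self.times[0]}, {self.times[-1]}] min"
            )
        out = np.interp(t_arr, self.times, self.values)
        return float(out) if np.isscalar(t) else out

    def to_csv(self, path: str | Path) -> None:
        """Write the curve as two-column CSV with a one-line header."""
        arr = np.column_stack([self.times, self.values])
        np.savetxt(path, arr, delimiter=",", header="time_min,kBq_per_mL", comments="")

    @classmethod
    def from_csv(cls, path: str | Path) -> "TimeActivityCurve":
        arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(times=arr[:, 0], values=arr[:, 1])


def macro_flux(rc: RateConstants) -> float:
    """Net plasma clearance to the bound compartment, ``K1*k3/(k2+k3)``.

    Raises
    ------
    DegenerateModelError
        If ``k2 + k3 == 0`` (the partition of extracted tracer is undefined).
    """
    denom = rc.k2 + rc.k3
    if denom <= 0:
        raise DegenerateModelError("k2 + k3 must be > 0 for the macro flux")
    return rc.K1 * rc.k3 / denom


def _impulse_response_terms(rc: RateConstants) -> list[tuple[float, float]]:
    """Decompose the tissue impulse response as sum of ``B * exp(-alpha t)`` terms.

    Returns ``[(B1, alpha1), (B2, alpha2)]``; one term may have B == 0.
    """
    s = rc.k2 + rc.k3 + rc.k4
    if s == 0.0:
        # no efflux anywhere: tissue integrates K1 * Cp
        return [(rc.K1, 0.0)]
    disc = s * s - 4.0 * rc.k2 * rc.k4
    d = math.sqrt(max(disc, 0.0))
    if d < 1e-9 * s:
        # repeated eigenvalue (k3 == 0, k2 == k4); nudge apart — the induced
        # relative error is ~1e-9, far below the simulator's tolerance
        d = 1e-9 * s
    a1 = 0.5 * (s - d)
    a2 = 0.5 * (s + d)
    b1 = rc.K1 * (rc.k3 + rc.k4 - a1) / (a2 - a1)
    b2 = rc.K1 * (a2 - rc.k3 - rc.k4) / (a2 - a1)
    return [(b1, a1), (b2, a2)]


def _convolve_exp(values: np.ndarray, h: float, alpha: float) -> np.ndarray:
    """Convolve ``exp(-alpha t)`` with a piecewise-linear signal on a uniform grid.

    Exact for the linearly interpolated signal: each step uses the closed-form
    integral of the kernel against the linear segment.
    """
    n = values.size
    out = np.zeros(n)
    if alpha == 0.0:
        # pure accumulation; trapezoid is exact for linear segments
        out[1:] = np.cumsum(0.5 * h * (values[1:] + values[:-1]))
        return out
    ah = alpha * h
    decay = math.exp(-ah)
    # w0 multiplies the segment's right endpoint, w1 the slope term
    w0 = -math.expm1(-ah) / alpha
    if ah < 1e-4:
        w1 = h * h * (0.5 - ah / 3.0 + ah * ah / 8.0)
    else:
        w1 = (-math.expm1(-ah) - ah * decay) / (alpha * alpha)
    slopes = (values[1:] - values[:-1]) / h
    # the step recursion acc <- acc*decay + u is a first-order IIR filter
    u = values[1:] * w0 - slopes * w1
    out[1:] = signal.lfilter([1.0], [1.0, -decay], u)
    return out


def simulate_tissue_curve(
    rc: RateConstants,
    plasma: TimeActivityCurve,
    sample_times: Sequence[float],
    blood_volume_fraction: float = 0.0,
    grid_step: float = DEFAULT_GRID_STEP,
) -> TimeActivityCurve:
    """Forward-simulate the total tissue curve driven by a plasma input.

    Total tissue concentration is free + bound compartment plus
    ``blood_volume_fraction`` times the plasma concentration, evaluated at
    ``sample_times``.

    Raises
    ------
    CoverageError
        If the plasma curve does not cover ``[0, max(sample_times)]``.
    """
    if not 0.0 <= blood_volume_fraction < 1.0:
        raise ValueError("blood_volume_fraction must be in [0, 1)")
    t_req = np.asarray(sample_times, dtype=float)
    if t_req.size == 0:
        raise ValueError("sample_times must be non-empty")
    t_max = float(np.max(t_req))
    if plasma.times[0] > 0.0 or plasma.times[-1] < t_max:
        raise CoverageError(
            f"plasma curve [{plasma.times[0]}, {plasma.times[-1]}] does not cover "
            f"[0, {t_max}]"
        )
    n_steps = max(int(math.ceil(t_max / grid_step)), 1)
    grid = np.linspace(0.0, t_max, n_steps + 1)
    cp = np.interp(grid, plasma.times, plasma.values)
    h = grid[1] - grid[0] if grid.size > 1 else grid_step
    tissue = np.zeros_like(grid)
    for b, alpha in _impulse_response_terms(rc):
        if b != 0.0:
            tissue += b * _convolve_exp(cp, h, alpha)
    values = np.interp(t_req, grid, tissue)
    if blood_volume_fraction > 0.0:
        values = values + blood_volume_fraction * np.interp(t_req, grid, cp)
    values = np.maximum(values, 0.0)
    order = np.argsort(t_req)
    return TimeActivityCurve(times=t_req[order], values=values[order])


def patlak_fit(
    tissue: TimeActivityCurve,
    plasma: TimeActivityCurve,
    t_star: float = 10.0,
) -> tuple[float, float]:
    """Graphical slope/intercept estimate for irreversible uptake.

    Ordinary least squares through the transformed points
    ``x = int_0^t Cp ds / Cp(t)`` and ``y = C_tissue(t) / Cp(t)`` restricted to
    ``t >= t_star``.  Returns ``(slope, intercept)`` — the net clearance
    estimate and the effective distribution volume.

    Raises
    ------
    ValueError
        If the two curves are not sampled on a common grid.
    InsufficientDataError
        If fewer than 3 points satisfy ``t >= t_star``.
    DivisionError
        If the plasma concentration is zero at any used point.
    """
    if len(tissue) != len(plasma) or not np.allclose(
        tissue.times, plasma.times, rtol=0.0, atol=1e-9
    ):
        raise ValueError("tissue and plasma must share a common time grid")
    t = plasma.times
    cp = plasma.values
    ct = tissue.values
    cumint = np.concatenate([[0.0], np.cumsum(0.5 * np.diff(t) * (cp[1:] + cp[:-1]))])
    mask = t >= t_star
    if int(np.count_nonzero(mask)) < 3:
        raise InsufficientDataError("need at least 3 points with t >= t_star")
    if np.any(cp[mask] == 0.0):
        raise DivisionError("plasma concentration is zero at a used point")
    x = cumint[mask] / cp[mask]
    y = ct[mask] / cp[mask]
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(intercept)
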