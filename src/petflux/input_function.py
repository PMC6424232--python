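"""Semi-population plasma input-function reconstruction.

A patient-specific input function is assembled from two late venous plasma
samples: a terminal exponential is fitted through them and a population
residual curve — the population input function minus its own fitted terminal
exponential — is added back to restore the early bolus/distribution phase
that late venous samples cannot see.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from petflux.errors import CoverageError, DomainError
from petflux.kinetics import TimeActivityCurve

__all__ = [
    "VenousSample",
    "TerminalExponential",
    "PopulationInputFunction",
    "fit_terminal_exponential",
    "reconstruct_input",
    "integrate_plasma",
    "DEFAULT_POPULATION_TERMS",
]

logger = logging.getLogger(__name__)

#: Documented fixture for the population input function: tri-exponential
#: (amplitude kBq/mL, rate 1/min) pairs.  The true population acquisition is
#: not public, so these defaults only need the right qualitative shape — a
#: fast distribution phase that has decayed away well before the 55-min
#: venous window, leaving an essentially single-exponential tail.
DEFAULT_POPULATION_TERMS: tuple[tuple[float, float], ...] = (
    (300.0, 3.0),
    (30.0, 0.25),
    (10.0, 0.01),
)

DEFAULT_RESIDUAL_WINDOW = (55.0, 85.0)


@dataclass(frozen=True)
class VenousSample:
    """One venous plasma measurement: minutes post-injection and kBq/mL."""

    time: float
    concentration: float

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise DomainError(f"sample time must be > 0, got {self.time}")
        if not self.concentration > 0:
            raise DomainError(
                f"plasma concentration must be > 0, got {self.concentration}"
            )


@dataclass(frozen=True)
class TerminalExponential:
    """Single exponential ``A * exp(-rate * t)`` describing the late plasma tail."""

    amplitude: float
    rate: float

    def __post_init__(self) -> None:
        if not self.amplitude > 0:
            raise DomainError(f"amplitude must be > 0, got {self.amplitude}")

    def __call__(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.amplitude * np.exp(-self.rate * np.asarray(t, dtype=float))


@dataclass(frozen=True)
class PopulationInputFunction:
    """Population plasma curve as a sum of exponentials plus its residual split.

    ``residual(t) = curve(t) - terminal(t)`` where ``terminal`` is the
    exponential fitted through the curve's own values at the two ends of
    ``residual_window``.  By construction the residual vanishes at the window
    endpoints and stays negligible beyond them whenever the tail is dominated
    by a single exponential term.
    """

    exponential_terms: tuple[tuple[float, float], ...] = DEFAULT_POPULATION_TERMS
    residual_window: tuple[float, float] = DEFAULT_RESIDUAL_WINDOW
    grid_step: float = 0.1

    def __post_init__(self) -> None:
        terms = tuple((float(a), float(r)) for a, r in self.exponential_terms)
        object.__setattr__(self, "exponential_terms", terms)
        if not terms:
            raise DomainError("at least one exponential term is required")
        if any(a < 0 for a, _ in terms):
            raise DomainError("amplitudes must be non-negative")
        lo, hi = self.residual_window
        if not 0 < lo < hi:
            raise DomainError("residual window must satisfy 0 < lo < hi")

    def curve(self, t: np.ndarray | float) -> np.ndarray | float:
        t_arr = np.asarray(t, dtype=float)
        out = np.zeros_like(t_arr)
        for a, r in self.exponential_terms:
            out = out + a * np.exp(-r * t_arr)
        return float(out) if np.isscalar(t) else out

    @property
    def terminal(self) -> TerminalExponential:
        lo, hi = self.residual_window
        return fit_terminal_exponential(
            VenousSample(lo, float(self.curve(lo))),
            VenousSample(hi, float(self.curve(hi))),
        )

    def residual(self, t: np.ndarray | float) -> np.ndarray | float:
        return self.curve(t) - self.terminal(t)

    def sample(self, grid: np.ndarray) -> TimeActivityCurve:
        grid = np.asarray(grid, dtype=float)
        return TimeActivityCurve(times=grid, values=np.maximum(self.curve(grid), 0.0))

    def to_json(self, path: str | Path) -> None:
        payload = {
            "exponential_terms": [list(t) for t in self.exponential_terms],
            "residual_window_min": list(self.residual_window),
            "grid_step_min": self.grid_step,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "PopulationInputFunction":
        payload = json.loads(Path(path).read_text())
        return cls(
            exponential_terms=tuple(
                (float(a), float(r)) for a, r in payload["exponential_terms"]
            ),
            residual_window=tuple(payload.get("residual_window_min", DEFAULT_RESIDUAL_WINDOW)),
            grid_step=float(payload.get("grid_step_min", 0.1)),
        )


def fit_terminal_exponential(
    s1: VenousSample,
    s2: VenousSample,
    *extra: VenousSample,
) -> TerminalExponential:
    """Fit ``A * exp(-rate * t)`` through venous samples.

    With exactly two samples the fit is the closed form
    ``rate = ln(c1/c2) / (t2 - t1)``, ``A = c1 * exp(rate * t1)`` and passes
    exactly through both points.  With three or more samples a log-linear
    least-squares fit is used instead.
    """
    samples = (s1, s2) + tuple(extra)
    times = np.array([s.time for s in samples])
    concs = np.array([s.concentration for s in samples])
    if len(samples) == 2:
        if s2.time <= s1.time:
            raise DomainError("samples must have strictly increasing times")
        rate = math.log(s1.concentration / s2.concentration) / (s2.time - s1.time)
        amplitude = s1.concentration * math.exp(rate * s1.time)
        return TerminalExponential(amplitude=amplitude, rate=rate)
    if np.unique(times).size < 2:
        raise DomainError("samples must span at least two distinct times")
    slope, intercept = np.polyfit(times, np.log(concs), 1)
    return TerminalExponential(amplitude=float(np.exp(intercept)), rate=float(-slope))


def reconstruct_input(
    te: TerminalExponential,
    pop: PopulationInputFunction,
    grid: Sequence[float] | np.ndarray,
    residual_scale: float | str = 1.0,
) -> TimeActivityCurve:
    """Assemble ``Cp(t) = te(t) + s * residual(t)`` on ``grid``.

    ``residual_scale`` is either a number (default 1, the unscaled addition)
    or the string ``"terminal-ratio"``, which scales the residual by the
    ratio of patient to population terminal value at the start of the
    residual window.  Negative sums are clipped to zero with a warning.

    Raises
    ------
    CoverageError
        If the grid extends beyond the residual's support (taken as
        ``[0, residual_window[1] + 5]`` minutes).
    """
    grid = np.asarray(grid, dtype=float)
    support_end = pop.residual_window[1] + 5.0
    if grid.size == 0:
        raise ValueError("grid must be non-empty")
    if grid[0] < 0 or grid[-1] > support_end:
        raise CoverageError(
            f"grid must lie within [0, {support_end}] min, got "
            f"[{grid[0]}, {grid[-1]}]"
        )
    if residual_scale == "terminal-ratio":
        t_ref = pop.residual_window[0]
        s = float(te(t_ref)) / float(pop.terminal(t_ref))
    else:
        s = float(residual_scale)
    values = np.asarray(te(grid)) + s * np.asarray(pop.residual(grid))
    if np.any(values < 0):
        logger.warning(
            "reconstructed input function negative at %d grid points; clipping to 0",
            int(np.count_nonzero(values < 0)),
        )
        values = np.maximum(values, 0.0)
    return TimeActivityCurve(times=grid, values=values)


def integrate_plasma(cp: TimeActivityCurve, t_end: float) -> float:
    """Trapezoidal integral of the plasma curve over ``[0, t_end]`` (kBq·min/mL)."""
    if t_end < 0:
        raise DomainError("t_end must be >= 0")
    if cp.times[0] > 0 or cp.times[-1] < t_end:
        raise CoverageError(
            f"curve [{cp.times[0]}, {cp.times[-1]}] does not cover [0, {t_end}]"
        )
    mask = cp.times <= t_end
    times = cp.times[mask]
    values = cp.values[mask]
    if times[-1] < t_end:
        times = np.append(times, t_end)
        values = np.append(values, cp.interp(t_end))
    return float(np.trapezoid(values, times))
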