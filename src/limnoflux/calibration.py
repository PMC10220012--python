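"""Radiocarbon calibration curves and single-date calibration.

A calibration curve maps calendar age (yr BP, 1950 datum) to conventional
radiocarbon age with a curve uncertainty.  Curves are plain three-column
tables (cal BP, 14C age, error), the layout used by published calibration
curve distributions (IntCal-style files load directly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from limnoflux.errors import CalibrationError, ParameterError

__all__ = ["CalibrationCurve", "calibrate_date"]


@dataclass(frozen=True)
class CalibrationCurve:
    """Gridded calendar-age -> conventional 14C age mapping.

    Parameters
    ----------
    cal_bp : array
        Calendar ages, yr BP (before 1950 CE), strictly increasing.
    c14_age : array
        Conventional radiocarbon age at each grid point, 14C yr.
    error : array
        One-sigma curve uncertainty, 14C yr, strictly positive.
    """

    cal_bp: np.ndarray
    c14_age: np.ndarray
    error: np.ndarray
    name: str = field(default="curve")

    def __post_init__(self) -> None:
        cal = np.asarray(self.cal_bp, dtype=float)
        c14 = np.asarray(self.c14_age, dtype=float)
        err = np.asarray(self.error, dtype=float)
        if cal.ndim != 1 or cal.size < 2:
            raise ParameterError("calibration curve needs >= 2 grid points")
        if not (cal.shape == c14.shape == err.shape):
            raise ParameterError("calibration curve columns differ in length")
        order = np.argsort(cal)
        cal, c14, err = cal[order], c14[order], err[order]
        if np.any(np.diff(cal) <= 0):
            raise ParameterError("calendar grid must be strictly increasing")
        if np.any(err <= 0):
            raise ParameterError("curve errors must be > 0")
        object.__setattr__(self, "cal_bp", cal)
        object.__setattr__(self, "c14_age", c14)
        object.__setattr__(self, "error", err)

    # -- evaluation ---------------------------------------------------------
    def c14_at(self, cal_bp) -> np.ndarray:
        """Interpolated conventional age mu(theta) at calendar age(s)."""
        return np.interp(np.asarray(cal_bp, dtype=float), self.cal_bp, self.c14_age)

    def error_at(self, cal_bp) -> np.ndarray:
        """Interpolated curve error sigma_curve(theta)."""
        return np.interp(np.asarray(cal_bp, dtype=float), self.cal_bp, self.error)

    def contains(self, cal_bp) -> np.ndarray:
        cal = np.asarray(cal_bp, dtype=float)
        return (cal >= self.cal_bp[0]) & (cal <= self.cal_bp[-1])

    @property
    def span(self) -> tuple[float, float]:
        return float(self.cal_bp[0]), float(self.cal_bp[-1])

    # -- constructors -------------------------------------------------------
    @classmethod
    def identity(
        cls,
        lo: float = -100.0,
        hi: float = 50000.0,
        error: float = 1e-6,
        step: float = 1.0,
    ) -> "CalibrationCurve":
        """Curve with mu(theta) = theta; useful for tests and calendar-only cores."""
        grid = np.arange(lo, hi + step, step)
        return cls(grid, grid.copy(), np.full(grid.size, error), name="identity")

    @classmethod
    def synthetic(
        cls,
        lo: float = -70.0,
        hi: float = 6000.0,
        step: float = 5.0,
        wiggle_amp: float = 25.0,
        wiggle_period: float = 400.0,
        error: float = 12.0,
        seed: int | None = None,
    ) -> "CalibrationCurve":
        """Smooth identity-like curve with sinusoidal wiggles for fixtures."""
        grid = np.arange(lo, hi + step, step)
        rng = np.random.default_rng(seed)
        phase = rng.uniform(0, 2 * np.pi) if seed is not None else 0.0
        c14 = grid + wiggle_amp * np.sin(2 * np.pi * grid / wiggle_period + phase)
        return cls(grid, c14, np.full(grid.size, error), name="synthetic")


def calibrate_date(
    age: float,
    error: float,
    curve: CalibrationCurve,
    grid: np.ndarray | None = None,
    kernel: str = "gaussian",
    t_df: float = 6.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Posterior density over calendar age for a single radiocarbon date.

    The density is proportional to a Gaussian (default) or Student-t kernel
    of ``age - mu(theta)`` with scale ``sqrt(error**2 + sigma_curve(theta)**2)``,
    normalized to integrate to one on the returned grid (trapezoid rule).

    Returns ``(cal_bp_grid, density)``.
    """
    if error <= 0:
        raise ParameterError("date error must be > 0")
    lo_c14 = float(np.min(curve.c14_age)) - 5 * error
    hi_c14 = float(np.max(curve.c14_age)) + 5 * error
    if not (lo_c14 <= age <= hi_c14):
        raise CalibrationError(
            f"14C age {age} outside curve '{curve.name}' span "
            f"[{np.min(curve.c14_age):.1f}, {np.max(curve.c14_age):.1f}] +/- 5 sigma"
        )
    if grid is None:
        grid = curve.cal_bp
    grid = np.asarray(grid, dtype=float)
    scale = np.sqrt(error**2 + curve.error_at(grid) ** 2)
    z = (age - curve.c14_at(grid)) / scale
    if kernel == "gaussian":
        log_d = stats.norm.logpdf(z) - np.log(scale)
    elif kernel == "t":
        log_d = stats.t.logpdf(z, df=t_df) - np.log(scale)
    else:
        raise ParameterError(f"unknown kernel {kernel!r}")
    log_d -= log_d.max()
    dens = np.exp(log_d)
    norm = np.trapezoid(dens, grid)
    if norm <= 0:
        raise CalibrationError("calibration density vanished on the grid")
    return grid, dens / norm
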