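"""Closed-form fluorescence recovery after Gaussian-spot photobleaching.

A focused Gaussian laser beam bleaches a fraction of the fluorophores in a
small membrane region; subsequent lateral diffusion of unbleached molecules
refills the spot.  For a species undergoing pure 2-D lateral diffusion with
coefficient ``D`` under a Gaussian beam of e^-2 radius ``w``, the fractional
fluorescence monitored with the same beam profile is the alternating series

    f(t) = sum_{n=0}^inf [(-K)^n / n!] * [1 + n (1 + 2 t / tau_D)]^(-1)

with bleach-depth parameter ``K`` and characteristic diffusion time
``tau_D = w^2 / (4 D)``.  The series is normalized so that the pre-bleach
level is 1; immediately after the bleach it equals ``(1 - e^-K)/K`` and it
recovers monotonically to 1.  A partially immobile population is handled by
mixing a mobile fraction ``R_f`` recovering per the series with an immobile
remainder frozen at the post-bleach level.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BeamProtocol",
    "MobilityParams",
    "SeriesConvergenceError",
    "bleach_depth_fraction",
    "mobile_recovery_fraction",
    "model_curve",
]

#: default truncation tolerance for the recovery series
SERIES_TOL = 1e-9
#: hard cap on the number of series terms; exceeding it raises
SERIES_MAX_TERMS = 200


class SeriesConvergenceError(RuntimeError):
    """The recovery series failed to converge within the term cap."""


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class BeamProtocol:
    """Optical geometry and bleach photophysics of one FRAP acquisition.

    Parameters
    ----------
    w : float
        Gaussian spot radius at e^-2 intensity, in micrometres.
    K : float
        Dimensionless bleach-depth parameter (> 0).  The post-bleach
        fractional fluorescence at the spot equals ``(1 - e^-K)/K``.
    t_grid : array-like
        Ordered post-bleach sample times in seconds, ``t_grid[0] >= 0``.
    n_pre : int
        Number of pre-bleach monitoring samples (>= 1).
    monitor_interval : float
        Spacing of the monitoring samples, seconds.
    """

    w: float
    K: float
    t_grid: np.ndarray
    n_pre: int = 10
    monitor_interval: float = 0.5

    def __post_init__(self) -> None:
        _require(math.isfinite(self.w) and self.w > 0, f"w must be finite and > 0, got {self.w}")
        _require(math.isfinite(self.K) and self.K > 0, f"K must be finite and > 0, got {self.K}")
        t = np.asarray(self.t_grid, dtype=float)
        _require(t.ndim == 1 and t.size >= 2, "t_grid must be a 1-D array of >= 2 times")
        _require(np.all(np.isfinite(t)), "t_grid must be finite")
        _require(t[0] >= 0, f"t_grid[0] must be >= 0, got {t[0]}")
        _require(np.all(np.diff(t) > 0), "t_grid must be strictly increasing")
        _require(self.n_pre >= 1, f"n_pre must be >= 1, got {self.n_pre}")
        _require(self.monitor_interval > 0, "monitor_interval must be > 0")
        object.__setattr__(self, "t_grid", t)

    @property
    def bleach_depth(self) -> float:
        """Fraction of fluorescence removed at the spot: ``1 - (1 - e^-K)/K``."""
        return 1.0 - bleach_depth_fraction(self.K)

    def pre_times(self) -> np.ndarray:
        """Pre-bleach sample times (negative, bleach at t = 0)."""
        return -self.monitor_interval * np.arange(self.n_pre, 0, -1, dtype=float)

    def replace(self, **kw) -> "BeamProtocol":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class MobilityParams:
    """Lateral mobility of one membrane species.

    ``D`` is the lateral diffusion coefficient in µm²/s and ``R_f`` the
    mobile fraction on the FRAP timescale (``1 - R_f`` is immobile).
    """

    D: float
    R_f: float

    def __post_init__(self) -> None:
        _require(math.isfinite(self.D) and self.D >= 0, f"D must be finite and >= 0, got {self.D}")
        _require(
            math.isfinite(self.R_f) and 0.0 <= self.R_f <= 1.0,
            f"R_f must lie in [0, 1], got {self.R_f}",
        )

    def tau_d(self, w: float) -> float:
        """Characteristic diffusion time w²/(4D), seconds."""
        _require(w > 0, f"w must be > 0, got {w}")
        if self.D == 0:
            return math.inf
        return w * w / (4.0 * self.D)


def bleach_depth_fraction(K: float) -> float:
    """Post-bleach fractional fluorescence at the spot, ``(1 - e^-K)/K``."""
    _require(math.isfinite(K) and K > 0, f"K must be finite and > 0, got {K}")
    return -math.expm1(-K) / K


def mobile_recovery_fraction(
    t,
    K: float,
    tau_d: float,
    tol: float = SERIES_TOL,
    max_terms: int = SERIES_MAX_TERMS,
):
    """Fractional recovery of a fully mobile species at time(s) ``t`` post-bleach.

    Evaluates the Gaussian-spot recovery series term by term until the next
    term's absolute value falls below ``tol`` everywhere.  Accepts a scalar
    or array ``t``; returns the same shape.

    Raises
    ------
    ValueError
        On non-finite or out-of-range arguments.
    SeriesConvergenceError
        If ``max_terms`` terms do not reach ``tol``; a partial sum is never
        returned silently.
    """
    t_arr = np.asarray(t, dtype=float)
    _require(np.all(np.isfinite(t_arr)) and np.all(t_arr >= 0), f"t must be finite and >= 0, got {t}")
    _require(math.isfinite(K) and K > 0, f"K must be finite and > 0, got {K}")
    _require(math.isfinite(tau_d) and tau_d > 0, f"tau_d must be finite and > 0, got {tau_d}")
    _require(tol > 0, f"tol must be > 0, got {tol}")

    # x = 1 + 2 t / tau_D; term_n = (-K)^n / n! / (1 + n x)
    x = 1.0 + 2.0 * t_arr / tau_d
    total = np.ones_like(x)  # n = 0 term
    coef = 1.0
    for n in range(1, max_terms + 1):
        coef *= -K / n
        term = coef / (1.0 + n * x)
        total += term
        if abs(coef) / (1.0 + n) < tol:
            # |term_m| <= |coef_m|/(1+m) for all later m at every t; the
            # factorial decay makes the bound monotone once n > K.
            if n > K:
                break
    else:
        raise SeriesConvergenceError(
            f"recovery series did not converge to tol={tol} within {max_terms} terms (K={K})"
        )
    return total if total.ndim else float(total)


def model_curve(beam: BeamProtocol, mob: MobilityParams, F_pre: float = 1.0) -> np.ndarray:
    """Noiseless post-bleach fluorescence on ``beam.t_grid``.

    ``F(t) = F_pre * [(1 - R_f) f(0) + R_f f(t)]`` where ``f`` is the
    fully-mobile recovery fraction.  The bleach instant ``F(0)`` is
    independent of ``R_f`` and the asymptote is
    ``F_pre * [(1 - R_f) f(0) + R_f]``, so the normalized recovery
    ``(F_inf - F(0)) / (F_pre - F(0))`` equals ``R_f`` exactly.
    """
    _require(math.isfinite(F_pre) and F_pre > 0, f"F_pre must be finite and > 0, got {F_pre}")
    f0 = bleach_depth_fraction(beam.K)
    if mob.D == 0 or mob.R_f == 0:
        f = np.full_like(beam.t_grid, f0)
    else:
        f = mobile_recovery_fraction(beam.t_grid, beam.K, mob.tau_d(beam.w))
    return F_pre * ((1.0 - mob.R_f) * f0 + mob.R_f * f)
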