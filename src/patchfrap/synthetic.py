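"""Synthetic FRAP data: noisy recovery curves and a patch/FRAP binding simulator.

Two generators live here.

``generate_curve`` / ``generate_cohort`` draw noisy recovery curves around
the closed-form diffusion model — the stand-in for a microscope acquisition
of one cell, with shot-noise-like measurement error and between-cell
variability of the mobility parameters.

``simulate_binding_frap`` is a particle-level reaction–diffusion Monte Carlo
of the patch/FRAP experiment itself: labeled receptors diffuse in a periodic
membrane patch and bind/unbind immobile traps (IgG-crosslinked receptor
patches) with first-order kinetics.  A Gaussian-spot bleach marks particles,
and the Gaussian-weighted count of unbleached particles is the recorded
fluorescence.  Sweeping the trap dissociation rate k_off against the
diffusion timescale 1/tau_D moves the fitted signature continuously from the
stable-complex regime (mobile fraction reduced, D unchanged) to the
transient regime (apparent D reduced toward the effective-diffusion limit
D_free * k_off / (k_on + k_off), mobile fraction unchanged).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .forward_model import BeamProtocol, MobilityParams, bleach_depth_fraction, model_curve

__all__ = [
    "NoiseModel",
    "RecoveryCurve",
    "BindingSimParams",
    "generate_curve",
    "generate_cohort",
    "simulate_binding_frap",
    "jitter_mobility",
    "effective_diffusion",
    "curves_to_frame",
    "frame_to_curves",
    "write_curves_csv",
    "read_curves_csv",
]

#: equilibration target, multiples of the relaxation time 1/(k_on + k_off)
EQUILIBRATION_RELAXATIONS = 5.0
#: hard cap on equilibration steps (slow kinetics would otherwise dominate runtime)
EQUILIBRATION_STEP_CAP = 10_000

_META_COLUMNS = ("condition", "crosslinked", "ligand")


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise added to a noiseless recovery curve.

    ``signal-scaled`` draws Gaussian noise with SD ``sigma0 * sqrt(F)``
    (Poisson-like shot noise in the Gaussian limit); ``constant`` uses a
    fixed SD ``sigma0``.
    """

    scheme: str = "signal-scaled"
    sigma0: float = 0.02

    def __post_init__(self) -> None:
        _require(self.scheme in ("signal-scaled", "constant"), f"unknown noise scheme {self.scheme!r}")
        _require(self.sigma0 >= 0, f"sigma0 must be >= 0, got {self.sigma0}")

    def sd(self, F: np.ndarray) -> np.ndarray:
        F = np.asarray(F, dtype=float)
        if self.scheme == "signal-scaled":
            return self.sigma0 * np.sqrt(np.clip(F, 0.0, None))
        return np.full_like(F, self.sigma0)


@dataclass
class RecoveryCurve:
    """One cell's fluorescence time series around a bleach event.

    ``t`` is strictly increasing (seconds, bleach at t = 0 by convention);
    ``F`` is fluorescence in arbitrary units; ``bleach_index`` is the index
    of the first post-bleach sample.  ``meta`` carries condition labels and,
    for synthetic curves, the ground-truth mobility.
    """

    cell_id: str
    t: np.ndarray
    F: np.ndarray
    bleach_index: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.F = np.asarray(self.F, dtype=float)
        _require(self.t.ndim == 1 and self.t.shape == self.F.shape, "t and F must be 1-D and equal length")
        _require(np.all(np.diff(self.t) > 0), "t must be strictly increasing")
        _require(np.all(np.isfinite(self.F)) and np.all(self.F >= 0), "F must be finite and >= 0")
        _require(1 <= self.bleach_index <= self.t.size - 10,
                 "need >= 1 pre-bleach and >= 10 post-bleach samples")
        pre_mean = float(np.mean(self.F[: self.bleach_index]))
        _require(self.F[self.bleach_index] < pre_mean,
                 "fluorescence must drop across the bleach event")

    @property
    def pre(self) -> np.ndarray:
        return self.F[: self.bleach_index]

    @property
    def post(self) -> np.ndarray:
        return self.F[self.bleach_index:]

    @property
    def t_post(self) -> np.ndarray:
        return self.t[self.bleach_index:]


def generate_curve(
    beam: BeamProtocol,
    mob: MobilityParams,
    noise: NoiseModel,
    seed: int,
    F_pre: float = 1.0,
    cell_id: str = "cell",
    meta: dict | None = None,
) -> RecoveryCurve:
    """Draw one noisy recovery curve around the closed-form model.

    Deterministic given ``seed``.  Rejects bleach depths >= 95% (outside the
    linearity assumed of the detector).  The returned curve's ``meta``
    records the ground-truth ``(D, R_f)``.
    """
    if beam.bleach_depth >= 0.95:
        raise ValueError(
            f"K={beam.K} implies bleach depth {beam.bleach_depth:.3f} >= 0.95; rejected"
        )
    rng = np.random.default_rng(seed)
    t_pre = beam.pre_times()
    post = model_curve(beam, mob, F_pre=F_pre)
    F = np.concatenate([np.full(beam.n_pre, F_pre), post])
    F = F + rng.standard_normal(F.size) * noise.sd(F)
    F = np.clip(F, 0.0, None)
    m = {"D_true": mob.D, "R_f_true": mob.R_f, "F_pre": F_pre}
    if meta:
        m.update(meta)
    return RecoveryCurve(
        cell_id=cell_id,
        t=np.concatenate([t_pre, beam.t_grid]),
        F=F,
        bleach_index=beam.n_pre,
        meta=m,
    )


def jitter_mobility(mob: MobilityParams, cv: float, rng: np.random.Generator) -> MobilityParams:
    """Between-cell variability: lognormal on D, logit-normal on R_f.

    ``cv`` is the coefficient of variation targeted on the natural scale of
    each parameter (delta-method calibration for R_f).  The lognormal is
    mean-preserving; the logit-normal is approximately so.
    """
    _require(0 <= cv < 1, f"cv must lie in [0, 1), got {cv}")
    if cv == 0:
        return mob
    s_ln = math.sqrt(math.log1p(cv * cv))
    D = mob.D * math.exp(rng.normal(-0.5 * s_ln * s_ln, s_ln)) if mob.D > 0 else 0.0
    if 0 < mob.R_f < 1:
        s_logit = cv / (1.0 - mob.R_f)
        z = math.log(mob.R_f / (1.0 - mob.R_f)) + rng.normal(0.0, s_logit)
        R_f = 1.0 / (1.0 + math.exp(-z))
    else:
        R_f = mob.R_f
    return MobilityParams(D=D, R_f=R_f)


def generate_cohort(
    spec: list[tuple[dict, MobilityParams, int]],
    beam: BeamProtocol,
    noise: NoiseModel,
    seed: int,
    cell_cv: float = 0.15,
) -> list[RecoveryCurve]:
    """Generate a reproducible multi-condition cohort of recovery curves.

    ``spec`` lists ``(condition_meta, MobilityParams, n_cells)`` triples;
    per-cell ground truth is jittered by ``jitter_mobility`` with
    coefficient of variation ``cell_cv`` (0 disables).  Cell seeds derive
    from ``seed`` plus the running cell index, so cohorts are
    bit-reproducible and individual cells re-creatable.
    """
    curves: list[RecoveryCurve] = []
    seen: set[str] = set()
    idx = 0
    for meta, mob, n_cells in spec:
        _require(n_cells >= 2, f"each condition needs n_cells >= 2, got {n_cells} for {meta}")
        cond = meta.get("condition", "cond")
        for j in range(n_cells):
            cell_seed = seed + idx
            rng = np.random.default_rng((cell_seed, 7919))  # jitter stream, distinct from noise
            cell_mob = jitter_mobility(mob, cell_cv, rng)
            cid = f"{cond}_{meta.get('crosslinked', 'no')}_{meta.get('ligand', 'none')}_{j:03d}"
            if cid in seen:
                raise ValueError(f"duplicate cell_id {cid!r}")
            seen.add(cid)
            curves.append(
                generate_curve(beam, cell_mob, noise, seed=cell_seed, cell_id=cid, meta=dict(meta))
            )
            idx += 1
    return curves


# ---------------------------------------------------------------------------
# Reaction–diffusion Monte Carlo of the patch/FRAP experiment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BindingSimParams:
    """Parameters of the receptor–trap binding simulation.

    Receptors diffuse freely with ``D_free`` and bind immobile traps with
    pseudo-first-order rate ``k_on`` (1/s), unbinding with ``k_off`` (1/s),
    on a periodic square membrane patch of side ``box_size`` µm.  ``dt`` is
    the kinetic time step; stability requires ``(k_on + k_off) dt < 0.1``
    and ``4 D_free dt < (box_size/100)^2``.
    """

    D_free: float
    k_on: float
    k_off: float
    box_size: float
    n_particles: int = 80_000
    dt: float = 0.01
    seed: int = 0
    trap_immobile: bool = True

    def __post_init__(self) -> None:
        _require(self.D_free >= 0, f"D_free must be >= 0, got {self.D_free}")
        _require(self.k_on >= 0 and self.k_off >= 0, "rates must be >= 0")
        _require(self.box_size > 0, "box_size must be > 0")
        _require(self.n_particles >= 10, f"n_particles must be >= 10, got {self.n_particles}")
        _require(self.dt > 0, "dt must be > 0")
        if (self.k_on + self.k_off) * self.dt >= 0.1:
            raise ValueError(
                f"dt={self.dt} too coarse for kinetics: (k_on+k_off)*dt = "
                f"{(self.k_on + self.k_off) * self.dt:.3g} >= 0.1"
            )
        if 4.0 * self.D_free * self.dt >= (self.box_size / 100.0) ** 2:
            raise ValueError(
                f"dt={self.dt} too coarse for diffusion: 4*D_free*dt = "
                f"{4 * self.D_free * self.dt:.3g} >= (box_size/100)^2 = "
                f"{(self.box_size / 100) ** 2:.3g}"
            )
        if not self.trap_immobile:
            raise NotImplementedError("mobile traps are not modeled")

    @property
    def bound_fraction(self) -> float:
        """Stationary bound fraction k_on / (k_on + k_off)."""
        s = self.k_on + self.k_off
        return self.k_on / s if s > 0 else 0.0


def effective_diffusion(D_free: float, k_on: float, k_off: float) -> float:
    """Fast-exchange effective diffusion coefficient D_free * k_off / (k_on + k_off)."""
    s = k_on + k_off
    return D_free if s == 0 else D_free * k_off / s


@njit(cache=True)
def _seed_rng(seed):  # pragma: no cover - trivial numba shim
    np.random.seed(seed)


@njit(cache=True)
def _draw_geometric(p):
    """Steps until a state flip; huge sentinel when the rate is zero."""
    if p <= 0.0:
        return np.int64(1) << 60
    u = np.random.random()
    # inverse CDF of the geometric distribution on {1, 2, ...}
    return max(np.int64(1), np.int64(math.ceil(math.log(1.0 - u) / math.log(1.0 - p))))


@njit(cache=True)
def _advance(x, y, bound, countdown, n_steps, p_on, p_off, sigma_step, L):
    """Advance every particle by ``n_steps`` kinetic steps.

    State flips follow per-sojourn geometric countdowns (exactly equivalent
    to per-step Bernoulli trials); the free-time displacement within the
    window is drawn as a single Gaussian with variance ``2 D dt * n_free``
    per axis, which is the exact distribution of the summed Brownian steps.
    Positions wrap on the periodic box [0, L).
    """
    n = x.size
    for i in range(n):
        remaining = n_steps
        free_steps = np.int64(0)
        while remaining > 0:
            take = countdown[i] if countdown[i] < remaining else remaining
            if not bound[i]:
                free_steps += take
            countdown[i] -= take
            remaining -= take
            if countdown[i] == 0:
                if bound[i]:
                    bound[i] = False
                    countdown[i] = _draw_geometric(p_on)
                else:
                    bound[i] = True
                    countdown[i] = _draw_geometric(p_off)
        if free_steps > 0 and sigma_step > 0.0:
            s = sigma_step * math.sqrt(float(free_steps))
            x[i] = (x[i] + s * np.random.normal()) % L
            y[i] = (y[i] + s * np.random.normal()) % L


def _spot_weights(x: np.ndarray, y: np.ndarray, cx: float, cy: float, w: float) -> np.ndarray:
    r2 = (x - cx) ** 2 + (y - cy) ** 2
    return np.exp(-2.0 * r2 / (w * w))


def simulate_binding_frap(
    params: BindingSimParams,
    beam: BeamProtocol,
    seed: int | None = None,
    cell_id: str = "sim",
    meta: dict | None = None,
) -> RecoveryCurve:
    """Simulate one patch/FRAP acquisition of receptors exchanging with traps.

    Particles start uniformly distributed with states drawn from the
    stationary bound fraction, then equilibrate for at least
    ``EQUILIBRATION_RELAXATIONS / (k_on + k_off)`` (capped, with a warning,
    at ``EQUILIBRATION_STEP_CAP`` steps).  The bleach pulse at t = 0 marks
    each particle bleached with probability ``1 - exp(-K exp(-2 r^2 / w^2))``
    at its instantaneous position; the recorded fluorescence is the
    Gaussian-weighted (e^-2 radius ``w``) count of unbleached particles at
    every monitoring time.  Deterministic given ``seed``.
    """
    _require(params.box_size >= 10.0 * beam.w,
             f"box_size must be >= 10*w = {10 * beam.w:.2f} µm, got {params.box_size}")
    seed = params.seed if seed is None else seed
    L = params.box_size
    n = params.n_particles
    rng = np.random.default_rng((int(seed), 104729))

    x = rng.uniform(0.0, L, n)
    y = rng.uniform(0.0, L, n)
    pb = params.bound_fraction
    bound = rng.random(n) < pb

    _seed_rng(int(seed) % (2**31))
    p_on = -math.expm1(-params.k_on * params.dt)
    p_off = -math.expm1(-params.k_off * params.dt)
    big = np.int64(1) << 60
    p_flip = np.where(bound, p_off, p_on)
    countdown = np.full(n, big, dtype=np.int64)
    active = p_flip > 0
    if np.any(active):
        countdown[active] = rng.geometric(p_flip[active])
    sigma_step = math.sqrt(2.0 * params.D_free * params.dt)

    # equilibrate binding/diffusion before any measurement
    rate_sum = params.k_on + params.k_off
    if rate_sum > 0:
        n_equil = int(math.ceil(EQUILIBRATION_RELAXATIONS / (rate_sum * params.dt)))
        if n_equil > EQUILIBRATION_STEP_CAP:
            warnings.warn(
                f"equilibration needs {n_equil} steps; capping at {EQUILIBRATION_STEP_CAP} "
                "(states were initialized at the stationary bound fraction)",
                RuntimeWarning,
                stacklevel=2,
            )
            n_equil = EQUILIBRATION_STEP_CAP
        _advance(x, y, bound, countdown, n_equil, p_on, p_off, sigma_step, L)

    cx = cy = L / 2.0
    bleached = np.zeros(n, dtype=bool)
    # scale of the raw weighted count, for display units
    scale = n * math.pi * beam.w**2 / (2.0 * L * L)

    def record() -> float:
        # Gaussian-weighted count of unbleached particles, normalized by the
        # same configuration's no-bleach count (control variate: cancels
        # particle-number fluctuations at the spot; identical in expectation
        # to the raw weighted count).
        wts = _spot_weights(x, y, cx, cy, beam.w)
        total = float(np.sum(wts))
        unb = float(np.sum(wts[~bleached]))
        return scale * unb / total if total > 0 else 0.0

    # pre-bleach monitoring
    F_pre = np.empty(beam.n_pre)
    steps_mon = max(1, round(beam.monitor_interval / params.dt))
    for k in range(beam.n_pre):
        F_pre[k] = record()
        _advance(x, y, bound, countdown, steps_mon, p_on, p_off, sigma_step, L)

    # bleach pulse at t = 0, applied at each particle's current position
    p_bleach = 1.0 - np.exp(-beam.K * _spot_weights(x, y, cx, cy, beam.w))
    bleached = rng.random(n) < p_bleach

    # post-bleach recording on beam.t_grid
    F_post = np.empty(beam.t_grid.size)
    t_prev = 0.0
    for k, tk in enumerate(beam.t_grid):
        gap = tk - t_prev
        if gap > 0:
            steps = max(1, round(gap / params.dt))
            _advance(x, y, bound, countdown, steps, p_on, p_off, sigma_step, L)
        F_post[k] = record()
        t_prev = tk

    m = {
        "D_free": params.D_free,
        "k_on": params.k_on,
        "k_off": params.k_off,
        "bound_fraction": pb,
        "n_particles": n,
    }
    if meta:
        m.update(meta)
    t_pre = beam.pre_times()
    return RecoveryCurve(
        cell_id=cell_id,
        t=np.concatenate([t_pre, beam.t_grid]),
        F=np.concatenate([F_pre, F_post]),
        bleach_index=beam.n_pre,
        meta=m,
    )


# ---------------------------------------------------------------------------
# Tidy CSV round-tripping
# ---------------------------------------------------------------------------

def curves_to_frame(curves: list[RecoveryCurve]):
    """Tidy long-format DataFrame: cell_id, condition, crosslinked, ligand, t_s, F_au, phase."""
    import pandas as pd

    rows = []
    for c in curves:
        phase = np.where(np.arange(c.t.size) < c.bleach_index, "pre", "post")
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": c.cell_id,
                    "condition": c.meta.get("condition", ""),
                    "crosslinked": c.meta.get("crosslinked", "no"),
                    "ligand": c.meta.get("ligand", "none"),
                    "t_s": c.t,
                    "F_au": c.F,
                    "phase": phase,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def frame_to_curves(df) -> list[RecoveryCurve]:
    curves = []
    for cid, g in df.groupby("cell_id", sort=False):
        g = g.sort_values("t_s")
        bleach_index = int((g["phase"] == "pre").sum())
        meta = {k: g[k].iloc[0] for k in _META_COLUMNS if k in g}
        curves.append(
            RecoveryCurve(
                cell_id=str(cid),
                t=g["t_s"].to_numpy(float),
                F=g["F_au"].to_numpy(float),
                bleach_index=bleach_index,
                meta=meta,
            )
        )
    return curves


def write_curves_csv(curves: list[RecoveryCurve], path) -> None:
    curves_to_frame(curves).to_csv(path, index=False)


def read_curves_csv(path) -> list[RecoveryCurve]:
    import pandas as pd

    df = pd.read_csv(path)
    required = {"cell_id", "t_s", "F_au", "phase"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"curve CSV missing columns: {sorted(missing)}")
    bad = df.index[~df["phase"].isin(["pre", "post"])]
    if len(bad):
        raise ValueError(f"curve CSV row {bad[0] + 2}: invalid phase {df.loc[bad[0], 'phase']!r}")
    for col in ("t_s", "F_au"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[vals.isna()]
        if len(bad):
            raise ValueError(
                f"curve CSV row {bad[0] + 2}, column {col!r}: not numeric ({df.loc[bad[0], col]!r})"
            )
        df[col] = vals
    return frame_to_curves(df)
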