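"""2D run-and-tumble simulator of early microcolony growth.

Rod-shaped (spherocylindrical) bacteria swim at speed ``v``, reorient
completely at Poisson-distributed tumbles (mean run time ``tau_run``),
repel each other sterically and attract weakly through a shallow
Lennard-Jones-like well of depth ``attraction_strength * epsilon`` —
the effective depletion attraction induced by the secreted polymer
matrix.  Cells elongate linearly from birth length ``l0`` to ``2 * l0``
over one duplication time and then split into two daughters placed
end-to-end along the mother's axis.

The run-and-tumble calibration is self-consistent with measured
single-cell transport of peritrichous swimmers: for complete
reorientation in 2D the long-time diffusion coefficient is
``D = v**2 * tau_run / 2``, so the defaults v = 0.2 um/s and
tau_run = 35 s give D = 0.7 um^2/s.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from ._active_core import R_MIN_FACTOR, advance_block, single_pair_force

__all__ = [
    "ActiveSimConfig",
    "Bacterium",
    "Colony",
    "ColonyTrajectory",
    "TimestepTooLargeError",
    "InsufficientSamplingError",
    "pair_force",
    "minimum_separation",
    "new_colony",
    "step",
    "grow_and_divide",
    "run_colony",
    "growth_curve",
    "fit_doubling_time",
    "run_single",
    "estimate_diffusion",
]


class TimestepTooLargeError(RuntimeError):
    """Raised when rods overlap deeper than half a width after a step."""


class InsufficientSamplingError(ValueError):
    """Raised when a trajectory is too short to estimate transport."""


@dataclass(frozen=True)
class ActiveSimConfig:
    """Parameters of the colony simulator.

    v: swim speed (um/s); tau_run: mean run time between tumbles (s);
    epsilon: repulsion energy scale (arbitrary units); the attraction
    well depth is ``attraction_strength * epsilon``; t_dup: duplication
    time (h); l0/w: birth length and width (um); dt: timestep (s);
    box: periodic square side (um).  ``mobility`` converts force to
    velocity (um/s per epsilon/um); per-step force displacements are
    capped at ``cap_frac * w``.
    """

    v: float = 0.2
    tau_run: float = 35.0
    epsilon: float = 1.0
    attraction_strength: float = 0.2
    t_dup: float = 1.0
    l0: float = 2.0
    w: float = 0.8
    dt: float = 0.05
    box: float = 200.0
    mobility: float = 1.0
    cap_frac: float = 0.05
    omega_tumble: float = 2.0
    division_noise: float = 0.1
    r_cut_factor: float = 2.5
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("v", "tau_run", "dt", "box", "l0", "w", "t_dup", "epsilon"):
            if getattr(self, name) <= 0 and name != "v":
                raise ValueError(f"{name} must be positive")
        if self.v < 0 or self.attraction_strength < 0:
            raise ValueError("v and attraction_strength must be non-negative")
        if self.dt >= self.tau_run:
            raise ValueError("dt must be much smaller than tau_run")
        if self.l0 <= self.w:
            raise ValueError("birth length must exceed the width")

    @property
    def r_cut(self) -> float:
        return self.r_cut_factor * self.w

    @property
    def elongation_rate(self) -> float:
        """Length growth rate (um/s): l0 -> 2*l0 over one t_dup."""
        return self.l0 / (self.t_dup * 3600.0)


@dataclass
class Bacterium:
    """One rod agent (view of a colony row)."""

    position: tuple[float, float]
    theta: float
    length: float
    age_since_division: float
    id: int
    parent: int


@dataclass
class Colony:
    """Array-of-struct state of all rods at one instant."""

    x: np.ndarray
    y: np.ndarray
    theta: np.ndarray
    target: np.ndarray
    length: np.ndarray
    birth_time: np.ndarray  # h
    ids: np.ndarray
    parents: np.ndarray
    t: float = 0.0  # h
    next_id: int = 0

    @property
    def n(self) -> int:
        return len(self.x)

    def bacteria(self) -> list[Bacterium]:
        return [
            Bacterium(
                position=(float(self.x[i]), float(self.y[i])),
                theta=float(self.theta[i]),
                length=float(self.length[i]),
                age_since_division=float(self.t - self.birth_time[i]),
                id=int(self.ids[i]),
                parent=int(self.parents[i]),
            )
            for i in range(self.n)
        ]

    def copy(self) -> "Colony":
        return Colony(
            self.x.copy(),
            self.y.copy(),
            self.theta.copy(),
            self.target.copy(),
            self.length.copy(),
            self.birth_time.copy(),
            self.ids.copy(),
            self.parents.copy(),
            self.t,
            self.next_id,
        )


@dataclass
class ColonyTrajectory:
    """Frame times (h), per-frame counts and (optionally) full states."""

    times: np.ndarray
    counts: np.ndarray
    config: ActiveSimConfig
    frames: list[Colony] | None = None


def pair_force(d: float, config: ActiveSimConfig) -> float:
    """Radial pair force (-dU/dd) at axis-axis distance ``d`` (um)."""
    return float(
        single_pair_force(d, config.epsilon, config.attraction_strength, config.w)
    )


def minimum_separation(config: ActiveSimConfig) -> float:
    """Axis-axis distance of zero pair force (the potential minimum)."""
    return R_MIN_FACTOR * config.w


def new_colony(config: ActiveSimConfig, n: int = 1, rng: np.random.Generator | None = None) -> Colony:
    """Fresh colony of ``n`` cells scattered near the box center."""
    rng = rng or np.random.default_rng(config.seed)
    half = config.box / 2.0
    spread = max(2.0 * config.l0 * math.sqrt(n), config.l0)
    x = (half + rng.uniform(-spread, spread, n)) % config.box
    y = (half + rng.uniform(-spread, spread, n)) % config.box
    theta = rng.uniform(0.0, 2.0 * np.pi, n)
    length = np.full(n, config.l0)
    return Colony(
        x=x,
        y=y,
        theta=theta,
        target=theta.copy(),
        length=length,
        birth_time=np.zeros(n),
        ids=np.arange(n, dtype=np.int64),
        parents=np.full(n, -1, dtype=np.int64),
        t=0.0,
        next_id=n,
    )


def step(
    colony: Colony,
    config: ActiveSimConfig,
    n_steps: int = 1,
    seed: int | None = None,
    grow: bool = True,
) -> Colony:
    """Advance motion (runs, tumbles, pair forces) by ``n_steps`` timesteps.

    Elongation is integrated alongside when ``grow`` is set; division is
    handled separately by :func:`grow_and_divide`.  Raises
    :class:`TimestepTooLargeError` if any pair overlaps deeper than half
    a width after the block.
    """
    if colony.n == 0:
        return colony
    block_seed = int(seed if seed is not None else config.seed) % (2**31 - 1)
    elong = config.elongation_rate if grow else 0.0
    max_overlap = advance_block(
        colony.x,
        colony.y,
        colony.theta,
        colony.target,
        colony.length,
        colony.n,
        n_steps,
        config.dt,
        config.v,
        config.tau_run,
        config.epsilon,
        config.attraction_strength,
        config.w,
        config.r_cut,
        config.mobility,
        config.cap_frac,
        config.omega_tumble,
        config.box,
        elong,
        block_seed,
    )
    colony.t += n_steps * config.dt / 3600.0
    if max_overlap > 0.5 * config.w:
        raise TimestepTooLargeError(
            f"overlap {max_overlap:.3f} um exceeds half a width ({0.5 * config.w:.3f} um) "
            f"at t={colony.t:.4f} h; reduce dt"
        )
    return colony


def grow_and_divide(
    colony: Colony, config: ActiveSimConfig, rng: np.random.Generator
) -> Colony:
    """Split every cell that has reached twice its birth length.

    Daughters are born at length ``l0``, placed end-to-end along the
    mother's axis (total body length is continuous across the event) and
    inherit her orientation up to Gaussian noise of s.d.
    ``division_noise`` radians.
    """
    ready = np.flatnonzero(colony.length >= 2.0 * config.l0)
    if ready.size == 0:
        return colony
    keep = np.setdiff1d(np.arange(colony.n), ready, assume_unique=True)
    new_x, new_y, new_th, new_len, new_birth, new_ids, new_par = [], [], [], [], [], [], []
    for i in ready:
        ux, uy = math.cos(colony.theta[i]), math.sin(colony.theta[i])
        off = colony.length[i] / 4.0  # daughter centers at +-L/4 along the axis
        for sgn in (+1.0, -1.0):
            new_x.append((colony.x[i] + sgn * off * ux) % config.box)
            new_y.append((colony.y[i] + sgn * off * uy) % config.box)
            new_th.append(colony.theta[i] + rng.normal(0.0, config.division_noise))
            new_len.append(config.l0)
            new_birth.append(colony.t)
            new_ids.append(colony.next_id)
            new_par.append(int(colony.ids[i]))
            colony.next_id += 1
    colony.x = np.concatenate([colony.x[keep], np.array(new_x)])
    colony.y = np.concatenate([colony.y[keep], np.array(new_y)])
    colony.theta = np.concatenate([colony.theta[keep], np.array(new_th)])
    colony.target = np.concatenate([colony.target[keep], np.array(new_th)])
    colony.length = np.concatenate([colony.length[keep], np.array(new_len)])
    colony.birth_time = np.concatenate([colony.birth_time[keep], np.array(new_birth)])
    colony.ids = np.concatenate([colony.ids[keep], np.array(new_ids, dtype=np.int64)])
    colony.parents = np.concatenate([colony.parents[keep], np.array(new_par, dtype=np.int64)])
    return colony


def run_colony(
    config: ActiveSimConfig,
    hours: float,
    seed: int | None = None,
    record_every_s: float = 60.0,
    store_frames: bool = False,
    division_check_s: float = 5.0,
) -> ColonyTrajectory:
    """Grow a colony from a single cell for ``hours`` simulated hours.

    Integrates in blocks of ``division_check_s`` seconds between division
    sweeps (cells overshoot 2*l0 by at most elongation_rate * block,
    ~3e-3 um at defaults).  Records the cell count every
    ``record_every_s`` seconds; full per-cell frames only when
    ``store_frames`` is set.
    """
    master = np.random.default_rng(config.seed if seed is None else seed)
    colony = new_colony(config, n=1, rng=master)
    block_steps = max(1, int(round(division_check_s / config.dt)))
    total_steps = int(round(hours * 3600.0 / config.dt))
    rec_stride = max(1, int(round(record_every_s / config.dt)))
    times = [0.0]
    counts = [colony.n]
    frames = [colony.copy()] if store_frames else None
    done = 0
    next_record = rec_stride
    while done < total_steps:
        n_sub = min(block_steps, total_steps - done)
        block_seed = int(master.integers(2**31 - 1))
        step(colony, config, n_steps=n_sub, seed=block_seed, grow=True)
        colony = grow_and_divide(colony, config, master)
        done += n_sub
        if done >= next_record or done == total_steps:
            times.append(done * config.dt / 3600.0)
            counts.append(colony.n)
            if store_frames:
                frames.append(colony.copy())
            while next_record <= done:
                next_record += rec_stride
    return ColonyTrajectory(
        times=np.array(times), counts=np.array(counts, dtype=float),
        config=config, frames=frames,
    )


def growth_curve(trajectory: ColonyTrajectory) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame cell counts ``(t_h, N)``."""
    if len(trajectory.times) < 2:
        raise ValueError("trajectory needs at least two frames")
    return trajectory.times, trajectory.counts


def fit_doubling_time(times_h: np.ndarray, counts: np.ndarray) -> float:
    """Doubling time (h) as the inverse slope of log2 N versus t."""
    times_h = np.asarray(times_h, dtype=float)
    counts = np.asarray(counts, dtype=float)
    if np.any(counts <= 0):
        raise ValueError("counts must be positive")
    slope = np.polyfit(times_h, np.log2(counts), 1)[0]
    if slope <= 0:
        raise ValueError("non-growing count series")
    return 1.0 / slope


def run_single(
    config: ActiveSimConfig,
    total_time_s: float,
    n_walkers: int = 1,
    seed: int | None = None,
    frame_dt_s: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Event-driven trajectories of isolated, non-growing swimmers.

    Runs are exact: exponential run durations (mean ``tau_run``),
    uniform fresh headings, ballistic flight in between — interactions
    and growth are irrelevant for an isolated cell.  Returns
    ``(times_s, positions)`` with positions of shape
    ``(n_frames, n_walkers, 2)`` in unwrapped coordinates (um).
    """
    rng = np.random.default_rng(config.seed if seed is None else seed)
    frame_t = np.arange(0.0, total_time_s + 0.5 * frame_dt_s, frame_dt_s)
    pos = np.zeros((len(frame_t), n_walkers, 2))
    for wlk in range(n_walkers):
        t_now, xw, yw = 0.0, 0.0, 0.0
        heading = rng.uniform(0.0, 2.0 * np.pi)
        idx = 1
        while t_now < total_time_s and idx < len(frame_t):
            run = rng.exponential(config.tau_run)
            t_next = min(t_now + run, total_time_s)
            ux, uy = math.cos(heading), math.sin(heading)
            while idx < len(frame_t) and frame_t[idx] <= t_next + 1e-12:
                dt_f = frame_t[idx] - t_now
                pos[idx, wlk, 0] = xw + config.v * dt_f * ux
                pos[idx, wlk, 1] = yw + config.v * dt_f * uy
                idx += 1
            xw += config.v * (t_next - t_now) * ux
            yw += config.v * (t_next - t_now) * uy
            t_now = t_next
            heading = rng.uniform(0.0, 2.0 * np.pi)
    return frame_t, pos


def estimate_diffusion(
    times_s: np.ndarray,
    positions: np.ndarray,
    tau_run: float,
    fit_window: tuple[float, float] = (10.0, 0.1),
) -> tuple[float, float]:
    """Long-time diffusion coefficient from the MSD slope.

    Parameters
    ----------
    times_s, positions:
        Uniform frame times and unwrapped positions, shape
        ``(n_frames, n_walkers, 2)``.
    tau_run:
        Mean run time; lags below ``fit_window[0] * tau_run`` (ballistic
        regime) are excluded, lags above ``fit_window[1] * total_time``
        are excluded as undersampled.

    Returns
    -------
    (D_eff, t_cross):
        ``MSD(lag) -> 4 * D_eff * lag`` in 2D, and the ballistic->
        diffusive crossover time ``t_cross = 2 * D_eff / v^2`` implied by
        the fitted D (equal to ``tau_run`` for ideal run-and-tumble).

    Raises
    ------
    InsufficientSamplingError
        If the trajectory is shorter than 10 mean run times.
    """
    times_s = np.asarray(times_s, dtype=float)
    positions = np.asarray(positions, dtype=float)
    total = times_s[-1] - times_s[0]
    if total < 10.0 * tau_run:
        raise InsufficientSamplingError(
            f"trajectory spans {total:.0f} s < 10 * tau_run = {10 * tau_run:.0f} s"
        )
    frame_dt = times_s[1] - times_s[0]
    lag_lo = max(fit_window[0] * tau_run, frame_dt)
    lag_hi = max(fit_window[1] * total, 2.0 * lag_lo)
    lags = np.unique(
        np.round(np.geomspace(lag_lo, lag_hi, 12) / frame_dt).astype(int)
    )
    lags = lags[lags >= 1]
    msd = np.empty(len(lags))
    for k, lag in enumerate(lags):
        disp = positions[lag:] - positions[:-lag]
        msd[k] = np.mean(np.sum(disp**2, axis=-1))
    lag_t = lags * frame_dt
    # affine fit: the intercept absorbs the finite-lag ballistic offset
    # (MSD = 4 D lag - 4 D tau + ... beyond the crossover)
    slope = float(np.polyfit(lag_t, msd, 1)[0])
    d_eff = max(slope / 4.0, 0.0)
    v_sq = np.mean(
        np.sum((positions[1] - positions[0]) ** 2, axis=-1)
    ) / frame_dt**2  # short-lag speed estimate
    t_cross = 2.0 * d_eff / v_sq if v_sq > 0 else math.inf
    return d_eff, t_cross
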