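"""Transport observables from particle trajectories.

Implements the standard MD estimators for nanopore transport: the
bin-crossing-free ionic current estimator

    I(t) = Σ_i q_i Δz_i / (Δt · L_z),

its mass-flow twin for electroosmotic volumetric flow, block averaging for
honest error bars on correlated series, central-difference particle
velocities, selectivity from per-species currents, and the MSD route to the
diffusion coefficient with the Einstein relation to mobility.

Axial displacements Δz_i are minimum-image along z: the estimator assumes
frames are sampled finely enough that no particle travels further than L_z/2
between snapshots (suspiciously large wrapped steps trigger a warning).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .trajectory import TrajectoryFrame
from .units import KB, molar_to_per_A3

__all__ = [
    "BlockSeries",
    "DiffusionFit",
    "instantaneous_current",
    "current_series",
    "volumetric_flow",
    "flow_series",
    "block_average",
    "finite_difference_velocities",
    "selectivity_from_currents",
    "msd",
    "msd_diffusion",
    "einstein_mobility",
]


def _minimum_image(delta: np.ndarray, length: float | np.ndarray) -> np.ndarray:
    return delta - length * np.round(delta / length)


def _check_pair(a: TrajectoryFrame, b: TrajectoryFrame) -> float:
    if not np.array_equal(a.ids, b.ids):
        raise ValueError("frames contain different particle sets / ordering")
    if not np.allclose(a.box, b.box):
        raise ValueError("box changed between frames; NVT frames expected")
    dt = b.time - a.time
    if dt <= 0:
        raise ValueError(f"frame pair must be time-ordered with dt > 0, got dt={dt}")
    return dt


def _axial_displacement(a: TrajectoryFrame, b: TrajectoryFrame) -> np.ndarray:
    lz = a.box[2]
    dz = _minimum_image(b.positions[:, 2] - a.positions[:, 2], lz)
    if dz.size and np.max(np.abs(dz)) > 0.4 * lz:
        warnings.warn(
            "axial step exceeds 0.4 Lz: sampling may be too coarse for the "
            "minimum-image displacement assumption",
            stacklevel=3,
        )
    return dz


def instantaneous_current(
    frame_a: TrajectoryFrame,
    frame_b: TrajectoryFrame,
    species: str | Iterable[str] | None = None,
) -> float:
    """Average axial ionic current over [t_a, t_b], in e/ns.

    I = Σ_i q_i Δz_i/(Δt·L_z) over the selected particles (all by default);
    per-species currents are obtained by restricting the sum.
    """
    dt = _check_pair(frame_a, frame_b)
    dz = _axial_displacement(frame_a, frame_b)
    if species is not None:
        mask = frame_a.select(species)
        return float(np.sum(frame_a.charge[mask] * dz[mask]) / (dt * frame_a.box[2]))
    return float(np.sum(frame_a.charge * dz) / (dt * frame_a.box[2]))


def current_series(
    frames: Sequence[TrajectoryFrame],
    species: str | Iterable[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval currents for consecutive frame pairs.

    Returns (interval midpoint times in ns, currents in e/ns).
    """
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    times = np.array(
        [(a.time + b.time) / 2.0 for a, b in zip(frames[:-1], frames[1:])]
    )
    currents = np.array(
        [instantaneous_current(a, b, species) for a, b in zip(frames[:-1], frames[1:])]
    )
    return times, currents


def volumetric_flow(
    frame_a: TrajectoryFrame,
    frame_b: TrajectoryFrame,
    bulk_density: float,
    molecular_mass: float | None = None,
    species: str | Iterable[str] | None = None,
) -> float:
    """Electroosmotic volumetric flow rate over [t_a, t_b], in Å³/ns.

    The axial mass flow rate Σ_i m_i Δz_i/(Δt·L_z) (the current estimator with
    mass in place of charge) is converted to a volumetric rate by dividing by
    the bulk liquid mass density ``n0·M``, where ``n0`` is ``bulk_density``
    (mol/L of fluid molecules) and ``M`` the molecular mass in Da — inferred
    as the mean mass of the selected particles when not given.
    """
    if bulk_density <= 0:
        raise ValueError(f"bulk_density must be > 0 mol/L, got {bulk_density}")
    dt = _check_pair(frame_a, frame_b)
    dz = _axial_displacement(frame_a, frame_b)
    mask = frame_a.select(species) if species is not None else slice(None)
    masses = frame_a.mass[mask]
    if masses.size == 0:
        return 0.0
    mass_rate = float(np.sum(masses * dz[mask]) / (dt * frame_a.box[2]))  # Da/ns
    m_mol = float(np.mean(masses)) if molecular_mass is None else float(molecular_mass)
    rho_mass = molar_to_per_A3(bulk_density) * m_mol  # Da/Å³
    return mass_rate / rho_mass


def flow_series(
    frames: Sequence[TrajectoryFrame],
    bulk_density: float,
    molecular_mass: float | None = None,
    species: str | Iterable[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-interval volumetric flow rates (midpoint times ns, Q in Å³/ns)."""
    if len(frames) < 2:
        raise ValueError("need at least two frames")
    times = np.array(
        [(a.time + b.time) / 2.0 for a, b in zip(frames[:-1], frames[1:])]
    )
    flows = np.array(
        [
            volumetric_flow(a, b, bulk_density, molecular_mass, species)
            for a, b in zip(frames[:-1], frames[1:])
        ]
    )
    return times, flows


@dataclass
class BlockSeries:
    """A sampled time series with block-average statistics.

    ``values`` are per-interval samples spaced ``dt`` ns apart (first sample
    at ``dt`` after the series origin); the first ``discard`` ns are dropped
    as equilibration transient, the rest is cut into contiguous blocks of
    ``block_length`` ns, and the standard error is the standard deviation of
    the block means over √N_blocks — the usual remedy for serial correlation.
    """

    values: np.ndarray
    dt: float
    block_length: float = 10.0
    discard: float = 30.0
    block_means: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0 or self.block_length <= 0:
            raise ValueError("dt and block_length must be > 0")
        if self.discard < 0:
            raise ValueError("discard must be >= 0")
        n_skip = int(round(self.discard / self.dt))
        kept = self.values[n_skip:]
        per_block = int(round(self.block_length / self.dt))
        if per_block < 1:
            raise ValueError("block_length shorter than the sampling interval")
        n_blocks = len(kept) // per_block
        if n_blocks < 2:
            raise ValueError(
                f"need >= 2 complete blocks after discard, got {n_blocks}"
            )
        self.block_means = kept[: n_blocks * per_block].reshape(
            n_blocks, per_block
        ).mean(axis=1)

    @property
    def n_blocks(self) -> int:
        return len(self.block_means)

    @property
    def mean(self) -> float:
        return float(np.mean(self.block_means))

    @property
    def sem(self) -> float:
        return float(
            np.std(self.block_means, ddof=1) / math.sqrt(self.n_blocks)
        )


def block_average(
    values: np.ndarray | BlockSeries,
    dt: float | None = None,
    block_length: float = 10.0,
    discard: float = 30.0,
) -> tuple[float, float]:
    """Block-averaged (mean, standard error) of a correlated series."""
    if not isinstance(values, BlockSeries):
        if dt is None:
            raise ValueError("dt (sampling interval, ns) is required")
        values = BlockSeries(values, dt, block_length, discard)
    return values.mean, values.sem


def finite_difference_velocities(
    prev: TrajectoryFrame, mid: TrajectoryFrame, nxt: TrajectoryFrame
) -> np.ndarray:
    """Central-difference per-particle velocities at the middle frame, Å/ns.

    v_i = minimum-image(x_i(f+1) − x_i(f−1)) / (2Δt), exact for uniform and
    uniformly accelerated motion; requires uniform frame spacing.
    """
    dt1 = _check_pair(prev, mid)
    dt2 = _check_pair(mid, nxt)
    if not math.isclose(dt1, dt2, rel_tol=1e-6):
        raise ValueError(f"non-uniform frame spacing: {dt1} ns vs {dt2} ns")
    delta = _minimum_image(nxt.positions - prev.positions, prev.box[np.newaxis, :])
    return delta / (dt1 + dt2)


def selectivity_from_currents(
    i_plus: float, i_minus: float, R: float, valence: int = 1
) -> float:
    """Selectivity ΔJ = (|I₊| − |I₋|)/(νe·πR²), in 1/(Å²·ns).

    Positive when the cation current dominates, matching the continuum-model
    sign convention (cation-selective pore ⇔ q_N > 0).
    """
    if R <= 0:
        raise ValueError("R must be > 0")
    if valence < 1:
        raise ValueError("valence must be >= 1")
    return (abs(i_plus) - abs(i_minus)) / (valence * math.pi * R**2)


def _unwrapped_positions(frames: Sequence[TrajectoryFrame]) -> np.ndarray:
    """(n_frames, n_particles, 3) positions with periodic jumps removed."""
    pos = np.array([f.positions for f in frames])
    box = frames[0].box[np.newaxis, np.newaxis, :]
    steps = _minimum_image(np.diff(pos, axis=0), box)
    out = np.empty_like(pos)
    out[0] = pos[0]
    np.cumsum(steps, axis=0, out=steps)
    out[1:] = pos[0] + steps
    return out


def msd(
    frames: Sequence[TrajectoryFrame],
    species: str | Iterable[str] | None = None,
    overlapping: bool = False,
    max_lag: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Ensemble 3D mean squared displacement vs lag time.

    Coordinates are unwrapped before differencing.  Non-overlapping time
    origins (the default) keep the lag samples nearly independent so that
    least-squares fit errors stay honest; ``overlapping=True`` uses every
    origin for smoother curves.

    Returns (lag times ns, MSD Å²) for lags 1..(n_frames−1)//2.
    """
    if len(frames) < 3:
        raise ValueError("need at least three frames for an MSD curve")
    for a, b in zip(frames[:-1], frames[1:]):
        _check_pair(a, b)
    dt = frames[1].time - frames[0].time
    pos = _unwrapped_positions(frames)
    if species is not None:
        pos = pos[:, frames[0].select(species), :]
    if pos.shape[1] == 0:
        raise ValueError("species selection matched no particles")
    n_frames = pos.shape[0]
    top = (n_frames - 1) // 2
    if max_lag is not None:
        top = min(top, max_lag)
    lags = np.arange(1, top + 1)
    max_lag = top
    out = np.empty(max_lag)
    for k, lag in enumerate(lags):
        origins = np.arange(0, n_frames - lag, 1 if overlapping else lag)
        disp = pos[origins + lag] - pos[origins]
        out[k] = np.mean(np.sum(disp**2, axis=-1))
    return lags * dt, out


@dataclass(frozen=True)
class DiffusionFit:
    """MSD linear-fit result: D = slope/6 (Å²/ns) plus fit diagnostics.

    ``poor_fit`` is set when the MSD in the fit window is visibly non-linear
    (low R² or a quadratic term carrying >20 % of the rise), e.g. for
    ballistic motion, where slope/6 is meaningless.
    """

    D: float
    slope: float
    intercept: float
    r_squared: float
    curvature_fraction: float
    n_points: int

    @property
    def poor_fit(self) -> bool:
        return self.r_squared < 0.95 or self.curvature_fraction > 0.2


def msd_diffusion(
    frames: Sequence[TrajectoryFrame],
    species: str | Iterable[str] | None = None,
    fit_window: tuple[float, float] | None = None,
    overlapping: bool = False,
    max_lag: int | None = None,
) -> DiffusionFit:
    """Diffusion coefficient from the MSD slope: D = d⟨Δr²⟩/dt / 6, Å²/ns.

    ``fit_window`` restricts the fit to lag times in [t_min, t_max] ns and
    ``max_lag`` caps the number of lag points computed (default: the full
    available lag range); at least 10 lag points must remain.
    """
    lag_t, curve = msd(frames, species, overlapping, max_lag)
    if fit_window is not None:
        sel = (lag_t >= fit_window[0]) & (lag_t <= fit_window[1])
        lag_t, curve = lag_t[sel], curve[sel]
    if len(lag_t) < 10:
        raise ValueError(
            f"need >= 10 lag points in the fit window, got {len(lag_t)}"
        )
    slope, intercept = np.polyfit(lag_t, curve, 1)
    pred = slope * lag_t + intercept
    ss_res = float(np.sum((curve - pred) ** 2))
    ss_tot = float(np.sum((curve - np.mean(curve)) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    c2, c1, _ = np.polyfit(lag_t, curve, 2)
    span = lag_t[-1] - lag_t[0]
    rise = abs(c1) * span + abs(c2) * span**2
    curvature = abs(c2) * span**2 / rise if rise > 0 else 0.0
    return DiffusionFit(
        D=float(slope) / 6.0,
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r2,
        curvature_fraction=curvature,
        n_points=len(lag_t),
    )


def einstein_mobility(D: float, T: float, valence: int = 1) -> float:
    """Einstein relation μ = νeD/(k_B T), in Å²/(V·ns).

    With D in Å²/ns and T in K (e = 1 in internal units).
    """
    if T <= 0:
        raise ValueError(f"T must be > 0 K, got {T}")
    if valence < 1:
        raise ValueError("valence must be >= 1")
    return valence * D / (KB * T)
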