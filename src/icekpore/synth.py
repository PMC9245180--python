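"""Synthetic trajectories with closed-form ground truth.

The generators emit non-interacting overdamped-Langevin (ideal-gas Brownian)
walkers,

    x(t+Δt) = x(t) + v·Δt + sqrt(2DΔt)·N(0, 1),

in a periodic box centered on the origin, optionally excluded from a
cavity-decorated membrane slab (the membrane occupies |z| < L/2 minus the pore
lumen and the cavity void; moves ending inside the solid are reflected off the
nearest slab face, or rejected if the reflection fails).  Because the walkers
do not interact, every planted observable — per-species drift current, mass
flow, diffusion constant, wall-decaying induced-Debye-layer charge — has an
exact closed form, which is what makes the analysis operations testable
without running molecular dynamics.

Each generator returns ``(frames, ground_truth)`` where ``ground_truth`` is a
JSON-serialisable record of everything planted (including the seed); the same
spec reproduces the same trajectory bit for bit.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .continuum import CavitySide, PoreGeometry
from .trajectory import TrajectoryFrame

__all__ = [
    "SpeciesSpec",
    "IDLSpec",
    "SynthSpec",
    "default_box",
    "generate_drift_trajectory",
    "generate_idl_configuration",
    "generate_poiseuille_like_profile",
    "write_ground_truth",
    "read_ground_truth",
]


@dataclass(frozen=True)
class SpeciesSpec:
    """One particle species: count, charge (e), mass (Da), drift velocity
    (Å/ns, 3-vector), diffusion constant (Å²/ns)."""

    name: str
    count: int
    charge: float = 0.0
    mass: float = 20.0
    drift: tuple[float, float, float] = (0.0, 0.0, 0.0)
    diffusion: float = 0.0

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("count must be >= 0")
        if self.diffusion < 0:
            raise ValueError("diffusion constant must be >= 0")
        if self.mass <= 0:
            raise ValueError("mass must be > 0")


@dataclass(frozen=True)
class IDLSpec:
    """Planted induced-Debye-layer structure.

    ``lambda_D``: decay length (Å) of the wall-adjacent excess charge density
    ∝ exp(−(R−r)/λ_D) in the lumen; ``q_star``: magnitude (e) of the planted
    net lumen charge, realised as unit-charge carriers (the mirror excess of
    opposite sign is placed in the cavity void); ``background_pairs``: neutral
    ± ion pairs scattered uniformly through the fluid for counting noise.
    """

    lambda_D: float
    q_star: float = 2.0
    background_pairs: int = 200
    carrier_mass: float = 40.0

    def __post_init__(self) -> None:
        if self.lambda_D <= 0:
            raise ValueError("lambda_D must be > 0")
        if self.q_star < 0 or self.background_pairs < 0:
            raise ValueError("q_star and background_pairs must be >= 0")


def default_box(geom: PoreGeometry) -> tuple[float, float, float]:
    """Lateral box from the hexagonal apothem rule a_h = 2.1(R+s+w), mapped to
    a square cell of equal area (side a_h·(2√3)^½), with Lz = 2a_h + L."""
    a_h = 2.1 * (geom.R + geom.s + geom.w)
    side = a_h * math.sqrt(2.0 * math.sqrt(3.0))
    return (side, side, 2.0 * a_h + geom.L)


@dataclass(frozen=True)
class SynthSpec:
    """Full recipe for a synthetic trajectory.

    The box is centered on the origin; the membrane slab (when ``geometry``
    is given) spans |z| < L/2 with the cavity opening on the biased (−z) face
    by default.  ``dt`` is the frame interval in ns.
    """

    species: tuple[SpeciesSpec, ...]
    box: tuple[float, float, float] | None = None
    geometry: PoreGeometry | None = None
    idl: IDLSpec | None = None
    dt: float = 0.05
    n_frames: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.box is None and self.geometry is None:
            raise ValueError("either box or geometry must be given")
        if self.box is not None and any(b <= 0 for b in self.box):
            raise ValueError("box lengths must be > 0")

    @property
    def box_array(self) -> np.ndarray:
        box = self.box if self.box is not None else default_box(self.geometry)
        return np.asarray(box, dtype=float)


# ---------------------------------------------------------------------------
# membrane geometry helpers (box centered at origin, membrane at |z| < L/2)
# ---------------------------------------------------------------------------

def _cavity_z_range(geom: PoreGeometry) -> tuple[float, float]:
    # opening on the face the cavity points toward: biased face is z = -L/2
    if geom.cavity_side is CavitySide.FACING_BIASED_RESERVOIR:
        return (-geom.L / 2.0, -geom.L / 2.0 + geom.d)
    return (geom.L / 2.0 - geom.d, geom.L / 2.0)


def _in_solid(geom: PoreGeometry, pos: np.ndarray) -> np.ndarray:
    r = np.hypot(pos[:, 0], pos[:, 1])
    z = pos[:, 2]
    in_slab = np.abs(z) < geom.L / 2.0
    in_lumen = r < geom.R
    z_lo, z_hi = _cavity_z_range(geom)
    in_cavity = (
        (r >= geom.R + geom.s)
        & (r < geom.R + geom.s + geom.w)
        & (z >= z_lo)
        & (z < z_hi)
    )
    return in_slab & ~in_lumen & ~in_cavity


def _reflect_or_reject(
    geom: PoreGeometry, old: np.ndarray, new: np.ndarray
) -> np.ndarray:
    """Reflect moves that ended in the solid off the nearest slab face; keep
    the old position where the reflection is still inside the solid."""
    bad = _in_solid(geom, new)
    if not np.any(bad):
        return new
    reflected = new[bad].copy()
    z = reflected[:, 2]
    half = geom.L / 2.0
    reflected[:, 2] = np.where(z >= 0, geom.L - z, -geom.L - z)
    still_bad = _in_solid(geom, reflected)
    reflected[still_bad] = old[bad][still_bad]
    out = new.copy()
    out[bad] = reflected
    return out


def _uniform_fluid_positions(
    rng: np.random.Generator,
    n: int,
    box: np.ndarray,
    geom: PoreGeometry | None,
) -> np.ndarray:
    """Rejection-sample n positions uniformly over the non-solid volume."""
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        cand = (rng.random((max(2 * (n - filled), 64), 3)) - 0.5) * box
        if geom is not None:
            cand = cand[~_in_solid(geom, cand)]
        take = min(len(cand), n - filled)
        out[filled : filled + take] = cand[:take]
        filled += take
    return out


def _wrap(pos: np.ndarray, box: np.ndarray) -> np.ndarray:
    # subtract whole box shifts only: exact no-op for in-box coordinates
    return pos - box * np.floor((pos + box / 2.0) / box)


def _make_frame(
    time: float,
    box: np.ndarray,
    ids: np.ndarray,
    species: np.ndarray,
    charge: np.ndarray,
    mass: np.ndarray,
    pos: np.ndarray,
) -> TrajectoryFrame:
    return TrajectoryFrame(
        time=time,
        box=box.copy(),
        ids=ids,
        species=species,
        charge=charge,
        mass=mass,
        positions=pos.copy(),
    )


def _species_arrays(species: Sequence[SpeciesSpec]):
    n = sum(s.count for s in species)
    ids = np.arange(1, n + 1)
    labels = np.concatenate(
        [np.full(s.count, s.name, dtype=object) for s in species]
    ) if n else np.empty(0, dtype=object)
    charge = np.concatenate([np.full(s.count, s.charge) for s in species]) if n else np.empty(0)
    mass = np.concatenate([np.full(s.count, s.mass) for s in species]) if n else np.empty(0)
    drift = np.concatenate(
        [np.tile(np.asarray(s.drift, dtype=float), (s.count, 1)) for s in species]
    ) if n else np.empty((0, 3))
    diff = np.concatenate([np.full(s.count, s.diffusion) for s in species]) if n else np.empty(0)
    return ids, labels, charge, mass, drift, diff


def generate_drift_trajectory(
    spec: SynthSpec,
) -> tuple[list[TrajectoryFrame], dict]:
    """Brownian walkers with per-species planted drift.

    For a species of ``n`` particles of charge ``q`` drifting at ``v_z`` in a
    box of height ``Lz``, the planted axial current is exactly n·q·v_z/Lz and
    the planted mass flow n·m·v_z/Lz — the ground truth for the current and
    flow estimators.  These closed forms assume unobstructed walkers: when a
    membrane ``geometry`` is attached, reflections suppress the axial drift
    and the recorded ground-truth currents no longer apply.
    """
    box = spec.box_array
    rng = np.random.default_rng(spec.seed)
    ids, labels, charge, mass, drift, diff = _species_arrays(spec.species)
    pos = _uniform_fluid_positions(rng, len(ids), box, spec.geometry)
    sigma = np.sqrt(2.0 * diff * spec.dt)[:, None]

    frames = [_make_frame(0.0, box, ids, labels, charge, mass, pos)]
    for k in range(1, spec.n_frames):
        step = drift * spec.dt + sigma * rng.standard_normal(pos.shape)
        new = _wrap(pos + step, box)
        if spec.geometry is not None:
            new = _reflect_or_reject(spec.geometry, pos, new)
        pos = new
        frames.append(_make_frame(k * spec.dt, box, ids, labels, charge, mass, pos))

    lz = float(box[2])
    ground_truth = {
        "kind": "drift",
        "seed": spec.seed,
        "dt": spec.dt,
        "n_frames": spec.n_frames,
        "box": [float(b) for b in box],
        "species": [asdict(s) for s in spec.species],
        "current_per_species": {
            s.name: s.count * s.charge * s.drift[2] / lz for s in spec.species
        },
        "total_current": sum(
            s.count * s.charge * s.drift[2] / lz for s in spec.species
        ),
        "mass_flow": sum(s.count * s.mass * s.drift[2] / lz for s in spec.species),
    }
    return frames, ground_truth


def _sample_idl_radii(
    rng: np.random.Generator, n: int, R: float, lambda_D: float
) -> np.ndarray:
    """Radii in (0, R) with number density ∝ exp(−(R−r)/λ_D) (volume pdf
    ∝ r·exp(−(R−r)/λ_D)), via inverse sampling of the exponential factor plus
    rejection on the Jacobian r/R."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        m = max(2 * (n - filled), 64)
        u = rng.random(m)
        # depth below the wall, truncated exponential on [0, R]
        depth = -lambda_D * np.log1p(-u * (1.0 - np.exp(-R / lambda_D)))
        r = R - depth
        keep = rng.random(m) < r / R
        r = r[keep][: n - filled]
        out[filled : filled + len(r)] = r
        filled += len(r)
    return out


def generate_idl_configuration(
    spec: SynthSpec, delta_V_sign: int
) -> tuple[list[TrajectoryFrame], dict]:
    """Static configurations with a planted induced-Debye-layer charge.

    Each frame is an independent realisation: ``background_pairs`` neutral ±
    pairs uniform over the fluid, plus ``round(q_star)`` unit carriers of
    charge −sign(ΔV) in the lumen with wall-peaked radial density
    ∝ exp(−(R−r)/λ_D), mirrored by carriers of charge +sign(ΔV) uniform in
    the cavity void.  The planted net lumen charge −sign(ΔV)·q_star is exact
    in every frame.
    """
    if spec.geometry is None or spec.idl is None:
        raise ValueError("SynthSpec.geometry and SynthSpec.idl are required")
    if delta_V_sign not in (-1, 1):
        raise ValueError("delta_V_sign must be +1 or -1")
    geom = spec.geometry
    idl = spec.idl
    box = spec.box_array
    rng = np.random.default_rng(spec.seed)

    n_exc = int(round(idl.q_star))
    lumen_sign = -delta_V_sign
    n_bg = idl.background_pairs

    ids = np.arange(1, 2 * n_bg + 2 * n_exc + 1)
    labels = np.concatenate(
        [
            np.full(n_bg, "CAT", dtype=object),
            np.full(n_bg, "ANI", dtype=object),
            np.full(n_exc, "CAT" if lumen_sign > 0 else "ANI", dtype=object),
            np.full(n_exc, "CAT" if lumen_sign < 0 else "ANI", dtype=object),
        ]
    )
    charge = np.concatenate(
        [
            np.ones(n_bg),
            -np.ones(n_bg),
            np.full(n_exc, float(lumen_sign)),
            np.full(n_exc, float(-lumen_sign)),
        ]
    )
    mass = np.full(len(ids), idl.carrier_mass)

    z_lo, z_hi = _cavity_z_range(geom)
    frames = []
    for k in range(spec.n_frames):
        bg = _uniform_fluid_positions(rng, 2 * n_bg, box, geom)
        # lumen excess: wall-peaked radial density, uniform in z and angle
        r = _sample_idl_radii(rng, n_exc, geom.R, idl.lambda_D)
        theta = rng.random(n_exc) * 2.0 * np.pi
        z = (rng.random(n_exc) - 0.5) * geom.L
        lumen = np.column_stack((r * np.cos(theta), r * np.sin(theta), z))
        # cavity mirror: uniform over the annular void
        r2 = np.sqrt(
            rng.random(n_exc) * ((geom.R + geom.s + geom.w) ** 2 - (geom.R + geom.s) ** 2)
            + (geom.R + geom.s) ** 2
        )
        th2 = rng.random(n_exc) * 2.0 * np.pi
        zc = z_lo + rng.random(n_exc) * (z_hi - z_lo)
        cavity = np.column_stack((r2 * np.cos(th2), r2 * np.sin(th2), zc))
        pos = np.vstack((bg, lumen, cavity))
        frames.append(
            _make_frame(k * spec.dt, box, ids, labels, charge, mass, pos)
        )

    ground_truth = {
        "kind": "idl",
        "seed": spec.seed,
        "delta_V_sign": delta_V_sign,
        "lambda_D": idl.lambda_D,
        "q_lumen": float(lumen_sign * n_exc),
        "q_cavity": float(-lumen_sign * n_exc),
        "background_pairs": n_bg,
        "n_frames": spec.n_frames,
        "box": [float(b) for b in box],
    }
    return frames, ground_truth


_PROFILES = ("parabolic", "plug")


def generate_poiseuille_like_profile(
    spec: SynthSpec, v_max: float, profile: str = "parabolic"
) -> tuple[list[TrajectoryFrame], dict]:
    """Tracer particles inside the lumen with a radius-dependent axial drift.

    ``parabolic``: v_z(r) = v_max·(1 − (r/R)²); ``plug``: v_z(r) = v_max.
    The drift is re-evaluated at the current radius each step, walkers reflect
    off the cylinder wall and wrap axially, so the planted profile is the
    stationary ground truth for velocity-field extraction.
    """
    if spec.geometry is None:
        raise ValueError("SynthSpec.geometry is required")
    if profile not in _PROFILES:
        raise ValueError(f"profile must be one of {_PROFILES}, got {profile!r}")
    if not math.isfinite(v_max):
        raise ValueError("v_max must be finite")
    geom = spec.geometry
    box = spec.box_array
    rng = np.random.default_rng(spec.seed)
    ids, labels, charge, mass, _, diff = _species_arrays(spec.species)
    n = len(ids)

    # uniform over the lumen cylinder
    r0 = geom.R * np.sqrt(rng.random(n))
    th0 = rng.random(n) * 2.0 * np.pi
    pos = np.column_stack(
        (r0 * np.cos(th0), r0 * np.sin(th0), (rng.random(n) - 0.5) * geom.L)
    )
    sigma = np.sqrt(2.0 * diff * spec.dt)[:, None]

    def v_of_r(r: np.ndarray) -> np.ndarray:
        if profile == "plug":
            return np.full_like(r, v_max)
        return v_max * (1.0 - (r / geom.R) ** 2)

    frames = [_make_frame(0.0, box, ids, labels, charge, mass, pos)]
    for k in range(1, spec.n_frames):
        r = np.hypot(pos[:, 0], pos[:, 1])
        step = sigma * rng.standard_normal(pos.shape)
        step[:, 2] += v_of_r(r) * spec.dt
        new = pos + step
        # reflect radially at the cylinder wall
        rn = np.hypot(new[:, 0], new[:, 1])
        out = rn > geom.R
        if np.any(out):
            scale = (2.0 * geom.R - rn[out]) / rn[out]
            new[out, 0] *= np.abs(scale)
            new[out, 1] *= np.abs(scale)
        new[:, 2] = _wrap(new[:, [2]], box[[2]])[:, 0]
        pos = new
        frames.append(_make_frame(k * spec.dt, box, ids, labels, charge, mass, pos))

    ground_truth = {
        "kind": "profile",
        "seed": spec.seed,
        "profile": profile,
        "v_max": v_max,
        "R": geom.R,
        "n_frames": spec.n_frames,
        "species": [asdict(s) for s in spec.species],
    }
    return frames, ground_truth


def write_ground_truth(ground_truth: dict, path: str | Path) -> None:
    """Persist the planted-observable sidecar as JSON."""
    Path(path).write_text(json.dumps(ground_truth, indent=2, sort_keys=True) + "\n")


def read_ground_truth(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
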