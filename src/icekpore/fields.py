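"""Azimuthally averaged (r, z) fields and pore-region integrals.

MD observables around a cylindrical pore are naturally reported in
cylindrical coordinates: particles are binned on an (r, z) grid about the
pore axis, the azimuthal angle is averaged out, and densities are normalised
by the true annular bin volume π(r_out² − r_in²)Δz.  Velocity fields use
central-difference particle velocities and are averaged per bin; empty
velocity bins are masked (zero-filling would bias profile averages), while
empty density bins are legitimately zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .analysis import finite_difference_velocities
from .trajectory import TrajectoryFrame

__all__ = ["RegionSpec", "CylindricalField", "cylindrical_map", "charge_in_pore"]

_QUANTITIES = ("charge", "number", "mass", "velocity_z")


@dataclass(frozen=True)
class RegionSpec:
    """Pore-interior cylinder: r < radius, |z − origin_z| < half_thickness.

    ``axial_margin`` (Å) shrinks the axial extent on both sides; velocity
    profiles are conventionally extracted with a margin of ~2λ_D to exclude
    the entrance regions, while charge integrals use the full thickness.
    """

    radius: float
    half_thickness: float
    axial_margin: float = 0.0
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.radius <= 0 or self.half_thickness <= 0:
            raise ValueError("radius and half_thickness must be > 0")
        if not 0 <= self.axial_margin < self.half_thickness:
            raise ValueError("axial_margin must be in [0, half_thickness)")

    def mask(self, positions: np.ndarray) -> np.ndarray:
        ox, oy, oz = self.origin
        r = np.hypot(positions[:, 0] - ox, positions[:, 1] - oy)
        z = positions[:, 2] - oz
        return (r < self.radius) & (
            np.abs(z) < self.half_thickness - self.axial_margin
        )


@dataclass
class CylindricalField:
    """Azimuthally averaged field on an (r, z) grid.

    ``values`` holds a density (per Å³) for scalar quantities or a mean
    velocity component (Å/ns); ``counts`` are total particle samples per bin
    (summed over frames); ``volumes`` are the annular bin volumes.  Velocity
    bins with zero count are NaN and exposed via :attr:`masked_values`.
    """

    r_edges: np.ndarray
    z_edges: np.ndarray
    values: np.ndarray
    counts: np.ndarray
    quantity: str
    n_frames: int
    volumes: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.r_edges = np.asarray(self.r_edges, dtype=float)
        self.z_edges = np.asarray(self.z_edges, dtype=float)
        r2 = self.r_edges**2
        dz = np.diff(self.z_edges)
        self.volumes = np.pi * np.diff(r2)[:, None] * dz[None, :]
        if self.values.shape != self.volumes.shape:
            raise ValueError("values shape does not match bin grid")
        if np.any(self.counts < 0):
            raise ValueError("counts must be >= 0")

    @property
    def r_centers(self) -> np.ndarray:
        return 0.5 * (self.r_edges[:-1] + self.r_edges[1:])

    @property
    def z_centers(self) -> np.ndarray:
        return 0.5 * (self.z_edges[:-1] + self.z_edges[1:])

    @property
    def masked_values(self) -> np.ma.MaskedArray:
        return np.ma.masked_invalid(self.values)

    def radial_profile(self, z_range: tuple[float, float] | None = None) -> np.ndarray:
        """Count-weighted average over z (optionally restricted), per r bin."""
        sel = (
            slice(None)
            if z_range is None
            else (self.z_centers >= z_range[0]) & (self.z_centers <= z_range[1])
        )
        vals = self.values[:, sel]
        cnts = self.counts[:, sel]
        if self.quantity == "velocity_z":
            with np.errstate(invalid="ignore"):
                num = np.nansum(vals * cnts, axis=1)
            den = np.sum(cnts, axis=1)
            return np.where(den > 0, num / np.maximum(den, 1), np.nan)
        vols = self.volumes[:, sel]
        return np.sum(vals * vols, axis=1) / np.sum(vols, axis=1)


def _cyl_coords(
    positions: np.ndarray, origin: Sequence[float]
) -> tuple[np.ndarray, np.ndarray]:
    ox, oy, oz = origin
    r = np.hypot(positions[:, 0] - ox, positions[:, 1] - oy)
    return r, positions[:, 2] - oz


def cylindrical_map(
    frames: Sequence[TrajectoryFrame],
    quantity: str,
    r_edges: np.ndarray,
    z_edges: np.ndarray,
    origin: Sequence[float] = (0.0, 0.0, 0.0),
    species: str | None = None,
) -> CylindricalField:
    """Bin a trajectory onto an (r, z) grid and average over frames and α.

    ``quantity``: ``charge`` (e/Å³), ``number`` (Å⁻³), ``mass`` (Da/Å³) give
    time-averaged densities; ``velocity_z`` (Å/ns) gives the per-bin mean
    central-difference axial velocity (interior frames only, binned at the
    midpoint frame position), with empty bins set to NaN.
    """
    if quantity not in _QUANTITIES:
        raise ValueError(f"quantity must be one of {_QUANTITIES}, got {quantity!r}")
    if len(frames) == 0:
        raise ValueError("no frames given")
    r_edges = np.asarray(r_edges, dtype=float)
    z_edges = np.asarray(z_edges, dtype=float)
    shape = (len(r_edges) - 1, len(z_edges) - 1)
    counts = np.zeros(shape)
    accum = np.zeros(shape)

    if quantity == "velocity_z":
        if len(frames) < 3:
            raise ValueError("velocity maps need at least three frames")
        used = 0
        for prev, mid, nxt in zip(frames[:-2], frames[1:-1], frames[2:]):
            v = finite_difference_velocities(prev, mid, nxt)[:, 2]
            sel = mid.select(species) if species is not None else slice(None)
            r, z = _cyl_coords(mid.positions[sel], origin)
            c, _, _ = np.histogram2d(r, z, bins=(r_edges, z_edges))
            w, _, _ = np.histogram2d(r, z, bins=(r_edges, z_edges), weights=v[sel])
            counts += c
            accum += w
            used += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            values = np.where(counts > 0, accum / np.maximum(counts, 1), np.nan)
        return CylindricalField(r_edges, z_edges, values, counts, quantity, used)

    for frame in frames:
        sel = frame.select(species) if species is not None else slice(None)
        pos = frame.positions[sel]
        r, z = _cyl_coords(pos, origin)
        if quantity == "charge":
            weights = frame.charge[sel]
        elif quantity == "mass":
            weights = frame.mass[sel]
        else:
            weights = np.ones(len(pos))
        c, _, _ = np.histogram2d(r, z, bins=(r_edges, z_edges))
        w, _, _ = np.histogram2d(r, z, bins=(r_edges, z_edges), weights=weights)
        counts += c
        accum += w
    field_obj = CylindricalField(
        r_edges, z_edges, np.zeros(shape), counts, quantity, len(frames)
    )
    field_obj.values = accum / (len(frames) * field_obj.volumes)
    return field_obj


def charge_in_pore(
    source: Sequence[TrajectoryFrame] | CylindricalField, region: RegionSpec
) -> float:
    """Time-averaged net charge (e) inside the pore cylinder.

    Accepts either raw frames (direct summation of q_i over particles inside
    the region, averaged over frames) or a precomputed ``charge``
    :class:`CylindricalField` (integral of density × bin volume over bins
    whose centers fall inside the region — identical to the direct count when
    the bin grid tiles the region).
    """
    if isinstance(source, CylindricalField):
        if source.quantity != "charge":
            raise ValueError("field must be a charge-density map")
        rc = source.r_centers[:, None]
        zc = source.z_centers[None, :]
        inside = (rc < region.radius) & (
            np.abs(zc - region.origin[2])
            < region.half_thickness - region.axial_margin
        )
        return float(np.sum(source.values[inside] * source.volumes[inside]))
    frames = list(source)
    if not frames:
        raise ValueError("no frames given")
    for frame in frames:
        half_box = frame.box / 2.0
        if region.radius > min(half_box[0], half_box[1]) or (
            region.half_thickness > half_box[2]
        ):
            raise ValueError("region exceeds the simulation box")
    total = 0.0
    for frame in frames:
        mask = region.mask(frame.positions)
        total += float(np.sum(frame.charge[mask]))
    return total / len(frames)
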