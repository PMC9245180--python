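"""Particle-trajectory container and columnar text I/O.

A trajectory is a list of :class:`TrajectoryFrame` objects.  The native file
format is deliberately plain text so fixtures stay diffable:

    # frame t=<time_ns> n=<n_particles> box=<Lx> <Ly> <Lz>
    <id> <species> <charge_e> <mass_Da> <x_A> <y_A> <z_A>
    ...

one header line per frame followed by one whitespace-delimited row per
particle.  Lines starting with ``##`` are comments.  An adapter seam for
standard MD containers (MDAnalysis) is provided behind a lazy import so the
core never depends on it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

import numpy as np

__all__ = [
    "TrajectoryFrame",
    "TrajectoryFormatError",
    "read_trajectory",
    "write_trajectory",
    "iter_frames",
    "frames_from_mdanalysis",
]


class TrajectoryFormatError(ValueError):
    """Malformed native trajectory file; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


@dataclass
class TrajectoryFrame:
    """One snapshot: time (ns), periodic box (Lx, Ly, Lz in Å) and per-particle
    arrays id, species, charge (e), mass (Da), positions (N, 3) (Å)."""

    time: float
    box: np.ndarray
    ids: np.ndarray
    species: np.ndarray
    charge: np.ndarray
    mass: np.ndarray
    positions: np.ndarray

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        self.ids = np.asarray(self.ids)
        self.species = np.asarray(self.species)
        self.charge = np.asarray(self.charge, dtype=float)
        self.mass = np.asarray(self.mass, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        n = len(self.ids)
        if self.positions.shape != (n, 3):
            raise ValueError(
                f"positions must have shape ({n}, 3), got {self.positions.shape}"
            )
        for name in ("species", "charge", "mass"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length {len(getattr(self, name))} != {n}")
        if self.box.shape != (3,) or not np.all(self.box > 0):
            raise ValueError(f"box must be 3 positive lengths, got {self.box!r}")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError("positions must be finite")

    @property
    def n_particles(self) -> int:
        return len(self.ids)

    def select(self, species: str | Iterable[str]) -> np.ndarray:
        """Boolean mask for one species label or an iterable of labels."""
        if isinstance(species, str):
            return self.species == species
        labels = set(species)
        return np.array([s in labels for s in self.species], dtype=bool)


def write_trajectory(frames: Iterable[TrajectoryFrame], path: str | Path) -> None:
    """Write frames in the native columnar text format."""
    path = Path(path)
    with path.open("w") as fh:
        for frame in frames:
            bx, by, bz = frame.box
            fh.write(
                f"# frame t={frame.time:.9g} n={frame.n_particles} "
                f"box={bx:.9g} {by:.9g} {bz:.9g}\n"
            )
            for i in range(frame.n_particles):
                x, y, z = frame.positions[i]
                fh.write(
                    f"{frame.ids[i]} {frame.species[i]} {frame.charge[i]:.9g} "
                    f"{frame.mass[i]:.9g} {x:.9g} {y:.9g} {z:.9g}\n"
                )


def _parse_header(line: str, lineno: int) -> tuple[float, int, np.ndarray]:
    # "# frame t=<t> n=<n> box=<Lx> <Ly> <Lz>"
    tokens = line.split()
    try:
        if tokens[:2] != ["#", "frame"] or len(tokens) != 7:
            raise ValueError
        time = float(tokens[2].removeprefix("t="))
        n = int(tokens[3].removeprefix("n="))
        box = np.array(
            [float(tokens[4].removeprefix("box=")), float(tokens[5]), float(tokens[6])]
        )
        if n < 0:
            raise ValueError
    except (ValueError, IndexError) as exc:
        raise TrajectoryFormatError(
            f"malformed frame header {line.rstrip()!r}", lineno
        ) from exc
    return time, n, box


def iter_frames(handle: IO[str]) -> Iterator[TrajectoryFrame]:
    """Stream frames from an open text handle, validating as it goes."""
    lineno = 0
    line = handle.readline()
    lineno += 1
    while line:
        if line.startswith("##") or not line.strip():
            line = handle.readline()
            lineno += 1
            continue
        if not line.startswith("# frame"):
            raise TrajectoryFormatError(
                f"expected frame header, got {line.rstrip()!r}", lineno
            )
        time, n, box = _parse_header(line, lineno)
        ids, species, charge, mass, pos = [], [], [], [], []
        for _ in range(n):
            row = handle.readline()
            lineno += 1
            if not row:
                raise TrajectoryFormatError("unexpected end of file", lineno)
            parts = row.split()
            if len(parts) != 7:
                raise TrajectoryFormatError(
                    f"expected 7 columns, got {len(parts)}", lineno
                )
            try:
                ids.append(int(parts[0]))
                species.append(parts[1])
                charge.append(float(parts[2]))
                mass.append(float(parts[3]))
                pos.append([float(parts[4]), float(parts[5]), float(parts[6])])
            except ValueError as exc:
                raise TrajectoryFormatError(
                    f"malformed particle row {row.rstrip()!r}", lineno
                ) from exc
        yield TrajectoryFrame(
            time=time,
            box=box,
            ids=np.array(ids, dtype=int),
            species=np.array(species, dtype=object),
            charge=np.array(charge),
            mass=np.array(mass),
            positions=np.array(pos) if pos else np.empty((0, 3)),
        )
        line = handle.readline()
        lineno += 1


def read_trajectory(path: str | Path) -> list[TrajectoryFrame]:
    """Load a native columnar trajectory file."""
    with Path(path).open() as fh:
        return list(iter_frames(fh))


def frames_from_mdanalysis(universe, charges=None, masses=None) -> list[TrajectoryFrame]:
    """Adapter seam: convert an ``MDAnalysis.Universe`` into native frames.

    MDAnalysis is imported lazily; the rest of the package never depends on
    it.  ``charges``/``masses`` override topology attributes when the source
    format lacks them.  Times are converted ps → ns (MDAnalysis convention).
    """
    import MDAnalysis  # noqa: F401  (lazy; raises ImportError if absent)

    atoms = universe.atoms
    n = len(atoms)
    q = np.asarray(charges if charges is not None else atoms.charges, dtype=float)
    m = np.asarray(masses if masses is not None else atoms.masses, dtype=float)
    species = np.array([str(s) for s in atoms.names], dtype=object)
    try:
        ids = np.asarray(atoms.ids, dtype=int)
    except AttributeError:  # topologies without an id attribute
        ids = np.arange(1, n + 1)
    frames = []
    for ts in universe.trajectory:
        frames.append(
            TrajectoryFrame(
                time=float(ts.time) * 1e-3,
                box=np.asarray(ts.dimensions[:3], dtype=float),
                ids=ids.copy(),
                species=species.copy(),
                charge=q.copy(),
                mass=m.copy(),
                positions=np.asarray(ts.positions, dtype=float).copy(),
            )
        )
    return frames
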