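"""Domain types and readers/writers for trajectories and particle tables.

A :class:`Trajectory` stores per-frame coordinates (Å), box dimensions
(Å) and times (ps) as dense numpy arrays.  A :class:`ParticleTable`
assigns each particle a species label and a charge in elementary-charge
units; it is the bridge from topology to the transport estimators.

Supported trajectory dialects:

``table``
    A plain TSV dialect designed for text-only fixtures: per-frame box
    header lines followed by one ``frame  id  x  y  z`` row per particle
    per frame.
``dcd`` / ``xtc``
    Binary MD formats, delegated to MDAnalysis.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SPECIES_LABELS",
    "Frame",
    "Trajectory",
    "ParticleTable",
    "RunMeta",
    "TrajectoryParseError",
    "TrajectoryStructureError",
    "ParticleTableError",
    "read_trajectory",
    "write_trajectory",
    "read_particle_table",
    "write_particle_table",
    "FORMAT_PRECISION",
]

SPECIES_LABELS = ("cation", "anion", "water_oxygen", "other")

#: Maximum absolute coordinate deviation (Å) expected after a
#: write/read round trip, per format.  DCD stores float32; XTC stores
#: nm compressed at 1e-3 nm precision.
FORMAT_PRECISION = {"table": 1e-6, "dcd": 1e-3, "xtc": 2e-2}


class TrajectoryParseError(ValueError):
    """File cannot be parsed under the named dialect."""


class TrajectoryStructureError(ValueError):
    """Parsed data violates a structural invariant (e.g. varying particle count)."""


class ParticleTableError(ValueError):
    """Particle table fails validation."""


@dataclass(frozen=True)
class Frame:
    """A single snapshot: time (ps), coordinates (n, 3) Å, box (3,) Å."""

    time: float
    coords: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        box = np.asarray(self.box, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise TrajectoryStructureError(
                f"coords must have shape (n, 3), got {coords.shape}"
            )
        if box.shape != (3,) or not np.all(box > 0):
            raise TrajectoryStructureError(f"box lengths must be positive, got {box}")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "box", box)

    @property
    def n_particles(self) -> int:
        return self.coords.shape[0]


@dataclass
class Trajectory:
    """Ordered frames with constant particle count.

    Parameters
    ----------
    coords : (n_frames, n_particles, 3) array, Å
    box : (n_frames, 3) array, Å
    times : (n_frames,) array, ps, strictly increasing
    wrapped : whether coordinates are folded into the periodic box.
        Defaults to True — MD engines typically emit wrapped output;
        estimators then apply minimum-image displacement correction.
    """

    coords: np.ndarray
    box: np.ndarray
    times: np.ndarray
    wrapped: bool = True

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.box = np.asarray(self.box, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise TrajectoryStructureError(
                f"coords must have shape (n_frames, n_particles, 3), got {self.coords.shape}"
            )
        n_frames = self.coords.shape[0]
        if n_frames < 1:
            raise TrajectoryStructureError("trajectory needs at least one frame")
        if self.box.shape != (n_frames, 3):
            raise TrajectoryStructureError(
                f"box must have shape ({n_frames}, 3), got {self.box.shape}"
            )
        if not np.all(self.box > 0):
            raise TrajectoryStructureError("box lengths must be positive")
        if self.times.shape != (n_frames,):
            raise TrajectoryStructureError(
                f"times must have shape ({n_frames},), got {self.times.shape}"
            )
        if n_frames > 1 and not np.all(np.diff(self.times) > 0):
            raise TrajectoryStructureError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_particles(self) -> int:
        return self.coords.shape[1]

    @property
    def frame_interval(self) -> float:
        """Time between saved frames, ps; requires uniform spacing."""
        if self.n_frames < 2:
            raise TrajectoryStructureError(
                "frame_interval undefined for a single-frame trajectory"
            )
        dts = np.diff(self.times)
        if not np.allclose(dts, dts[0], rtol=1e-9, atol=1e-9):
            raise TrajectoryStructureError("frame times are not uniformly spaced")
        return float(dts[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def __len__(self) -> int:
        return self.n_frames

    def __getitem__(self, i: int) -> Frame:
        return Frame(time=float(self.times[i]), coords=self.coords[i], box=self.box[i])

    def __iter__(self) -> Iterator[Frame]:
        for i in range(self.n_frames):
            yield self[i]

    def discard_initial(self, discard: float) -> "Trajectory":
        """Return the trajectory with the first `discard` ps removed."""
        if discard < 0:
            raise ValueError("discard must be >= 0")
        if discard == 0:
            return self
        keep = self.times >= self.times[0] + discard
        if not np.any(keep):
            raise ValueError(
                f"discard of {discard} ps removes the whole trajectory "
                f"(duration {self.duration} ps)"
            )
        return replace(
            self, coords=self.coords[keep], box=self.box[keep], times=self.times[keep]
        )


@dataclass
class ParticleTable:
    """Per-particle identity: unique id, species label, charge (e).

    water_oxygen entries are count markers for the electroosmotic-flow
    estimator: one entry ≡ one water molecule, charge ignored there.
    """

    ids: np.ndarray
    species: np.ndarray
    charge: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=np.int64)
        self.species = np.asarray(self.species, dtype=object)
        self.charge = np.asarray(self.charge, dtype=float)
        n = len(self.ids)
        if len(self.species) != n or len(self.charge) != n:
            raise ParticleTableError("ids, species, charge must have equal length")
        if len(np.unique(self.ids)) != n:
            raise ParticleTableError("particle ids must be unique")
        bad = set(self.species) - set(SPECIES_LABELS)
        if bad:
            raise ParticleTableError(
                f"unknown species labels {sorted(bad)}; allowed: {list(SPECIES_LABELS)}"
            )
        ion = (self.species == "cation") | (self.species == "anion")
        if np.any(self.charge[ion] == 0):
            raise ParticleTableError("cation/anion charges must be nonzero")

    def __len__(self) -> int:
        return len(self.ids)

    def mask(self, species: str | Sequence[str]) -> np.ndarray:
        """Boolean selection mask for one species label or a sequence of them."""
        if isinstance(species, str):
            species = (species,)
        unknown = set(species) - set(SPECIES_LABELS)
        if unknown:
            raise ParticleTableError(
                f"unknown species {sorted(unknown)}; allowed: {list(SPECIES_LABELS)}"
            )
        return np.isin(self.species, list(species))

    def counts(self) -> dict[str, int]:
        return {s: int(np.sum(self.species == s)) for s in SPECIES_LABELS}


@dataclass
class RunMeta:
    """Per-run metadata: applied voltage (mV), equilibration discard (ps)."""

    voltage: float = 0.0
    discard: float = 0.0
    label: str = ""
    concentration: float | None = None  # mol/L, for conductivity sweeps

    def __post_init__(self) -> None:
        if self.discard < 0:
            raise ValueError("discard must be >= 0")


# ---------------------------------------------------------------------------
# plain-table trajectory dialect
# ---------------------------------------------------------------------------

_TABLE_MAGIC = "#poreflux-trajectory\tv1"


def _write_table(traj: Trajectory, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_TABLE_MAGIC + "\n")
        fh.write(f"#wrapped\t{str(traj.wrapped).lower()}\n")
        for i in range(traj.n_frames):
            t = float(traj.times[i])
            bx, by, bz = (float(v) for v in traj.box[i])
            fh.write(f"#box\t{i}\t{t!r}\t{bx!r}\t{by!r}\t{bz!r}\n")
        fh.write("frame\tid\tx\ty\tz\n")
        for i in range(traj.n_frames):
            for j in range(traj.n_particles):
                x, y, z = (float(v) for v in traj.coords[i, j])
                fh.write(f"{i}\t{j}\t{x!r}\t{y!r}\t{z!r}\n")


def _read_table(path: str) -> Trajectory:
    wrapped = True
    times: list[float] = []
    boxes: list[list[float]] = []
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if first != _TABLE_MAGIC:
            raise TrajectoryParseError(
                f"{path}: line 1 is not a poreflux trajectory table header"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.startswith("#"):
                break
            parts = line.rstrip("\n").split("\t")
            if parts[0] == "#wrapped":
                wrapped = parts[1] == "true"
            elif parts[0] == "#box":
                try:
                    times.append(float(parts[2]))
                    boxes.append([float(p) for p in parts[3:6]])
                except (IndexError, ValueError) as exc:
                    raise TrajectoryParseError(
                        f"{path}: malformed #box header at line {lineno}"
                    ) from exc
    if not boxes:
        raise TrajectoryParseError(f"{path}: no #box headers found")
    try:
        df = pd.read_csv(path, sep="\t", comment="#")
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise TrajectoryParseError(f"{path}: cannot parse data rows: {exc}") from exc
    required = {"frame", "id", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise TrajectoryParseError(
            f"{path}: data header must contain columns {sorted(required)}"
        )
    n_frames = len(boxes)
    counts = df.groupby("frame").size()
    if len(counts) != n_frames:
        raise TrajectoryStructureError(
            f"{path}: {len(counts)} data frames but {n_frames} #box headers"
        )
    if counts.nunique() != 1:
        raise TrajectoryStructureError(
            f"{path}: particle count changes between frames "
            f"(min {counts.min()}, max {counts.max()})"
        )
    n_particles = int(counts.iloc[0])
    df = df.sort_values(["frame", "id"], kind="stable")
    coords = df[["x", "y", "z"]].to_numpy(dtype=float).reshape(n_frames, n_particles, 3)
    return Trajectory(
        coords=coords,
        box=np.asarray(boxes, dtype=float),
        times=np.asarray(times, dtype=float),
        wrapped=wrapped,
    )


# ---------------------------------------------------------------------------
# binary dialects via MDAnalysis
# ---------------------------------------------------------------------------


def _write_mda(traj: Trajectory, path: str, fmt: str) -> None:
    import MDAnalysis as mda

    with mda.Writer(path, n_atoms=traj.n_particles, format=fmt.upper()) as wr:
        u = mda.Universe.empty(traj.n_particles, trajectory=True)
        for i in range(traj.n_frames):
            u.atoms.positions = traj.coords[i].astype(np.float32)
            u.dimensions = [*traj.box[i], 90.0, 90.0, 90.0]
            u.trajectory.ts.frame = i
            u.trajectory.ts.time = traj.times[i]
            u.trajectory.ts.dt = traj.frame_interval if traj.n_frames > 1 else 1.0
            wr.write(u.atoms)


def _read_mda(
    path: str, fmt: str, frame_interval: float | None, wrapped: bool
) -> Trajectory:
    if fmt == "dcd":
        from MDAnalysis.coordinates.DCD import DCDReader as Reader
    else:
        from MDAnalysis.coordinates.XTC import XTCReader as Reader

    try:
        reader = Reader(path)
    except Exception as exc:
        raise TrajectoryParseError(f"{path}: cannot open as {fmt}: {exc}") from exc
    coords, boxes, times = [], [], []
    try:
        for ts in reader:
            coords.append(ts.positions.astype(float).copy())
            if ts.dimensions is None or not np.all(ts.dimensions[:3] > 0):
                raise TrajectoryParseError(
                    f"{path}: frame {ts.frame} carries no box dimensions"
                )
            boxes.append(np.array(ts.dimensions[:3], dtype=float))
            times.append(float(ts.time))
    except TrajectoryParseError:
        raise
    except Exception as exc:
        raise TrajectoryParseError(
            f"{path}: truncated or corrupt near frame {len(coords)}: {exc}"
        ) from exc
    finally:
        reader.close()
    times_arr = np.asarray(times)
    if frame_interval is not None:
        times_arr = np.arange(len(coords)) * float(frame_interval)
    elif len(times) > 1 and not np.all(np.diff(times_arr) > 0):
        # header carried no usable time information
        times_arr = np.arange(len(coords), dtype=float)
    return Trajectory(
        coords=np.asarray(coords),
        box=np.asarray(boxes),
        times=times_arr,
        wrapped=wrapped,
    )


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------


def read_trajectory(
    path: str,
    format: str = "table",
    frame_interval: float | None = None,
    wrapped: bool | None = None,
) -> Trajectory:
    """Read a trajectory in one of the supported dialects.

    ``frame_interval`` (ps) overrides per-frame times from the file,
    which binary headers often lack.  ``wrapped`` overrides the stored
    wrapped flag (table dialect) or sets it (binary dialects, default
    True).
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if format == "table":
        traj = _read_table(path)
        if wrapped is not None:
            traj.wrapped = wrapped
        if frame_interval is not None:
            traj.times = np.arange(traj.n_frames) * float(frame_interval)
        return traj
    if format in ("dcd", "xtc"):
        return _read_mda(
            path, format, frame_interval, True if wrapped is None else wrapped
        )
    raise ValueError(f"unsupported trajectory format {format!r}; use dcd, xtc or table")


def write_trajectory(traj: Trajectory, path: str, format: str = "table") -> str:
    """Write a trajectory; round-trips through :func:`read_trajectory`
    within ``FORMAT_PRECISION[format]``."""
    if traj.n_frames < 1:
        raise TrajectoryStructureError("cannot write an empty trajectory")
    if format == "table":
        _write_table(traj, path)
    elif format in ("dcd", "xtc"):
        _write_mda(traj, path, format)
    else:
        raise ValueError(
            f"unsupported trajectory format {format!r}; use dcd, xtc or table"
        )
    return path


def read_particle_table(path: str) -> ParticleTable:
    """Read a TSV particle table with header columns id, species, charge."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"id", "species", "charge"}
    if not required.issubset(df.columns):
        raise ParticleTableError(
            f"{path}: header must contain columns {sorted(required)}"
        )
    charge = pd.to_numeric(df["charge"], errors="coerce")
    if charge.isna().any():
        rows = df.index[charge.isna()].tolist()[:5]
        raise ParticleTableError(f"{path}: non-numeric charge at rows {rows}")
    return ParticleTable(
        ids=df["id"].to_numpy(),
        species=df["species"].to_numpy(dtype=object),
        charge=charge.to_numpy(dtype=float),
    )


def write_particle_table(table: ParticleTable, path: str) -> str:
    pd.DataFrame(
        {"id": table.ids, "species": table.species, "charge": table.charge}
    ).to_csv(path, sep="\t", index=False)
    return path
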