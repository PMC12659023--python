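"""Cylindrical density maps and ensemble comparison statistics.

Pipeline: 3-D cubic-cell binning of a particle selection →
angular averaging about a (user-set or auto-detected) axis into an
(r, z) map → L2 map distance over a region of interest →
intra-/inter-group all-against-all comparison across replica sets.

The map distance between two maps f_i, f_j over a region of interest
(ROI) is the discrete form of

    d_ij = sqrt( ∫_ROI [f_i(r,z) − f_j(r,z)]² dr dz ).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Mapping, Sequence

import numpy as np

from .core_io import ParticleTable, Trajectory

__all__ = [
    "DensityGrid3D",
    "CylMap",
    "ROI",
    "GroupComparison",
    "bin_density",
    "to_cylindrical",
    "map_distance",
    "group_compare",
]


@dataclass
class DensityGrid3D:
    """Time-averaged particle density on a cubic-cell grid.

    ``density`` holds particles/Å³ per cell; multiplying by the cell
    volume and summing recovers the mean per-frame particle count of
    the selection exactly (count mode).
    """

    origin: np.ndarray  # (3,) Å
    cell: float  # cube edge, Å
    density: np.ndarray  # (nx, ny, nz), particles/Å³
    n_frames: int
    species: str = "all"

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.cell <= 0:
            raise ValueError("cell edge must be positive")
        if self.density.ndim != 3:
            raise ValueError("density must be a 3-D array")

    @property
    def cell_volume(self) -> float:
        return self.cell**3

    def total_count(self) -> float:
        """Mean per-frame particle count represented by the grid."""
        return float(self.density.sum() * self.cell_volume)


@dataclass
class CylMap:
    """(r, z)-binned mean density after angular averaging.

    ``values`` is (n_r, n_z); bins with no contributing Cartesian cells
    hold NaN (missing, not zero).  ``volumes`` records the Cartesian
    volume accumulated into each annular bin, used for exact mass
    bookkeeping.
    """

    r_edges: np.ndarray  # (n_r + 1,), starting at 0, Å
    z_edges: np.ndarray  # (n_z + 1,), Å
    values: np.ndarray  # (n_r, n_z)
    volumes: np.ndarray  # (n_r, n_z), Å³
    axis: tuple[float, float] = (0.0, 0.0)
    species: str = "all"

    def __post_init__(self) -> None:
        self.r_edges = np.asarray(self.r_edges, dtype=float)
        self.z_edges = np.asarray(self.z_edges, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.volumes = np.asarray(self.volumes, dtype=float)
        if self.r_edges[0] != 0:
            raise ValueError("r bins must start at 0")
        expected = (len(self.r_edges) - 1, len(self.z_edges) - 1)
        if self.values.shape != expected or self.volumes.shape != expected:
            raise ValueError("values/volumes shape must match bin edges")

    def same_binning(self, other: "CylMap") -> bool:
        return np.array_equal(self.r_edges, other.r_edges) and np.array_equal(
            self.z_edges, other.z_edges
        )

    def total_mass(self) -> float:
        """Σ value·accumulated volume over defined bins (exact bookkeeping)."""
        ok = ~np.isnan(self.values)
        return float(np.sum(self.values[ok] * self.volumes[ok]))

    def normalized(self, bulk_density: float) -> "CylMap":
        """Relative-concentration map: values divided by a bulk density."""
        if bulk_density <= 0:
            raise ValueError("bulk density must be positive")
        return CylMap(
            r_edges=self.r_edges,
            z_edges=self.z_edges,
            values=self.values / bulk_density,
            volumes=self.volumes,
            axis=self.axis,
            species=self.species,
        )


@dataclass(frozen=True)
class ROI:
    """Rectangular (r, z) region of interest, Å."""

    r_min: float
    r_max: float
    z_min: float
    z_max: float

    def __post_init__(self) -> None:
        if not (self.r_max > self.r_min >= 0 and self.z_max > self.z_min):
            raise ValueError("ROI ranges must have positive extent and r >= 0")


@dataclass
class GroupComparison:
    """All-against-all map-distance statistics.

    ``intra`` maps group name → (mean, error, n_comparisons) over the
    n(n−1)/2 unordered within-group pairs; ``inter`` maps (a, b) →
    the same over the n_a·n_b cross pairs.
    """

    intra: dict[str, tuple[float, float, int]]
    inter: dict[tuple[str, str], tuple[float, float, int]]


def bin_density(
    traj: Trajectory,
    particles: ParticleTable,
    species: str | Sequence[str] = "all",
    cell: float = 1.0,
    wrap: bool = True,
) -> DensityGrid3D:
    """Bin a species selection into cubic cells, averaged over frames.

    The grid spans the frame-0 box from the origin, with enough cells
    to cover each box edge.  With ``wrap`` (default) coordinates are
    folded into the box first; otherwise a particle outside the grid
    raises an error naming the particle and frame.
    """
    if len(particles) != traj.n_particles:
        raise ValueError("particle table length does not match trajectory")
    if species == "all":
        mask = np.ones(len(particles), dtype=bool)
    else:
        mask = particles.mask(species)
    if not np.any(mask):
        raise ValueError(f"no particles of species {species!r}")
    box = traj.box[0]
    shape = tuple(int(np.ceil(b / cell - 1e-9)) for b in box)
    counts = np.zeros(shape, dtype=float)
    upper = np.array(shape) * cell
    for f in range(traj.n_frames):
        xyz = traj.coords[f][mask]
        if wrap:
            xyz = np.mod(xyz, box)
        elif np.any((xyz < 0) | (xyz >= upper)):
            bad = np.argwhere((xyz < 0) | (xyz >= upper))[0][0]
            pid = particles.ids[mask][bad]
            raise ValueError(
                f"particle id {pid} outside the grid at frame {f} and wrapping disabled"
            )
        idx = np.minimum((xyz / cell).astype(int), np.array(shape) - 1)
        np.add.at(counts, (idx[:, 0], idx[:, 1], idx[:, 2]), 1.0)
    density = counts / (traj.n_frames * cell**3)
    label = species if isinstance(species, str) else "+".join(species)
    return DensityGrid3D(
        origin=np.zeros(3),
        cell=cell,
        density=density,
        n_frames=traj.n_frames,
        species=label,
    )


def to_cylindrical(
    grid: DensityGrid3D,
    axis: tuple[float, float],
    r_bin: float = 1.0,
    z_bin: float = 1.0,
    refine: int = 1,
) -> CylMap:
    """Angular average of a Cartesian grid about a z-aligned axis.

    Each (r, z) value is the volume-weighted mean density of the
    Cartesian (sub)cells whose centers fall in that annulus, so a
    uniform grid maps to a uniform (r, z) map regardless of r.
    ``refine`` > 1 splits each cell into refine³ subcells for a finer
    Jacobian (cell-center assignment is exact only in the limit).
    Annuli receiving no cells are NaN.
    """
    if r_bin <= 0 or z_bin <= 0:
        raise ValueError("r_bin and z_bin must be positive")
    if refine < 1:
        raise ValueError("refine must be >= 1")
    nx, ny, nz = grid.density.shape
    x0, y0 = axis
    c = grid.cell
    lx, ly = nx * c, ny * c
    if not (grid.origin[0] <= x0 <= grid.origin[0] + lx) or not (
        grid.origin[1] <= y0 <= grid.origin[1] + ly
    ):
        raise ValueError("axis lies outside the grid footprint")

    # (sub)cell centers along each axis
    sub = (np.arange(refine) + 0.5) / refine * c
    cx = (grid.origin[0] + np.arange(nx)[:, None] * c + sub[None, :]).ravel()
    cy = (grid.origin[1] + np.arange(ny)[:, None] * c + sub[None, :]).ravel()
    cz = (grid.origin[2] + np.arange(nz)[:, None] * c + sub[None, :]).ravel()

    r = np.sqrt((cx[:, None] - x0) ** 2 + (cy[None, :] - y0) ** 2)  # (nx*rf, ny*rf)
    r_idx = (r / r_bin).astype(int)
    z_idx = ((cz - grid.origin[2]) / z_bin).astype(int)
    n_r = int(r_idx.max()) + 1
    n_z = int(z_idx.max()) + 1

    subvol = (c / refine) ** 3
    dens = np.repeat(
        np.repeat(np.repeat(grid.density, refine, 0), refine, 1), refine, 2
    )
    flat_rz = (r_idx[:, :, None] * n_z + z_idx[None, None, :]).ravel()
    wsum = np.bincount(flat_rz, minlength=n_r * n_z).astype(float) * subvol
    vsum = np.bincount(flat_rz, weights=dens.ravel(), minlength=n_r * n_z) * subvol
    with np.errstate(invalid="ignore"):
        values = np.where(wsum > 0, vsum / np.where(wsum > 0, wsum, 1.0), np.nan)
    return CylMap(
        r_edges=np.arange(n_r + 1) * r_bin,
        z_edges=grid.origin[2] + np.arange(n_z + 1) * z_bin,
        values=values.reshape(n_r, n_z),
        volumes=wsum.reshape(n_r, n_z),
        axis=(x0, y0),
        species=grid.species,
    )


def _roi_mask(m: CylMap, roi: ROI) -> np.ndarray:
    r_centers = 0.5 * (m.r_edges[:-1] + m.r_edges[1:])
    z_centers = 0.5 * (m.z_edges[:-1] + m.z_edges[1:])
    rm = (r_centers >= roi.r_min) & (r_centers <= roi.r_max)
    zm = (z_centers >= roi.z_min) & (z_centers <= roi.z_max)
    return rm[:, None] & zm[None, :]


def map_distance(f_i: CylMap, f_j: CylMap, roi: ROI) -> float:
    """L2 distance √(Σ_ROI [f_i − f_j]²·Δr·Δz) between two maps.

    Maps must share bin geometry exactly (no implicit regridding).
    Bins missing in either map are excluded pairwise, removing their
    area from the integral.
    """
    if not f_i.same_binning(f_j):
        raise ValueError("maps have mismatched binning; regrid explicitly")
    mask = _roi_mask(f_i, roi)
    if not np.any(mask):
        raise ValueError("ROI selects no bins on this map")
    dr = np.diff(f_i.r_edges)[:, None]
    dz = np.diff(f_i.z_edges)[None, :]
    ok = mask & ~np.isnan(f_i.values) & ~np.isnan(f_j.values)
    diff2 = (f_i.values - f_j.values) ** 2
    return float(np.sqrt(np.sum(diff2[ok] * (dr * dz)[ok])))


def _pair_stats(distances: list[float]) -> tuple[float, float, int]:
    n = len(distances)
    arr = np.asarray(distances)
    mean = float(arr.mean())
    err = float(np.std(arr, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return mean, err, n


def group_compare(
    groups: Mapping[str, Sequence[CylMap]], roi: ROI
) -> GroupComparison:
    """Intra- and inter-group mean map distances over replica sets.

    Intra statistics are over the n(n−1)/2 unordered within-group
    pairs (skipped with a zero count for singleton groups); inter
    statistics are over all n_a·n_b cross pairs.  Errors are the
    standard deviation of the pair distances over √(n comparisons).
    """
    for name, maps in groups.items():
        if len(maps) < 1:
            raise ValueError(f"group {name!r} is empty")
    intra: dict[str, tuple[float, float, int]] = {}
    for name, maps in groups.items():
        if len(maps) < 2:
            intra[name] = (float("nan"), float("nan"), 0)
            continue
        dists = [map_distance(a, b, roi) for a, b in combinations(maps, 2)]
        intra[name] = _pair_stats(dists)
    inter: dict[tuple[str, str], tuple[float, float, int]] = {}
    for name_a, name_b in combinations(groups.keys(), 2):
        dists = [
            map_distance(a, b, roi)
            for a in groups[name_a]
            for b in groups[name_b]
        ]
        inter[(name_a, name_b)] = _pair_stats(dists)
    return GroupComparison(intra=intra, inter=inter)
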