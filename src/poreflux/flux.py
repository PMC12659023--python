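"""Windowed ionic currents, electroosmotic water flux, and error estimation.

The current in a window [t, t+τ] is the charge-weighted sum of axial
displacements divided by τ·Lz,

    I(t) = (1 / (τ·Lz)) Σ_i q_i [z_i(t+τ) − z_i(t)],

converted from e/ps to nA.  Displacements of wrapped trajectories are
minimum-image corrected per consecutive saved frame pair and then
summed to span τ, which is robust to fast particles.  The water flux
uses the same displacement sum over water-oxygen particles with unit
weights, reported in molecules/ns.

Errors come from a block-average protocol on the window trace, or from
the spread of replica means when several independent runs exist.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import units
from .core_io import ParticleTable, Trajectory

__all__ = [
    "CurrentTrace",
    "FlowEstimate",
    "SelectivityIndicator",
    "AmbiguousDisplacementError",
    "windowed_current",
    "species_currents",
    "water_flux",
    "block_error",
    "replica_aggregate",
    "selectivity_indicator",
]


class AmbiguousDisplacementError(ValueError):
    """A minimum-image displacement is exactly Lz/2: direction undecidable.

    Save frames more densely so per-frame displacements stay below
    half the box height.
    """


@dataclass
class CurrentTrace:
    """Time series of windowed currents (nA) or fluxes (molecules/ns)."""

    times: np.ndarray  # window start times, ps
    values: np.ndarray
    species: str  # all | cation | anion | water
    tau: float  # window length, ps
    units: str = "nA"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal length")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class FlowEstimate:
    """Aggregated mean ± error of a current or flux."""

    mean: float
    error: float
    n: int  # blocks or replicas behind the error bar
    units: str = "nA"
    discard: float = 0.0  # ps of initial trajectory excluded

    def __post_init__(self) -> None:
        if self.error < 0:
            raise ValueError("error must be >= 0")


@dataclass
class SelectivityIndicator:
    """Cation/anion selectivity: current difference (robust) and ratio."""

    difference: float
    difference_error: float
    ratio: float
    ratio_error: float
    ratio_reliable: bool
    units: str = "nA"


def _window_displacements(
    traj: Trajectory, stride: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Sum per-frame-pair z displacements into non-overlapping windows.

    Returns (dz_sums (n_windows, n_particles), lz (n_windows,),
    window start times (n_windows,)).
    """
    z = traj.coords[:, :, 2]
    lz_pair = traj.box[:-1, 2]  # box of the window's first frame
    dz = np.diff(z, axis=0)
    if traj.wrapped:
        dz = dz - lz_pair[:, None] * np.round(dz / lz_pair[:, None])
        if np.any(np.abs(dz) == lz_pair[:, None] / 2.0):
            raise AmbiguousDisplacementError(
                "a displacement equals exactly Lz/2 after minimum-image "
                "correction; save frames more densely"
            )
    n_windows = dz.shape[0] // stride
    if n_windows < 1:
        raise ValueError(
            f"trajectory too short: {dz.shape[0]} frame pairs < stride {stride}"
        )
    dz = dz[: n_windows * stride].reshape(n_windows, stride, -1).sum(axis=1)
    lz = traj.box[0 : n_windows * stride : stride, 2]
    starts = traj.times[0 : n_windows * stride : stride]
    return dz, lz, starts


def _resolve_stride(traj: Trajectory, tau: float) -> int:
    dt = traj.frame_interval
    stride = tau / dt
    if abs(stride - round(stride)) > 1e-9 or round(stride) < 1:
        raise ValueError(
            f"tau = {tau} ps is not a positive multiple of the frame interval {dt} ps"
        )
    return int(round(stride))


def windowed_current(
    traj: Trajectory,
    particles: ParticleTable,
    tau: float,
    species_filter: str = "all",
    include_all_charges: bool = False,
) -> CurrentTrace:
    """Charge-displacement current trace, one value per τ window, in nA.

    ``species_filter`` is one of all | cation | anion.  By default
    "all" restricts the sum to ions (cation + anion); membrane/protein
    charges are typically constrained in the source simulations.  Pass
    ``include_all_charges=True`` to sum every charged particle.
    """
    if len(particles) != traj.n_particles:
        raise ValueError(
            f"particle table has {len(particles)} entries but trajectory "
            f"has {traj.n_particles} particles"
        )
    if species_filter == "all":
        mask = (
            np.ones(len(particles), dtype=bool)
            if include_all_charges
            else particles.mask(("cation", "anion"))
        )
    elif species_filter in ("cation", "anion"):
        mask = particles.mask(species_filter)
    else:
        raise ValueError(
            f"species_filter must be all, cation or anion, got {species_filter!r}"
        )
    stride = _resolve_stride(traj, tau)
    dz, lz, starts = _window_displacements(traj, stride)
    if not np.any(mask):
        warnings.warn(
            f"no particles match species filter {species_filter!r}; trace is zero",
            stacklevel=2,
        )
        values = np.zeros(len(starts))
    else:
        q = particles.charge[mask]
        values = (dz[:, mask] @ q) / (tau * lz) * units.E_PER_PS_TO_NA
    return CurrentTrace(
        times=starts, values=values, species=species_filter, tau=tau, units="nA"
    )


def species_currents(
    traj: Trajectory,
    particles: ParticleTable,
    tau: float,
    include_all_charges: bool = False,
) -> dict[str, CurrentTrace]:
    """Total, cationic and anionic current traces.

    The per-window identity I_all = I_cation + I_anion (+ others when
    ``include_all_charges``) holds to float round-off.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {
            "all": windowed_current(
                traj, particles, tau, "all", include_all_charges=include_all_charges
            ),
            "cation": windowed_current(traj, particles, tau, "cation"),
            "anion": windowed_current(traj, particles, tau, "anion"),
        }


def water_flux(traj: Trajectory, particles: ParticleTable, tau: float) -> CurrentTrace:
    """Electroosmotic water flux trace in molecules/ns.

    Sums axial displacements over water-oxygen particles (one particle
    per molecule, charge ignored) and divides by τ·Lz.
    """
    if len(particles) != traj.n_particles:
        raise ValueError("particle table length does not match trajectory")
    mask = particles.mask("water_oxygen")
    if not np.any(mask):
        raise ValueError("no water_oxygen particles in the table")
    stride = _resolve_stride(traj, tau)
    dz, lz, starts = _window_displacements(traj, stride)
    values = dz[:, mask].sum(axis=1) / (tau * lz) * units.PER_PS_TO_PER_NS
    return CurrentTrace(
        times=starts, values=values, species="water", tau=tau, units="molecules/ns"
    )


def block_error(trace: CurrentTrace, block: float, discard: float = 0.0) -> FlowEstimate:
    """Mean of the retained trace with a block-average error bar.

    Windows starting before ``discard`` ps (relative to the trace
    start) are dropped; the rest are grouped into consecutive blocks of
    ``block`` ps, the incomplete trailing block is dropped, and the
    error is the sample standard deviation of the block means divided
    by √(number of complete blocks).
    """
    if block <= 0:
        raise ValueError("block must be positive")
    keep = trace.times >= trace.times[0] + discard if len(trace) else np.array([], bool)
    values = trace.values[keep]
    per_block = block / trace.tau
    if abs(per_block - round(per_block)) > 1e-9 or round(per_block) < 1:
        raise ValueError(
            f"block = {block} ps is not a positive multiple of tau = {trace.tau} ps"
        )
    m = int(round(per_block))
    n_blocks = len(values) // m
    if n_blocks < 2:
        raise ValueError(
            f"need >= 2 complete blocks of {block} ps after discarding "
            f"{discard} ps; have {len(values)} windows of {trace.tau} ps "
            f"({n_blocks} complete blocks) — provide at least "
            f"{discard + 2 * block} ps of trace"
        )
    block_means = values[: n_blocks * m].reshape(n_blocks, m).mean(axis=1)
    error = float(np.std(block_means, ddof=1) / np.sqrt(n_blocks))
    return FlowEstimate(
        mean=float(values.mean()),
        error=error,
        n=n_blocks,
        units=trace.units,
        discard=discard,
    )


def replica_aggregate(estimates: list[FlowEstimate]) -> FlowEstimate:
    """Combine independent replicas: mean of means, error = std/√n."""
    if not estimates:
        raise ValueError("no replica estimates supplied")
    if len({e.units for e in estimates}) > 1:
        raise ValueError("replica estimates have mixed units")
    if len(estimates) == 1:
        warnings.warn(
            "single replica: falling back to its block error", stacklevel=2
        )
        e = estimates[0]
        return FlowEstimate(
            mean=e.mean, error=e.error, n=1, units=e.units, discard=e.discard
        )
    means = np.array([e.mean for e in estimates])
    return FlowEstimate(
        mean=float(means.mean()),
        error=float(np.std(means, ddof=1) / np.sqrt(len(means))),
        n=len(means),
        units=estimates[0].units,
        discard=estimates[0].discard,
    )


def selectivity_indicator(
    cation: FlowEstimate, anion: FlowEstimate
) -> SelectivityIndicator:
    """Cation−anion current difference (errors in quadrature) and the
    |I₊|/|I₋| ratio, flagged unreliable when either current is
    statistically indistinguishable from zero."""
    from .rescale import is_negligible

    if cation.units != anion.units:
        raise ValueError("cation and anion estimates must share units")
    diff = cation.mean - anion.mean
    diff_err = float(np.hypot(cation.error, anion.error))
    unreliable = is_negligible(cation) or is_negligible(anion)
    if anion.mean == 0:
        ratio, ratio_err, reliable = float("nan"), float("nan"), False
    else:
        ratio = abs(cation.mean) / abs(anion.mean)
        ratio_err = ratio * float(
            np.hypot(
                cation.error / abs(cation.mean) if cation.mean else np.inf,
                anion.error / abs(anion.mean),
            )
        )
        reliable = not unreliable
    return SelectivityIndicator(
        difference=diff,
        difference_error=diff_err,
        ratio=ratio,
        ratio_error=ratio_err,
        ratio_reliable=reliable,
        units=cation.units,
    )
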