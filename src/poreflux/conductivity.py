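"""I–V curve assembly, conductance fitting, and electrolyte conductivity.

The driving field follows from the applied voltage, E_z = ΔV/Lz; the
conductance G is the (by default through-origin, error-weighted) slope
of the I–V curve; and the geometry-independent conductivity is
σ = G·Lz/(Lx·Ly), reported in S/m.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from . import units
from .core_io import ParticleTable, RunMeta, Trajectory
from .flux import block_error, species_currents

__all__ = [
    "IVCurve",
    "ConductivityResult",
    "field_from_voltage",
    "fit_conductance",
    "conductivity_from_conductance",
    "concentration_mol_per_L",
    "conductivity_sweep",
]


@dataclass
class IVCurve:
    """Current–voltage points (ΔV mV, I nA, error nA) plus box geometry (Å)."""

    voltages: np.ndarray
    currents: np.ndarray
    errors: np.ndarray | None = None
    geometry: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.currents = np.asarray(self.currents, dtype=float)
        if self.errors is not None:
            self.errors = np.asarray(self.errors, dtype=float)
            if self.errors.shape != self.voltages.shape:
                raise ValueError("errors must match voltages in length")
        if self.voltages.shape != self.currents.shape:
            raise ValueError("voltages and currents must have equal length")
        if len(np.unique(self.voltages)) != len(self.voltages):
            raise ValueError("voltage values must be distinct")
        if self.geometry is not None and not all(g > 0 for g in self.geometry):
            raise ValueError("geometry must be positive")


@dataclass
class ConductivityResult:
    """Conductance and conductivity at one salt concentration."""

    concentration: float  # mol/L
    conductance: float  # nS
    conductance_error: float
    sigma: float  # S/m
    sigma_error: float
    species: str = "all"


def field_from_voltage(voltage: float, lz: float) -> float:
    """Uniform axial field (mV/Å) equivalent to voltage ΔV (mV) over Lz (Å)."""
    if lz <= 0:
        raise ValueError("Lz must be positive")
    return voltage / lz


def fit_conductance(iv: IVCurve, through_origin: bool = True) -> tuple[float, float]:
    """Weighted least-squares conductance from an I–V curve.

    Returns (G, error) in nS.  Weights are 1/error² when per-point
    errors are available, else unweighted.  ``through_origin``
    constrains the intercept to zero (the default: a symmetric bulk
    electrolyte conducts no current at zero bias).
    """
    v, i = iv.voltages, iv.currents
    n_min = 1 if through_origin else 2
    if len(v) < n_min:
        raise ValueError(f"need >= {n_min} points for this fit")
    if np.allclose(v, v[0]) and len(v) > 1:
        raise ValueError("singular design: all voltages equal")
    have_err = iv.errors is not None and np.all(iv.errors > 0)
    w = 1.0 / iv.errors**2 if have_err else np.ones_like(v)
    if through_origin:
        svv = np.sum(w * v * v)
        if svv == 0:
            raise ValueError("singular design: all voltages zero")
        slope = np.sum(w * v * i) / svv
        if have_err:
            slope_err = np.sqrt(1.0 / svv)
        elif len(v) > 1:
            resid = i - slope * v
            slope_err = np.sqrt(np.sum(resid**2) / (len(v) - 1) / svv)
        else:
            slope_err = 0.0
    else:
        sw, sv, si = np.sum(w), np.sum(w * v), np.sum(w * i)
        svv, svi = np.sum(w * v * v), np.sum(w * v * i)
        delta = sw * svv - sv**2
        if delta == 0:
            raise ValueError("singular design")
        slope = (sw * svi - sv * si) / delta
        if have_err:
            slope_err = np.sqrt(sw / delta)
        elif len(v) > 2:
            intercept = (svv * si - sv * svi) / delta
            resid = i - slope * v - intercept
            s2 = np.sum(resid**2) / (len(v) - 2)
            slope_err = np.sqrt(s2 * sw / delta)
        else:
            slope_err = 0.0
    # slope in nA/mV; conductance in nS = nA/V
    return (
        float(slope * units.NA_PER_MV_TO_NS),
        float(slope_err * units.NA_PER_MV_TO_NS),
    )


def conductivity_from_conductance(
    conductance: float,
    geometry: tuple[float, float, float],
    conductance_error: float = 0.0,
) -> tuple[float, float]:
    """σ = G·Lz/(Lx·Ly) with G in nS, geometry in Å; returns (σ, error) S/m."""
    lx, ly, lz = geometry
    if min(lx, ly, lz) <= 0:
        raise ValueError("geometry must be positive")
    factor = lz / (lx * ly) * units.NS_PER_A_TO_S_PER_M
    return conductance * factor, conductance_error * factor


def concentration_mol_per_L(particles: ParticleTable, box: np.ndarray) -> float:
    """Salt concentration (mol/L) from cation count and box volume (Å)."""
    n_pairs = particles.counts()["cation"]
    volume = float(np.prod(np.asarray(box, dtype=float)))
    return n_pairs / volume * units.PER_A3_TO_MOL_PER_L


def conductivity_sweep(
    runs: list[tuple[Trajectory, ParticleTable, RunMeta]],
    geometry: tuple[float, float, float],
    tau: float,
    block: float,
    through_origin: bool = True,
) -> list[ConductivityResult]:
    """Total, cationic and anionic conductivity per salt concentration.

    Each run contributes one I–V point at its voltage; runs are grouped
    by the concentration recorded in their :class:`RunMeta` (computed
    from counts and geometry when absent).  Concentrations with fewer
    than two distinct voltages are skipped with a warning.
    """
    by_conc: dict[float, list[tuple[Trajectory, ParticleTable, RunMeta]]] = {}
    for traj, particles, meta in runs:
        conc = meta.concentration
        if conc is None:
            conc = concentration_mol_per_L(particles, traj.box[0])
        by_conc.setdefault(round(conc, 9), []).append((traj, particles, meta))

    results: list[ConductivityResult] = []
    for conc in sorted(by_conc):
        group = by_conc[conc]
        voltages = {meta.voltage for _, _, meta in group}
        if len(voltages) < 2:
            warnings.warn(
                f"concentration {conc} mol/L has < 2 distinct voltages; skipped",
                stacklevel=2,
            )
            continue
        points: dict[str, list[tuple[float, float, float]]] = {
            "all": [],
            "cation": [],
            "anion": [],
        }
        for traj, particles, meta in group:
            work = traj.discard_initial(meta.discard) if meta.discard else traj
            traces = species_currents(work, particles, tau)
            for sp, trace in traces.items():
                est = block_error(trace, block)
                points[sp].append((meta.voltage, est.mean, est.error))
        for sp, pts in points.items():
            arr = np.array(pts)
            iv = IVCurve(
                voltages=arr[:, 0],
                currents=arr[:, 1],
                errors=arr[:, 2] if np.all(arr[:, 2] > 0) else None,
                geometry=geometry,
            )
            g, g_err = fit_conductance(iv, through_origin=through_origin)
            sigma, sigma_err = conductivity_from_conductance(g, geometry, g_err)
            results.append(
                ConductivityResult(
                    concentration=conc,
                    conductance=g,
                    conductance_error=g_err,
                    sigma=sigma,
                    sigma_error=sigma_err,
                    species=sp,
                )
            )
    return results
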