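"""End-to-end orchestration: manifests of runs → aggregated report tables.

A manifest lists one row per (trajectory, particle table, voltage,
replica, group); the pipeline applies the discard, computes windowed
species currents and water flux with block errors per run, then
aggregates replicas per (group, voltage).  The result is deterministic
given the inputs and equals manual composition of the module
operations (no hidden state).
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_io import read_particle_table, read_trajectory
from .flux import (
    FlowEstimate,
    block_error,
    replica_aggregate,
    species_currents,
    water_flux,
)

logger = logging.getLogger("poreflux.pipeline")

__all__ = ["AnalysisConfig", "RunManifest", "ReportTable", "run_manifest", "emit_report", "read_report"]

MANIFEST_COLUMNS = ["traj", "particles", "voltage_mV", "replica", "group"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Estimator parameters; defaults follow nanopore convention
    (τ = 20 ps windows, 10 ns blocks, 10 ns equilibration discard)."""

    tau: float = 20.0  # ps
    block: float = 10_000.0  # ps
    discard: float = 10_000.0  # ps
    traj_format: str = "table"
    frame_interval: float | None = None
    positive_current_direction: str = "trans_to_cis"  # logged sign convention


@dataclass
class RunManifest:
    """Tabular index of runs; extra columns (traj_format, concentration)
    are optional."""

    rows: pd.DataFrame

    def __post_init__(self) -> None:
        missing = set(MANIFEST_COLUMNS) - set(self.rows.columns)
        if missing:
            raise ValueError(f"manifest missing columns {sorted(missing)}")
        key = self.rows[["group", "voltage_mV", "replica"]]
        if key.duplicated().any():
            dup = key[key.duplicated()].iloc[0].tolist()
            raise ValueError(f"duplicate (group, voltage, replica) combination {dup}")

    @classmethod
    def from_tsv(cls, path: str) -> "RunManifest":
        return cls(rows=pd.read_csv(path, sep="\t", comment="#"))

    def __len__(self) -> int:
        return len(self.rows)


@dataclass
class ReportTable:
    """Aggregated per-(group, voltage) transport estimates."""

    rows: pd.DataFrame

    COLUMNS = [
        "group",
        "voltage_mV",
        "n_replicas",
        "I_total_nA",
        "I_total_err",
        "I_cation_nA",
        "I_cation_err",
        "I_anion_nA",
        "I_anion_err",
        "eof_per_ns",
        "eof_err",
    ]


def _estimate_row(
    traj_path: str,
    particles_path: str,
    config: AnalysisConfig,
    traj_format: str,
) -> dict[str, FlowEstimate | None]:
    traj = read_trajectory(
        traj_path, format=traj_format, frame_interval=config.frame_interval
    )
    particles = read_particle_table(particles_path)
    traces = species_currents(traj, particles, config.tau)
    out: dict[str, FlowEstimate | None] = {
        sp: block_error(trace, config.block, config.discard)
        for sp, trace in traces.items()
    }
    if np.any(particles.mask("water_oxygen")):
        out["water"] = block_error(
            water_flux(traj, particles, config.tau), config.block, config.discard
        )
    else:
        out["water"] = None
    return out


def run_manifest(manifest: RunManifest, config: AnalysisConfig | None = None) -> ReportTable:
    """Execute every manifest row and aggregate replicas per (group, ΔV).

    A failing row aborts only its (group, voltage) cell contribution;
    the failure is logged and the affected cell keeps its remaining
    replicas (or becomes missing).
    """
    config = config or AnalysisConfig()
    per_cell: dict[tuple[str, float], list[dict[str, FlowEstimate | None]]] = {}
    for _, row in manifest.rows.iterrows():
        cell = (str(row["group"]), float(row["voltage_mV"]))
        fmt = str(row.get("traj_format", config.traj_format) or config.traj_format)
        try:
            est = _estimate_row(str(row["traj"]), str(row["particles"]), config, fmt)
            digest = hashlib.sha256(open(row["traj"], "rb").read()).hexdigest()[:12]
            logger.info(
                "row group=%s dV=%s replica=%s traj=%s sha256=%s tau=%s block=%s discard=%s",
                row["group"], row["voltage_mV"], row["replica"], row["traj"],
                digest, config.tau, config.block, config.discard,
            )
        except Exception as exc:
            logger.error(
                "row group=%s dV=%s replica=%s failed: %s",
                row["group"], row["voltage_mV"], row["replica"], exc,
            )
            continue
        per_cell.setdefault(cell, []).append(est)

    records = []
    for (group, voltage), estimates in sorted(per_cell.items()):
        rec: dict[str, object] = {
            "group": group,
            "voltage_mV": voltage,
            "n_replicas": len(estimates),
        }
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for key, prefix in [
                ("all", "I_total"),
                ("cation", "I_cation"),
                ("anion", "I_anion"),
            ]:
                agg = replica_aggregate([e[key] for e in estimates])
                rec[f"{prefix}_nA"] = agg.mean
                rec[f"{prefix}_err"] = agg.error
            waters = [e["water"] for e in estimates if e["water"] is not None]
            if waters:
                agg = replica_aggregate(waters)
                rec["eof_per_ns"] = agg.mean
                rec["eof_err"] = agg.error
            else:
                rec["eof_per_ns"] = np.nan
                rec["eof_err"] = np.nan
        records.append(rec)
    if not records:
        warnings.warn("manifest produced no report rows", stacklevel=2)
        return ReportTable(rows=pd.DataFrame(columns=ReportTable.COLUMNS))
    return ReportTable(rows=pd.DataFrame.from_records(records)[ReportTable.COLUMNS])


def emit_report(
    table: ReportTable,
    path: str,
    format: str = "tsv",
    sign_convention: str = "positive current = net positive charge toward +z (trans to cis)",
) -> str:
    """Serialize a report losslessly; missing cells become NA tokens."""
    if format != "tsv":
        raise ValueError(f"unsupported report format {format!r}")
    with open(path, "w") as fh:
        fh.write("# poreflux report\n")
        fh.write(f"# sign convention: {sign_convention}\n")
        fh.write("# currents in nA, EOF in molecules/ns; errors are SEM over replicas\n")
        table.rows.to_csv(fh, sep="\t", index=False, na_rep="NA")
    return path


def read_report(path: str) -> ReportTable:
    return ReportTable(
        rows=pd.read_csv(path, sep="\t", comment="#", na_values=["NA"])
    )
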