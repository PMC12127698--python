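"""Delimited-text formats and run configuration.

Trace tables are comma-delimited with a header row and the columns
``trace_id, cell_id, stage, chrom, genomic_start_bp, x_nm, y_nm, z_nm,
present`` (0-based genomic interval starts, nm coordinates, 0/1 present
flag); optional extra columns (e.g. ``condition`` or QC metrics) ride along.
Output files embed provenance as ``#``-prefixed header lines (config hash
and seed); readers skip them.  Readers validate rather than coerce:
non-monotone coordinates, missing columns and unknown stage labels are
rejected with the offending trace or column named.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .traceops import STAGES, Trace

__all__ = [
    "TRACE_COLUMNS",
    "read_traces",
    "write_traces",
    "traces_to_frame",
    "frame_to_traces",
    "load_config",
    "config_hash",
    "write_table",
    "read_table",
]

TRACE_COLUMNS = ["trace_id", "cell_id", "stage", "chrom", "genomic_start_bp",
                 "x_nm", "y_nm", "z_nm", "present"]


def config_hash(config: dict) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _header_lines(meta: dict | None) -> str:
    if not meta:
        return ""
    return "".join(f"# {k}: {v}\n" for k, v in meta.items())


def write_table(df: pd.DataFrame, path: str | Path,
                meta: dict | None = None) -> None:
    """CSV with optional ``#`` provenance header lines."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_header_lines(meta))
        # %.17g round-trips float64 exactly
        df.to_csv(fh, index=False, float_format="%.17g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def traces_to_frame(traces: Iterable[Trace]) -> pd.DataFrame:
    frames = []
    for tr in traces:
        df = pd.DataFrame({
            "trace_id": tr.trace_id,
            "cell_id": tr.cell_id,
            "stage": tr.stage,
            "chrom": tr.chrom,
            "genomic_start_bp": tr.genomic,
            "x_nm": tr.xyz[:, 0],
            "y_nm": tr.xyz[:, 1],
            "z_nm": tr.xyz[:, 2],
            "present": tr.present.astype(int),
        })
        if tr.condition:
            df["condition"] = tr.condition
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=TRACE_COLUMNS)
    return pd.concat(frames, ignore_index=True)


def frame_to_traces(df: pd.DataFrame,
                    extra_stages: Sequence[str] = ()) -> list[Trace]:
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    allowed = set(STAGES) | set(extra_stages)
    bad = set(df["stage"].unique()) - allowed
    if bad:
        raise ValueError(f"unknown stage label(s): {sorted(bad)}; "
                         f"allowed: {sorted(allowed)}")
    traces = []
    for tid, sub in df.groupby("trace_id", sort=False):
        g = sub["genomic_start_bp"].to_numpy(dtype=np.int64)
        if np.any(np.diff(g) <= 0):
            raise ValueError(
                f"trace {tid!r}: genomic coordinates not strictly increasing")
        traces.append(Trace(
            trace_id=str(tid),
            cell_id=str(sub["cell_id"].iloc[0]),
            stage=str(sub["stage"].iloc[0]),
            genomic=g,
            xyz=sub[["x_nm", "y_nm", "z_nm"]].to_numpy(dtype=np.float64),
            present=sub["present"].to_numpy().astype(bool),
            chrom=str(sub["chrom"].iloc[0]),
            condition=str(sub["condition"].iloc[0])
            if "condition" in sub.columns else "",
        ))
    return traces


def write_traces(traces: Iterable[Trace], path: str | Path,
                 meta: dict | None = None) -> None:
    write_table(traces_to_frame(traces), path, meta=meta)


def read_traces(path: str | Path,
                column_map: dict[str, str] | None = None,
                extra_stages: Sequence[str] = ()) -> list[Trace]:
    """Read a trace table; ``column_map`` renames foreign column names onto
    the standard schema (e.g. external tables with different headers)."""
    df = read_table(path)
    if column_map:
        df = df.rename(columns=column_map)
    return frame_to_traces(df, extra_stages=extra_stages)


_CONFIG_SECTIONS = {
    "extrusion": {"chromosome_length", "lattice_resolution", "timestep",
                  "total_steps", "rng_seed", "snapshot_every", "species"},
    "polymer": {"n_monomers", "bp_per_monomer", "bond_length",
                "bond_stiffness", "thermal_energy", "friction", "timestep",
                "equilibration_steps", "steps_per_update", "neighbor_skin",
                "neighbor_every"},
    "forcefield": {"repulsion_emax", "repulsion_radius",
                   "extruder_bond_rest_frac", "extruder_bond_stiffness"},
    "analysis": {"min_points_per_trace", "distance_cutoff",
                 "min_genomic_span", "axis_window_bp", "bins",
                 "bins_per_decade", "min_completeness", "min_points"},
    "seed": None,
    "output_dir": None,
}

_SPECIES_KEYS = {"name", "density", "residence_time", "rate_mean", "rate_sd",
                 "sidedness", "traversal_policy", "load_time"}


def load_config(path: str | Path) -> dict:
    """Schema-validated hierarchical run configuration (YAML)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config root must be a mapping")
    for section, value in cfg.items():
        if section not in _CONFIG_SECTIONS:
            raise ValueError(f"unknown config section {section!r}")
        allowed = _CONFIG_SECTIONS[section]
        if allowed is None:
            continue
        if not isinstance(value, dict):
            raise ValueError(f"section {section!r} must be a mapping")
        unknown = set(value) - allowed
        if unknown:
            raise ValueError(
                f"unknown key(s) in {section!r}: {sorted(unknown)}")
        if section == "extrusion" and "species" in value:
            for sp in value["species"]:
                bad = set(sp) - _SPECIES_KEYS
                if bad:
                    raise ValueError(f"unknown species key(s): {sorted(bad)}")
    return cfg
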