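"""Readers/writers for traces, counts matrices, gene sets and run config.

On-disk formats are plain text: trace CSV (``time_s,i_nA,v_mV,z_um``)
with a sidecar ground-truth/annotation file, MatrixMarket counts with
TSV gene/cell annotations, GMT gene sets and YAML run configuration.
Internally everything is SI; the trace files use nA / mV / um at the
boundary.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
import yaml

from .phase_detect import PhaseAnnotation
from .trace_sim import GroundTruth, TraceChannel
from .transcriptomics import CountsMatrix

__all__ = [
    "ParseError",
    "read_trace",
    "write_trace",
    "read_ground_truth",
    "write_ground_truth",
    "write_annotation",
    "read_counts",
    "write_counts",
    "read_gmt",
    "write_gmt",
    "DEFAULT_CONFIG",
    "load_config",
    "config_hash",
]


class ParseError(ValueError):
    """A file does not conform to its expected on-disk format."""


# --- traces ---------------------------------------------------------------

TRACE_COLUMNS = ["time_s", "i_nA", "v_mV", "z_um"]


def write_trace(path, trace: TraceChannel) -> None:
    """Write a trace as delimited text (nA / mV / um at the boundary)."""
    df = pd.DataFrame(
        {
            "time_s": trace.time,
            "i_nA": trace.current * 1e9,
            "v_mV": trace.bias * 1e3,
            "z_um": trace.position * 1e6 if trace.position is not None else np.nan,
        }
    )
    df.to_csv(path, index=False, float_format="%.17g")


def read_trace(path) -> TraceChannel:
    """Read a trace CSV; round-trips ``write_trace`` losslessly."""
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise ParseError(f"{path}: empty trace file") from None
    missing = [c for c in TRACE_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ParseError(f"{path}: empty trace file")
    t = df["time_s"].to_numpy(float)
    bad = np.nonzero(np.diff(t) <= 0)[0]
    if len(bad):
        raise ParseError(f"{path}: non-monotone time at line {int(bad[0]) + 3}")
    sample_rate = 1.0 / float(np.median(np.diff(t))) if len(t) > 1 else 1.0
    z = None
    if "z_um" in df.columns and not df["z_um"].isna().all():
        z = df["z_um"].to_numpy(float) * 1e-6
    return TraceChannel(
        sample_rate=sample_rate,
        current=df["i_nA"].to_numpy(float) * 1e-9,
        bias=df["v_mV"].to_numpy(float) * 1e-3,
        position=z,
    )


def write_ground_truth(path, truth: GroundTruth) -> None:
    pd.DataFrame(
        [(k, v) for k, v in truth.present().items()], columns=["phase", "sample_index"]
    ).to_csv(path, index=False)


def read_ground_truth(path) -> GroundTruth:
    df = pd.read_csv(path)
    truth = GroundTruth()
    for _, row in df.iterrows():
        setattr(truth, str(row["phase"]), int(row["sample_index"]))
    return truth


def write_annotation(path, annotation: PhaseAnnotation, sample_rate: float) -> None:
    rows = [(k, v, v / sample_rate) for k, v in annotation.present().items()]
    pd.DataFrame(rows, columns=["phase", "sample_index", "time_s"]).to_csv(path, index=False)


# --- counts / gene sets ---------------------------------------------------

GENE_COLUMNS = ["gene_id", "protein_coding", "mito", "ribo"]


def write_counts(out_dir, matrix: CountsMatrix) -> None:
    """Write MatrixMarket counts plus genes.tsv / cells.tsv annotations."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(out_dir / "matrix.mtx", sp.coo_matrix(matrix.counts))
    matrix.genes.reset_index().to_csv(out_dir / "genes.tsv", sep="\t", index=False)
    matrix.cells.reset_index().to_csv(out_dir / "cells.tsv", sep="\t", index=False)


def read_counts(mtx_path, genes_path, cells_path) -> CountsMatrix:
    """Read a MatrixMarket counts triplet into a CountsMatrix."""
    mtx_path = Path(mtx_path)
    try:
        counts = sp.csr_matrix(scipy.io.mmread(mtx_path))
    except Exception as exc:
        raise ParseError(f"{mtx_path}: invalid MatrixMarket file ({exc})") from None
    genes = pd.read_csv(genes_path, sep="\t")
    cells = pd.read_csv(cells_path, sep="\t")
    for col in GENE_COLUMNS:
        if col not in genes.columns:
            raise ParseError(f"{genes_path}: missing column '{col}'")
    if genes["gene_id"].duplicated().any():
        dupes = genes["gene_id"][genes["gene_id"].duplicated()].tolist()
        raise ParseError(f"{genes_path}: duplicate gene identifiers {dupes[:5]}")
    genes = genes.set_index("gene_id")
    if "cell_id" not in cells.columns:
        raise ParseError(f"{cells_path}: missing column 'cell_id'")
    cells = cells.set_index("cell_id")
    if counts.shape != (len(genes), len(cells)):
        raise ParseError(
            f"{mtx_path}: matrix shape {counts.shape} does not match "
            f"{len(genes)} genes x {len(cells)} cells"
        )
    return CountsMatrix(counts, genes, cells)


def read_gmt(path) -> dict:
    """Read GMT gene sets: tab-separated name, description, members."""
    sets = {}
    path = Path(path)
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ParseError(f"{path}: line {lineno}: expected name, description, members")
        sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(path, sets: dict, description: str = "synthetic") -> None:
    lines = ["\t".join([name, description] + list(members)) for name, members in sets.items()]
    Path(path).write_text("\n".join(lines) + "\n")


# --- run configuration ----------------------------------------------------

DEFAULT_CONFIG: dict = {
    "sicm": {
        "r_tip_m": 75e-9,
        "taper": 0.0714,
        "length_m": 5e-3,
        "kappa_aq": 1.30,
        "kappa_org": 0.01,
        "kappa_cyt": 0.425,
        "v_aq_mv": 200.0,
        "v_org_hold_mv": 300.0,
        "v_org_extract_mv": -500.0,
        "z_sp_m": 100e-9,
        "r_aq_ohm": 45.7e6,
        "r_org_ohm": 2.7e9,
    },
    "injection": {
        "hop_height_m": 2e-6,
        "step_m": 100e-9,
        "descent_speed_m_s": 1e-5,
        "hold_duration_s": 60.0,
        "membrane_drop_fraction": 0.02,
        "inject_bias_v": -0.5,
        "membrane_z_m": 5.06e-6,
    },
    "extraction": {
        "pre_hold_na": 0.35,
        "peak_na": 2.83,
        "post_hold_na": 0.70,
        "extract_duration_s": 10.0,
        "ingress_tau_s": 1.5,
    },
    "noise": {
        "white_sd_a": 10e-12,
        "vibration_band_hz": [50.0, 500.0],
        "vibration_amp_a": 50e-12,
        "vibration_onset_distance_m": 300e-9,
    },
    "detection": {
        "setpoint_fraction": 0.995,
        "touch_fraction": 0.985,
        "vib_ratio_threshold": 8.0,
        "contact_floor_a": None,
        "baseline_window_s": 0.05,
    },
    "lineage": {
        "fov_um": [1300.0, 1300.0],
        "duration_h": 72.0,
        "step_interval_h": 2.0,
        "speed_scale_um_h": 35.0,
        "division_rate_per_h": 0.028881132523331052,  # ln 2 / 24 h
        "death_rate_per_h": 0.04,
        "max_progeny_tracked": 512,
    },
    "pipeline": {
        "min_genes": 150,
        "max_ribo_pct": 10.0,
        "max_mito_pct": 30.0,
        "n_hvg": 600,
        "n_pcs": 8,
        "scale_clip": 5.0,
        "volume_threshold_fl": 200.0,
    },
    "generator": {
        "n_genes": 2000,
        "n_noncoding": 100,
        "n_mito_genes": 20,
        "n_ribo_genes": 80,
        "module_size": 50,
        "dispersion": 0.5,
        "profile": "nanobiopsy",
        "effect_size": 2.0,
        "switch_p_untreated": 0.7,
        "switch_p_treated": 0.11,
        "n_pairs_untreated": 10,
        "n_pairs_treated": 9,
        "n_day1_only": 100,
    },
}


def _merge(defaults: dict, overrides: dict, path: str = "") -> dict:
    out = dict(defaults)
    for key, value in overrides.items():
        here = f"{path}.{key}" if path else key
        if key not in defaults:
            raise ParseError(f"unknown configuration key '{here}'")
        if isinstance(defaults[key], dict) and isinstance(value, dict):
            out[key] = _merge(defaults[key], value, here)
        else:
            out[key] = value
    return out


def load_config(path=None) -> dict:
    """Resolved run configuration: defaults overlaid with a YAML file.

    Unknown keys are rejected so typos cannot silently fall back to
    defaults.
    """
    if path is None:
        return json.loads(json.dumps(DEFAULT_CONFIG))
    text = Path(path).read_text()
    overrides = yaml.safe_load(text) or {}
    if not isinstance(overrides, dict):
        raise ParseError(f"{path}: configuration must be a mapping")
    return _merge(DEFAULT_CONFIG, overrides)


def config_hash(config: dict) -> str:
    """Stable short hash of a resolved configuration (for run logs)."""
    canon = json.dumps(config, sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:12]
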