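"""Readers and writers for every on-disk artifact.

Frames and images travel as full-precision CSV (human-inspectable, desk
scale); configs, protocols and summaries as JSON; the sensitivity and
reconstruction matrices as an ``.npz`` cache with a JSON sidecar carrying
the mesh/protocol hashes and lambda.  Electrode labels in files are
1-based; in-memory indices are 0-based.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .forward import FrameSeries
from .mesh import Mesh, N_ELECTRODES, Protocol, make_protocol
from .reconstruct import ReconstructionMatrix, SensitivityMatrix

__all__ = [
    "FrameParseError",
    "write_frames_csv",
    "read_frames_csv",
    "write_metadata",
    "read_metadata",
    "protocol_to_json",
    "protocol_from_json",
    "write_mesh_csv",
    "read_mesh_csv",
    "write_images_csv",
    "write_riv_csv",
    "write_summary_json",
    "save_matrices",
    "load_matrices",
]

_FMT = "%.17g"  # round-trips IEEE doubles exactly


class FrameParseError(ValueError):
    """A frames CSV file does not match the expected layout."""


def write_frames_csv(path, frames: FrameSeries) -> None:
    path = Path(path)
    n_ch = frames.voltages.shape[1]
    header = "time_s," + ",".join(f"ch{c + 1:03d}" for c in range(n_ch))
    data = np.column_stack([frames.times, frames.voltages])
    np.savetxt(path, data, fmt=_FMT, delimiter=",", header=header, comments="")


def read_frames_csv(path, protocol: Protocol | None = None,
                    metadata: dict | None = None) -> FrameSeries:
    path = Path(path)
    protocol = protocol or make_protocol()
    with open(path) as fh:
        header = fh.readline().strip()
    cols = header.split(",")
    expected = protocol.n_channels + 1
    if len(cols) != expected or cols[0] != "time_s":
        raise FrameParseError(
            f"{path}, line 1: expected 'time_s' plus {protocol.n_channels} "
            f"channel columns, found {len(cols)} columns"
        )
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise FrameParseError(f"{path}: {exc}") from exc
    if df.shape[1] != expected:
        raise FrameParseError(
            f"{path}: expected {expected} columns, found {df.shape[1]}"
        )
    values = df.to_numpy(dtype=float)
    return FrameSeries(times=values[:, 0], voltages=values[:, 1:],
                       protocol=protocol, metadata=metadata or {})


def write_metadata(path, metadata: dict) -> None:
    Path(path).write_text(json.dumps(metadata, indent=2, sort_keys=True))


def read_metadata(path) -> dict:
    return json.loads(Path(path).read_text())


def protocol_to_json(protocol: Protocol) -> str:
    """Serialize with 1-based electrode labels."""
    doc = {
        "n_electrodes": protocol.n_electrodes,
        "excitations": [[a + 1, b + 1] for a, b in protocol.excitations],
        "measurements": [[a + 1, b + 1] for a, b in protocol.measurements],
        "valid_mask": protocol.valid_mask.astype(int).tolist(),
    }
    return json.dumps(doc, indent=2)


def protocol_from_json(text: str) -> Protocol:
    doc = json.loads(text)
    if doc["n_electrodes"] != N_ELECTRODES:
        raise ValueError("only 16-electrode protocols are supported")
    ref = make_protocol()
    excitations = tuple((a - 1, b - 1) for a, b in doc["excitations"])
    measurements = tuple((a - 1, b - 1) for a, b in doc["measurements"])
    mask = np.array(doc["valid_mask"], dtype=bool)
    if (excitations != ref.excitations or measurements != ref.measurements
            or not np.array_equal(mask, ref.valid_mask)):
        raise ValueError("protocol file does not describe the supported "
                         "opposite-drive / adjacent-measurement protocol")
    return ref


def write_mesh_csv(prefix, mesh: Mesh) -> None:
    """Write ``<prefix>.nodes.csv`` and ``<prefix>.elements.csv``."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".nodes.csv"), mesh.nodes, fmt=_FMT,
               delimiter=",", header="x,y", comments="")
    elem = np.column_stack([mesh.triangles, mesh.areas])
    np.savetxt(prefix.with_suffix(".elements.csv"), elem,
               fmt=["%d", "%d", "%d", _FMT], delimiter=",",
               header="n1,n2,n3,area", comments="")
    meta = {
        "radius": mesh.radius,
        "electrode_nodes_1based": (mesh.electrode_nodes + 1).tolist(),
    }
    prefix.with_suffix(".mesh.json").write_text(json.dumps(meta, indent=2))


def read_mesh_csv(prefix) -> Mesh:
    prefix = Path(prefix)
    nodes = np.loadtxt(prefix.with_suffix(".nodes.csv"), delimiter=",",
                       skiprows=1, ndmin=2)
    elem = np.loadtxt(prefix.with_suffix(".elements.csv"), delimiter=",",
                      skiprows=1, ndmin=2)
    meta = json.loads(prefix.with_suffix(".mesh.json").read_text())
    return Mesh(
        nodes=nodes,
        triangles=elem[:, :3].astype(np.int64),
        areas=elem[:, 3],
        electrode_nodes=np.array(meta["electrode_nodes_1based"]) - 1,
        radius=float(meta["radius"]),
    )


def write_images_csv(path, images) -> None:
    """One row per frame: time_s then per-element impedance change."""
    n_el = images.values.shape[1]
    header = "time_s," + ",".join(f"el{e + 1:04d}" for e in range(n_el))
    data = np.column_stack([images.times, images.values])
    np.savetxt(path, data, fmt=_FMT, delimiter=",", header=header, comments="")


def write_riv_csv(path, riv_series) -> None:
    data = np.column_stack([riv_series.times, riv_series.volumes_ml,
                            riv_series.riv])
    np.savetxt(path, data, fmt=_FMT, delimiter=",",
               header="time_s,volume_ml,riv", comments="")


def write_summary_json(path, result) -> None:
    """JSON summary of an AnalysisResult (regression, groups, ROI)."""
    groups = None
    if result.groups is not None:
        groups = {
            "labels": result.groups.labels,
            "f_stat": result.groups.f_stat,
            "p_omnibus": result.groups.p_omnibus,
            "posthoc_p_vs_baseline": result.groups.posthoc_p,
        }
    doc = {
        "regression": {
            "slope_per_ml": result.regression.slope,
            "intercept": result.regression.intercept,
            "r_squared": result.regression.r_squared,
            "p_value": result.regression.p_value,
            "n": result.regression.n,
        },
        "groups": groups,
        "roi": {
            "n_elements": int(len(result.roi.elements)),
            "elements_1based": (result.roi.elements + 1).tolist(),
            "fraction": result.roi.fraction,
        },
        "params": result.params,
    }
    Path(path).write_text(json.dumps(doc, indent=2))


def save_matrices(path, sens: SensitivityMatrix, recon: ReconstructionMatrix,
                  protocol_hash: str = "") -> None:
    path = Path(path)
    np.savez(path, s=sens.values, v_ref=sens.reference_voltages, b=recon.b)
    header = {
        "lambda": recon.lam,
        "regularizer": recon.regularizer,
        "background_conductivity": sens.background_conductivity,
        "current": sens.current,
        "mesh_hash": sens.mesh_hash,
        "protocol_hash": protocol_hash,
        "sign_convention": sens.sign_convention,
    }
    path.with_suffix(".json").write_text(json.dumps(header, indent=2))


def load_matrices(path) -> tuple:
    path = Path(path)
    npz_path = path if path.suffix == ".npz" else path.with_suffix(".npz")
    data = np.load(npz_path)
    header = json.loads(npz_path.with_suffix(".json").read_text())
    sens = SensitivityMatrix(
        values=data["s"],
        reference_voltages=data["v_ref"],
        background_conductivity=header["background_conductivity"],
        current=header["current"],
        mesh_hash=header["mesh_hash"],
    )
    recon = ReconstructionMatrix(b=data["b"], lam=header["lambda"],
                                 mesh_hash=header["mesh_hash"])
    return sens, recon
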