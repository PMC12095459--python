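"""File formats: network JSON, attractor/scan/events CSV, landscape JSON,
trajectory containers.

All writers emit a ``format_version`` so readers can reject files from an
incompatible release; write-then-read is the identity (bit-exact for
integers and labels, to full float precision for reals).  Trajectories go
to CSV with a JSON provenance header line for small runs, or to ``.npz``
for large ones.
"""
from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .boolnet import Attractor, BooleanNetwork, ScanReport
from .landscape import Landscape
from .sde import FieldTrajectory, Trajectory
from .transitions import TransitionEvent

__all__ = [
    "FormatError",
    "read_network",
    "write_network",
    "read_attractors",
    "write_attractors",
    "read_landscape",
    "write_landscape",
    "read_trajectory",
    "write_trajectory",
    "read_events",
    "write_events",
    "write_scan",
]

FORMAT_VERSION = 1


class FormatError(ValueError):
    """Raised for malformed or version-incompatible files."""


def _check_version(payload: dict, path):
    v = payload.get("format_version")
    if v != FORMAT_VERSION:
        raise FormatError(
            f"{path}: format_version {v!r} not supported (expected {FORMAT_VERSION})"
        )


# -- network ----------------------------------------------------------------


def write_network(network: BooleanNetwork, path) -> None:
    payload = {
        "format_version": FORMAT_VERSION,
        "nodes": list(network.nodes),
        "rules": dict(network.rules),
        "clamps": dict(network.clamps),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_network(path) -> BooleanNetwork:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"{path}: not valid JSON ({e})") from e
    _check_version(payload, path)
    for key in ("nodes", "rules"):
        if key not in payload:
            raise FormatError(f"{path}: missing field {key!r}")
    return BooleanNetwork(
        nodes=tuple(payload["nodes"]),
        rules=payload["rules"],
        clamps={k: int(v) for k, v in payload.get("clamps", {}).items()},
    )


# -- attractor tables --------------------------------------------------------

ATTRACTOR_COLUMNS = [
    "attractor_id",
    "state_sequence",
    "basin_size",
    "basin_fraction",
    "phenotype",
]


def write_attractors(attractors: Sequence[Attractor], path) -> None:
    rows = []
    for i, a in enumerate(attractors):
        seq = ";".join("".join(str(b) for b in s) for s in a.states)
        rows.append((i, seq, a.basin_size, a.basin_fraction, a.phenotype or ""))
    pd.DataFrame(rows, columns=ATTRACTOR_COLUMNS).to_csv(path, index=False)


def read_attractors(path, nodes: Sequence[str] | None = None) -> list[Attractor]:
    """Read an attractor table; with ``nodes=None``, placeholder node names
    are synthesized from the state-string length."""
    try:
        df = pd.read_csv(path, dtype={"state_sequence": str, "phenotype": str})
    except Exception as e:  # noqa: BLE001 - reported with file context
        raise FormatError(f"{path}: cannot parse CSV ({e})") from e
    missing = set(ATTRACTOR_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    if nodes is None:
        if len(df) == 0:
            raise FormatError(f"{path}: empty table; cannot infer node count")
        width = len(str(df.iloc[0]["state_sequence"]).split(";")[0])
        nodes = tuple(f"n{i}" for i in range(width))
    nodes = tuple(nodes)
    out = []
    for row_no, row in df.iterrows():
        states = []
        for bits in str(row["state_sequence"]).split(";"):
            if len(bits) != len(nodes) or set(bits) - {"0", "1"}:
                raise FormatError(
                    f"{path}: row {row_no}: bad state string {bits!r} "
                    f"for {len(nodes)} nodes"
                )
            states.append(tuple(int(b) for b in bits))
        phen = row["phenotype"]
        out.append(
            Attractor(
                states=tuple(states),
                basin_size=int(row["basin_size"]),
                basin_fraction=float(row["basin_fraction"]),
                nodes=nodes,
                phenotype=None if pd.isna(phen) or phen == "" else str(phen),
            )
        )
    return out


# -- landscape ---------------------------------------------------------------


def write_landscape(landscape: Landscape, path) -> None:
    payload = {
        "format_version": FORMAT_VERSION,
        "labels": list(landscape.labels),
        "centers": landscape.centers.tolist(),
        "steepness": landscape.steepness.tolist(),
        "depth_rule": landscape.depth_rule,
        "scale": landscape.scale,
        "provenance": dict(landscape.provenance),
    }
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_landscape(path) -> Landscape:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise FormatError(f"{path}: not valid JSON ({e})") from e
    _check_version(payload, path)
    for key in ("labels", "centers", "steepness"):
        if key not in payload:
            raise FormatError(f"{path}: missing field {key!r}")
    return Landscape(
        labels=tuple(payload["labels"]),
        centers=np.asarray(payload["centers"], dtype=float),
        steepness=np.asarray(payload["steepness"], dtype=float),
        depth_rule=payload.get("depth_rule", "proportional"),
        scale=payload.get("scale", 1.0),
        provenance=payload.get("provenance", {}),
    )


# -- trajectories ------------------------------------------------------------


def write_trajectory(traj: Trajectory | FieldTrajectory, path) -> None:
    path = Path(path)
    header = {
        "format_version": FORMAT_VERSION,
        "kind": "field" if isinstance(traj, FieldTrajectory) else "point",
        "config": dict(traj.config),
    }
    if path.suffix == ".npz":
        if isinstance(traj, FieldTrajectory):
            np.savez_compressed(
                path, times=traj.times, u=traj.u, v=traj.v,
                header=json.dumps(header),
            )
        else:
            np.savez_compressed(
                path, times=traj.times, xy=traj.xy, header=json.dumps(header)
            )
        return
    if isinstance(traj, FieldTrajectory):
        N = traj.u.shape[1]
        cols = ["time"] + [f"u{i}" for i in range(N)] + [f"v{i}" for i in range(N)]
        data = np.column_stack([traj.times, traj.u, traj.v])
    else:
        cols = ["time", "u", "v"]
        data = np.column_stack([traj.times, traj.xy])
    with open(path, "w") as fh:
        fh.write("# " + json.dumps(header) + "\n")
        pd.DataFrame(data, columns=cols).to_csv(fh, index=False)


def read_trajectory(path) -> Trajectory | FieldTrajectory:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as z:
            header = json.loads(str(z["header"]))
            _check_version(header, path)
            if header["kind"] == "field":
                return FieldTrajectory(
                    times=z["times"], u=z["u"], v=z["v"], config=header["config"]
                )
            return Trajectory(times=z["times"], xy=z["xy"], config=header["config"])
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# "):
            raise FormatError(f"{path}: missing provenance header line")
        try:
            header = json.loads(first[2:])
        except json.JSONDecodeError as e:
            raise FormatError(f"{path}: bad provenance header ({e})") from e
        _check_version(header, path)
        df = pd.read_csv(fh)
    if header["kind"] == "field":
        ucols = [c for c in df.columns if c.startswith("u")]
        vcols = [c for c in df.columns if c.startswith("v")]
        return FieldTrajectory(
            times=df["time"].to_numpy(),
            u=df[ucols].to_numpy(),
            v=df[vcols].to_numpy(),
            config=header["config"],
        )
    return Trajectory(
        times=df["time"].to_numpy(),
        xy=df[["u", "v"]].to_numpy(),
        config=header["config"],
    )


# -- events & scans ----------------------------------------------------------

EVENT_COLUMNS = ["time", "source", "target", "u_cross", "v_cross", "pass_distance"]


def write_events(events: Sequence[TransitionEvent], path) -> None:
    rows = [
        (e.time, e.source, e.target, e.crossing[0], e.crossing[1],
         "" if e.pass_distance is None else e.pass_distance)
        for e in events
    ]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def read_events(path) -> list[TransitionEvent]:
    try:
        df = pd.read_csv(path)
    except Exception as e:  # noqa: BLE001
        raise FormatError(f"{path}: cannot parse CSV ({e})") from e
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing column(s) {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        pd_val = row["pass_distance"]
        out.append(
            TransitionEvent(
                time=float(row["time"]),
                source=str(row["source"]),
                target=str(row["target"]),
                crossing=np.array([row["u_cross"], row["v_cross"]], dtype=float),
                pass_distance=None if pd.isna(pd_val) else float(pd_val),
            )
        )
    return out


def write_scan(report: ScanReport, path, aggregates_path=None) -> None:
    report.rows.to_csv(path, index=False)
    if aggregates_path is not None:
        report.aggregates.to_csv(aggregates_path, index=False)
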