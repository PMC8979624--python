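"""File formats: HDF5 / CSV time series, adjacency stacks, masks and curves."""

from __future__ import annotations

import pathlib

import h5py
import numpy as np
import pandas as pd

from .connectivity import AdjacencyStack, DensitySweepGraphs
from .metrics import SWPCurveSet
from .spectral import CarrierGrid
from .synth import ROITimeSeriesSet, WeightedGraph

__all__ = [
    "write_timeseries",
    "read_timeseries",
    "write_timeseries_csv",
    "read_timeseries_csv",
    "write_edge_list",
    "write_adjacency",
    "read_adjacency",
    "write_density_masks",
    "write_curves",
    "read_curves",
]


def write_timeseries(path, ts: ROITimeSeriesSet) -> None:
    """HDF5 layout: /subjects/<id>/data with fs and node_labels attributes."""
    with h5py.File(path, "w") as f:
        f.attrs["fs"] = ts.fs
        f.attrs["node_labels"] = [str(x) for x in ts.node_labels]
        grp = f.create_group("subjects")
        for s, sid in enumerate(ts.subject_ids):
            grp.create_group(sid).create_dataset("data", data=ts.data[s])


def read_timeseries(path) -> ROITimeSeriesSet:
    path = pathlib.Path(path)
    if path.stat().st_size == 0:
        raise ValueError(f"{path}: empty file, not a valid time-series container")
    try:
        f = h5py.File(path, "r")
    except OSError as err:
        raise ValueError(f"{path}: not a readable HDF5 file ({err})") from err
    with f:
        fs = float(f.attrs["fs"])
        labels = [
            x.decode() if isinstance(x, bytes) else str(x)
            for x in f.attrs["node_labels"]
        ]
        sids = sorted(f["subjects"].keys())
        arrays, offenders = [], []
        for sid in sids:
            arr = np.asarray(f["subjects"][sid]["data"])
            if arr.shape[0] != len(labels):
                offenders.append(f"{sid} (nodes={arr.shape[0]}, expected {len(labels)})")
            arrays.append(arr)
        if offenders:
            raise ValueError("subjects with mismatched node sets: " + ", ".join(offenders))
        return ROITimeSeriesSet(
            data=np.stack(arrays), fs=fs, node_labels=labels, subject_ids=sids
        )


def write_timeseries_csv(directory, ts: ROITimeSeriesSet) -> None:
    """One CSV per subject: rows = samples, columns = node labels."""
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for s, sid in enumerate(ts.subject_ids):
        pd.DataFrame(ts.data[s].T, columns=ts.node_labels).to_csv(
            directory / f"{sid}.csv", index=False
        )


def read_timeseries_csv(directory, fs: float) -> ROITimeSeriesSet:
    directory = pathlib.Path(directory)
    paths = sorted(directory.glob("*.csv"))
    if not paths:
        raise ValueError(f"no CSV files found in {directory}")
    frames = {p.stem: pd.read_csv(p) for p in paths}
    labels = list(next(iter(frames.values())).columns)
    offenders = [
        f"{sid}: missing columns {sorted(set(labels) - set(df.columns))}"
        for sid, df in frames.items()
        if list(df.columns) != labels
    ]
    if offenders:
        raise ValueError("subjects with mismatched node sets: " + "; ".join(offenders))
    data = np.stack([frames[sid][labels].to_numpy().T for sid in frames])
    return ROITimeSeriesSet(
        data=data, fs=fs, node_labels=labels, subject_ids=list(frames)
    )


def write_edge_list(path, graph: WeightedGraph) -> None:
    """Ground-truth graph as TSV: node_i, node_j, weight."""
    iu, ju = np.triu_indices(graph.n, 1)
    present = graph.weights[iu, ju] > 0
    pd.DataFrame(
        {
            "node_i": iu[present],
            "node_j": ju[present],
            "weight": graph.weights[iu, ju][present],
        }
    ).to_csv(path, sep="\t", index=False)


def write_adjacency(path, stack: AdjacencyStack, subject_ids: list[str] | None = None) -> None:
    sids = subject_ids or [f"sub{s:03d}" for s in range(stack.n_subjects)]
    with h5py.File(path, "w") as f:
        f.attrs["carrier_exponents"] = stack.grid.exponents
        f.attrs["subject_ids"] = sids
        if stack.node_labels:
            f.attrs["node_labels"] = [str(x) for x in stack.node_labels]
        fc = f.create_group("fc")
        for s, sid in enumerate(sids):
            g = fc.create_group(sid)
            for ci in range(len(stack.grid)):
                g.create_dataset(f"carrier{ci:02d}", data=stack.weights[s, ci])


def read_adjacency(path) -> AdjacencyStack:
    with h5py.File(path, "r") as f:
        exponents = np.asarray(f.attrs["carrier_exponents"], dtype=float)
        grid = CarrierGrid(exponents=exponents, frequencies_hz=2.0**exponents)
        sids = [
            x.decode() if isinstance(x, bytes) else str(x) for x in f.attrs["subject_ids"]
        ]
        labels = None
        if "node_labels" in f.attrs:
            labels = [
                x.decode() if isinstance(x, bytes) else str(x)
                for x in f.attrs["node_labels"]
            ]
        weights = np.stack(
            [
                np.stack(
                    [
                        np.asarray(f["fc"][sid][f"carrier{ci:02d}"])
                        for ci in range(len(grid))
                    ]
                )
                for sid in sids
            ]
        )
    return AdjacencyStack(weights=weights, grid=grid, node_labels=labels)


def write_density_masks(path, sweep: DensitySweepGraphs) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("masks", data=sweep.masks)
        f.create_dataset("densities_pct", data=sweep.densities_pct)
        f.create_dataset("edge_cv", data=sweep.edge_cv)


def write_curves(path, curves: SWPCurveSet) -> None:
    """Long-format CSV: subject, carrier_hz, density_pct, swp, sigma, reliable."""
    n_subj, n_car, n_den = curves.swp.shape
    sids = curves.subject_ids or [f"sub{s:03d}" for s in range(n_subj)]
    s_idx, c_idx, d_idx = np.meshgrid(
        np.arange(n_subj), np.arange(n_car), np.arange(n_den), indexing="ij"
    )
    pd.DataFrame(
        {
            "subject": np.asarray(sids)[s_idx.ravel()],
            "carrier_hz": curves.carrier_hz[c_idx.ravel()],
            "density_pct": curves.densities_pct[d_idx.ravel()],
            "swp": curves.swp.ravel(),
            "sigma": curves.sigma.ravel(),
            "delta_c": curves.delta_c.ravel(),
            "delta_l": curves.delta_l.ravel(),
            "reliable": curves.reliable.ravel(),
        }
    ).to_csv(path, index=False)


def read_curves(path) -> pd.DataFrame:
    return pd.read_csv(path)
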