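"""Array-container and table output helpers (HDF5 + TSV + YAML)."""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .epochs import EpochSet
from .roitc import ROIEpochSet

__all__ = ["save_epochs", "load_epochs", "save_roi_epochs", "load_roi_epochs",
           "save_vertex_data", "load_vertex_data", "write_tsv", "write_manifest"]


def save_epochs(e: EpochSet, path: str | Path, key: str = "epochs") -> None:
    with h5py.File(path, "a") as f:
        if key in f:
            del f[key]
        g = f.create_group(key)
        g.create_dataset("data", data=e.data, compression="gzip")
        g.attrs["sampling_rate"] = e.sampling_rate
        g.attrs["t0_index"] = e.t0_index
        g.attrs["condition"] = e.condition
        g.attrs["channel_names"] = [str(c) for c in e.channel_names]


def load_epochs(path: str | Path, key: str = "epochs") -> EpochSet:
    with h5py.File(path, "r") as f:
        g = f[key]
        return EpochSet(data=g["data"][()],
                        sampling_rate=float(g.attrs["sampling_rate"]),
                        t0_index=int(g.attrs["t0_index"]),
                        channel_names=[str(c) for c in g.attrs["channel_names"]],
                        condition=str(g.attrs["condition"]))


def save_roi_epochs(e: ROIEpochSet, path: str | Path, key: str = "roi_epochs") -> None:
    with h5py.File(path, "a") as f:
        if key in f:
            del f[key]
        g = f.create_group(key)
        g.create_dataset("data", data=e.data, compression="gzip")
        g.attrs["sampling_rate"] = e.sampling_rate
        g.attrs["t0_index"] = e.t0_index
        g.attrs["condition"] = e.condition
        g.attrs["roi_names"] = [str(c) for c in e.roi_names]


def load_roi_epochs(path: str | Path, key: str = "roi_epochs") -> ROIEpochSet:
    with h5py.File(path, "r") as f:
        g = f[key]
        return ROIEpochSet(data=g["data"][()],
                           sampling_rate=float(g.attrs["sampling_rate"]),
                           t0_index=int(g.attrs["t0_index"]),
                           roi_names=[str(c) for c in g.attrs["roi_names"]],
                           condition=str(g.attrs["condition"]))


def save_vertex_data(v, path: str | Path, key: str = "vertex_data") -> None:
    """Store runs x vertices x samples plus the mesh (CSR adjacency, coords,
    labels) in one HDF5 group."""
    from scipy import sparse

    adj = sparse.csr_matrix(v.mesh.adjacency)
    with h5py.File(path, "a") as f:
        if key in f:
            del f[key]
        g = f.create_group(key)
        g.create_dataset("data", data=v.data, compression="gzip")
        g.create_dataset("coords", data=v.mesh.coords)
        g.create_dataset("labels", data=np.array([str(x) for x in v.mesh.labels],
                                                 dtype=h5py.string_dtype()))
        g.create_dataset("adj_indptr", data=adj.indptr)
        g.create_dataset("adj_indices", data=adj.indices)
        g.attrs["n_vertices"] = adj.shape[0]
        g.attrs["sampling_rate"] = v.sampling_rate
        g.attrs["t0_index"] = v.t0_index
        g.attrs["condition"] = v.condition


def load_vertex_data(path: str | Path, key: str = "vertex_data"):
    from scipy import sparse

    from .synthgen import Mesh, VertexData

    with h5py.File(path, "r") as f:
        g = f[key]
        n = int(g.attrs["n_vertices"])
        indptr = g["adj_indptr"][()]
        indices = g["adj_indices"][()]
        adj = sparse.csr_matrix((np.ones(indices.size, dtype=np.int8),
                                 indices, indptr), shape=(n, n))
        mesh = Mesh(adjacency=adj, coords=g["coords"][()],
                    labels=np.array([s.decode() if isinstance(s, bytes) else str(s)
                                     for s in g["labels"][()]], dtype=object))
        return VertexData(data=g["data"][()], mesh=mesh,
                          sampling_rate=float(g.attrs["sampling_rate"]),
                          t0_index=int(g.attrs["t0_index"]),
                          condition=str(g.attrs["condition"]))


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as f:
        yaml.safe_dump(_plain(manifest), f, sort_keys=True)


def _plain(obj):
    """Recursively convert numpy scalars/arrays so YAML output is portable."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return _plain(obj.tolist())
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj
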