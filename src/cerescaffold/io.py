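"""HDF5 file schemas and run manifests.

Placement file: dataset ``cells`` of shape (N, 5) with columns
[cell_id, type_code, x, y, z] (float storage, integral ids/codes) and
dataset ``aa_height`` of shape (n_GrC, 2) with [grc_id, height_um];
attributes record the configuration hash, seed and type-code map.

Connectome file: one (E, 3) dataset per connection type under
``connections/<name>`` with columns [pre_id, post_id, distance_um].

Spike file: dataset ``spikes`` of shape (M, 2) with [neuron_id, time_ms].

Every writer stamps a manifest (config hash, seed, schema version) so each
output can be traced to its inputs.
"""

from __future__ import annotations

import hashlib
import json
import time

import h5py
import numpy as np
import yaml

from .config import ScaffoldConfig
from .connectivity import Connectome
from .netsim import SpikeRecord
from .placement import PlacementTable

SCHEMA_VERSION = 1

__all__ = [
    "config_hash",
    "write_placement",
    "read_placement",
    "write_connectome",
    "read_connectome",
    "write_spikes",
    "read_spikes",
]


class SchemaError(IOError):
    """File does not match the expected schema version or layout."""


def config_hash(cfg: ScaffoldConfig) -> str:
    text = yaml.safe_dump(cfg.to_dict(), sort_keys=True)
    return hashlib.sha256(text.encode()).hexdigest()[:16]


def _stamp(f: h5py.File, cfg: ScaffoldConfig | None, seed: int) -> None:
    f.attrs["schema_version"] = SCHEMA_VERSION
    f.attrs["seed"] = int(seed)
    f.attrs["created"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    if cfg is not None:
        f.attrs["config_hash"] = config_hash(cfg)


def _check(f: h5py.File) -> None:
    v = int(f.attrs.get("schema_version", -1))
    if v != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema version {v} "
                          f"(expected {SCHEMA_VERSION})")


def write_placement(path, table: PlacementTable,
                    cfg: ScaffoldConfig | None = None) -> None:
    with h5py.File(path, "w") as f:
        data = np.column_stack([table.cell_id.astype(float),
                                table.type_code.astype(float), table.xyz])
        f.create_dataset("cells", data=data)
        f.create_dataset("aa_height", data=table.aa_height)
        f.attrs["type_names"] = json.dumps(table.type_names)
        _stamp(f, cfg, table.seed)


def read_placement(path) -> PlacementTable:
    with h5py.File(path, "r") as f:
        _check(f)
        data = f["cells"][:]
        aa = f["aa_height"][:]
        names = json.loads(f.attrs["type_names"])
        seed = int(f.attrs["seed"])
    return PlacementTable(cell_id=data[:, 0].astype(np.int64),
                          type_code=data[:, 1].astype(np.int64),
                          xyz=data[:, 2:5], aa_height=aa,
                          type_names={k: int(v) for k, v in names.items()},
                          seed=seed)


def write_connectome(path, conn: Connectome,
                     cfg: ScaffoldConfig | None = None) -> None:
    with h5py.File(path, "w") as f:
        grp = f.create_group("connections")
        for name, edges in conn.edges.items():
            d = grp.create_dataset(name, data=edges)
            if cfg is not None and name in cfg.rules:
                rule = cfg.rules[name]
                d.attrs["rule"] = json.dumps({
                    "geometry": rule.geometry,
                    "convergence": rule.convergence,
                    "divergence": rule.divergence})
        _stamp(f, cfg, conn.seed)


def read_connectome(path, known_names=None) -> Connectome:
    from .config import CONNECTION_TYPES
    known = set(CONNECTION_TYPES if known_names is None else known_names)
    conn = Connectome()
    with h5py.File(path, "r") as f:
        _check(f)
        for name, ds in f["connections"].items():
            if name not in known:
                raise SchemaError(f"unknown connection name {name!r}")
            conn.edges[name] = ds[:]
        conn.seed = int(f.attrs["seed"])
    return conn


def write_spikes(path, spikes: SpikeRecord,
                 cfg: ScaffoldConfig | None = None, seed: int = 0) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("spikes", data=np.column_stack(
            [spikes.ids.astype(float), spikes.times]))
        f.attrs["T"] = spikes.T
        _stamp(f, cfg, seed)


def read_spikes(path) -> SpikeRecord:
    with h5py.File(path, "r") as f:
        _check(f)
        data = f["spikes"][:]
        T = float(f.attrs["T"])
    return SpikeRecord(ids=data[:, 0].astype(np.int64), times=data[:, 1], T=T)
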