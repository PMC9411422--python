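"""Snapshot serialisation, mesh export and metric tables.

Snapshots are schema-versioned JSON containing every alive vertex/cell
field at full floating-point precision (Python float repr round-trips
IEEE doubles exactly), the RNG state, the event log, and optional
config hash/seed metadata.  Meshes additionally export as legacy ASCII
VTK polydata (one polygon per cell) with cell-type, polarity and
gene-concentration arrays for visualisation.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass

import numpy as np

from .core import EmbryoState

SCHEMA_VERSION = 1


class SnapshotError(RuntimeError):
    pass


def config_hash(config):
    """Stable sha256 of a configuration (dataclass or mapping)."""
    if is_dataclass(config) and not isinstance(config, type):
        config = asdict(config)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating)):
            return o.item()
        return repr(o)

    blob = json.dumps(config, sort_keys=True, default=default)
    return hashlib.sha256(blob.encode()).hexdigest()


def write_snapshot(state: EmbryoState, path, config=None, seed=None):
    vids = state.alive_vertices
    cids = state.alive_cells
    doc = {
        "schema_version": SCHEMA_VERSION,
        "config_hash": config_hash(config) if config is not None else None,
        "seed": seed,
        "phase": state.phase,
        "time": state.time,
        "boundary_beta0": state.boundary_beta0,
        "rng_state": state.rng.bit_generator.state,
        "n_vertex_rows": state._n_vertex_rows,
        "n_cell_rows": state._n_cell_rows,
        "vertices": {
            "id": vids.tolist(),
            "position": state.positions[vids].tolist(),
            "spring_k": state.spring_k[vids].tolist(),
            "pref_radius": state.pref_radius[vids].tolist(),
        },
        "cells": {
            "id": cids.tolist(),
            "ring": [state.ring(c) for c in cids],
            "cell_type": state.cell_type[cids].tolist(),
            "alpha": state.alpha[cids].tolist(),
            "gamma": state.gamma[cids].tolist(),
            "area0": state.area0[cids].tolist(),
            "perim0": state.perim0[cids].tolist(),
            "beta0": state.beta0[cids].tolist(),
            "pol_G": state.pol_G[cids].tolist(),
            "pol_kfd": state.pol_kfd[cids].tolist(),
            "polarity": state.polarity[cids].tolist(),
            "molecules": state.molecules[cids].tolist(),
            "source": state.source[cids].tolist(),
            "next_division": state.next_division[cids].tolist(),
            "divides": state.divides[cids].tolist(),
        },
        "event_log": [[t, kind, list(cs), list(vs)]
                      for t, kind, cs, vs in state.event_log],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_snapshot(path) -> EmbryoState:
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as err:
            raise SnapshotError(f"corrupt snapshot {path}: {err}") from err
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise SnapshotError(
            f"snapshot schema {doc.get('schema_version')} != "
            f"{SCHEMA_VERSION}")
    st = EmbryoState(phase=doc["phase"], seed=0,
                     boundary_beta0=doc["boundary_beta0"])
    st.time = doc["time"]
    nv = doc["n_vertex_rows"]
    nc = doc["n_cell_rows"]
    st._ensure_vertex_capacity(nv)
    st._ensure_cell_capacity(nc)
    st._n_vertex_rows = nv
    st._n_cell_rows = nc
    v = doc["vertices"]
    vid = np.asarray(v["id"], int)
    st.positions[vid] = np.asarray(v["position"])
    st.spring_k[vid] = v["spring_k"]
    st.pref_radius[vid] = v["pref_radius"]
    st._v_alive[vid] = True
    c = doc["cells"]
    cid = np.asarray(c["id"], int)
    st._rings = [None] * nc
    for i, ring in zip(cid, c["ring"]):
        st._rings[i] = list(ring)
    st.cell_type[cid] = c["cell_type"]
    for name in ("alpha", "gamma", "area0", "perim0", "beta0", "pol_G",
                 "pol_kfd", "source", "next_division"):
        getattr(st, name)[cid] = c[name]
    st.polarity[cid] = np.asarray(c["polarity"])
    st.molecules[cid] = np.asarray(c["molecules"])
    st.divides[cid] = c["divides"]
    st._c_alive[cid] = True
    st.rng.bit_generator.state = doc["rng_state"]
    st.event_log = [(t, kind, tuple(cs), tuple(vs))
                    for t, kind, cs, vs in doc["event_log"]]
    st.invalidate_topology()
    return st


def write_vtk(state: EmbryoState, path):
    """Legacy ASCII VTK polydata: one point per vertex, one polygon per
    cell, with cell-type / area / polarity / gene arrays."""
    from . import core as _core
    vids = state.alive_vertices
    remap = {int(v): i for i, v in enumerate(vids)}
    cids = state.alive_cells
    area, _, _, _ = _core.cell_geometry_arrays(state)
    lines = ["# vtk DataFile Version 3.0",
             f"sphervert embryo t={state.time:.6f}", "ASCII",
             "DATASET POLYDATA", f"POINTS {len(vids)} double"]
    for v in vids:
        p = state.positions[v]
        lines.append(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}")
    size = sum(len(state.ring(c)) + 1 for c in cids)
    lines.append(f"POLYGONS {len(cids)} {size}")
    for c in cids:
        ring = state.ring(c)
        lines.append(" ".join([str(len(ring))]
                              + [str(remap[v]) for v in ring]))
    lines.append(f"CELL_DATA {len(cids)}")
    lines.append("SCALARS cell_type int 1")
    lines.append("LOOKUP_TABLE default")
    lines += [str(int(state.cell_type[c])) for c in cids]
    lines.append("SCALARS area double 1")
    lines.append("LOOKUP_TABLE default")
    lines += [f"{a:.9g}" for a in area]
    for k, name in enumerate(("gene_X", "gene_Y", "gene_Z")):
        lines.append(f"SCALARS {name} double 1")
        lines.append("LOOKUP_TABLE default")
        lines += [f"{state.molecules[c, k]:.9g}" for c in cids]
    lines.append("VECTORS polarity double")
    for c in cids:
        g = state.polarity[c]
        lines.append(f"{g[0]:.9g} {g[1]:.9g} {g[2]:.9g}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def write_metrics_csv(trajectory, path):
    trajectory.to_dataframe().to_csv(path, index=False)


def write_event_csv(state: EmbryoState, path):
    with open(path, "w") as fh:
        fh.write("time,event,cell_ids,vertex_ids\n")
        for t, kind, cs, vs in state.event_log:
            fh.write(f"{t!r},{kind},{';'.join(map(str, cs))},"
                     f"{';'.join(map(str, vs))}\n")
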