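"""Initial blastoderm construction.

The source experiments start from cells "evenly distributed" on the egg
sphere; the construction used here samples seeded random generator
points on the sphere, applies Lloyd relaxation under the spherical
Voronoi diagram, and converts the relaxed diagram into the vertex/cell
records of :class:`~sphervert.core.EmbryoState`.  An optional region
constraint keeps a chosen fraction of the generators inside a spherical
cap during relaxation, which yields the density-contrasted tessellations
used as germ-band initial states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import SphericalVoronoi

from . import core
from .core import EmbryoState, EMBRYONIC


@dataclass
class InitMeshConfig:
    n_cells: int = 64
    radius: float = 270.0
    relaxation_iters: int = 50
    seed: int = 0


class ConfigError(ValueError):
    pass


def sample_sphere(n, radius, rng):
    """Uniform random points on the sphere of given radius."""
    v = rng.standard_normal((n, 3))
    v /= np.linalg.norm(v, axis=1, keepdims=True)
    return radius * v


def _region_centroids(sv):
    """Area-weighted (fan-triangulated) centroid of each Voronoi region,
    vectorised over all regions."""
    regions = sv.regions
    verts = sv.vertices
    lens = np.fromiter((len(r) for r in regions), dtype=np.int64,
                       count=len(regions))
    flat = np.concatenate([np.asarray(r, dtype=np.int64) for r in regions])
    off = np.zeros(len(regions) + 1, np.int64)
    np.cumsum(lens, out=off[1:])
    idx = np.arange(len(flat))
    nxt = idx + 1
    nxt[off[1:] - 1] = off[:-1]
    reg_id = np.repeat(np.arange(len(regions)), lens)
    p = verts[flat]
    pn = verts[flat[nxt]]
    m = np.stack([np.bincount(reg_id, p[:, k]) for k in range(3)],
                 axis=1) / lens[:, None]
    mf = m[reg_id]
    a = p - mf
    b = pn - mf
    cr = np.stack([a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1],
                   a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2],
                   a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]], axis=1)
    w = np.linalg.norm(cr, axis=1)
    tri_c = (p + pn + mf) / 3.0
    num = np.stack([np.bincount(reg_id, tri_c[:, k] * w)
                    for k in range(3)], axis=1)
    tot = np.bincount(reg_id, w)
    cents = np.where(tot[:, None] > 0, num / np.maximum(tot, 1e-300)[:, None],
                     m)
    return cents


def _voronoi(points, radius):
    sv = SphericalVoronoi(points, radius=radius,
                          center=np.zeros(3), threshold=1e-9)
    sv.sort_vertices_of_regions()
    return sv


def lloyd_points(points, radius, iters, constraint=None, rng=None):
    """Lloyd relaxation of generator points under the spherical Voronoi
    diagram.  ``constraint(points) -> points`` is applied after every
    move (used to confine subsets of generators to regions)."""
    pts = points.copy()
    for _ in range(iters):
        try:
            sv = _voronoi(pts, radius)
        except Exception:
            # coincident generators: jitter and retry
            if rng is None:
                rng = np.random.default_rng(0)
            pts = pts + rng.standard_normal(pts.shape) * (radius * 1e-6)
            pts *= radius / np.linalg.norm(pts, axis=1, keepdims=True)
            sv = _voronoi(pts, radius)
        c = _region_centroids(sv)
        c *= radius / np.linalg.norm(c, axis=1, keepdims=True)
        pts = c
        if constraint is not None:
            pts = constraint(pts)
            pts *= radius / np.linalg.norm(pts, axis=1, keepdims=True)
    return pts


def state_from_voronoi(sv, radius, *, phase="germ_disc", seed=0,
                       spring_constant=30.0, **cell_params):
    """Convert a sorted SphericalVoronoi diagram into an EmbryoState.

    Rings are stored counter-clockwise as seen from outside the sphere;
    regions that arrive clockwise are flipped.
    """
    used = sorted({v for reg in sv.regions for v in reg})
    remap = {v: i for i, v in enumerate(used)}
    st = EmbryoState(phase=phase, seed=seed)
    for v in used:
        st.add_vertex(sv.vertices[v], spring_constant, radius)
    for reg in sv.regions:
        ring = [remap[v] for v in reg]
        p = st.positions[ring]
        S = 0.5 * np.cross(p, np.roll(p, -1, axis=0)).sum(axis=0)
        if S @ p.mean(axis=0) < 0:
            ring = ring[::-1]
        st.add_cell(ring, **cell_params)
    return st


def build_initial_blastoderm(config: InitMeshConfig, **cell_params):
    """Build the spherical blastoderm: ``n_cells`` polygonal cells evenly
    tiling the sphere after Lloyd relaxation.  Deterministic for a given
    config.  All cells are embryonic with germ-disc-phase defaults unless
    overridden via ``cell_params``."""
    if config.n_cells < 4:
        raise ConfigError("need at least 4 cells to close a sphere")
    rng = np.random.default_rng(config.seed)
    pts = sample_sphere(config.n_cells, config.radius, rng)
    pts = lloyd_points(pts, config.radius, config.relaxation_iters, rng=rng)
    sv = _voronoi(pts, config.radius)
    defaults = dict(cell_type=EMBRYONIC, alpha=1.0, gamma=2.5,
                    area0=6400.0, perim0=0.0, beta0=1.0, divides=True)
    defaults.update(cell_params)
    return state_from_voronoi(sv, config.radius, seed=config.seed,
                              **defaults)


def build_cap_tessellation(n_inside, n_outside, radius, cap_axis,
                           cap_angle, seed, relaxation_iters=30,
                           **cell_params):
    """Tessellation with ``n_inside`` generators confined to the spherical
    cap of half-angle ``cap_angle`` about ``cap_axis`` and ``n_outside``
    confined to its complement.  Returns ``(state, inside_cell_ids)``.

    Used for germ-band initial states where the embryonic disc is packed
    more densely than the surrounding extraembryonic field.
    """
    rng = np.random.default_rng(seed)
    axis = np.asarray(cap_axis, float)
    axis /= np.linalg.norm(axis)

    def sample_cap(n, lo_cos, hi_cos):
        # uniform on the band lo_cos < cos(theta) <= hi_cos about axis
        z = rng.uniform(lo_cos, hi_cos, n)
        phi = rng.uniform(0, 2 * np.pi, n)
        r = np.sqrt(1 - z ** 2)
        e1 = np.array([1.0, 0, 0]) if abs(axis[0]) < 0.9 else \
            np.array([0, 1.0, 0])
        e1 = e1 - (e1 @ axis) * axis
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(axis, e1)
        return radius * (z[:, None] * axis + (r * np.cos(phi))[:, None] * e1
                         + (r * np.sin(phi))[:, None] * e2)

    cos_c = np.cos(cap_angle)
    pts = np.vstack([sample_cap(n_inside, cos_c, 1.0),
                     sample_cap(n_outside, -1.0, cos_c)])
    inside = np.zeros(len(pts), bool)
    inside[:n_inside] = True
    margin = 1e-3

    def constraint(p):
        ca = (p @ axis) / radius
        # pull strayed generators back to their side of the cap boundary
        out = inside & (ca < cos_c + margin)
        inn = ~inside & (ca > cos_c - margin)
        for mask, target in ((out, cos_c + margin), (inn, cos_c - margin)):
            if mask.any():
                q = p[mask]
                perp = q - (q @ axis)[:, None] * axis
                nrm = np.linalg.norm(perp, axis=1, keepdims=True)
                nrm[nrm == 0] = 1.0
                perp /= nrm
                s = np.sqrt(max(0.0, 1 - target ** 2))
                p[mask] = radius * (target * axis + s * perp)
        return p

    pts = lloyd_points(pts, radius, relaxation_iters,
                       constraint=constraint, rng=rng)
    pts = constraint(pts)
    pts *= radius / np.linalg.norm(pts, axis=1, keepdims=True)
    sv = _voronoi(pts, radius)
    st = state_from_voronoi(sv, radius, phase="germ_band", seed=seed,
                            **cell_params)
    # generator order matches cell-id order in state_from_voronoi
    inside_ids = [c for c in range(len(pts)) if inside[c]]
    return st, inside_ids


def cell_centroids(state):
    _, _, cent, _ = core.cell_geometry_arrays(state)
    return cent


def place_polar_cap(state, pole, n_target):
    """The ``n_target`` cells forming a connected cap nearest (by angular
    distance of their centroids) to ``pole``.

    Grows by edge-adjacency from the nearest cell, always absorbing the
    frontier neighbour closest to the pole, so the result is connected
    even where the plain nearest-by-angle set would not be.  Returns a
    list of cell ids.
    """
    import heapq
    top = state.topology
    if n_target > top.n_cells:
        raise ConfigError("n_target exceeds cell count")
    pole = np.asarray(pole, float)
    pole = pole / np.linalg.norm(pole)
    cent = cell_centroids(state)
    cent_n = cent / np.linalg.norm(cent, axis=1, keepdims=True)
    ang = np.arccos(np.clip(cent_n @ pole, -1, 1))
    # adjacency in compact indices
    nbrs = [[] for _ in range(top.n_cells)]
    for a, b in top.edge_cells:
        nbrs[a].append(b)
        nbrs[b].append(a)
    start = int(np.argmin(ang))
    taken = {start}
    heap = []
    for m in nbrs[start]:
        heapq.heappush(heap, (float(ang[m]), int(m)))
    while len(taken) < n_target:
        a, c = heapq.heappop(heap)
        if c in taken:
            continue
        taken.add(c)
        for m in nbrs[c]:
            if m not in taken:
                heapq.heappush(heap, (float(ang[m]), int(m)))
    return sorted(int(top.cell_ids[c]) for c in taken)
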