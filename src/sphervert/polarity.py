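"""Planar cell polarity and polarity-coupled junction adhesion.

Each cell n carries a polarity vector g_n lying in its own apical plane.
Polarity equilibrates with the edge-neighbours by a synchronous
consensus rule,

    dg_n = sum_m (g_m - g_n) / M_n ,    g_n <- g_n + k_fd dg_n ,

followed by projection back onto the cell plane.  The junction adhesion
coefficient of every edge is then refreshed from the polarity
directions of the two cells facing it:

    beta_ij = (b0/2)(1 + G_n cos(theta_gn - theta_ij))
            + (b0/2)(1 + G_m cos(theta_gm - theta_ij)) ,

where theta_ij is the edge direction seen by each cell.  Because both
angles are measured within the same cell plane, the cosine equals the
dot product of the in-plane unit polarity and unit edge vectors, so no
explicit angular frame is needed.  beta_ij may become negative
(edge-extending tension); that is intended.

The printed orientation convention of the source model is ambiguous, so
the edge direction entering each cell's cosine is selectable:

``ring``
    each cell measures the edge in its own ring orientation
    (cos theta_ij = -cos theta_ji between the two cells);
``shared``
    both cells use the (low id -> high id) direction;
``unsigned``
    magnitude coupling |cos|, insensitive to either convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import core
from .core import EMBRYONIC, EXTRAEMBRYONIC, ABEMBRYONIC, TopologyError


@dataclass
class PolarityParams:
    """Feedback strength k_fd and adhesion-coupling strength G per type."""
    k_fd: dict = None
    G: dict = None

    def __post_init__(self):
        if self.k_fd is None:
            self.k_fd = {EMBRYONIC: 0.1, ABEMBRYONIC: 0.0,
                         EXTRAEMBRYONIC: 0.0}
        if self.G is None:
            self.G = {EMBRYONIC: 10.0, ABEMBRYONIC: 0.0,
                      EXTRAEMBRYONIC: 0.0}


def apply_polarity_params(state, params: PolarityParams):
    for t, v in params.k_fd.items():
        state.pol_kfd[state.alive_cells[state.cell_type[state.alive_cells]
                                        == t]] = v
    for t, v in params.G.items():
        state.pol_G[state.alive_cells[state.cell_type[state.alive_cells]
                                      == t]] = v
    return state


def polarity_update(state, params: PolarityParams | None = None):
    """One synchronous neighbour-consensus update of all polarity vectors
    (computed from the pre-update field), then in-plane projection."""
    if params is not None:
        apply_polarity_params(state, params)
    top = state.topology
    cells = top.cell_ids
    g = state.polarity[cells]
    C = top.n_cells
    a = top.edge_cells[:, 0]
    b = top.edge_cells[:, 1]
    M = np.bincount(a, minlength=C) + np.bincount(b, minlength=C)
    if (M == 0).any():
        raise TopologyError("cell with no neighbours on a closed mesh")
    nbr_sum = np.stack(
        [np.bincount(a, g[b, k], minlength=C)
         + np.bincount(b, g[a, k], minlength=C) for k in range(3)], axis=1)
    dg = nbr_sum / M[:, None] - g
    g = g + state.pol_kfd[cells, None] * dg
    _, _, _, normal = core.cell_geometry_arrays(state)
    g = g - np.einsum("ij,ij->i", g, normal)[:, None] * normal
    state.polarity[cells] = g
    return state


def _inplane_unit(vec, normal):
    v = vec - np.einsum("ij,ij->i", vec, normal)[:, None] * normal
    n = np.linalg.norm(v, axis=1)
    ok = n > core.GEOM_ATOL
    v[ok] /= n[ok, None]
    v[~ok] = 0.0
    return v


def refresh_adhesion(state, params: PolarityParams | None = None,
                     orientation="ring", modulate_boundary=True):
    """Recompute beta_ij(t) for every edge from the current polarity
    field and store it on the topology cache (used by the next force
    evaluation).  Cells with zero polarity contribute their b0/2 term
    with the cosine factor taken as 0."""
    if params is not None:
        apply_polarity_params(state, params)
    top = state.topology
    cells = top.cell_ids
    P = state.positions
    _, _, _, normal = core.cell_geometry_arrays(state)
    nf = normal[top.ring_cell]
    d = P[top.ring_next] - P[top.ring_rows]
    if orientation == "shared":
        sign = np.where(top.ring_rows < top.ring_next, 1.0, -1.0)
        d = d * sign[:, None]
    u = _inplane_unit(d, nf)
    g = state.polarity[cells]
    gn = np.linalg.norm(g, axis=1)
    ghat = np.zeros_like(g)
    ok = gn > core.GEOM_ATOL
    ghat[ok] = g[ok] / gn[ok, None]
    ghat = _inplane_unit(ghat, normal)   # polarity already in-plane; safety
    cosv = np.einsum("ij,ij->i", ghat[top.ring_cell], u)
    if orientation == "unsigned":
        cosv = np.abs(cosv)
    elif orientation not in ("ring", "shared"):
        raise ValueError(f"unknown orientation {orientation!r}")
    beta0 = core.edge_base_adhesion(state, top)
    half = 0.5 * beta0[top.flat_edge] * \
        (1.0 + state.pol_G[cells][top.ring_cell] * cosv)
    beta = np.bincount(top.flat_edge, half, minlength=top.n_edges)
    if not modulate_boundary:
        # variant: heterotypic boundary junctions keep their constant
        # high adhesion; polarity anisotropy acts only within the
        # polarised epithelium
        t0 = state.cell_type[cells[top.edge_cells[:, 0]]]
        t1 = state.cell_type[cells[top.edge_cells[:, 1]]]
        hetero = t0 != t1
        beta[hetero] = beta0[hetero]
    top.edge_beta = beta
    return state


def edge_angle(state, edge, cell_id, reference_axis=(1.0, 0.0, 0.0)):
    """Angle (degrees, in (-180, 180]) of an edge within a cell's plane.

    The edge vector is taken in the cell's ring orientation, so the two
    incident cells see opposite directions (cos flips sign).  The
    in-plane reference axis is the projection of ``reference_axis`` onto
    the cell plane; only angle differences are ever physically
    meaningful, which makes the frame choice unobservable.
    """
    i, j = (edge.vertex_pair if hasattr(edge, "vertex_pair") else edge)
    ring = state.ring(cell_id)
    n = len(ring)
    vec = None
    for k in range(n):
        if ring[k] == i and ring[(k + 1) % n] == j:
            vec = state.positions[j] - state.positions[i]
            break
        if ring[k] == j and ring[(k + 1) % n] == i:
            vec = state.positions[i] - state.positions[j]
            break
    if vec is None:
        raise ValueError(f"edge {(i, j)} not incident to cell {cell_id}")
    _, _, _, normal = core.cell_geometry(state, cell_id)
    v = vec - (vec @ normal) * normal
    if np.linalg.norm(v) < core.GEOM_ATOL:
        raise ValueError("zero-length edge has no direction")
    ref = np.asarray(reference_axis, float)
    e1 = ref - (ref @ normal) * normal
    if np.linalg.norm(e1) < 1e-6:
        ref = np.array([0.0, 1.0, 0.0])
        e1 = ref - (ref @ normal) * normal
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    ang = np.degrees(np.arctan2(v @ e2, v @ e1))
    if ang <= -180.0:
        ang += 360.0
    return float(ang)


def polarity_angle(state, cell_id, reference_axis=(1.0, 0.0, 0.0)):
    """In-plane angle of a cell's polarity vector, same frame as
    :func:`edge_angle`."""
    g = state.polarity[cell_id]
    _, _, _, normal = core.cell_geometry(state, cell_id)
    v = g - (g @ normal) * normal
    if np.linalg.norm(v) < core.GEOM_ATOL:
        raise ValueError("zero polarity has no direction")
    ref = np.asarray(reference_axis, float)
    e1 = ref - (ref @ normal) * normal
    if np.linalg.norm(e1) < 1e-6:
        ref = np.array([0.0, 1.0, 0.0])
        e1 = ref - (ref @ normal) * normal
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    return float(np.degrees(np.arctan2(v @ e2, v @ e1)))


# -- rim initialisation ---------------------------------------------------

def rim_cells(state):
    """Embryonic cells sharing at least one edge with an extraembryonic
    cell (the rim of the germ disc)."""
    top = state.topology
    t0 = state.cell_type[top.cell_ids[top.edge_cells[:, 0]]]
    t1 = state.cell_type[top.cell_ids[top.edge_cells[:, 1]]]
    rim = set()
    for e in np.flatnonzero(t0 != t1):
        for side in (0, 1):
            c = int(top.cell_ids[top.edge_cells[e, side]])
            if state.cell_type[c] == EMBRYONIC:
                rim.add(c)
    return sorted(rim)


def _apdv_field(xyz, R):
    """Tangential rim polarity encoding the A-P (x) and D-V (z) axes.

    Closed-form reading of the source model's (typographically mangled)
    initial-polarity expression: componentwise

        ( sqrt(y^2+z^2)/R * (1 + z/(4R)),
          x/(2R) - 2 z/R,
          x/(2R) + 2 y z / (R sqrt(y^2+z^2)) ).

    Only the direction matters; the vector is subsequently projected
    onto the cell plane and normalised.
    """
    x, y, z = xyz[:, 0], xyz[:, 1], xyz[:, 2]
    rho = np.sqrt(y ** 2 + z ** 2)
    safe = np.maximum(rho, core.GEOM_ATOL)
    g = np.stack([
        rho / R * (1.0 + z / (4.0 * R)),
        x / (2.0 * R) - 2.0 * z / R,
        x / (2.0 * R) + 2.0 * y * z / (R * safe),
    ], axis=1)
    return g


class ScenarioError(RuntimeError):
    pass


def init_rim_polarity(state, variant="rim_apdv", posterior=(1.0, 0.0, 0.0)):
    """Set the initial polarity field: unit tangential vectors on the
    rim cells of the germ disc, zero everywhere else.

    Variants: ``rim_apdv`` (default; closed-form A-P + D-V field),
    ``rim_ap_only`` (polarity parallel to the A-P axis, the control that
    elongates off-axis), ``rim_circumferential`` (mediolateral field
    circulating about the A-P axis), ``none``.
    """
    cells = state.alive_cells
    state.polarity[cells] = 0.0
    if variant == "none":
        return state
    rim = rim_cells(state)
    if not rim:
        raise ScenarioError("no embryonic/extraembryonic interface; "
                            "cannot place rim polarity")
    rim = np.asarray(rim)
    _, _, cent_all, normal_all = core.cell_geometry_arrays(state)
    top = state.topology
    comp = np.array([top.cell_index[int(c)] for c in rim])
    cent = cent_all[comp]
    normal = normal_all[comp]
    R = float(np.mean(state.pref_radius[state.alive_vertices]))
    post = np.asarray(posterior, float)
    post /= np.linalg.norm(post)
    if variant == "rim_apdv":
        g = _apdv_field(cent, R)
    elif variant == "rim_ap_only":
        g = np.broadcast_to(post, cent.shape).copy()
    elif variant == "rim_circumferential":
        g = np.cross(post, cent / np.linalg.norm(cent, axis=1,
                                                 keepdims=True))
    else:
        raise ScenarioError(f"unknown polarity variant {variant!r}")
    g = g - np.einsum("ij,ij->i", g, normal)[:, None] * normal
    n = np.linalg.norm(g, axis=1)
    ok = n > core.GEOM_ATOL
    g[ok] /= n[ok, None]
    g[~ok] = 0.0
    state.polarity[rim] = g
    return state
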