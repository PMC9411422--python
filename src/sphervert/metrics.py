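"""Morphometrics of the embryonic region on the sphere.

The body-axis frame: the posterior pole sits on the +x axis; the A-P
axis is the great circle through the anterior and posterior poles whose
plane best fits the embryonic cell centroids (fitted, so the metrics
rotate with the tissue).  Each embryonic centroid c gets

* an A-P arc-length coordinate  s = R * alpha, where alpha is the
  in-plane angle from the posterior pole, and
* a mediolateral coordinate     m = R * arcsin(c_hat . b_hat), the
  signed arc distance from the A-P great-circle plane (unit normal
  b_hat).

Widths are full mediolateral spans of slab-selected cells; the
elongation index is the A-P extent divided by the largest slab width,
which is 1 for an isotropic disc and L/W for an L x W geodesic strip.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import core
from .core import EMBRYONIC


class MetricError(RuntimeError):
    pass


def _embryonic_centroids(state, cell_type=EMBRYONIC):
    cells = state.alive_cells
    sel = cells[state.cell_type[cells] == cell_type]
    if len(sel) == 0:
        raise MetricError("no embryonic cells present")
    _, _, cent, _ = core.cell_geometry_arrays(state)
    top = state.topology
    comp = np.array([top.cell_index[int(c)] for c in sel])
    c = cent[comp]
    return c / np.linalg.norm(c, axis=1, keepdims=True), sel


def ap_frame(state, posterior=(1.0, 0.0, 0.0)):
    """Orthonormal frame (p_hat, t_hat, b_hat): posterior axis, in-plane
    transverse axis, and the A-P plane normal fitted to the embryonic
    centroids (constrained to contain the posterior axis)."""
    chat, _ = _embryonic_centroids(state)
    p = np.asarray(posterior, float)
    p /= np.linalg.norm(p)
    # basis of the plane orthogonal to p
    e = np.eye(3)[int(np.argmin(np.abs(np.eye(3) @ p)))]
    q1 = e - (e @ p) * p
    q1 /= np.linalg.norm(q1)
    q2 = np.cross(p, q1)
    Q = np.stack([q1, q2], axis=1)             # 3 x 2
    M = Q.T @ (chat.T @ chat) @ Q
    w, v = np.linalg.eigh(M)
    b = Q @ v[:, 0]                             # least-variance direction
    b /= np.linalg.norm(b)
    t = np.cross(b, p)
    # orient t towards the bulk of the tissue
    if (chat @ t).sum() < 0:
        t, b = -t, -b
    return p, t, b


def ap_coordinates(state, posterior=(1.0, 0.0, 0.0)):
    """Per-embryonic-cell (s, m) arc-length coordinates and the sphere
    radius; see module docstring."""
    chat, sel = _embryonic_centroids(state)
    p, t, b = ap_frame(state, posterior)
    R = float(np.mean(state.pref_radius[state.alive_vertices]))
    m = R * np.arcsin(np.clip(chat @ b, -1.0, 1.0))
    proj = chat - (chat @ b)[:, None] * b
    nrm = np.linalg.norm(proj, axis=1)
    nrm[nrm == 0] = 1.0
    proj /= nrm[:, None]
    alpha = np.arctan2(proj @ t, proj @ p)
    s = R * alpha
    return s, m, R, sel


def germ_band_width(state, ap_fraction=0.5, posterior=(1.0, 0.0, 0.0),
                    slab_half_frac=0.05, min_cells=10):
    """Mediolateral width (um) of the embryonic region at a fractional
    position along its A-P extent (0.5 = the midpoint of the band)."""
    s, m, R, _ = ap_coordinates(state, posterior)
    s_lo, s_hi = s.min(), s.max()
    extent = s_hi - s_lo
    s_mid = s_lo + ap_fraction * extent
    slab = np.abs(s - s_mid) <= slab_half_frac * extent
    if slab.sum() < min_cells:
        raise MetricError(
            f"only {int(slab.sum())} embryonic cells in the slab at "
            f"fraction {ap_fraction}")
    return float(m[slab].max() - m[slab].min())


def embryonic_extent_ap(state, posterior=(1.0, 0.0, 0.0)):
    s, _, _, _ = ap_coordinates(state, posterior)
    return float(s.max() - s.min())


def elongation_index(state, posterior=(1.0, 0.0, 0.0),
                     fractions=(0.15, 0.25, 0.35, 0.45, 0.5, 0.55, 0.65,
                                0.75, 0.85)):
    """A-P extent over the widest slab width of the embryonic region.

    1 for an isotropic cap; L/W for an L x W strip.  Slabs with too few
    cells are skipped."""
    widths = []
    for f in fractions:
        try:
            widths.append(germ_band_width(state, f, posterior))
        except MetricError:
            continue
    if not widths:
        raise MetricError("no slab had enough embryonic cells")
    return float(embryonic_extent_ap(state, posterior) / max(widths))


def band_axis_direction(state, posterior=(1.0, 0.0, 0.0)):
    """Unit normal of the great-circle plane best fitting the embryonic
    centroids, *unconstrained* (used to measure off-axis elongation)."""
    chat, _ = _embryonic_centroids(state)
    M = chat.T @ chat
    w, v = np.linalg.eigh(M)
    return v[:, 0] / np.linalg.norm(v[:, 0])


def off_axis_angle(state, posterior=(1.0, 0.0, 0.0)):
    """Angle (degrees) between the tissue's own elongation great circle
    and the nominal A-P great circle: 0 when the band lies along the
    A-P axis."""
    b_free = band_axis_direction(state, posterior)
    p = np.asarray(posterior, float)
    p /= np.linalg.norm(p)
    # the A-P great circle contains p; off-axis elongation tilts the
    # fitted plane so that p acquires a component along its normal
    return float(np.degrees(np.arcsin(min(1.0, abs(b_free @ p)))))


def interface_perimeter(state, type_a, type_b):
    """Total length (um) of the edges between two cell types."""
    top = state.topology
    c0 = top.cell_ids[top.edge_cells[:, 0]]
    c1 = top.cell_ids[top.edge_cells[:, 1]]
    t0 = state.cell_type[c0]
    t1 = state.cell_type[c1]
    sel = ((t0 == type_a) & (t1 == type_b)) | ((t0 == type_b)
                                               & (t1 == type_a))
    P = state.positions
    L = np.linalg.norm(P[top.edge_rows[sel, 1]]
                       - P[top.edge_rows[sel, 0]], axis=1)
    return float(L.sum())


def mean_polarity_alignment(state):
    """Mean cosine between the unit polarities of edge-adjacent cell
    pairs where both are polarised; nan when no such pair exists."""
    top = state.topology
    g = state.polarity[top.cell_ids]
    n = np.linalg.norm(g, axis=1)
    a, b = top.edge_cells[:, 0], top.edge_cells[:, 1]
    ok = (n[a] > core.GEOM_ATOL) & (n[b] > core.GEOM_ATOL)
    if not ok.any():
        return float("nan")
    cos = np.einsum("ij,ij->i", g[a[ok]], g[b[ok]]) / (n[a[ok]] * n[b[ok]])
    return float(np.mean(cos))


@dataclass
class Morphometrics:
    time: float
    n_cells: int
    n_embryonic: int
    n_abembryonic: int
    n_extraembryonic: int
    total_area: float
    elongation_index: float = float("nan")
    midpoint_width: float = float("nan")
    embryonic_extent_ap: float = float("nan")
    polarity_alignment: float = float("nan")
    interface_perimeter: float = float("nan")


def morphometrics(state, posterior=(1.0, 0.0, 0.0), band_metrics=None):
    """Per-frame summary; band-shape metrics are attempted when the
    state is in the germ-band phase (or when forced via band_metrics)."""
    from .core import ABEMBRYONIC, EXTRAEMBRYONIC
    cells = state.alive_cells
    types = state.cell_type[cells]
    area, _, _, _ = core.cell_geometry_arrays(state)
    m = Morphometrics(
        time=state.time, n_cells=len(cells),
        n_embryonic=int((types == EMBRYONIC).sum()),
        n_abembryonic=int((types == ABEMBRYONIC).sum()),
        n_extraembryonic=int((types == EXTRAEMBRYONIC).sum()),
        total_area=float(area.sum()))
    other = ABEMBRYONIC if state.phase == "germ_disc" else EXTRAEMBRYONIC
    try:
        m.interface_perimeter = interface_perimeter(state, EMBRYONIC, other)
    except Exception:
        pass
    if band_metrics is None:
        band_metrics = state.phase == "germ_band"
    if band_metrics:
        try:
            m.elongation_index = elongation_index(state, posterior)
            m.midpoint_width = germ_band_width(state, 0.5, posterior)
            m.embryonic_extent_ap = embryonic_extent_ap(state, posterior)
        except MetricError:
            pass
        m.polarity_alignment = mean_polarity_alignment(state)
    return m
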