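"""Core data model for the spherical-surface cell vertex model.

The embryo is a closed, sphere-topology polygonal mesh: every face is the
apical polygon of one epithelial cell, every edge is a cell-cell junction,
and the vertex positions are the dynamic variables.  The hierarchy is

    vertex  ->  cell (ordered vertex ring)  ->  tissue/embryo (EmbryoState)

Storage is columnar for speed: vertex and cell attributes live in growable
numpy arrays indexed by integer id.  Ids are never reused; rows of removed
vertices/cells are simply masked dead.  Cell rings are Python lists of
vertex ids (counter-clockwise seen from outside the sphere).  A derived
:class:`TopologyCache` holds flat index arrays (CSR-style rings, unique
edges) and is rebuilt lazily after any topological change.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

EMBRYONIC = 0
ABEMBRYONIC = 1
EXTRAEMBRYONIC = 2

CELL_TYPE_NAMES = {EMBRYONIC: "embryonic", ABEMBRYONIC: "abembryonic",
                   EXTRAEMBRYONIC: "extraembryonic"}
CELL_TYPE_CODES = {v: k for k, v in CELL_TYPE_NAMES.items()}

#: absolute tolerance for floating-point geometry comparisons (um scale)
GEOM_ATOL = 1e-9


class TopologyError(RuntimeError):
    """Raised when the mesh violates closed-surface ring consistency."""


@dataclass
class VertexRecord:
    id: int
    position: np.ndarray
    spring_constant: float
    preferred_radius: float


@dataclass
class CellRecord:
    id: int
    vertex_ring: list
    cell_type: str
    alpha: float
    gamma: float
    preferred_area: float
    preferred_perimeter: float
    polarity: np.ndarray
    polarity_feedback: float
    polarity_strength: float
    next_division_time: float
    molecules: np.ndarray
    source_level: float


@dataclass
class EdgeRecord:
    vertex_pair: tuple
    incident_cells: tuple
    base_adhesion: float
    current_adhesion: float
    length: float


@dataclass
class TopologyReport:
    ok: bool
    violations: list = field(default_factory=list)
    #: geometric oddities (e.g. folded cells with inward normals) that
    #: do not break the mesh structure
    warnings: list = field(default_factory=list)

    def __bool__(self):
        return self.ok


class TopologyCache:
    """Flat index arrays derived from the cell rings of one topology.

    Attributes
    ----------
    cell_ids : (C,) int64
        Alive cell ids in ascending order; position in this array is the
        "compact index" used by all other per-cell arrays.
    ring_rows, ring_next, ring_prev : (F,) int64
        Vertex id of each flat ring entry and of its cyclic successor /
        predecessor within the same ring.
    ring_cell : (F,) int64
        Compact cell index owning each flat entry.
    ring_offsets : (C+1,) int64
        CSR offsets of each ring in the flat arrays.
    edge_rows : (E, 2) int64
        Unique undirected edges as (low, high) vertex ids, lexicographic.
    edge_cells : (E, 2) int64
        Compact indices of the two incident cells; column 0 is the cell
        traversing the edge low -> high in its ring orientation.
    flat_edge : (F,) int64
        Undirected-edge index of each flat (directed) ring entry.
    edge_beta : (E,) float64
        Current adhesion coefficient beta_ij(t); initialised to the base
        adhesion derived from incident cell types and overwritten by the
        polarity module each step.
    """

    def __init__(self, state):
        cell_ids = np.flatnonzero(state._c_alive)
        rings = [state._rings[c] for c in cell_ids]
        lens = np.fromiter((len(r) for r in rings), dtype=np.int64,
                           count=len(rings))
        bad = [int(cell_ids[i]) for i in np.flatnonzero(lens < 3)]
        if bad:
            raise TopologyError(f"cells with ring length < 3: {bad}")
        for i, r in enumerate(rings):
            if len(set(r)) != len(r):
                raise TopologyError(
                    f"cell {int(cell_ids[i])} lists a vertex twice: {r}")
        F = int(lens.sum())
        C = len(cell_ids)
        ring_rows = np.concatenate(
            [np.asarray(r, dtype=np.int64) for r in rings]) if C else \
            np.empty(0, np.int64)
        ring_cell = np.repeat(np.arange(C, dtype=np.int64), lens)
        offsets = np.zeros(C + 1, np.int64)
        np.cumsum(lens, out=offsets[1:])
        idx = np.arange(F, dtype=np.int64)
        nxt = idx + 1
        nxt[offsets[1:] - 1] = offsets[:-1]
        prv = idx - 1
        prv[offsets[:-1]] = offsets[1:] - 1
        self.cell_ids = cell_ids
        self.cell_index = {int(c): i for i, c in enumerate(cell_ids)}
        self.ring_rows = ring_rows
        self.ring_next = ring_rows[nxt]
        self.ring_prev = ring_rows[prv]
        self.ring_cell = ring_cell
        self.ring_offsets = offsets
        self.ring_len = lens

        a, b = ring_rows, self.ring_next
        lo = np.minimum(a, b)
        hi = np.maximum(a, b)
        M = int(state._n_vertex_rows)
        key = lo * M + hi
        uniq, inv, counts = np.unique(key, return_inverse=True,
                                      return_counts=True)
        if (counts != 2).any():
            badk = uniq[counts != 2]
            cells = set()
            for k in badk[:8]:
                cells.update(int(cell_ids[ci]) for ci in
                             ring_cell[key == k])
            raise TopologyError(
                "edges not shared by exactly 2 cells; offending cells "
                f"{sorted(cells)}")
        E = len(uniq)
        self.edge_rows = np.stack([uniq // M, uniq % M], axis=1)
        edge_cells = np.full((E, 2), -1, dtype=np.int64)
        forward = a < b
        edge_cells[inv[forward], 0] = ring_cell[forward]
        edge_cells[inv[~forward], 1] = ring_cell[~forward]
        if (edge_cells < 0).any():
            bad_e = np.flatnonzero((edge_cells < 0).any(axis=1))[:8]
            cells = sorted({int(cell_ids[c]) for e in bad_e
                            for c in edge_cells[e] if c >= 0})
            raise TopologyError(
                f"ring orientation mismatch at edges of cells {cells}")
        self.edge_cells = edge_cells
        self.flat_edge = inv
        self.n_vertices = len(np.unique(ring_rows))
        self.n_edges = E
        self.n_cells = C
        self.edge_beta = edge_base_adhesion(state, self)


class EmbryoState:
    """Full dynamic state of the virtual embryo.

    Parameters are stored per vertex / per cell in growable columnar
    arrays; see module docstring.  ``phase`` is ``"germ_disc"`` or
    ``"germ_band"``; ``time`` runs from 0 to 1 in model units.
    """

    _VCOLS = ("positions", "spring_k", "pref_radius")
    _CCOLS = ("cell_type", "alpha", "gamma", "area0", "perim0", "beta0",
              "pol_G", "pol_kfd", "polarity", "molecules", "source",
              "next_division", "divides")

    def __init__(self, phase="germ_disc", seed=0, boundary_beta0=40.0):
        self.phase = phase
        self.time = 0.0
        self.rng = np.random.default_rng(seed)
        #: base adhesion of heterotypic (type-boundary) edges, um
        self.boundary_beta0 = boundary_beta0
        self._n_vertex_rows = 0
        self._n_cell_rows = 0
        cap = 64
        self.positions = np.zeros((cap, 3))
        self.spring_k = np.zeros(cap)
        self.pref_radius = np.zeros(cap)
        self._v_alive = np.zeros(cap, bool)
        ccap = 32
        self.cell_type = np.zeros(ccap, np.int64)
        self.alpha = np.zeros(ccap)
        self.gamma = np.zeros(ccap)
        self.area0 = np.zeros(ccap)
        self.perim0 = np.zeros(ccap)
        self.beta0 = np.zeros(ccap)
        self.pol_G = np.zeros(ccap)
        self.pol_kfd = np.zeros(ccap)
        self.polarity = np.zeros((ccap, 3))
        self.molecules = np.zeros((ccap, 3))
        self.source = np.zeros(ccap)
        self.next_division = np.full(ccap, np.inf)
        self.divides = np.zeros(ccap, bool)
        self._c_alive = np.zeros(ccap, bool)
        self._rings = []
        self._cache = None
        self.event_log = []

    # -- growable storage ------------------------------------------------

    def _ensure_vertex_capacity(self, n):
        cap = len(self.spring_k)
        if n <= cap:
            return
        new = max(2 * cap, n)
        self.positions = np.resize(self.positions, (new, 3))
        self.spring_k = np.resize(self.spring_k, new)
        self.pref_radius = np.resize(self.pref_radius, new)
        alive = np.zeros(new, bool)
        alive[:cap] = self._v_alive[:cap]
        self._v_alive = alive

    def _ensure_cell_capacity(self, n):
        cap = len(self.alpha)
        if n <= cap:
            return
        new = max(2 * cap, n)
        for name in ("cell_type", "alpha", "gamma", "area0", "perim0",
                     "beta0", "pol_G", "pol_kfd", "source"):
            setattr(self, name, np.resize(getattr(self, name), new))
        self.polarity = np.resize(self.polarity, (new, 3))
        self.molecules = np.resize(self.molecules, (new, 3))
        nd = np.full(new, np.inf)
        nd[:cap] = self.next_division[:cap]
        self.next_division = nd
        dv = np.zeros(new, bool)
        dv[:cap] = self.divides[:cap]
        self.divides = dv
        alive = np.zeros(new, bool)
        alive[:cap] = self._c_alive[:cap]
        self._c_alive = alive

    def add_vertex(self, position, spring_constant=30.0,
                   preferred_radius=270.0):
        """Append a vertex; returns its (never reused) id."""
        i = self._n_vertex_rows
        self._ensure_vertex_capacity(i + 1)
        self.positions[i] = position
        self.spring_k[i] = spring_constant
        self.pref_radius[i] = preferred_radius
        self._v_alive[i] = True
        self._n_vertex_rows = i + 1
        self._cache = None
        return i

    def add_cell(self, ring, cell_type=EMBRYONIC, alpha=1.0, gamma=2.5,
                 area0=6400.0, perim0=0.0, beta0=1.0, pol_G=0.0,
                 pol_kfd=0.0, polarity=(0.0, 0.0, 0.0),
                 molecules=(0.0, 0.0, 0.0), source=0.0,
                 next_division=np.inf, divides=False):
        """Append a cell with the given vertex ring; returns its id."""
        c = self._n_cell_rows
        self._ensure_cell_capacity(c + 1)
        self.cell_type[c] = cell_type
        self.alpha[c] = alpha
        self.gamma[c] = gamma
        self.area0[c] = area0
        self.perim0[c] = perim0
        self.beta0[c] = beta0
        self.pol_G[c] = pol_G
        self.pol_kfd[c] = pol_kfd
        self.polarity[c] = polarity
        self.molecules[c] = molecules
        self.source[c] = source
        self.next_division[c] = next_division
        self.divides[c] = divides
        self._c_alive[c] = True
        self._rings.append(list(int(v) for v in ring))
        self._n_cell_rows = c + 1
        self._cache = None
        return c

    def remove_cell(self, cell_id):
        self._c_alive[cell_id] = False
        self._rings[cell_id] = None
        self._cache = None

    def remove_vertex(self, vertex_id):
        self._v_alive[vertex_id] = False
        self._cache = None

    def invalidate_topology(self):
        self._cache = None

    # -- views -----------------------------------------------------------

    @property
    def topology(self):
        if self._cache is None:
            self._cache = TopologyCache(self)
        return self._cache

    @property
    def alive_cells(self):
        return np.flatnonzero(self._c_alive)

    @property
    def alive_vertices(self):
        return np.flatnonzero(self._v_alive)

    @property
    def n_cells(self):
        return int(self._c_alive.sum())

    @property
    def n_vertices(self):
        return int(self._v_alive.sum())

    def ring(self, cell_id):
        return self._rings[cell_id]

    def vertex_record(self, i):
        return VertexRecord(int(i), self.positions[i].copy(),
                            float(self.spring_k[i]),
                            float(self.pref_radius[i]))

    def cell_record(self, c):
        return CellRecord(
            int(c), list(self._rings[c]), CELL_TYPE_NAMES[int(self.cell_type[c])],
            float(self.alpha[c]), float(self.gamma[c]), float(self.area0[c]),
            float(self.perim0[c]), self.polarity[c].copy(),
            float(self.pol_kfd[c]), float(self.pol_G[c]),
            float(self.next_division[c]), self.molecules[c].copy(),
            float(self.source[c]))

    def log_event(self, kind, cell_ids=(), vertex_ids=()):
        self.event_log.append((self.time, kind,
                               tuple(int(c) for c in cell_ids),
                               tuple(int(v) for v in vertex_ids)))

    def copy(self):
        import copy as _copy
        new = EmbryoState.__new__(EmbryoState)
        new.phase = self.phase
        new.time = self.time
        new.rng = _copy.deepcopy(self.rng)
        new.boundary_beta0 = self.boundary_beta0
        new._n_vertex_rows = self._n_vertex_rows
        new._n_cell_rows = self._n_cell_rows
        for name in ("positions", "spring_k", "pref_radius", "_v_alive",
                     "cell_type", "alpha", "gamma", "area0", "perim0",
                     "beta0", "pol_G", "pol_kfd", "polarity", "molecules",
                     "source", "next_division", "divides", "_c_alive"):
            setattr(new, name, getattr(self, name).copy())
        new._rings = [list(r) if r is not None else None
                      for r in self._rings]
        new._cache = None
        new.event_log = list(self.event_log)
        return new


# -- geometry ------------------------------------------------------------

def cell_geometry_arrays(state):
    """Vectorised per-cell geometry over all alive cells.

    Returns ``(area, perimeter, centroid, normal)`` with shapes
    ``(C,), (C,), (C,3), (C,3)`` ordered by the topology cache's compact
    cell index.  Area is the magnitude of the polygon vector area
    ``0.5 * sum_k p_k x p_{k+1}`` (equal to the planar polygon area for a
    flat ring, and to the area of the projection onto the best-fitting
    plane for a near-planar one).  The normal is the unit vector area,
    which points outward for counter-clockwise rings; degenerate (zero
    area) rings fall back to the normalised centroid direction.
    """
    top = state.topology
    P = state.positions
    p = P[top.ring_rows]
    pn = P[top.ring_next]
    cr = np.empty_like(p)
    cr[:, 0] = p[:, 1] * pn[:, 2] - p[:, 2] * pn[:, 1]
    cr[:, 1] = p[:, 2] * pn[:, 0] - p[:, 0] * pn[:, 2]
    cr[:, 2] = p[:, 0] * pn[:, 1] - p[:, 1] * pn[:, 0]
    C = top.n_cells
    S = 0.5 * np.stack([np.bincount(top.ring_cell, cr[:, k], minlength=C)
                        for k in range(3)], axis=1)
    area = np.linalg.norm(S, axis=1)
    L = np.linalg.norm(pn - p, axis=1)
    perim = np.bincount(top.ring_cell, L, minlength=C)
    cent = np.stack([np.bincount(top.ring_cell, p[:, k], minlength=C)
                     for k in range(3)], axis=1) / top.ring_len[:, None]
    normal = np.zeros_like(S)
    ok = area > GEOM_ATOL
    normal[ok] = S[ok] / area[ok, None]
    if (~ok).any():
        c = cent[~ok]
        n = np.linalg.norm(c, axis=1)
        normal[~ok] = c / np.maximum(n, GEOM_ATOL)[:, None]
    return area, perim, cent, normal


def cell_geometry(state, cell_id):
    """Geometry of one cell: ``(area, perimeter, centroid, normal)``."""
    ring = state._rings[cell_id]
    if ring is None or len(ring) < 3:
        raise TopologyError(f"cell {cell_id} has no valid ring")
    p = state.positions[np.asarray(ring)]
    pn = np.roll(p, -1, axis=0)
    S = 0.5 * np.cross(p, pn).sum(axis=0)
    area = float(np.linalg.norm(S))
    perim = float(np.linalg.norm(pn - p, axis=1).sum())
    cent = p.mean(axis=0)
    if area > GEOM_ATOL:
        normal = S / area
    else:
        normal = cent / max(np.linalg.norm(cent), GEOM_ATOL)
    return area, perim, cent, normal


def edge_base_adhesion(state, top=None):
    """Base adhesion beta0_ij per unique edge.

    Homotypic edges take the incident cells' own ``beta0``; edges between
    two different cell types take the heterotypic boundary value
    ``state.boundary_beta0`` (high boundary tension), no matter when the
    edge was created.
    """
    if top is None:
        top = state.topology
    c0 = top.cell_ids[top.edge_cells[:, 0]]
    c1 = top.cell_ids[top.edge_cells[:, 1]]
    hetero = state.cell_type[c0] != state.cell_type[c1]
    b = 0.5 * (state.beta0[c0] + state.beta0[c1])
    b[hetero] = state.boundary_beta0
    return b


def derive_edges(state):
    """Derive the unique cell-cell interfaces from the cell rings.

    Returns a list of :class:`EdgeRecord` in deterministic order (sorted
    by the (low, high) vertex-id pair).  Raises :class:`TopologyError` if
    any edge does not appear in exactly two rings with opposite
    orientation.
    """
    top = state.topology
    beta0 = edge_base_adhesion(state, top)
    P = state.positions
    L = np.linalg.norm(P[top.edge_rows[:, 1]] - P[top.edge_rows[:, 0]],
                       axis=1)
    out = []
    for e in range(top.n_edges):
        cells = tuple(int(top.cell_ids[c]) for c in top.edge_cells[e])
        out.append(EdgeRecord(
            (int(top.edge_rows[e, 0]), int(top.edge_rows[e, 1])), cells,
            float(beta0[e]), float(top.edge_beta[e]), float(L[e])))
    return out


def validate_topology(state):
    """Check closed-surface invariants; returns a :class:`TopologyReport`.

    Verified: rings have >= 3 distinct vertices, every edge lies in
    exactly two rings with opposite orientation, Euler characteristic
    V - E + F = 2, ring orientation is counter-clockwise seen from
    outside (outward normals), and the alive-vertex set matches the set
    of referenced vertices.
    """
    violations = []
    try:
        top = state.topology
    except TopologyError as err:
        return TopologyReport(False, [str(err)])
    euler = top.n_vertices - top.n_edges + top.n_cells
    if euler != 2:
        violations.append(
            f"Euler characteristic V-E+F = {euler} != 2 "
            f"(V={top.n_vertices}, E={top.n_edges}, F={top.n_cells})")
    referenced = np.unique(top.ring_rows)
    alive = state.alive_vertices
    if not np.array_equal(referenced, alive):
        violations.append("alive-vertex set does not match rings")
    warnings = []
    _, _, cent, normal = cell_geometry_arrays(state)
    inward = np.einsum("ij,ij->i", cent, normal) < 0
    if inward.any():
        bad = top.cell_ids[np.flatnonzero(inward)[:8]]
        warnings.append(
            f"cells with inward-pointing normals (folded): "
            f"{list(map(int, bad))}")
    return TopologyReport(not violations, violations, warnings)
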