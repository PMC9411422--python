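"""Discrete topological events: T1 neighbour exchange, T2 extrusion,
cell division along the short axis, division scheduling, preferred-area
growth.

All events operate on the cell rings in place, preserve the closed-mesh
Euler characteristic V - E + F = 2, and never crash on an inapplicable
candidate: a violated precondition skips the event (optionally logged).
Events are applied in deterministic sweeps (see :func:`sweep_events`):
T1 candidates in ascending edge length, then T2, then due divisions, at
most one event per edge/cell per sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import core
from .core import ABEMBRYONIC, EXTRAEMBRYONIC


@dataclass
class EventThresholds:
    #: T1 fires when an edge is shorter than this (um)
    t1_min_edge: float = 3.0
    #: length of the re-opened junction after a T1 (um); must exceed the
    #: trigger to avoid immediate re-firing
    t1_new_edge: float = 3.5
    #: T2 fires on triangular cells smaller than this (um^2)
    t2_min_area: float = 50.0


@dataclass
class DivisionSchedule:
    """Cell-cycle randomisation.

    Cycle lengths are drawn from a normal distribution truncated at
    ``min_cycle``; first divisions are uniform on
    ``[0, first_division_window]``.  Divisions stop exactly when the
    tissue reaches ``target_count`` cells.
    """
    cycle_mean: float = 0.2
    cycle_sd: float = math.sqrt(0.05)
    first_division_window: float = 0.25
    target_count: int = 1500
    min_cycle: float = 0.01
    #: retry delay when a division must be deferred (triangular or
    #: pathological ring); short so the target count is still reached
    defer_delay: float = 0.02


class VertexCellMap:
    """vertex id -> set of incident cell ids, updated incrementally."""

    def __init__(self, state):
        self.map = {}
        for c in state.alive_cells:
            for v in state.ring(c):
                self.map.setdefault(v, set()).add(int(c))

    def __getitem__(self, v):
        return self.map[v]


def _find_dir(ring, u, v):
    """Index k with ring[k] == u and ring[k+1] == v (cyclic), else None."""
    n = len(ring)
    for k in range(n):
        if ring[k] == u and ring[(k + 1) % n] == v:
            return k
    return None


def _edge_neighbour(state, vmap, cell_id, u, v):
    """The cell on the other side of the directed edge u->v of cell_id,
    i.e. the unique cell whose ring traverses v->u."""
    for cand in vmap[u] & vmap[v]:
        if cand != cell_id and _find_dir(state.ring(cand), v, u) is not None:
            return cand
    return None


def t1_transition(state, edge, thresholds=None, vmap=None, check_length=True):
    """Neighbour exchange on the edge (i, j).

    The junction shared by cells A, B collapses and re-opens
    perpendicular to its old direction (in the local tangent plane of
    the sphere) with length ``t1_new_edge``, now shared by the two cells
    C, D that previously met the junction only at its endpoints.
    Returns True if the swap fired, False if a precondition failed.
    """
    if thresholds is None:
        thresholds = EventThresholds()
    i, j = edge
    P = state.positions
    if check_length and np.linalg.norm(P[j] - P[i]) >= thresholds.t1_min_edge:
        return False
    if vmap is None:
        vmap = VertexCellMap(state)
    ci, cj = vmap[i], vmap[j]
    if len(ci) != 3 or len(cj) != 3:
        return False
    shared = ci & cj
    if len(shared) != 2:
        return False
    # A traverses i->j, B traverses j->i; verify actual ring adjacency
    # (a candidate can go stale when an earlier event in the same sweep
    # removed the junction while both vertices still share two cells)
    A = B = None
    for c in shared:
        if _find_dir(state.ring(c), i, j) is not None:
            A = c
        elif _find_dir(state.ring(c), j, i) is not None:
            B = c
    if A is None or B is None:
        return False
    ring_a, ring_b = state.ring(A), state.ring(B)
    if len(ring_a) < 4 or len(ring_b) < 4:
        return False
    (C,) = ci - shared
    (D,) = cj - shared
    if C == D or j in state.ring(C) or i in state.ring(D):
        return False

    cent_a = P[np.asarray(ring_a)].mean(axis=0)
    # topology edits
    ring_a.remove(j)
    ring_b.remove(i)
    ring_c = state.ring(C)
    ring_c.insert(ring_c.index(i), j)
    ring_d = state.ring(D)
    ring_d.insert(ring_d.index(j), i)
    vmap.map[i] = {A, C, D}
    vmap.map[j] = {B, C, D}

    # geometry: rotate the junction 90 degrees about the sphere normal
    m = 0.5 * (P[i] + P[j])
    old = P[j] - P[i]
    nold = np.linalg.norm(old)
    u = old / max(nold, core.GEOM_ATOL)
    nrm = m / max(np.linalg.norm(m), core.GEOM_ATOL)
    perp = np.array([nrm[1] * u[2] - nrm[2] * u[1],
                     nrm[2] * u[0] - nrm[0] * u[2],
                     nrm[0] * u[1] - nrm[1] * u[0]])
    perp /= max(np.linalg.norm(perp), core.GEOM_ATOL)
    if perp @ (cent_a - m) < 0:
        perp = -perp
    # i stays with cell A; place it on A's side
    half = 0.5 * thresholds.t1_new_edge
    P[i] = m + half * perp
    P[j] = m - half * perp

    state.invalidate_topology()
    state.log_event("t1", (A, B, C, D), (i, j))
    return True


def t2_extrusion(state, cell_id, thresholds=None, vmap=None,
                 check_area=True):
    """Extrude a small triangular cell: the cell is removed and its
    three vertices merge into a single new vertex at its centroid, which
    joins the rings of the three neighbouring cells."""
    if thresholds is None:
        thresholds = EventThresholds()
    ring = state.ring(cell_id)
    if ring is None or len(ring) != 3:
        return False
    area, _, cent, _ = core.cell_geometry(state, cell_id)
    if check_area and area >= thresholds.t2_min_area:
        return False
    if vmap is None:
        vmap = VertexCellMap(state)
    i, j, k = ring
    if any(len(vmap[v]) != 3 for v in (i, j, k)):
        return False
    nbrs = []
    for u, v in ((i, j), (j, k), (k, i)):
        nb = _edge_neighbour(state, vmap, cell_id, u, v)
        if nb is None:
            return False
        nbrs.append(nb)
    if len(set(nbrs)) != 3:
        return False
    if any(len(state.ring(n)) < 4 for n in nbrs):
        return False

    w = state.add_vertex(cent, state.spring_k[i], state.pref_radius[i])
    for n, (u, v) in zip(nbrs, ((i, j), (j, k), (k, i))):
        rn = state.ring(n)
        pos = _find_dir(rn, v, u)
        if pos is None:
            raise core.TopologyError(
                f"inconsistent rings at T2 of cell {cell_id}")
        nxt = (pos + 1) % len(rn)
        if nxt > pos:
            new = rn[:pos] + [w] + rn[nxt + 1:]
        else:   # pair wraps around the end of the list
            new = rn[1:pos] + [w]
        state._rings[n] = new
    for v in (i, j, k):
        state.remove_vertex(v)
        del vmap.map[v]
    vmap.map[w] = set(nbrs)
    state.remove_cell(cell_id)
    state.log_event("t2", (cell_id, *nbrs), (i, j, k, w))
    return True


def _division_axes(p, cent, normal):
    """In-plane unit short/long axes of the ring's second-moment ellipse."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(ref @ normal) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    e1 = ref - (ref @ normal) * normal
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(normal, e1)
    q = np.stack([(p - cent) @ e1, (p - cent) @ e2], axis=1)
    M = q.T @ q / len(q)
    w, v = np.linalg.eigh(M)
    short2, long2 = v[:, 0], v[:, 1]     # ascending eigenvalues
    to3 = lambda d: d[0] * e1 + d[1] * e2
    return to3(short2), to3(long2), e1, e2


def divide_cell(state, cell_id, next_times=(np.inf, np.inf), vmap=None):
    """Divide a cell along the short axis of its second-moment ellipse,
    through its geometric centre.

    Two new vertices are inserted where the cut line crosses the ring;
    daughters inherit the parent's type, parameters, polarity and
    molecule concentrations, each with half the parent's preferred area
    and the provided fresh division times.  Returns the two daughter ids
    or None if the division had to be deferred (triangle, or pathological
    ring where neither principal axis yields a clean 2-edge cut).
    """
    ring = state.ring(cell_id)
    if len(ring) < 4:
        return None
    if vmap is None:
        vmap = VertexCellMap(state)
    rv = np.asarray(ring)
    p = state.positions[rv]
    _, _, cent, normal = core.cell_geometry(state, cell_id)
    d_short, d_long, e1, e2 = _division_axes(p, cent, normal)

    q = np.stack([(p - cent) @ e1, (p - cent) @ e2], axis=1)
    n = len(ring)

    def try_axis(d3):
        d2 = np.array([d3 @ e1, d3 @ e2])
        s = d2[0] * q[:, 1] - d2[1] * q[:, 0]
        if np.any(np.abs(s) < 1e-9):
            # vertex exactly on the cut line: nudge the axis
            c, sn = math.cos(1e-4), math.sin(1e-4)
            d2 = np.array([c * d2[0] - sn * d2[1], sn * d2[0] + c * d2[1]])
            s = d2[0] * q[:, 1] - d2[1] * q[:, 0]
            if np.any(np.abs(s) < 1e-12):
                return None
        sn = s[np.arange(n)]
        sm = s[(np.arange(n) + 1) % n]
        crossings = np.flatnonzero(np.sign(sn) != np.sign(sm))
        if len(crossings) != 2:
            return None
        return crossings, sn, sm

    res = try_axis(d_short) or try_axis(d_long)
    if res is None:
        return None
    (a, b), sn, sm = res
    ta = sn[a] / (sn[a] - sm[a])
    tb = sn[b] / (sn[b] - sm[b])
    pa = p[a] + ta * (p[(a + 1) % n] - p[a])
    pb = p[b] + tb * (p[(b + 1) % n] - p[b])
    w1 = state.add_vertex(pa, state.spring_k[rv[a]],
                          state.pref_radius[rv[a]])
    w2 = state.add_vertex(pb, state.spring_k[rv[b]],
                          state.pref_radius[rv[b]])

    seg1 = [ring[k % n] for k in range(a + 1, b + 1)]
    seg2 = [ring[k % n] for k in range(b + 1, a + 1 + n)]
    ring1 = [w1] + seg1 + [w2]
    ring2 = [w2] + seg2 + [w1]

    def inherit(ringx, nt):
        return state.add_cell(
            ringx, cell_type=state.cell_type[cell_id],
            alpha=state.alpha[cell_id], gamma=state.gamma[cell_id],
            area0=0.5 * state.area0[cell_id],
            perim0=state.perim0[cell_id], beta0=state.beta0[cell_id],
            pol_G=state.pol_G[cell_id], pol_kfd=state.pol_kfd[cell_id],
            polarity=state.polarity[cell_id].copy(),
            molecules=state.molecules[cell_id].copy(),
            source=state.source[cell_id], next_division=nt,
            divides=bool(state.divides[cell_id]))

    d1 = inherit(ring1, next_times[0])
    d2 = inherit(ring2, next_times[1])

    # insert the new vertices into the two neighbours across the cut edges
    for w, (u, v) in ((w1, (ring[a], ring[(a + 1) % n])),
                      (w2, (ring[b], ring[(b + 1) % n]))):
        nb = _edge_neighbour(state, vmap, cell_id, u, v)
        if nb is None:
            raise core.TopologyError(
                f"cut edge of cell {cell_id} has no neighbouring ring")
        rn = state.ring(nb)
        rn.insert(_find_dir(rn, v, u) + 1, w)
        vmap.map[w] = {d1, d2, nb}
    for v in ring1[1:-1]:
        vmap.map[v].discard(cell_id)
        vmap.map[v].add(d1)
    for v in ring2[1:-1]:
        vmap.map[v].discard(cell_id)
        vmap.map[v].add(d2)
    vmap.map[w1].update((d1, d2))
    vmap.map[w2].update((d1, d2))

    state.remove_cell(cell_id)
    state.log_event("division", (cell_id, d1, d2), (w1, w2))
    return d1, d2


def draw_cycle(rng, sched: DivisionSchedule):
    """Truncated-normal cell-cycle draw (> min_cycle)."""
    for _ in range(1000):
        x = rng.normal(sched.cycle_mean, sched.cycle_sd)
        if x > sched.min_cycle:
            return x
    return sched.min_cycle


def initialize_division_times(state, sched: DivisionSchedule):
    """First divisions are uniformly staggered over the first quarter of
    the phase for every division-competent cell."""
    if sched.target_count < state.n_cells:
        raise ValueError("target_count below current cell count")
    for c in state.alive_cells:
        if state.divides[c]:
            state.next_division[c] = state.time + state.rng.uniform(
                0.0, sched.first_division_window)
    return state


def grow_preferred_area(state, dt, rate_abembryonic=200.0,
                        rate_extraembryonic=4800.0):
    """Preferred-area growth of the non-proliferative populations.

    Abembryonic cells grow during germ disc formation; extraembryonic
    cells grow during germ band formation; embryonic cells never grow
    (their A0 only halves at divisions).  Rates are in um^2 per unit
    model time.
    """
    cells = state.alive_cells
    if state.phase == "germ_disc":
        sel = cells[state.cell_type[cells] == ABEMBRYONIC]
        state.area0[sel] += rate_abembryonic * dt
    elif state.phase == "germ_band":
        sel = cells[state.cell_type[cells] == EXTRAEMBRYONIC]
        state.area0[sel] += rate_extraembryonic * dt
    return state


def sweep_events(state, thresholds: EventThresholds,
                 sched: DivisionSchedule | None = None):
    """One deterministic event sweep.

    Order: all T1 candidates (ascending current edge length), then T2
    candidates (ascending area), then due divisions (ascending due time);
    at most one event per edge / cell.  Division stops exactly at the
    schedule's target count.  Returns a dict of event counts.
    """
    top = state.topology
    P = state.positions
    L = np.linalg.norm(P[top.edge_rows[:, 1]] - P[top.edge_rows[:, 0]],
                       axis=1)
    cand = np.flatnonzero(L < thresholds.t1_min_edge)
    cand = cand[np.argsort(L[cand], kind="stable")]
    t1_edges = [tuple(map(int, top.edge_rows[e])) for e in cand]

    area, _, _, _ = core.cell_geometry_arrays(state)
    tri = (top.ring_len == 3) & (area < thresholds.t2_min_area)
    t2_cells = [int(top.cell_ids[c]) for c in
                np.flatnonzero(tri)[np.argsort(area[tri], kind="stable")]]

    vmap = VertexCellMap(state)
    counts = {"t1": 0, "t2": 0, "division": 0}
    done = set()
    for i, j in t1_edges:
        if (i, j) in done:
            continue
        done.add((i, j))
        if t1_transition(state, (i, j), thresholds, vmap):
            counts["t1"] += 1
    for c in t2_cells:
        if state._c_alive[c] and t2_extrusion(state, c, thresholds, vmap):
            counts["t2"] += 1

    if sched is not None:
        due = [int(c) for c in state.alive_cells
               if state.divides[c]
               and state.next_division[c] <= state.time]
        due.sort(key=lambda c: (state.next_division[c], c))
        for c in due:
            if state.n_cells >= sched.target_count:
                break
            if not state._c_alive[c]:
                continue
            nts = (state.time + draw_cycle(state.rng, sched),
                   state.time + draw_cycle(state.rng, sched))
            if divide_cell(state, c, nts, vmap) is None:
                # triangle or pathological ring: retry shortly
                state.next_division[c] = state.time + sched.defer_delay
            else:
                counts["division"] += 1
    return counts
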