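"""Vertex mechanics: potential energy, forces, explicit Euler step.

The tissue potential is

    E = sum_n 1/2 alpha_n (A_n - A0_n)^2        (area elasticity)
      + sum_(ij) beta_ij(t) L_ij                (junction adhesion)
      + sum_n 1/2 gamma_n (P_n - P0_n)^2        (perimeter contraction)

The adhesion term defaults to a constant line tension per junction
(energy beta L).  A junction-spring variant (force beta L along the
edge, energy 1/2 beta L^2, where a negative beta actively extends the
junction) is selectable via ``state.adhesion_model = "spring"``.

with each undirected edge counted once.  Vertices move down the exact
analytic gradient of E (overdamped dynamics, velocity = force), plus a
radial spring force -k_i (R_i - R0_i) r_hat that keeps vertices on the
egg sphere.  beta_ij(t) is treated as a constant during differentiation;
the polarity module refreshes it between steps.

The cell area entering E is the magnitude of the polygon vector area
(see :func:`sphervert.core.cell_geometry_arrays`); its gradient with
respect to a ring vertex p_m is  1/2 n_hat x (p_{m-1} - p_{m+1}).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import core


@dataclass
class IntegratorConfig:
    dt: float = 1e-3
    t_end: float = 1.0
    event_check_interval: int = 10
    #: per-step displacement cap (um); acts as local adaptive damping
    #: against explicit-Euler oscillation of isolated stiff vertices
    max_step: float = 2.0


@dataclass
class ForceField:
    constraint: np.ndarray
    area_elasticity: np.ndarray
    adhesion: np.ndarray
    contraction: np.ndarray

    @property
    def total(self):
        return (self.constraint + self.area_elasticity + self.adhesion
                + self.contraction)


class IntegrationError(RuntimeError):
    pass


def _scatter3(rows, values, n):
    return np.stack([np.bincount(rows, values[:, k], minlength=n)
                     for k in range(3)], axis=1)


def total_energy(state, include_spring=False):
    """Tissue potential energy; optionally adds the radial spring
    potential sum_i 1/2 k_i (R_i - R0_i)^2 (used by descent checks).

    The contraction term follows ``state.contraction_model``:
    ``"perimeter"`` is 1/2 gamma (P - P0)^2 per cell; ``"junctional"``
    is 1/2 gamma sum_k L_k^2 over the cell's junctions (tension
    gamma L per junction, so short junctions carry little isotropic
    tension and adhesion anisotropy can collapse them).
    """
    top = state.topology
    cells = top.cell_ids
    area, perim, _, _ = core.cell_geometry_arrays(state)
    alpha = state.alpha[cells]
    if getattr(state, "area_model", "absolute") == "scaled":
        alpha = alpha / state.area0[cells]
    e_area = 0.5 * alpha * (area - state.area0[cells]) ** 2
    P = state.positions
    if getattr(state, "contraction_model", "perimeter") == "junctional":
        Lf = np.linalg.norm(P[top.ring_next] - P[top.ring_rows], axis=1)
        e_per = 0.5 * np.bincount(top.ring_cell,
                                  state.gamma[cells][top.ring_cell]
                                  * Lf ** 2, minlength=top.n_cells)
    else:
        e_per = 0.5 * state.gamma[cells] * (perim
                                            - state.perim0[cells]) ** 2
    L = np.linalg.norm(P[top.edge_rows[:, 1]] - P[top.edge_rows[:, 0]],
                       axis=1)
    if getattr(state, "adhesion_model", "tension") == "spring":
        e_adh = 0.5 * top.edge_beta * L ** 2
    else:
        e_adh = top.edge_beta * L
    e = float(e_area.sum() + e_per.sum() + e_adh.sum())
    if include_spring:
        rows = state.alive_vertices
        R = np.linalg.norm(P[rows], axis=1)
        e += float((0.5 * state.spring_k[rows]
                    * (R - state.pref_radius[rows]) ** 2).sum())
    return e


def compute_forces(state):
    """Exact analytic force field -dE/dr plus the spherical constraint."""
    top = state.topology
    cells = top.cell_ids
    n = state._n_vertex_rows
    P = state.positions
    area, perim, _, normal = core.cell_geometry_arrays(state)

    # area elasticity
    alpha = state.alpha[cells]
    if getattr(state, "area_model", "absolute") == "scaled":
        alpha = alpha / state.area0[cells]
    coef_a = alpha * (area - state.area0[cells])   # (C,)
    pprev = P[top.ring_prev]
    pnext = P[top.ring_next]
    gradA = 0.5 * np.cross(normal[top.ring_cell], pprev - pnext)
    f_area = _scatter3(top.ring_rows, -coef_a[top.ring_cell, None] * gradA,
                       n)

    # contraction
    p = P[top.ring_rows]
    d = pnext - p
    L = np.linalg.norm(d, axis=1)
    u = d / np.maximum(L, core.GEOM_ATOL)[:, None]
    if getattr(state, "contraction_model", "perimeter") == "junctional":
        # tension gamma_n L on each junction of cell n
        cu = state.gamma[cells][top.ring_cell, None] * d
    else:
        # uniform line tension gamma_n (P_n - P0_n) on every junction
        coef_p = state.gamma[cells] * (perim - state.perim0[cells])
        cu = coef_p[top.ring_cell, None] * u
    f_per = _scatter3(top.ring_rows, cu, n) \
        - _scatter3(top.ring_next, cu, n)

    # adhesion on unique edges
    lo = top.edge_rows[:, 0]
    hi = top.edge_rows[:, 1]
    de = P[hi] - P[lo]
    if getattr(state, "adhesion_model", "tension") == "spring":
        # junction spring: force beta L along the edge (the adhesion
        # force grows with contact length); energy 1/2 beta L^2
        bu = top.edge_beta[:, None] * de
    else:
        # constant line tension beta; energy beta L
        Le = np.linalg.norm(de, axis=1)
        ue = de / np.maximum(Le, core.GEOM_ATOL)[:, None]
        bu = top.edge_beta[:, None] * ue
    f_adh = _scatter3(lo, bu, n) - _scatter3(hi, bu, n)

    # spherical constraint
    f_con = np.zeros((n, 3))
    rows = state.alive_vertices
    R = np.linalg.norm(P[rows], axis=1)
    if (R < core.GEOM_ATOL).any():
        raise IntegrationError("vertex at the sphere centre; cannot "
                               "normalise the radial direction")
    f_con[rows] = (-state.spring_k[rows] * (R - state.pref_radius[rows])
                   / R)[:, None] * P[rows]

    return ForceField(f_con, f_area, f_adh, f_per)


def euler_step(state, config: IntegratorConfig):
    """Advance every vertex by dt * total force (in place).

    Topology and beta_ij are untouched; discrete events and adhesion
    refresh are orchestrated by the scenario loop.
    """
    f = compute_forces(state).total
    rows = state.alive_vertices
    step = config.dt * f[rows]
    if config.max_step:
        mag = np.linalg.norm(step, axis=1)
        over = mag > config.max_step
        if over.any():
            step[over] *= (config.max_step / mag[over])[:, None]
    state.positions[rows] += step
    state.time += config.dt
    if not np.isfinite(state.positions[rows]).all():
        raise IntegrationError(
            f"non-finite vertex position after step at t={state.time}; "
            f"dt={config.dt}, max |F|={np.abs(f).max():g}")
    return state
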