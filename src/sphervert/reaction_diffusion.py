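"""Three-species gene network with neighbour diffusion on the cell graph.

Every cell n carries concentrations (X_n, Y_n, Z_n) >= 0 evolving as

    dX/dt = R_X + D_X L[X],   dY/dt = R_Y + D_Y L[Y],   dZ/dt = R_Z

with the reaction terms

    R_X = A_X X0 - B_X Y
    R_Y = A_Y Y - (Y - Y0)^3 - B_Y X + C_Y Z
    R_Z = A_Z X - B_Z Y - C_Z Z

where X0 is a per-cell constant source (1 on the rim of the embryo, 0
elsewhere) and L is a graph Laplacian over edge-neighbouring cells
weighted by the inverse squared centroid distance,

    L[C]_n = sum_m (C_m - C_n) / |c_m - c_n|^2 .

The reaction clock is decoupled from the developmental clock: the
morphogenetic phase spans one model time unit, while the network runs
``time_scale`` reaction time units per model time unit so that several
oscillation periods fit within one phase (see docs/methods.md).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import core


@dataclass
class RDParams:
    A_X: float = 1.2
    B_X: float = 1.0
    A_Y: float = 0.2
    B_Y: float = 1.0
    C_Y: float = 1.2
    A_Z: float = 1.0
    B_Z: float = 1.0
    C_Z: float = 0.5
    Y0: float = 1.0
    D_X: float = 20.0
    D_Y: float = 5.0
    D_Z: float = 0.0
    #: reaction time units per model time unit; the isolated rim-source
    #: oscillator has period ~9.8 reaction time units, so one
    #: morphogenetic phase spans about five emission cycles
    time_scale: float = 50.0
    #: reaction-clock step; None = one substep per mechanics step
    rd_dt: float | None = None
    #: Laplacian weighting: inverse squared centroid distance (the model
    #: default) or plain inverse distance (sensitivity check)
    weighting: str = "inv_sq_distance"


class RDError(RuntimeError):
    pass


def reaction_rates(X, Y, Z, X0, params: RDParams):
    """Reaction terms (R_X, R_Y, R_Z); elementwise over arrays."""
    RX = params.A_X * X0 - params.B_X * Y
    RY = params.A_Y * Y - (Y - params.Y0) ** 3 - params.B_Y * X \
        + params.C_Y * Z
    RZ = params.A_Z * X - params.B_Z * Y - params.C_Z * Z
    return RX, RY, RZ


def diffusion_term(state, values, D, params: RDParams | None = None,
                   centroids=None):
    """Graph-Laplacian exchange of a per-cell field ``values`` (compact
    cell order); returns the per-cell rate.  D = 0 short-circuits to 0."""
    top = state.topology
    C = top.n_cells
    if D == 0:
        return np.zeros(C)
    if centroids is None:
        _, _, centroids, _ = core.cell_geometry_arrays(state)
    a = top.edge_cells[:, 0]
    b = top.edge_cells[:, 1]
    d = np.linalg.norm(centroids[a] - centroids[b], axis=1)
    d = np.maximum(d, 1e-6)
    if params is not None and params.weighting == "inv_distance":
        w = 1.0 / d
    else:
        w = 1.0 / d ** 2
    flux = w * (values[b] - values[a])    # towards a when positive
    out = np.bincount(a, flux, minlength=C) - np.bincount(b, flux,
                                                          minlength=C)
    return D * out


def rd_step(state, params: RDParams, dt):
    """Advance the gene network by ``dt`` model time units (explicit
    Euler on the reaction clock, concentrations clamped at 0)."""
    top = state.topology
    cells = top.cell_ids
    tau = dt * params.time_scale
    sub = 1 if params.rd_dt is None else max(1, int(round(tau /
                                                          params.rd_dt)))
    h = tau / sub
    _, _, cent, _ = core.cell_geometry_arrays(state)
    X = state.molecules[cells, 0].copy()
    Y = state.molecules[cells, 1].copy()
    Z = state.molecules[cells, 2].copy()
    X0 = state.source[cells]
    for _ in range(sub):
        RX, RY, RZ = reaction_rates(X, Y, Z, X0, params)
        X = X + h * (RX + diffusion_term(state, X, params.D_X, params,
                                         cent))
        Y = Y + h * (RY + diffusion_term(state, Y, params.D_Y, params,
                                         cent))
        Z = Z + h * (RZ + diffusion_term(state, Z, params.D_Z, params,
                                         cent))
        np.maximum(X, 0.0, out=X)
        np.maximum(Y, 0.0, out=Y)
        np.maximum(Z, 0.0, out=Z)
    if not (np.isfinite(X).all() and np.isfinite(Y).all()
            and np.isfinite(Z).all()):
        raise RDError(f"non-finite concentration at t={state.time}; "
                      f"reaction step {h:g} too large")
    state.molecules[cells, 0] = X
    state.molecules[cells, 1] = Y
    state.molecules[cells, 2] = Z
    return state


def assign_rim_source(state, level=1.0):
    """Mark the current rim cells as constant X-input sources
    (X0 = ``level``); all other cells get X0 = 0.  Fixed cell property
    thereafter (inherited through divisions)."""
    from .polarity import rim_cells
    cells = state.alive_cells
    state.source[cells] = 0.0
    rim = rim_cells(state)
    state.source[rim] = level
    return state
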