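# sphervert

A cell vertex model on a spherical surface for simulating whole-embryo
morphogenesis in spider-like (spiral-cleaving, yolk-rich) eggs. The
embryo is one closed layer of polygonal apical cell surfaces tiling a
sphere; there are no tissue boundaries to prescribe, so whole-embryo
processes — germ disc formation, the germ disc → germ band transition,
and gene-expression patterning on the rearranging cell field — can be
simulated end to end. It is aimed at developmental biologists and
tissue-mechanics modellers who want a small, fully scripted, seedable
simulator of these processes.

## Model

Vertex positions r_i evolve by overdamped gradient dynamics

    dr_i/dt = F_constraint + F_area + F_adhesion + F_contraction

with the tissue energy

    E = Σ_n ½ α_n (A_n − A0_n)² + Σ_(ij) β_ij(t) L_ij
      + Σ_n ½ γ_n (P_n − P0_n)²

(area elasticity, junction adhesion, perimeter contraction) and a
radial spring F_constraint = −k_i (R_i − R0_i) r̂_i representing the
yolk-filled egg (R0 = 270 µm). Each cell carries a planar polarity
vector g_n that equilibrates with its neighbours
(g_n ← g_n + k_fd · Σ_m (g_m − g_n)/M_n) and modulates junction
adhesion anisotropically,

    β_ij = (β0/2)(1 + G cos(θ_gn − θ_ij)) + (β0/2)(1 + G cos(θ_gm − θ_ij)).

T1 neighbour exchanges, T2 extrusions and short-axis cell divisions
remodel the topology; two differentiated cell populations (abembryonic
in the disc phase, extraembryonic in the band phase) are
non-proliferative, mechanically soft, and meet the embryonic field at
high-adhesion boundary junctions. Optionally every cell runs a
three-gene network X, Y, Z with neighbour diffusion over the cell
adjacency graph. `docs/methods.md` documents every equation, parameter,
numerical choice, and the model's measured limitations.

## Worked example

```python
from sphervert import studies, metrics

traj = studies.band_run(seed=1, n_initial=300, extraembryonic_count=30,
                        target_count=1200, t_end=1.0)
st = traj.final_state
print("final cells:", st.n_cells)
print("midpoint width (um): %.1f" % metrics.germ_band_width(st, 0.5))
print("elongation index: %.2f" % metrics.elongation_index(st))
print("events:", traj.event_counts)
```

prints

```
final cells: 1200
midpoint width (um): 478.0
elongation index: 1.10
events: {'t1': 14704, 't2': 69, 'division': 969}
```

a quarter-size germ-band run: the tissue grows from 300 to exactly
1,200 cells while ~15,000 neighbour exchanges remodel it; the embryonic
field ends 478 µm wide at its anterior–posterior midpoint with an
elongation index of 1.10 (1.0 = isotropic disc — see the limitations
section of `docs/methods.md` for why elongation stays weak).
`traj.to_dataframe()` gives the per-frame morphometric time series, and
`sphervert.snapshots` writes JSON snapshots and VTK meshes for any
state.

The same scenarios run from a shell:

```
sphervert run --scenario germ_disc --seed 1 --out runs/disc
sphervert perturb --variant G_zero --seed 1 --out runs/g0
sphervert metrics runs/disc
```

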