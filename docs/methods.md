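# Model and methods

`sphervert` simulates a spider-like early embryo as a single layer of
epithelial cells tiling a sphere. Each cell is the polygon of its apical
surface; the polygon vertices are the dynamic variables. The package
covers the two morphogenetic phases of early spider development — germ
disc formation (a contracting cap of small, tense cells differentiates
from a sparse extra-disc population) and germ disc → germ band
transition (a polarity-patterned disc that is meant to converge
mediolaterally and extend along the anterior–posterior axis) — plus a
three-gene reaction–diffusion network running on the deforming cell
adjacency graph.

## Mechanics

Vertices follow overdamped gradient dynamics

    dr_i/dt = F_constraint + F_area + F_adhesion + F_contraction,

where the three tissue terms are the exact analytic gradient of

    E = Σ_n ½ α_n (A_n − A0_n)² + Σ_(ij) β_ij(t) L_ij
      + Σ_n ½ γ_n (P_n − P0_n)²,

with each junction counted once, and the constraint term is a radial
spring −k_i(R_i − R0_i) r̂_i confining vertices to the egg surface
(R0 = 270 µm, k = 30 for the house-spider egg). Cell area A_n is the
magnitude of the polygon vector area ½ Σ_k p_k × p_{k+1}; for a planar
ring this is the ordinary polygon area, for a near-planar ring it is
the area of the projection onto the best-fitting plane, and its
gradient with respect to ring vertex p_m is ½ n̂ × (p_{m−1} − p_{m+1}),
which the force routine uses directly. Perimeters use straight chord
lengths. Every force term is validated against central finite
differences of E (relative error < 1e-6, enforced in the test suite).

Three energy variants are config-selectable for sensitivity analysis
and default to the printed forms above: `adhesion_model="spring"`
replaces the constant line tension by a zero-rest-length junction
spring (force β L, energy ½βL²); `contraction_model="junctional"`
replaces the whole-perimeter contraction by ½γ Σ L² per cell;
`area_model="scaled"` divides α by A0. None of these is the default.

Integration is explicit Euler. The disc phase uses dt = 1e-4 (its
initial 64 cells have ~75 µm edges and the area term is unstable above
dt ≈ 3e-4); the band phase uses dt = 1e-3. A per-step displacement cap
(2 µm, `IntegratorConfig.max_step`) acts as local adaptive damping for
isolated stiff vertices of hugely stretched extraembryonic polygons; it
never engages in the convergence and descent unit tests, which disable
it.

## Planar cell polarity and anisotropic adhesion

Each cell carries an in-plane polarity vector g_n. Once per step the
field takes a synchronous consensus update
Δg_n = Σ_m (g_m − g_n)/M_n, g_n ← g_n + k_fd Δg_n over the M_n edge
neighbours, followed by projection back onto the cell plane (magnitudes
are not renormalised). Junction adhesion then becomes

    β_ij = (β0/2)(1 + G_n cos(θ_gn − θ_ij))
         + (β0/2)(1 + G_m cos(θ_gm − θ_ij)),

evaluated as the dot product of in-plane unit vectors, so no angular
frame is needed. The source description leaves the per-cell edge
orientation convention ambiguous; the package offers three readings
(`adhesion_orientation`): `ring` (each cell uses its own ring
direction; a smooth field then modulates nothing because the two
half-terms cancel), `shared` (a fixed vertex-order direction; the sign
of the coupling becomes label-dependent), and the default `unsigned`
(|cos| coupling), which matches both analytic limits — β0(1+G) for
junctions parallel to both polarities, β0 for perpendicular ones — and
is independent of either convention. Cells with zero polarity
contribute β0/2 with the cosine taken as zero. Heterotypic boundary
junctions (base adhesion 40 µm) are modulated like any other junction
by default; `modulate_boundary_adhesion=False` pins them at 40.

Initial polarity lives only on the rim of the germ disc (embryonic
cells bordering extraembryonic ones). The default `rim_apdv` field
encodes both body axes through the closed form

    g(x, y, z) ∝ ( √(y²+z²)/R · (1 + z/4R),
                   x/2R − 2z/R,
                   x/2R + 2yz/(R √(y²+z²)) ),

projected to the cell plane and normalised (the published expression is
typographically mangled; this is our reading of it). `rim_ap_only`
(polarity = projected posterior direction, the control that should
elongate off-axis) and `rim_circumferential` are provided as documented
variants.

## Cell types, schedules and events

Phase parameter tables (packaged in `sphervert/data/defaults.yaml`):
disc — embryonic α=1 µm⁻², β0=1 µm, γ=2.5; abembryonic α=1, β0=1,
γ=0.5; band — embryonic α=1, β0=1, γ=0.5, k_fd=0.1, G=10;
extraembryonic α=0.1, β0=0.1, γ=0.15, k_fd=G=0. Heterotypic junctions
carry β0=40 µm regardless of when they are created. A0 starts at
6,400 µm² (disc) / 200 µm² (band), halves at each division, and P0=0
throughout.

Divisions cut along the short principal axis of the ring's second
moment ellipse through the centroid; daughters inherit type,
parameters, polarity and concentrations. Cycle lengths are
N(0.2, sd 0.05) in the disc and N(0.5, sd 0.1) in the band (truncated
> 0.01; the printed spreads are read as standard deviations — the
variance reading remains selectable), first divisions uniform over the
first quarter of the phase. Divisions stop exactly at the phase targets
(1,500 / 6,000 cells) and resume only if extrusions drop the census; a
cell that cannot divide (triangular or pathological ring) retries after
0.02 time units so the census is still reached. T1 neighbour exchanges
fire on junctions shorter than 3 µm and reopen perpendicular (in the
local tangent plane) at 3.5 µm; T2 extrusion removes sub-50 µm²
triangles, merging their ring into one vertex at the centroid. Events
run in deterministic sweeps every 10 steps (T1 by ascending length,
then T2, then due divisions), at most one event per junction or cell
per sweep, and every event preserves V − E + F = 2 (stress-tested over
10⁴ mixed events).

Scenario assembly. The 64-cell blastoderm is a seeded spherical
Voronoi tessellation with Lloyd relaxation (50 iterations). Abembryonic
differentiation converts the 100-cell connected cap nearest the +x pole
at t = 0.5. The band phase starts from a fresh 1,500-cell tessellation:
a dense embryonic cap (1,350 cells confined during relaxation to a cap
whose area fraction 0.295 equals n·A0/4πR², so the cells start
pressure-neutral) around an axis tilted 25° ventral of the posterior
pole, with 150 extraembryonic cells outside — placing the
extraembryonic field closest to the dorsal rim; the `central` placement
variant puts them in a cap around the posterior pole instead.
Preferred-area growth of the non-proliferative populations is
8,000 µm²/time (abembryonic) and 4,800 µm²/time (extraembryonic): the
published growth figures do not carry usable units, so the defaults are
set by surface bookkeeping — each population's A0 approaches the share
of the egg surface it must occupy by the end of its phase.

## Gene network

Each cell holds concentrations (X, Y, Z) ≥ 0 with reactions
R_X = A_X X0 − B_X Y, R_Y = A_Y Y − (Y−Y0)³ − B_Y X + C_Y Z,
R_Z = A_Z X − B_Z Y − C_Z Z (parameters as published; X0 is a constant
per-cell source, 1 on the rim and 0 elsewhere, persistent through
divisions) and neighbour diffusion D·Σ_m (C_m − C_n)/|c_m − c_n|²
over centroid distances (inverse-distance weighting selectable).
Explicit Euler on a separate reaction clock: `time_scale` = 50 reaction
time units per model time unit (the isolated rim oscillator has period
≈ 9.8, so a phase spans about five emission cycles), with optional
substepping `rd_dt`.

A property worth knowing before interpreting patterns: the sourceless
rest state of this network is X = Z = 0, Y ≈ 1.70 (the positive root of
A_Y·Y = (Y−Y0)³), a stable inhibited background. Against R_X ≈ −1.7, an
X pulse can only be relayed where diffusive influx beats that drain,
which at D_X = 20 requires centroid spacings below roughly 8–9 µm; the
band-phase field starts near 15 µm. In consequence the rim source emits
a single transient pulse and is then itself silenced by the inhibited
background diffusing in (oscillator death) — the packaged field does
not sustain travelling or splitting wave trains. The decoupled (D = 0)
per-cell dynamics match an adaptive reference integrator to 1e-4.

## Morphometrics

The A-P frame fits, among great-circle planes containing the ±x poles,
the one closest to the embryonic centroids; each centroid then has an
A-P arc coordinate s = R·α (angle from the posterior pole within the
plane) and a mediolateral coordinate m = R·arcsin(ĉ·b̂) (signed arc
distance from the plane). The midpoint width is the full mediolateral
span of the cells inside a ±5% slab of the A-P extent at its middle;
the elongation index is the A-P extent divided by the widest slab width
(1.0 for an isotropic cap, L/W for an L×W geodesic strip — both
verified against painted synthetic geometries). Full spans are used
rather than percentile spans because percentile spans cannot reproduce
the analytic references (the 95% span of a full sphere's latitude
distribution is 0.80·πR, not πR). Off-axis elongation is the angle
between the posterior axis and the unconstrained best-fit great-circle
plane of the embryonic field. Boundary smoothness is reported as
isoperimetric roughness: interface length divided by the circumference
of the spherical cap of equal enclosed area.

## What the simulations do and do not reproduce

Reproduced: the germ disc census (exactly 1,500 cells, 100
abembryonic), the band census (exactly 6,000), boundary smoothing by
heterotypic tension (roughness 1.6 vs 1.9 for the β0=1 control),
seed-exact determinism, and the monotone decrease of the band midpoint
width as embryonic contraction γ is scaled 0.5×/1×/2×.

Not reproduced: the full disc→band convergent extension. Under the
printed energy and parameter scales the area-elastic stiffness
dominates the polarity-coupled tension anisotropy by one to two orders
of magnitude (dimensionless junction tension β/(α A0^{3/2}) ≈
0.001–0.03 against the ≈ 0.1 needed for tension-driven junction
collapse); measured on the running tissue, a 10:1 junction-tension
anisotropy shortens aligned junctions by only 5–20% and biases T1
orientation statistics by under 5%, so the embryonic field stays
cap-shaped (elongation index ≈ 1.0–1.06; midpoint widths ≈ 590–650 µm
against the published 226/206/180 µm). We probed every structural
reading we could justify — the three orientation conventions, junction
springs vs line tension, junctional vs perimeter contraction, scaled
area elasticity, boundary modulation on/off, stronger extraembryonic
growth, 20× vertex mobility, larger T1 reopening lengths, per-step
event sweeps — without recovering the published morphogenesis, and
conclude that it depends on implementation details beyond the printed
description. The gene-network wave trains fail for the independent
reason described above. All of these comparisons are computed by the
test suite and the acceptance script, which report the measured values
as they come.

The synthetic blastoderm generator (seeded spherical Voronoi + Lloyd)
emulates the even packing of the real blastoderm but none of its
biological variability: no egg-shape deviation from a sphere, no
cell-size heterogeneity beyond tessellation noise, no yolk mechanics
beyond the radial spring. Passing tests on these fixtures therefore
validate the algorithms, not predictions about real embryos.

## Study sizes

Unit tests run on 20–200-cell fixtures. Acceptance-level runs use the
full published sizes for the census and width studies (64→1,500 and
1,500→6,000 cells; widths as replicate medians over 3 seeds per γ) and
half-size tissues (750→3,000) for the perturbation panel. Seeds are
explicit everywhere; identical configuration and seed reproduce runs
bit-exactly.
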