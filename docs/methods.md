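# Methods

`coroperf` simulates contrast-agent (CA) perfusion of a 2D myocardial
slice with a hybrid model: a *discrete* coronary arterial tree generated
by constrained constructive optimization (CCO) carries the CA by
advection-diffusion on a node graph, and hands it over at the tree's
terminal segments to a *continuum* porous-media description of the
extravascular tissue, with an adsorbing fibrotic compartment for scar and
a 1D transit line for systemic recirculation. All concentrations are in
arbitrary units (the read-out mimics MRI signal intensity, which is
relative); internal units are mm, s, Pa, with flows in mm³/s
(1 mL/min = 1000/60 mm³/s) and pressures converted at the configuration
boundary (1 mmHg = 133.322 Pa).

## Arterial tree generation (CCO)

Each of the three coronary territories (LCX, LAD, RCA — equal 120°
sectors of the annular slice) receives its own binary tree of straight
rigid cylindrical segments, grown one terminal at a time:

1. a candidate terminal site is drawn uniformly over the territory's
   cells and rejected while it lies closer than
   `d_thresh = d_thresh_scale · sqrt(A_region / k)` to the existing tree
   (threshold shrunk by 0.9 after every 10 consecutive rejections);
2. trial connections are formed to the `n_candidate_segments = 20`
   nearest segments; for each, the bifurcation point is optimized over
   the interior of the triangle (proximal point, distal point, new site)
   by Nelder–Mead on barycentric coordinates (tolerance 1e-6 mm, capped
   at 120 evaluations) to minimize the total intravascular volume
   `V = π Σ l_s r_s²`;
3. the geometrically valid connection of least volume is committed.

Throughout growth the tree satisfies: Poiseuille resistance
`R_s = 8 η l_s / (π r_s⁴)` with η = 3.6e-3 Pa·s; equal terminal outflows
`Q_term = Q_perf / N_term` (Q_perf = 1 mL/min per tree); a common
terminal pressure p_term = 60 mmHg against the root pressure
p_perf = 100 mmHg; and the bifurcation power law
`r_p^γ = r_l^γ + r_r^γ` with γ = 3 (Murray's law; 2.55–3 supported).
Radii are not iterated: a bottom-up sweep computes reduced subtree
resistances and daughter/parent radius ratios from the equal-pressure
condition, the root radius follows from `Δp = Q_perf · R_subtree(root)`,
and a top-down sweep fixes every radius — the constraints then hold to
roundoff, which the tests verify (bifurcation-law residual < 1e-10
relative, terminal pressures within 1e-6 mmHg, exponent recovered by
bisection to 1e-6).

Two constants are our own: root inlets sit on the epicardial rim at each
sector's mid-angle, and segments shorter than 0.25 mm (the transport
resolution) are rejected during optimization — sub-resolution segments
cannot be represented on the transport graph and would throttle the
explicit time step. Both are exposed in `CCOParams`.

## Hemodynamics and stenosis

Flows are aggregated from the terminal outflows (exact conservation at
bifurcations), distal pressures accumulate `Δp_s = R_s Q_s` from the
root, and segment velocities are `v_j = Q_j / (π r_j²)`. A stenosis of
severity α divides the terminal outflows of the obstructed subtree by α;
by default the removed flow is redistributed proportionally over the
tree's other terminals so the root inflow stays exactly Q_perf
(switchable off, in which case the root inflow drops). Radii are left
unchanged, so obstructed-subtree pressures rise — the model prescribes
the flow reduction, not a local resistance increase. α = 1, 25, 30 for
the healthy, ischemia and infarction scenarios.

## Intravascular transport

Segments are split into `⌈l_s/Δx⌉` intervals (Δx = 0.25 mm), giving a
graph of root, regular (2 neighbours), bifurcation (3) and terminal (1)
nodes. Concentration advances by explicit Euler with first-order upwind
advection and central diffusion in *flux form*: each edge carries the
mass flux `A_e (v_e C_up − D (C_down − C_up)/dx_e)`, credited downstream
and debited upstream, so interior mass is conserved to machine
precision; at bifurcations the daughter faces enter with their own
cross-sectional areas (the area-weighted conservative update). On a
uniform line this reproduces the textbook upwind stencil exactly (tested
against an independently assembled dense operator to 1e-12 and against
the closed-form translated-Gaussian advection solution, first-order in
Δx).

Control volumes: regular nodes own half of each adjacent interval
(= π r² Δx); root, terminal and bifurcation nodes own their full
adjacent intervals. With half volumes at junction or boundary nodes the
explicit update's diagonal can go negative at the advective CFL limit
(coefficient up to 2 v Δt/dx), destroying positivity; full volumes
restore the discrete maximum principle. Consistently, `cfl_dt` is the
exact per-node monotonicity bound
`V_i / (Σ outgoing A v + Σ adjacent A D/dx [+ P·V_exchange])`, which
reduces to the familiar `min(dx/v, dx²/2D)` on uniform interiors.

The bolus enters at the three root nodes as an imposed
convective-diffusive influx `A v Q(t)` with
`Q(t) = exp(−((t−t_peak)/σ)²/2)/(σ√(2π)) + X(t)`: a normalized Gaussian
with t_peak = 25 s and σ = 6 s (σ is treated as the standard deviation)
plus the recirculation return X(t).

## Terminal coupling to tissue

Each terminal maps one-to-one to its nearest masked tissue cell
(collisions take the next-nearest free cell). The advective flux
continues *through* the terminal node (upwind in-minus-out): the blood
carrying the CA leaves the prearteriolar tree into the microcirculation.
Without this washout, CA piles up at the leaves until the leak balances
the inflow, the intravascular mean is inflated by a factor
`~Q_tot/(P·V_tree)` (about 10³ here), and the recirculation feedback
diverges — we verified this numerically before adopting the washout
form.

Delivery to tissue has two parts:

* an endothelial valve leak `P (C − Ce)` acting on the terminal node
  volume, active only while C > Ce (one-way), with P = 1 s⁻¹; the
  tissue-side concentration Ce is the mean over the terminal's
  territory — the value at the single mapped cell is ill-posed under a
  point source (it grows like log 1/h on refinement);
* a first-pass extraction of the advective outflow: the fraction
  `E = 1 − exp(−P·V_terr/Q_term)` of `Q_term·C` perfuses the mapped
  cell, the rest drains venously. `V_terr` is the terminal's perfused
  territory volume (masked tissue volume / number of terminals), so E is
  independent of both the node discretization and the tissue grid.

The extraction term is our closure of the exchange bookkeeping, which
the governing equations leave open (the intravascular sink and the
tissue source are both written as concentration rates, which cannot
simultaneously hold in two compartments of different volume). It follows
the classical Crone–Renkin form with permeability-surface product
`P·V_terr`: uptake is permeability-limited where flow is high and
flow-limited where flow is low, so an obstructed subtree (flow/α)
delivers ~α-fold less CA at first pass — the mechanism behind the dark
hypoperfused region — while total mass remains exactly accounted.

## Extravascular tissue and fibrosis

On the masked annulus (cell-centered grid, 0.25 mm default, unit slice
thickness), the interstitial concentration obeys
`(1−φ)λ ∂Ce/∂t = (1−φ)λ De ∇²Ce + f − (1−φ)λ k_e Ce − g` with a
five-point finite-volume Laplacian; faces toward unmasked cells or the
grid edge are closed (zero flux — the no-flux epicardial/endocardial
conditions). Interstitial advection is omitted (no velocity field is
solved in the interstitium). On fibrotic cells the adsorption flux
`g = (1−φ)λλ_f k_ef Ce` transfers CA into the trapped compartment,
`(1−φ)λλ_f ∂Cf/∂t = g − (1−φ)λλ_f k_f Cf`. Parameters follow the study
table: φ = 0.10; healthy/ischemia λ = 0.25, k_e = 0.007 s⁻¹, λ_f = 0;
infarction λ = 1.0, λ_f = 0.5, k_e = 0.002 s⁻¹, k_f = 0.001 s⁻¹,
k_ef = 0.01 s⁻¹; De = D_i = 1e-2 mm²/s (one isotropic scalar for both
media; a per-cell tensor hook is left for fiber anisotropy). The
late-enhancement read-out is `Ce + λ_f Cf` (volume-weighted sum,
switchable).

## Recirculation

A 1D advection-diffusion-decay line (v_out = 0.06 mm/s,
D_out = 0.05 mm²/s, k = 0.01 s⁻¹) is fed at x = 0 with the
volume-weighted mean intravascular concentration (Dirichlet) and drained
at x = L by free advective outflow; its outlet value X(t) = C(L,t) is
added to the root inflow of all three trees. L is not fixed by the
model; the default L = 6 mm gives a transit L/v_out = 100 s, a
physiological systemic return delay. The decay makes successive passage
peaks strictly decreasing (renal elimination); the line's own mass
budget (inlet flux, outlet flux, decay integral) closes to 1e-10 per
step. The line models signal timing, not a mass-conserving organ loop,
so its content is deliberately outside the myocardial mass ledger; the
CA it re-injects is accounted as root inflow.

## Scenarios, ROIs, read-outs

The stenosis site defaults to the segment nearest the right
endocardium within the RCA tree whose subtree feeds at least 3 and at
most 40% of the tree's terminals ("a branch close to the right side of
the endocardium"). The damaged region of interest is that subtree's
perfusion territory — every masked cell whose nearest terminal is
obstructed — and the remote ROI is the diametrically opposite patch of
equal polar extent; in the infarction scenario the fibrotic scar
coincides with the damaged territory. (The geometric sector + band ROI
constructors remain available in `coroperf.domain`; the territory form
is used by the driver because at reduced tree sizes a fixed geometric
patch can miss the obstructed territory almost entirely.)

Snapshots default to 50 s (first pass, FP) and 600 s (late enhancement,
LE). Expected phenomenology, asserted by the acceptance tests: FP
damaged-ROI signal ordered healthy > ischemia ≥ infarction; at LE only
the infarction scenario retains signal in the damaged ROI (Cf is
structurally zero when λ_f = 0), inverting the FP contrast.

## Time stepping

All couplings are explicit from pre-step states, in the splitting order
recirculation → tree (inflow, washout, leak) → tissue + fibrosis. The
fast step is set by the graph's monotonicity bound — in practice the
thin terminal vessels, Δt ≈ 1.3e-4 s for the full system — times a
safety factor 0.9. The tissue's 2D diffusion bound (h²/4De ≈ 1.5 s at
0.25 mm) is four orders larger, so the tissue advances every m fast
steps (tissue step additionally capped at 0.05 s — below the diffusion
bound of the finest grid in the refinement ladder, so grid refinement
does not change the temporal discretization),
receiving the leak mass accumulated exactly over those steps. The global
ledger Δ(tree + tissue + fibrosis) = inflow − venous clearance −
fibrotic clearance − microcirculatory outflow therefore closes to
machine precision (~1e-13 relative) regardless of the substepping;
`compute_timestep` exposes the strict single-rate bound.

## What the synthetic setup does and does not show

All inputs are synthetic: the slice is a canonical annulus (inner 5 mm,
outer 11 mm on a 25 mm, 100×100 grid — matching the grid-independence
grids 100²/200²/400²), the trees are CCO-generated, and the bolus is a
Gaussian. Passing tests therefore demonstrate the internal consistency
of the method — constraint satisfaction of the generated trees, exact
flow bookkeeping, convergent and conservative transport, and the
FP/LE contrast mechanism — not agreement with patient images: there is
no image registration, no fiber anisotropy, no interstitial pressure or
lymphatic drainage, 2D flow only, and a venous side reduced to decay
constants. Tree morphometry (flow/length/radius profiles) is available
via `coroperf.morphometry` for comparison against vascular statistics.

Problem sizes: the full configuration is 355 terminals over three trees
with a 100×100 tissue grid; the packaged test suite exercises the same
code paths at 50 terminals (generation constraints), 90 terminals
(scenario phenomenology; healthy/ischemia horizons cover the 50 s first
pass, infarction runs the full 600 s) and the full 100²–400² grid
ladder at a 40 s horizon (grid independence), sizes chosen so the whole
suite runs in minutes. `scripts/acceptance.py` regenerates the full
355-terminal system.

## Grid-independence read-out

The refinement study compares the whole-slice mean extravascular
concentration across tissue grids (100², 200², 400² cells) with the
tree discretization fixed. The mean is quadratured with the analytic
annulus area rather than the rasterized mask's cell count: the mask
area carries a non-monotone staircase error of up to ~1e-3 that would
otherwise swamp the discretization differences actually under study.
Because the coupling delivers *mass* (grid-independent by
construction), the corrected curves coincide to ~1e-10 and successive
deviations fall with refinement; the read-out chiefly certifies that no
hidden grid dependence leaks into the delivery, clearance or
bookkeeping paths.

## Numerical choices and edge cases

* Ties in terminal-to-cell mapping break toward the lower cell index;
  occupied cells fall through to the next-nearest free cell.
* `discretize_tree` warns and uses a single interval when Δx exceeds a
  segment's length.
* Degenerate geometry (zero-width annulus, empty ROI, empty territory)
  raises `GeometryError`/`ValueError`; CFL violations raise `CFLError`
  before any state is modified.
* Stepping a fibrosis state with an empty mask warns and is a no-op.
* Growth failure after the rejection budget raises `GrowthError` rather
  than looping forever; the distance threshold shrinks geometrically.
* Determinism: all randomness flows from `numpy.random.default_rng`
  seeds carried in the configuration; two runs with the same config are
  bit-identical (tested), and per-tree seeds are derived from the system
  seed.
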