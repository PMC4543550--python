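# Methods

`cryptsim` simulates the epithelium of a single small-intestinal crypt as a
hybrid stochastic system: off-lattice cell mechanics (subcellular element
method), a reaction–diffusion field for Paneth-cell-derived Wnt, prescribed
exogenous Wnt and BMP gradients, Notch contact signalling, and threshold
lineage rules.  This note records the model, its assumptions, the numerical
choices, and the places where the design was genuinely open.

## Geometry

The crypt wall is a rigid test tube: a hemisphere of radius R = 30 μm capped
by a cylinder, total height H = 160 μm (16 cell diameters tall, 6 wide).  The
base pole is the origin and z points up the crypt axis.  Position "up the
wall" is measured by the meridian arc length from the base pole (total arc
(π/2)R + H − R ≈ 177 μm); niche height is reported as the 95th percentile of
stem-cell arc positions divided by the 10 μm cell diameter.  The arc measure
(rather than bare z) is used because the stem compartment lives mostly on the
hemisphere, where z badly underestimates distance along the tissue.  With the
default thresholds the exogenous-gradient stem zone ends at z = 24 μm, i.e.
arc ≈ 41 μm ≈ 4.1 cell diameters — the classic "roughly four cells" niche.

## Cell mechanics

Each cell is N = 20 point elements.  Same-cell element pairs interact by a
harmonic spring V = μ(r − r0)²/2 (μ = 2.5, r0 = 1.5 μm, no cutoff); pairs in
different cells interact by a truncated Lennard-Jones potential
V = ε((σ/r)¹² − (σ/r)⁶) (ε = 0.05, σ = 4.5 μm, cutoff 10 μm).  The all-pairs
springs make a compact ~3 μm blob; the LJ minimum at 2^{1/6}σ ≈ 5.05 μm sets
the spacing between blobs, so centroids of touching cells sit ≈ 8–10 μm
apart, consistent with the nominal cell diameter.  Elements within 5 μm of
the wall feel a linear adhesion force ε_ext·r toward it (ε_ext = 0.001) and a
vertical drag: motion is overdamped, so the drag coefficient b_z = −0.3 is
applied as v_z ← (1 + b_z)·v_z for near-wall elements.  Paneth cells
additionally carry an active downhill migration velocity along the wall
tangent (Eph/ephrin repulsion); all other cells move passively.

Units: the published force constants are dimensionless, and reading them as
μm/s with the 3.6 s step makes forward Euler unstable (2μ·dt ≈ 18).  We
therefore introduce an explicit mobility (μm² s⁻¹ per force unit), default
0.015, chosen so that (i) spring relaxation is stable at the coupling steps
used (2μ·M·dt < 2 with margin), and (ii) passive cell speeds come out at a
few μm/h, giving day-scale transit of cells up a 160 μm crypt.  The Paneth
downhill speed is not published either; the default 8·10⁻⁴ μm/s ≈ 2.9 μm/h
was picked with the bisection helper `calibrate_paneth_bias` so a Paneth cell
holds station against the proliferative flux in the baseline crypt.  Both are
ordinary config parameters.

Integration is forward Euler with per-element displacement capped at 0.5 μm
per step (post-division overlaps otherwise produce unphysical jumps — the
inter-cell repulsion is also capped at its value at r = σ/2).  Pair
interactions come from a Verlet list (binned spatial hash, skin 1.5 μm)
rebuilt when accumulated motion could let a pair cross the cutoff; the test
suite checks the list against an all-pairs oracle.

## Signals and fates

Exogenous gradients are linear in z and normalised to [0, 1]: Wnt = 1 − z/H,
BMP = z/H, each optionally multiplied by (1 + σξ) with ξ ~ N(0,1) drawn
independently per cell and per lifecycle update (spatially and temporally
uncorrelated multiplicative noise; values floored at 0).  Notch activation of
a cell is the sum of ligand weights over contacting neighbours: 0.35 per
Paneth, 1.0 per Goblet, 0 otherwise.  Contact means any element pair within
6 μm; this radius deliberately exceeds the inter-cell LJ equilibrium
separation 2^{1/6}σ ≈ 5.05 μm, because with a radius below it (e.g. σ
itself) mechanically touching neighbours flicker out of "contact" as they
fluctuate about equilibrium, and — Paneth fate being absorbing — every
flicker irreversibly converts a stem cell, draining the niche within a day.
Total Wnt exposure is the mean of the diffusible field over the cell's
elements plus the exogenous value at its centroid.

Fate is a threshold table: Wnt ≥ 0.85 keeps a cell in the niche lineage
(stem if Notch ≥ TH_Notch, else Paneth); Wnt < 0.85 gives the differentiated
pair (enterocyte if Notch ≥ TH_Notch, else Goblet).  Paneth fate is
absorbing; Goblet and enterocyte interconvert freely with Notch;
differentiated → stem re-entry is off by default (config switch).  TH_Notch
is not published; the default 0.3 is chosen so that a single Paneth contact
(0.35) activates Notch while zero contacts do not, which produces the
salt-and-pepper stem/Paneth mosaic.

Two update-scheme details matter.  Fates are evaluated asynchronously:
cells are visited in random order and commit immediately, so each decision
sees its neighbours' current identities.  A synchronous sweep makes the
whole Goblet/enterocyte lateral-inhibition mosaic flip coherently (the
classic period-two artifact of synchronous lateral inhibition) instead of
settling into a stable mosaic.  And daughters born in an update keep their
inherited type until the next update, when their own exposures have been
measured.

Only stem cells cycle: lengths are Normal(24 h, 4 h) truncated to [20, 28]
(rejection sampling; the sampler is KS-checked against the analytic
truncated normal).  A stem cell whose timer expires divides unless its BMP
exposure exceeds 0.15 (evaluated at the update, with noise).  The division
plane contains the local wall normal at a uniformly random azimuth, so both
daughters keep wall contact; elements split by side of the plane, balanced to
within one.  Cells add one element at regular intervals (cycle/(N/2)) until
back at N, so a daughter regrows within one cycle.  Paneth lifetimes are
Normal(8 wk, 2 wk) truncated to [6, 10]; cells are removed at the rim
(z > H), on detachment (no element within 5 μm of the wall for two
consecutive updates — the one-update grace avoids false positives during
division), or at Paneth end-of-life.

## Diffusible Wnt

The local field obeys ∂c/∂t = ∇·(D∇c) + S − d·c on a regular grid (default
spacing 1 μm) in a box containing the crypt; nodes outside the epithelial
shell (outside the wall, or more than one cell diameter into the lumen) have
D = 0, which implements the impermeable basement membrane and lumen without
curved boundary conditions.  Inside the shell D decreases linearly with the
local element density (cells act as obstacles): D = D_c·max(floor, 1 −
ρ/ρ_sat) with ρ_sat = N·h³/V_cell, i.e. the density of confluent tissue, and
floor = 0.05.  At confluence the in-tissue diffusivity is therefore
≈ 0.5 μm²/s and the decay length √(D_eff/d) ≈ 22 μm — a cell-scale "mini
niche" halo around each Paneth cell, rather than the 100 μm free-medium
length.  Sources: each Paneth element deposits at a fixed rate onto its 8
surrounding nodes (cloud-in-cell; deposition is exactly conservative).
Cells read the field back by trilinear interpolation (exact on affine
fields).

Two solvers are provided.  `explicit` is the reference: forward Euler /
second-order central differences, 1000 substeps of 0.0036 s per 3.6 s
coupling step, stability guard D·dt/h² ≤ 1/6.  `quasi_steady` exploits the
separation of timescales (the field relaxes in ~1/d ≈ 17 min, fates react
over hours): it solves ∇·(D∇c) − d·c + S = 0 with Jacobi-preconditioned CG,
warm-started, refreshed on a configurable cadence (default 6 min simulated).
The two agree within 3% on a fixture with one Paneth cell mid-crypt.

### Production calibration

The printed production constant has no units, so production is pinned by an
operational definition instead: in a 1D half-line with flux P at x = 0, the
steady state is W_ss(x) = P/√(δD)·exp(−√(δ/D)x), and the critical rate is
the P for which W_ss(12.5 μm) = TH_Wnt = 0.85 — just enough to hold a stem
cell in near contact above threshold.  The closed form gives P ≈ 0.0963; an
independent finite-difference solve recovers the 12.5 μm crossing to
< 0.1 μm (the acceptance script recomputes this).

Carrying this into the 3D crypt needs one more decision, because a niche
stem cell touches two or three Paneth cells and their fields superpose.  The
engine therefore defines the "100%" per-element deposition rate against the
configuration the model actually runs: at initialization it solves the
unit-rate quasi-steady field of all Paneth cells in the canonical crypt and
rescales so that the mean stem-cell local exposure equals TH_Wnt.  At 100%
the typical niche stem cell is thus exactly marginal on local Wnt alone —
the operational meaning of the critical rate — so halving production (50%)
drops essentially every stem cell below threshold when the exogenous
gradient is removed (niche loss), while doubling it (200%) keeps essentially
all of them above (redundancy), reproducing the regime table.  A single-cell
variant (isolated Paneth cell's field = TH_Wnt at 12.5 μm from its centroid,
in confluent-tissue diffusivity) is provided as
`engine.calibrate_element_rate` for inspection; it is not used for runs
because superposition over contacts would shift every regime boundary by the
typical contact count.  `wnt_production_pct` scales the calibrated rate
(0–400%).

## Initial condition

A crypt is initialised by growing two identity-less cells at the base pole
until their descendants cover the wall, then assigning canonical identities.
The packing stage is an initial-condition generator, not part of the model
proper, and uses accelerated settings: ~1 h division cycles, boosted
mobility and inter-cell repulsion, daughters pre-separated to near the LJ
equilibrium spacing, and division planes steered so daughters separate
toward free wall area (only cells adjacent to uncovered wall divide — the
colony therefore grows as an advancing front at its natural density instead
of compressing at the base).  Packing ends when 95% of quasi-uniform wall
sample points lie within one cell diameter of a centroid — the whole wall,
including the rim band, carries cells, so turnover by rim removal starts
immediately — followed by a 1 h settle under the true force field.  Identities: cells within 4 cell diameters of the base (wall arc)
are interleaved stem/Paneth by a greedy checkerboard on the contact graph
(every stem touches a Paneth); cells above alternate enterocyte/Goblet the
same way.  Timers start at uniform random fractions of each cell's cycle,
Paneth ages at uniform fractions of their lifetimes.

Because the packing stage is by far the most expensive part of a run and is
identity-free, `initialize_crypt` accepts a pre-packed cell collection:
replicates of an ensemble may share the mechanical packing while identities,
timers and all dynamics derive from each replicate's own seed.

## Scenarios

`run_scenario` applies named switch sets: `baseline` (exogenous gradients
only), local-production sweeps with BMP off (`local_wnt_sweep`) or on
(`bmp_sweep`), `global_wnt_removal` (settle to steady state — trailing 12 h
niche-height slope below 0.05 cell diameters/h — then switch the exogenous
Wnt off and continue), four Paneth-migration deletion variants, drag and
cell-cycle perturbations, diffusivity/decay reduction, and noise sweeps.
`run_ensemble` runs replicates at seeds base..base+n−1 and reports per-time
mean and standard deviation.  Stability labels: "dies" if the stem pool is
empty at the end; "unstable" if the niche reaches 90% of the wall or the
trailing 24 h slope exceeds 0.1 cell diameters/h; else "stable".  The
occupancy/slope thresholds are package-defined (the regimes are classified
visually in the source literature) and are exposed as arguments.

## Problem sizes and numerical settings used by the tests

Full-fidelity settings (1 μm grid, 3.6 s steps, per-step lifecycle updates,
10-day ensembles of 10) are cluster-scale.  The shipped test suite and the
worked examples run at desk scale: 2 μm grid with quasi-steady chemistry
refreshed every 15 min simulated, 14.4 s mechanics steps (the overdamped
dynamics are stability-limited by 2μ·M·dt ≈ 1.1 < 2; packing, which uses a
higher mobility, always steps at ≤ 10.8 s), lifecycle updates every 62
steps (~15 min simulated — still far below the hour scale of growth, fate
and division), simulated durations of 1–3 days, and single-seed replicates
per condition.  The baseline-homeostasis check runs the full 160 × 60 μm
geometry; the regime contrasts run a reduced 80 × 40 μm crypt, where the
same threshold geometry (gradient stem zone at (1 − TH_Wnt)·H) and regime
logic apply at a quarter of the cost.  Unit tests verify the
discretisation-sensitive pieces (solvers, samplers, forces) at fine
resolution against closed forms and all-pairs oracles, so the desk-scale
settings affect statistical power, not correctness of the operators.
Noise redraw happens per lifecycle update, so the effective noise
correlation time at desk scale is ~15 min.  The desk-scale instability
detector used by the regime tests is sustained trailing niche-height growth
(slope above 0.0015 cell diameters per hour, 2–3× above the drift of
settled runs); the full-scale classifier thresholds in
`classify_stability` (occupancy 90%, slope 0.1 cd/h) are unchanged.

## Known limitations

Only stem cells proliferate (no transit-amplifying compartment); no +4
quiescent cells, cell polarity, basement-membrane deformation or crypt
fission mechanics; no density-dependent proliferation inhibition.  The BMP
and exogenous Wnt fields are prescribed gradients, not solved PDEs.  The
1D→3D production bridging and the packing accelerations described above are
artifact constructions; both are config-controlled.  Synthetic initial
conditions emulate the canonical crypt architecture but not biological
variability in crypt size or shape, so passing regime tests demonstrate the
model's internal logic, not quantitative agreement with tissue data.

A consequential mechanical limitation: with the published force constants
(weak linear wall adhesion, Lennard-Jones cohesion with an attractive tail)
the epithelium behaves as a soft cohesive colloid, and crowding pressure
relieves preferentially by live extrusion (cells squeezed off the wall and
removed by the detachment rule) rather than by bulk column flow up the
wall.  Threshold- and signalling-borne regimes — niche expansion without
BMP, BMP insensitivity of niche height at 100–300% production, loss versus
persistence of the niche under exogenous-Wnt removal — are insensitive to
this and reproduce at desk scale.  Regimes carried by passive bulk
transport, chiefly the spread of non-migrating Paneth cells to the upper
crypt and the resulting destabilisation when downward migration is deleted
in the redundant regime, express far more slowly than in the original
GPU-scale realisation and are not reached within desk-scale horizons; the
corresponding check is expected to fail and is retained as a known
divergence.  Rebalancing flow against extrusion would require changing
published force constants, which this package declines to do.
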