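# Methods

`hepasim` is a 3-D off-lattice agent-based simulator of liver tissue,
specialized to regeneration after partial hepatectomy (PH) and to the
regrowth of a residual hepatocellular-carcinoma (HCC) clone after an
extended resection.  This note records the model, its assumptions, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Microenvironment

Chemical substrates (oxygen, in mmHg, and an abstract injury **growth
factor**, GF, in units normalized to its secretion saturation density)
live on a Cartesian mesh of cubic voxels and obey reaction–diffusion
equations with first-order decay.  The solver uses first-order implicit
operator splitting: decay is applied implicitly, then the diffusion
operator is dimension-split (locally one-dimensional method) into x-, y-
and z-sweeps, each a backward-Euler tridiagonal solve per mesh strip via
the Thomas algorithm.  The scheme is unconditionally stable, preserves
non-negativity and, with the zero-flux finite-volume boundaries used on
all domain faces, conserves mass exactly up to round-off when decay,
sources and vessels are absent.  Because all strips along one axis share
the same matrix, the forward-elimination coefficients are factored once
and reused (`TridiagonalOperator`).

**Dirichlet nodes.** Any voxel can be registered as a vessel: its
substrate values are overwritten with clamp values after decay and after
every 1-D sweep, so vessels act as continuous sources within the
splitting.  A consequence worth knowing: with an *interior* Dirichlet node
the per-sweep re-clamping breaks exact x↔y symmetry of the operator at
finite step size (the clamped value diffuses along whichever axis is swept
next).  The asymmetry is a splitting artifact that shrinks with the step;
without interior nodes the sweeps commute exactly.

**Cell coupling.** Each cell contributes a secretion/uptake term in its
containing voxel (nearest-voxel assignment, no kernel spreading), with the
implicit per-voxel update

    rho <- (rho + dt * sum_i c_i S_i rho*_i) / (1 + dt * sum_i c_i (S_i + U_i)),

where `c_i` is the cell-to-voxel volume ratio.  Cells sharing a voxel are
applied simultaneously in one combined update (unconditionally
non-negative; secretion alone can never push past `rho*`).

Defaults: oxygen D = 2000 µm²/min, λ = 0.01/min, vessel clamp 60 mmHg;
GF D = 600 µm²/min, λ = 0.006/min.  These are *effective* constants — the
central veins and sinusoids are not modeled explicitly, so the oxygen
constants are tuned so that the vessel-column lattice produces
lobule-scale gradients (decay length ≈ 50 µm including cellular uptake).

## Cell agents

Cells are off-lattice spheres stored struct-of-arrays for vectorized
stepping.  Each carries three volume compartments (fluid `V_F`, nuclear
solid `V_NS`, cytoplasmic solid `V_CS`) relaxing toward targets,

    dV_F/dt = r_F (f_F V - V_F),   dV_NS/dt = r_N (V_NS* - V_NS),
    dV_CS/dt = r_C (f_CN V_NS - V_CS),

integrated forward-Euler at the phenotype step (rates ≤ 0.05/min at
dt = 6 min keep the explicit update stable).  Defaults describe a 2494 µm³
hepatocyte: 75% fluid, 135 µm³ nuclear solid, cytoplasmic:nuclear solid
ratio 3.62, r_F = 0.05/min, r_N = r_C = 0.0033/min (the solid-compartment
rates set the ~half-day swelling time scale seen in the scenarios).

**Cycle model.** The proliferative cycle is a three-node directed graph
following the Ki-67 stain: `Ki67−` (quiescent; stochastic exit with a
per-cell regulated rate), `Ki67+pre` (S+G2+M, fixed 780 min, division at
exit) and `Ki67+post` (residual Ki-67 degradation, fixed 150 min ≈ two
75-min half-lives), both daughters entering `Ki67+post`.  At the saturated
entry rate the expected cycle time is exactly the configured total
(hepatocytes 33.6 h, cancer cells 38.6 h).  Stochastic edges fire per step
with probability `1 − exp(−r dt)` (exact exponential dwell); fixed edges
fire when time-in-phase reaches the duration.  Death is modeled the same
way: apoptosis (single 516-min phase, all volume targets driven to zero,
removal at exit) and necrosis (swelling to ~95% fluid fraction with a
stochastic lysis edge, then a fixed degradation phase).  Necrosis triggers
when a cell sits below 2 mmHg oxygen for longer than a 12-h grace period;
the calibrated scenarios stay above this threshold.

**Division** halves every compartment exactly and places daughters at
parent ± (r/2)·û with û uniform on the sphere; generation increments;
total volume is conserved to round-off.

## Mechanics

Overdamped (inertialess) dynamics: velocity = net force / drag, with the
drag coefficient absorbed into force units (ν = 1), so the adhesion and
repulsion coefficients are speeds.  The pair force is piecewise quadratic
with compact support — repulsion `c_rep (1 − d/R)²` inside overlap
(R = sum of radii) and adhesion `c_adh (1 − d/R_A)²` up to
R_A = 1.25 R — giving a slightly compressed confluent equilibrium spacing
(≈ 0.94 diameters at the default c_rep/c_adh = 1/0.06).  Dying cells keep
repulsion but lose adhesion; lysed cells stop interacting.  Neighbor pairs
come from a k-d tree (every pair within range enumerated exactly once).
Positions advance with two-step Adams–Bashforth (forward Euler on a cell's
first step).  The scenario presets run mechanics at dt = 6 min; with the
default force scale the per-step displacement stays well under one cell
radius (a warning is logged if it does not).

## Liver scenario

The baseline liver is a sphere (default radius 130 µm in a 396 µm domain —
a deliberately reduced, representative parenchyma sample) of hepatocytes
packed HCP at mechanical equilibrium spacing, lightly jittered and
relaxed.  Portal triads are idealized as a 2-D triangular lattice
(spacing 90 µm) of voxel columns along z; columns inside the sphere start
as oxygen Dirichlet nodes, and *all* lattice columns are tagged as
potential vessels.  During a run, any tagged non-vessel voxel containing
five or more cells becomes a permanent oxygen vessel node (the
angiogenesis rule); with 36-µm voxels the baseline packing holds ~17 cells
per voxel and fully hypertrophied tissue ~8, so densifying tissue recruits
vessels and sparse regions do not.

**Hepatectomy** removes the cells in a half-space, the plane offset found
by bisection so the removed volume fraction matches the requested degree
within 1%; vessel nodes in the removed region are deactivated, while the
potential-vessel tags persist (they encode the lobule architecture, which
the regrown tissue re-expresses — this is what makes the vessel count
recover over the first days and then plateau).

**Regulation.** From the resection on, every surviving hepatocyte secretes
GF at rate `S0 · f · max(0, 1 − V/V_target)` with S0 = 0.02/min per unit
injury, f the resected fraction, and the set point
`V_target = (1.22 − 0.6 f) · V_pre` (regeneration terminates farther from
full restoration the larger the injury, as observed).  Cycle entry follows
the piecewise-linear law `r = (1/t_K−) · clamp((GF − GF_prol)/(GF* −
GF_prol), 0, 1)` with GF_prol = 0.032, GF* = 0.037, multiplied by a
clamped-linear oxygen factor (5–30 mmHg), so proliferation waits for
revascularization.  Hypertrophy ramps linearly from GF = 0.008 to 0.06
up to a maximal target-volume factor 2.4, with two asymmetries that the
data force: enlargement follows rising GF promptly, enlargement up to a
permanent cap of 1.35 is retained for good (ploidy-like committed growth),
and swelling beyond the cap reverses on a 1-day time scale.  The permanent
cap is what lets all three hepatectomy degrees settle at distinct
plateaus without the GF–volume feedback loop ringing; a purely
instantaneous h(GF) either cannot separate the scenarios or limit-cycles.

The calibration targets are the classic rodent partial-hepatectomy
measurements (fold-recovery curves, hypertrophy factors and division
counts for 30/50/70% resections).  Calibration reproduces, on the reduced
domain: plateau fold-levels ≈
0.94 / 0.89 / 0.72 for 30/50/70% PH (plateau = first day the volume's
relative change stays below 0.5%/day), plateau days ≈ 4.5 / 5.8 / 6.5,
divisions per remnant hepatocyte 0 / ≈0.32 / ≈0.55, a day-1 cell-volume
factor ≈1.9 at 70% PH relaxing to ≈1.5 by day 14, and a vessel count that
dips at resection, climbs for ~3 days and plateaus.  Three reported
quantities are *not* reproduced, for structural reasons documented here
rather than hidden: (i) a 1.6× peak cell *area* at 30% PH implies a 2×
volume and hence a transient fold-level of 1.4 for spherical cells, which
contradicts the 0.93 plateau with zero divisions — the model preserves the
fold curve and shows a ≈1.3× area peak; (ii) a 50% PH day-3 level of 0.78
below its plateau requires a multi-day volume rise while the 70% day-1
doubling requires a sub-day rise of the same machinery — the fast reading
is used, so the 50% day-3 level sits near its plateau; (iii) divisions per
cell at 70% PH reach ≈0.55 rather than 0.7 at the joint optimum of the
fold and division constraints.  The orderings (plateau 30% > 50% > 70%;
divisions 30% < 50% < 70%) hold throughout.

## Tumor recurrence

A residual clone (default one cell) is seeded on the remnant surface at
the hepatectomy — either at a uniformly random direction (replicate
experiments) or at a fixed point (sensitivity scans).  Cancer cells ignore
GF; their cycle entry scales clamped-linearly with local oxygen between 14
and 40 mmHg.  Early after a 70% PH the remnant is hypoxic (vessels lost),
so the clone stays dormant; as regeneration and angiogenesis restore
oxygen the clone activates — typically around day 8–10, after the liver
plateau — and then grows roughly exponentially, recruiting its own vessels
once its local density crosses the five-cell rule.  Final tumor volumes
across random seed positions are highly dispersed (peripheral seeds grow
fastest), which is the replicate-spread phenomenon the random-seeding
experiment quantifies; with the reduced domain and small replicate counts
the relative SD comes out larger (~80–170%) than the ~59% the model family
shows at full scale with tens of replicates.

The two-point specific growth rate `α = ln(V2/V1)/(t2 − t1)` is computed
from the simulated tumor trajectory between activation and day 30 and
reported in %/day.  A note on magnitudes: a tumor reaching ~0.002 mm³ from
one cell within a month has ln-growth ≈ 0.2/day ≈ 20 %/day, so α values
quoted in hundredths of a %/day for early HCC regrowth cannot describe the
same window; the package reports exactly what the formula yields on the
simulated series.  The Gompertz extrapolation demo uses clinically
motivated constants (carrying capacity = a 50 mm sphere, the largest
transplant-eligible tumor under the Milan criteria; V0 = 0.0028 mm³;
α = 0.053 %/day) and reports the closed-form detection day for a 5-mm
lesion (~day 1700 under those constants).

**Sensitivity scan.** Six inputs (oxygen uptake of hepatocytes and cancer
cells, both cycle durations, adhesion, repulsion) are varied ±10% and the
day-30 tumor volume compared with baseline.  Because the random-placement
variance dwarfs a ±10% effect at desk-scale replicate counts, the scan
fixes the clone position so arms are paired; directions then emerge
cleanly: less hepatocyte oxygen uptake → more tumor, shorter cancer cycle
→ more tumor, mechanics coefficients → no systematic effect.

## Scheduling, determinism, problem sizes

The main loop steps diffusion at dt = 2 min (implicit, so accuracy not
stability sets the step), mechanics and cell processes at dt = 6 min, and
records every 6 h; the hepatectomy (and clone seeding) fire once at their
configured minute.  All randomness derives from one seed through named
`SeedSequence` substreams, so a (config, seed) pair reproduces bitwise
identical outputs.  The shipped scenario sizes (≈3300 initial hepatocytes,
11³ voxels, 10–30 simulated days, single-digit replicate counts) are
chosen so a full scenario runs in tens of seconds on one core; all
reported per-cell and fold quantities are intensive, so the domain
reduction rescales absolute volumes only.

## Known limitations

Hepatocytes are the only liver cell type; sinusoid flow, bile transport,
lobe anatomy and patient-specific factors are outside scope.  The GF is a
single abstract species with a volume-feedback shutdown — one admissible
reading of "growth factor decreases as the liver regenerates".  Cell areas
are equatorial sections of volume-equivalent spheres, not histology-slice
areas.  The synthetic scenarios probe the model's own calibrated dynamics;
agreement there shows internal consistency with the published curves at
reduced scale, not validation against new experimental data.
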