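# Model and methods

`rootsim` simulates the growth of an *Arabidopsis*-like root meristem as a
coupled mechano-biochemical system on a 2D cellular mesh: position-based
dynamics (PBD) tissue mechanics, polar auxin transport with an auxin
feedback on PIN carrier placement, auxin-dependent wall relaxation, a
strain-driven anisotropy feedback, and cell-type-specific division rules.
This note documents the model as implemented, the choices made where the
design was genuinely open, and what the synthetic test conditions do and do
not show.

## Tissue representation

The tissue is a `CellComplex`: cells are simple, counter-clockwise polygons
over a shared vertex pool; every border edge is a wall segment adjoining
one (organ surface) or two cells.  A wall holds a shared apoplastic auxin
pool and one membrane side per adjoining cell with that cell's
membrane-bound carrier amounts (PIN, AUX/LAX) and the regulator/polarizer
species of the alternative polarization mechanism.  Cells are triangulated
by a fan from a per-cell center vertex; the center-to-ring edges stand for
the cytoskeleton in the mechanics.  Coordinates are micrometres with the
y axis pointing shootward; concentrations are nanomolar, defined as amount
per compartment area (apoplast area is segment length times a nominal
1 um wall thickness).

The synthetic template is an idealized heart-stage embryonic root:
five cell files per side (vascular, pericycle, endodermis, cortex,
epidermis) over a niche row with exactly two QC cells, cortex/endodermis
and epidermis/LRC initials, columella initials and columella below, and a
lateral root cap sheathing a tapered tip.  The top cell row is the shoot
boundary: stele-file cells are auxin sources, the remainder sinks.  The
generator is deterministic; all anisotropy vectors start at zero (the
embryo is non-polar), while carriers start at their auxin-free, *uniform*
steady state - the embryonic condition is non-polar, not carrier-free.

## Mechanics (PBD)

Each step predicts vertex positions and runs 8 Gauss-Seidel projection
passes over five constraint kinds, with the iteration-count correction
`k' = 1 - (1-k)^(1/n)`:

* **distance** - wall and cytoskeleton edges; walls have compression
  stiffness 1 (cells are incompressible) and an extension stiffness set by
  the cell's auxin (below); internal edges are soft springs (k = 0.05).
* **pressure** - an XPBD area constraint per cell (compliance 1e-4)
  whose target demands `growth_drive` (0.12/h) areal expansion for growing
  cells; non-growing types (QC, columella, the source/sink boundary row)
  keep a fixed target.  A turgor floor (half the cell's reference area)
  resists crushing by neighbors.
* **strain** - per cell edge, extra stiffness
  `min(1, 5 |af| (u_edge . u_af)^2)`: deformation along the anisotropy
  vector is penalized in proportion to its magnitude and alignment.
* **shape matching** - weak (k = 0.02) for growing cells, rigid (k = 0.4)
  for the non-growing types, which are effectively rigid bodies that may
  still translate with the tissue.
* **bending** - a virtual edge across each wall corner whose rest length
  is recomputed every step from the current adjacent edge lengths and a
  stored rest *angle* (law of cosines).  This makes the constraint
  scale-free: uniform growth is unopposed while wall folding is resisted,
  which matters because fixed-rest virtual edges were found to tax growth
  heavily.

Walls are viscoelastic: rest lengths (and rest shapes/angles) creep toward
the current configuration at a plastic yield rate of 0.3/h, converting
sustained elastic strain into permanent growth.  The solver is quasi-static
(velocities damped to zero; turgor-driven growth has no inertia).  Growth
dilutes every concentration by the achieved area (or wall length) change,
conserving amounts exactly.

The topmost cell row is the static attachment of the organ to the shoot:
its central columns are pinned, the rest of the row is pinned vertically
(the attachment cannot stretch rootward but may widen with the tissue).

## Anisotropy factor

The AF is a per-cell vector, |af| in [0,1], summarizing cytoskeletal and
wall anisotropy.  When the largest wall strain of a cell exceeds a
threshold (0.01), a non-polar cell seeds its AF perpendicular to the
most-strained wall segment; an existing AF then follows the discrete map

    af' = af + R_AF * sum_i u(af) |(u(af).u(mem_i)) eps_i| - d_AF af

with R_AF = 0.02 and d_AF = 0.01 *per update* (one update per mechanics
step).  Interpreting these rates per simulated hour instead makes the AF
respond on a ~100 h timescale, far beyond the run lengths over which the
anisotropy phenomenology is reported, so the per-step discrete map is the
operative reading.  |af| is clamped at 1; a cell whose AF has decayed to
zero re-seeds from the current strain pattern.  Daughters inherit the
mother's AF unchanged.

## Auxin transport

Carrier fluxes through a membrane section are linear in carrier and
substrate (`I = K_AUX1 AUX1_mem IAA_wall L`, `E = K_PIN PIN_mem IAA_cell
L`); amounts convert to concentrations through the receiving compartment's
area, which makes exchange exactly antisymmetric.  Wall pools additionally
diffuse to adjacent wall segments (rate `DI_IAA/(L_i+L_j)`) and exchange
passively with their cells (permeability `P_IAA` = 0.1 um/h; untabulated,
chosen small so that carrier-mediated transport dominates).  Degradation is
saturable:

    removal = [ d_IAAb + (d_IAAMax - d_IAAb) IAA^4/(K^4 + IAA^4) ] * IAA

i.e. the bracket is a first-order rate coefficient (basal 0.0125/h,
saturating at 0.125/h above ~5 nM).  The zero-order alternative reading
cannot remove more than 0.125 nM/h and therefore can never balance an
external auxin application, contradicting the degradation term's stated
purpose; the first-order reading also matches the tabulated 1/h unit of
the maximal rate.

Carrier expression is basal plus Hill(2) auxin induction, capped;
AUX/LAX is trafficked uniformly by membrane-length share, PIN by the
per-section PIN sensitivity; membrane pools cap at 15 nM and PIN's
membrane decay is auxin-gated (fast turnover in auxin-poor cells, enabling
the ~5-6 h repolarization after division).  Chemistry is integrated with
explicit Euler on a frozen entry snapshot (Jacobi), 5 substeps per
mechanics step (dt_chem = 0.004 h, comfortably below the fastest kinetic
timescales).

Boundary: each Source cell receives a constant total influx of
700 nM um^2/h (chosen so the vascular files run in the low-nanomolar range
of the kinetic constants and canalized transport outruns growth; the
amount does not increase as the root grows).  Sink cells export
first-order at 3/h.  One simulation step is 0.02 h, so the published
1500-step experiments span 30 h; patterning runs here use 2500 steps
(50 h).

## PIN sensitivity and the two polarization mechanisms

Raw per-section sensitivities combine the anisotropy input IAF, the
auxin-flow input IP and the geometry input IG
(`PinSR = kAF IAF + kP IP + kAFP (IAF + IP) + kG IG`, with kAF = 0 in the
default model) and are softmax-normalized per cell.  Columella-type cells
bypass the computation and traffic PIN uniformly (PIN3-like).

* **auxin-flux**: the cell's flux vector is the sum of unit
  centroid-to-midpoint vectors weighted by each section's net throughput
  (E - I), i.e. it points along the direction auxin moves through the
  cell; IP is a Hill(4) of its outward projection, clamped at zero for
  inward-facing sections (the quartic is sign-blind; without the clamp the
  upstream face would be boosted equally and the feedback could not
  canalize).
* **regulator-polarizer**: a molecular realization of flux sensing.
  Net auxin import per section (`Grad_mem`, amplified and normalized by
  cell area, clamped at zero for net-export sections for the same
  sign-blindness reason) promotes membrane binding of an auxin-activated
  regulator; a PIN-recruiting polarizer is trafficked auxin-dependently,
  diffuses along the ring of sections and is stochastically displaced
  toward the ring neighbor with less regulator (fixed batches
  `Kdisp_POL * POL_mem * dt`; displacement conserves the polarizer
  exactly and is the model's only stochastic element).  IP is a Hill(4)
  of the membrane polarizer.

## Growth and division

Wall extension stiffness follows the double-Hill auxin response
(`kE = kE_Max (K1^4/(IAA^4+K1^4) + IAA^4/(IAA^4+K2^4))`): stiff below
~0.05 nM and above ~3 nM, relaxed between - growth needs auxin but too
much arrests it.  A shared wall takes the mean of its two sides.

A cell divides when its area reaches `1.5 x` its template area.  The
division line passes through the centroid, by default parallel to the AF
(anticlinal; for non-polar cells the short principal axis is used).
Niche rules: CEI -> CEI + CEID (the daughter farther from the QC
differentiates); CEID divides periclinally into endodermis (inner) +
cortex (outer); epidermis/LRC initials alternate orthogonal/parallel
divisions producing LRC (outer) or epidermis (shootward) daughters;
columella and vascular initials divide asymmetrically, renewing themselves
toward the QC; QC and columella never grow or divide.  Daughters inherit
concentrations, AF, knockdowns and thresholds; the fresh wall starts with
empty membranes and an empty apoplast pool, so total auxin is conserved
exactly and repolarization is an emergent relaxation.  Cuts landing within
0.75 um of an existing vertex snap to it (sliver edges are mechanically
fragile).

## Numerical and degenerate-input choices

Positions are solved in double precision with a JIT-compiled Gauss-Seidel
inner loop (a reference per-constraint path is kept and tested for
bit-level equivalence).  Division lines failing to produce exactly two boundary
crossings retry with a small random angle perturbation, then skip.
Transient self-contact of a deformed polygon is tolerated during runs
(topological invariants are still enforced after every remeshing); strict
polygon simplicity is enforced on I/O.  Zero-length AF, zero-flux softmax
inputs and empty pools all take well-defined branches (uniform softmax,
pure decay, clamped at zero with the clamped amount booked in the mass
ledger).

## What the synthetic conditions show - and what they do not

The default 88-cell template is a deliberately small, idealized stand-in
for a segmented embryo mesh (rectangular files, tapered tip).  On it, the
model reproduces: rootward canalization of vascular PIN from an initially
non-polar state, under both polarization mechanisms; shootward return
flow through the outer tissues (reflux), including bipolar cortex PIN
under the regulator-polarizer mechanism; a growth-rate peak in the apical
meristem; division of labor among the niche division rules; PIN
repolarization on fresh division walls in ~5-6 h; reversible growth
inhibition by external auxin; and the qualitative contrasts of the
classic perturbations (carrier knockdowns, QC ablation, LRC removal, tip
excision, cytoskeleton-drug AF collapse, reflux blocking, source removal
with and without QC-local synthesis).

Two readouts are *not* reproduced at this scale and are reported as
computed. First, the longitudinal auxin profile keeps its global maximum
in the sub-source region rather than the QC-adjacent bin: with saturating
carrier capacity the concentration decays along the transport chain, and
at 88-200 cells the funneling of ten files into the tip does not overcome
that decrement (the QC pool is elevated - several nM against a ~0.1 nM
auxin-free baseline - but the entry region is higher still). Second,
organ-level elongation is modest: isotropic turgor with free flanks gives
the growing regions a radial bias that the strain-feedback only partly
cancels, so shape-based readouts are treated as paired ordinal contrasts
(e.g. oryzalin-like AF collapse widens the root *relative to* its paired
wild type).  Real roots differ in both respects, and passing tests here
accordingly certify mechanism behavior, not organ-scale morphology.
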