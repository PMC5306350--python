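# Methods

## Model

`cmapoly` simulates athermal polymer–solvent systems on a fully occupied
two-dimensional triangular lattice.  Every site carries exactly one
molecular element — a chain bead or a solvent particle of the same size —
so the model describes dense systems down to the incompressible-solvent
limit.  Chains are linear, monodisperse, and connected by unbreakable
bonds of length 1 (the lattice constant); the coordination number is six.
The only interaction is excluded volume (single occupancy), so every
allowed configuration has the same statistical weight and temperature
plays no role.  A quasi-2D variant stacks two lattice layers; each site
then also neighbours its mirror image (coordination seven), which lets
solvent cross over a chain — the control system for strictly-2D
solvent-exclusion effects.

Coordinates are axial integers `(a, b)` on a rhombic periodic cell of
edge `L`, embedded in Cartesian space as `x = a + b/2`,
`y = b·√3/2` (unit bonds).  The minimum image over the nine in-plane
periodic copies of the rhombic cell is exact for this geometry and is
used for all inter-site distances; single-chain quantities are computed
on unwrapped coordinates (bead 0 in-box, successive beads placed by
minimum-image bond steps).

The polymer concentration is `phi = n_chains·N / (layers·L²)`, computed
as an exact rational; `phi = 1` is the melt.  Lattice concentrations can
be compared with off-lattice disc-packing conventions through the close
packing fraction `pi/(2·√3) ≈ 0.9069`.

## Cooperative motion

At full occupancy no element can move alone.  Moves are cooperative
loops: a closed cycle of sites along which every element steps onto its
successor's site, so no vacancy is ever created (continuity) and the
displacement vectors cancel (up to lattice winding, for the rare loop
that wraps the torus).  A move is allowed iff every bond of every
affected chain is still a nearest-neighbour pair afterwards; the system
is athermal, so allowed moves carry no further weight.

Two proposal generators are implemented and cross-validated:

* **uniform walk** (reference): a uniformly random start site, then a
  displacement random walk with uniform direction choices; the walk
  closes when it steps onto its start, and the whole tentative
  permutation is accepted or rejected by the bond check.  A loop and
  its reverse are generated with equal probability, so detailed balance
  with respect to the uniform measure is immediate.  Walks that
  self-intersect, exceed `max_loop_len` (default 100) or would form a
  2-site swap are rejected.
* **guided vacancy walk** (production): the start element is set aside,
  and at each step one continuation is drawn uniformly among the *moves
  that are locally legal now* — a neighbouring element all of whose
  bonds reach the vacancy, or, once at least three sites are involved,
  loop closure.  Because each element validates its bonds when it moves
  and the later-moving endpoint of every bond re-validates it, a closed
  walk always produces a valid state.  The guided draw probabilities are
  not symmetric between a loop and its reverse, so the move is accepted
  with the Metropolis factor `min(1, S_rev/S_fwd)`, where `S` is the
  loop's total generation probability summed over its cyclic rotations
  (each a product of `1/|choices|`).  This restores exact detailed
  balance with respect to the uniform athermal measure.  The
  implementation of `S` is verified against brute-force enumeration of
  all guided walks on small systems.

All-solvent loops permute indistinguishable particles and are therefore
physical no-ops; the engine skips their application and Metropolis
bookkeeping (self-transitions do not affect the stationary law).

A third move complements the loops in melts: the **tail exchange**
(double bridging).  Two chains cut at the same contour index swap their
tails when the two cross bonds are lattice neighbours; occupied sites,
chain count and chain length are unchanged, the move is its own inverse
and is proposed symmetrically, so it preserves the same uniform
measure.  It exists because cooperative loops rearrange a melt only
locally — individual chain sizes keep correlation ~0.99 with their
start over thousands of time units — whereas a tail exchange renews
global conformations in one step (correlation drops to ~0.5, the
remainder being slow structural "texture" that only loop dynamics
remodels).  It is ineffective below roughly phi ~ 0.5, where aligned
inter-chain contacts are rare.

The whole sampling stack is validated against an exact brute-force
oracle: every one of the 1,042,944 partitions of the 4x4 periodic box
into four 4-bead chains is enumerated, giving the exact melt ensemble;
uniform, guided and guided-plus-exchange sampling all reproduce its
per-chain averages within statistical error (the guided sampler to
better than 0.5 combined sigma).

The uniform generator is efficient when loops mostly traverse solvent
(dilute and intermediate concentrations); in dense systems its
acceptance collapses (~10⁻³ in a melt) because a random walk almost
never traces a bond-compatible cycle, and the guided generator is then
roughly two orders of magnitude more effective per CPU second.  Both
modes are exposed; studies choose per regime (below).

Simulation time: one time unit elapses when the cumulative number of
attempted element displacements — walk steps, counted whether or not the
walk closes or the move is accepted — reaches the total site count, i.e.
on average one attempted move per element.  Both engine paths (a pure
Python reference and a numba kernel) consume one shared PCG32 stream and
produce bitwise-identical trajectories, which is tested.

## Initial conditions

The textbook initial condition lays chains fully extended along the
lattice `a` axis, folding at the box edge, stacked row by row.  Two
hazards are handled:

* when `N` is a multiple of `L`, the aligned fill makes every chain a
  straight torus-wrapping line; at `phi = 1` such a packing admits *no*
  acceptable cooperative loop of accessible length (verified by
  exhaustive loop enumeration on small boxes) and never melts.  The fill
  therefore starts mid-row in that case, giving every chain a hairpin;
  an optional `fold_width` produces strip-folded, hairpin-rich packings.
* more generally, any perfectly aligned dense packing is kinetically
  frozen, so dense production runs start from a *disordered* fill: a
  Hamiltonian path over the box, randomized by backbite moves, cut into
  consecutive chains (solvent filling the remainder).  This start is
  valid, defect-rich, and slightly compact relative to equilibrium.

Relaxation is strongly asymmetric: chain contraction is fast while
expansion of the global coil size is extremely slow under local
cooperative moves (measured: >10⁵–10⁶ time units for a dilute N = 64
chain).  Initialisation therefore matters, and each study regime uses
the start that makes its measurement reliable:

* **dilute** (`phi = 1/32`): chains are initialised from *equilibrium*
  single-chain conformations drawn by the pivot algorithm (an exact SAW
  sampler, validated against exhaustive enumeration), placed at random
  non-overlapping positions.  The cooperative dynamics then starts in
  its stationary distribution; independent replicas (24 by default)
  provide uncorrelated samples of the slow global modes, and the absence
  of drift under the CMA is itself a stationarity check of the engine
  (pivot references for N = 16/32/64: Rg² ≈ 6.3/17.8/51.2).
* **melt** (`phi = 1`): disordered fill, guided generator interleaved
  with tail-exchange bursts (one sweep of attempts per measurement
  interval), which renew global conformations that loops alone would
  leave correlated with the start.  The backbite depth of the fill (16
  sweeps) is past the point where the fill's statistics stop depending
  on it; deliberately under-randomized fills leave orientationally
  ordered domains that no accessible dynamics can melt — a genuine
  kinetic trap of dense 2D packings, excluded by construction.
  Plateaus agree across independent well-randomized fills.
* **intermediate** (`phi ≈ 0.3`): global mixing is slowest here — the
  swollen branch of the longest chains relaxes over ~10⁶ time units —
  so these runs trade volume for time: the box is reduced to 32 (still
  above five gyration radii for N = 64; the per-chain relaxation rate
  in time units depends on concentration, not box size, while the CPU
  cost of a time unit scales with the site count).  Each system is run
  from both sides of its equilibrium: replicas started from placed SAW
  conformations (swollen; chains that cannot be inserted at this
  density are grown on free sites) and replicas started from the
  disordered fill (compact), with the uniform generator plus
  tail-exchange bursts.  The equilibrium chain size is extracted by a
  joint relaxation fit: the replica-averaged block curves of the two
  branches are fitted as `A ± amplitude·exp(−t/τ)` with a *shared*
  asymptote `A`, constrained to the interval spanned by the branches'
  late-time means, so the estimate can never leave the physical
  bracket; if the fit degenerates (branches already flat) the bracket
  midpoint is used, and the bracket disagreement is folded into the
  quoted error.  On 3-million-step reference runs the branches meet,
  validating the extrapolation.  Trajectory lengths: N = 16: 150k;
  N = 32: 500k; N = 64: 1M time units, two replicas per side.

## Observables

Per chain: squared radius of gyration, squared end-to-end distance, and
the gyration tensor `T_kl = (1/N) Σ_i (r_ik − r_cm,k)(r_il − r_cm,l)` on
unwrapped coordinates, with eigenvalues `λ₁ ≤ λ₂ (≤ λ₃)`; `trace T =
Rg²` holds to 10⁻¹² and is asserted on every measurement.  The ensemble
asphericity is the ratio of means `A₂ = ⟨(λ₂−λ₁)²⟩ / ⟨(λ₂+λ₁)²⟩` (not a
mean of ratios): 1 for rods, 0 for disks; in the two-layer box the two
largest eigenvalues enter.

The intramolecular correlation `γ(r)` counts ordered same-chain bead
pairs per distance, divided by `N`, including the self pair at `r = 0`,
so its total weight is exactly `N`.  Distances are exact: on this
lattice `4r²` is an integer, so the pair-distance multiset is
accumulated without binning error.  The single-chain structure factor is
`S(q) = Σ_pairs γ(r)·sin(qr)/(qr)` with the self term contributing 1 per
bead, hence `S(q→0) = N`.  The `sin(qr)/qr` kernel is the printed
scattering convention for this quantity; a Bessel-`J₀` kernel (the
strictly-2D isotropic average) is available behind a flag and differs
only at high q.  The default grid is 64 log-spaced q in `[2π/L, π]`.

The centre-of-mass pair correlation uses unwrapped chain centroids
mapped back into the cell, histogrammed over minimum-image distances and
normalised by annulus area so that a uniform (ideal-gas) point pattern —
the tested oracle — gives `g(r) = 1`; the correlation hole appears as
`g < 1` at small r.  Valid for `r < L/2`.  Solvent domains are connected
components of solvent sites under lattice adjacency.

## Scaling analyses

Exponents are ordinary least-squares slopes in log-log space with OLS
standard errors (lower bounds under serial correlation; ensemble means
are pre-blocked by replica or into 16 blocks).  Implemented fits:

* `⟨Rg²⟩ ∼ N^{2ν}` across chain lengths — 2D references: 2ν = 1.5
  dilute good solvent, 1.0 melt/ideal;
* `⟨Rg²⟩ ∼ phi^{(1−2ν)/(dν−1)}` in the concentrated regime — the
  analytic reference reproduces −1 for ν = 3/4, d = 2;
* `S(q) ∼ q^{−1/ν}` in the fractal window, taken as
  `q ∈ [2π/Rg, π]` with Rg from the same ensemble — references −4/3
  (dilute) and −2 (dense);
* blob crossover: two-segment piecewise-linear fit of log S vs log q
  with the breakpoint on the q grid; `ξ = 2π/q*`; a slope change below
  0.2 is reported as "no crossover" (the expected outcome for a pure
  power law).

## Desk-scale study conditions

The standard studies use N ∈ {16, 32, 64}: dilute at phi = 1/32
(8/4/2 chains on a 64×64 box), melt at phi = 1 (64×64, replicated
fills), intermediate at phi ≈ 0.3 (32×32, bracketed relaxation).
These sizes keep the full reproduction suite (`scripts/acceptance.py`)
in the tens-of-minutes range on one CPU while the fitted exponents
remain within their theoretical bands.  Known finite-size/finite-N
effects at this scale: the melt 2ν comes out slightly above 1 (≈1.1,
dominated by the N = 16 point — the same short chains the lattice
literature flags as anomalous), the melt S(q) slope is ≈ −1.86 rather
than −2 because the fractal window `[2π/Rg, π]` spans barely a decade
at N = 64, and the intermediate-concentration slope lands near 1.3–1.4
between the dilute (1.5) and melt (≈1.1) limits.

## Synthetic reference generators and what they do (not) show

The fixtures module provides: rods and the hexagon-plus-centre "disk"
(closed-form Rg², eigenvalues, A₂ ∈ {1, 0}); exhaustive SAW enumeration
for N ≤ 10 beads (walk counts match the published triangular-lattice
census), the brute-force oracle for the dilute engine; ideal
(non-self-avoiding) walks with ⟨Ree²⟩ = N−1, the 2ν = 1 reference;
pivot-sampled SAWs (exact dilute equilibrium); and uniform point
patterns (the g(r) = 1 oracle).  These validate the observables and the
sampler exactly, but they are single-layer, monodisperse, and short-N;
agreement at desk scale shows the machinery is correct, not that
cluster-scale phenomenology (long-chain microphase separation,
asphericity above 0.8) is reproduced — those regimes need chains of
512–1024 beads on 256²–512² boxes, which the same code runs but no
desk-scale test asserts.

## Numerical and degenerate-input choices

Exact integer site bookkeeping throughout; the only floating-point
observables are Cartesian embeddings and eigenvalues.  Ties in the
crossover breakpoint search resolve to the first (lowest-q) minimum.
`N = 2` chains are valid everywhere except pivot sampling (needs N ≥ 3);
`phi = 1` melts simply have no solvent elements (the algorithm is
unchanged); a chain whose unwrapped extent exceeds the box edge triggers
a warning (box too small for the chain).  Equilibration monitoring
block-averages the ensemble-mean Rg² over successive windows and stops
after two consecutive agreements within two combined standard errors; a
cap raises a timeout carrying the window history.

## Known limitations

* Global conformational mixing of long dilute/semidilute chains under
  purely local cooperative moves is very slow; the package mitigates
  this with equilibrium (pivot) initialisation and two-sided brackets,
  but does not accelerate the dynamics itself beyond the guided
  generator.
* OLS errors on exponents underestimate uncertainty when measurements
  are serially correlated; replica/block structure is used where it
  matters.
* The two-layer (quasi-2D) box is implemented and tested at the
  geometry/engine level, but no quantitative two-layer study is part of
  the desk-scale suite.
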