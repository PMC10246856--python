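# Methods

## Model

Chromosomes are represented as coarse-grained bead–spring polymers: one
bead per 5 kbp of chromatin, bead diameter σ = 30 nm.  The potential
energy has four terms,

    U_tot = U_spring + U_bend + U_LJ + U_nucleus

* **Bonds** — harmonic springs between consecutive beads with rest length
  σ: `U = ½ k_spring Σ (|r_i − r_{i+1}| − σ)²`.  `k_spring` defaults to
  100 k_BT/σ², stiff enough that bond-length fluctuations stay below
  0.1 σ (the thermal width is k_spring^{-1/2}).
* **Bending** — `U = k_bend Σ (1 − cos θ)` over consecutive bond-vector
  angles.  `k_bend = l_p k_BT/σ` sets the persistence length: 5 for the
  semiflexible chromatin fiber (l_p = 150 nm = 5 beads), 1 for the
  flexible variant.
* **Pairs** — a truncated 12-6 Lennard-Jones potential between all
  non-bonded bead pairs, cutoff 2.5 σ for attractive pairs.  The
  attraction strength ε (in k_BT) is the central control parameter:
  ε = 0 is a phantom chain, ε below the theta point an open chain,
  larger ε a collapsed one.  Purely repulsive (excluded-volume-only)
  pairs use the 2^{1/6} σ cutoff and are always energy-shifted there
  (WCA form), so their energy is non-negative by construction.  The
  attractive branch is plainly truncated by default; an energy-shifted
  option exists because scaling results are insensitive to the choice.
* **Confinement** — the nuclear envelope is a sphere of radius R_c.  The
  hard-core wall is realized as a harmonic half-spring acting beyond
  |r| = R_c − σ/2 with stiffness 200 k_BT/σ² (the bead *surface* touches
  the wall at R_c).  The published radius list
  {164, 77, 36, 29, 25, 23, 21, 20} σ for volume fractions
  φ ∈ {0.001 … 0.6} is reproduced by the ceiling convention
  R_c = ⌈(N/φ)^{1/3}/2⌉; the realized φ = N/(8 R_c³) is therefore at
  most the nominal one and is reported alongside it.

Bead types: EU (euchromatin), HET (heterochromatin), LAMIN (immobile
shell beads), plus the effective type LAD (an EU bead carrying the
lamina-associated-domain flag).  The 4×4 ε/cutoff matrices encode the
block-copolymer model: ε_EE = 0.25, ε_HH = 0.5, EU–HET excluded volume
only, and LAMIN attracting only LAD beads.  The lamin–LAD strength is
not constrained by the sources available to us; the default 1.0 k_BT is
a declared assumption, exposed in the configuration.

## Units

Reduced units throughout: σ = 1, k_BT = 1, bead mass m = 1.  The
physical time unit is the Brownian time τ = 3πησ³/k_BT — the time a
free bead takes to diffuse its own diameter — which is 59.5 µs (~60 µs)
for a 30 nm bead in water-like nucleoplasm at 310 K.  `UnitSystem` is
the only place where reduced units meet SI; conversions use the Julian
year (3.1557×10⁷ s), giving 2.68×10¹² τ ≈ 5 years and 6.2×10⁷ τ ≈ 1 h.

## Integration

Langevin dynamics with the BAOAB splitting: velocity-Verlet drift/kick
sweeps around an exact Ornstein–Uhlenbeck velocity update.  With the
thermostat disabled the scheme reduces exactly to velocity Verlet
(energy drift halves ~4× when dt is halved, which the suite checks).
Defaults: dt = 0.01 τ for phantom/dilute systems, dt = 0.005 τ for
dense attractive systems (LJ core collisions heat the larger step by a
few percent); friction time 1 τ.  With m = γ = k_BT = 1 the free-bead
diffusion constant is 1 σ²/τ, so one simulation time unit equals one
Brownian time and no time-axis rescaling is needed; the general mapping
τ = σ²/D is applied whenever temperature or damping differ from 1.

Noise is counter-based: each bead's Gaussian kick is a splitmix64 hash
of (seed, step, bead) pushed through Box–Muller, so trajectories are
bitwise reproducible regardless of call order, segmentation or
threading.  An overdamped Euler–Maruyama mode is available behind a
flag for cross-checks.

Neighbor search uses a linked-cell grid over the bounding box with a
Verlet skin of 0.6 σ, rebuilt when any bead has moved half a skin.
Pair forces are capped at 10⁴ (reduced units) below r = 0.5 σ; during
the compression protocol a much smaller cap (50) acts as a soft
push-off, because freshly generated curves and ideal-chain starts
contain sub-σ overlaps whose uncapped LJ cores would eject beads.

## Initial conditions

Each chain starts as a cubic-spline curve resampled to exact unit bead
spacing by marching chords along the densely sampled spline.  Control
points are laid on a jittered serpentine (boustrophedon) sweep of a
grid filling the packing box rather than drawn independently at random:
a spline through more than a few dozen independent random points is
almost surely knotted, while the monotone sweep is unknotted by
construction and still yields an irregular, box-filling curve.  The
knot screen (KMT triangle-elision down to a minimal polygon, then the
minimal crossing count over ≥20 random projections; zero crossings ⇒
unknot) verifies every generated chain; it is conservative in the sense
that true knots retain crossings, while an awkward unknot may
occasionally be flagged.

Copies of the chain are placed with a minimum inter-chain bead distance
of 0.8 σ and compressed by a spherical indenter whose radius shrinks
geometrically over 20 stages to R_c − σ/2, with the inward force
K(r − R_indent)² saturating beyond 1 σ penetration (an unsaturated
quadratic with a ramped K makes the stage shrinks unstable at any
usable dt).  K starts at 10 k_BT/σ³ and ramps ×1.2 per stage, capped at
20.  During compression intra-chain pairs attract (ε = 1, cutoff 2.5 σ)
and inter-chain pairs only repel (ε = 1, WCA cutoff), producing
condensed, separated, unknotted territories — the post-mitotic starting
condition.

## Observables

* **Contacts** — two beads are in contact when their centers are closer
  than 1.5 σ (45 nm).  Bonded neighbours (|i−j| ≤ 1 in a chain) are
  excluded; the band is a parameter.  Contact maps average the trailing
  frames of a run (default half, capped at 500).
* **Mixing index** — α = (inter-chain contacts)/(intra-chain contacts).
  For n equal chains in the uniform-contact ideal this tends to n − 1
  (3 for four chromosomes); `ideal_mixing_alpha` evaluates the exact
  finite-chain pair-count ratio (3.046 for 4×200 beads), which is the
  right yardstick at reduced scale.  On binned maps the diagonal holds
  within-bin contacts and enters the intra sum at half weight, which
  makes α exactly invariant under rebinning.  For experimental maps the
  main diagonal and first off-diagonal band are dropped (mirroring the
  bonded-pair exclusion).  The time average ᾱ uses the trailing 30% of
  frames.
* **Contact probability** — P(s) = contacts at contour separation s
  over pairs at separation s, pooled over chains and frames, s ≥ 2.
  The default fit window for full-scale chains is 200 ≤ s ≤ 1000,
  rescaled proportionally ([0.02 M, 0.12 M]) for shorter chains.
* **Power-law fits** — least squares on log–log coordinates; the
  exponent is −slope for decays (γ) and +slope for growth laws (β).
  The two-regime variant fits a continuous broken line with exhaustive
  breakpoint search and is kept only when it cuts the squared residual
  by ≥20%.
* **Mixing-time extrapolation** — t_mix = t_ref (α_max/α(t_ref))^{1/β}
  from the final fitted segment; β ≤ 10⁻³ reports +∞ (no mixing).
  States are classified against the critical time t_c = 2.68×10¹² τ
  (≈5 years), with decade bins clipped to [7, 16] for heat-map
  rendering and a consistency flag against the β bands (mixing within
  t_c goes with β ∈ [1/8, 1/4]).
* **MSD** — averaged over beads with all-time-origin (FFT) or
  single-origin estimators.  For short chains the monomer MSD can be
  measured in the chain's center-of-mass frame, removing the 6Dt/N
  whole-chain diffusion that otherwise contaminates the intermediate
  t^{1/2} (Rouse) window — a finite-size correction that vanishes at
  full scale.

## Theta point

The second virial coefficient of the untruncated LJ potential is
evaluated two ways: the Γ-function series
B = −(2π/3)σ³ Σ_j 2^{j+1/2}/(4 j!) Γ((2j−1)/4) (ε/k_BT)^{(2j+1)/4}
(truncated at k = 30, converged to <10⁻¹⁰ of the absolute-term sum),
and adaptive quadrature of −2π∫(e^{−U/k_BT} − 1) r² dr as an
independent oracle.  Both are per-pair in σ³ — the Avogadro prefactor
of the molar convention cannot move the root.  The two agree to
machine precision and share the root ε_θ = 0.29257 k_BT, the theta
point, which matches the measured collapse threshold ε_c ≈ 0.3 of a
flexible chain.

## Genome model and synthetic data

The fly genome is four chains — Chr2/Chr3/Chr4/ChrX at 60.5/68.8/4.5/
42.4 Mbp → 12100/13760/900/8480 beads (35240 total) at 5 kbp/bead.
Bead classes come from BED-like interval tables by majority overlap;
LAD flags are kept only on euchromatic beads (LAD annotation exists
only for euchromatin).  When no experimental tracks are supplied, a
synthetic generator draws alternating EU/HET blocks with exponential
lengths (mean EU block 500 kbp; HET mean sized for a 30% genome
fraction) and LAD blocks similarly (mean 250 kbp, ~40% of euchromatin)
— a statistical stand-in for real annotation, reproducing block
structure but not the positional layout (e.g. pericentromeric
concentration) of real tracks.  The lamin shell is a Fibonacci-sphere
layer of immobile beads at the confinement surface, spacing 1.5 σ,
thickness 1 σ; the density is not constrained by our sources and is
configurable.

Contact-map fixtures are built with closed-form mixing indices: block
totals proportional to chain-size products give exactly
α = (N² − ΣL²)/ΣL² (n − 1 for equal chains; ≈2.04 for the fly size
vector), a block-diagonal pattern gives 0, and a graded pattern scales
inter blocks by m ∈ [0,1].  Freely-jointed-chain ensembles (unit bonds,
uniform random directions) provide the direct-sampling oracle for
γ = 3/2; with the finite 1.5 σ contact radius the fitted exponent over
20 ≤ s ≤ 200 is ≈1.46, the known downward bias of a finite contact
volume at small s.

These generators emulate the contact *statistics* of ideal systems;
they do not contain sequence-dependent structure, TADs, loops or
experimental noise, so passing tests certify the estimators and the
dynamics engine, not agreement with any particular real dataset.

## Problem sizes

The published production scale (4 chains × 8810 beads, 10⁶ τ) is a
cluster workload.  The bundled checks run reduced systems chosen to
preserve the governing ratios where possible: 4×200-bead chains for
mixing (confinement-to-coil-size ratio comparable to full scale at
φ = 0.1), a 500-bead flexible chain for the collapse sweep, 200-bead
chains for the Rouse regime, and 2000-bead/10⁴-sample ensembles for
P(s).  At these sizes the mixing index carries finite-size biases of
order 10%: the uniform-contact ideal is 3.046 rather than 3, and
semiflexible chains (l_p = 5) cannot form short-range intra-chain
contacts (beads 2–10 apart on a stiff strand sit beyond 1.5 σ), which
suppresses the intra count and pushes the phantom-chain plateau a few
percent above even that ideal.  Both effects vanish as chain length
grows and are documented where the tests account for them.

## Known limitations

* The exact published generalization of the mixing index to
  heteropolymers of unequal size (which yields α_max = 3.9 for the fly
  genome) is not in the material available to us.  The implemented
  ratio is pinned to the equal-chain ideal limit n − 1; for the fly
  size vector it gives ≈2.04, so absolute α values for unequal genomes
  are not comparable with that published maximum.
* Loop extrusion, condensins/topoisomerases, FENE bonds and
  hydrodynamic interactions are out of scope; the shifted-LJ flag
  exists but no systematic potential-robustness study is bundled.
* Experimental Hi-C comparisons (α ≈ 0.3, Pearson ρ ≈ 0.9) require
  external data; the operations (loading, rebinning, log₂ Pearson) are
  provided as a workflow and validated on synthetic fixtures only.
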