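# Methods

`cutoffmd` is a minimal molecular-dynamics engine whose purpose is not to
simulate biomolecules at scale but to isolate, on desk-scale synthetic
systems, the artifacts introduced by the way nonbonded interactions are cut
off. This note documents the model, the numerical choices, what the
synthetic systems do and do not emulate, and the known limitations.

## Model and units

Units are nm, ps, u, e and kJ/mol throughout; the Coulomb prefactor is
f = 1/(4πε₀) = 138.935458 kJ mol⁻¹ nm e⁻², k_B = 8.31446×10⁻³ kJ mol⁻¹ K⁻¹,
and 1 atm = 0.0610194 kJ mol⁻¹ nm⁻³.

The electrostatic pair energy is the reaction-field form

    V(r) = f q_i q_j [ 1/r − C_rf r² / (2 R_rf³) − (1 − C_rf/2) / R_rf ],

with C_rf = 2(ε_rf − 1)/(2 ε_rf + 1) for a homogeneous dielectric continuum
of relative permittivity ε_rf beyond the cutoff sphere of radius R_rf (zero
ionic strength, unit dielectric inside). The distance-independent term makes
V vanish at r = R_rf; in code the expression is regrouped as
(1/r − 1/R_rf) − (C_rf/2R_rf³)(r² − R_rf²) so the zero is exact in floating
point as well. The force magnitude is f q_i q_j (1/r² + C_rf r/R_rf³): note
the *force* does not vanish at the cutoff — only the energy does — which is
why pairs crossing the cutoff inject noise. Lennard-Jones interactions use
C12/r¹² − C6/r⁶ with no shift and no long-range dispersion correction, under
the same entity cutoff as electrostatics, so that every cutoff effect seen
is attributable to the cutoff machinery alone.

ε_rf defaults: 61 for solute-containing systems, 78 for pure water; both are
plain configuration values.

## Cutoff schemes and pairlists

A *cutoff scheme* decides between which entities the cutoff distance is
measured: every atom separately (atomistic, AT), or whole charge groups
(CG), located at their center of geometry (CG(cog)) or at a designated atom
such as the water oxygen (CG(OW)). Solute and solvent rules are independent,
which yields the solute-atomistic mixed scheme (SA). Membership is decided
at the entity level, but pair energies always use atomic distances — so
under a group cutoff the included atomic terms need not be zero when the
group pair leaves the list. That single fact produces the group scheme's
sudden energy jumps, quantified by the 1D probe.

Distances strictly below the cutoff are included (half-open shells
[R_short, R_long)); tie handling at exactly the cutoff is this package's
convention, chosen to make threshold behavior unambiguous.

Twin-range (TR) bookkeeping: short-range pairs are evaluated every step from
a pairlist rebuilt every `update_interval` steps; intermediate-range pairs
(between R_short and R_long) are evaluated only at rebuilds, and their
forces, energies and virial are frozen in between. An interval of 1
reproduces single-range (SR) evaluation exactly.

Neighbor search uses a periodic KD-tree above 200 entities when the cutoff
is small against the box, and a compiled O(N²) classifier otherwise (at
desk-scale densities the box is barely larger than twice the cutoff, where
tree pruning cannot help). Both paths apply identical squared-distance
comparisons and return identical, lexicographically ordered lists; the test
suite enforces exact agreement. For the common single-range case the
classification and evaluation are fused into one compiled pass that never
materializes a pairlist; it is numerically equivalent to the list-based
path (summation order differs at the 10⁻¹⁵ relative level).

## Synthetic systems

*Water*: rigid 3-site SPC parameters (q_O = −0.82 e, q_H = +0.41 e,
d_OH = 0.1 nm, H-O-H angle 109.47° ⇒ d_HH = 0.16330 nm; O-O Lennard-Jones
C6 = 2.61735×10⁻³, C12 = 2.634129×10⁻⁶), placed on a cubic lattice with
±0.01 nm uniform jitter and uniformly random orientations, rejecting boxes
that cannot guarantee a 0.24 nm minimum O-O separation. A box of 1000
molecules at edge 3.107 nm reproduces 997 kg/m³.

*Toy solute*: a chain of neutral dipolar residues (two atoms, ±0.4 e,
0.1 nm apart, one charge group each; consecutive residues linked by a
constrained 0.38 nm virtual bond; a water-oxygen-sized LJ site on each atom
prevents overlap). It exists so the solute/solvent cutoff distinction and
the two-bath thermostat are exercisable; it has no secondary structure, no
torsional physics and no claim to represent a protein.

What these systems do *not* emulate: protein force-field detail, ions,
long-range electrostatics beyond the reaction-field continuum, and
full-scale system sizes. Passing tests therefore demonstrate the *mechanism*
of cutoff artifacts — membership jumps, noise heating, structure at the
cutoff — not their magnitudes in production protein simulations.

## Dynamics

Leapfrog integration (default Δt = 2 fs) with SHAKE (relative tolerance
10⁻⁴ on d², iteration cap 500) restoring constrained bonds after each
unconstrained step; the position correction is fed back into the half-step
velocities, followed by an iterative mass-weighted projection that removes
residual bond-direction velocity components to below 10⁻¹² nm/ps. Solute and
solvent couple to separate weak-coupling baths
(λ = √(1 + (Δt/τ_T)(T_ref/T − 1)), τ_T = 0.1 ps) applied after the
constraint step using post-constraint kinetic energies; per-bath degrees of
freedom are 3N − N_constraints with no global COM-motion removal (COM drift
is negligible over the runs used here and roto-translational constraints are
out of scope). Optional weak-coupling pressure scaling
(μ = (1 − κ_T (Δt/τ_P)(P_ref − P))^{1/3}, τ_P = 0.5 ps, κ_T 4.575×10⁻⁴ or
7.51×10⁻⁴ (kJ mol⁻¹ nm⁻³)⁻¹, clamped to [0.9, 1.1] against pressure spikes)
rescales box and coordinates isotropically. The virial is accumulated
pairwise as Ξ = −½ Σ r_ij·F_ij with minimum image, frozen with the cached
intermediate-range forces under twin range, and the pressure is
P = (2/3)(E_kin − Ξ)/V.

Lattice-built boxes start far above the liquid's energy; a constrained
steepest-descent relaxation (force-directed moves capped at 0.01 nm, SHAKE
after each move, step halving on energy increase) precedes velocity
assignment. Without it, the released lattice strain can heat a small box
beyond where 2 fs integration is reliable.

On-step kinetic energies reported in the log average the two adjacent
half-step velocities; bath temperatures entering the thermostat use the
half-step values directly.

## The 1D probe

Two diatomics (bond length b = 0.1 nm) on the x-axis, scanned over
center-center separations (default grid 0.2–1.8 nm, step 10⁻³ nm,
R_rf = 1.4 nm, ε_rf = 61). Membership per scheme: atomistic — each of the
four atom pairs by its own distance; group — all four by the center-center
distance; mixed — per (atom of A, center of B). Preset charge magnitudes are
1 e (profiles are also reported normalized by q², making the shapes
magnitude-independent). The "center" of a two-atom molecule is its center of
geometry. The axial force is reported on molecule A, positive pointing away
from B, so F = −dE/ds between membership changes.

Discontinuity detection flags grid intervals whose value change exceeds 10×
the median absolute change of neighboring intervals (window 20 on each
side). Analytic structure of the dipole–dipole scan: the atomistic energy is
continuous everywhere (each pair term vanishes at R_rf) but its force jumps
at s = R_rf − b, R_rf and R_rf + b; the group energy has exactly one jump,
at s = R_rf, equal to the full four-term energy there (second order in b);
the mixed energy is continuous at s = R_rf where the group scheme jumps, but
is itself discontinuous at s = R_rf ∓ b/2 where an A atom's distance to B's
center crosses the cutoff — the dropped atom–group sum is first order in b
(≈14 kJ/mol at unit charges), so "mixed tracks the atomistic curve" holds
between, not across, those membership changes. These follow directly from
the pair-energy expression and are what the probe tests assert.

## Observables

g(r) histograms minimum-image ordered-pair distances, normalized per frame
by N_a N_b (4π r² Δr)/V (the r²Δr shell approximation biases small-r bins by
up to ~+1% relative to the exact shell volume; the tests compare against the
exact-shell expectation). The dipole orientation correlation C(r) averages
μ̂_i·μ̂_j binned by the O-O (designated-atom) distance, with molecular
dipoles Σ q_k(r_k − r_cog) about the center of geometry. Radius of gyration,
RMSD₁₀₀ = RMSD/(1 + ln√(N/100)) (flagged NaN below the formula's validity
range, N ≲ 14), hydrogen-bond counting (acceptor–donor distance < 0.25 nm
and acceptor—H—donor angle > 120°, with a switch to apply the distance to
the hydrogen–acceptor pair instead, since the printed donor–acceptor
convention is unusually tight), and NOE-style ⟨r⁻³⟩⁻¹ᐟ³ averaging complete
the set.

Trajectory re-evaluation rescores stored frames under an alternative scheme
with a fresh single-range pairlist at R_long per frame (no twin-range cache,
recorded in report metadata); the headline report is electrostatic-only,
with LJ available behind a flag. Normalization of the energy differences:
solute–solute by N_solute, solvent–solvent by N_solvent, solute–solvent by
√(N_solute·N_solvent).

## The scaled-down study

The shipped end-to-end comparison (`cutoffmd.study`) runs 216 rigid waters
at 997 kg/m³ (box edge 1.864 nm), single 0.9 nm cutoff with the reaction
field at ε_rf = 78, pairlist rebuilt every step, 10 ps thermostatted
equilibration + 50 ps production, seeds 1–3, for the AT and CG(OW) schemes.
Choices worth stating:

* **Constant volume.** The box edge sits 3.5% above the 2R minimum-image
  bound, leaving no safe room for barostat fluctuations; runs are NVT at the
  experimental density.
* **Per-step pairlists.** At a 0.9 nm boundary, a 10 fs-stale list lets fast
  hydrogens cross ±0.03 nm before membership catches up; each crossing pair
  carries ±2–5 kJ/mol, and the resulting churn heats the box by orders of
  magnitude more than the bath can remove. Rebuilding every step gives each
  scheme its exact membership and keeps the AT/CG comparison clean.
* **Magnitudes are desk-scale.** The short cutoff amplifies every artifact:
  solvent temperatures sit ~12 K (AT) and ~140 K (CG) above the 298.15 K
  reference, and the re-evaluation asymmetry is thousands of kJ/mol. At
  production settings (1.4 nm, 1000+ waters) the same mechanisms produce
  fractions of a kelvin and tens of kJ/mol. The study's claims are therefore
  directional: both re-evaluation differences positive with AT→CG(OW) much
  larger; an O-O RDF deviation concentrated at the cutoff radius; CG solvent
  temperature ≥ AT. The RDF comparison window is [R − 0.05, 0.93] nm because
  r_max must stay below half the box edge.
* The bound-dimer conservation probe (two opposite unit charges on the O-O
  Lennard-Jones well) integrates with a 1 fs step: its LJ-wall oscillation
  is stiffer than water's constrained modes and is not resolved at 2 fs.

## Numerical conventions and degenerate inputs

Pair energies group (q_i q_j) so swapping charges is bitwise neutral.
Empty subsystems produce flagged (NaN) rows in normalized reports rather
than errors; empty histogram bins carry NaN values in C(r) and zero in
g(r). A zero-temperature velocity assignment returns exact zeros. SHAKE
aborts with diagnostics after 500 iterations; the barostat clamps μ to
[0.9, 1.1] with a warning; runs refuse boxes smaller than twice the longest
cutoff, and the barostat raises if it shrinks a box through that bound.

## Limitations

No lattice-sum electrostatics, no switching/shifting beyond the
reaction-field form's built-in shift, no Verlet buffers, no
Nosé–Hoover chains, orthorhombic boxes only, and no claim of quantitative
transferability from the desk-scale systems to production simulations: the
package demonstrates mechanisms and directions, at sizes a laptop can
re-run in minutes.
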