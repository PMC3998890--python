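# Methods

`loopgrow` samples closed, clash-free conformations of a protein loop between
two fixed anchors by distance-guided sequential chain-growth Monte Carlo, and
ranks them with a loop-specific atom-pair distance-dependent statistical
potential. This note records the model, the fitted components, the numerical
choices, and what the synthetic test world does and does not establish.

## Model and procedure

A loop of residues *s..e* is grown residue by residue toward the fixed
C-terminal anchor atom (the N of residue *e+1*). Bond lengths and bond angles
are fixed at standard values (`loopgrow/data/bond_geometry.json`, a versioned
stand-in table of the classic refined values); the degrees of freedom are the
backbone dihedrals φ, ψ, ω and the side-chain χ angles.

One growth step adds C_j, O_j, N_{j+1} and Cα_{j+1}:

1. **C placement.** With N_j and Cα_j fixed, C_j lies on a circle (the φ_j
   locus). Its distance to the anchor is drawn from the empirical conditional
   density f(d_C | d_Cα) fitted at the current residue separation g, and the
   sphere/circle intersection gives ≤ 2 candidate positions, one of which is
   taken uniformly (the two are empirically near-equivalent).
2. **N placement.** N_{j+1} lies on the ψ_j circle; its anchor distance is
   drawn from f(d_N | d_C) the same way.
3. **Cα and O.** Cα_{j+1} follows from ω ~ Normal(180°, σ_ω); O_j is placed
   by standard planar geometry.
4. **Trial selection.** Steps 1–3 are repeated m times. A subset of k trials
   is kept with probability proportional to the empirical (φ, ψ) frequency
   of the residue's type, and one survivor is selected with Boltzmann weight
   exp(−E/T), where E is the interaction energy of the four new atoms with
   the fixed protein and the already-grown loop atoms.
5. **Closure.** When the growing end is three residues from the anchor
   (the last two loop residues plus the anchor residue remain), analytic
   triaxial closure generates all backbones (≤ 16) that reconnect the chain,
   and one is selected by the same Boltzmann rule. The anchor residue's N is
   re-derived by the closure for the junction constraint; the fixed structure
   is never modified.

Side chains are then built per residue from empirical rotamer tables
(χ vectors binned at 10°, sampling a populated bin by frequency and returning
its mean χ vector), selected by Boltzmann weight. Steric clashes — any pair
involving a loop side-chain atom whose distance falls below 0.7 of the
vdW-radius sum — are then removed per residue by the best of the twelve 30°
rotations about χ1 (χ2 for proline), falling back to fresh rotamer draws for
residues a rotation cannot clean. Backbone proximity is governed by the
potential's sub-contact energies, not by the clash machinery. A conformation
that stays clashed is flagged; ensemble generation redraws flagged members
from the member's own random stream (up to 12 times) so reported ensembles
are clash-free in practice.

### Closure formulation

The closure contract — fixed N-side frame (last three grown backbone
atoms), fixed C-side frame (anchor N, Cα, C), discrete solution set of at
most 16 — admits exactly one consistent geometry: pivot Cα atoms at the last
two loop residues and the anchor residue. Placing three full residues onto a
rigid anchor N instead would leave the anchor φ as a free parameter and a
one-dimensional solution family. The solver is a numerically robust
equivalent of the 16-degree-polynomial formulation: the middle Cα is
parameterized on its two-sphere intersection circle (angle α); the two rigid
peptide-unit rotations τ1, τ2 follow per branch in closed form from the
N–Cα–C angle constraints at the outer pivots (each of form
A·cosτ + B·sinτ = D); sign changes of the middle angle residual over a
512-point α grid are polished with Brent's method. Two extra root classes are
handled explicitly: roots at τ-branch validity boundaries (located as zeros
of the branch discriminant) and tangential double roots (refined as local
minima of |F|). Every returned solution is verified by forward rebuilding;
the residual tolerances are 1e-4 Å on junction bonds and 1e-3° on junction
angles. Geometry jitter (σ = 0.01 Å bonds, 1° angles, 2° ω) is applied on
retry to rescue marginally unreachable anchors.

## Fitted components

* **Distance models.** For every residue separation g and both placement
  kinds (C and N), the (d_prev, d_new) pairs collected over all database
  loops are Winsorized at the 99th percentile (upper tail only) and fitted
  with a diagonal-bandwidth 2D Gaussian KDE (Scott's rule,
  h_i = σ_i·n^(−1/6)) evaluated on a 32×32 grid over the data range padded by
  two bandwidths per axis; bilinear interpolation elsewhere; conditional
  slices are sampled by inverse CDF. Separations beyond the largest fitted g
  reuse the largest-g model; separations whose pair sets are degenerate
  (e.g. covalently fixed distances) are skipped and the nearest fitted
  separation substitutes.
* **Dihedral tables.** Per-residue-type (φ, ψ) frequencies on a 10° grid
  with a pseudocount of 1e-6 of the total mass.
* **Pair potential.** Heavy atoms map to 20 types (backbone N, Cα, C, O plus
  16 side-chain classes: 6 carbon, 6 nitrogen, 3 oxygen, 1 sulfur; the
  mapping ships as editable JSON). Distances bin into one sub-contact bin
  [0, 2 Å) plus 30 uniform 0.2 Å bins up to 8 Å. The energy of a cell is
  −ln of the ratio of its observed pair probability (database loops, every
  unordered pair with at least one loop atom) to its expected probability
  (geometry-only decoy loops grown with a flat potential, 3 decoys per loop,
  per-loop means summed over loops). Unobserved cells are capped at +3; the
  sub-contact bin always carries the +10 clash constant, so clashing
  placements are strongly but finitely penalized and remain drawable with
  vanishing weight. Pairs within one residue and 1-2/1-3 pairs across the
  peptide bond are excluded everywhere — they are fixed by covalent geometry
  and would only add a constant.
* **Redcell.** Per-residue effective radii (max center-to-atom distance over
  the corpus) drive a residue-level cutoff r_i + r_j + c (c = 8 Å) against
  the loop anchors; the loop ellipsoid has the anchors as foci and threshold
  equal to the loop's summed backbone bond lengths, enlarged by the maximum
  side-chain reach (computed from the shipped templates; arginine) plus the
  interaction cutoff. A fixed residue is retained when it passes either test
  (the anchors bound the unknown loop-residue centers, and the ellipsoid is
  the binding criterion), which makes the filtered environment a superset of
  everything within interaction range — filtered and unfiltered energies are
  identical by construction, and the environment size is independent of
  protein size. The same ellipsoid prunes growth trials.

## Defaults

| parameter | default | meaning |
|---|---|---|
| m, k | 32, 8 | distance trials per step; dihedral-filtered subset |
| T | 1.0 | effective temperature (dimensionless) |
| σ_ω | 5° | ω spread about trans |
| side-chain trials | 16 | rotamer candidates per residue |
| χ / (φ,ψ) bin width | 10° | frequency-table resolution |
| clash ratio | 0.7 | distance over vdW-radius sum |
| r_lo, r_hi, w | 2.0, 8.0, 0.2 Å | potential binning |
| redcell c, d_cut | 8.0, r_hi Å | cutoff constant; ellipsoid enlargement |
| Winsorization | 99th pct | upper-tail clamp before KDE fits |
| closure jitter | 0.01 Å / 1° / 2° | bond / angle / ω perturbations |
| max restarts | 100 | growth attempts per requested conformation |

All of these are configuration keys recorded in run metadata.

## Sampling policies (implementation choices)

* Conditional distance draws are restricted to the geometrically reachable
  band of the placement circle (the conditional slice renormalized over the
  band; a uniform draw over the band when the slice carries no mass there).
  Without this, draws from the unrestricted slice frequently miss the sphere
  at small separations and the step fails spuriously.
* The final growth step tries its Boltzmann-ranked candidates in turn until
  one admits a closure; only when none does is the whole loop regrown. This
  is the restart-until-success policy applied at the finest granularity that
  preserves the per-step proposal.
* During sampling, perturbed closure uses 3 attempts (jitter cures marginal
  reach, not a wrong approach orientation); the closure module's own default
  budget is 20.
* Ensembles split the master seed into independent per-member streams, so
  runs are reproducible and prefix-stable (the first n members of a longer
  run equal the shorter run exactly).

## The synthetic world

The fixture generator emulates: ideal-geometry polypeptides (exact standard
bonds/angles, exact trans ω) with helix/strand/coil plans; coil (φ, ψ) from
a mixture of broad Gaussians on the three classic Ramachandran basins with
one two-residue β-turn motif (types I, I', II, II') embedded per coil run;
backbones built as self-avoiding walks (no nonbonded heavy-atom pair below
2.0 Å between residues more than one apart); a compactness gate
(Rg ≤ 4.0·n^(1/3) Å); canonical rotamer side chains with a χ1 relief sweep.
The reference corpus is 40 such proteins (~90 database loops).

It does **not** emulate: real experimental geometry variation (the ideal
world has zero bond/angle noise, so closure self-recovery is exact by
construction); native-like tertiary packing pressure (fixtures are packed
but far less densely than real globular proteins, so the potential's
directional guidance is weaker than in practice); proline ring closure
(built from χ templates with near-canonical pucker; the ring's return to the
backbone N is approximate); sequence-dependent dihedral coupling beyond
per-type tables. Consequently the self-recovery benchmarks characterize the
machinery — exact closure, exact energy bookkeeping, reproducibility,
clash-freedom — while the attainable minimum RMSD at a given ensemble size
is limited by the directional entropy of weakly confined synthetic loops:
with 1000 samples the minimum fixed-frame backbone RMSD typically lands in
the 0.4–1 Å range for 4-residue and 1.5–2.3 Å for 8-residue excised loops
under the reference conditions, varying with the target drawn. Benchmarks on real, densely packed proteins with a
database of tens of thousands of loops are outside what this synthetic world
can certify.

Problem sizes used by the reference experiment (chosen so the whole pipeline
runs comfortably on one CPU): 40-structure corpus, 3 decoys per loop for the
reference state, 1000 samples per target, 20 seeded runs of 50 samples for
the trial-count comparison.

## Known limitations

* Growth is N→C only; bidirectional growth is out of scope.
* Importance weights of the sequential proposal are not tracked: the output
  is an ensemble for min/ranked statistics, not a reweighted expectation.
* The anchor residue's ψ is not defined by the closure output (no atom
  beyond the anchor C is placed); it is reported as NaN.
* Loops must be interior (both anchors present) and at least 2 residues
  long.
* The potential's reference state is only as good as the geometry-only decoy
  set; with few decoys many (type, type, bin) cells sit at the cap.
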