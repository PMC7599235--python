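# Methods

`dimerlab` studies how tightly the two monomers of a protein dimer bind,
using the two complementary routes that are standard for this question:
equilibrium sampling of the native state (interface analytics averaged over
a restrained conformational ensemble) and non-equilibrium constant-force
pulling (mechanical resistance measured as a first-passage time). The
motivating system is the cytosolic phosphoglucose isomerase (PgiC) of the
grass *Festuca ovina*, which occurs as two homodimers and a heterodimer
built from two homologous alleles; the package, however, operates on any
two-chain dimer and ships generators for fully synthetic test systems.

## Energy model

The potential is a structure-based (Gō-type) model defined relative to a
reference conformation:

* **Native contacts.** Every pair of model sites within `native_cutoff`
  (default 8 Å) in the reference, excluding bonded and same-residue pairs,
  contributes an attractive Gaussian well
  `−ε·exp(−(r−r₀)²/2w²)` centred at its reference distance `r₀`
  (depth `ε = well_depth`, default 1 kcal/mol; width `w = well_width`,
  default 0.5 Å). Inter-monomer well depths carry an extra factor
  `inter_monomer_scale`, the interface-strength dial used to emulate dimers
  of different binding tightness. The Gaussian form is one of the standard
  smooth native-well variants; its softness keeps Metropolis acceptance
  usable on reduced systems.
* **Excluded volume.** All other non-bonded pairs repel as
  `(σ/r)¹²` with `σ = excluded_volume_radius` (default 4 Å).
* **Connectivity.** Consecutive Cα sites along a chain, and each side-chain
  pseudo-atom to its own Cα, are joined by harmonic pseudo-bonds
  `k_b(r−r₀)²` with `k_b = bond_k` (default 20 kcal/mol/Å²).
* **Backbone-RMSD restraint.** `k_rmsd·(RMSD_A + RMSD_B)`, one term per
  monomer, each the backbone RMSD from the reference after optimal rigid
  superposition (recomputed at every evaluation). The restraint suppresses
  large internal rearrangements while leaving rigid-body translation and
  rotation of each monomer — and hence the relative organisation of the
  dimer — completely free. `k_rmsd` defaults to 3 kcal/mol per Å, set so
  that unforced toy dimers fluctuate at backbone RMSD ≈ 1–1.4 Å (95th
  percentile below 2.5 Å), i.e. native-like but not frozen.
* **Pulling term.** `−F·|x₁−x₂|`, where x₁, x₂ are the Cα atoms closest to
  the centre of mass of each monomer and F is the constant force
  (protocol default 368 pN; 1 pN·Å = 0.01439 kcal/mol, derived from CODATA
  constants at import time, never hard-coded). The sign makes the force
  *reward* separation; written as `+F|x₁−x₂|` the term would penalise it,
  which contradicts a description of equal and opposite forces pulling the
  monomers apart, so the separation-favouring sign is implemented. The
  anchor distance uses the minimum-image convention, so the observed
  levelling-off of the anchor distance in a finite periodic box emerges
  rather than being imposed.

Model sites are Cα atoms by default (`site_level="ca"`); the reduced toy
dimers use `site_level="heavy"` so their planted side-chain pseudo-atoms
take part in the energetics.

## Monte Carlo protocol

Sampling is Metropolis MC at 300 K in a periodic cubic box of side 120 Å.
One cycle attempts one move per move slot: a Gaussian Cartesian
displacement of every site (σ = 0.15 Å), then one rigid translation
(σ = 0.15 Å per component; 0.3 Å in the pulling studies) and one rigid
rotation (σ = 0.02 rad) per monomer. The move-slot count is the package's
degree-of-freedom definition; the published protocol that this mirrors
works in torsional coordinates, which is one of the deliberate reductions
here.

Energies are updated incrementally per move. The restraint term is made
affordable by a rank-1 update of the Kabsch covariance: because the
covariance against a centred reference is independent of the instantaneous
mean, a single-site displacement updates it in O(1), after which the
signed singular values of the 3×3 matrix are obtained in closed form
(trigonometric eigenvalues of covᵀcov, sign from det). The cached total is
compared against a full recomputation every `check_interval` cycles
(default 1000) and resynchronised; the observed drift stays below
10⁻⁶ kcal/mol, which a test enforces.

Independent runs draw their generators from seed-sequence streams spawned
from (master seed, run index): a run set is reproducible bit for bit and
runs can be regenerated individually.

**Native-state protocol.** `n_runs` independent runs (default 24) of
`n_cycles` cycles (default 500,000), the first `burn_in` (default 200,000)
discarded, then `n_snapshots` (default 3,000) stored at a uniform stride —
100 cycles at the defaults. Properties are evaluated conformation by
conformation and averaged per run; the ensemble standard error is taken
over the independent-run means, never over pooled snapshots, because
snapshots within a run are autocorrelated. A separate bootstrap route
(10,000 resamples, seeded) provides standard errors of medians.

**Pulling protocol.** Runs start from the native reference (optionally
after a short unforced pre-equilibration, so the first-passage clock
starts from the restrained native ensemble rather than one exact
coordinate set), the constant force is applied, and the anchor–anchor
distance D_ca is recorded every cycle. The dissociation time t_dis is the
first cycle with D_ca above the threshold (default 41 Å); runs that never
cross are censored and reported as such. λ = 1/mean(t_dis) parameterises
the two-state model P(t) = 1 − e^(−λt); λ is deliberately not fitted to
the P(t) curve. An exponential MLE that uses censoring times is available
when runs are short.

**Exponentiality check.** The times are tested against Exp(1/mean) with a
Kolmogorov–Smirnov statistic whose p-value is calibrated by parametric
bootstrap (the rate is re-estimated on every simulated sample), since the
plain KS p-value is conservative when the rate comes from the same data.

## Interface analytics

* **Contacts.** Two residues across the interface are in contact if any
  pair of their heavy atoms is within 5.5 Å; the count n_c uses unordered
  residue pairs. The search runs on k-d trees and is tested against an
  O(n²) scan.
* **Typed interactions** (all cutoffs config keys): hydrogen bond =
  donor/acceptor heavy atoms ≤ 3.5 Å (the donor-H angle criterion applies
  only when explicit hydrogens exist); ionic = opposite-charge side-chain
  N/O pair ≤ 4.0 Å, counted per residue pair and excluded from the
  hydrogen-bond count so salt bridges are not double-counted; hydrophobic
  = apolar side-chain carbon pair ≤ 5.0 Å, counted at the residue-pair
  level (the atom-pair alternative is a config flag); cation–π = cationic
  nitrogen within 6.0 Å of an aromatic ring centroid, ring-normal offset
  ≤ 60°. These are standard geometric definitions; ensemble *comparisons*
  between dimers, not absolute counts, are the intended use.
* **Binding affinity.** The contact-based linear model
  ΔG = Σ_k w_k·IC_k + w_a·%NIS_apolar + w_c·%NIS_charged + w₀, with
  interface contacts IC classified by the residue-class pair
  (charged/polar/apolar; table: charged {D,E,K,R,H}, apolar
  {A,C,G,F,I,M,L,P,V,W}, polar {N,Q,S,T,Y}) at the same 5.5 Å rule, and
  the non-interacting-surface (NIS) percentages computed from per-residue
  relative SASA in the complex (surface = relative SASA > 5%,
  non-interacting = surface residues outside the interface). The
  coefficients are data, not code: a versioned config block carrying the
  published contacts+NIS regression (charged-charged −0.09459,
  charged-apolar −0.10007, polar-polar +0.19577, polar-apolar −0.22671,
  %NIS_apolar +0.18681, %NIS_charged +0.13810, intercept −15.9433
  kcal/mol; the charged-polar and apolar-apolar classes carry zero weight
  in that model but remain configurable).
* **SASA.** Shrake–Rupley quadrature on a golden-spiral point set
  (960 points/atom, probe 1.4 Å), ProtOr-flavoured van der Waals radii
  (config), hydrogens ignored; apolar SASA is the carbon+sulfur
  contribution. Totals in nm², per-residue values in Å².
* **Secondary structure.** A simplified DSSP-style assignment from
  Kabsch–Sander hydrogen-bond energies (−0.5 kcal/mol threshold; amide H
  rebuilt from backbone geometry when absent): α-helix from consecutive
  i→i+4 turns, 3₁₀ from i→i+3, strand from parallel/antiparallel bridge
  patterns, isolated turns T, else coil. Helix fraction counts {H, G} and
  strand fraction {E} (both config keys). This is a declared stand-in for
  a full STRIDE/DSSP implementation, adequate for comparing fractions
  between closely related ensembles, not for per-residue agreement with
  those programs.
* **Per-position decomposition.** For two dimers analysed under identical
  rules, the difference in each typed-interaction count is split into the
  part attributable to interactions involving a given set of positions
  (e.g. the variable residues near the interface), with per-position
  contributions and an explicit count of pairs spanning two set members
  (which the per-position sum double-counts).

## Sequence comparison

Equal-length protein pairs only (the motivating alleles are both 567
residues); variable positions are reported 1-based on full-length
numbering, and the 6–554 trimming used for structure-based work is an
explicit operation that preserves original numbering. Interface membership
of a position is computed structurally from a reference conformation (any
inter-monomer heavy-atom contact), never hard-coded; the published
position set {200, 372, 466, 521} serves as a regression fixture. The two
GenBank alleles themselves are not bundled: a deterministic synthetic
stand-in pair reproduces their length and the 20 published variable
positions (with charged substitutions at 466 and 521, mirroring the
reported chemistry), and user-supplied FASTA files take the same code path.

## Synthetic data: what it emulates and what it does not

`make_toy_dimer` builds two ideal α-helical Cα traces (rise 1.5 Å, radius
2.3 Å, 100°/residue) facing each other at 13 Å axis separation, with
side-chain pseudo-atoms planted at the midpoint of each interaction rule's
distance window (hydrophobic Leu CD1–CD1 at 4.0 Å, ionic Lys NZ–Glu OE1
at 3.5 Å, hydrogen-bond Ser OG–OG at 3.0 Å). Interface slots are spaced 4
residues (6 Å) apart so distinct planted pairs never cross any cutoff, and
are centred on the chain: with an off-centre contact a bound dimer can
swing its anchors apart by pivoting about the contact and cross a
dissociation threshold without dissociating, which contaminates
first-passage statistics (observed directly during development). All
non-planted inter-monomer residue pairs exceed the 5.5 Å contact cutoff by
construction, so the planted interface is the exact ground truth for
contact counts and typed-interaction counts.

The toys emulate: controllable interface composition and strength,
native-like fluctuation under the restraint, and planted sequence
differences. They do not emulate: real protein packing, side-chain
rotamers, realistic secondary-structure context at the interface, or
absolute energetics — so passing tests demonstrate that the *pipeline*
recovers planted truth and qualitative orderings, not that the reduced
model reproduces any real dimer's absolute numbers.

## Desk-scale study conditions

The published protocol (24 × 500,000 cycles on >1000-residue all-atom
dimers) is cluster-scale. The packaged studies run the same logic at desk
scale on the toy systems, with conditions chosen once and fixed in
`dimerlab.protocols`:

* Pulling toy: 10 residues/monomer, one planted hydrophobic contact at
  the chain centre; model built at `native_cutoff` 4.5 Å (the interface
  natives are then exactly the planted contacts — a broad set of weak
  Cα-level cross wells turns escape into a many-step ladder with
  Gamma-distributed, not exponential, times), `well_width` 0.3 Å,
  interface scale 7.5, force 300 pN, rigid-translation σ 0.3 Å,
  100-cycle unforced pre-equilibration.
* Dissociation threshold 20 Å for this toy: the smallest distance that,
  once crossed under force, is never re-crossed — the same criterion that
  fixes 41 Å for the full-size dimer, whose bound anchor distance is much
  larger. The force level follows the published criterion: small enough
  that the bound state persists for a significant time (escape is
  barrier-limited, hence near-exponential), large enough that all runs
  dissociate within budget. Under these conditions 200 runs give mean
  t_dis ≈ 900 cycles with no censoring.
* The weak/medium/strong comparison scales the interface wells by
  (7.0, 7.5, 8.0)/7.5; the force study uses 300/350/400 pN at fixed scale.
  24 runs per condition, matching the published run count.

## Numerical choices and degenerate inputs

* Kabsch superposition guards against reflections (smallest singular value
  negated when det < 0); RMSD of congruent sets is 0 to 10⁻⁹ Å.
* Ties in the central-Cα selection break to the lowest residue index;
  centre of mass is mass-weighted by default with a geometric option.
* Boundary p-values (exactly 0.05/0.01/0.001) take the less significant
  star label. Degenerate ANOVA input (all groups constant and equal)
  reports p = 1. Identical paired samples give Wilcoxon p = 1 rather than
  an error.
* Censored pulling runs are excluded from the plain mean (count reported);
  the censoring-aware exponential MLE is provided separately.
* PDB output is fixed-width with 3-decimal coordinates; write→read is a
  fixed point at that precision. Altloc codes other than blank/'A' are
  rejected; HETATM records are skipped with a logged count.

## Known limitations

* The energy model is a reduced stand-in: no transferable force field, no
  torsional move set, no side-chain chemistry beyond the planted
  pseudo-atoms. Absolute dissociation times, ΔG values and SASA of real
  dimers are out of reach by design; the reproduction surface is the
  protocol logic and the qualitative orderings.
* The secondary-structure assignment approximates DSSP patterns and is not
  expected to match STRIDE residue-by-residue.
* First-passage times contain a small deterministic component (well exit
  plus drift to the threshold), so their distribution is exponential only
  in the barrier-limited regime the fixed protocol targets; at much higher
  forces the drift dominates and the two-state picture degrades.
* The affinity model is linear in contact classes and NIS percentages; it
  inherits the applicability limits of that regression (globular,
  non-obligate complexes) and is used here for ensemble comparisons.
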