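# Methods

This note documents the models, conventions and numerical choices behind
`turnext`, and what the synthetic validation does and does not demonstrate.

## Turn detection and geometry

A candidate turn is any 4-residue window *i..i+3* with

* geometric continuity: every residue complete (N, CA, C present) and every
  consecutive Cα–Cα distance in **[2.7, 4.3] Å** — wide enough to admit both
  trans (≈3.8 Å) and cis (≈2.9 Å) peptides while rejecting windows that span
  missing density;
* Cα(*i*)–Cα(*i+3*) **< 7 Å**;
* central residues *i+1*, *i+2* non-helical under the 3-class reduction of
  DSSP states (H/G/I → helix, E → strand, everything else → coil);
* when any window residue is a strand, at least one must be coil (a turn
  buried entirely in a sheet is not a turn).

All qualifying windows are emitted; overlapping turns are deliberately not
suppressed.  Dihedrals are computed from the standard quadruples
(φ: C<sub>i−1</sub>–N–CA–C; ψ: N–CA–C–N<sub>i+1</sub>;
ω: CA<sub>i−1</sub>–C<sub>i−1</sub>–N–CA), wrapped into (−180°, 180°], with
termini reported as undefined rather than sentinel values.  The
implementation is cross-checked in the tests against an independent
geometry library on random point sets.

PDB input is parsed with gemmi; alternate conformers resolve to the highest
occupancy (ties alphabetically by altloc), and hetero records are kept only
when they carry a full backbone inside the polymer chain.  DSSP files are
consumed through Biopython's classic-format parser.  When no DSSP file is
given, an all-coil fallback lets detection run but cannot exclude helical
centres; this is logged loudly because it overcounts turns in helical
proteins.

## Type assignment

The matching rule is the classical one: a quad matches a type when at least
three wrapped absolute deviations from the canonical quad are **≤ 30°** and
the remaining one **≤ 45°**.  Both tolerances are inclusive; inclusivity is
what lets the retired type III (−60, −30, −60, −30), which deviates from
type I by exactly (0, 0, 30, 30), fall inside type I — the historical
reason type III was dropped.  Assignment order:

1. the eight classical types (VIa1/VIa2/VIb only when residue *i+2* is a
   proline with |ω| ≤ 30°);
2. failing all of those, the turn is type IV and is tested against the four
   extended centers IV₁–IV₄ under the same rule;
3. failing those too, IV_misc.

Multiple matches within a step resolve to the smallest RMSDA to the
canonical quad (then alphabetically — a tie of exact RMSDA is essentially
impossible on real data but the order must be deterministic).  Obsolete
types (III, III′, V, V′) are evaluated separately and reported as an
annotation, never as the main type.

One arithmetic consequence worth knowing: the IV₄ center (−97, −2, −117,
−11) deviates from the type-I canonical by (37, 28, 27, 11)°, which the
30/45 rule accepts, so a conformation at *exactly* the IV₄ center is
assigned type I.  This is not a defect of the implementation but of the
nomenclature's geometry: the extended types were derived from conformations
that individually failed classical matching, yet the mean of that set falls
back inside the (non-convex) type-I acceptance region.  Real IV₄ members
are those that fail classical matching, so in practice the label is
reachable; the package's self-assignment tests document the exception.

Canonical quads (classical, extended, obsolete), Ramachandran region boxes
and PB prototypes all ship as editable config files, so revised values can
be dropped in without code changes.  The region boxes are axis-aligned
approximations of the Wilmot–Thornton and Efimov nomenclatures (the
original publications print no machine-readable boundaries); they are
validated for non-overlap at load time and label the four extended-type
centers consistently with their published descriptions (IV₁: β_E→α_L;
IV₂: α_R→β_E / γ→δ; IV₃, IV₄ in the helical region).  The turn *extent*
follows Efimov's two classes: the angle between u₁ = Cα<sub>i+1</sub>−Cα<sub>i</sub>
and u₂ = Cα<sub>i+3</sub>−Cα<sub>i+2</sub> is a chain reversal (≥135°,
"full") or a direction change ("half"); the 135° boundary is the midpoint
between the nominal 180° and 90° classes.

## Two-stage clustering

The discovery procedure is a winner-take-all competitive learner (an SOM
with no neighbourhood diffusion) on 4-vectors of angles:

* **Dissimilarity**: RMSDA = √(Σ Δ²/4) with Δ the per-angle difference
  wrapped to the shortest arc.  The normalization by the number of angles
  follows the structural-alphabet convention.
* **Stage 1** (20 cycles): codebook initialized with k distinct quads drawn
  from the data; each cycle presents T random samples (with replacement);
  the minimal-RMSDA vector moves toward the sample by α·Δ per angle.
* **α schedule**: cycle *c* uses α = α₀/*c*, α₀ = 0.35.  Only cycle
  boundaries advance the schedule; within a cycle α is constant, and
  stage-2 rejections do not advance it.
* **Stage 2** (20 cycles, schedule restarted): identical, except the winner
  is updated only when the sample satisfies the 30/45 rule against it.
  This anchors vectors on recurrent conformations and prevents diffuse
  turns from dragging them.
* Ties in the winner search resolve to the lowest cluster index; training
  is bit-reproducible under a fixed seed.

**Reported centers.**  Clusters are ranked by member count
(minimal-RMSDA assignment of every quad).  The *observed center* of a
cluster is the per-angle circular mean of the members that satisfy the
30/45 rule against its codebook vector — i.e. the observed angles of the
conformations the cluster stands for.  This matters numerically: the raw
codebook vector keeps a residual stochastic jitter of order
σ·√(α_final/2) ≈ 1° (σ = 10°, α_final = 0.35/20), whereas the rule-filtered
observed mean is limited only by membership churn at the acceptance
boundary and is stable across runs to a few hundredths of a degree at
n = 50,000.  Both values are reported; comparisons across runs
(`match_codebooks`, optimal assignment via the Hungarian algorithm on an
RMSDA cost matrix) use the observed centers.

## Synthetic benchmark population

`type_iv_benchmark(n, seed)` emulates the *structure* of a type-IV turn
population: four recurrent conformations embedded in a diffuse majority.
It mixes four wrapped-normal modes (σ = 10° per angle, equal weights,
12.5% each — together half the mass, matching the share the four extended
types hold of the miscellaneous category) with a uniform component at 50%
standing in for the unclassifiable remainder.  Mode centers are the IV₁ and
IV₂ canonical quads plus two synthetic centers, (60, 40, 80, −170) and
(140, −100, 170, −80), chosen pairwise well-separated relative to σ.  Two
deliberate deviations from a literal "four recurrent types" population:

* **The diffuse component is essential, not decorative.**  With k = 10 and
  *all* mass in four modes, surplus codebook vectors necessarily sit inside
  modes and split them (each half-centroid is displaced by ≈0.8σ ≈ 8°);
  recovered centers are then off by several degrees and irreproducible
  across runs.  The uniform component gives surplus vectors somewhere to
  live — exactly the role IV_misc plays in real data — and with it the
  top-4 clusters recover the generating centers to <1° per angle at
  n = 10,000.
* **The real IV₃/IV₄ centers are not used as modes** because they are only
  26–45° apart per angle — not well-separated at σ = 10° — and adjacent
  modes merge under a single codebook vector, which would test the
  benchmark's geometry rather than the algorithm.

Wrapped-normal (not von Mises) sampling keeps the spread parameter an
ordinary pre-wrap standard deviation.  Component identity is recorded with
every sample so tests can compare against the generator directly.

What passing these benchmarks shows: the trainer recovers well-separated
recurrent conformations and is stable run-to-run under realistic population
structure.  What it does not show: performance on real PDB-derived turn
sets, where modes are anisotropic, correlated across angles and unevenly
weighted, and where the miscellaneous mass is far from uniform.

## Propensity statistics

For each turn type and window position *j*, n_exp(i, j) = N_j · f_i with
f_i the background frequency over the supplied sequences (or, by default,
the turn windows themselves — a documented simplification; supply full
chain sequences for databank-style backgrounds).  The default Z denominator
is the Poisson approximation √n_exp; a binomial option
√(n_exp·(1−f_i)) is selectable.  Tiers: |z| ≥ 4.42 strong (p < 10⁻⁵),
1.96 ≤ |z| < 4.42 weak (p < 0.05), inclusive at each lower bound; report
convention: strong letters uppercase, weak lowercase.  Unknown residues
count under 'X' and are excluded from backgrounds and Z-scores.  The same
machinery applies unchanged to the 16-letter Protein Block alphabet.

## Protein Blocks

Assignment is nearest-prototype over the 8-angle window
(ψ<sub>n−2</sub>…φ<sub>n+2</sub>) with the same wrapped RMSDA; the first
and last two residues of a chain (and any residue with an undefined window
angle) are 'Z'.  Ties resolve alphabetically.  The prototype angles ship as
a data file carrying the standard published Protein Blocks values; this
package does not re-derive the alphabet.

## Toy backbones

`build_backbone` places N/CA/C/O by sequential internal-coordinate (NeRF)
construction at fixed ideal geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N
1.329 Å, C=O 1.231 Å; angles N–CA–C 111.2°, CA–C–N 116.2°, C–N–CA 121.7°).
The constants only need to be self-consistent: the builder's purpose is
round-trip testing (recomputed dihedrals match the specification to ≲10⁻¹⁰°,
asserted at 0.1°) and fixture construction, not physical realism — there
are no side chains and no clash checking.

## Problem sizes and limitations

Validation uses n = 10,000 for center recovery and n = 50,000 with two
independent trainings for the stability figure (~25 s per training run);
the rule-equivalence check uses 10,000 random quads against a brute-force
enumerator, and the round-trip check 1,000 random backbones.  Known
limitations: no mmCIF input, no X-ray quality filtering, no
hydrogen-bond-based secondary structure (DSSP is consumed, not
reimplemented), turn orders n = 3, 5, 6 (γ/α/π-turns) out of scope, and the
region boxes are approximations intended for orientation, not adjudication.
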