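# Methods

## The problem

Many protein domains are built from structurally similar units arranged
with an internal (pseudo-)symmetry: closed rings such as β-propellers,
β-trefoils and TIM barrels, and open helical arrays such as α/α
superhelices, β-helices and leucine-rich repeats. `symscan` detects this
symmetry directly, rather than hunting for repeated sub-structures: the
structure is aligned against its own copy after circularly permuting the
copy's sequence by every possible number of residues. If the structure
carries an n-fold symmetry, the shift equal to one repeat length turns
the non-trivial self-match into a *full-length* match — the whole chain
superposes onto its rotated self — so the signal is amplified from
(n−1)/n of the chain to all of it, and symmetry-breaking insertions or
deletions in individual units cost only their own contribution.

## The alignment scan

For a trace of N Cα atoms the scan runs N−3 refinements. The k-th one is
seeded by pairing residue i of the copy with residue i+k of the
original; residues pushed past the C-terminus start unaligned. Each seed
is refined by alternating two steps (RSE refinement):

1. **Superposition** — the least-squares optimal proper rotation and
   translation over the currently aligned pairs (Kabsch's SVD solution,
   reflections excluded by the determinant sign correction).
2. **Realignment** — a gap-penalty-free structure-based alignment of the
   superposed coordinates (the SE step): maximal runs of ≥ 3 consecutive
   same-offset pairs under 3.5 Å seed the alignment, each run extends
   residue-by-residue while pairs stay under 6.0 Å, and a mutually
   consistent subset is selected greedily by total kernel weight, with
   conflicting pairs trimmed from the lighter run.

Iteration stops at an alignment fixed point or after `max_iterations`
(default 20; convergence is typically well under 10 cycles); the cycle
with the best T-score is reported, which also makes period-2 alignment
oscillations harmless.

The refinement operates in the *permuted index space* of the copy
(position p of the permuted copy holds residue ((p−1−k) mod N)+1). A
circular alignment of a closed structure straddles the sequence wrap
point; in permuted indices it is sequentially monotone, so the standard
no-crossing alignment machinery applies unchanged. The self-exclusion
rule, noise labelling and the average alignment shift always use the
original sequential indices.

## Scoring

The T-score is a weighted count of aligned residues,

    T = Σ 1 / (1 + (d_ij / d0)²),   d0 = 2.0 Å,

summed over aligned pairs whose sequential separation |i−j| exceeds
s = 3; closer pairs contribute nothing, which suppresses the trivial
self-alignment. The kernel halves at d0 and is ≈ 0.1 at 6 Å, which is
why the SE extension cutoff sits there.

## Screw-axis decomposition

Every proper rigid motion is a screw (Chasles): rotation by an angle
about an axis line plus a translation along it. The rotation angle and
axis direction come from the rotation matrix's rotation vector; the
translation splits into an axis-parallel part (the helical rise per
application) and an in-plane part absorbed into the axis position, the
minimum-norm solution of (R−I)p = −t_perp. Angles are reported signed in
(−180°, 180°], with the axis direction canonicalized against the best
alignment's axis (else +z) so all records of one scan share a sign
convention; presentation-level unwrapping past 360° is available in
reports only, never in stored values. Below 1° of rotation the axis
position is ill-defined; the transform is treated as a pure translation
(direction from the translation vector, point at the structure
centroid) — this is exactly the near-pure-translation one-layer screw
of square β-helices.

## Z-scores and classification

Raw T-scores grow with protein size, so significance is judged against
'noise' alignments: refined records whose rotation axis differs from the
best one (axis cosine < 0.95) and that align nothing within s of the
diagonal. Noise T-scores from a calibration batch are pooled in an
11-residue sliding window of protein sizes, and the window means and
standard deviations are each fitted with the saturating exponential
y = a + b(1 − exp(−cN)) by nonlinear least squares (deterministic
initialization a₀ = min y, b₀ = range y, c₀ = 1/median N). Then
Z = (T − mean(N)) / sd(N), sizes clamped to the fitted range, and a
structure is called symmetric when the best alignment's Z exceeds 8
(permissive) or 10 (strict) — strictly above, at both cutoffs. No
fitted constants ship with the package: the background depends on the
calibration set, so the model is always fitted (from generated decoys or
user structures) and stored as a JSON artifact with a provenance hash.
All-α and all-β structures tend to have elevated noise T-scores (helix
bundles, β-sandwiches); calibration can exclude them via a
caller-supplied class label, on by default when labels are given.
Generated decoys are labelled "other" (mixed class).

## Synthetic structures

The generators provide ground truth for every pipeline surface:

- **Cyclic rings / helical solenoids** — one repeating unit is a closed
  loop whose circumference matches `unit_length` × 3.8 Å (the trans
  Cα–Cα virtual bond), and the generating screw (twist about z, rise
  along z) is applied *per residue* as a continuous winding. Advancing
  one unit is then exactly the generating operation, so noise-free
  traces are invariant under it to machine precision — the strongest
  available oracle — while the chain stays continuous and rings close
  (termini adjacent). Defaults: 20 residues per unit, rise 4.8 Å and
  twist 100° per unit for solenoids (a β-helix-like geometry).
- **Random coils** — self-avoiding walks with exact 3.8 Å steps,
  bond angles in 60–120°, and ≥ 4.0 Å between non-neighbours; the null
  population for calibration.
- **Indels** are applied after symmetry construction, so the remaining
  residues' ground-truth symmetry is exact. Insertions are jittered
  linear bridges inside a unit.

What the generators do *not* emulate: real secondary structure and
backbone dihedrals, packing density, class-specific noise backgrounds
(the all-α/all-β elevation above), or the size-dependent complexity of
real domains. Passing tests therefore demonstrate the correctness of
the machinery — seeding, wrap handling, screw recovery, calibration
logic — not field performance on crystallographic structures.

## Numerical choices and degenerate inputs

- Traces need ≥ 8 residues (shifts run to N−3 and a superposition needs
  3 pairs); smaller inputs are rejected with a named error.
- Missing Cα atoms are skipped and counted, never interpolated; altlocs
  resolve to the highest-occupancy conformer (ties: first encountered);
  waters and ligands are ignored, modified amino acids with a Cα kept.
- All separation tests use the 1-based *sequential* Cα index; author
  numbering (often gapped in curated domains) is provenance only.
- Kabsch superposes all aligned pairs equally; the s-rule applies only
  to the T-score.
- Collinear point sets still superpose but are flagged degenerate.
- A shift whose refinement fails yields an empty record with T = 0; the
  scan never aborts on a single k.
- Fit non-convergence raises with diagnostics; there is no silent
  fallback.
- The fit-recovery simulation in the tests draws window means on a size
  grid spanning 10–600 residues: the exponential's intercept is poorly
  identified when all data sit on the plateau, and the wide grid makes
  all three parameters recoverable.

## Problem sizes used in tests and the acceptance script

Ring recovery uses C₂…C₈ at 15–20 residues per unit (N = 30–160);
the solenoid is 8 × 20 residues; calibration uses 200 decoys with sizes
uniform in 80–250 and a fresh set of 100 decoys at N = 150. These sizes
are representative of single domains while keeping a full run to a few
minutes on one core.

## Known limitations

- One symmetry axis per structure: the best alignment defines the axis,
  and all reporting is relative to it. Structures with two independent
  axes are reported by their dominant one.
- Global symmetry only: a symmetric sub-domain inside a larger
  asymmetric structure lowers T relative to the whole-chain background
  and will generally not be called.
- Symmetry *type* (closed vs open vs compound screw families) is
  reported through the angle-group summary but not classified
  automatically.
- The average alignment shift uses raw sequential differences; for
  wrapped circular alignments of closed structures it mixes positive and
  negative branches and is only meaningful for open structures and
  small-shift alignments.
- The SE seed/extension constants (3.5 Å / 6.0 Å / run ≥ 3) are this
  package's choices, exposed in the configuration; alignments near the
  cutoffs can shift slightly under different choices.
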