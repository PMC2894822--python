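# symscan

Detection of internal (pseudo-)symmetry in protein structures by
scanning a Cα trace against its own circularly permuted copy.

Many protein domains are built from similar units arranged with an
internal symmetry — β-propellers, β-trefoils, TIM barrels, α/α
superhelices, β-helices, leucine-rich repeats. `symscan` is for
structural biologists and bioinformaticians who want to ask, for a
single-chain structure: *is it symmetric, of what order, about which
axis, and with what helical translation?*

## Method

For a trace of N residues the scan runs N−3 structure self-alignments.
The k-th is seeded by pairing residue *i* of the duplicate with residue
*i+k* of the original, then refined by alternating Kabsch superposition
with a gap-penalty-free structure-based realignment until the alignment
is stable. Alignment quality is the T-score, a weighted aligned-residue
count

&nbsp;&nbsp;&nbsp;&nbsp;T = Σ 1 / (1 + (d_ij / d₀)²), d₀ = 2.0 Å,

over pairs with sequential separation |i−j| > s = 3 (near-diagonal pairs
are excluded to suppress the trivial self-alignment). For an n-fold
symmetric structure, the shift of one repeat length turns the structure
into a full-length match with its rotated self, so symmetry is detected
as a strong peak family rather than as isolated sub-alignments — and
insertions or deletions in single units only subtract their own
contribution.

Each refined superposition is decomposed into its screw elements:
rotation angle, axis direction, a point on the axis, and the translation
along the axis (the helical rise). Significance is a Z-score of the best
T against the size-dependent background of 'noise' alignments (those
whose rotation axis disagrees with the best one, axis cosine < 0.95):
noise T-scores are windowed over protein size (11-residue windows) and
their mean and spread fitted with y = a + b(1 − exp(−cN)); a structure
is called symmetric when the best Z exceeds 8 (permissive) or 10
(strict). The background model is always calibrated — from generated
random-coil decoys or from your own structure set — and stored as a JSON
artifact.

## Worked example

Generate a 3-fold ring of 18-residue units, calibrate a noise model from
40 random-coil decoys, and scan:

```sh
symscan generate --kind cyclic --n-units 3 --unit-length 18 --out c3.pdb
symscan calibrate --decoys 40 --size-min 50 --size-max 110 --seed 2 --out noise.json
symscan scan c3.pdb --calibration noise.json
```

The scan writes `c3.tsv` (one row per shift: T, Z, angle, translation,
axis, average shift, noise flag) and `c3.json`, and prints the report:

```json
{
  "label": "c3",
  "n_residues": 54,
  "best_shift": 36,
  "best_t_score": 53.99999639745055,
  "n_aligned": 54,
  ...
  "best_axis": {
    "angle_deg": -120.00000000892969,
    "translation_along_axis": -1.0291688140319292e-33,
    "direction": [-9.5e-18, 3.1e-18, 1.0],
    ...
  },
  "angle_groups": [
    {"n_members": 10, "top_angle_deg": 120.0, "top_z": 36.1, ...},
    {"n_members": 4, "top_angle_deg": -120.0, "top_z": 36.1, ...}
  ],
  "repeat_units": [[1, 18], [19, 36], [37, 54]]
}
```

Reading it: all 54 residues align onto the copy rotated by a third of a
turn about +z with zero translation along the axis — a pure 3-fold
rotation. The
two angle groups are the two non-trivial rotations of C₃ (120° and
240°, the latter reported as −120° in the (−180°, 180°] convention);
Z ≈ 36 is far above the strict cutoff of 10, and the best alignment's
orbit splits the chain into the three 18-residue units. An open helical
structure would instead show a non-zero `translation_along_axis` (the
rise per unit) and successively decreasing peak families.

Other subcommands: `symscan batch DIR --out summary.tsv` scans a
directory; `symscan scan --chain A --range 10:120` selects a domain;
`--write-alignment` / `--write-transform` emit the best pairing and the
3×4 transform as text.

## Layout

| module | role |
| --- | --- |
| `symscan.trace` / `symscan.tables` | PDB/mmCIF → Cα trace; TSV/JSON/alignment/transform output |
| `symscan.geometry` | Kabsch superposition, screw-axis decomposition |
| `symscan.sealign` | gap-penalty-free alignment of superposed traces |
| `symscan.refine` | T-score and superpose/realign refinement |
| `symscan.scan` | the N−3 shift scan, noise labelling, angle grouping |
| `symscan.calibration` / `symscan.decoys` | noise model fit, Z-scores, classification |
| `symscan.synthetic` | generators with exact known symmetry |
| `symscan.report` / `symscan.cli` | repeat units, JSON report, command line |

See `docs/methods.md` for the model, parameter defaults, numerical
choices, and known limitations.
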