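# tcrmotion

Quantifying conformational changes in the TCR:pMHC-I binding interface.

T cells recognise antigen when their αβ T-cell receptor (TCR) engages a
peptide presented by a class I MHC molecule. Whether the binding
interface is rigid ("lock-and-key") or moves during engagement
("induced fit" / "conformational selection") is a long-standing
question: case studies of individual crystal structures have reported
both behaviours. `tcrmotion` is a library for answering this question
systematically from collections of IMGT-numbered crystal structures of
unbound (*apo*) TCRs, unbound pMHC-Is, and bound (*holo*) TCR:pMHC-I
complexes. It is aimed at structural immunologists and at developers of
TCR structure-prediction and specificity models who need quantitative,
per-loop descriptions of binding-associated movement.

## What it computes

Given curated apo/holo structure pairs (matched by the TCR's six CDR
sequences, or by peptide sequence plus MHC allele):

- **Movement**: after least-squares (Kabsch) superposition on the TCR
  framework regions or the β-sheet floor of the MHC groove, backbone
  RMSD per CDR loop / peptide / MHC region, where
  RMSD = √(Σᵢ dᵢ² / n) over corresponding atoms (N, Cα, C, O for
  region-level comparisons; all heavy atoms for per-residue profiles).
  Comparison groups apo:apo, apo:holo, holo:holo separate binding-
  associated change from crystallographic variability.
- **Deformation**: the same RMSD after additionally superposing the
  loop pair itself, isolating internal shape change from bulk motion;
  plus the dihedral-space D-score
  D(A,B) = Σᵢ [2(1−cos Δφᵢ) + 2(1−cos Δψᵢ)].
- **Canonical clustering**: length-independent dynamic-time-warping
  (DTW) distances between loops superposed on the five flanking anchor
  residues each side, clustered with HDBSCAN (minimum cluster size 5);
  clusters with > 2 unique sequences are *canonical*, others *pseudo*;
  apo→holo label transitions fall into an 11-way shift taxonomy.
- **Contact fingerprints**: all heavy-atom pairs < 5 Å between CDR
  loops and the pMHC, aggregated per MHC IMGT position / peptide
  position into the fraction of contacts contributed by each loop,
  with dominant-loop maps (> 1 % threshold) and peptide-half summaries.
- **Anchor modes**: simplified per-position motifs from allele
  frequency tables (dominant > 60 %, high 30–60 %, medium 20–30 %,
  low 10–20 %, very-low ≤ 10 %); dominant/high positions are groove
  anchors, grouping pMHCs into p2–p9 vs p2–p5–p9 anchoring modes.
- **Statistics**: entity-level normalization (one mean value per TCR or
  pMHC identity), Kruskal-Wallis tests, post-hoc Wilcoxon rank-sum
  tests with Bonferroni correction, rigid/flexible binding-mode
  classification at 0.5 / 1.0 Å thresholds, and gene-usage /
  CDR-length comparisons against a background repertoire
  (10 uniform samples of 1000 unique TCRs).

A seeded synthetic-data generator (`tcrmotion.synthetic_data`) builds
idealized IMGT-numbered structures with planted, closed-form ground
truth — rigid loop displacements, mid-peak internal deformations,
loop families with cluster structure, controlled contact geometries,
motif tables and repertoires — so the entire pipeline is testable
without any database access.

## Worked example

Plant a 2 Å rigid displacement on CDR3β and recover it
(`examples/01_movement_recovery.py`):

```
framework fit RMSD:        2.82e-14 A  (744 atoms)
CDR3b backbone RMSD:       2.000000 A  (planted 2.000000 A)
CDR3b loop-superposed RMSD: 1.01e-13 A
```

The framework fit is numerically exact (the framework never moved), the
loop backbone RMSD in the framework frame recovers the planted
displacement, and superposing the loop first removes it entirely — the
loop moved as a rigid body without deforming. Contrast
`examples/02_loop_deformation.py`, where a planted internal deformation
survives loop superposition (0.737 Å, equal to its closed-form value)
with a per-residue profile that peaks mid-loop.

The full pipeline (`examples/06_full_pipeline.py`, or the `tcrmotion`
CLI with subcommands `simulate`, `curate`, `movement`, `deformation`,
`cluster`, `contacts`, `anchors`, `report`) prints, for a 6-entity
synthetic study:

```
mean apo:holo backbone RMSD per loop (A):
  CDR1a: 0.000 ... CDR3a: 1.089 ...
Kruskal-Wallis across loops: H = 16.24, p = 6.18e-03
pMHC region movement (A):
  mhc_non_contact: 0.000  mhc_tcr_contact: 0.000  peptide: 0.935
dual-mode TCR loops (both < 0.5 A and > 1.0 A seen): 0
```

i.e. movement concentrates in the loop it was planted in, peptide
movement dominates the pMHC side, and no loop shows both rigid and
flexible behaviour — exactly the planted study conditions.

The other examples cover loop clustering and the shift taxonomy (`03`),
contact fingerprints and peptide-half dominance (`04`), and anchor-mode
inference with mode-conditioned movement profiles (`05`).

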