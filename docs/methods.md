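# Methods

This note documents the models, conventions and design choices behind
`tcrmotion`, and what its synthetic validation does and does not show
about real crystallographic data.

## Structures and curation

Inputs are PDB-format files whose residue numbers already follow the
IMGT scheme; renumbering is out of scope (an optional `numberer` hook
on `read_structure` lets callers plug in an external renumberer before
region assignment). Hydrogens, waters and non-polymer heteroatoms are
dropped at ingestion; alternate locations resolve to the
highest-occupancy conformer; only model 1 of multi-model files is read.

Region semantics follow the standard IMGT delimitation: CDR1 = 27–38,
CDR2 = 56–65, CDR3 = 105–117, framework = the rest of positions 1–128.
The MHC groove floor — the reference for pMHC superposition — defaults
to heavy-chain positions 1–49 and 94–139, the stretches containing the
β-strands beneath the groove; the exact strand set used in published
analyses is not standardized, so this list (like all region sets) is a
config value (`RegionConfig`) rather than a constant.

Curation removes structures with resolution strictly greater than
3.50 Å (a structure at exactly 3.50 Å is kept, reading the cutoff as a
strict bound) and structures missing any backbone atom (N, Cα, C, O)
in a CDR loop (TCR-containing states) or in the peptide
(pMHC-containing states). Side-chain gaps do not reject: all
region-level metrics are backbone metrics. Apo and holo forms match on
exact identity keys — the six concatenated CDR sequences for TCRs,
peptide sequence plus allele name for pMHCs — and all apo × holo
combinations are kept; entity-level normalization (below) absorbs the
redundancy.

## Movement and deformation metrics

All correspondence between structures is by IMGT (number, insertion
code); residues present on one side only are excluded, never imputed.

Superposition is least-squares rigid fitting (Kabsch, SVD-based, with
the reflection corrected to a proper rotation). A covariance spectrum
whose second singular value falls below 1e-10 (collinear or coincident
selections) raises a degeneracy error rather than returning an
ill-defined rotation. TCR pairs align on the pooled α+β framework
backbone; pMHC pairs on the groove-floor backbone.

Backbone RMSD over a region, measured in that common frame, captures
bulk movement. Re-fitting the two copies of the loop itself before
measuring (`superpose_first=True`) removes the rigid component and
leaves internal deformation only; by construction the superposed value
never exceeds the unsuperposed one. Per-residue profiles use all
shared heavy atoms so side-chain rearrangement is visible; a residue
pair sharing no atoms is reported absent, not zero.

The dihedral D-score sums 2(1−cos Δφ) + 2(1−cos Δψ) over matched
residues. φ/ψ are computed from coordinates with the IUPAC sign
convention; angles across chain breaks (C–N distance > 2.5 Å) and at
segment termini are undefined and the corresponding angle pairs are
skipped, with the count of contributing pairs available to callers.
The raw sum is the default (bounded by 8·n); a length-normalized
variant is exposed as an option since per-residue averaging changes
how loops of different lengths compare.

## Loop clustering

Two loops of one type are compared by superposing one onto the other
on the backbone of the five anchor residues flanking each side (40
atoms), then running dynamic time warping over their residue
sequences. Three conventions are deliberate choices, since "a DTW
distance between backbones" underdetermines them:

- local cost = mean Euclidean distance over the four backbone atoms of
  a matched residue pair (not Cα-only), keeping sensitivity to
  backbone orientation;
- symmetric unit steps (diagonal/horizontal/vertical) with both
  endpoints pinned;
- the accumulated cost is divided by the warping-path length, making
  the measure comparable across loop lengths (ties in accumulated cost
  resolve to the shorter path, deterministically).

Clustering uses HDBSCAN on the precomputed distance matrix with
minimum cluster size 5; points outside any cluster are noise. Inputs
are sorted by loop id before clustering so label extraction is
deterministic. A cluster containing more than two unique sequences is
canonical, otherwise pseudo; pseudo clusters therefore have at least
`min_cluster_size` members, since the clusterer cannot emit smaller
ones. Apo and holo conformations of all TCRs of one loop type are
pooled into a single clustering — labels from separate runs are not
comparable, and `classify_shift` enforces shared provenance before
mapping an (apo label, holo label) pair onto the 11 transition
categories (same/shift/to-noise/to-pseudo/etc.).

## Contacts

A contact is a heavy-atom pair, one atom in a CDR loop and one in the
MHC heavy chain or peptide, at strictly less than 5.0 Å (a pair at
exactly the cutoff is not a contact). Search uses a k-d tree and is
verified against an all-pairs scan in the tests. Contacts are counted
at atom-pair granularity; when fingerprinting several complexes,
per-complex fractions are computed first and then averaged across
complexes, so heavily crystallized TCRs do not dominate the map (the
same normalization principle applied to the movement statistics).
Dominant-loop maps keep the argmax loop per position when its fraction
exceeds 1 %, breaking exact ties by the fixed loop order CDR1α…CDR3β
and logging them. Peptide halves are p1…p⌈N/2⌉ and the remainder.

## Anchor modes

Allele motifs are per-position amino-acid proportion tables. Banding
is half-open: dominant requires proportion > 0.60 (exactly 0.60 is
high), high > 0.30, medium > 0.20, low > 0.10, else very-low.
Positions holding a dominant or high residue are anchor positions; a
structure is annotated only when allele and peptide length both match
a motif, and only at positions where its own residue is one of the
motif's dominant/high residues.

Mode assignment considers the canonical slots p2, the middle position
(p5 for nonamers, ⌈N/2⌉ otherwise) and the C-terminus: all three
anchored → P2_P5_P9; a subset of {p2, C-terminus} (including a single
end, assumed to be anchored by an unobserved residue type at the other
end) → P2_P9; anything else falls back to the nearer group by set
distance and is logged. Anchors at non-canonical positions are
recorded but never mode-determining.

## Statistics

Every raw metric is first reduced to one value per
(entity, region, comparison, metric) by averaging — the operation is
idempotent — so entities appearing in many crystals contribute once.
Group differences use the tie-corrected Kruskal-Wallis test (identical
values in all groups return p = 1 by contract) and post-hoc two-sided
Wilcoxon rank-sum tests at a Bonferroni-corrected level α/m (α = 0.05
by default, configurable). Binding-mode classification applies the
0.5 / 1.0 Å thresholds to an entity's apo:holo values within one loop
across binding contexts: flexible if any value exceeds 1.0 Å and none
falls below 0.5 Å, rigid for the reverse, intermediate otherwise, and
a dual-mode flag when both extremes occur. Background comparisons draw
10 uniform samples of 1000 unique TCRs from the repertoire table and
report percent enrichment 100·(f_dataset − f_background)/f_background
per gene after stripping allele suffixes.

## Synthetic data and what it shows

The generator builds backbones in internal coordinates (standard bond
lengths/angles, trans peptide bonds), so Cα spacing (~3.8 Å) and φ/ψ
torsions are exact by construction. Geometry is idealized: no
Ramachandran statistics beyond the chosen torsion bins, side chains
truncated at Cβ, and no packing or energetics — sufficient because all
pipeline metrics are geometric.

Planted motions carry closed-form expectations. A pure translation of
magnitude t gives unsuperposed backbone RMSD exactly t and superposed
RMSD 0. Internal deformations displace all atoms of a residue jointly
with a weight profile (uniform; mid-peak, a sine bump vanishing at the
loop flanks; or anchored, sine bumps between peptide anchor
positions). For the superposed RMSD to equal the closed-form
√(Σ|dᵢ|²/n) exactly, the displacement field must contain no rigid
component — otherwise the Kabsch fit would absorb part of it — so the
generator projects the raw field orthogonal to the six rigid-body
modes of the loop backbone (zero net translation and zero net moment),
after alternating the sign of the per-residue direction so the
projection barely disturbs the planted weight profile. Anchored
peptide fields skip the projection: the measurement frame there is the
(unperturbed) MHC floor, not a fit of the peptide itself, so planted
per-residue magnitudes are recovered exactly, including exact zeros at
anchor positions.

Toy complexes pin CDR loop residues over their engagement targets
(CDR3α over the peptide's N-terminal half, CDR3β over the C-terminal
half, CDR1/CDR2 over the helices) with margins verified against the
5 Å cutoff; the toy peptide spacing is widened to 7 Å per position so
per-position contact assignments are unambiguous. Pinning breaks the
pinned loops' backbone continuity, so dihedral-based metrics are
undefined for them (the D-score machinery is validated on bonded
segments instead); this is the one respect in which the toy complexes
are deliberately non-physical.

Passing tests on this synthetic data demonstrates that the metrics,
clustering, fingerprinting and statistics compute what they claim to
compute, with exact recovery of planted ground truth. It does not
demonstrate anything about real structures — real data adds
crystallographic noise, missing density, alternate conformations,
numbering idiosyncrasies and genuinely ambiguous cluster structure
that the generator does not emulate.

## Problem sizes and reproducibility

The default end-to-end study uses 6 entities (one holo complex, one or
two apo TCRs, one apo pMHC each, plus extra holo crystals for three
entities) and a 4000-row background repertoire; the acceptance script
uses 50 rigid-recovery pairs, 100 oracle comparisons for DTW and
D-score, 20 complexes for the contact oracle and 1000 permutation
replicates — sizes chosen so the full validation completes in well
under a minute per stage on one CPU while keeping oracle enumeration
exhaustive. All randomness flows from explicit seeds; every pipeline
stage writes byte-identical artifacts when re-run with the same seed
(HDBSCAN is deterministic on a fixed distance matrix, and all
iteration orders are sorted).

## Known limitations

- mmCIF, assemblies and symmetry mates are unsupported; PDB only.
- Numbering is trusted as given; no internal renumbering or sequence
  alignment fallback when IMGT correspondence fails.
- The canonical-cluster coverage statistic requires a user-supplied
  reference loop set and is an optional report, not a default output.
- Docking-angle geometry, buried surface area and hydrogen-bond
  analysis are out of scope; the contact fingerprint is the interface
  descriptor.
- The "expected noise" reference line in movement reports defaults to
  0.5 Å (the rigid-mode threshold); it is a display aid, not a tested
  quantity.
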