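"""Infer peptide anchoring modes from allele motifs and condition
peptide movement profiles on them.

Builds simplified motifs with planted dominant residues, infers anchor
positions, assigns the p2-p9 vs p2-p5-p9 anchoring mode (including the
single-end fallback), then shows that peptides anchored in the two
modes move with unimodal vs bimodal per-position profiles.
"""

from tcrmotion import anchors as an
from tcrmotion import analysis_stats as st
from tcrmotion import synthetic_data as sd
from tcrmotion.structure_io import ApoHoloPair

print("anchor-mode assignment from planted motifs:")
for planted, peptide in [
    ({2: ("L", 0.7), 9: ("V", 0.8)}, "ALAAAAAAV"),
    ({2: ("L", 0.7), 5: ("F", 0.45), 9: ("V", 0.8)}, "ALAAFAAAV"),
    ({9: ("V", 0.8)}, "AAAAAAAAV"),
]:
    library = {("AL", 9): an.build_simplified_motif(sd.make_motif_table(planted, 9, "AL"))}
    ann = an.assign_mode(an.annotate_structure(peptide, "AL", library))
    print(f"  anchors {sorted(ann.anchor_positions)!s:<10} -> {ann.mode.value}")

pairs, annotations = [], {}
for i, mode in enumerate(["P2_P9"] * 3 + ["P2_P5_P9"] * 3):
    cx = sd.make_toy_complex(800 + i, anchor_mode=mode, allele=f"AL{i}",
                             structure_id=f"cx{i}")
    anchors = frozenset({2, 9} | ({5} if mode == "P2_P5_P9" else set()))
    spec = sd.PerturbationSpec("peptide", internal_amplitude=1.5, profile="anchored",
                               anchor_positions=anchors, project_rigid_modes=False,
                               seed=900 + i)
    apo, _, _ = sd.make_apo_holo_pair(sd.extract_pmhc(cx, f"b{i}"), spec)
    entity = f"p{i}|AL{i}"
    pairs.append(ApoHoloPair(entity, apo, cx, "pmhc"))
    annotations[entity] = an.assign_mode(
        an.AnchorAnnotation(entity, f"AL{i}", 9, set(anchors)))

profiles = st.anchor_conditioned_peptide_profile(pairs, annotations)
for mode, prof in profiles.items():
    values = dict(zip(prof["position"], prof["mean"]))
    shape = " ".join(f"p{p}:{values[p]:.2f}" for p in sorted(values))
    print(f"\n{mode.value} mean per-position movement:\n  {shape}")
print()
print("p2-p9 peptides bulge mid-peptide (unimodal); the extra p5 anchor pins")
print("the centre, pushing movement into two flanking lobes (bimodal).")
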