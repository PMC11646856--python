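"""Peptide anchor-position inference from MHC allele motifs.

An allele's peptide-binding preferences are summarized as a per-position
amino-acid frequency table (a motif, in the style of large pMHC ligand
atlases).  Frequencies are banded — dominant (> 60%), high (30-60%],
medium (20-30%], low (10-20%], very_low (<= 10%) — and positions with a
dominant or high residue are taken as groove anchor positions.  pMHC
structures are annotated by matching their peptide residues against the
motif (same allele, same length) and grouped into the two anchoring
modes seen in class I data: p2 + C-terminus (P2_P9) or an additional
middle anchor (P2_P5_P9).
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from pathlib import Path

__all__ = [
    "Band",
    "AnchorMode",
    "MotifProfile",
    "SimplifiedMotif",
    "AnchorAnnotation",
    "build_simplified_motif",
    "infer_anchor_positions",
    "annotate_structure",
    "assign_mode",
    "read_motif_library",
    "write_motif_library",
    "BAND_THRESHOLDS",
]

#: band lower bounds (exclusive): proportion p is dominant if p > 0.60, etc.
BAND_THRESHOLDS = {"dominant": 0.60, "high": 0.30, "medium": 0.20, "low": 0.10}


class Band(str, enum.Enum):
    DOMINANT = "dominant"
    HIGH = "high"
    MEDIUM = "medium"
    LOW = "low"
    VERY_LOW = "very_low"


class AnchorMode(str, enum.Enum):
    P2_P9 = "P2_P9"
    P2_P5_P9 = "P2_P5_P9"


class ProfileError(ValueError):
    """Motif proportions do not form per-position distributions."""


@dataclass
class MotifProfile:
    """Per-position amino-acid proportions for one (allele, length)."""

    allele: str
    peptide_length: int
    proportions: dict[int, dict[str, float]]  # position -> aa -> proportion

    def validate(self) -> None:
        for pos, table in self.proportions.items():
            total = sum(table.values())
            if abs(total - 1.0) > 1e-6:
                raise ProfileError(
                    f"{self.allele} p{pos}: proportions sum to {total:.6f}, not 1"
                )


@dataclass
class SimplifiedMotif:
    allele: str
    peptide_length: int
    bands: dict[int, dict[str, Band]]  # position -> aa -> band


@dataclass
class AnchorAnnotation:
    entity_id: str
    allele: str
    peptide_length: int
    anchor_positions: set[int] = field(default_factory=set)
    mode: AnchorMode | None = None
    notes: list[str] = field(default_factory=list)


def band_of(proportion: float) -> Band:
    """Band for one proportion; boundaries are half-open (0.60 is high)."""
    if proportion > BAND_THRESHOLDS["dominant"]:
        return Band.DOMINANT
    if proportion > BAND_THRESHOLDS["high"]:
        return Band.HIGH
    if proportion > BAND_THRESHOLDS["medium"]:
        return Band.MEDIUM
    if proportion > BAND_THRESHOLDS["low"]:
        return Band.LOW
    return Band.VERY_LOW


def build_simplified_motif(profile: MotifProfile) -> SimplifiedMotif:
    """Band every nonzero-proportion amino acid of every position."""
    profile.validate()
    bands = {
        pos: {aa: band_of(p) for aa, p in table.items() if p > 0}
        for pos, table in profile.proportions.items()
    }
    return SimplifiedMotif(profile.allele, profile.peptide_length, bands)


def infer_anchor_positions(motif: SimplifiedMotif) -> set[int]:
    """Positions holding any dominant or high amino acid."""
    return {
        pos
        for pos, table in motif.bands.items()
        if any(b in (Band.DOMINANT, Band.HIGH) for b in table.values())
    }


def annotate_structure(
    peptide_sequence: str,
    allele: str,
    motif_library: dict[tuple[str, int], SimplifiedMotif],
    entity_id: str | None = None,
) -> AnchorAnnotation | None:
    """Anchor annotation of one pMHC by motif matching.

    Requires a motif for the exact (allele, peptide length); anchors
    are assigned at positions where the peptide's residue is one of the
    motif's dominant/high residues there.  Returns None (a logged
    non-annotation) when no motif matches.
    """
    length = len(peptide_sequence)
    motif = motif_library.get((allele, length))
    if motif is None:
        return None
    annotation = AnchorAnnotation(
        entity_id=entity_id or f"{peptide_sequence}|{allele}",
        allele=allele,
        peptide_length=length,
    )
    for pos in infer_anchor_positions(motif):
        aa = peptide_sequence[pos - 1]
        band = motif.bands.get(pos, {}).get(aa)
        if band in (Band.DOMINANT, Band.HIGH):
            annotation.anchor_positions.add(pos)
    return annotation


def canonical_anchor_slots(peptide_length: int) -> tuple[int, int, int]:
    """(p2, middle, C-terminus) positions for a peptide of given length.

    For nonamers the middle slot is p5; for other lengths ceil(N/2).
    """
    middle = 5 if peptide_length == 9 else -(-peptide_length // 2)
    return 2, middle, peptide_length


def assign_mode(annotation: AnchorAnnotation) -> AnchorAnnotation:
    """Assign the anchoring mode from the anchor-position set.

    Only the canonical slots (p2, middle, C-terminus) determine the
    mode; other anchor positions are recorded but not mode-determining.
    A full {2, middle, C} set maps to P2_P5_P9; subsets of {2, C}
    (including a single end, assumed anchored by an unobserved residue
    type at the other end) map to P2_P9; any other nonempty pattern
    falls back to the nearer of the two groups by set distance, logged.
    Empty anchors leave the mode unassigned.
    """
    if not annotation.anchor_positions:
        annotation.mode = None
        annotation.notes.append("no anchors; mode unassigned")
        return annotation
    p2, mid, cterm = canonical_anchor_slots(annotation.peptide_length)
    canonical = annotation.anchor_positions & {p2, mid, cterm}
    extra = annotation.anchor_positions - {p2, mid, cterm}
    if extra:
        annotation.notes.append(f"non-canonical anchor positions recorded: {sorted(extra)}")
    if {p2, mid, cterm} <= annotation.anchor_positions:
        annotation.mode = AnchorMode.P2_P5_P9
    elif canonical and canonical <= {p2, cterm}:
        annotation.mode = AnchorMode.P2_P9
    else:
        # nearest group by symmetric set distance on canonical slots
        d_29 = len(canonical ^ {p2, cterm})
        d_259 = len(canonical ^ {p2, mid, cterm})
        annotation.mode = AnchorMode.P2_P9 if d_29 <= d_259 else AnchorMode.P2_P5_P9
        annotation.notes.append(
            f"non-standard anchor pattern {sorted(canonical)}; "
            f"assigned nearest group {annotation.mode.value}"
        )
    return annotation


# ---------------------------------------------------------------------------
# Motif library CSV interface
# ---------------------------------------------------------------------------

def read_motif_library(path: str | Path) -> dict[tuple[str, int], SimplifiedMotif]:
    """Read a motif CSV (allele, length, position, amino_acid, proportion)."""
    profiles: dict[tuple[str, int], MotifProfile] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            key = (row["allele"], int(row["length"]))
            prof = profiles.setdefault(key, MotifProfile(key[0], key[1], {}))
            prof.proportions.setdefault(int(row["position"]), {})[
                row["amino_acid"]
            ] = float(row["proportion"])
    return {key: build_simplified_motif(p) for key, p in profiles.items()}


def write_motif_library(profiles: list[MotifProfile], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["allele", "length", "position", "amino_acid", "proportion"])
        for prof in profiles:
            for pos in sorted(prof.proportions):
                for aa, p in sorted(prof.proportions[pos].items()):
                    w.writerow([prof.allele, prof.peptide_length, pos, aa, repr(p)])
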