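"""TCR-to-pMHC contact fingerprinting.

A contact is a pair of heavy atoms, one in a TCR CDR loop and one in
the pMHC-I (MHC heavy chain or peptide), strictly closer than a cutoff
(default 5.0 Å).  Aggregating contacts per target position gives a
fingerprint: for every MHC IMGT position or peptide position, the
fraction of its contacting atom pairs contributed by each CDR loop.
When several complexes are pooled, per-complex fractions are averaged
so heavily crystallized TCRs do not dominate the fingerprint.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure_io import StructureRecord
from .superposition import LOOP_NAMES

__all__ = [
    "ContactPair",
    "ContactFingerprint",
    "DominantLoopMap",
    "find_contacts",
    "fingerprint",
    "dominant_loops",
    "peptide_half_profile",
    "partition_mhc_positions",
    "DEFAULT_CONTACT_CUTOFF",
]

DEFAULT_CONTACT_CUTOFF = 5.0

#: fixed loop order used for deterministic tie-breaking
LOOP_ORDER = LOOP_NAMES


class StructureError(ValueError):
    """The complex lacks a chain required for contact mapping."""


@dataclass(frozen=True)
class ContactPair:
    """One heavy-atom contact between a CDR loop atom and a pMHC atom."""

    complex_id: str
    tcr_loop: str  # CDR1a ... CDR3b
    tcr_residue: tuple[str, int]  # (chain role, imgt number)
    pmhc_role: str  # mhc_heavy | peptide
    pmhc_position: int  # IMGT number (MHC) or peptide position
    atom_pair: tuple[str, str]
    distance: float


@dataclass
class ContactFingerprint:
    """Per target position, the loop-wise share of its contacts.

    ``fractions[position][loop]`` holds the (complex-averaged) fraction
    of the position's contacting atom pairs contributed by that loop;
    ``counts[position]`` the total number of contributing atom pairs.
    """

    target: str  # "mhc" | "peptide"
    fractions: dict[int, dict[str, float]] = field(default_factory=dict)
    counts: dict[int, int] = field(default_factory=dict)

    def positions(self) -> list[int]:
        return sorted(self.fractions)


@dataclass
class DominantLoopMap:
    """Per position, the single loop with the largest contact share."""

    target: str
    dominant: dict[int, str] = field(default_factory=dict)
    ties: list[int] = field(default_factory=list)


def _cdr_atoms(record: StructureRecord):
    """(coords, metadata) for all heavy atoms of the six CDR loops."""
    coords, meta = [], []
    for role, suffix in (("tcr_alpha", "a"), ("tcr_beta", "b")):
        for chain in record.chains_with_role(role):
            for region in ("CDR1", "CDR2", "CDR3"):
                loop = f"{region}{suffix}"
                for res in chain.region_residues(region):
                    for atom in res.atoms.values():
                        coords.append(atom.coords)
                        meta.append((loop, (role, res.imgt_number), atom.name))
    return np.array(coords), meta


def _pmhc_atoms(record: StructureRecord):
    coords, meta = [], []
    for role in ("mhc_heavy", "peptide"):
        for chain in record.chains_with_role(role):
            for res in chain.residues:
                for atom in res.atoms.values():
                    coords.append(atom.coords)
                    meta.append((role, res.imgt_number, atom.name))
    return np.array(coords), meta


def find_contacts(
    holo: StructureRecord, cutoff: float = DEFAULT_CONTACT_CUTOFF
) -> list[ContactPair]:
    """All (CDR heavy atom, pMHC heavy atom) pairs strictly under ``cutoff``.

    Non-CDR TCR atoms are ignored; the distance test is a strict
    inequality, so a pair at exactly the cutoff is not a contact.
    Search uses a k-d tree; results are ordered deterministically.
    """
    if not holo.chains_with_role("peptide"):
        raise StructureError(f"{holo.structure_id}: no peptide chain")
    tcr_xyz, tcr_meta = _cdr_atoms(holo)
    pmhc_xyz, pmhc_meta = _pmhc_atoms(holo)
    if len(tcr_xyz) == 0 or len(pmhc_xyz) == 0:
        return []
    tree_t = cKDTree(tcr_xyz)
    tree_p = cKDTree(pmhc_xyz)
    pairs = tree_t.query_ball_tree(tree_p, r=cutoff)
    out: list[ContactPair] = []
    for i, neighbors in enumerate(pairs):
        loop, tres, tname = tcr_meta[i]
        for j in neighbors:
            d = float(np.linalg.norm(tcr_xyz[i] - pmhc_xyz[j]))
            if d >= cutoff:  # enforce strict boundary
                continue
            role, pos, pname = pmhc_meta[j]
            out.append(
                ContactPair(
                    holo.structure_id, loop, tres, role, pos, (tname, pname), d
                )
            )
    out.sort(key=lambda c: (c.tcr_loop, c.tcr_residue, c.pmhc_role, c.pmhc_position, c.atom_pair))
    return out


def fingerprint(
    contacts: list[ContactPair], target: str, per_complex_average: bool = True
) -> ContactFingerprint:
    """Loop-share fingerprint over MHC or peptide positions.

    Counting is at atom-pair granularity.  With several complexes in
    the input and ``per_complex_average`` (default), fractions are
    computed per complex first and then averaged over the complexes
    touching each position, so no single complex dominates.
    """
    role = {"mhc": "mhc_heavy", "peptide": "peptide"}[target]
    relevant = [c for c in contacts if c.pmhc_role == role]
    fp = ContactFingerprint(target=target)
    if not relevant:
        return fp

    # complex -> position -> loop -> atom-pair count
    by_complex: dict[str, dict[int, dict[str, int]]] = defaultdict(
        lambda: defaultdict(lambda: defaultdict(int))
    )
    for c in relevant:
        by_complex[c.complex_id][c.pmhc_position][c.tcr_loop] += 1

    if not per_complex_average:
        merged: dict[int, dict[str, int]] = defaultdict(lambda: defaultdict(int))
        for table in by_complex.values():
            for pos, loops in table.items():
                for loop, k in loops.items():
                    merged[pos][loop] += k
        for pos, loops in merged.items():
            total = sum(loops.values())
            fp.fractions[pos] = {lp: k / total for lp, k in loops.items()}
            fp.counts[pos] = total
        return fp

    position_fracs: dict[int, dict[str, list[float]]] = defaultdict(lambda: defaultdict(list))
    counts: dict[int, int] = defaultdict(int)
    for table in by_complex.values():
        for pos, loops in table.items():
            total = sum(loops.values())
            counts[pos] += total
            for loop in LOOP_ORDER:
                position_fracs[pos][loop].append(loops.get(loop, 0) / total)
    for pos, loop_lists in position_fracs.items():
        means = {lp: float(np.mean(v)) for lp, v in loop_lists.items()}
        norm = sum(means.values())  # 1.0 by construction; guard roundoff
        fp.fractions[pos] = {lp: m / norm for lp, m in means.items() if m > 0}
        fp.counts[pos] = counts[pos]
    return fp


def dominant_loops(fp: ContactFingerprint, min_fraction: float = 0.01) -> DominantLoopMap:
    """The top contacting loop per position, kept only above ``min_fraction``.

    Exact ties resolve to the first loop in the fixed CDR1a..CDR3b
    order and the position is recorded in ``ties``.
    """
    out = DominantLoopMap(target=fp.target)
    for pos in fp.positions():
        fracs = fp.fractions[pos]
        best = max(fracs.values())
        if best <= min_fraction:
            continue
        winners = [lp for lp in LOOP_ORDER if fracs.get(lp, 0.0) == best]
        out.dominant[pos] = winners[0]
        if len(winners) > 1:
            out.ties.append(pos)
    return out


@dataclass
class HalfProfile:
    """Loop contact shares aggregated over one peptide half."""

    positions: list[int]
    shares: dict[str, float]
    dominant: str | None


def peptide_half_profile(
    fp: ContactFingerprint, peptide_length: int
) -> dict[str, HalfProfile]:
    """Aggregate loop contact shares over the two peptide halves.

    The first half is p1..p(ceil(N/2)), the second the remainder; per
    half the position-wise loop fractions are summed, renormalized and
    the dominant loop reported.
    """
    if fp.target != "peptide":
        raise ValueError("peptide-target fingerprint required")
    if peptide_length < 8:
        import warnings

        warnings.warn(f"peptide length {peptide_length} < 8; halves are very short")
    mid = -(-peptide_length // 2)  # ceil
    halves = {
        "first_half": [p for p in fp.positions() if p <= mid],
        "second_half": [p for p in fp.positions() if p > mid],
    }
    out: dict[str, HalfProfile] = {}
    for half, positions in halves.items():
        sums: dict[str, float] = defaultdict(float)
        for pos in positions:
            for loop, frac in fp.fractions[pos].items():
                sums[loop] += frac
        total = sum(sums.values())
        shares = {lp: v / total for lp, v in sums.items()} if total > 0 else {}
        dominant = (
            max(shares, key=lambda lp: (shares[lp], -LOOP_ORDER.index(lp)))
            if shares
            else None
        )
        out[half] = HalfProfile(positions, shares, dominant)
    return out


def partition_mhc_positions(
    fp: ContactFingerprint, antigen_binding_positions: set[int]
) -> tuple[set[int], set[int]]:
    """Split MHC antigen-binding-domain positions by TCR contact.

    Positions with any retained contact form the tcr_contact set; the
    remaining domain positions the non_contact set (disjoint cover).
    """
    contacted = set(fp.positions()) & set(antigen_binding_positions)
    return contacted, set(antigen_binding_positions) - contacted
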