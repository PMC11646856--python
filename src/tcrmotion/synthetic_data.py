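"""Seeded generators of toy IMGT-numbered structures with known ground truth.

Everything the pipeline consumes can be synthesized here: idealized
TCR and pMHC-I structures, apo/holo pairs whose CDR loops (or peptide)
carry planted rigid-body displacements and internal deformations with
closed-form expected RMSDs, loop families with planted cluster
structure, allele motif tables with controllable per-position dominance
and background repertoires with controllable gene usage.

Backbones are built in internal coordinates (standard bond lengths and
angles, trans peptide bonds) so consecutive C-alpha atoms sit ~3.8 Å
apart and phi/psi torsions are well defined.  Geometry is idealized,
not energetically realistic: all pipeline metrics are purely geometric.

Ground-truth bookkeeping for internal deformations: the raw
displacement field is projected orthogonal to the six rigid-body modes
of the loop's backbone (zero net translation and zero net moment),
which makes the identity transform the optimal Kabsch fit and hence the
superposed RMSD exactly equal to the closed-form root-mean-square of
the planted per-atom displacements.
"""

from __future__ import annotations

import itertools
import json
import string
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd

from .structure_io import (
    AtomRecord,
    NumberedChain,
    RegionConfig,
    Residue,
    StructureRecord,
    DEFAULT_REGIONS,
    assign_all_regions,
)
from .loop_clustering import LoopConformation
from .anchors import MotifProfile
from .superposition import LOOP_NAMES

__all__ = [
    "PerturbationSpec",
    "GroundTruth",
    "build_backbone",
    "make_toy_tcr",
    "make_toy_pmhc",
    "make_toy_complex",
    "make_apo_holo_pair",
    "make_loop_families",
    "make_motif_table",
    "make_background_repertoire",
    "make_study_dataset",
    "extract_tcr",
    "extract_pmhc",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# standard backbone internal coordinates (Å, degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_CA_CB = 1.458, 1.525, 1.329, 1.231, 1.530
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_A_CA_C_O, _A_N_CA_CB = 120.5, 110.5
_OMEGA = 180.0


class SpecError(ValueError):
    """A perturbation spec references an absent loop or invalid value."""


# ---------------------------------------------------------------------------
# Internal-coordinate backbone construction
# ---------------------------------------------------------------------------

def _place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
                bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom d from a-b-c by bond length, angle b-c-d, torsion a-b-c-d."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(angle),
        bond * np.sin(angle) * np.cos(torsion),
        bond * np.sin(angle) * np.sin(torsion),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_backbone(
    phi_psi: list[tuple[float, float]], include_cb: bool = True
) -> list[dict[str, np.ndarray]]:
    """Build N/CA/C/O(/CB) coordinates for a chain with given torsions.

    ``phi_psi`` lists (phi, psi) in degrees per residue; the first
    residue's phi and the last residue's psi only orient terminal
    atoms.  Peptide bonds are trans (omega 180).
    """
    n_res = len(phi_psi)
    atoms: list[dict[str, np.ndarray]] = []
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_B_N_CA, 0.0, 0.0])
    # a virtual predecessor defines the first residue's phi frame
    C = _place_atom(np.array([-1.0, 1.0, 0.0]), N, CA, _B_CA_C, _A_N_CA_C, phi_psi[0][0])
    atoms.append({"N": N, "CA": CA, "C": C})
    for i in range(1, n_res):
        prev = atoms[-1]
        psi_prev = phi_psi[i - 1][1]
        N_next = _place_atom(prev["N"], prev["CA"], prev["C"], _B_C_N, _A_CA_C_N, psi_prev)
        CA_next = _place_atom(prev["CA"], prev["C"], N_next, _B_N_CA, _A_C_N_CA, _OMEGA)
        C_next = _place_atom(prev["C"], N_next, CA_next, _B_CA_C, _A_N_CA_C, phi_psi[i][0])
        atoms.append({"N": N_next, "CA": CA_next, "C": C_next})
    # carbonyl O: anti to the next N (torsion psi + 180 about N-CA-C)
    for i in range(n_res):
        psi = phi_psi[i][1]
        atoms[i]["O"] = _place_atom(
            atoms[i]["N"], atoms[i]["CA"], atoms[i]["C"], _B_C_O, _A_CA_C_O, psi + 180.0
        )
        if include_cb:
            atoms[i]["CB"] = _place_atom(
                atoms[i]["C"], atoms[i]["N"], atoms[i]["CA"], _B_CA_CB, _A_N_CA_CB, 122.6
            )
    return atoms


_ELEMENTS = {"N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C"}


def _make_residue(imgt: int, aa: str, coords: dict[str, np.ndarray],
                  icode: str = "") -> Residue:
    atoms = {}
    for name, xyz in coords.items():
        if name == "CB" and aa == "G":
            continue
        element = _ELEMENTS.get(name, name[0])
        atoms[name] = AtomRecord(name, element, np.asarray(xyz, float))
    return Residue(imgt, icode, aa, atoms)


def imgt_loop_numbers(lo: int, hi: int, length: int) -> list[int]:
    """IMGT numbers for a loop of given length within [lo, hi].

    Positions are taken from both ends toward the middle, leaving the
    gap at the loop centre as in the IMGT delimitation of shorter
    loops.
    """
    capacity = hi - lo + 1
    if not 1 <= length <= capacity:
        raise SpecError(f"loop length {length} outside 1..{capacity}")
    head = (length + 1) // 2
    tail = length - head
    return list(range(lo, lo + head)) + list(range(hi - tail + 1, hi + 1))


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


def _chain_phi_psi(rng: np.random.Generator, n: int, is_loop: np.ndarray) -> list:
    """Beta-strand-like framework torsions, coil-like loop torsions."""
    out = []
    coil_bins = [(-60.0, -40.0), (-80.0, 150.0), (60.0, 40.0), (-120.0, 120.0)]
    for i in range(n):
        if is_loop[i]:
            phi0, psi0 = coil_bins[int(rng.integers(len(coil_bins)))]
            out.append((phi0 + rng.normal(0, 8), psi0 + rng.normal(0, 8)))
        else:
            out.append((-120.0 + rng.normal(0, 5), 130.0 + rng.normal(0, 5)))
    return out


# ---------------------------------------------------------------------------
# Toy TCR
# ---------------------------------------------------------------------------

DEFAULT_LOOP_LENGTHS = {
    "alpha": {"CDR1": 6, "CDR2": 6, "CDR3": 11},
    "beta": {"CDR1": 5, "CDR2": 6, "CDR3": 12},
}


def _build_tcr_chain(
    rng: np.random.Generator,
    chain_id: str,
    lengths: dict[str, int],
    config: RegionConfig,
    offset: np.ndarray,
) -> NumberedChain:
    numbers: list[int] = []
    ranges = {"CDR1": config.cdr1, "CDR2": config.cdr2, "CDR3": config.cdr3}
    cdr_numbers = {
        name: set(imgt_loop_numbers(*ranges[name], lengths[name])) for name in ranges
    }
    lo, hi = config.variable_domain
    all_cdr_pos = set().union(*cdr_numbers.values())
    for num in range(lo, hi + 1):
        if config.cdr_of(num) is None or num in all_cdr_pos:
            numbers.append(num)
    is_loop = np.array([config.cdr_of(n) is not None for n in numbers])
    torsions = _chain_phi_psi(rng, len(numbers), is_loop)
    coords = build_backbone(torsions)
    seq = _random_sequence(rng, len(numbers))
    residues = [
        _make_residue(num, seq[i], {k: v + offset for k, v in coords[i].items()})
        for i, num in enumerate(numbers)
    ]
    return NumberedChain(chain_id, f"tcr_{'alpha' if chain_id == 'A' else 'beta'}",
                         residues)


def make_toy_tcr(
    seed: int,
    loop_lengths: dict[str, dict[str, int]] | None = None,
    config: RegionConfig = DEFAULT_REGIONS,
    structure_id: str | None = None,
    resolution: float = 2.0,
) -> StructureRecord:
    """A deterministic idealized apo TCR (alpha chain A, beta chain B)."""
    lengths = loop_lengths or DEFAULT_LOOP_LENGTHS
    rng = np.random.default_rng(seed)
    alpha = _build_tcr_chain(rng, "A", lengths["alpha"], config, np.zeros(3))
    beta = _build_tcr_chain(rng, "B", lengths["beta"], config, np.array([40.0, 0.0, 0.0]))
    record = StructureRecord(
        structure_id=structure_id or f"toy_tcr_{seed}",
        state="apo_tcr",
        chains=[alpha, beta],
        resolution=resolution,
    )
    return assign_all_regions(record, config)


# ---------------------------------------------------------------------------
# Toy pMHC
# ---------------------------------------------------------------------------

#: peptide geometry parameters (Å)
#: toy peptide spacing is widened well beyond the 3.8 Å of a real extended
#: chain so per-position contact assignments stay unambiguous at a 5 Å cutoff
_PEPTIDE_SPACING = 7.0
_PEPTIDE_BASE_Z = 6.8
_ANCHOR_DIP = 3.0
_ANCHOR_FLOOR_CUTOFF = 4.5

_AXIS_ROT = {
    "x": np.eye(3),
    "y": np.array([[0.0, -1.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 1.0]]),
    "z": np.array([[0.0, 0.0, -1.0], [0.0, 1.0, 0.0], [1.0, 0.0, 0.0]]),
}


def _residue_template(axis: str = "y") -> dict[str, np.ndarray]:
    """A single-residue backbone template centered at the origin.

    ``axis`` orients the N->C direction (long axis) of the residue.
    """
    coords = build_backbone([(-120.0, 130.0)])[0]
    center = np.mean([coords[a] for a in ("N", "CA", "C", "O")], axis=0)
    rot = _AXIS_ROT[axis]
    return {k: rot @ (v - center) for k, v in coords.items()}


def _placed_residue(imgt: int, aa: str, center: np.ndarray,
                    template: dict[str, np.ndarray] | None = None) -> Residue:
    tpl = template if template is not None else _residue_template()
    return _make_residue(imgt, aa, {k: v + center for k, v in tpl.items()})


def _principal_axis_to_x(points: np.ndarray) -> np.ndarray:
    """Rotation taking the principal axis of a point cloud onto +x."""
    centered = points - points.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    axis = vt[0]
    if axis[0] < 0:
        axis = -axis
    v = np.cross(axis, np.array([1.0, 0.0, 0.0]))
    s = np.linalg.norm(v)
    c = float(axis @ np.array([1.0, 0.0, 0.0]))
    if s < 1e-12:
        return np.eye(3)
    K = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + K + K @ K * ((1 - c) / s**2)


def _build_floor_and_helices(rng: np.random.Generator, config: RegionConfig):
    """MHC heavy chain: beta-sheet floor at z=0, helices flanking the groove."""
    residues: list[Residue] = []
    floor_positions = list(config.groove_floor)
    per_row = 13
    seq = _random_sequence(rng, 200)
    for idx, num in enumerate(floor_positions):
        row, col = divmod(idx, per_row)
        center = np.array([4.5 * col, -16.0 + 4.8 * row, 0.0])
        residues.append(_placed_residue(num, seq[num % len(seq)], center))
    for (lo, hi), y in ((config.alpha1_helix, -14.0), (config.alpha2_helix, 14.0)):
        span = hi - lo + 1
        torsions = [(-57.0, -47.0)] * span
        coords = build_backbone(torsions)
        cas = np.array([c["CA"] for c in coords])
        rot = _principal_axis_to_x(cas)
        centroid = cas.mean(axis=0)
        offset = np.array([26.0, y, 6.0])
        for i, num in enumerate(range(lo, hi + 1)):
            shifted = {k: rot @ (v - centroid) + offset for k, v in coords[i].items()}
            residues.append(_make_residue(num, seq[num % len(seq)], shifted))
    return NumberedChain("M", "mhc_heavy", residues)


def peptide_position_x(pos: int) -> float:
    """Groove-frame x coordinate of peptide position p (1-based)."""
    return _PEPTIDE_SPACING * (pos - 1)


def _build_peptide(
    sequence: str, anchor_positions: set[int]
) -> NumberedChain:
    template = _residue_template(axis="y")
    residues = []
    for pos, aa in enumerate(sequence, start=1):
        z = _PEPTIDE_BASE_Z - (_ANCHOR_DIP if pos in anchor_positions else 0.0)
        center = np.array([peptide_position_x(pos), 0.0, z])
        residues.append(_placed_residue(pos, aa, center, template))
    return NumberedChain("P", "peptide", residues)


def make_toy_pmhc(
    seed: int,
    peptide_length: int = 9,
    anchor_mode: str = "P2_P9",
    allele: str | None = None,
    peptide_sequence: str | None = None,
    config: RegionConfig = DEFAULT_REGIONS,
    structure_id: str | None = None,
    resolution: float = 2.0,
) -> StructureRecord:
    """A deterministic idealized apo pMHC-I (heavy chain M, peptide P).

    Anchor residues (p2 and the C-terminus, plus the middle position for
    ``anchor_mode="P2_P5_P9"``) are dipped toward the groove floor so
    they sit within 4.5 Å of floor atoms; other residues ride higher.
    """
    if peptide_length < 8:
        raise SpecError("peptide_length must be >= 8")
    rng = np.random.default_rng(seed)
    mhc = _build_floor_and_helices(rng, config)
    middle = 5 if peptide_length == 9 else -(-peptide_length // 2)
    anchors = {2, peptide_length}
    if anchor_mode == "P2_P5_P9":
        anchors.add(middle)
    elif anchor_mode != "P2_P9":
        raise SpecError(f"unknown anchor_mode {anchor_mode!r}")
    sequence = peptide_sequence or _random_sequence(rng, peptide_length)
    peptide = _build_peptide(sequence, anchors)
    record = StructureRecord(
        structure_id=structure_id or f"toy_pmhc_{seed}",
        state="apo_pmhc",
        chains=[mhc, peptide],
        resolution=resolution,
        allele=allele or f"TOY-{anchor_mode}",
    )
    return assign_all_regions(record, config)


# ---------------------------------------------------------------------------
# Toy holo complex
# ---------------------------------------------------------------------------

#: hover height of pinned CDR residues above their peptide target (Å)
_LOOP_HOVER = 4.6
#: hover height above helix targets
_HELIX_HOVER = 4.0
#: extra residues beyond the target count stack upward by this much
_STACK_RISE = np.array([0.0, 0.0, 1.0])


def _pin_loop_over_targets(
    chain: NumberedChain,
    region: str,
    targets: list[np.ndarray],
) -> None:
    """Re-place a CDR loop's residues over target points (in place).

    Residues are assigned round-robin to the targets, oriented
    vertically (long axis z) and stacked upward when a target hosts
    several residues, giving guaranteed sub-cutoff contacts to the
    intended positions only.
    """
    template = _residue_template(axis="z")
    rmap = chain.residue_map()
    keys = chain.regions[region]
    for i, key in enumerate(keys):
        res = rmap[key]
        center = targets[i % len(targets)] + _STACK_RISE * (i // len(targets))
        for name in list(res.atoms):
            res.atoms[name] = AtomRecord(
                name, res.atoms[name].element, template.get(name, np.zeros(3)) + center
            )


def make_toy_complex(
    seed: int,
    peptide_length: int = 9,
    anchor_mode: str = "P2_P9",
    loop_lengths: dict[str, dict[str, int]] | None = None,
    allele: str | None = None,
    peptide_sequence: str | None = None,
    config: RegionConfig = DEFAULT_REGIONS,
    structure_id: str | None = None,
    resolution: float = 2.0,
) -> StructureRecord:
    """A holo TCR:pMHC-I complex with a controlled contact geometry.

    The TCR body floats above the groove; CDR loop residues are pinned
    over their engagement targets: CDR3a over the first peptide half,
    CDR3b over the second half, CDR1a/CDR2a over the alpha2 helix and
    CDR1b/CDR2b over the alpha1 helix.  Pinning breaks the loops'
    backbone continuity (loop torsions are undefined) but gives exact,
    margin-safe contact patterns for fingerprinting.
    """
    pmhc = make_toy_pmhc(seed, peptide_length, anchor_mode, allele,
                         peptide_sequence, config, resolution=resolution)
    tcr = make_toy_tcr(seed + 10_000, loop_lengths, config, resolution=resolution)
    # float the TCR body high above the groove
    tcr = tcr.transformed(np.eye(3), np.array([0.0, 0.0, 60.0]))

    peptide = pmhc.chain("peptide")
    pep_xyz = {r.imgt_number: np.mean([a.coords for a in r.atoms.values()], axis=0)
               for r in peptide.residues}
    n_pep = len(pep_xyz)
    mid = -(-n_pep // 2)

    def hover(p: int) -> np.ndarray:
        c = pep_xyz[p].copy()
        # clamp above the non-anchor peptide plane so residues hovering a
        # dipped anchor stay out of contact range of its neighbours
        c[2] = max(c[2] + _LOOP_HOVER, _PEPTIDE_BASE_Z + 3.4)
        return c

    first = [hover(p) for p in range(1, mid + 1)]
    second = [hover(p) for p in range(mid + 1, n_pep + 1)]

    mhc = pmhc.chain("mhc_heavy")
    mmap = mhc.residue_map()

    def helix_targets(region: str, picks: list[int]) -> list[np.ndarray]:
        keys = [k for k in mhc.regions[region]]
        out = []
        for i in picks:
            res = mmap[keys[i]]
            center = np.mean([a.coords for a in res.atoms.values()], axis=0)
            out.append(center + np.array([0.0, 0.0, _HELIX_HOVER]))
        return out

    alpha = next(c for c in tcr.chains if c.role == "tcr_alpha")
    beta = next(c for c in tcr.chains if c.role == "tcr_beta")
    _pin_loop_over_targets(alpha, "CDR3", first)
    _pin_loop_over_targets(beta, "CDR3", second)
    _pin_loop_over_targets(alpha, "CDR1", helix_targets("alpha2_helix", [4, 8, 12]))
    _pin_loop_over_targets(alpha, "CDR2", helix_targets("alpha2_helix", [18, 22, 26]))
    _pin_loop_over_targets(beta, "CDR1", helix_targets("alpha1_helix", [4, 8, 12]))
    _pin_loop_over_targets(beta, "CDR2", helix_targets("alpha1_helix", [18, 22, 26]))

    record = StructureRecord(
        structure_id=structure_id or f"toy_complex_{seed}",
        state="holo_complex",
        chains=[alpha, beta, mhc, peptide],
        resolution=resolution,
        allele=pmhc.allele,
    )
    return assign_all_regions(record, config)


def extract_tcr(record: StructureRecord, structure_id: str) -> StructureRecord:
    """The TCR chains of a complex as an apo_tcr record (coordinates kept)."""
    chains = [c for c in record.chains if c.role in ("tcr_alpha", "tcr_beta")]
    out = StructureRecord(structure_id, "apo_tcr",
                          [NumberedChain(c.chain_id, c.role,
                                         [Residue(r.imgt_number, r.insertion_code, r.aa,
                                                  dict(r.atoms)) for r in c.residues],
                                         dict(c.regions)) for c in chains],
                          record.resolution)
    return out


def extract_pmhc(record: StructureRecord, structure_id: str) -> StructureRecord:
    """The MHC + peptide chains of a complex as an apo_pmhc record."""
    chains = [c for c in record.chains if c.role in ("mhc_heavy", "beta2m", "peptide")]
    return StructureRecord(structure_id, "apo_pmhc",
                           [NumberedChain(c.chain_id, c.role,
                                          [Residue(r.imgt_number, r.insertion_code, r.aa,
                                                   dict(r.atoms)) for r in c.residues],
                                          dict(c.regions)) for c in chains],
                           record.resolution, record.allele)


# ---------------------------------------------------------------------------
# Apo/holo pairs with planted ground truth
# ---------------------------------------------------------------------------

@dataclass
class PerturbationSpec:
    """A planted loop/peptide perturbation.

    ``loop_type`` is one of CDR1a..CDR3b or "peptide".  The rigid part
    translates the whole selection by ``rigid_displacement`` Å along a
    deterministic direction and rotates it by ``rigid_rotation_deg``
    about the axis through the loop ends.  The internal part displaces
    residues by ``internal_amplitude`` times a weight profile:
    ``uniform`` (all residues equally), ``midpeak`` (sine bump, maximal
    mid-loop, zero at the flanks) or ``anchored`` (zero at the given
    anchor positions, sine bumps between them — peptide use).
    """

    loop_type: str
    rigid_displacement: float = 0.0
    rigid_rotation_deg: float = 0.0
    internal_amplitude: float = 0.0
    profile: str = "midpeak"
    anchor_positions: frozenset[int] | None = None
    project_rigid_modes: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rigid_displacement < 0 or self.internal_amplitude < 0:
            raise SpecError("amplitudes must be >= 0")
        if self.profile not in ("uniform", "midpeak", "anchored"):
            raise SpecError(f"unknown profile {self.profile!r}")


@dataclass
class GroundTruth:
    """Exact expected metric values for one planted perturbation."""

    loop_type: str
    displacements: dict = dc_field(default_factory=dict)  # (chain, key, atom) -> vec
    expected_unsuperposed_rmsd: float = 0.0
    expected_superposed_rmsd: float | None = 0.0
    expected_per_residue: dict = dc_field(default_factory=dict)  # key -> Å
    rigid_rotation: np.ndarray | None = None
    rigid_translation: np.ndarray | None = None


def _loop_selection(record: StructureRecord, loop_type: str):
    if loop_type == "peptide":
        chain = record.chain("peptide")
        return chain, list(chain.residues)
    if loop_type not in LOOP_NAMES:
        raise SpecError(f"unknown loop_type {loop_type!r}")
    role = "tcr_alpha" if loop_type.endswith("a") else "tcr_beta"
    region = loop_type[:-1]
    try:
        chain = record.chain(role)
    except KeyError as exc:
        raise SpecError(str(exc)) from exc
    residues = chain.region_residues(region)
    if not residues:
        raise SpecError(f"{record.structure_id}: empty region {region} on {role}")
    return chain, residues


def _profile_weights(spec: PerturbationSpec, residues: list[Residue]) -> np.ndarray:
    n = len(residues)
    if spec.profile == "uniform":
        return np.ones(n)
    if spec.profile == "midpeak":
        i = np.arange(1, n + 1)
        return np.sin(np.pi * i / (n + 1))
    anchors = sorted(spec.anchor_positions or ())
    if len(anchors) < 2:
        raise SpecError("anchored profile needs >= 2 anchor positions")
    w = np.zeros(n)
    for idx, res in enumerate(residues):
        p = res.imgt_number
        for a, b in itertools.pairwise(anchors):
            if a < p < b:
                w[idx] = np.sin(np.pi * (p - a) / (b - a))
    return w


def _project_out_rigid_modes(
    positions: np.ndarray, displacements: np.ndarray,
    fit_mask: np.ndarray,
) -> np.ndarray:
    """Remove the least-squares rigid component a + omega x p of the field.

    The fit is over the rows selected by ``fit_mask`` (the backbone
    atoms that later RMSD fits use); the correction applies to all
    rows.  The returned field has zero net translation and zero net
    moment over the fitted atoms, which makes the identity the optimal
    rigid superposition for small amplitudes.
    """
    P = positions[fit_mask]
    D = displacements[fit_mask]
    n = len(P)
    A = np.zeros((3 * n, 6))
    for k, p in enumerate(P):
        A[3 * k: 3 * k + 3, :3] = np.eye(3)
        A[3 * k: 3 * k + 3, 3:] = -np.array([
            [0, -p[2], p[1]],
            [p[2], 0, -p[0]],
            [-p[1], p[0], 0],
        ])
    x, *_ = np.linalg.lstsq(A, D.reshape(-1), rcond=None)
    a, omega = x[:3], x[3:]
    rigid = a + np.cross(omega, positions)
    return displacements - rigid


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    theta = np.deg2rad(angle_deg)
    K = np.array([
        [0, -axis[2], axis[1]],
        [axis[2], 0, -axis[0]],
        [-axis[1], axis[0], 0],
    ])
    return np.eye(3) + np.sin(theta) * K + (1 - np.cos(theta)) * (K @ K)


def make_apo_holo_pair(
    base: StructureRecord, spec: PerturbationSpec
) -> tuple[StructureRecord, StructureRecord, GroundTruth]:
    """(apo, holo, ground truth): holo is ``base``, apo carries the motion.

    Only the selected loop (or the peptide) moves; flanking residues
    and all other chains are untouched, so framework / groove-floor
    alignment between apo and holo is exact.  Expected RMSDs follow
    from per-atom displacement bookkeeping: a pure translation of
    magnitude t gives unsuperposed backbone RMSD exactly t and
    superposed RMSD 0; a rigid-mode-projected internal field d gives
    superposed RMSD exactly sqrt(sum |d_i|^2 / n) over backbone atoms.
    """
    rng = np.random.default_rng(spec.seed)
    apo = base.transformed(np.eye(3), np.zeros(3))  # deep copy
    apo.structure_id = f"{base.structure_id}_apo"
    chain, residues = _loop_selection(apo, spec.loop_type)

    atom_index: list[tuple] = []   # (residue position in list, atom name)
    positions = []
    for ri, res in enumerate(residues):
        for name, atom in res.atoms.items():
            atom_index.append((ri, res.key, name))
            positions.append(atom.coords)
    positions = np.asarray(positions)
    backbone_mask = np.array([name in ("N", "CA", "C", "O") for _, _, name in atom_index])

    # --- internal deformation -------------------------------------------
    weights = _profile_weights(spec, residues)
    direction = rng.normal(size=3)
    direction /= np.linalg.norm(direction)
    # with projection on, alternate the sign per residue: the raw field is
    # then nearly orthogonal to the rigid modes already, so projecting them
    # out barely disturbs the planted weight profile
    signs = np.array([(-1.0) ** ri if spec.project_rigid_modes else 1.0
                      for ri, _, _ in atom_index])
    internal = (spec.internal_amplitude * weights[[ri for ri, _, _ in atom_index]]
                * signs)[:, None] * direction
    if spec.internal_amplitude > 0 and spec.project_rigid_modes:
        internal = _project_out_rigid_modes(positions, internal, backbone_mask)
    deformed = positions + internal

    # --- rigid motion ----------------------------------------------------
    R = np.eye(3)
    t = np.zeros(3)
    if spec.rigid_rotation_deg != 0.0:
        first_bb = residues[0].backbone_coords().mean(axis=0)
        last_bb = residues[-1].backbone_coords().mean(axis=0)
        axis = last_bb - first_bb
        pivot = 0.5 * (first_bb + last_bb)
        R = _rotation_about_axis(axis, spec.rigid_rotation_deg)
        t = pivot - R @ pivot
    if spec.rigid_displacement > 0:
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        t = t + spec.rigid_displacement * u
    final = deformed @ R.T + t

    # write back
    rmap = chain.residue_map()
    for (ri, key, name), xyz in zip(atom_index, final):
        res = rmap[key]
        res.atoms[name] = AtomRecord(name, res.atoms[name].element, xyz)

    # --- bookkeeping -----------------------------------------------------
    total = final - positions
    gt = GroundTruth(loop_type=spec.loop_type)
    gt.rigid_rotation = R
    gt.rigid_translation = t
    for (ri, key, name), d in zip(atom_index, total):
        gt.displacements[(chain.chain_id, key, name)] = d
    bb_total = total[backbone_mask]
    gt.expected_unsuperposed_rmsd = float(np.sqrt(np.mean(np.sum(bb_total ** 2, axis=1))))
    bb_internal = internal[backbone_mask]
    if spec.internal_amplitude == 0:
        gt.expected_superposed_rmsd = 0.0
    elif spec.project_rigid_modes:
        gt.expected_superposed_rmsd = float(
            np.sqrt(np.mean(np.sum(bb_internal ** 2, axis=1)))
        )
    else:
        gt.expected_superposed_rmsd = None  # field not orthogonal to rigid modes
    for ri, res in enumerate(residues):
        rows = [k for k, (rj, _, _) in enumerate(atom_index) if rj == ri]
        gt.expected_per_residue[res.key] = float(
            np.sqrt(np.mean(np.sum(internal[rows] ** 2, axis=1)))
        )
    return apo, base, gt


# ---------------------------------------------------------------------------
# Loop families for clustering
# ---------------------------------------------------------------------------

def make_loop_families(
    k: int,
    m: int,
    intra_sigma: float,
    inter_sep: float,
    unique_seqs: int | list[int] = 5,
    seed: int = 0,
    loop_type: str = "CDR3a",
    loop_length: int = 9,
) -> list[LoopConformation]:
    """``k`` planted loop families of ``m`` members each.

    All loops share identical anchor frames, so anchor superposition is
    the identity and family templates separated by ``inter_sep`` in
    space are separated by about ``inter_sep`` in DTW distance; members
    scatter around their template with Gaussian backbone noise of scale
    ``intra_sigma``.  ``unique_seqs`` (int or per-family list) controls
    how many distinct sequences a family holds, steering its
    canonical (> 2) or pseudo (<= 2) label.
    """
    if k == 0:
        return []
    rng = np.random.default_rng(seed)
    uniques = [unique_seqs] * k if isinstance(unique_seqs, int) else list(unique_seqs)
    if len(uniques) != k:
        raise SpecError("unique_seqs list must have k entries")

    span = 10 + loop_length
    torsions = [(-120.0 + rng.normal(0, 5), 130.0 + rng.normal(0, 5)) for _ in range(span)]
    coords = build_backbone(torsions, include_cb=False)
    stack = np.array([[c[a] for a in ("N", "CA", "C", "O")] for c in coords])
    anchors_n = stack[:5]
    anchors_c = stack[5 + loop_length:]
    base_loop = stack[5:5 + loop_length]

    out: list[LoopConformation] = []
    for fam in range(k):
        template = base_loop + np.array([0.0, 0.0, inter_sep * fam])
        seqs = [_random_sequence(rng, loop_length) for _ in range(max(1, uniques[fam]))]
        for member in range(m):
            noise = rng.normal(0, intra_sigma, size=template.shape)
            out.append(
                LoopConformation(
                    loop_id=f"fam{fam}_m{member}",
                    loop_type=loop_type,
                    sequence=seqs[member % len(seqs)],
                    backbone=template + noise,
                    anchors_n=anchors_n.copy(),
                    anchors_c=anchors_c.copy(),
                )
            )
    return out


# ---------------------------------------------------------------------------
# Motif tables and background repertoires
# ---------------------------------------------------------------------------

def make_motif_table(
    anchors: dict[int, tuple[str, float]],
    peptide_length: int = 9,
    allele: str = "TOY-A*01:01",
) -> MotifProfile:
    """A motif profile with planted per-position dominance.

    ``anchors`` maps position -> (amino acid, proportion); the
    remaining probability mass at that position is spread uniformly
    over the other 19 amino acids.  Unlisted positions are uniform.
    """
    proportions: dict[int, dict[str, float]] = {}
    for pos in range(1, peptide_length + 1):
        if pos in anchors:
            aa, p = anchors[pos]
            if not 0 <= p <= 1:
                raise SpecError(f"proportion {p} at p{pos} outside [0, 1]")
            rest = (1.0 - p) / (len(AMINO_ACIDS) - 1)
            proportions[pos] = {x: (p if x == aa else rest) for x in AMINO_ACIDS}
        else:
            proportions[pos] = {x: 1.0 / len(AMINO_ACIDS) for x in AMINO_ACIDS}
    profile = MotifProfile(allele, peptide_length, proportions)
    profile.validate()
    return profile


DEFAULT_V_GENES = {
    "TRAV": {f"TRAV{i}": 1 / 12 for i in range(1, 13)},
    "TRBV": {f"TRBV{i}": 1 / 12 for i in range(1, 13)},
    "TRAJ": {f"TRAJ{i}": 1 / 8 for i in range(1, 9)},
    "TRBJ": {f"TRBJ{i}": 1 / 8 for i in range(1, 9)},
}

DEFAULT_CDR_LENGTHS = {
    "cdr1_alpha": {5: 0.2, 6: 0.6, 7: 0.2},
    "cdr2_alpha": {5: 0.2, 6: 0.5, 7: 0.3},
    "cdr3_alpha": {9: 0.15, 10: 0.2, 11: 0.3, 12: 0.2, 13: 0.15},
    "cdr1_beta": {5: 0.6, 6: 0.4},
    "cdr2_beta": {6: 0.7, 7: 0.3},
    "cdr3_beta": {10: 0.15, 11: 0.25, 12: 0.3, 13: 0.2, 14: 0.1},
}


def make_background_repertoire(
    n: int,
    gene_freqs: dict[str, dict[str, float]] | None = None,
    cdr_length_dist: dict[str, dict[int, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """``n`` unique synthetic TCR rows with sampled gene calls and CDRs.

    Gene frequencies must sum to 1 per gene family; CDR sequences are
    drawn with lengths from ``cdr_length_dist``.  Row uniqueness is
    guaranteed (long random CDR3s; duplicates redrawn).
    """
    genes = gene_freqs or DEFAULT_V_GENES
    lengths = cdr_length_dist or DEFAULT_CDR_LENGTHS
    for fam, freqs in genes.items():
        total = sum(freqs.values())
        if abs(total - 1.0) > 1e-9:
            raise SpecError(f"{fam} frequencies sum to {total}, not 1")
    rng = np.random.default_rng(seed)
    rows = []
    seen: set[tuple] = set()
    while len(rows) < n:
        row = {}
        for fam, freqs in genes.items():
            names = sorted(freqs)
            row[fam] = str(rng.choice(names, p=[freqs[g] for g in names]))
        # allele-style suffix exercises gene-level harmonization downstream
        row["TRAV"] += "*01"
        row["TRBV"] += "*01"
        for loop, ldist in lengths.items():
            ls = sorted(ldist)
            length = int(rng.choice(ls, p=[ldist[l] for l in ls]))
            row[loop] = _random_sequence(rng, length)
        key = tuple(row.values())
        if key in seen:
            continue
        seen.add(key)
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full study dataset
# ---------------------------------------------------------------------------

@dataclass
class StudyDataset:
    """A complete synthetic study: records, planted truths, side tables."""

    records: list[StructureRecord]
    ground_truths: dict[str, GroundTruth]          # apo structure_id -> truth
    motifs: list[MotifProfile]
    repertoire: pd.DataFrame
    dataset_genes: dict[str, list[str]]            # gene family -> per-entity calls
    meta: dict[str, dict] = dc_field(default_factory=dict)


def make_study_dataset(
    seed: int,
    n_entities: int = 6,
    peptide_length: int = 9,
    repertoire_size: int = 4000,
) -> StudyDataset:
    """The default end-to-end fixture set.

    ``n_entities`` TCR:pMHC systems, each contributing one holo complex,
    one perturbed apo TCR and one perturbed apo pMHC; the first two
    entities carry a second apo TCR so apo:apo comparisons exist.
    Even-indexed entities use P2_P9 peptides with a mid-peptide bulge
    between the anchors; odd-indexed use P2_P5_P9 with movement
    suppressed at the middle anchor.  TCR CDR3 loops alternate between
    flexible-scale (> 1 Å) and rigid-scale (< 0.5 Å) planted motions.
    """
    rng = np.random.default_rng(seed)
    records: list[StructureRecord] = []
    truths: dict[str, GroundTruth] = {}
    meta: dict[str, dict] = {}
    motif_anchor_specs: dict[str, dict[int, tuple[str, float]]] = {}
    middle = 5 if peptide_length == 9 else -(-peptide_length // 2)

    for i in range(n_entities):
        mode = "P2_P9" if i % 2 == 0 else "P2_P5_P9"
        allele = f"TOY-{mode}-{i:02d}"
        sub = int(rng.integers(2**31 - 10_000))
        complex_record = make_toy_complex(
            sub, peptide_length, mode, allele=allele,
            structure_id=f"complex_{i:02d}",
        )
        records.append(complex_record)
        meta[complex_record.structure_id] = {"entity": i, "anchor_mode": mode}

        # apo TCR: planted CDR3a motion, flexible for even entities
        apo_base = extract_tcr(complex_record, f"tcr_{i:02d}")
        delta = 1.8 if i % 2 == 0 else 0.3
        spec = PerturbationSpec("CDR3a", rigid_displacement=delta,
                                internal_amplitude=0.4, profile="midpeak",
                                seed=sub + 1)
        apo, _, gt = make_apo_holo_pair(apo_base, spec)
        apo.structure_id = f"tcr_{i:02d}_apo0"
        records.append(apo)
        truths[apo.structure_id] = gt
        if i < 2:  # a second apo crystal of the same TCR, same motion class
            spec2 = PerturbationSpec("CDR3a", rigid_displacement=0.8 * delta,
                                     internal_amplitude=0.2, profile="midpeak",
                                     seed=sub + 2)
            apo2, _, gt2 = make_apo_holo_pair(apo_base, spec2)
            apo2.structure_id = f"tcr_{i:02d}_apo1"
            records.append(apo2)
            truths[apo2.structure_id] = gt2
        if i < 3:  # a second holo crystal: small CDR3a variation of the complex
            spec3 = PerturbationSpec("CDR3a", rigid_displacement=0.15,
                                     internal_amplitude=0.05, profile="midpeak",
                                     seed=sub + 4)
            holo2, _, _ = make_apo_holo_pair(complex_record, spec3)
            holo2.structure_id = f"complex_{i:02d}b"
            records.append(holo2)
            meta[holo2.structure_id] = {"entity": i, "anchor_mode": mode}

        # apo pMHC: anchored peptide movement field
        pep_anchors = frozenset({2, peptide_length} | ({middle} if mode == "P2_P5_P9" else set()))
        pmhc_base = extract_pmhc(complex_record, f"pmhc_{i:02d}")
        pspec = PerturbationSpec("peptide", internal_amplitude=1.5, profile="anchored",
                                 anchor_positions=pep_anchors,
                                 project_rigid_modes=False, seed=sub + 3)
        apo_pmhc, _, pgt = make_apo_holo_pair(pmhc_base, pspec)
        apo_pmhc.structure_id = f"pmhc_{i:02d}_apo0"
        records.append(apo_pmhc)
        truths[apo_pmhc.structure_id] = pgt

        # a motif that marks exactly the planted anchors as dominant
        peptide_seq = complex_record.chain("peptide").sequence()
        motif_anchor_specs[allele] = {
            p: (peptide_seq[p - 1], 0.75) for p in sorted(pep_anchors)
        }

    motifs = [
        make_motif_table(spec_map, peptide_length, allele)
        for allele, spec_map in sorted(motif_anchor_specs.items())
    ]
    repertoire = make_background_repertoire(repertoire_size, seed=seed + 77)
    # dataset gene calls drawn from the same background distribution
    dataset_genes = {}
    for fam, freqs in DEFAULT_V_GENES.items():
        names = sorted(freqs)
        p = [freqs[g] for g in names]
        dataset_genes[fam] = [str(rng.choice(names, p=p)) for _ in range(n_entities)]
    return StudyDataset(records, truths, motifs, repertoire, dataset_genes, meta)
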