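"""Rigid-body superposition and conformational-difference metrics.

Implements least-squares (Kabsch) fitting on named atom selections, the
framework / groove-floor alignment conventions used to compare apo and
holo states, backbone and per-residue heavy-atom RMSD, and the
dihedral-space D-score

    D(A, B) = sum_i [ 2(1 - cos(phi_i^A - phi_i^B))
                    + 2(1 - cos(psi_i^A - psi_i^B)) ]

Residue correspondence between structures is always by IMGT
(number, insertion code); unmatched residues are excluded, never
imputed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .structure_io import (
    BACKBONE_ATOMS,
    NumberedChain,
    RegionConfig,
    Residue,
    StructureRecord,
    DEFAULT_REGIONS,
)

__all__ = [
    "Transform",
    "SuperpositionResult",
    "DihedralSeries",
    "MovementRecord",
    "kabsch_fit",
    "align_tcr_framework",
    "align_mhc_floor",
    "backbone_rmsd",
    "per_residue_heavy_rmsd",
    "compute_dihedrals",
    "dscore",
    "rmsd",
    "DegeneracyError",
    "EmptySelectionError",
    "AlignmentError",
]

LOOP_NAMES = ("CDR1a", "CDR2a", "CDR3a", "CDR1b", "CDR2b", "CDR3b")

#: C-N distance above which consecutive residues are treated as a chain break
CHAIN_BREAK_CN = 2.5

_DEGENERACY_TOL = 1e-10


class DegeneracyError(ValueError):
    """Point sets too degenerate (collinear / coincident) for a unique fit."""


class EmptySelectionError(ValueError):
    """An RMSD/D-score selection matched no atoms or angles."""


class AlignmentError(ValueError):
    """Too few shared residues to define the alignment frame."""


@dataclass(frozen=True)
class Transform:
    """Proper rigid motion ``x -> R x + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        t = np.asarray(self.translation, float)
        if R.shape != (3, 3) or t.shape != (3,):
            raise ValueError("rotation must be 3x3 and translation a 3-vector")
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or np.linalg.det(R) < 0:
            raise ValueError("rotation must be orthonormal with determinant +1")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation

    def inverse(self) -> "Transform":
        return Transform(self.rotation.T, -self.rotation.T @ self.translation)


@dataclass(frozen=True)
class SuperpositionResult:
    transform: Transform
    fit_rmsd: float
    n_atoms: int
    selection_name: str = ""


@dataclass
class DihedralSeries:
    """Per-residue backbone torsions in radians, NaN where undefined."""

    imgt_keys: list[tuple[int, str]]
    phi: np.ndarray
    psi: np.ndarray


@dataclass(frozen=True)
class MovementRecord:
    """One loop/region comparison between two structures of an entity."""

    entity_id: str
    loop_or_region: str
    comparison: str  # apo_apo | apo_holo | holo_holo
    metric: str  # backbone_rmsd | superposed_backbone_rmsd | dscore
    value: float
    n_atoms: int = 0


# ---------------------------------------------------------------------------
# Kabsch fitting
# ---------------------------------------------------------------------------

def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square deviation between corresponding coordinates."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.size == 0:
        raise EmptySelectionError("coordinate arrays must be nonempty and equal-shaped")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_fit(
    mobile: np.ndarray, target: np.ndarray, selection_name: str = ""
) -> SuperpositionResult:
    """Least-squares rigid fit of ``mobile`` onto ``target``.

    Correspondence is by array order.  The returned rotation is proper
    (reflections corrected via the sign of the smallest singular value).
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(target, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("mobile and target must be equal-shaped (n, 3) arrays")
    n = P.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for a rigid fit")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    spread = np.linalg.svd((P - pc), compute_uv=False)
    if spread[1] < _DEGENERACY_TOL:  # all points on a line or a point
        raise DegeneracyError("point set is collinear or coincident")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = qc - R @ pc
    transform = Transform(R, t)
    fitted = transform.apply(P)
    return SuperpositionResult(transform, rmsd(fitted, Q), n, selection_name)


# ---------------------------------------------------------------------------
# Residue correspondence helpers
# ---------------------------------------------------------------------------

def _matched_residues(
    a: Sequence[Residue], b: Sequence[Residue], require_backbone: bool = True
) -> list[tuple[Residue, Residue]]:
    bmap = {r.key: r for r in b}
    out = []
    for ra in a:
        rb = bmap.get(ra.key)
        if rb is None:
            continue
        if require_backbone and not (ra.is_complete_backbone and rb.is_complete_backbone):
            continue
        out.append((ra, rb))
    return out


def _backbone_stack(pairs: Iterable[tuple[Residue, Residue]]) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for ra, rb in pairs:
        xs.append(ra.backbone_coords())
        ys.append(rb.backbone_coords())
    if not xs:
        raise EmptySelectionError("no matched residues with complete backbone")
    return np.concatenate(xs), np.concatenate(ys)


def backbone_rmsd(
    a: Sequence[Residue], b: Sequence[Residue], superpose_first: bool = False
) -> float:
    """Backbone (N, CA, C, O) RMSD over IMGT-matched residues.

    With ``superpose_first`` the two selections are Kabsch-fitted on
    those same atoms before measuring, leaving only internal
    deformation (the loop-superposed mode); without it, the value also
    carries rigid-body movement relative to the shared frame.
    """
    pairs = _matched_residues(a, b)
    X, Y = _backbone_stack(pairs)
    if superpose_first:
        return kabsch_fit(X, Y).fit_rmsd
    return rmsd(X, Y)


def per_residue_heavy_rmsd(
    a: Sequence[Residue], b: Sequence[Residue]
) -> list[tuple[tuple[int, str], float]]:
    """Per-residue all-heavy-atom RMSD over IMGT-matched residues.

    Atom names are intersected per residue pair (side chains included);
    a pair sharing no atoms is recorded as absent rather than zero.
    Callers superpose the loops beforehand.
    """
    out = []
    for ra, rb in _matched_residues(a, b, require_backbone=False):
        shared = sorted(set(ra.atoms) & set(rb.atoms))
        if not shared:
            continue
        X = np.array([ra.atoms[n].coords for n in shared])
        Y = np.array([rb.atoms[n].coords for n in shared])
        out.append((ra.key, rmsd(X, Y)))
    return out


# ---------------------------------------------------------------------------
# Structure-level alignments
# ---------------------------------------------------------------------------

def _collect_region_backbone(
    record: StructureRecord, roles: Sequence[str], region: str
) -> dict[tuple[str, int, str], Residue]:
    out = {}
    for role in roles:
        for chain in record.chains_with_role(role):
            for res in chain.region_residues(region):
                if res.is_complete_backbone:
                    out[(role, *res.key)] = res
    return out


def _align_on(
    mobile: StructureRecord,
    target: StructureRecord,
    roles: Sequence[str],
    region: str,
    selection_name: str,
) -> tuple[StructureRecord, SuperpositionResult]:
    a = _collect_region_backbone(mobile, roles, region)
    b = _collect_region_backbone(target, roles, region)
    shared = sorted(set(a) & set(b))
    if len(shared) < 3:
        raise AlignmentError(
            f"only {len(shared)} shared {region} residues between "
            f"{mobile.structure_id} and {target.structure_id}"
        )
    X = np.concatenate([a[k].backbone_coords() for k in shared])
    Y = np.concatenate([b[k].backbone_coords() for k in shared])
    fit = kabsch_fit(X, Y, selection_name)
    moved = mobile.transformed(fit.transform.rotation, fit.transform.translation)
    return moved, fit


def align_tcr_framework(
    apo: StructureRecord, holo: StructureRecord
) -> tuple[StructureRecord, SuperpositionResult]:
    """Move ``apo`` onto ``holo`` fitted on pooled alpha+beta FR backbone."""
    return _align_on(apo, holo, ("tcr_alpha", "tcr_beta"), "FR", "tcr_framework")


def align_mhc_floor(
    apo: StructureRecord, holo: StructureRecord
) -> tuple[StructureRecord, SuperpositionResult]:
    """Move ``apo`` onto ``holo`` fitted on the MHC groove-floor backbone."""
    return _align_on(apo, holo, ("mhc_heavy",), "groove_floor", "mhc_groove_floor")


# ---------------------------------------------------------------------------
# Dihedrals and D-score
# ---------------------------------------------------------------------------

def _dihedral(p0: np.ndarray, p1: np.ndarray, p2: np.ndarray, p3: np.ndarray) -> float:
    """Signed torsion angle of four points in (-pi, pi], IUPAC convention."""
    b0 = p0 - p1
    b1 = p2 - p1
    b1 = b1 / np.linalg.norm(b1)
    b2 = p3 - p2
    v = b0 - (b0 @ b1) * b1
    w = b2 - (b2 @ b1) * b1
    x = v @ w
    y = np.cross(b1, v) @ w
    angle = float(np.arctan2(y, x))
    return np.pi if angle == -np.pi else angle


def compute_dihedrals(residues: Sequence[Residue]) -> DihedralSeries:
    """Backbone phi/psi torsions for a consecutive residue segment.

    phi_i = C(i-1)-N(i)-CA(i)-C(i); psi_i = N(i)-CA(i)-C(i)-N(i+1).
    Angles across a chain break (C-N distance > 2.5 Å) and at segment
    termini are NaN.
    """
    n = len(residues)
    phi = np.full(n, np.nan)
    psi = np.full(n, np.nan)
    ok = [r.is_complete_backbone for r in residues]

    def connected(i: int) -> bool:
        if not (ok[i] and ok[i + 1]):
            return False
        c = residues[i].atoms["C"].coords
        nn = residues[i + 1].atoms["N"].coords
        return float(np.linalg.norm(c - nn)) <= CHAIN_BREAK_CN

    for i in range(n):
        if not ok[i]:
            continue
        r = residues[i]
        if i > 0 and connected(i - 1):
            phi[i] = _dihedral(
                residues[i - 1].atoms["C"].coords,
                r.atoms["N"].coords,
                r.atoms["CA"].coords,
                r.atoms["C"].coords,
            )
        if i < n - 1 and connected(i):
            psi[i] = _dihedral(
                r.atoms["N"].coords,
                r.atoms["CA"].coords,
                r.atoms["C"].coords,
                residues[i + 1].atoms["N"].coords,
            )
    return DihedralSeries([r.key for r in residues], phi, psi)


def dscore(a: DihedralSeries, b: DihedralSeries, normalize: bool = False) -> float:
    """Dihedral difference score between two IMGT-matched segments.

    Sums ``2(1 - cos(d_phi)) + 2(1 - cos(d_psi))`` over residues;
    angle pairs with either side undefined are skipped, not imputed.
    ``normalize`` divides by the number of contributing angle pairs
    (the raw sum is the default).
    """
    amap = {k: i for i, k in enumerate(a.imgt_keys)}
    total = 0.0
    n_pairs = 0
    for j, key in enumerate(b.imgt_keys):
        i = amap.get(key)
        if i is None:
            continue
        for series_a, series_b in ((a.phi, b.phi), (a.psi, b.psi)):
            if np.isnan(series_a[i]) or np.isnan(series_b[j]):
                continue
            total += 2.0 * (1.0 - np.cos(series_a[i] - series_b[j]))
            n_pairs += 1
    if n_pairs == 0:
        raise EmptySelectionError("no shared defined dihedral pairs")
    return total / n_pairs if normalize else total


# ---------------------------------------------------------------------------
# Loop extraction convenience
# ---------------------------------------------------------------------------

def loop_residues(
    record: StructureRecord, loop: str, config: RegionConfig = DEFAULT_REGIONS
) -> list[Residue]:
    """Residues of one CDR loop named CDR{1,2,3}{a,b}."""
    if loop not in LOOP_NAMES:
        raise ValueError(f"unknown loop {loop!r}")
    role = "tcr_alpha" if loop.endswith("a") else "tcr_beta"
    region = loop[:-1]
    return record.chain(role).region_residues(region)
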