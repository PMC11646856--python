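"""Canonical clustering of CDR loop conformations.

Loops of one type (CDR1a ... CDR3b) are compared pairwise by first
superposing them on the backbone of the five anchor residues flanking
each side, then measuring a dynamic-time-warping (DTW) distance between
their backbones, which makes loops of different lengths comparable.
Density-based hierarchical clustering (HDBSCAN, minimum cluster size 5)
on the resulting distance matrix yields structural clusters; a cluster
with more than two unique loop sequences is a *canonical* cluster,
otherwise a *pseudo* cluster, and unassigned loops are *noise*.
Comparing the joint labels of the apo and holo conformation of the same
loop gives an 11-way cluster-shift taxonomy.

DTW conventions (the backbone distance itself admits choices): local
cost is the mean Euclidean distance over the four backbone atoms of a
matched residue pair; steps are the symmetric unit moves (diagonal,
horizontal, vertical) with both endpoints pinned; the accumulated cost
is divided by the warping-path length so the measure does not grow with
loop length.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import HDBSCAN

from .superposition import EmptySelectionError, kabsch_fit

__all__ = [
    "LoopConformation",
    "DistanceMatrix",
    "ClusterAssignment",
    "ShiftCategory",
    "anchor_superpose",
    "dtw_distance",
    "build_distance_matrix",
    "cluster_loops",
    "classify_shift",
    "AnchorError",
    "ProvenanceError",
]

N_ANCHOR_RESIDUES = 5


class AnchorError(ValueError):
    """A loop lacks the 5+5 complete-backbone anchor residues."""


class ProvenanceError(ValueError):
    """Cluster labels being compared come from different clustering runs."""


@dataclass
class LoopConformation:
    """One CDR loop: sequence, backbone coordinates and flanking anchors.

    ``backbone`` is (n_residues, 4, 3) over atoms N, CA, C, O ordered
    N-terminus to C-terminus; ``anchors_n`` / ``anchors_c`` are
    (5, 4, 3) arrays for the five flanking residues on each side.
    """

    loop_id: str
    loop_type: str
    sequence: str
    backbone: np.ndarray
    anchors_n: np.ndarray
    anchors_c: np.ndarray

    def __post_init__(self) -> None:
        self.backbone = np.asarray(self.backbone, float)
        self.anchors_n = np.asarray(self.anchors_n, float)
        self.anchors_c = np.asarray(self.anchors_c, float)
        if self.backbone.ndim != 3 or self.backbone.shape[1:] != (4, 3):
            raise ValueError("backbone must be (n, 4, 3)")
        for name, arr in (("anchors_n", self.anchors_n), ("anchors_c", self.anchors_c)):
            if arr.shape != (N_ANCHOR_RESIDUES, 4, 3):
                raise AnchorError(f"{self.loop_id}: {name} must be (5, 4, 3)")
        if len(self.sequence) != self.backbone.shape[0]:
            raise ValueError(f"{self.loop_id}: sequence length != backbone length")

    @property
    def n_residues(self) -> int:
        return int(self.backbone.shape[0])

    def anchor_atoms(self) -> np.ndarray:
        """The 40 anchor backbone atoms as a (40, 3) array."""
        return np.concatenate([self.anchors_n, self.anchors_c]).reshape(-1, 3)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "LoopConformation":
        def move(arr: np.ndarray) -> np.ndarray:
            return arr @ rotation.T + translation

        return LoopConformation(
            self.loop_id,
            self.loop_type,
            self.sequence,
            move(self.backbone),
            move(self.anchors_n),
            move(self.anchors_c),
        )


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        V = np.asarray(self.values, float)
        n = len(self.ids)
        if V.shape != (n, n):
            raise ValueError("matrix shape must match ids")
        if not np.allclose(V, V.T, atol=1e-9) or np.any(V < 0) or np.any(np.diag(V) != 0):
            raise ValueError("matrix must be symmetric, nonnegative, zero-diagonal")
        self.values = V


class LabelKind(str, enum.Enum):
    CANONICAL = "canonical"
    PSEUDO = "pseudo"
    NOISE = "noise"


@dataclass(frozen=True)
class ClusterAssignment:
    """Label of one loop: canonical(k), pseudo(k) or noise."""

    loop_id: str
    kind: LabelKind
    cluster: int | None = None  # None for noise
    run_id: str = ""

    def __str__(self) -> str:
        if self.kind is LabelKind.NOISE:
            return "noise"
        return f"{self.kind.value}({self.cluster})"


class ShiftCategory(str, enum.Enum):
    """The 11 apo-to-holo cluster-transition categories."""

    CANONICAL_TO_PSEUDO = "Canonical to Pseudo Cluster"
    CANONICAL_TO_NOISE = "Canonical Cluster to Noise"
    CANONICAL_SAME = "Canonical Cluster Same"
    CANONICAL_SHIFT = "Canonical Cluster Shift"
    NOISE = "Noise"
    NOISE_TO_CANONICAL = "Noise to Canonical Cluster"
    NOISE_TO_PSEUDO = "Noise to Pseudo Cluster"
    PSEUDO_TO_CANONICAL = "Pseudo to Canonical"
    PSEUDO_TO_NOISE = "Pseudo Cluster to Noise"
    PSEUDO_SAME = "Pseudo Cluster Same"
    PSEUDO_SHIFT = "Pseudo Cluster Shift"


# ---------------------------------------------------------------------------
# Anchor superposition and DTW
# ---------------------------------------------------------------------------

def anchor_superpose(a: LoopConformation, b: LoopConformation) -> LoopConformation:
    """Move loop ``a`` by the Kabsch fit of its 40 anchor atoms onto ``b``'s."""
    fit = kabsch_fit(a.anchor_atoms(), b.anchor_atoms(), "loop_anchors")
    return a.transformed(fit.transform.rotation, fit.transform.translation)


def _residue_cost_matrix(a: LoopConformation, b: LoopConformation) -> np.ndarray:
    """Pairwise local cost: mean distance over the four backbone atoms."""
    diff = a.backbone[:, None, :, :] - b.backbone[None, :, :, :]
    return np.linalg.norm(diff, axis=3).mean(axis=2)


def dtw_distance(
    a: LoopConformation, b: LoopConformation, superpose: bool = True
) -> float:
    """Length-normalized DTW distance between two loop backbones.

    ``a`` is anchor-superposed onto ``b`` first (disable with
    ``superpose=False`` when the caller already placed the loops in a
    common frame).  Over all boundary-pinned monotone warping paths the
    minimal accumulated cost is found; ties in cost resolve to the
    shortest path.  Returns accumulated cost / path length.
    """
    if a.n_residues == 0 or b.n_residues == 0:
        raise EmptySelectionError("empty loop")
    if superpose:
        a = anchor_superpose(a, b)
    cost = _residue_cost_matrix(a, b)
    n, m = cost.shape
    # DP over (accumulated cost, path length), lexicographic minimum
    acc = np.full((n, m), np.inf)
    plen = np.zeros((n, m), int)
    acc[0, 0] = cost[0, 0]
    plen[0, 0] = 1
    for i in range(n):
        for j in range(m):
            if i == 0 and j == 0:
                continue
            best = (np.inf, 0)
            for pi, pj in ((i - 1, j - 1), (i - 1, j), (i, j - 1)):
                if pi < 0 or pj < 0:
                    continue
                cand = (acc[pi, pj], plen[pi, pj])
                if cand < best:
                    best = cand
            acc[i, j] = best[0] + cost[i, j]
            plen[i, j] = best[1] + 1
    return float(acc[n - 1, m - 1] / plen[n - 1, m - 1])


def build_distance_matrix(loops: list[LoopConformation]) -> DistanceMatrix:
    """All-pairs anchor-superposed DTW distances for loops of one type."""
    ids = [lp.loop_id for lp in loops]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate loop_id")
    types = {lp.loop_type for lp in loops}
    if len(types) > 1:
        raise ValueError(f"loops of mixed types {types}")
    n = len(loops)
    V = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = dtw_distance(loops[i], loops[j])
            V[i, j] = V[j, i] = d
    return DistanceMatrix(ids, V)


# ---------------------------------------------------------------------------
# Clustering and labelling
# ---------------------------------------------------------------------------

def cluster_loops(
    matrix: DistanceMatrix,
    sequences: dict[str, str],
    min_cluster_size: int = 5,
    run_id: str = "run",
) -> list[ClusterAssignment]:
    """Density-based clustering of a precomputed loop distance matrix.

    Loops are ordered by loop_id before clustering so label extraction
    is deterministic.  Clusters with more than two unique sequences are
    canonical, others pseudo; unassigned loops are noise.  Fewer loops
    than ``min_cluster_size`` yields all-noise.
    """
    order = sorted(range(len(matrix.ids)), key=lambda i: matrix.ids[i])
    ids = [matrix.ids[i] for i in order]
    if len(ids) < min_cluster_size:
        labels = np.full(len(ids), -1)
    else:
        V = matrix.values[np.ix_(order, order)]
        model = HDBSCAN(min_cluster_size=min_cluster_size, metric="precomputed", copy=True)
        labels = model.fit_predict(V.copy())

    out = []
    for cluster in sorted(set(labels[labels >= 0])):
        members = [ids[i] for i in range(len(ids)) if labels[i] == cluster]
        unique_seqs = {sequences[m] for m in members}
        kind = LabelKind.CANONICAL if len(unique_seqs) > 2 else LabelKind.PSEUDO
        out.extend(
            ClusterAssignment(m, kind, int(cluster), run_id) for m in members
        )
    out.extend(
        ClusterAssignment(ids[i], LabelKind.NOISE, None, run_id)
        for i in range(len(ids))
        if labels[i] < 0
    )
    return sorted(out, key=lambda a: a.loop_id)


def classify_shift(apo: ClusterAssignment, holo: ClusterAssignment) -> ShiftCategory:
    """Classify the apo-to-holo label transition of one loop.

    Both labels must come from one joint clustering of the pooled apo
    and holo conformations, otherwise cluster indices are not
    comparable.
    """
    if apo.run_id != holo.run_id:
        raise ProvenanceError("labels come from different clustering runs")
    a, h = apo.kind, holo.kind
    if a is LabelKind.CANONICAL:
        if h is LabelKind.CANONICAL:
            return (
                ShiftCategory.CANONICAL_SAME
                if apo.cluster == holo.cluster
                else ShiftCategory.CANONICAL_SHIFT
            )
        if h is LabelKind.PSEUDO:
            return ShiftCategory.CANONICAL_TO_PSEUDO
        return ShiftCategory.CANONICAL_TO_NOISE
    if a is LabelKind.PSEUDO:
        if h is LabelKind.CANONICAL:
            return ShiftCategory.PSEUDO_TO_CANONICAL
        if h is LabelKind.PSEUDO:
            return (
                ShiftCategory.PSEUDO_SAME
                if apo.cluster == holo.cluster
                else ShiftCategory.PSEUDO_SHIFT
            )
        return ShiftCategory.PSEUDO_TO_NOISE
    # apo is noise
    if h is LabelKind.CANONICAL:
        return ShiftCategory.NOISE_TO_CANONICAL
    if h is LabelKind.PSEUDO:
        return ShiftCategory.NOISE_TO_PSEUDO
    return ShiftCategory.NOISE
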