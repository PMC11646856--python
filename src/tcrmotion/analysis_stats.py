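"""Statistical layer: entity normalization, comparison groups, testing.

Crystal structures are redundant — one TCR may appear in many apo
crystals and many complexes — so every raw metric is first averaged per
entity (a TCR identified by its six CDR sequences, or a pMHC by peptide
plus allele) before any test is run.  Comparison groups are built from
all same-entity structure pairs: apo:apo (crystallographic variability
of the unbound form), apo:holo (the binding-associated change) and
holo:holo (the bound-state baseline).  Group differences are assessed
with the Kruskal-Wallis test and post-hoc two-sided Wilcoxon rank-sum
tests at a Bonferroni-corrected level.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Hashable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .structure_io import ApoHoloPair, StructureRecord
from .superposition import (
    LOOP_NAMES,
    MovementRecord,
    align_mhc_floor,
    align_tcr_framework,
    backbone_rmsd,
    compute_dihedrals,
    dscore,
    loop_residues,
    per_residue_heavy_rmsd,
)
from .anchors import AnchorAnnotation, AnchorMode

__all__ = [
    "BindingMode",
    "EnrichmentResult",
    "normalize_by_entity",
    "build_comparison_groups",
    "enumerate_comparisons",
    "tcr_pair_metrics",
    "pmhc_pair_metrics",
    "kruskal_wallis",
    "posthoc_wilcoxon_bonferroni",
    "classify_binding_mode",
    "per_position_profile",
    "peptide_region_movement",
    "anchor_conditioned_peptide_profile",
    "sample_background",
    "gene_usage_enrichment",
    "frequency_table",
]

MOVEMENT_COLUMNS = ["entity_id", "loop_or_region", "comparison", "metric", "value", "n_atoms"]

#: binding-mode thresholds on apo:holo backbone RMSD, Å
RIGID_THRESHOLD = 0.5
FLEXIBLE_THRESHOLD = 1.0


@dataclass
class BindingMode:
    """Rigid / flexible / intermediate classification of one entity."""

    entity_id: str
    mode: str  # rigid | flexible | intermediate
    values: list[float]
    dual_mode: bool = False


@dataclass
class EnrichmentResult:
    """Dataset-vs-background frequency comparison for one gene/feature."""

    label: str
    dataset_frequency: float
    background_frequency: float
    percent_enrichment: float | None  # None when background frequency is 0


# ---------------------------------------------------------------------------
# Movement tables
# ---------------------------------------------------------------------------

def movement_frame(records: Iterable[MovementRecord]) -> pd.DataFrame:
    rows = [
        (r.entity_id, r.loop_or_region, r.comparison, r.metric, r.value, r.n_atoms)
        for r in records
    ]
    return pd.DataFrame(rows, columns=MOVEMENT_COLUMNS)


def normalize_by_entity(records: Iterable[MovementRecord] | pd.DataFrame) -> pd.DataFrame:
    """One value per (entity, loop, comparison, metric): the mean of the raws.

    Idempotent: normalizing an already-normalized table returns it
    unchanged.
    """
    df = records if isinstance(records, pd.DataFrame) else movement_frame(records)
    if df.empty:
        return df.copy()
    keys = ["entity_id", "loop_or_region", "comparison", "metric"]
    out = (
        df.groupby(keys, as_index=False, sort=True)
        .agg(value=("value", "mean"), n_atoms=("n_atoms", "max"))
    )
    return out[MOVEMENT_COLUMNS]


def enumerate_comparisons(
    apo: Sequence[StructureRecord], holo: Sequence[StructureRecord]
) -> list[tuple[str, StructureRecord, StructureRecord]]:
    """All same-entity structure pairs with their comparison group.

    apo:apo and holo:holo are unordered pairs (C(n,2) each); apo:holo is
    the full product (n_apo * n_holo).
    """
    out: list[tuple[str, StructureRecord, StructureRecord]] = []
    for a, b in itertools.combinations(sorted(apo, key=lambda r: r.structure_id), 2):
        out.append(("apo_apo", a, b))
    for a in sorted(apo, key=lambda r: r.structure_id):
        for h in sorted(holo, key=lambda r: r.structure_id):
            out.append(("apo_holo", a, h))
    for a, b in itertools.combinations(sorted(holo, key=lambda r: r.structure_id), 2):
        out.append(("holo_holo", a, b))
    return out


def _entity_state_sets(
    pairs: Sequence[ApoHoloPair],
) -> dict[str, tuple[list[StructureRecord], list[StructureRecord]]]:
    by_entity: dict[str, tuple[dict, dict]] = defaultdict(lambda: ({}, {}))
    for p in pairs:
        apo_map, holo_map = by_entity[p.entity_id]
        apo_map[p.apo.structure_id] = p.apo
        holo_map[p.holo.structure_id] = p.holo
    return {
        e: (list(a.values()), list(h.values())) for e, (a, h) in sorted(by_entity.items())
    }


def tcr_pair_metrics(
    entity_id: str, comparison: str, a: StructureRecord, b: StructureRecord
) -> list[MovementRecord]:
    """Framework-aligned per-loop metrics for one TCR structure pair.

    Emits, per CDR loop: backbone RMSD in the framework frame (bulk
    movement), loop-superposed backbone RMSD (deformation only) and the
    dihedral D-score.
    """
    moved, _ = align_tcr_framework(a, b)
    out = []
    for loop in LOOP_NAMES:
        res_a = loop_residues(moved, loop)
        res_b = loop_residues(b, loop)
        if not res_a or not res_b:
            continue
        n_atoms = 4 * min(len(res_a), len(res_b))
        out.append(
            MovementRecord(entity_id, loop, comparison, "backbone_rmsd",
                           backbone_rmsd(res_a, res_b), n_atoms)
        )
        out.append(
            MovementRecord(entity_id, loop, comparison, "superposed_backbone_rmsd",
                           backbone_rmsd(res_a, res_b, superpose_first=True), n_atoms)
        )
        try:
            d = dscore(compute_dihedrals(res_a), compute_dihedrals(res_b))
            out.append(MovementRecord(entity_id, loop, comparison, "dscore", d, n_atoms))
        except ValueError:
            pass
    return out


def pmhc_pair_metrics(
    entity_id: str, comparison: str, a: StructureRecord, b: StructureRecord
) -> list[MovementRecord]:
    """Groove-floor-aligned peptide backbone RMSD for one pMHC pair."""
    moved, _ = align_mhc_floor(a, b)
    res_a = moved.chain("peptide").residues
    res_b = b.chain("peptide").residues
    value = backbone_rmsd(res_a, res_b)
    return [
        MovementRecord(entity_id, "peptide", comparison, "backbone_rmsd",
                       value, 4 * min(len(res_a), len(res_b)))
    ]


def build_comparison_groups(
    pairs: Sequence[ApoHoloPair],
    metric_fn: Callable[[str, str, StructureRecord, StructureRecord], list[MovementRecord]],
) -> pd.DataFrame:
    """Movement table over apo:apo / apo:holo / holo:holo comparisons.

    Entities and their apo/holo structure sets come from the matched
    pairs; every same-entity pair is measured with ``metric_fn`` in the
    designated reference frame (TCR framework or MHC groove floor).
    """
    records: list[MovementRecord] = []
    for entity_id, (apo, holo) in _entity_state_sets(pairs).items():
        for comparison, a, b in enumerate_comparisons(apo, holo):
            records.extend(metric_fn(entity_id, comparison, a, b))
    return movement_frame(records)


# ---------------------------------------------------------------------------
# Hypothesis tests
# ---------------------------------------------------------------------------

def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H and p-value over two or more value groups.

    Tie-corrected, rank-based; all-identical values return (0, 1) by
    contract instead of an error.
    """
    if len(groups) < 2 or any(len(g) < 1 for g in groups):
        raise ValueError("need >=2 groups, each with >=1 value")
    flat = np.concatenate([np.asarray(g, float) for g in groups])
    if np.all(flat == flat[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def posthoc_wilcoxon_bonferroni(
    groups: dict[str, Sequence[float]],
    comparisons: Sequence[tuple[str, str]],
    alpha: float = 0.05,
) -> list[dict]:
    """Two-sided Wilcoxon rank-sum tests at a Bonferroni-corrected level.

    The corrected level is ``alpha / len(comparisons)``; each result
    reports the raw p-value and whether it clears the corrected level.
    Pairs naming an empty group are skipped with a note.
    """
    corrected = alpha / len(comparisons) if comparisons else alpha
    out = []
    for ga, gb in comparisons:
        xa, xb = np.asarray(groups[ga], float), np.asarray(groups[gb], float)
        if len(xa) < 1 or len(xb) < 1:
            out.append({"pair": (ga, gb), "p_raw": None, "significant": None,
                        "note": "empty group; skipped"})
            continue
        if np.all(np.concatenate([xa, xb]) == xa[0]):
            p = 1.0
        else:
            _, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
            p = float(p)
        out.append({
            "pair": (ga, gb),
            "p_raw": p,
            "corrected_level": corrected,
            "significant": p < corrected,
        })
    return out


def classify_binding_mode(
    entity_id: str,
    apo_holo_values: Sequence[float],
    rigid_threshold: float = RIGID_THRESHOLD,
    flexible_threshold: float = FLEXIBLE_THRESHOLD,
) -> BindingMode:
    """Classify an entity from its apo:holo backbone RMSD values.

    flexible: some value above the flexible threshold and none below
    the rigid one; rigid: the reverse; intermediate: everything in
    between.  An entity showing both extremes across contexts is
    flagged dual-mode (and reported as intermediate).
    """
    values = [float(v) for v in apo_holo_values]
    if not values:
        raise ValueError("need at least one apo:holo value")
    has_flex = any(v > flexible_threshold for v in values)
    has_rigid = any(v < rigid_threshold for v in values)
    if has_flex and has_rigid:
        return BindingMode(entity_id, "intermediate", values, dual_mode=True)
    if has_flex:
        return BindingMode(entity_id, "flexible", values)
    if has_rigid:
        return BindingMode(entity_id, "rigid", values)
    return BindingMode(entity_id, "intermediate", values)


# ---------------------------------------------------------------------------
# Per-position profiles
# ---------------------------------------------------------------------------

def per_position_profile(
    values: Iterable[tuple[str, Hashable, float]],
) -> pd.DataFrame:
    """Entity-normalized mean +/- SD per position.

    ``values`` yields (entity_id, position, value); several values of
    one entity at a position are averaged first, then positions are
    summarized over entities.  Positions observed in a single entity
    carry no dispersion (SD is NaN).
    """
    df = pd.DataFrame(values, columns=["entity_id", "position", "value"])
    if df.empty:
        return pd.DataFrame(columns=["position", "mean", "sd", "n_entities"])
    per_entity = df.groupby(["position", "entity_id"], sort=True)["value"].mean()
    out = per_entity.groupby("position").agg(["mean", "std", "count"]).reset_index()
    out.columns = ["position", "mean", "sd", "n_entities"]
    return out


def peptide_region_movement(
    pairs: Sequence[ApoHoloPair],
    tcr_contact_positions: set[int],
    non_contact_positions: set[int],
) -> pd.DataFrame:
    """Backbone RMSD of peptide vs MHC region groups, per pMHC pair.

    Each apo pMHC is aligned to its holo partner on the groove floor;
    backbone RMSD is then measured separately over the peptide, the
    TCR-contacted MHC positions and the remaining antigen-binding-domain
    positions.  Empty regions are skipped.
    """
    records: list[MovementRecord] = []
    for p in pairs:
        moved, _ = align_mhc_floor(p.apo, p.holo)
        regions = {
            "peptide": (moved.chain("peptide").residues, p.holo.chain("peptide").residues),
        }
        mhc_a = moved.chain("mhc_heavy").residues
        mhc_b = p.holo.chain("mhc_heavy").residues
        for name, pos_set in (
            ("mhc_tcr_contact", tcr_contact_positions),
            ("mhc_non_contact", non_contact_positions),
        ):
            regions[name] = (
                [r for r in mhc_a if r.imgt_number in pos_set],
                [r for r in mhc_b if r.imgt_number in pos_set],
            )
        for name, (res_a, res_b) in regions.items():
            if not res_a or not res_b:
                continue
            records.append(
                MovementRecord(p.entity_id, name, "apo_holo", "backbone_rmsd",
                               backbone_rmsd(res_a, res_b), 4 * len(res_a))
            )
    return movement_frame(records)


def anchor_conditioned_peptide_profile(
    pairs: Sequence[ApoHoloPair],
    annotations: dict[str, AnchorAnnotation],
) -> dict[AnchorMode, pd.DataFrame]:
    """Per-residue peptide movement profiles split by anchoring mode.

    For every annotated pMHC pair the apo structure is groove-floor
    aligned to the holo one and per-residue heavy-atom RMSD of the
    peptide measured; profiles are entity-normalized within the P2_P9
    and P2_P5_P9 groups separately.  Pairs without an assigned mode are
    excluded.
    """
    per_mode: dict[AnchorMode, list[tuple[str, Hashable, float]]] = {
        AnchorMode.P2_P9: [],
        AnchorMode.P2_P5_P9: [],
    }
    for p in pairs:
        ann = annotations.get(p.entity_id)
        if ann is None or ann.mode is None:
            continue
        moved, _ = align_mhc_floor(p.apo, p.holo)
        values = per_residue_heavy_rmsd(
            moved.chain("peptide").residues, p.holo.chain("peptide").residues
        )
        per_mode[ann.mode].extend(
            (p.entity_id, key[0], v) for key, v in values
        )
    return {mode: per_position_profile(vals) for mode, vals in per_mode.items()}


# ---------------------------------------------------------------------------
# Background-repertoire comparisons
# ---------------------------------------------------------------------------

def sample_background(
    repertoire: pd.DataFrame, n: int = 1000, reps: int = 10, seed: int = 0
) -> list[pd.DataFrame]:
    """Uniform samples of unique TCR rows from a background repertoire.

    ``reps`` independent samples of ``n`` rows each, drawn without
    replacement; seeded and reproducible.
    """
    if len(repertoire) < n:
        raise ValueError(f"repertoire has {len(repertoire)} rows < sample size {n}")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(reps):
        idx = rng.choice(len(repertoire), size=n, replace=False)
        out.append(repertoire.iloc[np.sort(idx)].reset_index(drop=True))
    return out


def strip_allele(gene_call: str) -> str:
    """Harmonize a V/J call to gene level (drop the ``*NN`` allele suffix)."""
    return gene_call.split("*")[0]


def frequency_table(values: Iterable[Hashable]) -> dict[Hashable, float]:
    """Relative frequencies of the values."""
    counts: dict[Hashable, int] = defaultdict(int)
    total = 0
    for v in values:
        counts[v] += 1
        total += 1
    return {k: c / total for k, c in counts.items()} if total else {}


def gene_usage_enrichment(
    dataset_genes: Sequence[str],
    background_samples: Sequence[pd.DataFrame],
    gene_column: str,
) -> list[EnrichmentResult]:
    """Percent enrichment/depletion of gene usage vs a sampled background.

    Gene calls are harmonized to gene level on both sides; the
    background frequency of a gene is the mean of its per-sample
    frequencies.  Genes absent from the background carry no percentage
    (flagged with ``percent_enrichment=None``).
    """
    ds_freq = frequency_table([strip_allele(g) for g in dataset_genes])
    sample_freqs = [
        frequency_table([strip_allele(g) for g in s[gene_column]])
        for s in background_samples
    ]
    genes = sorted(set(ds_freq) | {g for f in sample_freqs for g in f})
    out = []
    for gene in genes:
        bg = float(np.mean([f.get(gene, 0.0) for f in sample_freqs]))
        ds = ds_freq.get(gene, 0.0)
        pct = 100.0 * (ds - bg) / bg if bg > 0 else None
        out.append(EnrichmentResult(gene, ds, bg, pct))
    return out
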