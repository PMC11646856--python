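"""Reading, writing and curating IMGT-numbered TCR / pMHC-I structures.

Structures enter the pipeline as PDB files whose residue numbers already
follow the IMGT scheme (renumbering is an upstream concern; a hook is
provided for plugging in an external numberer).  This module attaches
region semantics (framework vs CDR loops on TCR chains, groove floor and
helices on the MHC heavy chain), applies the resolution / completeness
curation filters, and matches apo structures to holo complexes by
sequence identity keys.
"""

from __future__ import annotations

import csv
from collections.abc import Callable, Iterable, Mapping, Sequence
from dataclasses import dataclass, field, replace
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "Residue",
    "NumberedChain",
    "StructureRecord",
    "ApoHoloPair",
    "DatasetManifest",
    "RegionConfig",
    "ChainRole",
    "StructureState",
    "read_structure",
    "write_structure",
    "assign_regions",
    "filter_quality",
    "match_apo_holo",
    "tcr_entity_id",
    "pmhc_entity_id",
    "write_manifest_csv",
]

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: chain roles understood by the pipeline
ChainRole = str
TCR_ROLES = ("tcr_alpha", "tcr_beta")
PMHC_ROLES = ("mhc_heavy", "beta2m", "peptide")

#: structure states
StructureState = str
STATES = ("apo_tcr", "apo_pmhc", "holo_complex")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


class FormatError(ValueError):
    """Raised for unparseable or structurally invalid input files."""


class ConfigurationError(ValueError):
    """Raised when a role map or region config does not fit the input."""


class AnnotationError(ValueError):
    """Raised when region assignment finds no residues to annotate."""


@dataclass(frozen=True)
class AtomRecord:
    """A single heavy atom: PDB atom name, element and position in Å."""

    name: str
    element: str
    coords: np.ndarray

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (3,) or not np.all(np.isfinite(coords)):
            raise ValueError(f"atom {self.name!r}: coords must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be nonempty")
        object.__setattr__(self, "coords", coords)


@dataclass
class Residue:
    """One residue with its IMGT number, insertion code and heavy atoms."""

    imgt_number: int
    insertion_code: str
    aa: str
    atoms: dict[str, AtomRecord] = field(default_factory=dict)

    @property
    def key(self) -> tuple[int, str]:
        return (self.imgt_number, self.insertion_code)

    @property
    def is_complete_backbone(self) -> bool:
        return all(a in self.atoms for a in BACKBONE_ATOMS)

    def backbone_coords(self) -> np.ndarray:
        """(4, 3) array of N, CA, C, O positions; raises if incomplete."""
        if not self.is_complete_backbone:
            raise ValueError(f"residue {self.key} has an incomplete backbone")
        return np.array([self.atoms[a].coords for a in BACKBONE_ATOMS])

    def heavy_atom_names(self) -> list[str]:
        return sorted(self.atoms)


@dataclass
class NumberedChain:
    """An IMGT-numbered chain with a role and named region subsets.

    ``regions`` maps a region name (``FR``, ``CDR1`` ... or
    ``groove_floor``, ``alpha1_helix``, ``alpha2_helix``, ``peptide``)
    to the ordered list of residue keys belonging to it.
    """

    chain_id: str
    role: ChainRole
    residues: list[Residue]
    regions: dict[str, list[tuple[int, str]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.residues.sort(key=lambda r: (r.imgt_number, r.insertion_code))

    def residue_map(self) -> dict[tuple[int, str], Residue]:
        return {r.key: r for r in self.residues}

    def region_residues(self, name: str) -> list[Residue]:
        rmap = self.residue_map()
        return [rmap[k] for k in self.regions.get(name, []) if k in rmap]

    def sequence(self, region: str | None = None) -> str:
        if region is None:
            return "".join(r.aa for r in self.residues)
        return "".join(r.aa for r in self.region_residues(region))


@dataclass
class StructureRecord:
    """A curated structure: an apo TCR, an apo pMHC-I or a holo complex."""

    structure_id: str
    state: StructureState
    chains: list[NumberedChain]
    resolution: float | None = None
    allele: str | None = None

    def chains_with_role(self, role: ChainRole) -> list[NumberedChain]:
        return [c for c in self.chains if c.role == role]

    def chain(self, role: ChainRole) -> NumberedChain:
        matches = self.chains_with_role(role)
        if not matches:
            raise KeyError(f"{self.structure_id}: no chain with role {role!r}")
        return matches[0]

    def validate(self) -> None:
        roles = {c.role for c in self.chains}
        if self.state == "holo_complex":
            required = {"tcr_alpha", "tcr_beta", "mhc_heavy", "peptide"}
            if not required <= roles:
                raise FormatError(
                    f"{self.structure_id}: holo complex missing roles {required - roles}"
                )
        elif self.state == "apo_tcr":
            if not {"tcr_alpha", "tcr_beta"} <= roles or "mhc_heavy" in roles:
                raise FormatError(f"{self.structure_id}: invalid apo TCR chain roles {roles}")
        elif self.state == "apo_pmhc":
            if not {"mhc_heavy", "peptide"} <= roles or roles & {"tcr_alpha", "tcr_beta"}:
                raise FormatError(f"{self.structure_id}: invalid apo pMHC chain roles {roles}")
        else:
            raise FormatError(f"{self.structure_id}: unknown state {self.state!r}")

    def all_coords(self) -> np.ndarray:
        return np.array(
            [a.coords for c in self.chains for r in c.residues for a in r.atoms.values()]
        )

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "StructureRecord":
        """A copy with every atom moved by ``x -> R x + t``."""
        new_chains = []
        for chain in self.chains:
            new_res = []
            for res in chain.residues:
                atoms = {
                    name: AtomRecord(a.name, a.element, rotation @ a.coords + translation)
                    for name, a in res.atoms.items()
                }
                new_res.append(Residue(res.imgt_number, res.insertion_code, res.aa, atoms))
            new_chains.append(
                NumberedChain(chain.chain_id, chain.role, new_res, dict(chain.regions))
            )
        return StructureRecord(
            self.structure_id, self.state, new_chains, self.resolution, self.allele
        )


@dataclass
class ApoHoloPair:
    """A matched apo/holo pair sharing an entity identity key."""

    entity_id: str
    apo: StructureRecord
    holo: StructureRecord
    side: str  # "tcr" or "pmhc"


@dataclass
class DatasetManifest:
    """The curated dataset: retained records, matched pairs, rejections."""

    records: list[StructureRecord] = field(default_factory=list)
    pairs: list[ApoHoloPair] = field(default_factory=list)
    rejection_log: list[tuple[str, str]] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


@dataclass
class RegionConfig:
    """IMGT region delimitations.

    CDR boundaries follow the standard IMGT delimitation (CDR1 27-38,
    CDR2 56-65, CDR3 105-117); the framework is the rest of the variable
    domain (positions 1-128).  The MHC groove floor defaults to the
    beta-strand stretches of the alpha1/alpha2 domain; all position sets
    are overridable.
    """

    cdr1: tuple[int, int] = (27, 38)
    cdr2: tuple[int, int] = (56, 65)
    cdr3: tuple[int, int] = (105, 117)
    variable_domain: tuple[int, int] = (1, 128)
    groove_floor: tuple[int, ...] = tuple(range(1, 50)) + tuple(range(94, 140))
    alpha1_helix: tuple[int, int] = (50, 86)
    alpha2_helix: tuple[int, int] = (140, 176)
    antigen_binding_domain: tuple[int, int] = (1, 180)

    def cdr_range(self, n: int) -> tuple[int, int]:
        return (self.cdr1, self.cdr2, self.cdr3)[n - 1]

    def cdr_of(self, imgt_number: int) -> int | None:
        for n in (1, 2, 3):
            lo, hi = self.cdr_range(n)
            if lo <= imgt_number <= hi:
                return n
        return None


DEFAULT_REGIONS = RegionConfig()


# ---------------------------------------------------------------------------
# PDB input / output (gemmi-backed)
# ---------------------------------------------------------------------------

def read_structure(
    path: str | Path,
    role_map: Mapping[str, ChainRole],
    state: StructureState,
    structure_id: str | None = None,
    allele: str | None = None,
    numberer: Callable[[NumberedChain], NumberedChain] | None = None,
) -> StructureRecord:
    """Read a PDB file into a :class:`StructureRecord`.

    Residue numbers in the file are taken as IMGT numbers.  Hydrogens,
    waters and non-polymer heteroatoms are dropped; alternate locations
    resolve to the highest-occupancy conformer; only model 1 is read.

    Parameters
    ----------
    role_map
        chain id -> role for every polymer chain of interest; chains
        absent from the map are ignored.
    numberer
        optional hook rewriting residue numbering (e.g. an external
        IMGT renumberer) applied per chain before region assignment.
    """
    path = Path(path)
    try:
        st = gemmi.read_pdb(str(path))
    except (RuntimeError, ValueError) as exc:
        raise FormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if len(st) == 0:
        raise FormatError(f"{path}: no models")
    st.setup_entities()
    model = st[0]
    if len(model) == 0:
        raise FormatError(f"{path}: no chains parsed")

    present = {ch.name for ch in model}
    missing = set(role_map) - present
    if missing:
        raise ConfigurationError(f"{path}: role map references missing chains {sorted(missing)}")

    chains: list[NumberedChain] = []
    for ch in model:
        role = role_map.get(ch.name)
        if role is None:
            continue
        residues: list[Residue] = []
        for res in ch:
            one = _THREE_TO_ONE.get(res.name)
            if one is None:  # waters, ligands, ions
                continue
            # highest-occupancy altloc per atom name
            best: dict[str, gemmi.Atom] = {}
            for atom in res:
                if atom.is_hydrogen():
                    continue
                prev = best.get(atom.name)
                if prev is None or atom.occ > prev.occ:
                    best[atom.name] = atom
            atoms = {
                name: AtomRecord(
                    name,
                    a.element.name if a.element.name else name[0],
                    np.array([a.pos.x, a.pos.y, a.pos.z]),
                )
                for name, a in best.items()
            }
            if not atoms:
                continue
            icode = res.seqid.icode.strip()
            residues.append(Residue(res.seqid.num, icode, one, atoms))
        chain = NumberedChain(ch.name, role, residues)
        if numberer is not None:
            chain = numberer(chain)
        chains.append(chain)

    resolution = st.resolution if st.resolution and st.resolution > 0 else None
    record = StructureRecord(
        structure_id=structure_id or path.stem,
        state=state,
        chains=chains,
        resolution=resolution,
        allele=allele,
    )
    record.validate()
    return record


def write_structure(record: StructureRecord, path: str | Path) -> None:
    """Write a record to a PDB file (coordinates at PDB 1e-3 Å precision)."""
    st = gemmi.Structure()
    st.name = record.structure_id
    if record.resolution is not None:
        st.resolution = record.resolution
    model = gemmi.Model("1")
    for chain in record.chains:
        gch = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = _ONE_TO_THREE.get(res.aa, "UNK")
            gres.seqid = gemmi.SeqId(res.imgt_number, res.insertion_code or " ")
            for atom in res.atoms.values():
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = 1.0
                gres.add_atom(ga)
            gch.add_residue(gres)
        model.add_chain(gch)
    st.add_model(model)
    st.setup_entities()
    doc = st.make_pdb_string()
    Path(path).write_text(doc)


# ---------------------------------------------------------------------------
# Region semantics
# ---------------------------------------------------------------------------

def assign_regions(
    chain: NumberedChain, config: RegionConfig = DEFAULT_REGIONS
) -> NumberedChain:
    """Populate the region map of a TCR, MHC heavy or peptide chain.

    TCR chains are partitioned into FR / CDR1 / CDR2 / CDR3 over the
    variable domain; MHC heavy chains get groove_floor and the two
    helices; peptide chains carry a single whole-chain region.
    """
    regions: dict[str, list[tuple[int, str]]] = {}
    if chain.role in TCR_ROLES:
        lo, hi = config.variable_domain
        domain = [r for r in chain.residues if lo <= r.imgt_number <= hi]
        if not domain:
            raise AnnotationError(
                f"chain {chain.chain_id}: no residues in the variable domain range"
            )
        regions = {"FR": [], "CDR1": [], "CDR2": [], "CDR3": []}
        for res in domain:
            n = config.cdr_of(res.imgt_number)
            regions["FR" if n is None else f"CDR{n}"].append(res.key)
    elif chain.role == "mhc_heavy":
        floor = set(config.groove_floor)
        regions["groove_floor"] = [r.key for r in chain.residues if r.imgt_number in floor]
        for name, (lo, hi) in (
            ("alpha1_helix", config.alpha1_helix),
            ("alpha2_helix", config.alpha2_helix),
        ):
            regions[name] = [r.key for r in chain.residues if lo <= r.imgt_number <= hi]
        if not regions["groove_floor"]:
            raise AnnotationError(f"chain {chain.chain_id}: empty groove floor")
    elif chain.role == "peptide":
        regions["peptide"] = [r.key for r in chain.residues]
    else:
        regions = {}
    return NumberedChain(chain.chain_id, chain.role, list(chain.residues), regions)


def assign_all_regions(
    record: StructureRecord, config: RegionConfig = DEFAULT_REGIONS
) -> StructureRecord:
    """assign_regions applied to every chain with a known role."""
    chains = []
    for ch in record.chains:
        if ch.role in TCR_ROLES or ch.role in ("mhc_heavy", "peptide"):
            chains.append(assign_regions(ch, config))
        else:
            chains.append(ch)
    return replace(record, chains=chains)


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def _cdr_backbone_complete(record: StructureRecord) -> bool:
    for chain in record.chains:
        if chain.role not in TCR_ROLES:
            continue
        for region in ("CDR1", "CDR2", "CDR3"):
            for res in chain.region_residues(region):
                if not res.is_complete_backbone:
                    return False
    return True


def _peptide_backbone_complete(record: StructureRecord) -> bool:
    for chain in record.chains:
        if chain.role == "peptide":
            for res in chain.residues:
                if not res.is_complete_backbone:
                    return False
    return True


def filter_quality(
    records: Iterable[StructureRecord],
    max_resolution: float = 3.50,
) -> DatasetManifest:
    """Apply the curation filters.

    A record is rejected when its resolution is strictly greater than
    ``max_resolution`` (structures at exactly the cutoff are retained),
    or when any CDR residue (TCR-containing states) or peptide residue
    (pMHC-containing states) lacks a complete N/CA/C/O backbone.
    Each rejection carries one primary reason; resolution is checked
    first.
    """
    manifest = DatasetManifest()
    for record in records:
        if record.resolution is not None and record.resolution > max_resolution:
            manifest.rejection_log.append((record.structure_id, "resolution"))
            continue
        needs_tcr = record.state in ("apo_tcr", "holo_complex")
        needs_pep = record.state in ("apo_pmhc", "holo_complex")
        if needs_tcr and not _cdr_backbone_complete(record):
            manifest.rejection_log.append((record.structure_id, "missing residues"))
            continue
        if needs_pep and not _peptide_backbone_complete(record):
            manifest.rejection_log.append((record.structure_id, "missing residues"))
            continue
        manifest.records.append(record)
    return manifest


# ---------------------------------------------------------------------------
# Apo-holo matching
# ---------------------------------------------------------------------------

def tcr_entity_id(record: StructureRecord) -> str:
    """TCR identity: the six CDR sequences concatenated (alpha then beta)."""
    parts = []
    for role in ("tcr_alpha", "tcr_beta"):
        chain = record.chain(role)
        for region in ("CDR1", "CDR2", "CDR3"):
            parts.append(chain.sequence(region))
    return "-".join(parts)


def pmhc_entity_id(record: StructureRecord) -> str:
    """pMHC identity: peptide sequence plus MHC allele name."""
    peptide = record.chain("peptide").sequence()
    return f"{peptide}|{record.allele or 'unknown'}"


def match_apo_holo(manifest: DatasetManifest) -> DatasetManifest:
    """Match apo structures to holo complexes by entity identity.

    TCRs match on their six CDR sequences; pMHC-Is on peptide sequence
    plus allele name.  All apo x holo combinations with equal keys are
    kept (entity normalization downstream handles the redundancy);
    structures without a partner stay in ``records`` with a log note.
    """
    ids = [r.structure_id for r in manifest.records]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate structure_id in manifest")

    holo = [r for r in manifest.records if r.state == "holo_complex"]
    pairs: list[ApoHoloPair] = []
    matched: set[str] = set()
    for record in sorted(manifest.records, key=lambda r: r.structure_id):
        if record.state == "apo_tcr":
            key, side = tcr_entity_id(record), "tcr"
            key_of = tcr_entity_id
        elif record.state == "apo_pmhc":
            key, side = pmhc_entity_id(record), "pmhc"
            key_of = pmhc_entity_id
        else:
            continue
        for h in sorted(holo, key=lambda r: r.structure_id):
            if key_of(h) == key:
                pairs.append(ApoHoloPair(key, record, h, side))
                matched.add(record.structure_id)
                matched.add(h.structure_id)
    notes = [
        f"{r.structure_id}: no apo/holo partner"
        for r in manifest.records
        if r.structure_id not in matched
    ]
    return DatasetManifest(
        records=list(manifest.records),
        pairs=pairs,
        rejection_log=list(manifest.rejection_log),
        notes=manifest.notes + notes,
    )


# ---------------------------------------------------------------------------
# Tabular interfaces
# ---------------------------------------------------------------------------

def write_manifest_csv(manifest: DatasetManifest, out_dir: str | Path) -> None:
    """Write manifest.csv and rejections.csv into ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["structure_id", "state", "resolution", "entity_id"])
        for r in manifest.records:
            if r.state == "apo_pmhc" or (r.state == "holo_complex" and r.allele):
                entity = pmhc_entity_id(r)
            else:
                try:
                    entity = tcr_entity_id(r)
                except KeyError:
                    entity = ""
            w.writerow([r.structure_id, r.state, r.resolution, entity])
    with open(out / "rejections.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["structure_id", "reason"])
        w.writerows(manifest.rejection_log)
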