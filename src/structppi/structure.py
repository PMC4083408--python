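"""Hierarchical protein structure model with faithful author numbering.

Structure > Chain > Residue > Atom, carrying exactly what the downstream
analysis needs: heavy-atom coordinates, author residue numbers with insertion
codes, and per-chain provenance tags (experimental vs homology model, conformer
label for ensemble inputs).  PDB reading/writing is delegated to gemmi; this
module applies the pipeline's policies on top: HETATM, waters and nucleic
chains are dropped, hydrogens are dropped by default, and alternate locations
are resolved to the highest-occupancy record (tie -> first encountered).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterator

import gemmi
import numpy as np

from .errors import EmptyStructureError, TotalTruncationError
from .potentials import AA3_TO_AA1, STANDARD_AA3

#: Engine size rule: chains shorter than this are loadable but flagged, and the
#: prediction engine refuses to dock them.
MIN_CHAIN_RESIDUES = 15


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray
    occupancy: float = 1.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be nonempty")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass(frozen=True, order=True)
class ResidueID:
    chain_id: str
    author_number: int
    insertion_code: str = ""

    def __str__(self) -> str:
        return f"{self.chain_id}{self.author_number}{self.insertion_code}"


@dataclass
class Residue:
    id: ResidueID
    aa3: str
    seq_index: int
    atoms: list[Atom] = field(default_factory=list)

    @property
    def aa1(self) -> str:
        return AA3_TO_AA1.get(self.aa3, "X")

    @property
    def is_standard(self) -> bool:
        return self.aa3 in STANDARD_AA3

    @property
    def incomplete(self) -> bool:
        """Standard residues without a CA atom are usable only with care."""
        return self.is_standard and self.atom("CA") is None

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    @property
    def ca(self) -> Atom | None:
        return self.atom("CA")

    @property
    def scoring_atom(self) -> Atom | None:
        """Side-chain proxy for pair potentials: CB, falling back to CA (Gly)."""
        return self.atom("CB") or self.atom("CA")

    def heavy_coords(self) -> np.ndarray:
        pts = [a.position for a in self.atoms if a.is_heavy]
        return np.array(pts) if pts else np.empty((0, 3))


@dataclass
class Chain:
    id: str
    residues: list[Residue] = field(default_factory=list)
    source: str = "experimental"  # or "homology-model"
    conformer_label: str | None = None

    def __len__(self) -> int:
        return len(self.residues)

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    @property
    def is_short(self) -> bool:
        return len(self.residues) < MIN_CHAIN_RESIDUES

    def residue(self, rid: ResidueID) -> Residue | None:
        for r in self.residues:
            if r.id == rid:
                return r
        return None

    def residue_by_number(self, author_number: int, insertion_code: str = "") -> Residue | None:
        return self.residue(ResidueID(self.id, author_number, insertion_code))

    def ca_coords(self) -> np.ndarray:
        """CA coordinates of residues that have one, in chain order."""
        pts = [r.ca.position for r in self.residues if r.ca is not None]
        return np.array(pts) if pts else np.empty((0, 3))

    def residues_with_ca(self) -> list[Residue]:
        return [r for r in self.residues if r.ca is not None]

    def heavy_coords(self) -> np.ndarray:
        parts = [r.heavy_coords() for r in self.residues]
        parts = [p for p in parts if len(p)]
        return np.vstack(parts) if parts else np.empty((0, 3))

    def copy(self) -> "Chain":
        return copy.deepcopy(self)


@dataclass
class Structure:
    entry_id: str
    chains: dict[str, Chain] = field(default_factory=dict)
    title: str = ""

    def add_chain(self, chain: Chain) -> None:
        if chain.id in self.chains:
            raise ValueError(f"duplicate chain id {chain.id!r} in {self.entry_id}")
        self.chains[chain.id] = chain

    def __getitem__(self, chain_id: str) -> Chain:
        return self.chains[chain_id]

    def __contains__(self, chain_id: str) -> bool:
        return chain_id in self.chains

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for c in self.chains.values() for r in c.residues)

    def copy(self) -> "Structure":
        return copy.deepcopy(self)


# ---------------------------------------------------------------------------
# PDB I/O


def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Highest-occupancy altloc wins; ties keep the first record encountered."""
    best: dict[str, gemmi.Atom] = {}
    for atom in res:
        prev = best.get(atom.name)
        if prev is None or atom.occ > prev.occ + 1e-9:
            best[atom.name] = atom
    # preserve file order of the winning records
    chosen = set(id(a) for a in best.values())
    return [a for a in res if id(a) in chosen]


def parse_pdb(path, keep_hydrogens: bool = False, source: str = "experimental",
              conformer_label: str | None = None) -> Structure:
    """Read a PDB file into a Structure.

    HETATM records, waters and non-protein residues are ignored.  Raises
    EmptyStructureError if no protein ATOM records survive the filters.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    structure = Structure(entry_id=st.name.lower() or "unnamed", title=st.name)
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]
    for gchain in model:
        chain = Chain(id=gchain.name, source=source, conformer_label=conformer_label)
        seq_index = 0
        for gres in gchain:
            if gres.het_flag != "A":
                continue  # HETATM (ligands, waters)
            if gres.name not in STANDARD_AA3 and gres.name != "UNK":
                continue  # nucleic / modified residues out of scope
            rid = ResidueID(gchain.name, gres.seqid.num, (gres.seqid.icode or " ").strip())
            residue = Residue(id=rid, aa3=gres.name, seq_index=seq_index)
            for gatom in _resolve_altlocs(gres):
                element = gatom.element.name.upper() or "C"
                if not keep_hydrogens and element in ("H", "D"):
                    continue
                residue.atoms.append(Atom(
                    name=gatom.name, element=element,
                    position=np.array([gatom.pos.x, gatom.pos.y, gatom.pos.z]),
                    occupancy=gatom.occ,
                ))
            if residue.atoms:
                chain.residues.append(residue)
                seq_index += 1
        if chain.residues:
            structure.add_chain(chain)
    if not structure.chains:
        raise EmptyStructureError(f"{path}: no protein ATOM records")
    return structure


def write_pdb(structure: Structure, path) -> None:
    """Write fixed-column PDB; inverse of parse_pdb up to 1e-3 A formatting."""
    if not structure.chains or structure.n_atoms() == 0:
        raise EmptyStructureError("refusing to write an empty structure")
    st = gemmi.Structure()
    st.name = structure.entry_id
    model = gemmi.Model("1")
    for chain in structure.chains.values():
        gchain = gemmi.Chain(chain.id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.aa3
            gres.seqid = gemmi.SeqId(res.id.author_number, res.id.insertion_code or " ")
            for atom in res.atoms:
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.element = gemmi.Element(atom.element)
                gatom.occ = atom.occupancy
                gatom.pos = gemmi.Position(*atom.position)
                gres.add_atom(gatom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    st.write_pdb(str(path))


def truncate_chain(chain: Chain, first_lost_author_number: int) -> Chain:
    """Model a premature stop: keep residues with author_number < cut position.

    Numbering is unchanged.  Raises TotalTruncationError when nothing would
    remain (total loss of the protein).
    """
    kept = [copy.deepcopy(r) for r in chain.residues
            if r.id.author_number < first_lost_author_number]
    if not kept:
        raise TotalTruncationError(
            f"truncation at {first_lost_author_number} removes every residue of "
            f"chain {chain.id}")
    out = Chain(id=chain.id, residues=kept, source=chain.source,
                conformer_label=chain.conformer_label)
    for i, r in enumerate(out.residues):
        r.seq_index = i
    return out


def sequence_of(chain: Chain) -> str:
    """One-letter sequence, UNK -> 'X'; length equals residue count."""
    if not chain.residues:
        raise EmptyStructureError(f"chain {chain.id} is empty")
    return "".join(r.aa1 for r in chain.residues)
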