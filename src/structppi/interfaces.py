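"""Two-sided interface extraction from known complexes and the template library.

A template is the reusable unit of the prediction engine: the contacting and
nearby residues of both partners of a known complex, kept with full heavy-atom
coordinates in the complex frame, plus the contact list and computational hot
spots.  Contact definition: a residue of one chain is *contacting* iff any of
its heavy atoms lies within `contact_cutoff` (default 5.0 A) of a heavy atom of
the partner chain; *nearby* residues flank the contacting set (CA within
`nearby_cutoff`, default 6.0 A, of a contacting CA on the same side) without
touching the partner themselves.
"""

from __future__ import annotations

import copy
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist

from .errors import LibraryError, NoInterfaceError
from .structure import Chain, Residue, ResidueID, Structure, write_pdb

log = logging.getLogger(__name__)

LIBRARY_FORMAT_VERSION = 1

CONTACT_CUTOFF = 5.0  # A, heavy-atom
NEARBY_CUTOFF = 6.0   # A, CA-CA


@dataclass
class ContactPair:
    residue_a: ResidueID
    residue_b: ResidueID
    min_heavy_distance: float


@dataclass
class InterfaceSide:
    contacting: set[ResidueID]
    nearby: set[ResidueID]
    residues: Chain  # sub-structure: contacting + nearby residues, chain order

    def ordered_residues(self) -> list[Residue]:
        return list(self.residues.residues)


@dataclass
class InterfaceTemplate:
    template_id: str
    side_a: InterfaceSide
    side_b: InterfaceSide
    contacts: list[ContactPair]
    hotspots_a: set[ResidueID] = field(default_factory=set)
    hotspots_b: set[ResidueID] = field(default_factory=set)
    provenance: str = ""

    def side_for_chain(self, chain_id: str) -> InterfaceSide | None:
        if self.side_a.residues.id == chain_id:
            return self.side_a
        if self.side_b.residues.id == chain_id:
            return self.side_b
        return None


def _residue_heavy_arrays(chain: Chain):
    """Heavy-atom coordinates stacked per chain + residue index of each atom."""
    coords, owner = [], []
    for idx, res in enumerate(chain.residues):
        for atom in res.atoms:
            if atom.is_heavy:
                coords.append(atom.position)
                owner.append(idx)
    return (np.array(coords) if coords else np.empty((0, 3))), np.array(owner, dtype=int)


def extract_interface(structure: Structure, chain_a: str, chain_b: str,
                      contact_cutoff: float = CONTACT_CUTOFF,
                      nearby_cutoff: float = NEARBY_CUTOFF) -> InterfaceTemplate:
    """Extract the two-sided interface between chains `chain_a` and `chain_b`."""
    ca_chain, cb_chain = structure[chain_a], structure[chain_b]
    A, owner_a = _residue_heavy_arrays(ca_chain)
    B, owner_b = _residue_heavy_arrays(cb_chain)
    if len(A) == 0 or len(B) == 0:
        raise NoInterfaceError(f"{structure.entry_id}: empty chain(s)")
    D = cdist(A, B)
    contacts: list[ContactPair] = []
    contacting_a: set[ResidueID] = set()
    contacting_b: set[ResidueID] = set()
    n_res_a, n_res_b = len(ca_chain.residues), len(cb_chain.residues)
    min_pair = np.full((n_res_a, n_res_b), np.inf)
    hits = np.argwhere(D < contact_cutoff)
    for ai, bi in hits:
        ra, rb = owner_a[ai], owner_b[bi]
        if D[ai, bi] < min_pair[ra, rb]:
            min_pair[ra, rb] = D[ai, bi]
    for ra, rb in np.argwhere(np.isfinite(min_pair)):
        rid_a = ca_chain.residues[ra].id
        rid_b = cb_chain.residues[rb].id
        contacts.append(ContactPair(rid_a, rid_b, float(min_pair[ra, rb])))
        contacting_a.add(rid_a)
        contacting_b.add(rid_b)
    if not contacts:
        raise NoInterfaceError(
            f"{structure.entry_id}: no contacting residues between "
            f"{chain_a} and {chain_b} at {contact_cutoff} A")
    side_a = _build_side(ca_chain, contacting_a, nearby_cutoff)
    side_b = _build_side(cb_chain, contacting_b, nearby_cutoff)
    template_id = f"{structure.entry_id}{chain_a}{chain_b}"
    return InterfaceTemplate(template_id=template_id, side_a=side_a, side_b=side_b,
                             contacts=sorted(contacts, key=lambda c: (c.residue_a, c.residue_b)),
                             provenance=f"extracted from {structure.entry_id} "
                                        f"chains {chain_a}/{chain_b}")


def _build_side(chain: Chain, contacting: set[ResidueID], nearby_cutoff: float) -> InterfaceSide:
    contact_cas = np.array([r.ca.position for r in chain.residues
                            if r.id in contacting and r.ca is not None])
    nearby: set[ResidueID] = set()
    for res in chain.residues:
        if res.id in contacting or res.ca is None or len(contact_cas) == 0:
            continue
        if np.min(np.linalg.norm(contact_cas - res.ca.position, axis=1)) < nearby_cutoff:
            nearby.add(res.id)
    keep = contacting | nearby
    sub = Chain(id=chain.id, source=chain.source, conformer_label=chain.conformer_label,
                residues=[copy.deepcopy(r) for r in chain.residues if r.id in keep])
    return InterfaceSide(contacting=set(contacting), nearby=nearby, residues=sub)


def build_template_library(complexes, hotspot_fn=None) -> dict[str, InterfaceTemplate]:
    """One template per (Structure, (chain_a, chain_b)) pair.

    `hotspot_fn(structure, template) -> (hotspots_a, hotspots_b)` fills the hot
    spot sets; complexes without an interface are skipped with a warning.
    """
    library: dict[str, InterfaceTemplate] = {}
    for structure, (a, b) in complexes:
        try:
            tpl = extract_interface(structure, a, b)
        except NoInterfaceError as exc:
            log.warning("SKIP-TEMPLATE %s", exc)
            continue
        if hotspot_fn is not None:
            tpl.hotspots_a, tpl.hotspots_b = hotspot_fn(structure, tpl)
        key = tpl.template_id
        suffix = 1
        while key in library:  # same complex given twice stays twice
            suffix += 1
            key = f"{tpl.template_id}#{suffix}"
        library[key] = tpl
    if not library:
        raise LibraryError("no complex yielded a valid interface")
    return library


# ---------------------------------------------------------------------------
# On-disk library: JSON index (authoritative, full float precision) plus one
# PDB fragment per template for inspection with standard viewers.


def _rid_to_list(rid: ResidueID):
    return [rid.chain_id, rid.author_number, rid.insertion_code]


def _rid_from_list(v) -> ResidueID:
    return ResidueID(v[0], int(v[1]), v[2])


def _side_to_json(side: InterfaceSide):
    return {
        "chain_id": side.residues.id,
        "source": side.residues.source,
        "conformer_label": side.residues.conformer_label,
        "contacting": sorted(map(_rid_to_list, side.contacting)),
        "nearby": sorted(map(_rid_to_list, side.nearby)),
        "residues": [
            {
                "id": _rid_to_list(r.id), "aa3": r.aa3, "seq_index": r.seq_index,
                "atoms": [{"name": a.name, "element": a.element,
                           "occupancy": a.occupancy,
                           "xyz": [float(x) for x in a.position]} for a in r.atoms],
            }
            for r in side.residues.residues
        ],
    }


def _side_from_json(d) -> InterfaceSide:
    from .structure import Atom
    chain = Chain(id=d["chain_id"], source=d["source"],
                  conformer_label=d["conformer_label"])
    for rj in d["residues"]:
        res = Residue(id=_rid_from_list(rj["id"]), aa3=rj["aa3"],
                      seq_index=int(rj["seq_index"]))
        for aj in rj["atoms"]:
            res.atoms.append(Atom(name=aj["name"], element=aj["element"],
                                  position=np.array(aj["xyz"]),
                                  occupancy=aj["occupancy"]))
        chain.residues.append(res)
    return InterfaceSide(contacting={_rid_from_list(v) for v in d["contacting"]},
                         nearby={_rid_from_list(v) for v in d["nearby"]},
                         residues=chain)


def save_library(library: dict[str, InterfaceTemplate], path) -> None:
    if not library:
        raise LibraryError("refusing to save an empty library")
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    index = {"format_version": LIBRARY_FORMAT_VERSION, "templates": {}}
    for key, tpl in library.items():
        index["templates"][key] = {
            "template_id": tpl.template_id,
            "provenance": tpl.provenance,
            "side_a": _side_to_json(tpl.side_a),
            "side_b": _side_to_json(tpl.side_b),
            "contacts": [[_rid_to_list(c.residue_a), _rid_to_list(c.residue_b),
                          float(c.min_heavy_distance)] for c in tpl.contacts],
            "hotspots_a": sorted(map(_rid_to_list, tpl.hotspots_a)),
            "hotspots_b": sorted(map(_rid_to_list, tpl.hotspots_b)),
        }
        frag = Structure(entry_id=tpl.template_id)
        side_a = copy.deepcopy(tpl.side_a.residues)
        side_b = copy.deepcopy(tpl.side_b.residues)
        if side_a.id == side_b.id:
            side_b.id = "+" if side_a.id != "+" else "-"
        frag.add_chain(side_a)
        frag.add_chain(side_b)
        write_pdb(frag, root / f"{key.replace('#', '_')}.pdb")
    (root / "index.json").write_text(json.dumps(index, indent=1))


def load_library(path) -> dict[str, InterfaceTemplate]:
    root = Path(path)
    index = json.loads((root / "index.json").read_text())
    version = index.get("format_version")
    if version != LIBRARY_FORMAT_VERSION:
        raise LibraryError(f"library format version {version!r} != "
                           f"{LIBRARY_FORMAT_VERSION}")
    library = {}
    for key, tj in index["templates"].items():
        library[key] = InterfaceTemplate(
            template_id=tj["template_id"],
            side_a=_side_from_json(tj["side_a"]),
            side_b=_side_from_json(tj["side_b"]),
            contacts=[ContactPair(_rid_from_list(a), _rid_from_list(b), float(d))
                      for a, b, d in tj["contacts"]],
            hotspots_a={_rid_from_list(v) for v in tj["hotspots_a"]},
            hotspots_b={_rid_from_list(v) for v in tj["hotspots_b"]},
            provenance=tj["provenance"],
        )
    if not library:
        raise LibraryError(f"{path}: empty template library")
    return library
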