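"""Schematic ideal-geometry side-chain construction.

Builds side chains atom-by-atom from the backbone in an extended chi rotamer:
linear-chain atoms continue along the CA->CB direction with ideal bond lengths
in a zig-zag plane; terminal branch pairs (e.g. NH1/NH2, OD1/OD2) and rings are
placed symmetrically about the chain axis.  The geometry is intentionally
schematic - good enough for atom counts, residue-level contact potentials and
occlusion-based accessibility, with no claim of rotamer realism and no
minimization.
"""

from __future__ import annotations

import numpy as np

from .errors import StructPPIError
from .structure import Atom, Residue

BOND = 1.52          # A, generic heavy-atom bond length
RING_RADIUS = 1.39   # A, aromatic C-C
ZIGZAG_DEG = 35.0    # half-angle of the extended zig-zag

#: (linear chain beyond CB, terminal branch atoms, ring atoms)
SIDECHAIN_TOPOLOGY: dict[str, tuple[list[str], list[str], list[str]]] = {
    "GLY": ([], [], []),
    "ALA": ([], [], []),
    "SER": (["OG"], [], []),
    "CYS": (["SG"], [], []),
    "THR": (["OG1"], ["CG2"], []),
    "VAL": ([], ["CG1", "CG2"], []),
    "LEU": (["CG"], ["CD1", "CD2"], []),
    "ILE": (["CG1", "CD1"], ["CG2"], []),
    "MET": (["CG", "SD", "CE"], [], []),
    "PRO": (["CG", "CD"], [], []),
    "ASP": (["CG"], ["OD1", "OD2"], []),
    "ASN": (["CG"], ["OD1", "ND2"], []),
    "GLU": (["CG", "CD"], ["OE1", "OE2"], []),
    "GLN": (["CG", "CD"], ["OE1", "NE2"], []),
    "LYS": (["CG", "CD", "CE", "NZ"], [], []),
    "ARG": (["CG", "CD", "NE", "CZ"], ["NH1", "NH2"], []),
    "HIS": (["CG"], [], ["ND1", "CD2", "CE1", "NE2"]),
    "PHE": (["CG"], [], ["CD1", "CD2", "CE1", "CE2", "CZ"]),
    "TYR": (["CG"], [], ["CD1", "CD2", "CE1", "CE2", "CZ", "OH"]),
    "TRP": (["CG"], [], ["CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"]),
}

#: heavy-atom count of each full residue (backbone N,CA,C,O + side chain)
HEAVY_ATOM_COUNT = {aa: 4 + (0 if aa == "GLY" else 1) + sum(map(len, topo))
                    for aa, topo in SIDECHAIN_TOPOLOGY.items()}


def _element_of(atom_name: str) -> str:
    return atom_name[0]  # side-chain names start with the element letter


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise StructPPIError("degenerate direction in side-chain construction")
    return v / n


def ideal_cb(n: np.ndarray, ca: np.ndarray, c: np.ndarray) -> np.ndarray:
    """Tetrahedral CB position from backbone N, CA, C."""
    b1 = _unit(n - ca)
    b2 = _unit(c - ca)
    bisector = -_unit(b1 + b2)
    perp = np.cross(b2, b1)
    if np.linalg.norm(perp) < 1e-9:
        perp = np.array([0.0, 0.0, 1.0])
    perp = _unit(perp)
    direction = _unit(bisector * np.cos(np.radians(54.25)) +
                      perp * np.sin(np.radians(54.25)))
    return ca + BOND * direction


def build_sidechain(residue: Residue, new_aa3: str) -> list[Atom]:
    """Atoms (CB onward) of `new_aa3` grafted onto `residue`'s backbone."""
    if new_aa3 not in SIDECHAIN_TOPOLOGY:
        raise StructPPIError(f"unknown residue type {new_aa3}")
    n_at, ca_at, c_at = residue.atom("N"), residue.atom("CA"), residue.atom("C")
    if n_at is None or ca_at is None or c_at is None:
        raise StructPPIError(f"{residue.id}: backbone incomplete, cannot rebuild")
    if new_aa3 == "GLY":
        return []
    n, ca, c = n_at.position, ca_at.position, c_at.position
    cb_at = residue.atom("CB")
    cb = cb_at.position if cb_at is not None else ideal_cb(n, ca, c)
    atoms = [Atom(name="CB", element="C", position=cb)]
    chain_names, branch_names, ring_names = SIDECHAIN_TOPOLOGY[new_aa3]

    axis = _unit(cb - ca)
    ref = _unit(np.cross(axis, _unit(n - ca)))
    if np.linalg.norm(np.cross(axis, n - ca)) < 1e-6:
        ref = _unit(np.cross(axis, np.array([1.0, 0.0, 0.0])))
    up = _unit(np.cross(ref, axis))

    cos_z, sin_z = np.cos(np.radians(ZIGZAG_DEG)), np.sin(np.radians(ZIGZAG_DEG))
    pos = cb
    sign = 1.0
    for name in chain_names:
        pos = pos + BOND * (axis * cos_z + up * sin_z * sign)
        atoms.append(Atom(name=name, element=_element_of(name), position=pos))
        sign = -sign
    tip, prev = pos, (atoms[-2].position if len(atoms) >= 2 else ca)
    out_dir = _unit(tip - prev)
    for k, name in enumerate(branch_names):
        side = ref if k % 2 == 0 else -ref
        bpos = tip + BOND * _unit(out_dir * 0.6 + side * 0.8)
        atoms.append(Atom(name=name, element=_element_of(name), position=bpos))
    if ring_names:
        center = tip + out_dir * RING_RADIUS
        start = np.arctan2(0.0, -1.0)  # ring atom 0 opposite the attachment
        n_ring = len(ring_names)
        for k, name in enumerate(ring_names):
            ang = start + 2.0 * np.pi * (k + 1) / (n_ring + 1)
            rpos = (center + RING_RADIUS * (np.cos(ang) * (-out_dir) +
                                            np.sin(ang) * ref))
            atoms.append(Atom(name=name, element=_element_of(name), position=rpos))
    return atoms


def ideal_residue(aa3: str, rid=None) -> Residue:
    """A free residue of type `aa3` with ideal backbone + extended side chain."""
    from .structure import ResidueID
    rid = rid or ResidueID("A", 1, "")
    n = np.array([-1.458, 0.0, 0.0])
    ca = np.array([0.0, 0.0, 0.0])
    c = np.array([0.55, 1.42, 0.0])
    o = c + np.array([1.10, 0.50, 0.0]) / np.linalg.norm([1.10, 0.50, 0.0]) * 1.23
    res = Residue(id=rid, aa3=aa3, seq_index=0, atoms=[
        Atom("N", "N", n), Atom("CA", "C", ca), Atom("C", "C", c), Atom("O", "O", o),
    ])
    res.atoms.extend(build_sidechain(res, aa3))
    return res
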