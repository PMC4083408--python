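"""Residue-level knowledge-based contact potential and shared amino-acid tables.

The pair potential is a quasi-chemical-style 20x20 contact table in the spirit of
Miyazawa-Jernigan contact energies: hydrophobic-hydrophobic contacts are strongly
favorable, polar contacts weakly so, opposite charges gain a salt-bridge bonus and
like charges pay a penalty.  Entries are generated once from the additive formula

    e(a, b) = -(H_a + H_b) + charge_term(a, b)

with per-residue interactivity strengths ``H`` (dimensionless, roughly tracking
transfer hydrophobicity) and charge_term = -1.5 for opposite charges, +1.0 for like
charges.  The scale is chosen so that a cluster of three or more strong hydrophobic
contacts exceeds the hot-spot pair-potential operating point (18.0) used by the
hotspot module.  Scores summed from this table are dimensionless "energy units"
(negative = favorable); they are not physical free energies and are not comparable
to scores printed by other docking tools.
"""

from __future__ import annotations

AA3_TO_AA1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "UNK": "X",
}
AA1_TO_AA3 = {v: k for k, v in AA3_TO_AA1.items()}
STANDARD_AA3 = frozenset(k for k in AA3_TO_AA1 if k != "UNK")
STANDARD_AA1 = frozenset(v for k, v in AA3_TO_AA1.items() if k != "UNK")

# Interactivity strengths feeding the contact table (one-letter keyed).
_STRENGTH = {
    "W": 3.1, "F": 3.0, "I": 2.8, "L": 2.8, "M": 2.6, "V": 2.4,
    "C": 2.5, "Y": 2.3, "A": 1.2, "H": 1.6, "T": 1.1, "P": 1.0,
    "G": 0.9, "S": 0.9, "Q": 1.0, "N": 0.9, "E": 0.8, "D": 0.8,
    "K": 0.7, "R": 1.0,
}
_POSITIVE = frozenset("KR")  # His treated as neutral at physiological pH
_NEGATIVE = frozenset("DE")

SALT_BRIDGE_BONUS = -1.5
LIKE_CHARGE_PENALTY = +1.0


def _charge_term(a: str, b: str) -> float:
    if (a in _POSITIVE and b in _NEGATIVE) or (a in _NEGATIVE and b in _POSITIVE):
        return SALT_BRIDGE_BONUS
    if (a in _POSITIVE and b in _POSITIVE) or (a in _NEGATIVE and b in _NEGATIVE):
        return LIKE_CHARGE_PENALTY
    return 0.0


def _build_table() -> dict[tuple[str, str], float]:
    table = {}
    for a in _STRENGTH:
        for b in _STRENGTH:
            table[(a, b)] = -(_STRENGTH[a] + _STRENGTH[b]) + _charge_term(a, b)
    return table


class PotentialTable:
    """Symmetric 20x20 residue-pair contact potential, 'X' pairs score 0."""

    def __init__(self, entries: dict[tuple[str, str], float] | None = None):
        self.entries = dict(entries) if entries is not None else _build_table()

    def get(self, aa1_a: str, aa1_b: str) -> float:
        return self.entries.get((aa1_a, aa1_b), 0.0)

    def get3(self, aa3_a: str, aa3_b: str) -> float:
        return self.get(AA3_TO_AA1.get(aa3_a, "X"), AA3_TO_AA1.get(aa3_b, "X"))


DEFAULT_POTENTIAL = PotentialTable()

# Van der Waals radii (Angstrom) for SASA; unknown elements fall back to 1.8.
VDW_RADII = {
    "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "H": 1.20, "D": 1.20, "SE": 1.90,
}
DEFAULT_VDW_RADIUS = 1.80

# Free-residue reference accessible areas (Angstrom^2): SASA of each amino acid
# built in isolation with ideal geometry, probe 1.4 A, 960 sphere points, computed
# once with this package's own sphere-sampling routine and frozen here.  Relative
# accessibility = observed residue SASA / this reference.
REFERENCE_AREA = {
    "ALA": 210.9, "ARG": 357.3, "ASN": 279.1, "ASP": 278.0, "CYS": 241.5,
    "GLN": 306.2, "GLU": 305.3, "GLY": 188.1, "HIS": 302.9, "ILE": 291.8,
    "LEU": 288.7, "LYS": 312.4, "MET": 292.9, "PHE": 317.0, "PRO": 264.7,
    "SER": 232.0, "THR": 264.0, "TRP": 323.4, "TYR": 316.2, "VAL": 256.8,
    "UNK": 210.9,
}
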