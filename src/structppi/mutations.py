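"""Somatic mutation tables, structural mapping, in-silico mutagenesis and verdicts.

Workflow: parse a COSMIC-export-like table, map each protein change onto the
modelled structure (with an explicit per-gene numbering offset and a wild-type
identity guard), classify its interface location, apply it structurally
(side-chain rebuild for missense, chain truncation for nonsense), re-run the
prediction engine with the mutant, and compare binding scores.

Verdicts: *abolished* when no clash-passing favorable (score < 0) candidate
exists for the mutant; *weakened* / *strengthened* when the score shifts by at
least `delta_threshold` energy units or changes magnitude by the ratio
threshold; otherwise *unchanged*.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import pandas as pd

from .docking import PredictedComplex, PredictionConfig, predict_interaction
from .errors import FormatError, MappingError, MutationParseError
from .interfaces import InterfaceTemplate
from .potentials import AA1_TO_AA3, DEFAULT_POTENTIAL, STANDARD_AA1, PotentialTable
from .sidechains import build_sidechain
from .structure import Chain, ResidueID, Structure, truncate_chain

log = logging.getLogger(__name__)

STOP = "*"

_CHANGE_RE = re.compile(r"^(?:p\.)?([A-Z])(\d+)([A-Z*])$")

BACKBONE_ATOMS = ("N", "CA", "C", "O", "OXT")


@dataclass
class MutationRecord:
    gene: str
    protein_change: str
    mclass: str            # missense | nonsense | coding-silent | other
    histology: str = ""
    source: str = "other"  # COSMIC | TCGA | other
    parse_ok: bool = True

    @property
    def parsed(self):
        return parse_protein_change(self.protein_change)


@dataclass
class StructureMapping:
    gene: str
    entry_id: str
    chain_id: str
    numbering_offset: int = 0  # author_number = protein position + offset


@dataclass
class MutationEffect:
    record: MutationRecord
    location: str               # contacting | nearby | non-interface | unresolved
    wt_score: float | None
    mut_score: float | None
    delta: float | None
    verdict: str                # abolished | weakened | unchanged | strengthened | not-applicable


@dataclass
class VerdictThresholds:
    delta_threshold: float = 5.0  # energy units
    ratio: float = 0.5            # |mut| <= ratio*|wt| -> weakened (and mirror)


def parse_protein_change(s: str) -> tuple[str, int, str]:
    """'R198W' -> ('R', 198, 'W'); 'E41*' -> ('E', 41, '*'); 'p.' prefix tolerated."""
    m = _CHANGE_RE.match(s.strip())
    if not m:
        raise MutationParseError(f"cannot parse protein change {s!r}")
    wt, pos, new = m.group(1), int(m.group(2)), m.group(3)
    if wt not in STANDARD_AA1:
        raise MutationParseError(f"{s!r}: invalid wild-type amino acid {wt!r}")
    if new != STOP and new not in STANDARD_AA1:
        raise MutationParseError(f"{s!r}: invalid replacement amino acid {new!r}")
    return wt, pos, new


def classify_mclass(change: str, declared: str | None = None) -> str:
    try:
        wt, _, new = parse_protein_change(change)
    except MutationParseError:
        return (declared or "other").lower()
    if new == STOP:
        return "nonsense"
    if wt == new:
        return "coding-silent"
    return "missense"


DEFAULT_COLUMNS = {
    "gene": ("gene", "gene name", "gene_name"),
    "protein_change": ("protein_change", "mutation aa", "mutation_aa", "aa mutation"),
    "mclass": ("mclass", "class", "mutation description", "mutation_description"),
    "histology": ("histology", "primary histology", "primary_histology"),
    "source": ("source",),
}


def read_mutation_table(path, columns: dict[str, tuple[str, ...]] | None = None
                        ) -> list[MutationRecord]:
    """Read a COSMIC-export-like CSV/TSV of somatic protein changes.

    Unparseable protein-change strings are kept but flagged (parse_ok=False);
    duplicated rows are preserved.  Raises FormatError when the gene or
    protein-change column cannot be found.
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep, dtype=str).fillna("")
    lower = {c.lower().strip(): c for c in df.columns}
    colmap = dict(DEFAULT_COLUMNS)
    if columns:
        colmap.update(columns)

    def find(key, mandatory=False):
        for alias in colmap[key]:
            if alias.lower() in lower:
                return lower[alias.lower()]
        if mandatory:
            raise FormatError(f"mutation table is missing a {key!r} column "
                              f"(tried {colmap[key]})")
        return None

    gene_c = find("gene", mandatory=True)
    change_c = find("protein_change", mandatory=True)
    class_c = find("mclass")
    hist_c = find("histology")
    source_c = find("source")

    records: list[MutationRecord] = []
    counts: dict[str, int] = {}
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        change = row[change_c].strip()
        if change.lower().startswith("p."):
            change = change[2:]
        declared = row[class_c].strip() if class_c else None
        try:
            parse_protein_change(change)
            ok = True
        except MutationParseError as exc:
            ok = False
            log.warning("FLAGGED-MUTATION %s", exc)
        mclass = classify_mclass(change, declared) if ok else (declared or "other")
        rec = MutationRecord(
            gene=row[gene_c].strip(), protein_change=change, mclass=mclass,
            histology=row[hist_c].strip() if hist_c else "",
            source=row[source_c].strip() if source_c else "other", parse_ok=ok)
        records.append(rec)
        counts[rec.mclass] = counts.get(rec.mclass, 0) + 1
    log.info("mutation table %s: %s", path, counts)
    return records


def map_mutation(record: MutationRecord, mapping: StructureMapping,
                 structure: Structure) -> ResidueID | None:
    """Map a record onto the structure; None = position outside the model.

    A wild-type identity mismatch raises MappingError: it signals numbering
    drift between the mutation table and the model, which must never be
    silently absorbed.
    """
    wt, pos, _ = record.parsed
    author_number = pos + mapping.numbering_offset
    chain = structure[mapping.chain_id]
    res = chain.residue_by_number(author_number)
    if res is None:
        return None
    if res.aa1 != wt:
        raise MappingError(
            f"{record.gene} {record.protein_change}: structure has {res.aa3} "
            f"({res.aa1}) at {mapping.chain_id}{author_number}, expected {wt}")
    return res.id


def classify_location(residue: ResidueID, interface: InterfaceTemplate) -> str:
    for side in (interface.side_a, interface.side_b):
        if residue in side.contacting:
            return "contacting"
        if residue in side.nearby:
            return "nearby"
    return "non-interface"


def apply_missense(structure: Structure, residue_id: ResidueID, new_aa1: str
                   ) -> Structure:
    """Substitute a residue: keep backbone (+CB where applicable), rebuild the
    side chain in an extended ideal-geometry rotamer.  No minimization."""
    new_aa3 = AA1_TO_AA3[new_aa1]
    out = structure.copy()
    chain = out[residue_id.chain_id]
    res = chain.residue(residue_id)
    if res is None:
        raise MappingError(f"residue {residue_id} absent from structure")
    if res.aa3 == new_aa3:
        return out
    backbone = [a for a in res.atoms if a.name in BACKBONE_ATOMS]
    if not any(a.name == "CA" for a in backbone):
        raise MappingError(f"{residue_id}: missing backbone, cannot mutate")
    keep_cb = res.atom("CB")
    res.aa3 = new_aa3
    res.atoms = list(backbone)
    if new_aa3 != "GLY":
        if keep_cb is not None:  # graft the new side chain onto the existing CB
            res.atoms.append(keep_cb)
        rebuilt = build_sidechain(res, new_aa3)  # rebuilt[0] is CB
        res.atoms.extend(rebuilt[1:] if keep_cb is not None else rebuilt)
    return out


def apply_nonsense(structure: Structure, residue_id: ResidueID) -> Structure:
    """Premature stop: truncate the chain at the mutated position."""
    out = structure.copy()
    out.chains[residue_id.chain_id] = truncate_chain(
        out[residue_id.chain_id], residue_id.author_number)
    return out


def apply_mutation(structure: Structure, residue_id: ResidueID, record: MutationRecord
                   ) -> Structure:
    _, _, new = record.parsed
    if new == STOP:
        return apply_nonsense(structure, residue_id)
    return apply_missense(structure, residue_id, new)


def evaluate_effect(wt_a: list[Chain], wt_b: list[Chain], mutated_side: str,
                    mutated_conformers: list[Chain],
                    library: dict[str, InterfaceTemplate],
                    config: PredictionConfig | None = None,
                    thresholds: VerdictThresholds | None = None,
                    potential_table: PotentialTable = DEFAULT_POTENTIAL,
                    record: MutationRecord | None = None,
                    location: str = "unresolved",
                    wt_prediction: PredictedComplex | None = None,
                    ) -> MutationEffect:
    """Re-run the prediction engine with the mutant and compare binding scores.

    `mutated_side` is 'a' or 'b'.  Coding-silent records bypass the engine: by
    definition they cannot change the structure, so the wild-type score is
    reported unchanged.
    """
    if mutated_side not in ("a", "b"):
        raise ValueError("mutated_side must be 'a' or 'b'")
    config = config or PredictionConfig()
    thresholds = thresholds or VerdictThresholds()
    wt = wt_prediction or predict_interaction(wt_a, wt_b, library, config,
                                              potential_table)
    if wt is None or wt.energy_score >= 0:
        return MutationEffect(record=record, location=location, wt_score=None,
                              mut_score=None, delta=None, verdict="not-applicable")
    wt_score = wt.energy_score
    if record is not None and record.mclass == "coding-silent":
        return MutationEffect(record=record, location=location, wt_score=wt_score,
                              mut_score=wt_score, delta=0.0, verdict="unchanged")
    if mutated_side == "a":
        mut = predict_interaction(mutated_conformers, wt_b, library, config,
                                  potential_table)
    else:
        mut = predict_interaction(wt_a, mutated_conformers, library, config,
                                  potential_table)
    if mut is None or mut.energy_score >= 0:
        mut_score = mut.energy_score if mut is not None else None
        return MutationEffect(record=record, location=location, wt_score=wt_score,
                              mut_score=mut_score, delta=None, verdict="abolished")
    mut_score = mut.energy_score
    delta = mut_score - wt_score
    t = thresholds
    if delta >= t.delta_threshold or abs(mut_score) <= t.ratio * abs(wt_score):
        verdict = "weakened"
    elif delta <= -t.delta_threshold or abs(mut_score) >= abs(wt_score) / t.ratio:
        verdict = "strengthened"
    else:
        verdict = "unchanged"
    return MutationEffect(record=record, location=location, wt_score=wt_score,
                          mut_score=mut_score, delta=delta, verdict=verdict)


def effect_report(effects: list[MutationEffect]) -> str:
    lines = ["gene\tprotein_change\tmclass\tlocation\twt_score\tmut_score\tdelta\tverdict"]
    for e in effects:
        rec = e.record
        fmt = lambda v: f"{v:.2f}" if v is not None else "N/A"
        lines.append(f"{rec.gene if rec else '-'}\t"
                     f"{rec.protein_change if rec else '-'}\t"
                     f"{rec.mclass if rec else '-'}\t{e.location}\t"
                     f"{fmt(e.wt_score)}\t{fmt(e.mut_score)}\t{fmt(e.delta)}\t"
                     f"{e.verdict}")
    return "\n".join(lines) + "\n"
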