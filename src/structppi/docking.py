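"""Template-based interaction prediction (rigid motif matching).

Two targets are docked by structurally matching each onto one side of a known
interface template, transplanting both into the template frame, filtering on
steric clashes, and scoring the resulting pose with the residue-level contact
potential plus a hot-spot bonus.  Ensemble inputs (several conformers per
target) are all tried and the best clash-passing, lowest-energy candidate wins;
ties break lexicographically on (template id, conformer labels) so results are
bit-reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .errors import GeometryError, LibraryError, StructPPIError
from .geometry import AlignmentResult, RigidTransform, align_coords, kabsch_superpose
from .interfaces import InterfaceSide, InterfaceTemplate
from .potentials import DEFAULT_POTENTIAL, PotentialTable
from .structure import Chain, Structure, sequence_of

log = logging.getLogger(__name__)

MATCH_PAIR_DISTANCE = 3.0  # A, a template residue counts as matched below this


@dataclass
class PredictionConfig:
    min_residues: int = 15            # engine size rule (fixed by protocol)
    min_matched_fraction: float = 0.5
    interface_identity_min: float = 0.5  # conservation of matched contacting residues
    max_clashes: int = 5
    clash_distance: float = 2.5       # A, heavy-atom
    potential_contact_distance: float = 6.5  # A, CB-CB (CA for Gly)
    hotspot_match_min: int = 1
    hotspot_bonus: float = -1.0       # energy units per matched template hot spot

    def __post_init__(self):
        if self.min_residues != 15:
            raise ValueError("min_residues is fixed at 15 by the prediction protocol")
        for name in ("min_matched_fraction", "max_clashes", "clash_distance",
                     "potential_contact_distance", "hotspot_match_min"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class SideMatch:
    alignment: AlignmentResult
    matched_fraction: float
    hotspot_matches: int


@dataclass
class PredictedComplex:
    target_a: str
    target_b: str
    template_id: str
    transform_a: RigidTransform
    transform_b: RigidTransform
    pose: Structure
    energy_score: float
    matched_fraction_a: float
    matched_fraction_b: float
    hotspot_matches: int
    clash_count: int
    conformer_a: str | None = None
    conformer_b: str | None = None


class SizeRuleRejection(StructPPIError):
    """Target below the 15-residue size rule (distinct from geometric failure)."""


def match_side(target: Chain, side: InterfaceSide, config: PredictionConfig,
               hotspots: set | None = None) -> SideMatch | None:
    """Match a target chain onto one interface side.

    Accepts iff (i) >= min_matched_fraction of the side's contacting residues
    pair within 3 A post-superposition, (ii) at least `hotspot_match_min`
    template hot spots (when any are annotated) are among the paired residues,
    and (iii) at least `interface_identity_min` of the paired contacting
    residues conserve their residue type in the target — the interface-motif
    conservation requirement that keeps geometrically promiscuous folds (e.g.
    any helix on any helical motif) from matching arbitrary templates.
    """
    target_res = target.residues_with_ca()
    if len(target_res) < config.min_residues:
        raise SizeRuleRejection(
            f"target {target.id} has {len(target_res)} residues (< "
            f"{config.min_residues})")
    side_res = [r for r in side.ordered_residues() if r.ca is not None]
    if len(side_res) < 3:
        return None
    A = np.array([r.ca.position for r in target_res])
    B = np.array([r.ca.position for r in side_res])
    # numbering prior: template side residues carry their source-chain seq_index,
    # a reasonable initial correspondence for homologous targets
    tgt_by_seq = {r.seq_index: k for k, r in enumerate(target_res)}
    seq_seed = [(tgt_by_seq[r.seq_index], j) for j, r in enumerate(side_res)
                if r.seq_index in tgt_by_seq]
    try:
        with warnings.catch_warnings():
            # small interface sides routinely trip the TM d0 floor; expected here
            warnings.simplefilter("ignore", UserWarning)
            aln = align_coords(A, B, "".join(r.aa1 for r in target_res),
                               "".join(r.aa1 for r in side_res),
                               L_target=len(side_res),
                               extra_seeds=[seq_seed] if len(seq_seed) >= 3 else None)
    except GeometryError:
        return None
    moved = aln.transform.apply(A)
    matched_side_rids = set()
    identical = 0
    for ti, sj in aln.pairs:
        if np.linalg.norm(moved[ti] - B[sj]) < MATCH_PAIR_DISTANCE:
            matched_side_rids.add(side_res[sj].id)
            if side_res[sj].id in side.contacting and \
                    side_res[sj].aa1 == target_res[ti].aa1:
                identical += 1
    n_contact = max(len(side.contacting), 1)
    matched_contacting = len(matched_side_rids & side.contacting)
    frac = matched_contacting / n_contact
    hs = hotspots if hotspots is not None else set()
    hs_matched = len(matched_side_rids & hs)
    if frac < config.min_matched_fraction:
        return None
    if matched_contacting and identical / matched_contacting < config.interface_identity_min:
        return None
    if hs and hs_matched < config.hotspot_match_min:
        return None
    return SideMatch(alignment=aln, matched_fraction=frac, hotspot_matches=hs_matched)


def assemble_pose(target_a: Chain, align_a: AlignmentResult, target_b: Chain,
                  align_b: AlignmentResult,
                  template: InterfaceTemplate) -> Structure:
    """Transplant both targets into the template frame; chain ids A/B kept."""
    pose = Structure(entry_id=f"pose_{template.template_id}")
    for chain, aln in ((target_a, align_a), (target_b, align_b)):
        moved = chain.copy()
        for res in moved.residues:
            for atom in res.atoms:
                atom.position = aln.transform.apply(atom.position[None, :])[0]
        if moved.id in pose.chains:  # identical chain labels: relabel second side
            from .structure import ResidueID
            moved.id = "B" if moved.id != "B" else "C"
            for res in moved.residues:
                res.id = ResidueID(moved.id, res.id.author_number, res.id.insertion_code)
        pose.add_chain(moved)
    return pose


def clash_filter(pose: Structure, config: PredictionConfig) -> tuple[bool, int]:
    """Count inter-chain heavy-atom pairs below the clash distance."""
    ids = list(pose.chains)
    if len(ids) != 2:
        raise ValueError("clash_filter expects a two-chain pose")
    A = pose[ids[0]].heavy_coords()
    B = pose[ids[1]].heavy_coords()
    if len(A) == 0 or len(B) == 0:
        return True, 0
    count = int(np.count_nonzero(cdist(A, B) < config.clash_distance))
    return count <= config.max_clashes, count


def score_energy(pose: Structure, potential_table: PotentialTable = DEFAULT_POTENTIAL,
                 contact_distance: float = 6.5) -> float:
    """Contact-potential sum over inter-chain residue pairs within range.

    Residue positions are taken at CB (CA for Gly); residues lacking both are
    skipped with a warning.  Symmetric under chain relabelling.
    """
    ids = list(pose.chains)
    if len(ids) != 2:
        raise ValueError("score_energy expects a two-chain pose")
    sides = []
    for cid in ids:
        pts, aas = [], []
        for res in pose[cid].residues:
            anchor = res.scoring_atom
            if anchor is None:
                log.warning("SKIP-SCORE residue %s has neither CB nor CA", res.id)
                continue
            pts.append(anchor.position)
            aas.append(res.aa1)
        sides.append((np.array(pts) if pts else np.empty((0, 3)), aas))
    (PA, aa_a), (PB, aa_b) = sides
    if len(PA) == 0 or len(PB) == 0:
        return 0.0
    D = cdist(PA, PB)
    total = 0.0
    for i, j in np.argwhere(D < contact_distance):
        total += potential_table.get(aa_a[i], aa_b[j])
    return float(total)


def _conformer_key(chain: Chain) -> str:
    return chain.conformer_label or chain.id


def predict_interaction(targets_a: list[Chain], targets_b: list[Chain],
                        library: dict[str, InterfaceTemplate],
                        config: PredictionConfig | None = None,
                        potential_table: PotentialTable = DEFAULT_POTENTIAL,
                        ) -> PredictedComplex | None:
    """Best clash-passing pose over all conformer/template/side combinations."""
    if not library:
        raise LibraryError("empty template library")
    config = config or PredictionConfig()

    def usable(chains: list[Chain]) -> list[Chain]:
        kept = []
        for c in chains:
            if len(c.residues_with_ca()) < config.min_residues:
                log.warning("SIZE-RULE skipping conformer %s (%d residues)",
                            _conformer_key(c), len(c.residues_with_ca()))
            else:
                kept.append(c)
        return kept

    ua = usable(targets_a)
    ub = usable(targets_b)
    candidates: list[tuple] = []
    for tkey in sorted(library):
        tpl = library[tkey]
        assignments = [(tpl.side_a, tpl.hotspots_a, tpl.side_b, tpl.hotspots_b, False),
                       (tpl.side_b, tpl.hotspots_b, tpl.side_a, tpl.hotspots_a, True)]
        for ca in ua:
            for cb in ub:
                for side_x, hs_x, side_y, hs_y, swapped in assignments:
                    try:
                        ma = match_side(ca, side_x, config, hs_x)
                        mb = match_side(cb, side_y, config, hs_y)
                    except SizeRuleRejection:
                        continue
                    if ma is None or mb is None:
                        continue
                    pose = assemble_pose(ca, ma.alignment, cb, mb.alignment, tpl)
                    ok, n_clash = clash_filter(pose, config)
                    if not ok:
                        continue
                    hs_matches = ma.hotspot_matches + mb.hotspot_matches
                    energy = (score_energy(pose, potential_table,
                                           config.potential_contact_distance)
                              + config.hotspot_bonus * hs_matches)
                    candidates.append((
                        energy, tkey, _conformer_key(ca), _conformer_key(cb),
                        PredictedComplex(
                            target_a=ca.id, target_b=cb.id, template_id=tkey,
                            transform_a=ma.alignment.transform,
                            transform_b=mb.alignment.transform,
                            pose=pose, energy_score=energy,
                            matched_fraction_a=ma.matched_fraction,
                            matched_fraction_b=mb.matched_fraction,
                            hotspot_matches=hs_matches, clash_count=n_clash,
                            conformer_a=ca.conformer_label,
                            conformer_b=cb.conformer_label)))
    if not candidates:
        return None
    candidates.sort(key=lambda t: (t[0], t[1], t[2], t[3]))
    return candidates[0][4]


def ternary_compatibility(pose_ab: PredictedComplex, pose_ac: PredictedComplex,
                          shared: str, config: PredictionConfig | None = None,
                          ) -> tuple[bool, int]:
    """Can B and C bind the shared partner simultaneously without clashing?

    Superposes the shared chain of pose_ac onto that of pose_ab (CA Kabsch) and
    counts heavy-atom clashes between the two non-shared chains.
    """
    config = config or PredictionConfig()
    for pose in (pose_ab.pose, pose_ac.pose):
        if shared not in pose.chains:
            raise ValueError(f"shared chain {shared!r} absent from pose")
    sa = pose_ab.pose[shared]
    sb = pose_ac.pose[shared]
    if sequence_of(sa) != sequence_of(sb):
        raise StructPPIError("shared chain sequence mismatch between poses")
    tr = kabsch_superpose(sb.ca_coords(), sa.ca_coords())
    other_ab = next(c for cid, c in pose_ab.pose.chains.items() if cid != shared)
    other_ac = next(c for cid, c in pose_ac.pose.chains.items() if cid != shared)
    B = other_ab.heavy_coords()
    C = tr.apply(other_ac.heavy_coords())
    n = int(np.count_nonzero(cdist(B, C) < config.clash_distance))
    return n <= config.max_clashes, n


def prediction_report(predictions: list[PredictedComplex]) -> str:
    lines = ["target_a\tconformer_a\ttarget_b\tconformer_b\ttemplate_id\t"
             "energy_score\tmatched_fraction_a\tmatched_fraction_b\tclash_count"]
    for p in predictions:
        lines.append(f"{p.target_a}\t{p.conformer_a or '-'}\t{p.target_b}\t"
                     f"{p.conformer_b or '-'}\t{p.template_id}\t"
                     f"{p.energy_score:.2f}\t{p.matched_fraction_a:.2f}\t"
                     f"{p.matched_fraction_b:.2f}\t{p.clash_count}")
    return "\n".join(lines) + "\n"
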