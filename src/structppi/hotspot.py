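"""Solvent accessibility and computational hot-spot identification.

Hot spots are interface residues that contribute disproportionately to binding.
Following the operating point of burial-plus-potential hot-spot predictors, a
contacting residue is called a hot spot iff

    relative SASA in the complex <= rel_asa_max  (default 0.20)
    AND  sum of favorable pair potentials to cross-interface partners
         within the contact distance >= potential_min  (default 18.0)
    AND, when a conservation map is supplied, conservation >= the per-chain
         median.

SASA uses Shrake-Rupley-style even sphere sampling (deterministic golden-spiral
points), heavy atoms only, probe 1.4 A.  Relative accessibility divides by the
free-residue reference areas shipped in `potentials.REFERENCE_AREA`.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .interfaces import InterfaceTemplate
from .potentials import (DEFAULT_POTENTIAL, DEFAULT_VDW_RADIUS, REFERENCE_AREA,
                         VDW_RADII, PotentialTable)
from .structure import Chain, ResidueID, Structure

log = logging.getLogger(__name__)

PROBE_RADIUS = 1.4
N_SPHERE_POINTS = 960
REL_ASA_MAX = 0.20
POTENTIAL_MIN = 18.0
POTENTIAL_CONTACT_DISTANCE = 6.5  # A, CB-CB (CA for Gly)


@dataclass
class ResidueSASA:
    residue: ResidueID
    area: float      # A^2
    relative: float  # fraction of the residue type's reference area


@dataclass
class HotSpotCall:
    residue: ResidueID
    rel_asa_complex: float
    rel_asa_monomer: float
    potential_sum: float
    conservation: float | None
    is_hotspot: bool


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic near-even unit-sphere sampling (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.stack([np.cos(theta) * np.sin(phi),
                     np.sin(theta) * np.sin(phi),
                     np.cos(phi)], axis=1)


def _radius_of(element: str) -> float:
    r = VDW_RADII.get(element.upper())
    if r is None:
        warnings.warn(f"unknown element {element!r}: using default vdW radius "
                      f"{DEFAULT_VDW_RADIUS} A")
        return DEFAULT_VDW_RADIUS
    return r


def sasa(structure: Structure, probe: float = PROBE_RADIUS,
         points: int = N_SPHERE_POINTS) -> dict[ResidueID, ResidueSASA]:
    """Per-residue solvent-accessible surface area over all chains of `structure`."""
    coords, radii, owners = [], [], []
    residues: list = []
    for chain in structure.chains.values():
        for res in chain.residues:
            ridx = len(residues)
            residues.append(res)
            for atom in res.atoms:
                if atom.is_heavy:
                    coords.append(atom.position)
                    radii.append(_radius_of(atom.element))
                    owners.append(ridx)
    if not coords:
        return {}
    coords = np.asarray(coords)
    radii = np.asarray(radii)
    owners = np.asarray(owners)
    sphere = _sphere_points(points)
    tree = cKDTree(coords)
    max_reach = 2.0 * (radii.max() + probe)
    areas = np.zeros(len(residues))
    for i in range(len(coords)):
        ri = radii[i] + probe
        test = coords[i] + ri * sphere
        neighbors = [j for j in tree.query_ball_point(coords[i], max_reach) if j != i]
        accessible = np.ones(points, dtype=bool)
        for j in neighbors:
            rj = radii[j] + probe
            d2 = np.sum((test - coords[j]) ** 2, axis=1)
            accessible &= d2 > rj * rj
        areas[owners[i]] += 4.0 * np.pi * ri * ri * accessible.mean()
    out: dict[ResidueID, ResidueSASA] = {}
    for res, area in zip(residues, areas):
        ref = REFERENCE_AREA.get(res.aa3, REFERENCE_AREA["UNK"])
        out[res.id] = ResidueSASA(residue=res.id, area=float(area),
                                  relative=float(area / ref))
    return out


def _single_chain_structure(chain: Chain) -> Structure:
    s = Structure(entry_id=f"_{chain.id}")
    s.add_chain(chain)
    return s


def find_hotspots(pose: Structure, interface: InterfaceTemplate,
                  potential_table: PotentialTable = DEFAULT_POTENTIAL,
                  conservation: dict[ResidueID, float] | None = None,
                  rel_asa_max: float = REL_ASA_MAX,
                  potential_min: float = POTENTIAL_MIN,
                  contact_distance: float = POTENTIAL_CONTACT_DISTANCE,
                  ) -> list[HotSpotCall]:
    """Call hot spots among the contacting residues of `interface` on `pose`."""
    complex_sasa = sasa(pose)
    calls: list[HotSpotCall] = []
    chain_ids = list(pose.chains)
    if len(chain_ids) != 2:
        raise ValueError("find_hotspots expects a two-chain pose")
    sides = {chain_ids[0]: chain_ids[1], chain_ids[1]: chain_ids[0]}
    monomer_sasa: dict[ResidueID, ResidueSASA] = {}
    for cid in chain_ids:
        monomer_sasa.update(sasa(_single_chain_structure(pose[cid].copy())))

    medians: dict[str, float] = {}
    if conservation:
        for cid in chain_ids:
            vals = [v for rid, v in conservation.items() if rid.chain_id == cid]
            if vals:
                medians[cid] = float(np.median(vals))

    contacting = [rid for side in (interface.side_a, interface.side_b)
                  for rid in sorted(side.contacting)]
    for rid in contacting:
        if rid.chain_id not in pose.chains:
            continue
        res = pose[rid.chain_id].residue(rid)
        if res is None or rid not in complex_sasa:
            log.warning("SKIP-SASA residue %s missing from pose", rid)
            continue
        partner_chain = pose[sides[rid.chain_id]]
        anchor = res.scoring_atom
        psum = 0.0
        if anchor is not None:
            for pres in partner_chain.residues:
                patom = pres.scoring_atom
                if patom is None:
                    continue
                if np.linalg.norm(anchor.position - patom.position) < contact_distance:
                    psum += -potential_table.get(res.aa1, pres.aa1)
        cons = conservation.get(rid) if conservation else None
        is_hs = (complex_sasa[rid].relative <= rel_asa_max and psum >= potential_min)
        if conservation and rid.chain_id in medians:
            is_hs = is_hs and (cons is not None and cons >= medians[rid.chain_id])
        calls.append(HotSpotCall(
            residue=rid,
            rel_asa_complex=complex_sasa[rid].relative,
            rel_asa_monomer=monomer_sasa.get(rid, complex_sasa[rid]).relative,
            potential_sum=psum,
            conservation=cons,
            is_hotspot=is_hs,
        ))
    return calls


def hotspot_sets(pose: Structure, interface: InterfaceTemplate, **kwargs
                 ) -> tuple[set[ResidueID], set[ResidueID]]:
    """Hot-spot residue sets for the two sides, for template-library storage."""
    calls = find_hotspots(pose, interface, **kwargs)
    hs = {c.residue for c in calls if c.is_hotspot}
    return (hs & interface.side_a.contacting, hs & interface.side_b.contacting)


def hotspot_report(calls: list[HotSpotCall]) -> str:
    lines = ["chain\tresidue\trel_asa_complex\trel_asa_monomer\tpotential_sum"
             "\tconservation\tcall"]
    for c in calls:
        cons = f"{c.conservation:.3f}" if c.conservation is not None else "NA"
        lines.append(f"{c.residue.chain_id}\t{c.residue.author_number}"
                     f"{c.residue.insertion_code}\t{c.rel_asa_complex:.3f}\t"
                     f"{c.rel_asa_monomer:.3f}\t{c.potential_sum:.2f}\t{cons}\t"
                     f"{'hotspot' if c.is_hotspot else '-'}")
    return "\n".join(lines) + "\n"


def read_conservation(path) -> dict[ResidueID, float]:
    """TSV: chain, author_number, score."""
    import pandas as pd
    df = pd.read_csv(path, sep="\t", dtype={"chain": str})
    missing = {"chain", "author_number", "score"} - set(df.columns)
    if missing:
        from .errors import FormatError
        raise FormatError(f"conservation file missing columns: {sorted(missing)}")
    return {ResidueID(r.chain, int(r.author_number), ""): float(r.score)
            for r in df.itertuples()}
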