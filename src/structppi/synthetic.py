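"""Seeded generators for every input class the pipeline consumes.

These stand in for the study-style inputs (complex structures, somatic
mutation exports, seed-centered interaction lists) so that the full pipeline is
exercisable offline.  Complexes are schematic two-helix bundles: two ideal
alpha-helices packed face to face with an exactly controlled number of
contacting residue pairs, a designed buried hot-spot pair given high-potential
residue types (interface side chains tilted into the core, the real-interface
feature the hot-spot caller keys on), and everything returned with its ground
truth so each analysis stage can be checked against construction.

All randomness flows through one numpy Generator derived from FixtureSpec.seed;
identical specs produce bit-identical output.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .errors import StructPPIError
from .interfaces import InterfaceTemplate, extract_interface
from .structure import Atom, Chain, Residue, ResidueID, Structure

HELIX_RISE = 1.5          # A per residue
HELIX_TURN = 100.0        # degrees per residue
HELIX_RADIUS = 2.3        # A, CA circle
CB_LENGTH = 1.53          # A, CA->CB

HOT_AA = "TRP"            # high-potential residue type at designed hot spots


@dataclass
class FixtureSpec:
    seed: int
    n_complexes: int = 1
    chain_length: int = 40
    n_contacts: int = 6
    noise: float = 0.1  # coordinate jitter sigma, A

    def __post_init__(self):
        if min(self.seed, self.n_complexes, self.chain_length, self.n_contacts) < 0 \
                or self.noise < 0:
            raise ValueError("FixtureSpec fields must be non-negative")


def make_helix(n: int, start=(0.0, 0.0, 0.0), chain_id: str = "A",
               sequence: str | None = None, phase_deg: float = 0.0,
               first_author_number: int = 1) -> Chain:
    """Ideal poly-Ala alpha-helix backbone (N, CA, C, O, CB), axis along +z."""
    if n < 15:
        raise StructPPIError(f"helix of {n} residues is below the 15-residue "
                             "engine size rule")
    if sequence is not None and len(sequence) != n:
        raise StructPPIError("sequence length must equal n")
    start = np.asarray(start, dtype=float)
    chain = Chain(id=chain_id)
    from .potentials import AA1_TO_AA3
    for i in range(n):
        theta = np.radians(phase_deg + HELIX_TURN * i)
        z = HELIX_RISE * i
        radial = np.array([np.cos(theta), np.sin(theta), 0.0])
        ca = start + HELIX_RADIUS * radial + np.array([0.0, 0.0, z])
        tn = np.radians(phase_deg + HELIX_TURN * i - 28.0)
        tc = np.radians(phase_deg + HELIX_TURN * i + 28.0)
        npos = start + 1.6 * np.array([np.cos(tn), np.sin(tn), 0.0]) \
            + np.array([0.0, 0.0, z - 0.9])
        cpos = start + 1.7 * np.array([np.cos(tc), np.sin(tc), 0.0]) \
            + np.array([0.0, 0.0, z + 0.7])
        opos = cpos + np.array([0.0, 0.0, 1.23])
        cb = ca + CB_LENGTH * radial
        aa3 = AA1_TO_AA3[sequence[i]] if sequence else "ALA"
        res = Residue(id=ResidueID(chain_id, first_author_number + i, ""),
                      aa3=aa3, seq_index=i,
                      atoms=[Atom("N", "N", npos), Atom("CA", "C", ca),
                             Atom("C", "C", cpos), Atom("O", "O", opos)])
        if aa3 != "GLY":
            res.atoms.append(Atom("CB", "C", cb))
        chain.residues.append(res)
    return chain


def _jitter(chain: Chain, rng: np.random.Generator, sigma: float) -> None:
    for res in chain.residues:
        for atom in res.atoms:
            atom.position = atom.position + rng.normal(0.0, sigma, 3)


def _point_cb_at(res: Residue, direction: np.ndarray) -> None:
    ca = res.atom("CA")
    cb = res.atom("CB")
    if ca is None or cb is None:
        return
    d = np.asarray(direction, dtype=float)
    cb.position = ca.position + CB_LENGTH * d / np.linalg.norm(d)


def _contact_pairs(chain_a: Chain, chain_b: Chain, cutoff: float = 5.0):
    from scipy.spatial.distance import cdist

    def stack(chain):
        pts, owner = [], []
        for i, r in enumerate(chain.residues):
            for atom in r.atoms:
                if atom.is_heavy:
                    pts.append(atom.position)
                    owner.append(i)
        return np.array(pts), np.array(owner)

    A, oa = stack(chain_a)
    B, ob = stack(chain_b)
    hits = np.argwhere(cdist(A, B) < cutoff)
    return {(int(oa[i]), int(ob[j])) for i, j in hits}


@dataclass
class ComplexGroundTruth:
    structure: Structure
    template: InterfaceTemplate
    hotspots: dict[str, set[ResidueID]]   # chain id -> designed hot spots
    contact_index_pairs: set[tuple[int, int]]
    hot_index_a: int
    hot_index_b: int


CORE_BETA_DEG = 100.0     # lean of the central hot-spot side chain off the radial
SPLAY_SLOPE = 0.25        # A of extra axis separation per A of height off the core
SIDECHAIN_REACH = 2.3  # A, CB + CG stub of core tryptophans


def _set_sidechain(res: Residue, direction: np.ndarray, with_cg: bool) -> None:
    ca = res.atom("CA").position
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    cb = res.atom("CB")
    if cb is None:
        cb = Atom("CB", "C", ca + CB_LENGTH * d)
        res.atoms.append(cb)
    else:
        cb.position = ca + CB_LENGTH * d
    if with_cg and res.atom("CG") is None:
        res.atoms.append(Atom("CG", "C", ca + SIDECHAIN_REACH * d))


def _to_gly(res: Residue) -> None:
    res.aa3 = "GLY"
    res.atoms = [a for a in res.atoms if a.name in ("N", "CA", "C", "O")]


def make_complex(spec: FixtureSpec) -> ComplexGroundTruth:
    """Two-helix complex with exactly `spec.n_contacts` contacting residue pairs.

    The interface is a designed dense core: a central tryptophan pair plus its
    four flanking tryptophans carry CB+CG stubs aimed into the inter-helix gap
    (the fixture analog of interface side chains packing into a binding core),
    otherwise-facing positions are glycine, and the partner helix is splayed
    slightly away from the core so contacts concentrate there.  The axis
    separation is scanned until the heavy-atom contact scan reports the
    requested count.  The central pair satisfies the hot-spot thresholds by
    construction (buried, >= 3 strong cross-partners each); ground truth is
    returned alongside.  Raises after 100 failed packing attempts.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.chain_length
    if L < 30:
        raise StructPPIError("make_complex needs chain_length >= 30")
    i_hot = min(int(round(L * 0.65)), L - 3)
    j_hot = 11  # early interface on chain B: upstream truncations fall below
    #             the engine size rule, as for a receptor losing its ectodomain
    z_core = HELIX_RISE * i_hot
    beta = np.radians(CORE_BETA_DEG)

    def build(d: float, jit: np.ndarray, noise_seed: int):
        seq_a, seq_b = ["A"] * L, ["A"] * L
        for k in (-1, 0, 1):
            seq_a[i_hot + k] = "W"
            seq_b[j_hot + k] = "W"
        phase_a = -HELIX_TURN * i_hot
        phase_b = 180.0 - HELIX_TURN * j_hot
        z0 = HELIX_RISE * (i_hot - j_hot)
        a = make_helix(L, (0.0, 0.0, 0.0), "A", "".join(seq_a), phase_a)
        b = make_helix(L, (d, 0.0, z0), "B", "".join(seq_b), phase_b)
        # splay the partner helix away from the core height
        for res in b.residues:
            for atom in res.atoms:
                atom.position = atom.position + np.array(
                    [SPLAY_SLOPE * abs(atom.position[2] - z_core), 0.0, 0.0])
        # glycine at facing positions outside the core (no side chain to touch)
        for chain, hot in ((a, i_hot), (b, j_hot)):
            for idx, res in enumerate(chain.residues):
                if abs(idx - hot) > 1 and np.cos(np.radians(HELIX_TURN * (idx - hot))) > 0.5:
                    _to_gly(res)
        # central hot-spot side chains lean off-radial into the gap
        ca_a = a.residues[i_hot].atom("CA").position
        ca_b = b.residues[j_hot].atom("CA").position
        dir_a0 = np.array([np.cos(beta), 0.0, np.sin(beta)])
        dir_b0 = np.array([-np.cos(beta), 0.0, np.sin(beta)])
        _set_sidechain(a.residues[i_hot], dir_a0, with_cg=True)
        _set_sidechain(b.residues[j_hot], dir_b0, with_cg=True)
        tip_a = ca_a + CB_LENGTH * dir_a0  # partner flankers aim at the CB itself
        tip_b = ca_b + CB_LENGTH * dir_b0
        # flanking tryptophans aim at the partner's central tip (jittered)
        perp = np.array([0.0, 1.0, 0.0])
        for m, (chain, k, target) in enumerate((
                (a, i_hot - 1, tip_b), (a, i_hot + 1, tip_b),
                (b, j_hot - 1, tip_a), (b, j_hot + 1, tip_a))):
            res = chain.residues[k]
            u = target - res.atom("CA").position
            u = u / np.linalg.norm(u)
            u = u + jit[m] * perp
            _set_sidechain(res, u, with_cg=True)
        _jitter(a, np.random.default_rng(noise_seed), spec.noise)
        _jitter(b, np.random.default_rng(noise_seed + 1), spec.noise)
        return a, b

    for _attempt in range(100):
        jit = rng.uniform(-0.15, 0.15, size=4)
        noise_seed = int(rng.integers(0, 2 ** 30))
        found = None
        d = 10.5
        while d > 6.0:
            a, b = build(float(d), jit, noise_seed)
            pairs = _contact_pairs(a, b)
            if len(pairs) >= spec.n_contacts:
                clashes = _contact_pairs(a, b, cutoff=2.5)
                if len(pairs) == spec.n_contacts and len(clashes) <= 2:
                    found = (a, b, pairs)
                break
            d -= 0.03
        if found is not None:
            a, b, pairs = found
            structure = Structure(entry_id=f"syn{spec.seed}")
            structure.add_chain(a)
            structure.add_chain(b)
            template = extract_interface(structure, "A", "B")
            hs_a = {a.residues[i_hot].id}
            hs_b = {b.residues[j_hot].id}
            template.hotspots_a = set(hs_a)
            template.hotspots_b = set(hs_b)
            return ComplexGroundTruth(
                structure=structure, template=template,
                hotspots={"A": hs_a, "B": hs_b},
                contact_index_pairs=pairs,
                hot_index_a=i_hot, hot_index_b=j_hot)
    raise StructPPIError(f"packing failed after 100 attempts (spec={spec})")


# ---------------------------------------------------------------------------
# Mutation tables


def make_mutation_table(spec: FixtureSpec, truth: ComplexGroundTruth,
                        gene_a: str = "PROTA", gene_b: str = "PROTB",
                        include_malformed: bool = False) -> str:
    """COSMIC-export-like CSV hitting hot-spot / non-interface / upstream
    positions of the fixture; returns the CSV text."""
    a = truth.structure["A"]
    b = truth.structure["B"]
    hot_a = a.residues[truth.hot_index_a]
    contacts_b = sorted(j for _, j in truth.contact_index_pairs)
    first_contact_b = b.residues[contacts_b[0]]
    far_idx = next(i for i, r in enumerate(a.residues)
                   if r.aa3 == "ALA" and all(abs(i - ci) > 2
                                             for ci, _ in truth.contact_index_pairs)
                   and abs(i - truth.hot_index_a) > 2)
    far_a = a.residues[far_idx]
    rows = [
        "gene,protein_change,mclass,histology,source",
        f"{gene_a},{hot_a.aa1}{hot_a.id.author_number}G,missense,"
        "carcinoma,COSMIC",
        f"{gene_a},{far_a.aa1}{far_a.id.author_number}V,missense,"
        "adenocarcinoma,COSMIC",
        f"{gene_b},{first_contact_b.aa1}{first_contact_b.id.author_number}*,"
        "nonsense,lung adenocarcinoma,TCGA",
        f"{gene_b},{b.residues[-1].aa1}{b.residues[-1].id.author_number}*,"
        "nonsense,carcinoma,COSMIC",
        f"{gene_a},{far_a.aa1}{far_a.id.author_number}{far_a.aa1},"
        "coding-silent,carcinoma,COSMIC",
    ]
    if include_malformed:
        rows.append(f"{gene_a},X99Z!,other,carcinoma,other")
    return "\n".join(rows) + "\n"


# ---------------------------------------------------------------------------
# Seed-centered network fixtures


def make_network_fixture(seed_label: str = "IL10", n_first: int = 4,
                         n_second: int = 45, n_extra_edges: int = 22,
                         n_below_threshold: int = 3, rng_seed: int = 0,
                         ) -> tuple[str, str]:
    """Star + second shell emulating a seed-centered interaction export.

    Returns (protein_list_csv, edge_list_csv).  One second-shell protein is
    attached only by a below-threshold edge (emulating a listed but
    unmodelable entry); a few more below-threshold and reversed-duplicate
    edges exercise the loader's filtering and deduplication.
    """
    rng = np.random.default_rng(rng_seed)
    firsts = [f"F{i+1:02d}" for i in range(n_first)]
    seconds = [f"S{i+1:02d}" for i in range(n_second)]
    proteins = [(seed_label, 0)] + [(f, 1) for f in firsts] + [(s, 2) for s in seconds]
    edges: list[tuple[str, str, float]] = []
    for f in firsts:
        edges.append((seed_label, f, round(float(rng.uniform(0.7, 0.99)), 3)))
    weak = seconds[-1]  # listed, but its only edge fails the confidence filter
    for s in seconds:
        f = firsts[int(rng.integers(0, n_first))]
        conf = 0.3 if s == weak else round(float(rng.uniform(0.45, 0.99)), 3)
        edges.append((f, s, conf))
    strong_seconds = seconds[:-1]
    existing = {tuple(sorted((a, b))) for a, b, _ in edges}
    added = 0
    while added < n_extra_edges:
        x, y = rng.choice(len(strong_seconds), size=2, replace=False)
        key = tuple(sorted((strong_seconds[int(x)], strong_seconds[int(y)])))
        if key in existing:
            continue
        existing.add(key)
        edges.append((key[0], key[1], round(float(rng.uniform(0.5, 0.99)), 3)))
        added += 1
    added = 0
    while added < n_below_threshold:
        x, y = rng.choice(len(strong_seconds), size=2, replace=False)
        key = tuple(sorted((strong_seconds[int(x)], strong_seconds[int(y)])))
        if key in existing:
            continue
        existing.add(key)
        edges.append((key[0], key[1], round(float(rng.uniform(0.05, 0.39)), 3)))
        added += 1
    # a reversed duplicate of the first seed edge, lower confidence (dedup keeps max)
    a0, b0, c0 = edges[0]
    edges.append((b0, a0, round(max(c0 - 0.2, 0.41), 3)))

    pbuf = io.StringIO()
    pbuf.write("protein,degree\n")
    for p, d in proteins:
        pbuf.write(f"{p},{d}\n")
    ebuf = io.StringIO()
    ebuf.write("a,b,confidence\n")
    for a, b, c in edges:
        ebuf.write(f"{a},{b},{c}\n")
    return pbuf.getvalue(), ebuf.getvalue()
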