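"""Rigid superposition, RMSD, TM-score, structural alignment and redundancy clustering.

The alignment here is a deliberately compact TM-align-flavoured heuristic, not a
re-implementation of TM-align: correspondences are seeded from a sequence
alignment (when the sequences are clearly related) and from all gapless fragment
superpositions, then refined by iterating "superpose -> re-pair nearby CA atoms
monotonically -> re-superpose" until the TM-score stops improving.  It is
deterministic for fixed inputs, which the redundancy clustering and the docking
engine both rely on.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from Bio import Align

from .errors import GeometryError
from .structure import Chain

PAIR_DISTANCE_CUTOFF = 5.0   # A, re-pairing radius during refinement
FRAGMENT_LENGTH = 15
FRAGMENT_STRIDE = 4
SEQ_IDENTITY_SEED = 0.40
MAX_REFINE_ITER = 30
TM_CONVERGENCE = 1e-4


@dataclass
class RigidTransform:
    """Proper rotation + translation: x -> R @ x + t."""
    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        R = np.asarray(self.rotation, dtype=float)
        if R.shape != (3, 3) or np.linalg.norm(R.T @ R - np.eye(3)) > 1e-6:
            raise GeometryError("rotation must be 3x3 orthonormal")
        if abs(np.linalg.det(R) - 1.0) > 1e-6:
            raise GeometryError("rotation must be proper (det +1)")
        self.rotation = R
        self.translation = np.asarray(self.translation, dtype=float).reshape(3)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))


@dataclass
class AlignmentResult:
    pairs: list[tuple[int, int]]
    rmsd: float
    tm_score: float
    transform: RigidTransform
    pair_distances: np.ndarray = field(default_factory=lambda: np.empty(0))


@dataclass
class ClusterSet:
    groups: dict[int, list[str]]
    representatives: dict[int, str]

    def group_of(self, label: str) -> int:
        for gid, members in self.groups.items():
            if label in members:
                return gid
        raise KeyError(label)


def kabsch_superpose(P: np.ndarray, Q: np.ndarray) -> RigidTransform:
    """Least-squares rigid superposition of paired points P onto Q (no reflection)."""
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError("P and Q must be paired n x 3 arrays")
    if len(P) < 3:
        raise GeometryError("at least 3 point pairs required")
    pc, qc = P.mean(axis=0), Q.mean(axis=0)
    H = (P - pc).T @ (Q - qc)
    U, S, Vt = np.linalg.svd(H)
    # degenerate (collinear) sets leave the rotation about the line unconstrained
    if S[1] < 1e-8 * max(S[0], 1.0):
        raise GeometryError("degenerate (collinear) point set")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    return RigidTransform(R, qc - R @ pc)


def rmsd(P: np.ndarray, Q: np.ndarray, transform: RigidTransform | None = None) -> float:
    P = np.asarray(P, dtype=float)
    Q = np.asarray(Q, dtype=float)
    if P.shape != Q.shape:
        raise GeometryError("length mismatch between paired coordinate sets")
    if transform is not None:
        P = transform.apply(P)
    return float(np.sqrt(np.mean(np.sum((P - Q) ** 2, axis=1)))) if len(P) else 0.0


def tm_d0(L_target: int) -> float:
    """Standard TM-score normalization length d0, floored at 0.5 A."""
    if L_target <= 15:
        warnings.warn(f"L_target={L_target} <= 15: applying d0 floor of 0.5 A")
        return 0.5
    return max(0.5, 1.24 * (L_target - 15) ** (1.0 / 3.0) - 1.8)


def tm_score(alignment: AlignmentResult, L_target: int) -> float:
    """Length-normalized similarity in (0, 1]; >0.5 indicates shared topology."""
    d0 = tm_d0(L_target)
    d = np.asarray(alignment.pair_distances, dtype=float)
    s = float(np.sum(1.0 / (1.0 + (d / d0) ** 2))) / max(L_target, 1)
    return min(s, 1.0)


def _tm_sum(dists: np.ndarray, d0: float) -> float:
    return float(np.sum(1.0 / (1.0 + (dists / d0) ** 2)))


def _monotone_pairs(A: np.ndarray, B: np.ndarray, d0: float,
                    cutoff: float = PAIR_DISTANCE_CUTOFF) -> list[tuple[int, int]]:
    """Best sequence-order-preserving matching of CA atoms within `cutoff`.

    Dynamic program over the distance matrix maximizing the summed TM-weight of
    the chosen pairs; pairs beyond the cutoff are never chosen.
    """
    n, m = len(A), len(B)
    D = np.linalg.norm(A[:, None, :] - B[None, :, :], axis=2)
    W = np.where(D < cutoff, 1.0 / (1.0 + (D / d0) ** 2), -1.0)
    f = np.zeros((n + 1, m + 1))
    for i in range(1, n + 1):
        diag = f[i - 1, :-1] + W[i - 1]
        f[i, 1:] = np.maximum.accumulate(np.maximum(f[i - 1, 1:], diag))
        f[i, 0] = 0.0
    pairs: list[tuple[int, int]] = []
    i, j = n, m
    while i > 0 and j > 0:
        if f[i, j] == f[i - 1, j]:
            i -= 1
        elif f[i, j] == f[i, j - 1]:
            j -= 1
        else:
            if D[i - 1, j - 1] < cutoff:
                pairs.append((i - 1, j - 1))
            i -= 1
            j -= 1
    pairs.reverse()
    return pairs


_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.match_score = 1.0
_aligner.mismatch_score = 0.0
_aligner.open_gap_score = -1.0
_aligner.extend_gap_score = -0.2


def _sequence_seed(seq_a: str, seq_b: str) -> tuple[list[tuple[int, int]], float]:
    aln = _aligner.align(seq_a, seq_b)[0]
    pairs: list[tuple[int, int]] = []
    matches = 0
    for (a0, a1), (b0, b1) in zip(*aln.aligned):
        for k in range(a1 - a0):
            pairs.append((a0 + k, b0 + k))
            if seq_a[a0 + k] == seq_b[b0 + k]:
                matches += 1
    ident = matches / max(min(len(seq_a), len(seq_b)), 1)
    return pairs, ident


def _refine(A: np.ndarray, B: np.ndarray, seed_pairs: list[tuple[int, int]],
            d0: float, L_target: int) -> AlignmentResult | None:
    if len(seed_pairs) < 3:
        return None
    pairs = seed_pairs
    best: AlignmentResult | None = None
    prev_tm = -1.0
    for _ in range(MAX_REFINE_ITER):
        ia = [p[0] for p in pairs]
        ib = [p[1] for p in pairs]
        try:
            tr = kabsch_superpose(A[ia], B[ib])
        except GeometryError:
            return best
        moved = tr.apply(A)
        pairs = _monotone_pairs(moved, B, d0)
        if len(pairs) < 3:
            return best
        ia = [p[0] for p in pairs]
        ib = [p[1] for p in pairs]
        dists = np.linalg.norm(tr.apply(A[ia]) - B[ib], axis=1)
        tm = min(_tm_sum(dists, d0) / max(L_target, 1), 1.0)
        if best is None or tm > best.tm_score:
            best = AlignmentResult(
                pairs=pairs, rmsd=rmsd(A[ia], B[ib], tr), tm_score=tm,
                transform=tr, pair_distances=dists)
        if tm - prev_tm < TM_CONVERGENCE:
            break
        prev_tm = tm
    return best


def align_coords(A: np.ndarray, B: np.ndarray, seq_a: str | None = None,
                 seq_b: str | None = None, L_target: int | None = None,
                 extra_seeds: list[list[tuple[int, int]]] | None = None
                 ) -> AlignmentResult:
    """Structural alignment of two ordered CA coordinate sets.

    `extra_seeds` lets callers inject prior correspondences (e.g. a shared
    numbering scheme); they compete with the built-in seeds on TM-score.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    n, m = len(A), len(B)
    if n < 3 or m < 3:
        raise GeometryError("need at least 3 CA atoms per side")
    L = L_target if L_target is not None else max(n, m)
    d0 = tm_d0(L)
    seeds: list[list[tuple[int, int]]] = list(extra_seeds or [])
    if seq_a and seq_b:
        pairs, ident = _sequence_seed(seq_a, seq_b)
        if ident >= SEQ_IDENTITY_SEED:
            seeds.append(pairs)
    # gapless fragment superpositions (always tried: low-complexity sequences can
    # be sequence-identical yet structurally unrelated)
    L_frag = min(FRAGMENT_LENGTH, n, m)
    for i in range(0, n - L_frag + 1, FRAGMENT_STRIDE):
        for j in range(0, m - L_frag + 1, FRAGMENT_STRIDE):
            seeds.append([(i + k, j + k) for k in range(L_frag)])
    best: AlignmentResult | None = None
    for seed in seeds:
        res = _refine(A, B, seed, d0, L)
        if res is not None and (best is None or res.tm_score > best.tm_score):
            best = res
    if best is None:
        # no refinable seed: return the least-bad direct superposition of the
        # leading fragments so the caller can observe the (low) score
        k = min(n, m)
        tr = kabsch_superpose(A[:k], B[:k])
        d = np.linalg.norm(tr.apply(A[:k]) - B[:k], axis=1)
        best = AlignmentResult(pairs=[(i, i) for i in range(k)],
                               rmsd=rmsd(A[:k], B[:k], tr),
                               tm_score=min(_tm_sum(d, d0) / L, 1.0),
                               transform=tr, pair_distances=d)
    return best


def structural_align(A: Chain, B: Chain) -> AlignmentResult:
    """Align two chains on their CA traces; requires >= 16 residues each."""
    ra, rb = A.residues_with_ca(), B.residues_with_ca()
    if len(ra) < 16 or len(rb) < 16:
        raise GeometryError("structural_align requires chains of >= 16 CA residues")
    return align_coords(
        np.array([r.ca.position for r in ra]),
        np.array([r.ca.position for r in rb]),
        "".join(r.aa1 for r in ra), "".join(r.aa1 for r in rb))


def cluster_structures(chains: dict[str, Chain], tm_threshold: float = 0.5,
                       rmsd_threshold: float = 2.5) -> ClusterSet:
    """Single-linkage redundancy grouping at TM > threshold AND RMSD < threshold.

    TM-score is normalized by the longer chain of each pair (symmetric
    criterion).  Representative = member with maximal mean TM to its group,
    ties broken by lexicographically smallest label.
    """
    if not chains:
        raise GeometryError("no chains to cluster")
    labels = sorted(chains)
    tm = {(a, a): 1.0 for a in labels}
    g = nx.Graph()
    g.add_nodes_from(labels)
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            aln = structural_align(chains[a], chains[b])
            L = max(len(chains[a].residues_with_ca()), len(chains[b].residues_with_ca()))
            t = tm_score(aln, L)
            tm[(a, b)] = tm[(b, a)] = t
            if t > tm_threshold and aln.rmsd < rmsd_threshold:
                g.add_edge(a, b)
    groups: dict[int, list[str]] = {}
    representatives: dict[int, str] = {}
    components = sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])
    for gid, comp in enumerate(components):
        members = sorted(comp)
        groups[gid] = members
        mean_tm = {m: np.mean([tm[(m, o)] for o in members]) for m in members}
        representatives[gid] = max(members, key=lambda m: (mean_tm[m], ), default=members[0])
        best_val = max(mean_tm.values())
        representatives[gid] = min(m for m in members if mean_tm[m] >= best_val - 1e-12)
    return ClusterSet(groups=groups, representatives=representatives)


def cluster_report(clusters: ClusterSet, chains: dict[str, Chain]) -> str:
    """TSV report: label, group id, representative flag, mean TM to representative."""
    lines = ["label\tgroup\trepresentative\ttm_to_representative"]
    for gid in sorted(clusters.groups):
        rep = clusters.representatives[gid]
        for label in clusters.groups[gid]:
            if label == rep:
                t = 1.0
            else:
                aln = structural_align(chains[label], chains[rep])
                L = max(len(chains[label].residues_with_ca()),
                        len(chains[rep].residues_with_ca()))
                t = tm_score(aln, L)
            lines.append(f"{label}\t{gid}\t{int(label == rep)}\t{t:.4f}")
    return "\n".join(lines) + "\n"
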