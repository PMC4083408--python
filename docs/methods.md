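# Methods

This note documents the models, algorithms, parameters and design choices
behind `structppi`, and what the synthetic fixtures do and do not establish.

## Structure model and I/O

Structures are protein-only hierarchies (Structure → Chain → Residue → Atom)
with author numbering and insertion codes kept verbatim. PDB reading and
writing go through gemmi; on top of it the package applies fixed policies:
HETATM records, waters, nucleic and modified residues are dropped; hydrogens
are dropped by default (all geometry downstream is heavy-atom based);
alternate locations resolve to the highest-occupancy record, ties to the first
record encountered. These policies are deterministic choices made for
reproducibility — different readers of the same entry will agree bit-for-bit.
Chains shorter than 15 residues load but are flagged; the prediction engine
refuses them (the 15-residue size rule of the docking protocol).

## Geometry

Superposition is standard Kabsch (SVD with reflection correction); collinear
point sets are rejected rather than silently resolved. TM-score uses the
published normalization d0(L) = 1.24·(L−15)^⅓ − 1.8, floored at 0.5 Å, with a
warning when L ≤ 15.

`structural_align` is a compact TM-align-flavoured heuristic, not a TM-align
reimplementation: candidate correspondences are seeded from (a) a global
sequence alignment when identity ≥ 40%, (b) all gapless fragment
superpositions of length 15 at stride 4, and (c) any caller-supplied prior
(the docking engine passes a shared-numbering seed). Each seed is refined by
iterating superpose → monotone re-pairing of CA atoms within 5 Å (dynamic
program maximizing summed TM-weight) → re-superpose, until the TM-score gains
less than 1e-4 or 30 iterations; the best-scoring result over all seeds is
kept. The fragment seeds are always tried, not only below the sequence-identity
threshold: low-complexity chains (poly-Ala fixtures, coiled coils) can be
sequence-identical yet structurally unrelated, and a sequence-only seed can
strand the refinement in a wrong basin. The procedure is deterministic for
fixed inputs.

Redundancy clustering is single linkage under the joint criterion TM > 0.5 AND
RMSD < 2.5 Å, with TM normalized by the longer chain of each pair so the
criterion is symmetric and small chains are not inflated. The representative
of a group is the member with maximal mean TM to its group, ties to the
lexicographically smallest label; the linkage and representative rules are
package choices where the protocol is otherwise silent.

## Interfaces and templates

A residue of chain A is *contacting* iff any heavy atom lies within 5.0 Å of a
heavy atom of chain B; *nearby* residues are non-contacting residues whose CA
is within 6.0 Å of a contacting CA on the same side. Both cutoffs are config
keys; the defaults follow the conventions of knowledge-based interface
analysis. Templates store full heavy-atom residues for both sides (so clash
checks and SASA on assembled poses are possible), the symmetric contact list
with minimum heavy-atom distances, and per-side hot-spot sets. The on-disk
library is a directory with a JSON index that holds coordinates at full float
precision (bit-exact round trip) plus one PDB fragment per template for
viewers; a format-version field guards against silent schema drift.

## Docking

`match_side` aligns a target chain onto the contacting+nearby residues of one
template side and accepts iff

1. ≥ 50% of the side's contacting residues are paired within 3 Å
   post-superposition (`min_matched_fraction`),
2. ≥ 50% of those paired contacting residues conserve their residue type in
   the target (`interface_identity_min`), and
3. ≥ 1 annotated template hot spot is among the paired residues
   (`hotspot_match_min`, vacuous for templates without hot-spot annotations).

Criterion 2 is the package's concrete reading of interface-motif conservation:
purely geometric matching lets any helix land on any helical motif, which
produces spurious high-contact poses between unrelated proteins; requiring the
matched interface core to keep its residue types suppresses these while
remaining insensitive to mutations that change a single position. All three
thresholds are config keys.

Accepted alignments transplant both targets rigidly into the template frame
(no flexible refinement — the rigid pose plus a clash tolerance stands in for
post-docking minimization). Clash filtering counts inter-chain heavy-atom
pairs under 2.5 Å and admits at most 5. The pose score is the contact
potential summed over inter-chain residue pairs with Cβ–Cβ distance < 6.5 Å
(CA for glycine; residues lacking both are skipped with a warning) plus a
−1.0 bonus per matched template hot spot. Over all conformer pairs, templates
and side assignments (both orientations are tried), the lowest-scoring
clash-passing candidate wins; ties break lexicographically on template id and
conformer labels, so identical inputs give bit-identical predictions.

Ternary compatibility of two poses sharing a partner superposes the shared
chain (CA Kabsch) and counts clashes between the two non-shared chains, with
the same ≤ 5 tolerance.

## Contact potential

The 20×20 table is generated once from e(a,b) = −(H_a + H_b) + charge(a,b)
with per-residue interactivity strengths H (W 3.1 … K 0.7), a −1.5 salt-bridge
bonus for opposite charges and a +1.0 penalty for like charges, giving a range
of roughly −6.2 (Trp–Trp) to +1 — a quasi-chemical-style spectrum in which a
cluster of three strong hydrophobic contacts sums to ≈ 18.6, just above the
hot-spot operating point below. Energies are dimensionless and intentionally
not comparable to any published docking score; only signs and orderings carry
meaning, which is all the mutation verdicts use.

## Solvent accessibility and hot spots

SASA is computed by even sphere sampling (deterministic golden-spiral points,
960 per atom, probe 1.4 Å) over heavy atoms with Bondi-type element radii
(C 1.70, N 1.55, O 1.52, S 1.80; unknown elements default to 1.80 with a
warning). Relative accessibility divides the residue sum by a *free-residue*
reference: the SASA of each amino acid built in isolation with the package's
ideal-geometry builder, computed once with this same routine and frozen as a
data asset. Free-residue references were chosen over tripeptide-context tables
because the pipeline must score burial on reduced-representation models
(backbone + Cβ); an isolated residue then cleanly defines "fully exposed"
(relative ≈ 1.0), and the burial threshold keeps its meaning across
representations.

A contacting residue is called a hot spot iff relative SASA in the complex is
≤ 0.20 and the summed pair potential (positive sense) to partner residues
within 6.5 Å of its side-chain anchor is ≥ 18.0 — burial plus interaction
strength, the operating point of burial-and-potential hot-spot predictors.
When a per-residue conservation file is supplied, calls additionally require
conservation at or above the residue's chain median; a uniform map is neutral
by construction. Conservation is always an input file, never computed from
sequences here.

## Mutations

Protein changes parse from `<AA><pos><AA|*>` strings (a `p.` prefix is
tolerated); the class (missense / nonsense / coding-silent) is derived from
the parsed change, and records that fail to parse are kept but flagged.
Mapping onto a structure adds an explicit per-gene numbering offset and hard-
fails on a wild-type identity mismatch — numbering drift between a mutation
table and a model must never be absorbed silently. Positions outside the
modelled range are reported unresolved.

Missense application keeps the backbone (and Cβ when both types have one) and
rebuilds the side chain atom-by-atom in an extended χ rotamer with ideal bond
lengths; rings are placed as schematic planar polygons. There is no rotamer
search and no minimization: the residue-level potential only reads the Cβ
position and residue type, so all-atom relaxation would add cost without
changing any downstream quantity; the rebuilt atoms matter only for burial and
clash checks. Nonsense application truncates the chain at the stop position
(author numbering preserved); truncating away every modelled residue is an
explicit total-loss error.

Verdicts compare the best wild-type and mutant predictions: *abolished* when
no clash-passing pose with score < 0 remains; *weakened* when Δ ≥ 5.0 energy
units or |mut| ≤ 0.5·|wt|; *strengthened* under the mirrored conditions;
otherwise *unchanged*. The two thresholds are config keys; they encode
"qualitatively worse/better" on the package's own score scale. Coding-silent
records short-circuit to *unchanged* without touching the structure.

## Network assembly

Edge lists are filtered at confidence strictly greater than 0.4 (the
conventional default confidence of interaction databases; read as a strict
inequality), self-loops dropped, and (a,b)/(b,a) duplicates merged keeping the
maximum confidence. Degrees of contiguity are BFS distances from the seed;
unreachable proteins (listed but attached only by sub-threshold evidence) are
flagged and excluded from the final node set rather than deleted silently.
Edge status is known-complex ≻ modeled ≻ unmodeled, with known complexes
taking precedence; summary counts are always recomputed from the edge list,
never cached. Exports: GraphML with node/edge attributes, TSV edge list, JSON
summary.

## Synthetic data

The generators emulate the statistical structure the analysis assumes, with
one RNG per fixture spec (bit-identical output for identical specs).

*Complexes* are two ideal α-helices (rise 1.5 Å, 100°/residue, CA radius
2.3 Å; backbone N/CA/C/O + Cβ) packed face to face. The interface is a dense
designed core: a central tryptophan pair whose side chains (Cβ + a 2.3 Å Cγ
stub) lean into the inter-helix gap, flanked by four tryptophans aimed at the
partner's central side chain — the fixture analog of interface side chains
packing into a binding core. Positions that would otherwise face the partner
are glycine, and the partner helix is splayed 0.25 Å/Å away from the core
height, so contacts concentrate at the core; the axis separation is then
scanned (0.03 Å steps, up to 100 jittered attempts) until the heavy-atom scan
reports exactly the requested number of contacting pairs (default 6). By
construction the central pair is buried (relative SASA ≈ 0.02–0.07) with three
strong cross-partners each (pair-potential sum 18.6), so the hot-spot caller
recovers it at default thresholds; the interface sits early on chain B
(centered near residue 12), so a premature stop upstream of it leaves fewer
than 15 residues and trips the engine's size rule — the fixture analog of a
receptor losing its ectodomain. Coordinates carry Gaussian jitter (σ = 0.1 Å
default).

*Mutation tables* hit the designed hot spot (missense to glycine), a
non-interface position, positions upstream and downstream of the interface
(nonsense), and a silent change, in a COSMIC-export-like CSV; a malformed row
can be injected to exercise the parser's flagging.

*Network fixtures* are a star with 4 first-degree and 45 second-degree
neighbors around the seed plus 22 extra second-shell edges — 50 listed
proteins of which one is attached only by a below-threshold (0.3) edge, so the
loaders end at 49 reachable proteins and 70 retained interactions, the shape
of the study's seed-centered network. Reversed-duplicate and sub-threshold
edges exercise deduplication and filtering.

What passing fixtures shows — and does not. The fixtures establish that each
stage recovers designed ground truth and that the stages compose; they are
schematic (ideal helices, reduced side chains, one template per complex) and
say nothing about prediction accuracy on real folds, conformational change on
binding, or the absolute energetics of real interfaces.

## Problem sizes and numerical choices

The statistical properties are measured over 20 seeded complexes
(self-template pose recovery, hot-spot recovery) and 10 seeded fixtures
(mutation verdicts) at 40 residues per chain — sizes at which the full suite
runs in well under five minutes on one CPU while every rate is stable at 100%
across seeds. Degenerate inputs fail loudly by policy: empty structures,
collinear point sets, interfaces with no contacts, empty template libraries
and total truncations all raise typed errors rather than returning sentinel
values. Ties are broken deterministically everywhere (altloc → first record;
cluster representative → smallest label; pose candidates → lexicographic on
template and conformer labels).

## Known limitations

- Rigid-body matching only; no backbone flexibility or refinement of poses.
- The contact potential is residue-level and coarse: absolute energies are
  arbitrary units, and only within-package comparisons (wild type vs mutant,
  candidate vs candidate) are meaningful.
- The side-chain builder is schematic (extended rotamer, polygonal rings) and
  unsuitable for any analysis that reads atomic detail beyond Cβ.
- The alignment heuristic approximates TM-align behaviour at desk scale; it is
  not sequence-order-independent and can undershoot TM-score on hard remote
  homologies.
- Interface-motif conservation (the 50% identity rule) is a blunt stand-in for
  evolutionary conservation profiles; with real cross-protein templates a
  user may need to relax `interface_identity_min`.
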