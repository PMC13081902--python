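"""Delineation of the metalloBSH enzyme family.

The family is carved out of a broader amidohydrolase sequence set in four
steps:

1. an all-vs-all sequence similarity network (SSN) thresholded on alignment
   score and percent identity,
2. extraction of the connected component containing a seed metalloBSH,
3. greedy identity clustering (default 65%) with a summed-score
   representative rule, and
4. a conserved active-site residue filter that removes partial or truncated
   sequences lacking a complete dinuclear metal center, using the
   metal-coordinating residues (H110, H112, KCX373 as K, H441, H474, D583 in
   BwBSH1 numbering) and the substrate-recognition residues (S194, H196,
   Q381, N443, H544).

Sequences outside the family cluster, plus cluster members failing the
residue filter, become decoys in the search database so that reads more
similar to non-family amidohydrolases are excluded from family counts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx

from .alignment import (
    AlignmentResult,
    ProteinRecord,
    SubstitutionMatrix,
    global_align,
)
from .errors import ConfigError, InvalidInputError, NotFoundError

#: metal-coordinating residues of BwBSH1 (1-based; carboxylated lysine as K)
BWBSH1_METAL_POSITIONS: dict[int, str] = {110: "H", 112: "H", 373: "K", 441: "H", 474: "H", 583: "D"}
#: substrate (sulfonate) recognition and carbonyl-activating residues
BWBSH1_SUBSTRATE_POSITIONS: dict[int, str] = {194: "S", 196: "H", 381: "Q", 443: "N", 544: "H"}


@dataclass(frozen=True)
class KeyResidueProfile:
    """Expected active-site residues at 1-based positions on a reference."""

    reference_id: str
    metal_positions: Mapping[int, str]
    substrate_positions: Mapping[int, str]

    def __post_init__(self) -> None:
        for positions in (self.metal_positions, self.substrate_positions):
            for pos, aa in positions.items():
                if pos < 1:
                    raise ConfigError(f"profile position {pos} is not 1-based positive")
                if len(aa) != 1 or aa not in "ACDEFGHIKLMNPQRSTVWY":
                    raise ConfigError(f"expected residue {aa!r} at {pos} is not a standard amino acid")

    @property
    def all_positions(self) -> dict[int, str]:
        return {**self.metal_positions, **self.substrate_positions}


def bwbsh1_profile(reference_id: str = "BwBSH1") -> KeyResidueProfile:
    """The canonical BwBSH1 active-site profile."""
    return KeyResidueProfile(reference_id, dict(BWBSH1_METAL_POSITIONS), dict(BWBSH1_SUBSTRATE_POSITIONS))


@dataclass
class SSNGraph:
    """Sequence similarity network above a score and identity threshold."""

    graph: nx.Graph
    score_cutoff: float
    min_identity: float

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str, float, float]]:
        return [
            (a, b, d["score"], d["identity"]) for a, b, d in self.graph.edges(data=True)
        ]

    def connected_components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph)]

    def write_tsv(self, edges_path: str | Path, nodes_path: str | Path | None = None) -> None:
        with open(edges_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["id_a", "id_b", "score", "identity"])
            for a, b, s, i in sorted(self.edges):
                w.writerow([a, b, f"{s:g}", f"{i:.4f}"])
        if nodes_path is not None:
            with open(nodes_path, "w", newline="") as fh:
                w = csv.writer(fh, delimiter="\t")
                w.writerow(["id"])
                for n in sorted(self.nodes):
                    w.writerow([n])


def build_ssn(
    seqs: list[ProteinRecord],
    min_identity: float = 31.0,
    score_cutoff: float = 122.0,
    matrix: SubstitutionMatrix | None = None,
    denominator: str = "columns",
) -> SSNGraph:
    """All-vs-all SSN: edge (a, b) iff score >= cutoff and identity >= minimum.

    The score cutoff is a raw alignment-score threshold here (tool-specific
    E-value-derived scores are not portable); calibrate it so that
    within-family pairs connect and unrelated pairs do not.
    """
    if len(seqs) < 2:
        raise InvalidInputError("an SSN needs at least two sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ConfigError("duplicate sequence ids in SSN input")
    g = nx.Graph()
    g.add_nodes_from(ids)
    for i, a in enumerate(seqs):
        for b in seqs[i + 1 :]:
            res = global_align(a, b, matrix=matrix, denominator=denominator)
            if res.score >= score_cutoff and res.identity_pct >= min_identity:
                g.add_edge(a.id, b.id, score=res.score, identity=res.identity_pct)
    return SSNGraph(g, score_cutoff, min_identity)


def extract_cluster(ssn: SSNGraph, seed_id: str) -> set[str]:
    """Connected component of the SSN containing the seed sequence."""
    if seed_id not in ssn.graph:
        raise NotFoundError(f"seed {seed_id!r} is not a node of the SSN")
    return set(nx.node_connected_component(ssn.graph, seed_id))


@dataclass
class Cluster:
    members: list[str]
    representative: str


def _representative(
    members: list[ProteinRecord], score: Mapping[tuple[str, str], float]
) -> str:
    """Member with the highest total alignment score to its co-members.

    Ties broken by longer sequence, then lexicographically smaller id.
    """
    best = None
    for m in members:
        total = sum(score[m.id, o.id] for o in members if o.id != m.id)
        key = (-total, -m.length_aa, m.id)
        if best is None or key < best[0]:
            best = (key, m.id)
    return best[1]


def greedy_cluster(
    seqs: list[ProteinRecord],
    identity_threshold: float = 65.0,
    matrix: SubstitutionMatrix | None = None,
    denominator: str = "columns",
) -> dict[str, Cluster]:
    """Greedy incremental identity clustering with summed-score representatives.

    Sequences are visited in descending length (ties by id); each joins the
    first existing cluster whose current representative it matches at or
    above the identity threshold, else founds a new cluster. After each
    assignment the cluster representative is recomputed as the member with
    the highest total alignment score to its co-members.
    """
    if not seqs:
        raise InvalidInputError("greedy_cluster needs at least one sequence")
    by_id = {s.id: s for s in seqs}
    if len(by_id) != len(seqs):
        raise ConfigError("duplicate sequence ids in clustering input")
    order = sorted(seqs, key=lambda s: (-s.length_aa, s.id))
    score_cache: dict[tuple[str, str], float] = {}
    ident_cache: dict[tuple[str, str], float] = {}

    def _align(a: ProteinRecord, b: ProteinRecord) -> tuple[float, float]:
        key = (a.id, b.id)
        if key not in score_cache:
            res = global_align(a, b, matrix=matrix, denominator=denominator)
            score_cache[key] = score_cache[(b.id, a.id)] = res.score
            ident_cache[key] = ident_cache[(b.id, a.id)] = res.identity_pct
        return score_cache[key], ident_cache[key]

    clusters: list[Cluster] = []
    for seq in order:
        joined = False
        for cl in clusters:
            _, ident = _align(seq, by_id[cl.representative])
            if ident >= identity_threshold:
                cl.members.append(seq.id)
                for other in cl.members:
                    if other != seq.id:
                        _align(seq, by_id[other])
                cl.representative = _representative(
                    [by_id[m] for m in cl.members], score_cache
                )
                joined = True
                break
        if not joined:
            clusters.append(Cluster([seq.id], seq.id))
    return {f"cluster_{i}": cl for i, cl in enumerate(clusters)}


@dataclass
class ResidueCheck:
    position: int
    expected: str
    observed: str  # '-' when the candidate has a gap at the reference column
    present: bool
    residue_set: str  # 'metal' or 'substrate'


@dataclass
class FilterReport:
    candidate_id: str
    checks: list[ResidueCheck]
    metal_complete: bool
    substrate_complete: bool
    passed: bool

    @property
    def absent_positions(self) -> list[int]:
        return [c.position for c in self.checks if not c.present]


def check_key_residues(
    candidate: ProteinRecord,
    reference: ProteinRecord,
    profile: KeyResidueProfile,
    require_substrate_set: bool = True,
    matrix: SubstitutionMatrix | None = None,
) -> FilterReport:
    """Check conservation of active-site residues in a candidate sequence.

    The candidate is globally aligned to the full-length reference; a profile
    position is *present* iff the candidate residue aligned to that reference
    column equals the expected amino acid (a gap means absent). A sequence
    passes when the metal-coordinating set is complete and, if requested, the
    substrate-recognition set as well — truncations that lose part of the
    dinuclear metal center therefore fail.
    """
    max_pos = max(profile.all_positions)
    if max_pos > reference.length_aa:
        raise ConfigError(
            f"profile position {max_pos} beyond reference length {reference.length_aa}"
        )
    res: AlignmentResult = global_align(reference, candidate, matrix=matrix)
    # map reference column -> candidate residue
    ref_pos = 0
    column_residue: dict[int, str] = {}
    for ref_char, cand_char in zip(res.aligned_a, res.aligned_b):
        if ref_char != "-":
            ref_pos += 1
            column_residue[ref_pos] = cand_char
    checks = []
    for residue_set, positions in (
        ("metal", profile.metal_positions),
        ("substrate", profile.substrate_positions),
    ):
        for pos in sorted(positions):
            expected = positions[pos]
            observed = column_residue.get(pos, "-")
            checks.append(ResidueCheck(pos, expected, observed, observed == expected, residue_set))
    metal_ok = all(c.present for c in checks if c.residue_set == "metal")
    substrate_ok = all(c.present for c in checks if c.residue_set == "substrate")
    passed = metal_ok and (substrate_ok or not require_substrate_set)
    return FilterReport(candidate.id, checks, metal_ok, substrate_ok, passed)


def write_filter_report(reports: list[FilterReport], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow(["id", "position", "expected", "observed", "present"])
        for rep in reports:
            for c in rep.checks:
                w.writerow([rep.candidate_id, c.position, c.expected, c.observed, int(c.present)])


@dataclass
class ReferenceDB:
    """Target metalloBSHs plus decoy amidohydrolases for translated search."""

    targets: list[ProteinRecord]
    decoys: list[ProteinRecord]
    provenance: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        overlap = {t.id for t in self.targets} & {d.id for d in self.decoys}
        if overlap:
            raise ConfigError(f"ids present as both target and decoy: {sorted(overlap)}")

    @property
    def target_ids(self) -> set[str]:
        return {t.id for t in self.targets}

    def is_decoy(self, seq_id: str) -> bool:
        return seq_id not in self.target_ids

    def all_records(self) -> list[ProteinRecord]:
        return list(self.targets) + list(self.decoys)

    def lengths(self) -> dict[str, int]:
        return {r.id: r.length_aa for r in self.all_records()}


def assemble_reference_db(
    cluster_members: set[str],
    all_seqs: list[ProteinRecord],
    filter_reports: Mapping[str, FilterReport],
) -> ReferenceDB:
    """Targets = cluster members passing the residue filter; everything else decoys."""
    ids = {s.id for s in all_seqs}
    missing = cluster_members - ids
    if missing:
        raise ConfigError(f"cluster members not in the sequence set: {sorted(missing)}")
    targets, decoys, provenance = [], [], {}
    for seq in all_seqs:
        if seq.id in cluster_members:
            report = filter_reports.get(seq.id)
            if report is not None and report.passed:
                targets.append(seq)
                provenance[seq.id] = "cluster:pass"
            else:
                decoys.append(seq)
                provenance[seq.id] = "cluster:fail" if report is not None else "cluster:unchecked"
        else:
            decoys.append(seq)
            provenance[seq.id] = "outside_cluster"
    if not targets:
        import warnings

        warnings.warn("reference database has no target sequences", stacklevel=2)
    return ReferenceDB(targets, decoys, provenance)
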