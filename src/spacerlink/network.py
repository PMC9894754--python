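"""Gene-sharing network over MGE proteomes.

Proteins are grouped into families by greedy centroid clustering; genome
pairs are scored by the hypergeometric tail probability of their shared
family count, Bonferroni-corrected over all genome pairs, and the network's
connected components delineate candidate family-level groups.

For genomes A and B with a = |families(A)|, b = |families(B)|, c shared
families and n total families in the dataset, the edge p-value is
P(X >= c) for X ~ Hypergeometric(n, a, b), computed by exact summation; the
significance score is -log10(p * n_pairs) with n_pairs = C(#genomes, 2).
"""

from __future__ import annotations

import math
import sys
from collections import defaultdict
from dataclasses import dataclass

import networkx as nx
from Bio import Align


@dataclass
class ProteinFamily:
    family_id: str
    members: list[tuple[str, str]]        # (protein_id, genome_id)
    representative: str                   # centroid sequence

    @property
    def genomes(self) -> set[str]:
        return {g for _, g in self.members}


@dataclass(frozen=True)
class NetworkEdge:
    a: str
    b: str
    shared: int
    p: float
    score: float


@dataclass
class GeneNetwork:
    nodes: dict[str, frozenset]           # genome -> family ids
    edges: list[NetworkEdge]              # edges passing the threshold
    clusters: dict[str, str]              # genome -> cluster id
    n_total_families: int
    n_pairs_tested: int
    sig_threshold: float


# ---------------------------------------------------------------------------
# protein family clustering


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    return aligner


def _kmer_set(seq: str, k: int = 4) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def local_identity(query: str, target: str,
                   aligner: Align.PairwiseAligner | None = None) -> tuple[float, float]:
    """(identity, coverage) from the best local alignment: identity over
    aligned columns, coverage as the aligned span fraction of the shorter
    sequence."""
    aligner = aligner or _make_aligner()
    alns = aligner.align(query, target)
    if len(alns) == 0:
        return 0.0, 0.0
    aln = alns[0]
    qblocks, tblocks = aln.aligned
    matches = 0
    cols = 0
    for (qs, qe), (ts, te) in zip(qblocks, tblocks):
        cols += qe - qs
        matches += sum(query[qs + i] == target[ts + i]
                       for i in range(qe - qs))
    if cols == 0:
        return 0.0, 0.0
    short = min(len(query), len(target))
    if len(query) <= len(target):
        span = qblocks[-1][1] - qblocks[0][0]
    else:
        span = tblocks[-1][1] - tblocks[0][0]
    return matches / cols, span / short


def cluster_proteins(proteins: list[tuple[str, str, str]], *,
                     min_identity: float = 0.5,
                     min_coverage: float = 0.8) -> list[ProteinFamily]:
    """Greedy centroid clustering of (protein_id, genome_id, sequence).

    Proteins are sorted by decreasing length (ties by id); each joins the
    first existing centroid reaching min_identity over min_coverage of the
    shorter sequence, else founds a new family. A shared-4-mer prescreen
    skips alignments that cannot plausibly reach the identity floor.
    """
    if not proteins:
        raise ValueError("cluster_proteins: no proteins")
    aligner = _make_aligner()
    order = sorted(proteins, key=lambda p: (-len(p[2]), p[0]))
    centroids: list[tuple[str, set[str]]] = []   # (sequence, kmers)
    families: list[ProteinFamily] = []
    for pid, genome, seq in order:
        kmers = _kmer_set(seq)
        placed = False
        for fi, (cseq, ckmers) in enumerate(centroids):
            if len(kmers & ckmers) < 3:
                continue
            ident, cov = local_identity(seq, cseq, aligner)
            if ident >= min_identity and cov >= min_coverage:
                families[fi].members.append((pid, genome))
                placed = True
                break
        if not placed:
            centroids.append((seq, kmers))
            families.append(ProteinFamily(
                family_id=f"pf{len(families):05d}",
                members=[(pid, genome)],
                representative=seq))
    return families


def genome_family_sets(families: list[ProteinFamily]) -> dict[str, frozenset]:
    sets: dict[str, set[str]] = defaultdict(set)
    for fam in families:
        for _, genome in fam.members:
            sets[genome].add(fam.family_id)
    return {g: frozenset(fs) for g, fs in sets.items()}


# ---------------------------------------------------------------------------
# hypergeometric edge significance


def edge_significance(a: int, b: int, c: int, n: int) -> float:
    """P(X >= c) for X ~ Hypergeometric(population n, successes a,
    draws b), by exact integer summation of the tail."""
    if not (0 <= c <= min(a, b) <= n and a <= n and b <= n):
        raise ValueError(
            f"require 0 <= c <= min(a,b) <= n and a,b <= n; "
            f"got a={a} b={b} c={c} n={n}")
    num = sum(math.comb(a, k) * math.comb(n - a, b - k)
              for k in range(c, min(a, b) + 1))
    denom = math.comb(n, b)
    p = num / denom
    return max(p, sys.float_info.min)  # guard underflow for the log score


def build_network(genome_families: dict[str, frozenset | set],
                  sig_threshold: float = 1.0) -> GeneNetwork:
    """Score every genome pair sharing >= 1 family; keep edges with
    -log10(p * n_pairs) >= sig_threshold; clusters are the connected
    components of the kept-edge graph (isolated genomes are singleton
    clusters)."""
    genomes = sorted(genome_families)
    nodes = {g: frozenset(genome_families[g]) for g in genomes}
    n_total = len(set().union(*nodes.values())) if nodes else 0
    n_pairs = len(genomes) * (len(genomes) - 1) // 2
    edges: list[NetworkEdge] = []
    for i, ga in enumerate(genomes):
        for gb in genomes[i + 1:]:
            c = len(nodes[ga] & nodes[gb])
            if c < 1:
                continue
            p = edge_significance(len(nodes[ga]), len(nodes[gb]), c, n_total)
            score = -math.log10(p * n_pairs) if n_pairs else math.inf
            if score >= sig_threshold:
                edges.append(NetworkEdge(ga, gb, c, p, score))
    graph = nx.Graph()
    graph.add_nodes_from(genomes)
    graph.add_edges_from((e.a, e.b) for e in edges)
    clusters: dict[str, str] = {}
    comps = sorted(nx.connected_components(graph), key=min)
    for idx, comp in enumerate(comps):
        for g in comp:
            clusters[g] = f"gc{idx:04d}"
    return GeneNetwork(nodes=nodes, edges=edges, clusters=clusters,
                       n_total_families=n_total, n_pairs_tested=n_pairs,
                       sig_threshold=sig_threshold)
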