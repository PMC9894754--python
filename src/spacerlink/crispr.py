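"""CRISPR repeat-spacer array detection and the trusted spacer catalogue.

The array model is deliberately exact and explicit so that an exhaustive
all-substrings scan reproduces it on small contigs:

* a repeat is a string of length ``min_repeat_len..max_repeat_len`` occurring
  at least ``min_copies`` times on the contig, every copy an exact match;
* consecutive copies in an array are separated by a spacer gap of
  ``min_spacer_len..max_spacer_len`` bp;
* arrays are maximal chains of copies (no copy can be prepended or appended),
  and overlapping candidate arrays on a contig are resolved by keeping the
  one with more copies, then the longer span, then the leftmost.

Spacers are trusted at the clade level: a repeat must be seen on at least
three distinct contigs (MAG-binning artefacts rarely replicate across
contigs), and repeats shared with an off-target sister clade are discarded.
Spacer sequences are canonicalized to the lexicographic minimum of the two
strands before deduplication, because array orientation is not observable
from sequence alone.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

from .sequtils import canonical, find_all_exact, revcomp


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class Spacer:
    """One spacer with 0-based half-open coordinates on its contig."""
    seq: str
    start: int
    end: int


@dataclass
class CrisprArray:
    """A repeat-spacer locus on a host contig, strand as-found."""
    contig_id: str
    start: int
    end: int
    repeat_consensus: str
    repeat_copies: int
    spacers: list[Spacer]
    repeat_starts: list[int] = field(default_factory=list)

    @property
    def key(self) -> tuple[str, int]:
        return (self.contig_id, self.start)

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class ArrayParams:
    """Detection bounds (CRT-like community defaults)."""
    min_repeat_len: int = 20
    max_repeat_len: int = 50
    min_spacer_len: int = 15
    max_spacer_len: int = 75
    min_copies: int = 3

    def validate(self) -> None:
        if not (0 < self.min_repeat_len <= self.max_repeat_len):
            raise ValueError("invalid repeat length bounds")
        if not (0 < self.min_spacer_len <= self.max_spacer_len):
            raise ValueError("invalid spacer length bounds")
        if self.min_copies < 2:
            raise ValueError("min_copies must be >= 2")


@dataclass
class RepeatCluster:
    """Repeats judged to be 'the same' across contigs of one clade."""
    cluster_id: str
    members: list[tuple[str, int, str]]  # (contig_id, array start, canonical repeat)
    consensus: str
    n_distinct_contigs: int
    trusted: bool

    @property
    def member_keys(self) -> set[tuple[str, int]]:
        return {(c, s) for c, s, _ in self.members}


@dataclass
class SpacerEntry:
    spacer_id: str
    seq: str  # canonical orientation
    sources: list[tuple[str, int, int]]  # (contig_id, start, end)


@dataclass
class SpacerCatalogue:
    """Deduplicated clade-trusted spacers with provenance."""
    entries: list[SpacerEntry]
    metadata: dict = field(default_factory=dict)

    @property
    def n_unique(self) -> int:
        return len(self.entries)

    def sequences(self) -> list[str]:
        return [e.seq for e in self.entries]


# ---------------------------------------------------------------------------
# array detection


def _maximal_chains(occs: list[int], rlen: int, gmin: int, gmax: int,
                    min_copies: int) -> list[list[int]]:
    """All maximal chains of exact-copy positions with spacer gaps in
    [gmin, gmax]. Chains are maximal in the sense that no occurrence can be
    prepended or appended."""
    succ = {
        p: [q for q in occs if gmin <= q - (p + rlen) <= gmax]
        for p in occs
    }
    has_pred = {q for nxt in succ.values() for q in nxt}
    chains: list[list[int]] = []

    def extend(chain: list[int]) -> None:
        nxt = succ[chain[-1]]
        if not nxt:
            if len(chain) >= min_copies:
                chains.append(chain)
            return
        for q in nxt:
            extend(chain + [q])

    for p in occs:
        if p not in has_pred:
            extend([p])
    return chains


def _candidate_arrays(contig_id: str, seq: str, params: ArrayParams,
                      candidate_repeats: set[str]) -> list[CrisprArray]:
    out: list[CrisprArray] = []
    for rep in sorted(candidate_repeats):
        if "N" in rep:  # repeats must be unambiguous
            continue
        occs = find_all_exact(rep, seq)
        if len(occs) < params.min_copies:
            continue
        for chain in _maximal_chains(occs, len(rep), params.min_spacer_len,
                                     params.max_spacer_len, params.min_copies):
            spacers = [
                Spacer(seq[a + len(rep):b], a + len(rep), b)
                for a, b in zip(chain, chain[1:])
            ]
            out.append(CrisprArray(
                contig_id=contig_id,
                start=chain[0],
                end=chain[-1] + len(rep),
                repeat_consensus=rep,
                repeat_copies=len(chain),
                spacers=spacers,
                repeat_starts=list(chain),
            ))
    return out


def select_non_overlapping(cands: list[CrisprArray]) -> list[CrisprArray]:
    """Resolve overlapping candidate arrays per contig: more copies first,
    then longer span, then leftmost; deterministic final tie-break on the
    repeat string."""
    kept: list[CrisprArray] = []
    by_contig: dict[str, list[tuple[int, int]]] = defaultdict(list)
    order = sorted(
        cands,
        key=lambda a: (-a.repeat_copies, -a.span, a.start, a.repeat_consensus),
    )
    for arr in order:
        intervals = by_contig[arr.contig_id]
        if any(arr.start < e and s < arr.end for s, e in intervals):
            continue
        intervals.append((arr.start, arr.end))
        kept.append(arr)
    kept.sort(key=lambda a: (a.contig_id, a.start))
    return kept


def detect_arrays(contigs: dict[str, str],
                  params: ArrayParams | None = None) -> list[CrisprArray]:
    """Detect repeat-spacer arrays on each contig.

    Seeding: only substrings whose leading ``min_repeat_len``-mer recurs at
    least ``min_copies`` times can be repeats, so candidate repeat strings
    are enumerated from repeated seed k-mers only. On random sequence this
    makes detection near-linear while provably enumerating every string that
    occurs >= min_copies times.
    """
    params = params or ArrayParams()
    params.validate()
    if not contigs:
        raise ValueError("detect_arrays: empty contig set")
    results: list[CrisprArray] = []
    k = params.min_repeat_len
    for contig_id, seq in contigs.items():
        seq = seq.upper()
        n = len(seq)
        if n < k * params.min_copies:
            continue
        seeds: dict[str, list[int]] = defaultdict(list)
        for i in range(n - k + 1):
            seeds[seq[i:i + k]].append(i)
        candidates: set[str] = set()
        for kmer, positions in seeds.items():
            if len(positions) < params.min_copies or "N" in kmer:
                continue
            for p in positions:
                maxlen = min(params.max_repeat_len, n - p)
                for L in range(params.min_repeat_len, maxlen + 1):
                    candidates.add(seq[p:p + L])
        results.extend(
            select_non_overlapping(
                _candidate_arrays(contig_id, seq, params, candidates)
            )
        )
    return results


# ---------------------------------------------------------------------------
# repeat clustering and the trusted set


def repeat_identity(a: str, b: str) -> float:
    """Identity between two repeats: best ungapped offset alignment of the
    shorter within the longer, on either strand, as a fraction of the
    shorter length."""
    best = 0.0
    for cand in (b, revcomp(b)):
        short, long_ = (a, cand) if len(a) <= len(cand) else (cand, a)
        for off in range(len(long_) - len(short) + 1):
            m = sum(x == y for x, y in zip(short, long_[off:off + len(short)]))
            best = max(best, m / len(short))
    return best


def same_repeat(a: str, b: str, *, min_identity: float = 0.9,
                max_len_diff: int = 2) -> bool:
    if abs(len(a) - len(b)) > max_len_diff:
        return False
    return repeat_identity(a, b) >= min_identity


def cluster_repeats(arrays: list[CrisprArray], min_contigs: int = 3, *,
                    min_identity: float = 0.9,
                    max_len_diff: int = 2) -> list[RepeatCluster]:
    """Single-linkage clustering of array repeats; a cluster is trusted iff
    its members span >= min_contigs distinct contigs."""
    items = [
        (arr.contig_id, arr.start, canonical(arr.repeat_consensus))
        for arr in sorted(arrays, key=lambda a: (a.contig_id, a.start))
    ]
    parent = list(range(len(items)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(items)):
        for j in range(i + 1, len(items)):
            if same_repeat(items[i][2], items[j][2],
                           min_identity=min_identity,
                           max_len_diff=max_len_diff):
                parent[find(i)] = find(j)

    groups: dict[int, list[int]] = defaultdict(list)
    for i in range(len(items)):
        groups[find(i)].append(i)

    clusters: list[RepeatCluster] = []
    for gid, idxs in sorted(groups.items(), key=lambda kv: min(kv[1])):
        members = [items[i] for i in idxs]
        counts = Counter(m[2] for m in members)
        top = max(counts.values())
        consensus = min(s for s, c in counts.items() if c == top)
        n_contigs = len({m[0] for m in members})
        clusters.append(RepeatCluster(
            cluster_id=f"rc{len(clusters):04d}",
            members=members,
            consensus=consensus,
            n_distinct_contigs=n_contigs,
            trusted=n_contigs >= min_contigs,
        ))
    return clusters


def exclude_cross_clade(target: list[RepeatCluster],
                        offtarget: list[RepeatCluster], *,
                        min_identity: float = 0.9,
                        max_len_diff: int = 2) -> list[RepeatCluster]:
    """Drop target clusters whose consensus matches any off-target clade
    consensus; repeats shared across clades cannot anchor clade-specific
    spacer provenance."""
    if not offtarget:
        return list(target)
    kept = []
    for cl in target:
        if any(same_repeat(cl.consensus, off.consensus,
                           min_identity=min_identity,
                           max_len_diff=max_len_diff)
               for off in offtarget):
            continue
        kept.append(cl)
    return kept


# ---------------------------------------------------------------------------
# spacer catalogue


def catalogue_from_spacers(
    spacers: list[tuple[str, tuple[str, int, int]]],
) -> SpacerCatalogue:
    """Canonicalize + exact-deduplicate (sequence, source) pairs into a
    catalogue; first-seen order fixes spacer ids."""
    by_seq: dict[str, list[tuple[str, int, int]]] = {}
    raw_seqs = set()
    for seq, source in spacers:
        raw_seqs.add(seq.upper())
        by_seq.setdefault(canonical(seq), []).append(source)
    entries = [
        SpacerEntry(spacer_id=f"sp{i:05d}", seq=seq, sources=sources)
        for i, (seq, sources) in enumerate(by_seq.items())
    ]
    return SpacerCatalogue(
        entries=entries,
        metadata={
            "n_unique_canonical": len(entries),
            "n_unique_strand_aware": len(raw_seqs),
            "n_total": len(spacers),
        },
    )


def build_spacer_catalogue(arrays: list[CrisprArray],
                           trusted: list[RepeatCluster]) -> SpacerCatalogue:
    """Spacers from arrays whose repeat cluster is trusted, deduplicated in
    canonical orientation with provenance."""
    trusted_keys: set[tuple[str, int]] = set()
    for cl in trusted:
        if cl.trusted:
            trusted_keys |= cl.member_keys
    collected: list[tuple[str, tuple[str, int, int]]] = []
    for arr in sorted(arrays, key=lambda a: (a.contig_id, a.start)):
        if arr.key not in trusted_keys:
            continue
        for sp in arr.spacers:
            collected.append((sp.seq, (arr.contig_id, sp.start, sp.end)))
    return catalogue_from_spacers(collected)
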