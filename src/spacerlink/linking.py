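"""Protospacer search and the stringent MGE retention filters.

Matching is gap-free over the full spacer length with at most
``max_mismatch`` substitutions, on both strands — the strictest defensible
reading of spacer-to-protospacer mapping. Retention applies two filters in
series: at least three distinct protospacer loci per contig (accidental
single matches to unrelated elements are common at permissive stringency)
and contig length above 10 kb.

The search uses the pigeonhole principle: a window with <= m mismatches
must contain an exact copy of at least one of m+1 disjoint chunks of the
spacer, so candidate windows are seeded from exact chunk hits and verified
by Hamming count. This is exactly equivalent to a sliding-window scan.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, field

from .crispr import ArrayParams, SpacerCatalogue, detect_arrays
from .sequtils import revcomp

MIN_SPACER_LEN = 15


@dataclass(frozen=True)
class ProtospacerHit:
    """One spacer match on a target contig, coordinates on the forward
    strand, 0-based half-open."""
    spacer_id: str
    target_contig: str
    start: int
    end: int
    strand: str      # "+" or "-"
    mismatches: int


@dataclass
class MgeCandidate:
    contig_id: str
    length: int
    source_label: str
    hits: list[ProtospacerHit] = field(default_factory=list)
    retained_flag: bool = False

    @property
    def n_protospacer_loci(self) -> int:
        """Distinct (start, strand) loci: near-identical spacers hammering
        one locus count once."""
        return len({(h.start, h.strand) for h in self.hits})

    @property
    def n_distinct_spacers(self) -> int:
        return len({h.spacer_id for h in self.hits})

    def retained(self, min_protospacers: int = 3, min_len: int = 10_000,
                 *, count_by: str = "locus") -> bool:
        n = (self.n_protospacer_loci if count_by == "locus"
             else self.n_distinct_spacers)
        return n >= min_protospacers and self.length > min_len


def _chunk_offsets(length: int, n_chunks: int) -> list[tuple[int, int]]:
    """Split [0, length) into n_chunks near-equal disjoint intervals."""
    base, extra = divmod(length, n_chunks)
    out, pos = [], 0
    for i in range(n_chunks):
        size = base + (1 if i < extra else 0)
        out.append((pos, pos + size))
        pos += size
    return out


def _scan_one(pattern: str, text: str, max_mismatch: int) -> dict[int, int]:
    """start -> mismatch count for every window of len(pattern) within
    max_mismatch substitutions of pattern."""
    L = len(pattern)
    n = len(text)
    if n < L:
        return {}
    found: dict[int, int] = {}
    for c0, c1 in _chunk_offsets(L, max_mismatch + 1):
        chunk = pattern[c0:c1]
        i = text.find(chunk)
        while i != -1:
            start = i - c0
            if 0 <= start <= n - L and start not in found:
                window = text[start:start + L]
                mm = sum(a != b for a, b in zip(pattern, window))
                if mm <= max_mismatch:
                    found[start] = mm
            i = text.find(chunk, i + 1)
    return found


def array_masks(pool: dict[str, str],
                array_params: ArrayParams | None = None) -> dict[str, list[tuple[int, int]]]:
    """CRISPR arrays on the target pool, padded by one repeat length on each
    side; spacer self-matches inside arrays are not protospacers."""
    params = array_params or ArrayParams()
    masks: dict[str, list[tuple[int, int]]] = defaultdict(list)
    try:
        arrays = detect_arrays(pool, params)
    except ValueError:
        return masks
    for arr in arrays:
        pad = len(arr.repeat_consensus)
        masks[arr.contig_id].append((max(0, arr.start - pad), arr.end + pad))
    return masks


def find_protospacers(catalogue: SpacerCatalogue, pool: dict[str, str],
                      max_mismatch: int = 1, *,
                      mask_arrays: bool = True,
                      array_params: ArrayParams | None = None) -> list[ProtospacerHit]:
    """All gap-free full-length spacer matches on either strand of the pool.

    Palindromic double counting is resolved by preferring the forward
    strand; hits overlapping a CRISPR array on the target (padded by one
    repeat length) are suppressed.
    """
    if not catalogue.entries:
        raise ValueError("find_protospacers: empty spacer catalogue")
    if not pool:
        return []
    masks = array_masks(pool, array_params) if mask_arrays else {}
    hits: list[ProtospacerHit] = []
    for entry in catalogue.entries:
        spacer = entry.seq.upper()
        if len(spacer) < MIN_SPACER_LEN:
            warnings.warn(
                f"spacer {entry.spacer_id} shorter than {MIN_SPACER_LEN} bp "
                "rejected", stacklevel=2)
            continue
        rc = revcomp(spacer)
        for contig_id, seq in pool.items():
            seq = seq.upper()
            fwd = _scan_one(spacer, seq, max_mismatch)
            rev = _scan_one(rc, seq, max_mismatch)
            starts = sorted(set(fwd) | set(rev))
            contig_masks = masks.get(contig_id, [])
            for start in starts:
                end = start + len(spacer)
                if any(start < e and s < end for s, e in contig_masks):
                    continue
                if start in fwd and (start not in rev
                                     or fwd[start] <= rev[start]):
                    strand, mm = "+", fwd[start]
                else:
                    strand, mm = "-", rev[start]
                hits.append(ProtospacerHit(entry.spacer_id, contig_id,
                                           start, end, strand, mm))
    hits.sort(key=lambda h: (h.target_contig, h.start, h.spacer_id, h.strand))
    return hits


def link_mges(hits: list[ProtospacerHit], pool: dict[str, str],
              min_protospacers: int = 3, min_len: int = 10_000, *,
              source_labels: dict[str, str] | None = None,
              count_by: str = "locus") -> list[MgeCandidate]:
    """One candidate per contig with >= 1 hit; ``retained`` encodes the
    two stringent filters (>= min_protospacers loci AND length > min_len)."""
    if count_by not in ("locus", "spacer"):
        raise ValueError("count_by must be 'locus' or 'spacer'")
    by_contig: dict[str, list[ProtospacerHit]] = defaultdict(list)
    for h in hits:
        if h.target_contig not in pool:
            raise ValueError(f"hit refers to unknown contig {h.target_contig}")
        by_contig[h.target_contig].append(h)
    out = []
    for contig_id in sorted(by_contig):
        label = (source_labels or {}).get(contig_id, "pool")
        cand = MgeCandidate(
            contig_id=contig_id, length=len(pool[contig_id]),
            source_label=label, hits=by_contig[contig_id])
        cand.retained_flag = cand.retained(min_protospacers, min_len,
                                           count_by=count_by)
        out.append(cand)
    return out


def retained_mges(mges: list[MgeCandidate], min_protospacers: int = 3,
                  min_len: int = 10_000, *,
                  count_by: str = "locus") -> list[MgeCandidate]:
    return [m for m in mges
            if m.retained(min_protospacers, min_len, count_by=count_by)]


def tally_by_source(mges: list[MgeCandidate], min_protospacers: int = 3,
                    min_len: int = 10_000, *,
                    count_by: str = "locus") -> dict[str, int]:
    """Retained-element counts per source label; sums to the total."""
    tally: dict[str, int] = {}
    for m in mges:
        tally.setdefault(m.source_label, 0)
        if m.retained(min_protospacers, min_len, count_by=count_by):
            tally[m.source_label] += 1
    return dict(sorted(tally.items()))
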