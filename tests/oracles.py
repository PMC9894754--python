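"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive and written without reference to the
package internals: exhaustive enumeration, sliding-window scans and
plain-dictionary translation, so that agreement with the fast
implementations is meaningful.
"""

from __future__ import annotations

from itertools import combinations

from Bio.Data import CodonTable

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# exhaustive tandem-repeat array scan (contigs <= ~5 kb)


def _occurrences(pattern: str, text: str) -> list[int]:
    out, i = [], text.find(pattern)
    while i != -1:
        out.append(i)
        i = text.find(pattern, i + 1)
    return out


def _all_maximal_chains(occs, rlen, gmin, gmax, min_copies):
    succ = {p: [q for q in occs if gmin <= q - (p + rlen) <= gmax]
            for p in occs}
    preds = {q for v in succ.values() for q in v}
    chains = []

    def walk(chain):
        nxt = succ[chain[-1]]
        if not nxt:
            if len(chain) >= min_copies:
                chains.append(chain)
            return
        for q in nxt:
            walk(chain + [q])

    for p in occs:
        if p not in preds:
            walk([p])
    return chains


def brute_force_arrays(seq: str, *, min_repeat_len=20, max_repeat_len=50,
                       min_spacer_len=15, max_spacer_len=75, min_copies=3):
    """All-substrings tandem scan; returns the same selection as the
    detector: (start, end, repeat, copies, spacers) tuples, sorted."""
    seq = seq.upper()
    n = len(seq)
    seen: set[str] = set()
    candidates = []
    for L in range(min_repeat_len, max_repeat_len + 1):
        for s in range(n - L + 1):
            rep = seq[s:s + L]
            if rep in seen or "N" in rep:
                continue
            seen.add(rep)
            occs = _occurrences(rep, seq)
            if len(occs) < min_copies:
                continue
            for chain in _all_maximal_chains(occs, L, min_spacer_len,
                                             max_spacer_len, min_copies):
                start, end = chain[0], chain[-1] + L
                spacers = tuple(seq[a + L:b]
                                for a, b in zip(chain, chain[1:]))
                candidates.append((start, end, rep, len(chain), spacers))
    # overlap resolution: more copies, longer span, leftmost, repeat string
    kept = []
    for cand in sorted(candidates,
                       key=lambda c: (-c[3], -(c[1] - c[0]), c[0], c[2])):
        if any(cand[0] < e and s < cand[1] for s, e, *_ in kept):
            continue
        kept.append(cand)
    return sorted(kept)


# ---------------------------------------------------------------------------
# sliding-window Hamming protospacer scan


def hamming_scan(spacer: str, contigs: dict[str, str], max_mismatch: int):
    """Exhaustive both-strand scan. Returns {(contig, start): (strand, mm)}
    with the forward strand preferred on ties, mirroring the reporting
    convention."""
    spacer = spacer.upper()
    rcsp = rc(spacer)
    L = len(spacer)
    out = {}
    for cid, seq in contigs.items():
        seq = seq.upper()
        for start in range(len(seq) - L + 1):
            window = seq[start:start + L]
            mm_f = sum(a != b for a, b in zip(spacer, window))
            mm_r = sum(a != b for a, b in zip(rcsp, window))
            if min(mm_f, mm_r) <= max_mismatch:
                strand = "+" if mm_f <= mm_r else "-"
                out[(cid, start)] = (strand, min(mm_f, mm_r))
    return out


# ---------------------------------------------------------------------------
# six-frame ORF scan


_T11 = CodonTable.unambiguous_dna_by_id[11].forward_table


def _translate(cds: str) -> str:
    aas = [_T11.get(cds[i:i + 3], "X") for i in range(0, len(cds) - 2, 3)]
    return "M" + "".join(aas[1:])


def brute_force_orfs(seq: str, min_len_aa: int = 50):
    """(start, end, strand, protein) tuples, forward coordinates, stop
    codon included in [start, end)."""
    seq = seq.upper()
    n = len(seq)
    results = []
    for strand, s in (("+", seq), ("-", rc(seq))):
        for frame in range(3):
            codon_starts = list(range(frame, len(s) - 2, 3))
            stops = [p for p in codon_starts
                     if s[p:p + 3] in ("TAA", "TAG", "TGA")]
            region_start = frame
            for stop in stops:
                starts = [p for p in range(region_start, stop, 3)
                          if s[p:p + 3] in ("ATG", "GTG", "TTG")]
                if starts and (stop - starts[0]) // 3 >= min_len_aa:
                    a, b = starts[0], stop + 3
                    prot = _translate(s[a:stop])
                    if strand == "+":
                        results.append((a, b, "+", prot))
                    else:
                        results.append((n - b, n - a, "-", prot))
                region_start = stop + 3
    return sorted(results)


# ---------------------------------------------------------------------------
# hypergeometric tail by exhaustive enumeration


def hypergeom_tail_enum(a: int, b: int, c: int, n: int) -> float:
    """P(|draw of size b intersects a marked set of size a| >= c) over all
    C(n, b) equally likely draws."""
    marked = set(range(a))
    total = 0
    ge = 0
    for draw in combinations(range(n), b):
        total += 1
        if len(marked.intersection(draw)) >= c:
            ge += 1
    return ge / total if total else 1.0
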