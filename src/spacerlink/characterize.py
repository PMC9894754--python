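"""ORF calling, terminal-repeat detection and topology/completeness calls.

A direct terminal repeat (DTR) indicates a circularly permuted assembly of
a circular (or terminally redundant) genome; an inverted terminal repeat
(ITR) indicates a complete linear genome. Completeness here is strictly
termini-based: no terminal evidence means completeness is unknown, whatever
other signals a curator might accept.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Seq import Seq

from .sequtils import gc_fraction, revcomp, validate_dna

START_CODONS = {"ATG", "GTG", "TTG"}
STOP_CODONS = {"TAA", "TAG", "TGA"}


@dataclass(frozen=True)
class Orf:
    """Coordinates are forward-strand, 0-based half-open, stop codon
    included; ``frame`` is the codon phase (0-2) on the reading strand."""
    start: int
    end: int
    strand: str
    frame: int
    protein: str


@dataclass
class MgeRecord:
    contig_id: str
    sequence: str
    length: int
    orfs: list[Orf]
    topology: str          # circular-DTR | linear-ITR | unresolved
    completeness: str      # complete | unknown
    tr_len: int
    gc: float
    source_label: str = "pool"
    n_protospacer_loci: int = 0

    def proteins(self) -> list[tuple[str, str]]:
        """(orf_id, protein) pairs; ids encode locus for traceability."""
        return [
            (f"{self.contig_id}|orf{i:04d}|{o.start}-{o.end}({o.strand})",
             o.protein)
            for i, o in enumerate(self.orfs)
        ]


def _translate(cds: str) -> str:
    # table 11; alternative starts (GTG/TTG) are translated as Met
    prot = str(Seq(cds).translate(table=11))
    return "M" + prot[1:]


def _orfs_one_strand(seq: str, strand: str, total_len: int,
                     min_len_aa: int) -> list[Orf]:
    out = []
    n = len(seq)
    for frame in range(3):
        start_candidate: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos:pos + 3]
            if codon in STOP_CODONS:
                if (start_candidate is not None
                        and (pos - start_candidate) // 3 >= min_len_aa):
                    a, b = start_candidate, pos + 3
                    protein = _translate(seq[a:pos])
                    if strand == "+":
                        out.append(Orf(a, b, "+", frame, protein))
                    else:
                        out.append(Orf(total_len - b, total_len - a, "-",
                                       frame, protein))
                start_candidate = None
            elif start_candidate is None and codon in START_CODONS:
                start_candidate = pos
        # ORFs running off the contig end are not stop-terminated: dropped
    return out


def call_orfs(sequence: str, min_len_aa: int = 50) -> list[Orf]:
    """Maximal stop-terminated ORFs on all 6 frames, starts ATG/GTG/TTG.

    Within a stop-bounded segment the earliest start wins, so nested ORFs
    sharing a stop collapse to the longest. Proteins use translation table
    11 with alternative starts as M; the terminal stop is not translated.
    """
    sequence = sequence.upper()
    validate_dna(sequence)
    if len(sequence) < 3:
        raise ValueError("sequence shorter than one codon")
    orfs = _orfs_one_strand(sequence, "+", len(sequence), min_len_aa)
    orfs += _orfs_one_strand(revcomp(sequence), "-", len(sequence),
                             min_len_aa)
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def _longest_border(seq: str) -> int:
    """Longest proper prefix of seq that is also a suffix, capped at
    len(seq)//2 (terminal repeats may not overlap)."""
    n = len(seq)
    fail = [0] * n  # KMP failure function
    k = 0
    for i in range(1, n):
        while k and seq[i] != seq[k]:
            k = fail[k - 1]
        if seq[i] == seq[k]:
            k += 1
        fail[i] = k
    b = fail[-1] if n else 0
    while b > n // 2:
        b = fail[b - 1]
    return b


def _itr_len(seq: str) -> int:
    """Longest k with seq[:k] reverse-complementary to seq[-k:], i.e. the
    longest common prefix of seq and its reverse complement."""
    rc = revcomp(seq)
    k = 0
    limit = len(seq) // 2
    while k < limit and seq[k] == rc[k]:
        k += 1
    return k


def detect_termini(sequence: str, min_tr: int = 20) -> tuple[str, int]:
    """(topology, terminal-repeat length); exact matching, DTR checked
    before ITR (palindromic termini satisfy both)."""
    sequence = sequence.upper()
    if len(sequence) < 2 * min_tr:
        raise ValueError(
            f"sequence of {len(sequence)} bp is shorter than 2 x min_tr")
    dtr = _longest_border(sequence)
    if dtr >= min_tr:
        return "circular-DTR", dtr
    itr = _itr_len(sequence)
    if itr >= min_tr:
        return "linear-ITR", itr
    return "unresolved", max(dtr, itr)


def characterize_mge(contig_id: str, sequence: str, *, min_len_aa: int = 50,
                     min_tr: int = 20, source_label: str = "pool",
                     n_protospacer_loci: int = 0) -> MgeRecord:
    """Full per-MGE characterization: ORFs, termini, GC."""
    sequence = sequence.upper()
    topology, tr_len = detect_termini(sequence, min_tr)
    return MgeRecord(
        contig_id=contig_id,
        sequence=sequence,
        length=len(sequence),
        orfs=call_orfs(sequence, min_len_aa),
        topology=topology,
        completeness="complete" if topology != "unresolved" else "unknown",
        tr_len=tr_len,
        gc=gc_fraction(sequence),
        source_label=source_label,
        n_protospacer_loci=n_protospacer_loci,
    )
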