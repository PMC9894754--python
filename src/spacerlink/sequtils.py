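"""Small nucleotide-string helpers shared across the pipeline.

Sequences are plain upper-case Python strings over the DNA alphabet; all
coordinates in the package are 0-based, half-open.
"""

from __future__ import annotations

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DNA = "ACGT"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Strand-canonical form: lexicographic minimum of seq and its reverse
    complement. Used to deduplicate spacers whose array orientation is
    unknown."""
    seq = seq.upper()
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def hamming(a: str, b: str) -> int:
    """Substitution distance between equal-length strings."""
    if len(a) != len(b):
        raise ValueError(f"hamming: unequal lengths {len(a)} != {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def find_all_exact(pattern: str, text: str) -> list[int]:
    """All (possibly overlapping) start positions of pattern in text."""
    hits = []
    i = text.find(pattern)
    while i != -1:
        hits.append(i)
        i = text.find(pattern, i + 1)
    return hits


def validate_dna(seq: str, *, name: str = "sequence") -> None:
    """Raise ValueError naming the first offending position if seq contains
    characters outside ACGTN (case-insensitive)."""
    for i, ch in enumerate(seq):
        if ch.upper() not in "ACGTN":
            raise ValueError(
                f"{name}: non-ACGTN character {ch!r} at position {i}"
            )


def gc_fraction(seq: str) -> float:
    seq = seq.upper()
    acgt = sum(seq.count(b) for b in DNA)
    if acgt == 0:
        return 0.0
    return (seq.count("G") + seq.count("C")) / acgt
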