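"""FASTA and table I/O.

Reading goes through Bio.SeqIO; record ids are tokenized at the first
whitespace. Writing is done with a fixed 70-column wrap so that identical
inputs always produce byte-identical files (the synthetic generator's
determinism contract depends on this).
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Mapping
from pathlib import Path

from Bio import SeqIO


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Read a multi-FASTA into an ordered {id: sequence} dict.

    Ids are the header token before the first whitespace. Duplicate ids or
    unparseable records raise ValueError naming the record.
    """
    records: dict[str, str] = {}
    try:
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in records:
                raise ValueError(f"duplicate FASTA id {rec.id!r} in {path}")
            records[rec.id] = str(rec.seq).upper()
    except ValueError:
        raise
    except Exception as exc:  # malformed input surfaced with context
        raise ValueError(f"malformed FASTA {path}: {exc}") from exc
    return records


def write_fasta(records: Mapping[str, str] | Iterable[tuple[str, str]],
                path: str | os.PathLike, *, width: int = 70) -> None:
    """Write records (id -> sequence) as wrapped multi-FASTA."""
    items = records.items() if isinstance(records, Mapping) else records
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for name, seq in items:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_tsv(rows: Iterable[Mapping[str, object]], path: str | os.PathLike,
              columns: list[str]) -> None:
    """Write rows as a TSV with a fixed column order and header line."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write("\t".join(str(row[c]) for c in columns) + "\n")
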