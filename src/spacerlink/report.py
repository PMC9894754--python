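"""Virus vs unclassified-MGE calls and the integrated report.

The classification rule is structural: an element carrying at least one
recognizable virion-structure hallmark (a major capsid protein variant,
portal, or large terminase) is called a virus; replication hallmarks alone
(pPolB, rPolB) never suffice — plasmids borrow replicases freely.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import asdict, dataclass
from pathlib import Path

from .characterize import MgeRecord
from .io import read_fasta, write_tsv
from .network import _kmer_set, _make_aligner, local_identity

MARKER_CLASSES = {
    "HK97-MCP", "portal", "TerL", "DJR-MCP", "SJR-MCP",
    "alpha-helical-MCP", "spindle-MCP", "pPolB", "rPolB", "other",
}
STRUCTURAL_CLASSES = {
    "HK97-MCP", "portal", "TerL", "DJR-MCP", "SJR-MCP",
    "alpha-helical-MCP", "spindle-MCP",
}


@dataclass(frozen=True)
class MarkerHit:
    mge_id: str
    orf_index: int
    marker_id: str
    marker_class: str
    identity: float
    coverage: float


@dataclass
class MgeReportRow:
    mge_id: str
    length: int
    topology: str
    completeness: str
    n_protospacer_loci: int
    cluster_id: str
    status: str                 # virus | unclassified-MGE
    marker_classes: str         # comma-joined, sorted, "" if none
    source_label: str = "pool"


def parse_marker_records(records: dict[str, str]) -> dict[str, tuple[str, str]]:
    """'marker_id|class' headers -> {marker_id: (class, sequence)}."""
    markers: dict[str, tuple[str, str]] = {}
    for header, seq in records.items():
        if "|" not in header:
            raise ValueError(
                f"marker header {header!r} lacks the 'marker_id|class' form")
        marker_id, cls = header.split("|", 1)
        if cls not in MARKER_CLASSES:
            raise ValueError(f"unknown marker class token {cls!r} "
                             f"in header {header!r}")
        markers[marker_id] = (cls, seq.upper())
    return markers


def load_marker_fasta(path) -> dict[str, tuple[str, str]]:
    return parse_marker_records(read_fasta(path))


def scan_markers(orfs: list[tuple[str, int, str]],
                 markers: dict[str, tuple[str, str]],
                 min_identity: float = 0.3,
                 min_coverage: float = 0.5) -> list[MarkerHit]:
    """Best marker per ORF by identity, thresholded on identity over the
    alignment and coverage of the marker length.

    ``orfs`` rows are (mge_id, orf_index, protein sequence).
    """
    aligner = _make_aligner()
    marker_kmers = {
        mid: _kmer_set(seq) for mid, (_, seq) in markers.items()}
    hits: list[MarkerHit] = []
    for mge_id, orf_index, protein in orfs:
        best: MarkerHit | None = None
        kmers = _kmer_set(protein)
        for mid in sorted(markers):
            cls, mseq = markers[mid]
            if len(kmers & marker_kmers[mid]) < 3:
                continue
            ident, _ = local_identity(protein, mseq, aligner)
            # coverage is defined on the marker, not the shorter sequence
            alns = aligner.align(protein, mseq)
            if len(alns) == 0:
                continue
            tblocks = alns[0].aligned[1]
            cov = ((tblocks[-1][1] - tblocks[0][0]) / len(mseq)
                   if len(tblocks) else 0.0)
            if ident >= min_identity and cov >= min_coverage:
                if best is None or ident > best.identity:
                    best = MarkerHit(mge_id, orf_index, mid, cls, ident, cov)
        if best is not None:
            hits.append(best)
    return hits


def assign_status(mge: MgeRecord, hits: list[MarkerHit],
                  cluster_id: str = "") -> MgeReportRow:
    """Virus iff >= 1 structural marker class among this MGE's hits."""
    own = [h for h in hits if h.mge_id == mge.contig_id]
    classes = sorted({h.marker_class for h in own})
    is_virus = any(c in STRUCTURAL_CLASSES for c in classes)
    return MgeReportRow(
        mge_id=mge.contig_id,
        length=mge.length,
        topology=mge.topology,
        completeness=mge.completeness,
        n_protospacer_loci=mge.n_protospacer_loci,
        cluster_id=cluster_id,
        status="virus" if is_virus else "unclassified-MGE",
        marker_classes=",".join(classes),
        source_label=mge.source_label,
    )


def summarize(rows: list[MgeReportRow]) -> dict:
    return {
        "n_mges": len(rows),
        "by_status": dict(sorted(Counter(r.status for r in rows).items())),
        "by_topology": dict(sorted(Counter(r.topology for r in rows).items())),
        "by_cluster": dict(sorted(Counter(r.cluster_id for r in rows).items())),
        "by_source": dict(sorted(Counter(r.source_label for r in rows).items())),
    }


REPORT_COLUMNS = ["mge_id", "length", "topology", "completeness",
                  "n_protospacer_loci", "cluster_id", "status",
                  "marker_classes", "source_label"]


def write_report(rows: list[MgeReportRow], tsv_path, json_path) -> dict:
    """Deterministic report: rows sorted by mge_id, summary JSON with
    sorted keys. Returns the summary."""
    ordered = sorted(rows, key=lambda r: r.mge_id)
    write_tsv([asdict(r) for r in ordered], tsv_path, REPORT_COLUMNS)
    summary = summarize(ordered)
    json_path = Path(json_path)
    json_path.parent.mkdir(parents=True, exist_ok=True)
    json_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    return summary
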