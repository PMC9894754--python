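"""End-to-end orchestration: host contigs + candidate pools -> report.

Stage order mirrors the discovery logic: trusted repeats -> spacer
catalogue -> protospacer linkage -> stringent retention -> per-MGE
characterization -> gene-sharing network -> hallmark classification.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .characterize import MgeRecord, characterize_mge
from .crispr import (ArrayParams, CrisprArray, RepeatCluster, SpacerCatalogue,
                     build_spacer_catalogue, cluster_repeats, detect_arrays,
                     exclude_cross_clade)
from .io import read_fasta, write_fasta, write_tsv
from .linking import (MgeCandidate, ProtospacerHit, find_protospacers,
                      link_mges, retained_mges, tally_by_source)
from .network import (GeneNetwork, ProteinFamily, build_network,
                      cluster_proteins, genome_family_sets)
from .report import (MarkerHit, MgeReportRow, assign_status,
                     parse_marker_records, scan_markers, summarize,
                     write_report)


@dataclass
class PipelineParams:
    array_params: ArrayParams = field(default_factory=ArrayParams)
    min_contigs: int = 3             # repeat trust: distinct contigs
    max_mismatch: int = 1            # protospacer substitutions
    min_protospacers: int = 3        # distinct loci per retained MGE
    min_len: int = 10_000            # retained MGE length floor, bp
    count_by: str = "locus"
    min_len_aa: int = 50
    min_tr: int = 20
    protein_min_identity: float = 0.5
    protein_min_coverage: float = 0.8
    sig_threshold: float = 1.0
    marker_min_identity: float = 0.3
    marker_min_coverage: float = 0.5
    clade_label: str = "target-clade"


@dataclass
class PipelineResult:
    params: PipelineParams
    arrays: list[CrisprArray]
    repeat_clusters: list[RepeatCluster]
    trusted_clusters: list[RepeatCluster]
    catalogue: SpacerCatalogue
    hits: list[ProtospacerHit]
    candidates: list[MgeCandidate]
    retained: list[MgeCandidate]
    records: list[MgeRecord]
    families: list[ProteinFamily]
    network: GeneNetwork
    marker_hits: list[MarkerHit]
    rows: list[MgeReportRow]
    summary: dict

    def predicted_pairs(self) -> set[tuple[str, str]]:
        """(clade label, MGE id) pairs for retained elements — spacers are
        pooled at clade level, so the host side is the clade."""
        return {(self.params.clade_label, m.contig_id) for m in self.retained}

    def tally(self) -> dict[str, int]:
        return tally_by_source(self.candidates, self.params.min_protospacers,
                               self.params.min_len,
                               count_by=self.params.count_by)


def run_pipeline(hosts: dict[str, str], pool: dict[str, str],
                 offtarget: dict[str, str] | None = None,
                 markers: dict[str, str] | None = None,
                 source_labels: dict[str, str] | None = None,
                 params: PipelineParams | None = None) -> PipelineResult:
    params = params or PipelineParams()

    arrays = detect_arrays(hosts, params.array_params) if hosts else []
    clusters = cluster_repeats(arrays, params.min_contigs)
    trusted = [c for c in clusters if c.trusted]
    if offtarget:
        off_arrays = detect_arrays(offtarget, params.array_params)
        off_clusters = cluster_repeats(off_arrays, params.min_contigs)
        # the off-target clade is screened with the same trust rule
        trusted = exclude_cross_clade(
            trusted, [c for c in off_clusters if c.trusted])
    catalogue = build_spacer_catalogue(arrays, trusted)

    hits: list[ProtospacerHit] = []
    if catalogue.entries and pool:
        hits = find_protospacers(catalogue, pool, params.max_mismatch,
                                 array_params=params.array_params)
    candidates = link_mges(hits, pool, params.min_protospacers,
                           params.min_len, source_labels=source_labels,
                           count_by=params.count_by)
    retained = retained_mges(candidates, params.min_protospacers,
                             params.min_len, count_by=params.count_by)

    records = [
        characterize_mge(m.contig_id, pool[m.contig_id],
                         min_len_aa=params.min_len_aa, min_tr=params.min_tr,
                         source_label=m.source_label,
                         n_protospacer_loci=m.n_protospacer_loci)
        for m in retained
    ]

    proteins = [(orf_id, rec.contig_id, prot)
                for rec in records for orf_id, prot in rec.proteins()]
    families = cluster_proteins(
        proteins, min_identity=params.protein_min_identity,
        min_coverage=params.protein_min_coverage) if proteins else []
    fam_sets = genome_family_sets(families)
    genome_families = {rec.contig_id: fam_sets.get(rec.contig_id, frozenset())
                       for rec in records}
    network = build_network(genome_families, params.sig_threshold)

    marker_hits: list[MarkerHit] = []
    if markers:
        marker_db = parse_marker_records(markers)
        orf_rows = [(rec.contig_id, i, orf.protein)
                    for rec in records for i, orf in enumerate(rec.orfs)]
        marker_hits = scan_markers(orf_rows, marker_db,
                                   params.marker_min_identity,
                                   params.marker_min_coverage)

    rows = [assign_status(rec, marker_hits,
                          network.clusters.get(rec.contig_id, ""))
            for rec in records]
    return PipelineResult(
        params=params, arrays=arrays, repeat_clusters=clusters,
        trusted_clusters=trusted, catalogue=catalogue, hits=hits,
        candidates=candidates, retained=retained, records=records,
        families=families, network=network, marker_hits=marker_hits,
        rows=rows, summary=summarize(rows))


# ---------------------------------------------------------------------------
# artefact writing


def write_outputs(result: PipelineResult, outdir: str | Path,
                  pool: dict[str, str] | None = None) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_tsv(
        [{"contig": a.contig_id, "start": a.start, "end": a.end,
          "copies": a.repeat_copies, "repeat": a.repeat_consensus,
          "spacers": ",".join(s.seq for s in a.spacers)}
         for a in result.arrays],
        out / "arrays.tsv",
        ["contig", "start", "end", "copies", "repeat", "spacers"])
    write_fasta(
        [(f"{e.spacer_id} {';'.join('%s:%d-%d' % s for s in e.sources)}",
          e.seq) for e in result.catalogue.entries],
        out / "spacers.fasta")
    write_tsv(
        [{"spacer_id": h.spacer_id, "contig": h.target_contig,
          "start": h.start, "end": h.end, "strand": h.strand,
          "mismatches": h.mismatches} for h in result.hits],
        out / "protospacer_hits.tsv",
        ["spacer_id", "contig", "start", "end", "strand", "mismatches"])
    write_tsv(
        [{"contig": m.contig_id, "length": m.length, "source": m.source_label,
          "n_loci": m.n_protospacer_loci, "n_spacers": m.n_distinct_spacers,
          "retained": m.retained_flag} for m in result.candidates],
        out / "mge_candidates.tsv",
        ["contig", "length", "source", "n_loci", "n_spacers", "retained"])
    if pool:
        write_fasta({m.contig_id: pool[m.contig_id]
                     for m in result.retained}, out / "retained_mges.fasta")
    write_fasta([(pid, prot) for rec in result.records
                 for pid, prot in rec.proteins()], out / "proteins.faa")
    write_tsv(
        [{"contig": r.contig_id, "length": r.length, "gc": f"{r.gc:.4f}",
          "n_orfs": len(r.orfs), "topology": r.topology,
          "completeness": r.completeness, "tr_len": r.tr_len}
         for r in result.records],
        out / "mge_summary.tsv",
        ["contig", "length", "gc", "n_orfs", "topology", "completeness",
         "tr_len"])
    write_tsv(
        [{"a": e.a, "b": e.b, "shared": e.shared, "p": f"{e.p:.6g}",
          "score": f"{e.score:.4f}"} for e in result.network.edges],
        out / "network_edges.tsv", ["a", "b", "shared", "p", "score"])
    write_tsv(
        [{"genome": g, "cluster": c}
         for g, c in sorted(result.network.clusters.items())],
        out / "network_clusters.tsv", ["genome", "cluster"])
    write_report(result.rows, out / "report.tsv", out / "report.json")
    meta = {
        "n_arrays": len(result.arrays),
        "n_repeat_clusters": len(result.repeat_clusters),
        "n_trusted_clusters": len(result.trusted_clusters),
        "spacers": result.catalogue.metadata,
        "n_hits": len(result.hits),
        "tally_by_source": result.tally(),
        "summary": result.summary,
    }
    (out / "run_meta.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n")


def run_from_config(config_path: str | Path, outdir: str | Path) -> PipelineResult:
    """Drive a full run from a YAML config (paths + parameter overrides)."""
    cfg = yaml.safe_load(Path(config_path).read_text()) or {}
    hosts = read_fasta(cfg["hosts"])
    pool = read_fasta(cfg["mge_pool"])
    offtarget = (read_fasta(cfg["offtarget_hosts"])
                 if cfg.get("offtarget_hosts") else None)
    markers = read_fasta(cfg["markers"]) if cfg.get("markers") else None
    source_labels = cfg.get("source_labels") or None
    params = PipelineParams()
    for key, value in (cfg.get("params") or {}).items():
        if key == "array_params":
            params.array_params = ArrayParams(**value)
        elif hasattr(params, key):
            setattr(params, key, value)
        else:
            raise ValueError(f"unknown pipeline parameter {key!r}")
    result = run_pipeline(hosts, pool, offtarget, markers, source_labels,
                          params)
    write_outputs(result, outdir, pool)
    (Path(outdir) / "params.json").write_text(json.dumps(
        dataclasses.asdict(params), indent=2, sort_keys=True) + "\n")
    return result
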