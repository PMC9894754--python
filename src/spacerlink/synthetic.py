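"""Seeded synthetic host-virus communities with a full truth table.

The generator emulates the data regime the pipeline assumes: host contigs
carrying repeat-spacer arrays whose spacers are (optionally mutated) copies
of loci on a subset of viral genomes; viral genomes with family-structured
shared gene content, injected hallmark marker genes and DTR/ITR/blunt
termini; decoy contigs with no linkage; and off-target-clade hosts whose
repeats are far from every target-clade repeat.

Everything is drawn from one ``numpy.random.default_rng(seed)`` in a fixed
order, so identical configs reproduce byte-identical FASTA/TSV output.
Background sequence is i.i.d. uniform A/C/G/T and mutations are
substitutions only, matching the gap-free Hamming model of the matcher.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import write_fasta, write_tsv
from .sequtils import revcomp

_AA = "ACDEFGHIKLMNPQRSTVWY"

# codons per amino acid, standard code, stops excluded
_CODONS = {
    "A": ["GCT", "GCC", "GCA", "GCG"], "C": ["TGT", "TGC"],
    "D": ["GAT", "GAC"], "E": ["GAA", "GAG"],
    "F": ["TTT", "TTC"], "G": ["GGT", "GGC", "GGA", "GGG"],
    "H": ["CAT", "CAC"], "I": ["ATT", "ATC", "ATA"],
    "K": ["AAA", "AAG"], "L": ["TTA", "TTG", "CTT", "CTC", "CTA", "CTG"],
    "M": ["ATG"], "N": ["AAT", "AAC"],
    "P": ["CCT", "CCC", "CCA", "CCG"], "Q": ["CAA", "CAG"],
    "R": ["CGT", "CGC", "CGA", "CGG", "AGA", "AGG"],
    "S": ["TCT", "TCC", "TCA", "TCG", "AGT", "AGC"],
    "T": ["ACT", "ACC", "ACA", "ACG"], "V": ["GTT", "GTC", "GTA", "GTG"],
    "W": ["TGG"], "Y": ["TAT", "TAC"],
}

# structural marker classes cycled over family groups when injecting markers
_STRUCTURAL_CYCLE = [
    "HK97-MCP", "DJR-MCP", "alpha-helical-MCP", "spindle-MCP", "SJR-MCP",
    "portal", "TerL",
]

_TERMINUS_LEN = 60          # planted DTR/ITR length, bp
_GENE_MARGIN = 200          # gene/locus-free zone at each genome end, bp
_HOST_BACKBONE = 3000       # host background bp outside arrays
_ARRAY_GAP = 1000           # bp between consecutive arrays on a host


@dataclass
class CommunityConfig:
    """Stated world for one synthetic community; see docs for rationale."""
    n_hosts: int = 5
    n_viruses: int = 12
    n_decoys: int = 6
    n_offtarget_hosts: int = 3
    arrays_per_host: int = 2
    spacers_per_array: int = 8
    spacer_len_range: tuple[int, int] = (30, 40)
    repeat_len: int = 30
    viral_len_range: tuple[int, int] = (11000, 18000)
    spacer_mutation_rate: float = 0.0
    frac_viruses_targeted: float = 0.75
    topology_mix: dict[str, float] = field(
        default_factory=lambda: {"DTR": 0.4, "ITR": 0.4, "none": 0.2})
    n_protein_families_core: int = 20
    n_family_groups: int = 3
    marker_injection: bool = True
    seed: int = 0

    def validate(self) -> None:
        counts = dict(n_hosts=self.n_hosts, n_viruses=self.n_viruses,
                      n_decoys=self.n_decoys,
                      n_offtarget_hosts=self.n_offtarget_hosts,
                      arrays_per_host=self.arrays_per_host,
                      spacers_per_array=self.spacers_per_array,
                      n_protein_families_core=self.n_protein_families_core,
                      n_family_groups=self.n_family_groups)
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for name, v in (("spacer_mutation_rate", self.spacer_mutation_rate),
                        ("frac_viruses_targeted", self.frac_viruses_targeted)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        lo, hi = self.spacer_len_range
        if not (15 <= lo <= hi <= 80):
            raise ValueError("spacer_len_range must lie within [15, 80]")
        if self.repeat_len < 20 or self.repeat_len > 50:
            raise ValueError("repeat_len must be within [20, 50]")
        vlo, vhi = self.viral_len_range
        if not (0 < vlo <= vhi):
            raise ValueError("invalid viral_len_range")
        if abs(sum(self.topology_mix.values()) - 1.0) > 1e-9:
            raise ValueError("topology_mix proportions must sum to 1")
        if set(self.topology_mix) - {"DTR", "ITR", "none"}:
            raise ValueError("topology_mix keys must be DTR/ITR/none")


@dataclass(frozen=True)
class PlantedLocus:
    """One protospacer locus planted on a virus (0-based, half-open)."""
    virus_id: str
    start: int
    end: int
    strand: str
    spacer_id: str


@dataclass
class TruthTable:
    linked_pairs: set[tuple[str, str]]
    protospacer_loci: list[PlantedLocus]
    virus_topology: dict[str, str]
    family_group: dict[str, int]

    def linked_mge_ids(self) -> set[str]:
        return {v for _, v in self.linked_pairs}


@dataclass
class SyntheticCommunity:
    config: CommunityConfig
    hosts: dict[str, str]
    offtarget_hosts: dict[str, str]
    mge_pool: dict[str, str]
    markers: dict[str, str]           # "marker_id|class" -> protein
    truth: TruthTable
    planted_spacers: dict[str, str]   # spacer_id -> spacer sequence as stored
    planted_proteins: dict[str, list[tuple[str, str]]]
    # virus_id -> [(protein_id, protein)] for every planted gene

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write FASTAs, truth TSV and a flat key-value config file."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "hosts": outdir / "hosts.fasta",
            "offtarget_hosts": outdir / "offtarget_hosts.fasta",
            "mge_pool": outdir / "mge_pool.fasta",
            "markers": outdir / "markers.faa",
            "truth": outdir / "truth.tsv",
            "config": outdir / "config.txt",
        }
        write_fasta(self.hosts, paths["hosts"])
        write_fasta(self.offtarget_hosts, paths["offtarget_hosts"])
        write_fasta(self.mge_pool, paths["mge_pool"])
        write_fasta(self.markers, paths["markers"])
        rows = []
        for h, v in sorted(self.truth.linked_pairs):
            rows.append({"record_type": "link", "id1": h, "id2": v,
                         "start": "", "end": "", "strand": "", "extra": ""})
        for loc in self.truth.protospacer_loci:
            rows.append({"record_type": "protospacer", "id1": loc.virus_id,
                         "id2": loc.spacer_id, "start": loc.start,
                         "end": loc.end, "strand": loc.strand, "extra": ""})
        for vid in sorted(self.truth.virus_topology):
            rows.append({"record_type": "topology", "id1": vid, "id2": "",
                         "start": "", "end": "", "strand": "",
                         "extra": self.truth.virus_topology[vid]})
        for vid in sorted(self.truth.family_group):
            rows.append({"record_type": "family_group", "id1": vid, "id2": "",
                         "start": "", "end": "", "strand": "",
                         "extra": self.truth.family_group[vid]})
        write_tsv(rows, paths["truth"],
                  ["record_type", "id1", "id2", "start", "end", "strand",
                   "extra"])
        with open(paths["config"], "w") as fh:
            for f in dataclasses.fields(self.config):
                fh.write(f"{f.name}\t{getattr(self.config, f.name)}\n")
        return paths


def _infeasible(msg: str) -> ValueError:
    return ValueError(f"config infeasible: {msg}")


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


def _random_protein(rng: np.random.Generator, n_aa: int) -> str:
    body = "".join(np.array(list(_AA))[rng.integers(0, 20, n_aa - 1)])
    return "M" + body


def _backtranslate(rng: np.random.Generator, protein: str) -> str:
    return "".join(
        _CODONS[aa][rng.integers(0, len(_CODONS[aa]))] for aa in protein)


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Per-base substitutions at ``rate``, with the per-spacer count capped
    at ceil(len * rate * 3): a spacer is a mutated copy of its protospacer,
    never an unrecognizably distant one (generator contract)."""
    if rate <= 0:
        return seq
    cap = math.ceil(len(seq) * rate * 3)
    flip = [i for i in range(len(seq)) if rng.random() < rate][:cap]
    out = list(seq)
    for i in flip:
        out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


def _gene_cassette(rng: np.random.Generator, protein: str) -> str:
    """In-frame stop, start codon + body, stop codon. The leading stop pins
    the ORF caller's earliest-start rule to the planted start."""
    return "TAA" + "ATG" + _backtranslate(rng, protein[1:]) + "TAA"


def generate_community(config: CommunityConfig) -> SyntheticCommunity:
    """Build one community; see module docstring for the generative model.

    Raises ValueError("config infeasible: ...") when the requested spacer
    load cannot be donated by the viral genomes, and on invalid configs.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    sp_lo, sp_hi = config.spacer_len_range

    n_targeted = (round(config.frac_viruses_targeted * config.n_viruses)
                  if config.n_viruses else 0)
    slots_per_host = config.arrays_per_host * config.spacers_per_array
    if n_targeted:
        if config.n_hosts == 0:
            raise _infeasible("targeted viruses but no hosts")
        if config.spacers_per_array < 2 or config.arrays_per_host < 1:
            raise _infeasible("arrays cannot hold the minimum 3 loci/virus")
        per_host = -(-n_targeted // config.n_hosts)  # ceil
        if slots_per_host < 3 * per_host:
            raise _infeasible(
                f"{slots_per_host} spacer slots per host cannot give >=3 "
                f"protospacers to each of {per_host} assigned viruses")

    # ----- viruses: family groups, planted genes, termini -----------------
    groups = max(1, config.n_family_groups)
    core_prots: dict[int, list[tuple[str, str]]] = {}
    core_nt: dict[str, str] = {}
    markers: dict[str, str] = {}
    marker_of_group: dict[int, tuple[str, str]] = {}
    for g in range(groups):
        prots = []
        for j in range(config.n_protein_families_core):
            pid = f"core_g{g:02d}_{j:02d}"
            prot = _random_protein(rng, int(rng.integers(80, 131)))
            prots.append((pid, prot))
            core_nt[pid] = _gene_cassette(rng, prot)
        core_prots[g] = prots
        if config.marker_injection:
            cls = _STRUCTURAL_CYCLE[g % len(_STRUCTURAL_CYCLE)]
            mid = f"mk{g:02d}"
            prot = _random_protein(rng, int(rng.integers(150, 251)))
            markers[f"{mid}|{cls}"] = prot
            marker_of_group[g] = (mid, prot)
            core_nt[mid] = _gene_cassette(rng, prot)

    topo_items = sorted(config.topology_mix.items())
    topo_labels = [k for k, _ in topo_items]
    topo_probs = np.array([p for _, p in topo_items], dtype=float)
    topo_probs /= topo_probs.sum()

    mge_pool: dict[str, str] = {}
    virus_ids: list[str] = []
    gene_regions: dict[str, list[tuple[int, int]]] = {}
    planted_proteins: dict[str, list[tuple[str, str]]] = {}
    virus_topology: dict[str, str] = {}
    family_group: dict[str, int] = {}

    for i in range(config.n_viruses):
        vid = f"virus{i:04d}"
        virus_ids.append(vid)
        g = i % groups
        family_group[vid] = g
        length = int(rng.integers(config.viral_len_range[0],
                                  config.viral_len_range[1] + 1))
        seq = list(_random_dna(rng, length))
        cassettes = list(core_prots[g])
        if config.marker_injection:
            cassettes.append(marker_of_group[g])
        regions: list[tuple[int, int]] = []
        pos = _GENE_MARGIN
        planted_proteins[vid] = []
        for pid, prot in cassettes:
            pos += int(rng.integers(20, 81))  # intergenic gap
            cass = core_nt[pid]
            strand = "+" if rng.random() < 0.5 else "-"
            ins = cass if strand == "+" else revcomp(cass)
            if pos + len(ins) > length - _GENE_MARGIN:
                raise _infeasible(
                    f"virus of {length} bp cannot hold "
                    f"{len(cassettes)} planted genes")
            seq[pos:pos + len(ins)] = ins
            regions.append((pos, pos + len(ins)))
            planted_proteins[vid].append((pid, prot))
            pos += len(ins)
        gene_regions[vid] = regions

        topo = topo_labels[int(rng.choice(len(topo_labels), p=topo_probs))]
        virus_topology[vid] = topo
        k = _TERMINUS_LEN
        if topo == "DTR":
            seq[-k:] = seq[:k]
        elif topo == "ITR":
            seq[-k:] = list(revcomp("".join(seq[:k])))
        mge_pool[vid] = "".join(seq)

    # ----- spacer donation plan -------------------------------------------
    targeted = virus_ids[:n_targeted]
    host_ids = [f"host{i:04d}" for i in range(config.n_hosts)]
    viruses_of_host: dict[str, list[str]] = {h: [] for h in host_ids}
    for i, vid in enumerate(targeted):
        viruses_of_host[host_ids[i % config.n_hosts]].append(vid)

    linked_pairs: set[tuple[str, str]] = set()
    loci: list[PlantedLocus] = []
    planted_spacers: dict[str, str] = {}
    used: dict[str, list[tuple[int, int]]] = {v: list(gene_regions[v])
                                              for v in virus_ids}

    def donate_locus(vid: str, spacer_id: str) -> str:
        length = len(mge_pool[vid])
        sp_len = int(rng.integers(sp_lo, sp_hi + 1))
        for _ in range(200):
            start = int(rng.integers(_GENE_MARGIN,
                                     length - _GENE_MARGIN - sp_len))
            end = start + sp_len
            if any(start < e and s < end for s, e in used[vid]):
                continue
            used[vid].append((start, end))
            strand = "+" if rng.random() < 0.5 else "-"
            proto = mge_pool[vid][start:end]
            spacer = proto if strand == "+" else revcomp(proto)
            spacer = _mutate(rng, spacer, config.spacer_mutation_rate)
            loci.append(PlantedLocus(vid, start, end, strand, spacer_id))
            return spacer
        raise _infeasible(
            f"cannot place a protospacer locus on {vid}: the requested "
            "spacer load exceeds what the viral lengths can donate")

    # ----- hosts with repeat-spacer arrays --------------------------------
    clade_repeat = _random_dna(rng, config.repeat_len)
    hosts: dict[str, str] = {}
    for h in host_ids:
        donors = viruses_of_host[h]
        spacer_seqs: list[str] = []
        slot = 0
        for a in range(config.arrays_per_host):
            for s in range(config.spacers_per_array):
                spacer_id = f"{h}_a{a}_s{s}"
                if donors:
                    vid = donors[slot % len(donors)]
                    spacer = donate_locus(vid, spacer_id)
                    linked_pairs.add((h, vid))
                else:
                    spacer = _random_dna(
                        rng, int(rng.integers(sp_lo, sp_hi + 1)))
                spacer_seqs.append(spacer)
                planted_spacers[spacer_id] = spacer
                slot += 1
        contig = _random_dna(rng, _HOST_BACKBONE)
        pieces = [contig[:_HOST_BACKBONE // 2]]
        idx = 0
        for a in range(config.arrays_per_host):
            arr = clade_repeat
            for s in range(config.spacers_per_array):
                arr += spacer_seqs[idx] + clade_repeat
                idx += 1
            pieces.append(arr)
            pieces.append(_random_dna(rng, _ARRAY_GAP))
        pieces.append(contig[_HOST_BACKBONE // 2:])
        hosts[h] = "".join(pieces)

    # ----- off-target-clade hosts -----------------------------------------
    offtarget: dict[str, str] = {}
    if config.n_offtarget_hosts:
        while True:
            off_repeat = _random_dna(rng, config.repeat_len)
            dist = sum(x != y for x, y in zip(off_repeat, clade_repeat))
            if dist >= 10:
                break
        for i in range(config.n_offtarget_hosts):
            oid = f"ofth{i:04d}"
            spacer_seqs = [
                _random_dna(rng, int(rng.integers(sp_lo, sp_hi + 1)))
                for _ in range(config.spacers_per_array)
            ]
            arr = off_repeat
            for sp in spacer_seqs:
                arr += sp + off_repeat
            flank = _random_dna(rng, _HOST_BACKBONE)
            offtarget[oid] = (flank[:_HOST_BACKBONE // 2] + arr
                              + flank[_HOST_BACKBONE // 2:])

    # ----- decoys ----------------------------------------------------------
    for i in range(config.n_decoys):
        length = int(rng.integers(config.viral_len_range[0],
                                  config.viral_len_range[1] + 1))
        mge_pool[f"decoy{i:04d}"] = _random_dna(rng, length)

    truth = TruthTable(linked_pairs=linked_pairs, protospacer_loci=loci,
                       virus_topology=virus_topology,
                       family_group=family_group)
    return SyntheticCommunity(
        config=config, hosts=hosts, offtarget_hosts=offtarget,
        mge_pool=mge_pool, markers=markers, truth=truth,
        planted_spacers=planted_spacers, planted_proteins=planted_proteins)


def evaluate_predictions(predicted: set, truth) -> tuple[float, float]:
    """Set precision/recall with the empty-set conventions: precision is 1.0
    when nothing was predicted, recall is 1.0 when the truth is empty.

    ``truth`` may be a plain set or a TruthTable; with a TruthTable both
    sides are reduced to MGE ids (the pipeline links at clade level, so a
    predicted pair's last element is the MGE id).
    """
    if isinstance(truth, TruthTable):
        truth_set = truth.linked_mge_ids()
        predicted = {p[-1] if isinstance(p, tuple) else p for p in predicted}
    else:
        truth_set = set(truth)
        predicted = set(predicted)
    tp = len(predicted & truth_set)
    precision = tp / len(predicted) if predicted else 1.0
    recall = tp / len(truth_set) if truth_set else 1.0
    return precision, recall
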