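"""Array detection, repeat trust, cross-clade exclusion, spacer catalogue."""

import numpy as np
import pytest

from spacerlink import (ArrayParams, CommunityConfig, CrisprArray,
                        build_spacer_catalogue, cluster_repeats,
                        detect_arrays, exclude_cross_clade,
                        generate_community)
from spacerlink.crispr import Spacer, catalogue_from_spacers, same_repeat
from spacerlink.sequtils import canonical, revcomp

from .conftest import random_dna
from .oracles import brute_force_arrays


def _mk_array(contig, start, repeat, spacers):
    pos = start
    spacer_objs = []
    for sp in spacers:
        pos += len(repeat)
        spacer_objs.append(Spacer(sp, pos, pos + len(sp)))
        pos += len(sp)
    return CrisprArray(contig_id=contig, start=start,
                       end=pos + len(repeat), repeat_consensus=repeat,
                       repeat_copies=len(spacers) + 1, spacers=spacer_objs)


# ---------------------------------------------------------------------------
# detect_arrays


def test_detect_planted_array_with_exact_coordinates(rng):
    repeat = random_dna(rng, 30)
    spacers = [random_dna(rng, 34) for _ in range(3)]
    u0, u1 = random_dna(rng, 500), random_dna(rng, 500)
    contig = u0 + repeat
    for sp in spacers:
        contig += sp + repeat
    contig += u1
    arrays = detect_arrays({"c1": contig})
    assert len(arrays) == 1
    arr = arrays[0]
    assert arr.start == 500
    assert arr.end == 500 + 4 * 30 + 3 * 34
    assert arr.repeat_copies == 4
    assert arr.repeat_consensus == repeat
    assert [s.seq for s in arr.spacers] == spacers
    assert len(arr.spacers) == arr.repeat_copies - 1
    # coordinates index back into the contig
    for s in arr.spacers:
        assert contig[s.start:s.end] == s.seq


def test_random_contig_has_no_arrays(rng):
    assert detect_arrays({"c": random_dna(rng, 10_000)}) == []


def test_two_repeat_copies_are_below_threshold(rng):
    repeat = random_dna(rng, 30)
    contig = (random_dna(rng, 400) + repeat + random_dna(rng, 34)
              + repeat + random_dna(rng, 400))
    assert detect_arrays({"c": contig}) == []


def test_detection_matches_exhaustive_scan_on_small_contigs(rng):
    """Spot-check of the equivalence oracle on mixed contigs (the full
    50-pool sweep lives in the acceptance suite)."""
    for trial in range(5):
        repeat = random_dna(rng, int(rng.integers(20, 41)))
        contig = random_dna(rng, 300) + repeat
        for _ in range(int(rng.integers(2, 5))):
            contig += random_dna(rng, int(rng.integers(15, 60))) + repeat
        contig += random_dna(rng, 300)
        got = [(a.start, a.end, a.repeat_consensus, a.repeat_copies,
                tuple(s.seq for s in a.spacers))
               for a in detect_arrays({"c": contig})]
        assert sorted(got) == brute_force_arrays(contig)


def test_malformed_fasta_names_record(tmp_path):
    from spacerlink.io import read_fasta
    bad = tmp_path / "dup.fasta"
    bad.write_text(">x\nACGT\n>x\nACGT\n")
    with pytest.raises(ValueError, match="x"):
        read_fasta(bad)


# ---------------------------------------------------------------------------
# repeat clustering and trust


def test_repeat_on_three_contigs_is_trusted(rng):
    rep = random_dna(rng, 32)
    arrays = [_mk_array(c, 10, rep, [random_dna(rng, 30)] * 2)
              for c in ("c1", "c2", "c3")]
    (cluster,) = cluster_repeats(arrays)
    assert cluster.n_distinct_contigs == 3
    assert cluster.trusted


def test_repeat_on_two_contigs_is_untrusted(rng):
    rep = random_dna(rng, 32)
    arrays = [_mk_array(c, 10, rep, [random_dna(rng, 30)] * 2)
              for c in ("c1", "c2")]
    (cluster,) = cluster_repeats(arrays)
    assert not cluster.trusted


def test_three_arrays_on_one_contig_count_as_one_contig(rng):
    rep = random_dna(rng, 32)
    arrays = [_mk_array("c1", s, rep, [random_dna(rng, 30)] * 2)
              for s in (10, 500, 1000)]
    (cluster,) = cluster_repeats(arrays)
    assert cluster.n_distinct_contigs == 1
    assert not cluster.trusted


def test_same_repeat_tolerates_near_identity_and_strand(rng):
    rep = random_dna(rng, 30)
    mutated = "G" + rep[1:] if rep[0] != "G" else "C" + rep[1:]
    assert same_repeat(rep, mutated)          # 29/30 identity
    assert same_repeat(rep, revcomp(rep))     # strand-agnostic
    assert not same_repeat(rep, random_dna(rng, 30))


def test_exclude_cross_clade(rng):
    reps = [random_dna(rng, 30) for _ in range(3)]
    target = cluster_repeats(
        [_mk_array(f"c{i}{j}", 10, rep, [random_dna(rng, 30)] * 2)
         for i, rep in enumerate(reps) for j in range(3)])
    assert all(c.trusted for c in target)
    # empty off-target list: unchanged
    assert exclude_cross_clade(target, []) == target
    # one consensus shared with the off-target clade: dropped
    off = cluster_repeats(
        [_mk_array(f"o{j}", 10, reps[0], [random_dna(rng, 30)] * 2)
         for j in range(3)])
    kept = exclude_cross_clade(target, off)
    assert len(kept) == 2
    assert canonical(reps[0]) not in {c.consensus for c in kept}


def test_distant_offtarget_repeat_is_retained(rng):
    rep = random_dna(rng, 30)
    # Hamming distance 12: far below the 90% identity threshold
    far = list(rep)
    for i in range(12):
        far[i] = "A" if rep[i] != "A" else "C"
    far = "".join(far)
    target = cluster_repeats(
        [_mk_array(f"c{j}", 10, rep, [random_dna(rng, 30)] * 2)
         for j in range(3)])
    off = cluster_repeats(
        [_mk_array(f"o{j}", 10, far, [random_dna(rng, 30)] * 2)
         for j in range(3)])
    assert exclude_cross_clade(target, off) == target


# ---------------------------------------------------------------------------
# spacer catalogue


def test_canonicalization_merges_reverse_complements():
    s = "ACGTACGTACGTACGTAC"
    cat = catalogue_from_spacers([(s, ("c1", 0, 18)),
                                  (revcomp(s), ("c2", 5, 23))])
    assert cat.n_unique == 1
    assert len(cat.entries[0].sources) == 2


def test_distinct_spacers_stay_distinct(rng):
    rep = random_dna(rng, 32)
    arrays = [
        _mk_array(f"c{i}", 10, rep, [random_dna(rng, 31) for _ in range(3)])
        for i in range(3)
    ]
    clusters = cluster_repeats(arrays)
    cat = build_spacer_catalogue(arrays, clusters)
    assert cat.n_unique == 9


def test_dedup_is_idempotent(rng):
    seqs = [random_dna(rng, 30) for _ in range(6)] * 2
    cat = catalogue_from_spacers([(s, ("c", i, i + 30))
                                  for i, s in enumerate(seqs)])
    again = catalogue_from_spacers([(e.seq, e.sources[0])
                                    for e in cat.entries])
    assert [e.seq for e in again.entries] == [e.seq for e in cat.entries]
    assert again.n_unique == cat.n_unique


def test_untrusted_arrays_contribute_no_spacers(rng):
    rep = random_dna(rng, 32)
    arrays = [_mk_array("c1", 10, rep, [random_dna(rng, 30)] * 2)]
    clusters = cluster_repeats(arrays)  # one contig: untrusted
    cat = build_spacer_catalogue(arrays, clusters)
    assert cat.n_unique == 0


def test_revcomp_of_all_contigs_preserves_catalogue(rng):
    """Strand invariance of the full detect -> trust -> catalogue chain."""
    com = generate_community(CommunityConfig(seed=23))
    fwd = com.hosts
    rev = {k: revcomp(v) for k, v in fwd.items()}
    cats = []
    for contigs in (fwd, rev):
        arrays = detect_arrays(contigs)
        clusters = cluster_repeats(arrays)
        cats.append(build_spacer_catalogue(arrays, clusters))
    assert cats[0].n_unique == cats[1].n_unique
    assert set(cats[0].sequences()) == set(cats[1].sequences())


def test_planted_arrays_recovered_exactly_over_seeds():
    """Mutation-free communities: every planted spacer sequence appears in
    the detected catalogue (recall 1.0), over 20 seeded runs."""
    small = dict(n_viruses=4, n_decoys=0, n_offtarget_hosts=0,
                 n_protein_families_core=3, n_family_groups=2,
                 frac_viruses_targeted=1.0)
    for seed in range(20):
        com = generate_community(CommunityConfig(seed=seed, **small))
        arrays = detect_arrays(com.hosts)
        clusters = cluster_repeats(arrays)
        cat = build_spacer_catalogue(arrays, clusters)
        planted = {canonical(s) for s in com.planted_spacers.values()}
        assert planted <= set(cat.sequences())
        n_arrays = sum(1 for _ in arrays)
        assert n_arrays == com.config.n_hosts * com.config.arrays_per_host


def test_detect_rejects_empty_input():
    with pytest.raises(ValueError):
        detect_arrays({})


def test_params_bounds_validated():
    with pytest.raises(ValueError):
        detect_arrays({"c": "ACGT" * 100}, ArrayParams(min_copies=1))
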