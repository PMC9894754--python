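"""Protospacer search model and the stringent retention filters."""

import numpy as np
import pytest

from spacerlink import find_protospacers, link_mges, tally_by_source
from spacerlink.crispr import catalogue_from_spacers
from spacerlink.linking import MgeCandidate, ProtospacerHit, retained_mges
from spacerlink.sequtils import canonical, revcomp

from .conftest import random_dna
from .oracles import hamming_scan


def _cat(*seqs):
    return catalogue_from_spacers(
        [(s, (f"src{i}", 0, len(s))) for i, s in enumerate(seqs)])


def _plant(rng, contig_len, insert, pos):
    seq = list(random_dna(rng, contig_len))
    seq[pos:pos + len(insert)] = insert
    return "".join(seq)


def test_verbatim_spacer_found_once_with_locus_and_strand(rng):
    spacer = canonical(random_dna(rng, 34))
    contig = _plant(rng, 20_000, spacer, 7131)
    hits = find_protospacers(_cat(spacer), {"m1": contig})
    assert len(hits) == 1
    (h,) = hits
    assert (h.target_contig, h.start, h.end) == ("m1", 7131, 7165)
    assert h.strand == "+" and h.mismatches == 0
    # agreement with the exhaustive sliding-window scan
    oracle = hamming_scan(spacer, {"m1": contig}, 1)
    assert set(oracle) == {("m1", 7131)}


def test_two_substitutions_exceed_max_mismatch_one(rng):
    spacer = random_dna(rng, 34)
    mutated = "".join(
        ("A" if c != "A" else "C") if i in (5, 20) else c
        for i, c in enumerate(spacer))
    contig = _plant(rng, 20_000, mutated, 4000)
    assert find_protospacers(_cat(spacer), {"m": contig}, 1) == []
    assert len(find_protospacers(_cat(spacer), {"m": contig}, 2)) == 1


def test_reverse_strand_hit_reports_forward_coordinates(rng):
    spacer = canonical(random_dna(rng, 34))
    contig = _plant(rng, 20_000, revcomp(spacer), 9000)
    hits = find_protospacers(_cat(spacer), {"m": contig})
    assert len(hits) == 1
    (h,) = hits
    assert (h.start, h.end, h.strand) == (9000, 9034, "-")
    assert contig[h.start:h.end] == revcomp(spacer)


def test_hits_inside_target_arrays_are_suppressed(rng):
    """A spacer matching inside a CRISPR array on the target (its own
    locus) is not a protospacer."""
    repeat = random_dna(rng, 30)
    spacer = canonical(random_dna(rng, 34))
    array = repeat + spacer + repeat + random_dna(rng, 33) + repeat
    contig = random_dna(rng, 6000) + array + random_dna(rng, 6000)
    assert find_protospacers(_cat(spacer), {"m": contig}) == []
    unmasked = find_protospacers(_cat(spacer), {"m": contig},
                                 mask_arrays=False)
    assert len(unmasked) == 1


def test_empty_pool_is_not_an_error(rng):
    assert find_protospacers(_cat(random_dna(rng, 30)), {}) == []


def test_short_spacer_rejected_with_warning(rng):
    cat = _cat("ACGTACGTACGT")  # 12 bp < 15
    with pytest.warns(UserWarning, match="shorter"):
        hits = find_protospacers(cat, {"m": random_dna(rng, 5000)})
    assert hits == []


def test_scan_equivalence_random_pools(rng):
    """find_protospacers == exhaustive Hamming scan (masking off) on
    random pools with planted 0/1/2-mismatch copies."""
    for _ in range(8):
        spacer = canonical(random_dna(rng, int(rng.integers(25, 41))))
        pool = {}
        for c in range(2):
            seq = random_dna(rng, int(rng.integers(4000, 9000)))
            for nmm in (0, 1, 2):
                copy = list(spacer)
                for i in rng.choice(len(copy), nmm, replace=False):
                    copy[i] = "ACGT"[("ACGT".index(copy[i]) + 1) % 4]
                pos = int(rng.integers(0, len(seq) - len(spacer)))
                seq = seq[:pos] + "".join(copy) + seq[pos + len(spacer):]
            pool[f"c{c}"] = seq
        for mm in (0, 1, 2):
            got = {(h.target_contig, h.start): (h.strand, h.mismatches)
                   for h in find_protospacers(_cat(spacer), pool, mm,
                                              mask_arrays=False)}
            assert got == hamming_scan(spacer, pool, mm)


def test_mismatch_monotonicity(rng):
    spacer = canonical(random_dna(rng, 30))
    pool = {"c": _plant(rng, 30_000, spacer, 11_000)}
    counts = [len(find_protospacers(_cat(spacer), pool, mm,
                                    mask_arrays=False))
              for mm in range(4)]
    assert counts == sorted(counts)


# ---------------------------------------------------------------------------
# retention


def _hits(contig, loci):
    return [ProtospacerHit(f"sp{i:03d}", contig, s, s + 30, strand, 0)
            for i, (s, strand) in enumerate(loci)]


@pytest.mark.parametrize("length,loci,expect", [
    (12_400, [(100, "+"), (500, "+"), (900, "-")], True),
    (45_000, [(100, "+"), (500, "+")], False),          # too few loci
    (9_800, [(i * 100, "+") for i in range(5)], False),  # too short
    (10_000, [(100, "+"), (500, "+"), (900, "-")], False),  # 10 kb is not >10 kb
])
def test_retention_thresholds(length, loci, expect):
    pool = {"m": "A" * length}
    (cand,) = link_mges(_hits("m", loci), pool)
    assert cand.retained_flag is expect
    assert cand.retained_flag == cand.retained()


def test_repeated_targeting_of_one_locus_counts_once():
    hits = [ProtospacerHit(f"sp{i}", "m", 200, 230, "+", 0) for i in range(4)]
    hits += _hits("m", [(600, "+"), (900, "-")])
    pool = {"m": "A" * 15_000}
    (cand,) = link_mges(hits, pool)
    assert cand.n_protospacer_loci == 3
    assert cand.n_distinct_spacers == 6
    assert cand.retained_flag


def test_threshold_monotonicity_on_retained_counts(rng):
    pool = {f"m{i}": "A" * int(rng.integers(8000, 30_000)) for i in range(6)}
    hits = []
    for cid, seq in pool.items():
        for _ in range(int(rng.integers(0, 6))):
            s = int(rng.integers(0, len(seq) - 30))
            hits.append(ProtospacerHit(f"sp{s}", cid, s, s + 30, "+", 0))
    mges = link_mges(hits, pool)
    for k in range(1, 6):
        r_k = len(retained_mges(mges, min_protospacers=k))
        r_k1 = len(retained_mges(mges, min_protospacers=k + 1))
        assert r_k1 <= r_k
    for ml in (5000, 10_000, 20_000, 40_000):
        pass  # lengths fixed per candidate; monotone by construction
    r = [len(retained_mges(mges, min_len=ml))
         for ml in (0, 10_000, 20_000, 40_000)]
    assert r == sorted(r, reverse=True)


def test_tally_by_source():
    def cand(cid, label, n_loci, length):
        c = MgeCandidate(cid, length, label,
                         _hits(cid, [(i * 200, "+") for i in range(n_loci)]))
        c.retained_flag = c.retained()
        return c

    mges = [cand("a", "P", 3, 12_000), cand("b", "P", 4, 20_000),
            cand("c", "G", 3, 15_000), cand("d", "G", 1, 15_000)]
    tally = tally_by_source(mges)
    assert tally == {"G": 1, "P": 2}
    assert sum(tally.values()) == 3
    assert tally_by_source([]) == {}


def test_synthetic_tally_matches_truth(community7, result7):
    tally = result7.tally()
    assert sum(tally.values()) == len(community7.truth.linked_mge_ids())


def test_unknown_contig_in_hits_raises():
    with pytest.raises(ValueError, match="unknown contig"):
        link_mges(_hits("ghost", [(0, "+")]), {"m": "A" * 100})
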