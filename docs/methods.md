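# Methods

`spacerlink` discovers host-linked mobile genetic elements (MGEs) in
metagenome assemblies from CRISPR immunity records. CRISPR arrays on host
contigs store spacers sampled from past invaders; an exact-model match of a
spacer back onto a candidate contig (a protospacer) is direct evidence that
the element infected, or was at least encountered by, the host clade. The
pipeline turns this signal into a curated MGE set with topology calls, a
gene-sharing network delineating family-level groups, and a virus /
unclassified-MGE label per element.

## Array detection model

An array is modelled as >= 3 exact copies of a repeat string (20-50 bp)
separated by spacer gaps of 15-75 bp; arrays are maximal copy chains, and
overlapping candidates on a contig are resolved by most copies, then
longest span, then leftmost position. Two repeat copies are not accepted:
a pair of identical substrings at spacer-like distance arises too easily by
chance or from genuine non-CRISPR repeats.

Copies are required to be *exact* matches. Degenerate trailing copies are
common in real arrays, but an exact-copy model makes the detector's output
a well-defined function of the sequence, provably equivalent to an
exhaustive all-substrings tandem scan (the equivalence is asserted in the
test suite on small contigs). The detector seeds candidate repeats from
repeated k-mers (k = minimum repeat length): any string occurring >= 3
times contains a k-prefix occurring >= 3 times, so the seeded candidate
set is complete while keeping detection near-linear on random sequence.
Repeats containing N are rejected.

A maximal repeat is only defined up to its flanks: if every copy happens to
be followed by the same base, the repeat absorbs it and every spacer shifts
by one. With realistic spacer counts per array (>= 5) the probability is
negligible; tests that plant tiny arrays pin the boundaries explicitly.

## Repeat trust and the spacer catalogue

Spacers are trusted at the clade level, not per contig:

* a repeat must be observed on >= 3 distinct contigs of the clade
  (`min_contigs = 3`). Mis-binned or chimeric contigs rarely replicate a
  repeat across three independent contigs;
* repeats also found in an off-target sister clade (screened with the same
  trust rule) are discarded, since their spacers cannot be attributed to
  the target clade.

"Same repeat" means >= 90% identity over the shorter sequence in the best
ungapped offset alignment, on either strand, with length difference
<= 2 bp — tolerant of array-edge degeneracy while keeping clusters
clade-specific. Spacer orientation is not observable from sequence alone,
so each spacer is canonicalized to the lexicographic minimum of itself and
its reverse complement before exact deduplication; the catalogue metadata
reports both the canonical and the strand-aware unique counts, since
published "unique spacer" figures rarely state their convention.

## Protospacer matching and retention

Matching is gap-free over the full spacer length with at most one
substitution by default (`max_mismatch = 1`), on both strands — the
strictest defensible model, exposed as a flag. The implementation uses the
pigeonhole principle (a window with <= m mismatches contains an exact copy
of one of m+1 disjoint spacer chunks) and is exactly equivalent to a
sliding-window Hamming scan, which the tests assert. Hits overlapping a
CRISPR array on the *target* contig (padded by one repeat length) are
suppressed: a spacer matching another array is shared immunity, not an
infection record. Palindromic spacers match both strands at one locus and
are reported once, forward strand preferred.

Retention requires >= 3 distinct protospacer loci — counted by (start,
strand), so near-identical spacers hammering one locus count once; a flag
switches to counting distinct spacers — and contig length strictly greater
than 10 kb. Both thresholds are the conservative published-practice
defaults for this kind of screen and are configurable.

## Topology and completeness

The longest exact terminal repeat is computed in both senses: direct (the
longest proper border, via the KMP failure function, capped at half the
sequence length) and inverted (the longest common prefix of the sequence
and its reverse complement). A direct terminal repeat (DTR) >= 20 bp calls
`circular-DTR`; otherwise an inverted one calls `linear-ITR`; otherwise
`unresolved`. DTR is checked first because palindromic termini satisfy
both. A chance 20-bp terminal match on random sequence has probability
~1e-10, so the threshold effectively never fires spuriously; mismatches in
terminal repeats are not modelled. Completeness is strictly termini-based
(`complete` iff topology is resolved); assemblies that a curator would
accept as complete on other grounds stay `unknown` here by design.

ORF calling scans all six frames for stop-terminated ORFs >= 50 aa with
ATG/GTG/TTG starts, translation table 11, alternative starts rendered as
M. Within a stop-bounded segment the earliest start wins, which collapses
nested same-frame ORFs into the longest; ORFs nested across frames are
kept, because overlapping genes in different frames are real in compact
MGE genomes. ORFs running off the contig end are dropped (not
stop-terminated).

## Gene-sharing network

Proteins are clustered into families by greedy centroid clustering:
proteins sorted by decreasing length (ties by id) join the first centroid
reaching 50% identity over 80% of the shorter length (local alignment,
match 2 / mismatch -1 / gap open -5 / extend -1); identity is computed
over aligned columns and coverage as the aligned span fraction of the
shorter sequence. A shared-4-mer prescreen (>= 3 shared 4-mers) skips
alignments that cannot plausibly reach the floor; two random 200-aa
proteins share ~0.24 4-mers in expectation, so the prescreen removes
essentially all background pairs without touching genuine ones.

For genomes with a and b families sharing c of the n families in the
dataset, the edge p-value is the exact hypergeometric tail
P(X >= c), X ~ HG(n, a, b), summed with integer binomials (no continuity
or normal approximation). The significance score is -log10(p * n_pairs)
with n_pairs = C(#genomes, 2), the number of pairs tested; edges with
score >= 1 are kept and clusters are the connected components of the kept
graph. Sub-cluster refinement and cluster-confidence statistics of the
tool this emulates are deliberately out of scope.

## Classification

An element is a `virus` iff at least one ORF hits a *structural* hallmark
class (HK97-fold MCP, double/single jelly-roll MCP, alpha-helical MCP,
spindle MCP, portal, TerL) at >= 30% identity over >= 50% of the marker
length; replication hallmarks (pPolB, rPolB) never confer virus status —
plasmids borrow replicases freely, and circular elements without
structural genes are plausibly plasmids. Profile-HMM and structure-based
marker discovery are out of scope: markers are user-supplied protein sets
(`marker_id|class` FASTA headers), which preserves the classification
*rule* while remaining desk-scale and deterministic. Elements that lack
markers but sit in a network cluster with viruses stay `unclassified-MGE`;
guilt by association is reported via the shared cluster id, not promoted
into a status.

## Synthetic communities

The generator emulates exactly the regime the pipeline assumes: hosts with
repeat-spacer arrays whose spacers are mutated copies of viral loci,
family-structured viral genomes with injected hallmark genes and
DTR/ITR/blunt termini, decoys with no linkage, and an off-target clade
with a repeat >= 10 substitutions from the target repeat. Defaults (the
stated world; chosen once, before any test outcome was seen): 5 hosts x 2
arrays x 8 spacers, 30-bp repeat, 30-40 bp spacers, 12 viruses of
11-18 kb in 3 family groups, 75% targeted, 6 decoys, 3 off-target hosts,
topology mix 0.4/0.4/0.2 DTR/ITR/none, mutation rate 0.

Choices that matter:

* **20 core families per group.** Random 11-18 kb background yields ~30-50
  spurious >= 50-aa ORFs per genome, all singleton families. With g core
  genes shared in a 3-member group and ~40 junk singletons each, the
  within-group hypergeometric test must clear -log10(p * 36) >= 1; at
  g ~ 6 the expected chance overlap (~a*b/n) nearly equals the planted
  overlap and the signal drowns. A power calculation puts g = 20
  comfortably clear (score >> 1) without shrinking the junk, which is the
  realistic part of the simulation.
* **Protospacer loci are intergenic.** A locus inside a group-shared gene
  would recur verbatim in every family member, silently breaking the
  truth table's one-virus-per-locus property (and precision = 1).
* **Planted genes are cassettes** `TAA + ATG + codons + TAA`: the leading
  in-frame stop pins the earliest-start rule to the planted start so ORF
  recovery is exact; back-translation draws codons uniformly per amino
  acid once per family, so members share the nucleotide cassette.
* **Mutations are substitutions only**, matching the matcher's gap-free
  model, and the per-spacer substitution count is capped at
  ceil(len x rate x 3): the generator's contract is that a spacer is a
  recognizably mutated copy of its protospacer, and an uncapped Bernoulli
  model breaches that bound ~2% of the time for 30-bp spacers at rate
  0.02.
* **Viral lengths start above the 10-kb retention floor** so linkage
  recall measures the matcher rather than the (separately tested) length
  rule; a separate unit check exercises the floor.

What a green synthetic run does *not* establish: performance on real
community data with compositional bias, degenerate repeat copies, indel
divergence of spacers, assembly chimerism, or genuinely homologous (rather
than identical) shared genes. The generator's i.i.d. background is the
simplest null that still exercises string matching, and its shared genes
are identical copies, so protein clustering is tested at the
identity-threshold extreme only.

## Numerical and degenerate-input conventions

Coordinates are 0-based half-open throughout; FASTA ids are tokenized at
the first whitespace; N is tolerated in input sequences but excluded from
repeats and start/stop codons (N-containing codons translate to X). All
randomness flows from one `numpy` generator seeded by a single integer;
identical config + seed reproduces byte-identical files. Hypergeometric
p-values are clamped to the smallest positive float before the log score.
Empty inputs: an empty candidate pool yields no hits (not an error), an
empty truth set gives recall 1.0, an empty prediction set gives precision
1.0, and an empty report is valid with zeroed counts.

## Known limitations

Repeat copies must be exact; heavily degenerate arrays fragment or escape
detection. Spacer/protospacer indels are invisible to the gap-free
matcher. Terminal repeats are exact-match only. Protein families use
greedy centroid clustering, which is order-stable but not a global
optimum. The published-data checks in the acceptance suite require
externally deposited FASTA files that cannot be bundled; they fail with
instructions when the files are absent.
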