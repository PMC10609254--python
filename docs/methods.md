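# Methods

## The problem the package models

Whole-genome average nucleotide identity (ANI) at the 95% boundary is the
operational species definition for bacteria, but it needs assembled
genomes. A single-gene marker that tracks ANI lets one type isolates and
profile communities from one PCR product. This package quantifies how well
a candidate gene does that, and then applies the resulting thresholds to
amplicon data. All components run on plain FASTA/FASTQ/Newick and on
simulated data with analytic ground truth.

## Pairwise identity

`global_align` is semi-global Needleman–Wunsch: affine gap costs (a gap of
length L costs `gap_open + gap_extend·(L−1)`; defaults +1/−1/−2/−1 for
match/mismatch/open/extend, BLASTN-like ratios) with terminal gaps free
along the dynamic-programming boundary. Identity is, by default, computed
over *internal* columns only — the terminal-gap columns are excluded — so
a sub-region compared against a full gene is scored on the overlap. This
matters because the whole workflow repeatedly compares gene regions
(tilS 420–1003 or 596–956, rpoB 481–836, 1-based inclusive) against whole
genes and genomes; penalising length differences would distort every such
number. Degenerate IUPAC bases count as matches when their base sets
intersect, so primers (Y, M, …) and ambiguous assembly positions (N) never
produce spurious mismatches. The engine is Bio.Align.PairwiseAligner with
an IUPAC substitution matrix; traceback ties resolve deterministically for
a fixed biopython version. Reported identities are rounded to 2 decimals
at the output boundary only.

The K2P distance uses transition proportion P and transversion proportion
Q over ungapped, unambiguous columns:

    d = −½ ln((1 − 2P − Q) · √(1 − 2Q))

When either logarithm argument is non-positive the distance is undefined
(substitution saturation) and an explicit `SaturationError` is raised —
never a clamped value.

## Fragment ANI

Both genomes are cut per contig into consecutive non-overlapping 1020 bp
windows (the OrthoANI fragment convention; trailing remainders are
dropped). Candidate fragment pairs are found by exact 15-mer seeding on
both strands; the top 4 candidates per fragment and strand get a full
semi-global alignment, and reciprocal best-hit pairs with per-fragment
aligned coverage ≥ 0.35 are kept. ANI is the mean identity over kept
pairs. Design choices worth knowing:

* The two genomes are ordered canonically (by id) before matching, so
  `ani(a, b) == ani(b, a)` exactly rather than approximately.
* A pair with no RBH fragments raises `AniUndefinedError`. Coercing to 0
  would silently corrupt the species-partition logic downstream; the
  matrix writer emits `NA` cells instead.
* 15-mer seeding keeps full sensitivity to ~15–20% divergence — far below
  any within-genus comparison this workflow targets; beyond that ANI is
  undefined here anyway.
* At the deep end of the intended range (≈10% divergence) the gapped
  score-optimal alignment can shift measured identity a few tenths of a
  point relative to the indel-free analytic expectation; the acceptance
  script reports the measured maximum error.

## Trees

Neighbor-joining is implemented directly (numpy) because two contracts are
pinned: ties in the Q-criterion join the lexicographically smallest label
pair, and negative branch lengths are clamped to zero with the deficit
moved to the sibling branch so the joined pair's distance is preserved. On
additive matrices NJ is exact (tested against matrices built from random
trees). Bootstrap resamples alignment columns with replacement from one
RNG stream per seed; supports are the percentage of successful replicates
containing each internal bipartition of the point tree, and replicates
that saturate are dropped and counted. Robinson–Foulds distance counts
non-trivial bipartitions present in exactly one tree; the implementation
is cross-checked in the tests against dendropy's.

A deliberate scope decision: distance trees (K2P + NJ + bootstrap) stand
in for maximum-likelihood search. The quantity the evaluation actually
consumes is topology concordance (RF distance), which at within-genus
divergences (1–10%) is insensitive to this substitution. Supports from
NJ bootstrap are not comparable one-to-one with likelihood-based branch
supports, and no test asserts support values against published ones.

## Marker evaluation

Species partitions are the single-linkage connected components of the
graph with edges ANI ≥ 95 (threshold configurable). Single linkage is the
minimal closure that turns the pairwise rule into a partition; borderline
cases (e.g. a 94.6% pair) therefore split, and the scan output flags the
violating pairs explicitly rather than deciding silently.

For each candidate gene the report carries: mean/max |gene identity −
ANI| over unordered pairs (percentage points, diagonal excluded); the RF
distance of the gene's NJ tree (p-distances from identity) to the
reference tree; min within-species and max between-species identity, and
their difference (margin). When the margin is positive, the best threshold
is the midpoint of the gap; otherwise the threshold minimising
misclassified pairs is chosen and every misclassified pair is listed.
Ranking is lexicographic: fewest violations, lowest RF, lowest mean
deviation. The shipped `paper_2023` thresholds (tilS 91.85, rpoB 95.59)
are applied as published constants, not re-derived — their derivation is
not reconstructible from printed values, and re-deriving them from a
different genome panel would silently change every downstream call.

## Amplicon profiling

The pipeline is the classic USEARCH-style workflow with every stage
deterministic:

1. expected-error filter: keep reads with Σ 10^(−Q/10) ≤ 1.0 (default);
2. forward-primer anchoring: only reads starting at the forward primer
   are profiled, and the primer footprint is trimmed;
3. exact dereplication, abundance-sorted (ties lexicographic);
4. de-novo chimera screen on the uniques: a candidate is flagged when
   some breakpoint splits it into a prefix and suffix each matching a
   *different* eligible parent (abundance ≥ 2× the candidate's) at ≥ 99%
   identity over ≥ 20 bases, while no single parent explains it at ≥ 99%
   full length;
5. greedy centroid clustering at 97%: first centroid (creation order)
   above threshold wins, else a new centroid is founded;
6. read mapping back to centroids, best match wins, ties to the earlier
   OTU;
7. best-hit species assignment against a labelled reference FASTA, using
   the marker's threshold; a cross-species tie within 0.5 points yields
   `ambiguous`, a best hit below threshold `novel-species-level`.

Every input read ends in exactly one bin (dropped-quality, dropped-length,
unanchored, low-abundance, chimeric, mapped, unmapped) — an invariant the
tests enforce end-to-end.

Known limitation: the hard 99%-per-segment chimera rule is insensitive to
chimeras whose minor segment is short (< 20 bp) or carries sequencing
errors; measured sensitivity on simulated two-parent chimeras is roughly
40–70%, so the flagged fraction at a 5% simulated chimera rate lands near
2–4%. Surviving chimeras either map to a parent OTU or, rarely, found a
singleton OTU; the `--min-abundance` flag (default 1, i.e. singletons
retained) is the standard recourse on real data.

## The simulator and what passing tests mean

`synthetic` generates the study conditions: a pure-birth (Yule) tree
scaled to a root-to-tip height of 0.05 substitutions/site over 8 taxa
(pairwise divergences then span roughly 1–10%), 60 kb genomes (40 kb in
the test fixtures; fragment ANI at this size carries ~50+ fragments per
genome, enough for a stable mean), K80 substitution with κ = 2, and three
embedded markers: a clock-like tilS-style gene (rate ×1.0, 1300 bp)
carrying invariant footprints for the packaged TilS primers so every
genome amplifies a 619 bp product; an rpoB-style gene (×0.8, 3500 bp);
and a slow decoy (×0.1) reproducing the near-uniform-identity failure
mode of typical housekeeping genes. There are no indels, so the expected
proportion of differing sites between two taxa is the closed-form K80
value p(d) (multiple-hit corrected) and "truth ANI" is 100·(1 − p(d)) —
an analytic oracle for every estimate. Read sets draw per-read error
rates lognormally (σ = 0.6) around the nominal 0.5% so the expected-error
filter selects the better tail, exactly as on real runs, with Phred
values consistent with each read's realised rate; optional two-parent
chimeras splice amplicons at a breakpoint inside the sequenced window
with both segments substantial, so a simulated chimera is an observable
artifact. Everything is byte-deterministic per seed.

What the simulator does **not** emulate: indels and rearrangements, GC
and codon structure, PCR amplification bias, paired-end reads, and
position-dependent quality decay. Passing tests therefore demonstrate the
correctness of the algorithms under the stated model, not performance on
real MiSeq runs; the published-anchor acceptance test against the real
GenBank assemblies exists precisely to close that gap and requires the
user to download those assemblies (see `data/README.md`).

## Numerical and degenerate-input choices

* All internal coordinates are 0-based half-open; the 1-based inclusive
  convention appears only in user-facing gene-region interfaces.
* NJ Q-criterion ties use an absolute tolerance of 1e-12 before the
  lexicographic tie-break.
* `k2p_from_proportions` clamps the analytically non-negative result at
  0 to absorb floating-point −0.0.
* Parsers reject rather than repair: empty sequences, duplicate ids,
  length-mismatched quality strings, gap characters in input FASTA, and
  duplicate Newick leaf labels are all hard errors naming the offender.
* Test problem sizes (40 kb genomes, 500–2000 reads, 50 kb distance
  recovery) are chosen so the full suite exercises every stage at
  statistically meaningful depth while remaining a desk-scale run.
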