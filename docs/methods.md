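# Methods

## Problem setting

An allopolyploid genome contains two (or more) subgenomes contributed by
distinct parental lineages. Given an assembly of the polyploid (the
*target*) and a panel of candidate relative genomes, the package ranks
candidate *pairs* by how much of the target their combined exact-match
footprints cover, and nominates the top pair as the progenitors. The
statistic deliberately uses only exact matches: no scoring matrices, gap
models or alignment heuristics enter, which makes every downstream number
an exactly defined function of the input sequences.

## Maximal unique matches

A match between target and candidate is a triple (ref_start, qry_start,
length) on one strand with identical (or reverse-complementary) sequence
content. It is *maximal* when extending one base in either direction
breaks the identity, and *unique* when the matched string occurs exactly
once in the target and — in the default `both` mode — exactly once in the
candidate, counting both candidate strands. The `reference_only` mode
drops the candidate-side requirement, matching the convention of
anchor-based aligners whose uniqueness flag is unknown for any given
published run; it is exposed as a parameter rather than guessed.

Implementation: a generalized suffix array (prefix doubling, numpy
`lexsort`) over target + candidate(+) + candidate(−) with a unique integer
sentinel between records and at every N position. Unique codes make N and
record boundaries universal mismatches, so matches can never cross either.
Adjacent-suffix LCPs and arbitrary longest-common-extension queries use
binary lifting over the retained doubling rank tables, all vectorized. In
`both` mode a MUM corresponds exactly to an adjacent suffix-array pair
(one target suffix, one candidate-side suffix) whose LCP is at least the
minimum length, strictly exceeds both neighboring LCPs (string uniqueness)
and is left-maximal; in `reference_only` mode each candidate suffix is
paired with its nearest target suffix of maximal extension, with explicit
uniqueness checks against the partner's target neighbors.

`find_mums_naive` re-derives the same contract by quadratic diagonal
dynamic programming plus literal substring-occurrence counting, guarded to
20 kb combined input. It is intentionally independent of the suffix-array
path and stays in the package permanently as the test oracle.

Default minimum match length is 20 bp — the customary anchor length of
whole-genome aligners; configurable.

## One-to-one filtering

The raw MUM set may still cover a target or candidate region more than
once (e.g. one-vs-many homeologous relationships). The filter keeps a
subset with no overlap on either axis, preferring maximal total matched
bases, with whole-match drops (no trimming, so every retained match keeps
its exactness invariants).

Two paths share this contract:

* **small inputs (≤ 16 matches)** are solved *exactly* by include-first
  branch-and-bound over feasible subsets (feasible = pairwise
  non-overlapping on both axes and non-crossing within a
  (ref, qry, strand) group). Exhaustive optimality at small scale is a
  stated guarantee of the filter and is what the test oracle checks; a
  greedy pass cannot promise it, which is why the small-scale path exists.
* **larger inputs** use per-group maximum-weight collinear chaining — a
  weighted longest-increasing-subsequence sweep with a Fenwick tree over
  candidate-axis endpoints, O(n log n) — followed by greedy cross-group
  conflict resolution in descending chain weight. This mirrors the
  classical one-to-one delta-filtering strategy and scales to the tens of
  thousands of anchors a real genome pair produces.

Ties everywhere prefer the chain whose first match has the smallest
(ref_start, qry_start); the result is fully deterministic and idempotent.
The greedy path is a heuristic: on adversarial cross-group conflict
structures it can retain less weight than the true optimum, a property it
shares with the tooling it emulates.

## Coverage and pair ranking

Match footprints on the target are merged into sorted, disjoint half-open
intervals (adjacent intervals merge). Single-species coverage is
100 × covered bases / target length. The pairwise cumulative percentage is
the coverage of the **union** of two species' interval sets — not the sum
of their percentages. Union semantics are the only interpretation that
can never exceed 100% and that stays below the sum whenever the two
species cover shared regions, which is the behavior the published
statistic exhibits; the sum is nevertheless written alongside in reports
for transparency. Pairs are ranked by cumulative percentage, ties broken
lexicographically. Coverage is computed after one-to-one filtering by
default; raw-MUM coverage is available behind a flag.

Percentages are reported to two decimals; all comparisons in code use
full precision.

## K-mer genome-size estimation

Every k-window of every read is counted as-read (no canonical collapse),
skipping windows containing N; k ≤ 31 uses 2-bit packed integer counting,
larger k falls back to string counting. The estimator is

    G = (N·(L−K+1) − B) / D

with D the histogram mode at or above the low-frequency cutoff (default
4; ties toward the smaller multiplicity) and B the multiplicity-weighted
instance count of the bins below the cutoff. B is instance-weighted
because it is subtracted from the instance total N·(L−K+1); a
distinct-k-mer alternative is available with a warning. Peak detection is
a plain argmax — no mixture model — so heterozygosity and repeat shoulder
peaks are out of scope. Note D is the *k-mer* depth, ≈ base depth ×
(L−K+1)/L; the formula's numerator shrinks by the same factor, which is
why it recovers genome length. The default k for desk-scale work is 21;
41 and above, as used on real high-coverage data, is supported through
the same interface (string path above k = 31).

## The simulator

`simulate` emulates the study design the pipeline targets, and its
defaults are the package's reference conditions:

| parameter | default | rationale |
|---|---|---|
| ancestor length | 200 kb | large enough for thousands of anchors per pair, small enough for minutes-scale runs |
| chromosomes | 2 | exercises multi-record bookkeeping |
| GC | 0.36 | typical crucifer genome composition |
| panel | 6 lineages at 0.03, 0.05, 0.05, 0.075, 0.12, 0.20 subs/site | progenitors at 0.05; nearest decoy at 1.5× the progenitor divergence; one decoy *closer* to the ancestor than the progenitors to make ranking non-trivial |
| post-hybridization divergence | 0.02 subs/site | recent hybrid origin relative to lineage splits |
| indels | 1e-3 events/site, length U[1,10] | breaks exact matches the way small indels do |
| inversions | 2 per lineage, each 1–5% of a chromosome | mimics pre-hybridization rearrangement |
| reads | single-end, uniform placement, flat error rate | read length 100–125; pairing and quality profiles are irrelevant to every in-scope statistic |

Evolution applies inversions, then substitutions (uniform change to one
of the three other bases — Jukes–Cantor-like; exact-match statistics
depend only on mismatch spacing, not on the substitution matrix), then
Poisson-thinned indels. Lineages radiate independently from the ancestor
(star phylogeny); a nested tree is future work. Everything is
bit-reproducible from a single integer seed via `numpy.random.default_rng`.

What the simulator does **not** emulate — and therefore what passing
tests do not demonstrate about real data: repeat families and segmental
duplications (real assemblies lose far more coverage to the uniqueness
requirement), assembly fragmentation and gaps, homeologous gene
conversion, structured phylogenies with shared internal branches, and
sequencing-quality structure. The recovery rates measured here are upper
bounds for idealized inputs, not field performance claims.

## Phenotype formulas

Chlorophyll a, b and total from 664/649 nm absorbances of an ethanol
extract use the standard two-wavelength coefficients; the coefficients
satisfy total ≡ a + b identically, which the tests assert at machine
precision. Amounts are normalized per leaf area as concentration ×
extract volume / area; outputs are in the formulas' own units and the
code does not relabel them as µg/ml. Fold change is the reference-
normalized treated quantity over the control quantity, on linear-scale
inputs; Cq-to-quantity conversion and significance testing are out of
scope.

## Numerical and procedural choices

* Coordinates are 0-based half-open everywhere; reverse-strand matches
  store the forward-strand start of the leftmost matched base.
* Output orderings are fully specified (lexicographic sort keys at every
  stage), so reruns are byte-identical; reports contain no timestamps and
  carry SHA-256 input checksums.
* Degenerate inputs fail loudly: empty FASTA, duplicate ids,
  non-nucleotide-dominant records, mismatched FASTQ qualities, spectra
  with no bin above the cutoff, zero-length targets, single-candidate
  pair ranking. A candidate with zero matches yields a 0% row, not an
  error.
* Validation problem sizes (chosen to keep the full suite in minutes on
  one CPU): 200 random pairs up to 2 kb for engine/oracle equivalence;
  100 random sets of ≤ 12 matches for filter optimality; 20 seeds of the
  default 200 kb scenario for progenitor recovery; 100 kb genomes at
  depth 30 for size recovery.

## Known limitations

The one-to-one heuristic above 16 matches is not globally optimal; the
MUM engine holds whole genomes in memory (fine to ~10⁸ bp, no
disk-backed index); the size estimator fits no error/heterozygosity
mixture model; the simulator's star phylogeny makes decoys easier to
reject than nested real clades would be.
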