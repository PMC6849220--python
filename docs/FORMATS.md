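# File formats

All coordinates are 0-based, half-open (start inclusive, end exclusive),
on the forward strand. Percentages in reports carry two decimals.

## FASTA / FASTQ

Standard dialects; multi-line and single-line FASTA, CRLF and transparent
gzip (`.gz`) accepted. On input, sequences are normalized to uppercase
{A,C,G,T,N}: U→T, other IUPAC codes→N (warning logged). Records that are
more than 50% non-nucleotide characters are rejected. Simulated reads are
written as FASTQ with a constant quality string.

## Match TSV (PAF-like)

Written by `mums` / `filter`, read by `filter` / `coverage`. Header line
starts with `#`. Columns:

    qry_id  qry_len  qry_start  qry_end  strand  ref_id  ref_len  ref_start  ref_end  match_length

`qry_start`/`qry_end` are forward-strand coordinates of the leftmost
matched base also for `-` strand matches. `qry_len`/`ref_len` are 0 when
the genomes were not available at writing time.

## Pair coverage TSV

`pair_coverage.tsv`: first column `species`, then one column per species,
values are percentages; diagonal = single-species coverage, off-diagonal
= cumulative (union) pair coverage. Species sorted by name.

## Ancestry report JSON

`ancestry_report.json` keys:

* `target` — target genome name;
* `candidates` — sorted candidate names;
* `singles` — per candidate: `species`, `covered_bp`, `target_bp`,
  `percent`;
* `pairs` — ranked list with `pair`, `cumulative_percent`, and the
  transparency column `sum_of_singles_percent`; `null` with < 2
  candidates;
* `winner` — the nominated progenitor pair (first ranked pair);
* `provenance` — tool version, parameter echo, SHA-256 of every input.

No timestamps: identical inputs give byte-identical reports.

## K-mer outputs

`kmer_histogram.tsv`: two columns, `multiplicity` and `distinct_kmers`.
`genome_size.json`: `{N, L, K, B, D, G, cutoff}` — reads, read length,
k, low-frequency k-mer instances, peak depth, estimated size (bases).

## Scenario config (flat key = value)

Accepted keys for `simulate --config`: `ancestor_length`,
`n_chromosomes`, `gc`, `panel` (e.g. `p1:0.05, p2:0.05, p3:0.12`),
`progenitors` (`p1, p2`), `post_hybrid_divergence`, `indel_rate`,
`indel_max`, `n_inversions`, `seed`. `#` starts a comment. The simulate
command writes `hybrid.fa`, `candidates/<name>.fa`, optional `reads.fq`,
and `truth.json` (`true_pair`, divergences, seed).

## Phenotype CSV

`chlorophyll --in`: columns `sample, A664, A649[, volume_ml,
leaf_area_cm2]`; adds `chl_a, chl_b, chl_total[, chl_total_per_cm2]`.
`foldchange --in`: columns `sample, target_treated, reference_treated,
target_control, reference_control`; adds `fold_change`.
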