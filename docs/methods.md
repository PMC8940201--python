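# Methods

## Annotation-transfer model

The engine treats annotation transfer as a deterministic function of three
inputs: a grouped 12-column tabular alignment file, a key→ID-set mapping,
and a set of thresholds. Its assumptions:

* **Grouped input.** BLAST and DIAMOND emit all hits for a query
  contiguously, so the file can be processed in one pass holding only the
  current query's hits. A query id that reappears later violates this
  assumption; the default policy is to abort naming the query, with an
  explicit `merge` policy for hand-edited files that buffers the whole
  stream (trading away the memory bound).
* **Inclusive thresholds.** All comparisons are inclusive (identity ≥,
  bit score ≥, length ≥, e-value ≤), so a hit at exactly the 80% identity
  default passes. Strictness at the boundary is a convention this package
  fixes and echoes into every run summary, since either choice is
  defensible and the difference only matters for boundary hits.
* **Best-hit order.** Hits are ranked by bit score descending — the
  standard BLAST ranking, independent of database size — with e-value,
  percent identity and original file order as successive tie-breaks. The
  last key makes the ranking a total order, so output is byte-stable.
* **Best *mappable* hit.** When the top-ranked hit's subject has no
  dictionary entry, the walk continues down the ranked list. The stricter
  reading (only the top hit, `Unknown` if it does not map) is available as
  `strict_best`. Reads with no passing or no mappable hit get the literal
  label `Unknown`.

### Tunable parameters

| parameter | default | units | why |
|---|---|---|---|
| `min_percent_identity` | 80 | % of alignment columns | restricts transfer to close homologs; thresholds above 70% are common practice for accurate functional transfer, and 80 favours precision |
| `max_e_value` | unset | expected chance hits | optional; DIAMOND output is usually pre-filtered |
| `min_bit_score` | unset | bits | optional alternative strength filter |
| `min_alignment_length` | unset | alignment columns | optional guard against short spurious matches |
| `value_separator` | `;` | — | matches common UniProt/GO exports; `,` configurable |
| `strip_versions` | off | — | NCBI-nr subjects carry `.N` versions, some dictionaries do not; stripping applies to both build and lookup so the two sides stay consistent |

The store backend is embedded SQLite: a single file, persistent across
processes, B-tree (O(log n)) lookups, no server. The backend name and
build provenance (source path, timestamp, separator) are recorded in the
store's metadata table. Duplicate dictionary keys union their value sets,
which makes the store independent of line order — the property the tests
exercise by shuffling dictionaries.

## Evaluation model

Scoring is per read, with negative controls (NC) anchoring the negative
class: an NC read models an organism absent from every reference, so *any*
assignment to it is a false positive and leaving it unassigned is a true
negative. For non-NC reads, a correct label at the evaluated rank is a TP,
a wrong non-empty label an FP, no label an FN. Functional scoring is the
same with "correct" meaning the assigned ID set intersects the expected
set (a single shared GO ID suffices). Each read lands in exactly one cell,
so the four counts partition the truth table — an invariant asserted in
the tests.

Choices the file formats forced or left open:

* Taxon labels are compared as exact strings after whitespace
  normalisation. The classification and truth schemas carry rank labels
  only (no numeric taxon-ID columns), so no ID-based matching is
  performed.
* Reads present in the truth but missing from the prediction table count
  as unclassified rather than erroring, because classifiers routinely omit
  unclassified reads. Prediction reads *absent from the truth* are an
  error: they indicate mismatched files.
* A partial lineage (classified at genus, empty at species) is
  unclassified at the empty ranks.
* A non-NC truth row with an empty expected-ID set (legal in the TSV,
  absent from the intended study design) is scored like a negative:
  annotating it is an FP, leaving it alone a TN. This keeps the partition
  invariant exact.
* Map-all annotation output has several records per read; they are merged
  by union before functional scoring.
* MCC uses the conventional value 0 when any denominator factor is zero,
  and an exact integer square root when the denominator is a perfect
  square so the analytic extremes come out exactly ±1 in floating point.

Rank recovery reports, per rank, the share of distinct true taxa with at
least one TP read, rounded to the nearest integer percent; classification
rate is the percentage of reads with the classified flag, rounded to two
decimals.

## Synthetic data

The generators emulate the statistical design of a benchmark dataset, not
any particular sequencing instrument:

* **Windowed shuffling** permutes residues uniformly within consecutive
  non-overlapping windows (default width 500; the final window may be
  shorter). Total and per-window residue multisets — hence GC content —
  are preserved while homology is destroyed, so shuffled sequences remain
  realistically alignable yet belong to no reference organism. This is the
  negative-control construction.
* **Read simulation** draws reads from named sources at uniform positions
  under a supplied or lognormal abundance profile (sigma parameterises the
  skew; mu is fixed at 0 and weights normalised, since only relative
  abundances matter), with i.i.d. substitutions. Negative-control reads
  are drawn identically from shuffled source copies. Not modelled: Illumina
  quality profiles, position-dependent error rates, indels, paired-end
  inserts. Consequently, passing tests demonstrate the correctness of the
  transfer and scoring logic under the stated design, not robustness to
  real sequencing artefacts.
* **Planted alignment fixtures** assign each read one of four outcomes —
  `clean` (best passing hit maps), `sub_threshold` (hits present, all
  below threshold), `unmappable_best` (top passing hit absent from the
  store, a lower-ranked passing hit present — exercising the fallback),
  `no_hit` (absent from the file) — and emit the expected annotation
  records alongside. Hit metrics are generated to round-trip exactly
  through the text format (values quantised before writing), so expected
  and produced records compare with `==`.

All randomness flows through `numpy.random.default_rng` (PCG64) with
explicit seeds; generators are pure functions of their arguments.

### Problem sizes

The test suite and acceptance script run at desk scale by design: random
equivalence fixtures of 20–1,000 reads (100 fixtures), planted end-to-end
scenarios of 500 and 2,000 reads, 10,000-key dictionaries, 1,000 shuffled
sequences up to ~600 nt. These sizes give exact, fully checkable
expectations; the streaming design itself is what scales to real
alignment files (memory bounded by the largest single query group).

## Known limitations

* Only the 12-column `outfmt 6` dialect is parsed; XML/pairwise/DAA/SAM
  outputs are out of scope, as is performing alignments.
* The store is single-writer; concurrent builds to the same path are not
  supported.
* No ontology awareness: GO IDs are opaque strings, so ancestor/descendant
  relationships do not count as matches in scoring.
* Taxonomic scoring is label-based; synonymous names for the same taxon
  score as mismatches.
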