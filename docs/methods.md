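# Methods

## Model and assumptions

`barcodeid` performs molecular taxonomic identification by local alignment
of query sequences against a curated Reference Sequences Library (RSL).
The underlying assumptions are those of single-marker DNA barcoding:

- the RSL contains one taxonomically verified sequence per species-level
  lineage, with a unique identifier per record — reliability of the output
  is bounded by the quality of this library;
- the marker exhibits a barcoding gap, so a single interspecific
  divergence value (`intersp_div`, percent) separates conspecific from
  heterospecific comparisons; the similarity threshold for a confident
  identification is `100 − intersp_div`;
- percent identity of a local alignment is an adequate ranking statistic
  once alignments resting on short spans are removed.

A query is *identified* as the lineage of its best retained hit. It is
flagged for manual checking when identity < threshold, when query coverage
< 75%, or when its subject identifier matches a user-supplied taxa warning
(markers without species-level resolution in some genera, voucher series
to re-examine, etc.). A query with no retained hit at or above
`cutoff_pident` is an *outgroup*.

## Filters and selection

Query coverage is computed from the alignment coordinates,
`qcov = 100·(qend − qstart + 1)/qlen`, not taken from the aligner's
per-subject `qcovs` column: `qcovs` merges multiple HSPs per subject and
can exceed the span of any single alignment. The column is still parsed
and carried for reference. On single-HSP hits the two agree to well under
half a percentage point; for multi-HSP pairs they may differ, which is
documented rather than asserted.

Both filter boundaries are read strictly: hits are removed when coverage
is *below* 75% or the alignment is *below* 90% of the subject length, so
`qcov = 75.0` and `aln_len = 0.9·slen` are retained. The 90% comparison is
done in floating point with a 1e−9 guard so exact boundaries never fail by
representation error. Each HSP competes as its own row; HSPs are never
merged, because the coverage formula operates on a single row's
coordinates.

Best-match selection takes the maximum percent identity per query; ties
break on bitscore (desc), alignment length (desc), then subject id (asc).
The paper trail for the tie order is determinism: identical inputs give
identical reports on any platform and any input row order. Identity
flagging uses the strict inequality `pident < threshold`; with thresholds
like 97 and aligner identities printed to three decimals the choice is
immaterial in practice, but it is fixed and documented here. Taxa-warning
patterns match as case-sensitive substrings of the subject identifier by
default; case-insensitive matching and matching against the lineage name
are switches, since the natural patterns ("Mantella", "MRSN") are
identifier fragments.

## Parameters

| parameter | units | default | rationale |
|---|---|---|---|
| `cutoff_pident` | % identity | 90 | hits below are discarded at search time; 90 suits fast-evolving mitochondrial barcodes |
| `intersp_div` | % divergence | 3 | typical interspecific divergence floor for such markers; threshold becomes 97 |
| coverage floor | % of query | 75 (fixed) | removes identifications carried by a fraction of the query |
| subject-span floor | fraction of subject | 0.90 (fixed) | removes alignments much shorter than the reference |
| lineage convention | — | first two underscore tokens | matches `Genus_species_VOUCHER` headers; `full` and user-regex conventions cover candidate-species naming like `Genus_sp_Ca5` |

One `intersp_div` applies per run. Mixed datasets spanning groups with
different divergence thresholds should be split and run per group; per-taxon
thresholds in a single run are deliberately out of scope.

## Synthetic data

The fixture generator emulates a small barcoding study: a 25-lineage RSL
of i.i.d. random 500 bp sequences, nine in-group queries spread over seven
lineages, and one outgroup. In-group query *j* is its source reference
with exactly `round(d·L/100)` point substitutions for divergence *d*; the
default divergences (0, 0, 0, 1, 1, 2, 4, 5, 6)% place six queries above
the 97% threshold and three below it while all stay above the 90% cutoff.
Outgroups are fresh random sequences, which at these lengths cannot seed
an alignment against the library. Substitutions avoid the terminal ~5% of
the sequence when there is room, because a local aligner trims alignments
ending in mismatches, which would break the closed-form identity
`100·(1 − subs/L)` the fixtures guarantee. A single seeded generator
drives everything; the truth table records source lineage, substitution
count and expected identity per query.

What the fixtures do **not** emulate: indels (identity would become
alignment-parameter-dependent), rate heterogeneity, real phylogenetic
correlation between references, ambiguity codes, and sequencing error.
Passing tests therefore demonstrate the correctness of the filtering,
selection, flagging and reporting logic — not the field accuracy of
identification on real data, which depends on the user's RSL and marker.

The companion hit-table generator emits the one full-length row per
in-group query the aligner would ideally report (optionally plus
half-length decoy rows that the coverage filter must remove), so the
entire downstream pipeline is testable without BLAST+ installed. When
BLAST+ is present, integration tests additionally verify that aligner mode
and hit-table mode agree byte-for-byte when fed the aligner's own output,
and that aligner-reported identity matches the closed form within 0.01.

## Numerical and design choices

- The extended tabular format is the 12 standard columns plus
  `qlen slen gaps qcovs`, in that order; files are read back with full
  invariant checks and line-numbered errors, and `write ∘ read` is the
  identity at the aligner's printed precision (identity at 3 decimals).
- Pre-computed hit tables are re-checked against `cutoff_pident` on
  consumption, so third-party files obey the same contract as aligner
  output.
- Percentages in the summary sheet print as integers when whole, else one
  decimal.
- Report output is XLSX (red fill for identity flags, amber for coverage
  flags, machine-readable `flag` column so nothing is lost in TSV mode) or
  four TSV files whose bytes are stable across runs.
- Empty inputs are ordinary results: an empty query file or hit table
  yields an empty best-match sheet, all queries pooled below cutoff, and
  100% processed.

## Problem sizes

Tests and the acceptance script run the benchmark layout above (25
references × 500 bp, 10 queries); property checks use ~1000 randomized
hit tables of ≤ 12 rows against a brute-force selection oracle. These
sizes exercise every code path while keeping the suite near-instant; the
pipeline itself streams plain-text tables and scales to the thousands of
queries typical of barcoding projects.

## Known limitations

- Nucleotide space only; no remote BLAST, no XML parsing, no automatic
  taxonomy lookup or RSL curation.
- One divergence threshold per run (see above).
- The lineage is derived from the identifier; malformed headers under the
  chosen convention are a hard error rather than a guess.
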