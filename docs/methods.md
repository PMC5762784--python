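# Methods

`mirprof` implements a comparative small-RNA expression analysis of the kind
used to screen transgenic plant lines against a wild-type control: several
treatment libraries are pooled into one group, compared against a control
library, and the conserved-miRNA expression differences are summarised as a
fold-change table, a log2-ratio heatmap, and a GO enrichment of predicted
targets. This note records the model, the defaults, and the design choices
made where the procedure was genuinely open.

## Read cleaning

Raw 36-nt single-end reads are filtered in a fixed order; the first failing
step claims the read, so the per-step removal counts partition the input
exactly (`input = clean + Σ removed`):

1. **low_quality** — mean Phred < 20 (configurable). "Low quality" has no
   universal definition at the vendor level; a whole-read mean is the
   simplest criterion that is monotone in the quality threshold.
2. **poly_n** — N fraction > 5%.
3. **no_3p_adapter_or_insert** — no 3'-adapter match, or a match at position
   0 (adapter dimer, i.e. no insert). Surviving reads are trimmed here.
4. **5p_contaminant** — the insert begins with an 8-nt prefix of the
   5' adapter at ≤ 1 mismatch.
5. **homopolymer** — one base makes up ≥ 80% of the insert (poly A/T/G/C).
6. **too_short** — trimmed insert < 18 nt.

Adapter detection is a best ungapped overlap scan: the leftmost position
where the adapter — or, for read-through near the 3' end, an adapter prefix
of ≥ 6 nt — matches with a mismatch rate ≤ 10%. Leftmost-first is the
standard trimmer behaviour (it maximises the matched adapter length) and
makes trimming deterministic.

*Idempotence.* Cleaning is not literally idempotent under the default
configuration: a trimmed insert no longer carries an adapter, so a second
pass would discard it at step 3. `CleaningConfig.require_3p_adapter=False`
lifts the adapter-presence requirement (reads without a match are kept whole
as their own insert); under that setting re-cleaning clean output removes
nothing, which the suite asserts. Raw-library cleaning keeps the default
`True`, matching the "reads without a 3' primer are contaminants" view.

## Quantification

Clean inserts are collapsed to unique tags (a multiset partition — total tag
count equals the clean read count), and each tag is assigned to the mature
miRNA of *identical length* within Hamming distance ≤ 2 on the sense strand.
No indels, no partial overlaps: mature-miRNA reads are full-length sense
copies of the reference, so equal-length substitution distance is the
appropriate notion of "up to two mismatches". Ties on distance go to the
lexicographically smallest miRNA id, making assignment order-independent.
The count matrix keeps every reference miRNA (zeros included) and carries
each library's total clean-read count as its size.

The matcher takes an exact-dictionary fast path and falls back to a
vectorised distance computation per length class; it is verified against an
exhaustive all-pairs Hamming oracle in the suite.

## Differential expression

* **Normalisation**: `TPM = count × 10⁶ / lib_size`, with `lib_size` the
  library's total clean reads (not its assigned reads), so TPM is comparable
  across libraries regardless of assignment rates.
* **Group summary**: unweighted mean TPM over the treatment libraries
  (L1..L6) versus the mean over control libraries (a single CK just
  contributes its own TPM).
* **Fold change**: `group_tpm / ck_tpm` on the ratio scale, substituting a
  pseudo-TPM of 0.01 for either side when it is exactly zero; always finite
  and positive. Display rounding is half-up to 2 decimals, computed in
  decimal arithmetic so quotients that land exactly on a half round upward
  the way published tables do.
* **Test**: two-sided Fisher's exact test per miRNA on the 2×2 table of
  (pooled treatment count, remaining treatment reads) vs (control count,
  remaining control reads); p = 1 when both pooled counts are zero. An exact
  conditional test is the natural choice for single-library-per-line pooled
  counts; a dispersion-modelling GLM is deliberately out of scope because
  the procedure being implemented is the simpler pooled comparison. Exact
  tests on discrete counts are mildly conservative; on null simulations the
  empirical type-I error sits slightly below the nominal 5%.
* **Multiple testing**: Benjamini–Hochberg step-up, hand-implemented
  (sorted `p·n/rank`, reverse cumulative minimum, capped at 1) and
  cross-checked against `statsmodels.stats.multitest.multipletests` in the
  suite.
* **Calling**: UP iff `max(group_tpm, ck_tpm) > 30` and `adj_p < 0.05` and
  `fold_change > 2`; DOWN symmetrically with `fold_change < 0.5`. All
  inequalities are strict and evaluated on unrounded values. The expression
  floor applies to *either* group — a down-regulated miRNA may be well
  expressed only in the control. The fold-change bounds are on the plain
  ratio (2 and 0.5 are ratio-scale bounds, as the reference fold-change
  column confirms).

The curated published comparison table bundled in `mirprof.published`
(21 rows: 7 up, 14 down, from a six-line transgenic vs wild-type rice seed
survey that detected 568 conserved miRNAs) is used as a golden fixture: the
printed fold changes must reproduce exactly under the display rounding, and
the calling rules above must reproduce all 21 direction calls when fed the
published TPM pairs and significance values. The table's two published
significance columns come from an unnamed test and are not targets for this
package's own p-values.

## Clustering report

For each DE miRNA the heatmap value in treatment library ℓ is
`log2((TPM_ℓ or pseudo) / (TPM_CK or pseudo))`; the control column is pinned
to 0 so the wild type is the reference point. Rows are put in canonical
(miRNA-id) order before clustering, which makes every report file
independent of input row order. Row ordering is agglomerative clustering —
average linkage on Euclidean distances by default (the original analysis
names neither, so both are configurable: complete/single, correlation).
Correlation distance is rejected with an explicit error for constant rows.
The dendrogram is emitted as Newick text; the raster heatmap (red up, green
down, black = no change, symmetric around 0) is optional and cosmetic.
Columns are not clustered: the fixed CK-first, L1..L6 order keeps the
control reference visually anchored and the lines comparable across reports.

## GO enrichment

Target prediction is consumed, not computed: a miRNA→target table and a
gene→GO table (flat labels, no ontology propagation). For each term with at
least one annotated gene in the universe, the statistic is the upper-tail
hypergeometric probability `P(X ≥ k | N, K, n)`, BH-adjusted across all
tested terms, sorted by `(adj_p, raw_p, term_id)` and cut to the top 40 by
default. The universe defaults to all annotated genes and is overridable.

## Synthetic data

The generator emulates the study conditions every stage assumes: 1 control +
6 treatment libraries, 36-nt reads, insert lengths bimodal at 21/24 nt,
log-normal abundances, ~4% junk (so effective reads are > 95% of the total,
as in deep real libraries), a 0.5% per-base substitution error rate, and a
spike table multiplying selected miRNAs' expected abundance in every
treatment library by a known fold change. Defaults: 300 reference miRNAs,
200,000 reads/library — a desk-scale stand-in for production libraries of
>10M reads, chosen so a full run stays interactive; depth is a config knob.

Design points:

* miRNA-derived reads are `insert + 3' adapter` (cycled) truncated to 36 nt,
  substitution errors confined to the insert; inserts ≥ 36 nt would be
  emitted truncated without adapter (cannot occur with an 18–26 nt mature
  reference). Adapters default to the canonical Illumina small-RNA pair and
  are configurable; real vendor adapters vary and are never assumed.
* `length_weights` is a read-level sampling probability: log-normal draws
  are rescaled within each insert-length class so class totals follow the
  weights. Without this, one randomly dominant miRNA can displace the
  21/24-nt modes at small reference sizes.
* Each junk class is constructed to be claimed by exactly one cleaning step
  under the default configuration: poly-N reads carry Q2 only on their N
  bases (as basecallers emit) so they pass the mean-quality gate and fail
  the N filter; homopolymer and short-fragment reads carry normal qualities
  and a real adapter; adapter dimers start with the adapter; unassignable
  reads are rejection-sampled to contain no qualifying adapter match.
* All randomness flows from `SimConfig.seed` through a `SeedSequence` tree:
  identical configurations give byte-identical FASTQ files. Read headers
  carry a `source=` comment naming the originating miRNA or junk class.
* `simulate_counts` draws the identical per-library multinomial realisation
  as the FASTQ path (same seed child, same first draw) without materialising
  reads; multi-seed power/calibration studies use it. `GroundTruth` records
  the expected matrix, the realisation, the per-miRNA true fold change
  (1.0 when unspiked) and the injected junk counts.

**What passing tests do and do not show.** The simulator has uniform
per-read qualities, position-independent errors, no isomiRs, no degradation
ladders, no rRNA/tRNA background, and error-free adapters. Recovery results
on it demonstrate the pipeline's correctness and calibration under its own
stated model, not performance on real libraries with structured error and
unknown contaminant composition.

## Numerical choices and degenerate inputs

* Strict inequalities throughout DE calling; rounding only for display.
* Empty read stream: empty clean output, all-zero stats (not an error).
  Empty tag set: all-zero count matrix over the full reference.
* `adjust_bh([])` is `[]`; a single p-value is returned unchanged; exact
  zeros (underflow from extreme Fisher tables) are accepted.
* Fold change with both sides zero is 1.0 (pseudo/pseudo).
* Single-row clustering returns order `[0]` and a one-leaf Newick without
  invoking linkage.
* Chi-square truth-consistency testing pools cells with expected count < 5.

## Known limitations

* Hamming-only matching misses isomiRs with shifted ends and any
  indel-bearing variants — by design, as the quantity of interest is the
  conserved mature sequence census.
* The pooled Fisher test treats each group's reads as one pool; with one
  library per line there are no biological replicates, so between-line
  variability is not modelled (the heatmap shows per-line ratios for visual
  inspection instead).
* GO terms are flat labels; no parent-term propagation.
* The cleaning/trimming defaults are declared, not inferred from any
  specific vendor pipeline.
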