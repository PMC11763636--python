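# Methods

## The div statistic

For one miRNA observed in `n = num_down + num_up` experiments,
`div = (num_down − num_up) / n`.  The statistic is computed through exact
rational arithmetic (`fractions.Fraction`) before conversion to float, so
boundary identities hold exactly: `div = 1 ⟺ num_up = 0`,
`div = −1 ⟺ num_down = 0`, and `div(a, b) = −div(b, a)`.  `n = 0` raises
rather than returning 0, since a miRNA with no experiments has no defined
direction.

Modeling assumptions: experiments are exchangeable Bernoulli trials with a
per-miRNA down-probability *p*; experiment types are pooled by default (an
optional predicate restricts to cancer-vs-normal comparisons).  Under this
model `E[div] = 2p − 1` and `SD[div] = 2·sqrt(p(1−p)/n)`, which is why the
experiment-count filter matters: at `n ≤ 5` the noise band is ±0.4 or worse.
The default `min_experiments = 6` keeps miRNAs with at least six
experiments.  No shrinkage is applied to low-n miRNAs; the filter is the
only guard, matching the flat sorting-and-thresholding character of the
pipeline.

Direction classification uses an inclusive boundary (`div ≥ div_cut` →
down, `div ≤ −div_cut` → up) so ties are deterministic; `div_cut = 0`
switches to a strict sign rule in which `div = 0` stays ambiguous.  The
default `div_cut = 0.2` was fixed a priori as a mild consistency
requirement (at least 60/40 down/up split); the down/up population ratio is
reported at this cut.

## Gene integration

`mean_logFC` is the unweighted mean of a gene's log2 fold changes across
cancer entries; `mean_div` the unweighted mean of div over the *distinct*
miRNAs targeting it (links are deduplicated; miRNAs that failed the
experiment filter do not contribute, and genes left with no surviving miRNA
are omitted and counted).  Quadrants are assigned canonically from the
coordinate signs — I: (+,+), II: (−,+), III: (−,−), IV: (+,−) — with exact
zeros labelled `axis`; the output header makes the convention explicit
since verbal descriptions of such figures are notoriously easy to garble.

Distance from the origin is taken after z-scoring each axis over the input
gene set (population SD; a zero-variance axis contributes 0).  This is a
design choice forced by the axes having incommensurable units (a bounded
ratio vs a log fold change); it makes the ranking scale-free and invariant
to swapping the axes, at the cost of making each gene's distance depend on
the cohort it is ranked within.  Ties break by gene id.

Concordance between the two axes is a Spearman rank correlation with a
two-sided permutation p-value, `p = (1 + #{|r_perm| ≥ |r_obs|}) / (1 + N)`,
shuffling the `mean_logFC` vector with a seeded generator (default
`N = 999`).  A permutation test was chosen over the parametric t
approximation because gene values are cross-correlated means of shared
miRNAs and bounded; under exchangeability the permutation p-value is exact
up to resolution `1/(N+1)`.  Permutations are evaluated as dot products of
centered unit-norm rank vectors, so the test is O(N·genes) after ranking.

## Complementarity scoring

`value = matched_positions / min(len a, len b) ∈ [0, 1]`, with
match = 1, mismatch = 0, gap = −1 defaults.  Three modes: `global`
(Needleman–Wunsch over the full lengths — the default, reading
substitutability as percent similarity), `local` (Smith–Waterman best
segment; a perfect containment scores 1.0 because of the shorter-sequence
denominator), and `duplex` (global alignment against the reverse
Watson–Crick complement, scoring the hybridization duplex; G·U wobble
pairs optionally count as matches).  No thermodynamic duplex energy or
seed-region weighting is modelled: the comparison is purely miRNA–miRNA.

Numerical definition of `matched_positions`: the DP maximizes the pair
(score, match-columns) lexicographically, so among all score-optimal
alignments the one with the most matches defines the value.  This matters
because with mismatch = 0 distinct score-optimal alignments can carry
different match counts (e.g. `CCCCA` vs `CCCCGGA`: two optimal global
alignments with 5 and 4 matches); a traceback-order-dependent value would
be an artifact.  Residual ties prefer diagonal over up over left moves, so
every score is bit-reproducible.  A corollary worth knowing: the *score* of
the best local alignment always dominates the global score (the full
alignment is one feasible segment), but the local *value* can be smaller
than the global value, because trimming a net-negative end may discard a
match column (the example above: local 4/5 vs global 5/5).  Tests assert
the score-level dominance.

The aligner is hand-written because this bounded matched-fraction statistic
with lexicographic tie-breaking is the package's core primitive; its scores
are cross-checked in the test suite against Biopython's `PairwiseAligner`
(score level) and against an exhaustive enumeration oracle that scores
every monotone position-pairing of short sequences (value level, all three
modes).

Plant ranking sorts by `delta = avg_comp_down − avg_comp_up` descending,
then `avg_comp_down` descending, then id.  `delta_exceed_fraction` reports
the fraction of plants with `|delta|` above a threshold (default 0.10); on
unstructured libraries it should be small, since a random plant resembles
both human sets about equally.

## Synthetic universe

The generators are the package's study conditions, not fixtures:

* **Expression corpus** — per-miRNA down-probability from a three-component
  Beta mixture: weights (0.60, 0.24, 0.16) over Beta(8, 2) (down-biased),
  Beta(2, 8) (up-biased) and Beta(60, 60) (neutral).  The weights and
  shapes were fixed a priori so that, at `div_cut = 0.2` and ~100
  experiments per miRNA, the expected down/up-classified ratio is ≈ 2.5,
  the imbalance large cancer compendia show.  Experiment counts are
  `1 + Poisson(mean − 1)` (default mean 100); logFC magnitudes
  `|Normal(1, 0.5)|` signed to agree with status (they are decorative for
  div, which counts statuses, but keep the reader's sign invariant);
  cancer types uniform over a fixed 10-name vocabulary.
* **Gene layer** — each of `n_genes` (default 300) genes links to
  `1 + Poisson(links_per_gene − 1)` miRNAs sampled without replacement;
  the true signal is `s_g = mean(2p − 1)` over linked miRNAs and per-cancer
  `logFC = ρ·s_g + sqrt(1 − ρ²)·Normal(0, noise_sd)` across the 10 cancer
  types (defaults ρ = 0, `noise_sd` = 0.5).
* **Sequences** — uniform random A/C/G/U, lengths uniform in 20–24 nt
  (mature-miRNA range; the readers accept 15–30).
* **Planted plant library** — 5 planted sequences copy random members of a
  designated down set and mutate `round((1 − identity)·L)` positions to a
  different base (identity 0.95 on a 20-nt source ⇒ exactly 1 mutation),
  hidden among 195 uniform decoys.

All draws come from `numpy` generators seeded as `(seed, stream)` with a
fixed stream id per generator, so outputs are byte-reproducible and
independent of call order.

What the universe does *not* emulate: cancer-type-specific biology, tissue
or batch effects, correlated experiments from one study, realistic miRNA
sequence composition or families, or thermodynamics of targeting.  Passing
tests therefore demonstrate statistical correctness and calibration of the
*procedures*, not biological validity of any particular substitute call on
real exports.

## Benchmark problem sizes and design choices

* div parameter recovery: 500 miRNAs × ~100 experiments; the binomial bound
  predicts mean |div − (2p−1)| ≈ 0.06, asserted ≤ 0.1.
* Population ratio: 2,000 miRNAs; observed ratio asserted within 2.5 ± 0.3
  (a design-target check of the generator, not a database reproduction).
* Concordance calibration: 200 replicates of a 300-gene layer (miRNA layer
  200 × ~30), 999 permutations; type-I error asserted 0.05 ± 0.02 at ρ = 0
  and power ≥ 0.95 at ρ = 0.9.
* Planted recovery: the human context is 1 depleted miRNA (the planted
  mutants' source) against a 20-miRNA up-regulated background.  A design
  power analysis showed the margin signal scales as
  `(0.95 − baseline)/|down set|` while the 195-decoy noise floor does not
  shrink with it, so a single-source benchmark is the regime in which
  perfect top-5 recovery is a fair demand; the large up set stabilizes
  `avg_comp_up` for planted and decoys alike.  Asserted precision@5 = 1.0.
* Null margin exceedance: 500 decoy plants vs 25/25 random human sets;
  asserted fraction < 0.10 at threshold 0.10.
* Exhaustive alignment oracle: 200 random pairs of length 4–8 per mode
  (enumeration is `C(la+lb, la)` pairings, ≤ 12,870 at 8+8).

## Degenerate inputs and edge rules

Readers: status strings are authoritative for direction; logFC sign
disagreements are counted, never corrected or dropped.  More than 50%
unparsable rows aborts (wrong file).  FASTA records outside 15–30 nt or
with non-ACGU characters after T→U/uppercase normalization are rejected
and counted; zero valid records aborts.  `write_tsv` on an empty list
raises (no schema to write).  Ranking a single gene yields distance 0
(zero-variance rule).  `down_up_ratio` with no up-classified miRNA and
concordance on a constant axis raise instead of returning sentinels.  The
pipeline removes partial outputs when a stage fails and reports the stage
name.

## Known limitations

The div grading ignores effect sizes and experiment heterogeneity; the
gene distance depends on the ranked cohort (z-scores are per-input); the
complementarity value is not symmetric under containment in local mode by
construction (shorter-sequence denominator); and no multiple-testing
machinery is included because the pipeline tests a single global
concordance hypothesis.
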