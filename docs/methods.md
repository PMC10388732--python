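# Methods

`binet` implements Boolean implication network analysis of gene
expression: an asymmetric-relation alternative to correlation networks in
which pairwise dependencies are read off the *sparsity* of scatter-plot
quadrants after each gene is discretized at its own step threshold. The
package's worked application is macrophage polarization — building a
reactive/tolerant (M1-like/M2-like) continuum from a labelled expression
cohort — but every stage is generic.

## Step-function discretization

For a gene's values sorted ascending, a one-step (two-segment-mean)
function is fitted by evaluating every step position `k`; the `k`
minimizing the residual sum of squares wins (ties resolve to the smallest
`k`, for determinism). The threshold is the midpoint of the two segment
means, and the regression F statistic is

    F = [Σ(X̂ᵢ − X̄)² / (m − 1)] / [Σ(Xᵢ − X̂ᵢ)² / (n − m)]

with `m = 3` model degrees of freedom (two segment means plus the step
position; exposed as a parameter). Because the fit operates on the sorted
vector, every step is rising and no separate falling-step branch is
needed. Vectors need at least 4 finite values (both segments non-empty
and `n > m`); constant vectors are a degenerate fit. The F statistic is
reported but not used as a downstream gate.

Values are coded LOW / INTERMEDIATE / HIGH around the threshold with a
noise margin of ±0.5 — a 2-fold band on the log2 scale — and intermediate
values are excluded from all Boolean calls. Missing values code
INTERMEDIATE.

## Boolean implication calls

For genes A and B the retained samples fall into quadrants `a00, a01,
a10, a11` (first index = A, 0 = low). Under independence the expected
count is `e_ij = (A-margin × B-margin) / total`; the sparsity statistic
is `S_ij = (e_ij − a_ij) / √e_ij` and the error rate `p_ij` is the mean
of the two conditional probabilities of landing in the quadrant given the
A row and given the B column. A quadrant is sparse iff `S > sThr` (3) and
`p < pThr` (0.1). One sparse quadrant gives the matching asymmetric
implication; sparse 01+10 gives EQUIVALENT and sparse 00+11 OPPOSITE.
Design points the source formulas leave open, resolved here:

- `√e` in the denominator of `S` (the classical BooleanNet form).
- `e` and `p` for quadrants other than 00 are generalized by symmetry
  from the 00-quadrant formulas.
- Undefined statistics (zero expectation or margin) are never sparse;
  sparse patterns that match neither one quadrant nor a diagonal (e.g.
  three sparse quadrants) call NONE.
- Pairs with fewer than 8 retained samples call NONE (parameterized);
  sparsity statistics on smaller totals are meaningless — note that with
  balanced 50/50 margins a quadrant can only reach `S > 3` at all once
  the expected count exceeds 9, i.e. ~36 retained samples.

The permutation FDR shuffles every gene's ternary codes independently
across samples. This is exactly equivalent to permuting raw expression
and re-discretizing (the step threshold is a function of the sorted
values, which a permutation preserves) at a fraction of the cost.

## Network construction and clustering

Genes whose coding is nearly one-sided (less than 5% HIGH or less than 5%
LOW, boundary inclusive) are dropped before the all-pairs scan. The
EQUIVALENT subgraph is clustered by computing a minimum spanning forest
(edge weight `1 − Jaccard`, preferring strong ties; the source specifies
the spanning tree but not its weights), where the Jaccard coefficient
compares the two endpoints' equivalence-neighbor sets excluding the
endpoints themselves; forest edges with `J < 0.5` are cut and the
surviving components are the clusters, numbered from 1 by decreasing
size. Genes with no equivalences stay outside the clustered network.
An isolated equivalent pair (empty neighborhoods on both sides) is given
`J = 1` — vacuously, they share all their connections.

Cluster members are ranked by within-cluster equivalence degree. Edges
between clusters are typed by majority vote: cluster A's top-ranked gene
against a rank-sampled set of B's members (ranks {1, 2, ⌊n/2⌋, ⌊n/2⌋−1,
⌊n/4⌋, ⌊n/8⌋} for n > 10, deduplicated; top two plus the middle member
⌊n/2⌋+1 for 2 ≤ n ≤ 10; the lone member for n = 1). A strict majority
among non-NONE tallies becomes the edge; ties leave the pair
unconnected (conservative). Each unordered pair is evaluated once in the
lower-id → higher-id orientation; the reverse orientation follows by
relation mirroring (`A low ⇒ B low` ≡ `B high ⇒ A high`). The log-log
rank/size regression (`check_scale_free`) is a diagnostic for tuning the
Jaccard cut-off, nothing more.

## Boolean paths and supervised selection

A Boolean path is a cluster chain with exactly one HIGH_LOW or OPPOSITE
edge (the pivot) flanked by low⇒low chains; weights are consecutive
integers, negative before the pivot and positive from it (−1, 1, 2 in the
three-node case). Discovery is the greedy size-first traversal: from each
of the top-5 clusters, walk the low⇒low chain (bigger successors first,
ties to the lower id), pivot to the largest OPPOSITE/HIGH_LOW partner,
walk a second chain, and emit the concatenation. Starts without a pivot
emit their single arm with a warning. `enumerate_3node_paths` lists all
transitive pivot-first triples; the mirrored reading of a triple
describes the same continuum and is not emitted twice.

Selection computes each candidate's composite score on the labelled
samples and multiplies the one-vs-rest ROC-AUCs of the designated
positive classes (default M1 × M2). The score axis runs reactive(low) →
tolerant(high), so the AUC of a class expected at the low end (M1-like;
`low_labels`) is evaluated on the reversed score, classes designated high
on the score itself, and undesignated classes report the direction-free
separability max(a, 1−a). Under random labels each designated AUC
centres on 0.5 and the two-class objective on 0.25.

## Composite scores

Per gene, a modified z-score `z = (expr − thr) / (3·sd)` centres the
expression on its own step threshold; cluster scores are per-sample means
over the cluster's genes, and the path score is the weighted sum.
Thresholds and standard deviations are recomputed on the cohort being
scored (population sd over finite values), so external datasets are
scored stand-alone without carrying training-set state. Missing signature
genes intersect-and-warn; only an empty intersection is an error. The
score's own step threshold plus a propagated noise margin
`Σᵢ |wᵢ| · 0.5 / (3 · mean sd of cluster i)` assign REACTIVE /
INTERMEDIATE / TOLERANT calls; an explicit margin can be passed instead.

Survival stratification evaluates three candidate cut-offs — the score
threshold and threshold ± margin — runs the two-group log-rank test for
each candidate leaving ≥ 2 samples per side, and returns the smallest-p
candidate together with all three p-values, so the selection multiplicity
stays visible.

Circadian normalization rescales score (y) and clock-gene value (x) per
sample group by the group's dynamic ranges S1 (score) and S2 (clock):
with (S3, S4) the sample's offsets from the group mean point,
`x' = x − S3(S2+1)/(S1+1)` and `y' = y + S4(S1+1)/(S2+1)`; a single
linear regression of y' on x' across all samples then estimates the
residual trend, which is subtracted. The normalized scores are the
regression residuals (trend *subtraction*, i.e. `y' − (mx' + c)`); they
are used for rank ordering, which the transform preserves when clock and
score are unrelated.

## Single-cell analysis

Cells are scored exactly like bulk samples on two axes (reactive
signature with weight −1; tolerant signature with weights 1, 2), step
thresholds are computed on the full per-dataset cell population (one pair
of thresholds, not per group), and quadrants assigned with boundary cells
on the low side; the quadrant margin defaults to 0. Group enrichment per
quadrant uses the two-tailed two-proportion z-test. A generic two-marker
gate (`gate_cells`) selects populations such as macrophages before
scoring. Cells with no detected signature genes contribute all-zero
z-values rather than NA — the sparse-dropout convention.

Pseudobulk mixtures are averaged on the count scale and re-logged
(`log2(mean+1)`). The log compression is the operative mechanism behind
mixture detection: a 30% M1 + 30% M2 mixture in a non-expressing
background sits at ~74% of the pure samples' log signal, which is why it
crosses both the reactive and the tolerant score thresholds while a
linear (log-scale) average would not.

## Synthetic study conditions

The default blueprint plants three clusters of 48/90/47 genes with the
relation plan 13 OPPOSITE 14, 14 LOW_LOW 3 — and, transitively implied by
the state geometry, 13 HIGH_LOW 3. Three latent states realize it: M1-like
(13-high/14-low/3-low), M2-like (13-low/14-high/3-high) and M0-like
(13-low/14-high/3-low); the M0-like state is what leaves the (14-low,
3-high) quadrant the *only* empty one, turning 14–3 into a one-quadrant
LOW_LOW rather than a symmetric relation. The labelled subset is 47 M0 +
13 M1 + 8 M2; 43 further unlabelled samples per state complete a cohort
of 197. The unlabelled fill is load-bearing: with only the 68 labelled
samples the expected count in the planned sparse quadrant of the 14–3
pair is 13·8/68 ≈ 1.5, so `S ≈ 1.2` can never clear `sThr = 3` and the
plan would be statistically unrealizable; the full cohort pushes every
planned quadrant's expectation past 14 (`S ≳ 3.8`).

Expression is `low + offset_g + span·activity + ε` with low = 4, high = 8
(log2-scale units), per-gene baseline offsets (sd 0.3), latent per-sample
jitter (sd 0.05) and noise sd 0.25 — a 16-sd class separation, so the
planted calls survive the ±0.5 margin comfortably. Thirty background
genes are i.i.d. N(6, 1) noise. Single-cell matrices reuse the state
templates plus a `BG` class (signature genes at log level ~0.3,
emulating a non-macrophage background) and Bernoulli dropout. Survival
cohorts draw exponential event times whose rate is multiplied by the
hazard ratio above the score threshold, with independent uniform
censoring. Every generator is a pure function of its seed.

What the generator does **not** emulate: multi-platform batch structure,
probe-set redundancy, count-distribution realism (negative-binomial
library-size effects beyond dropout), correlated background genes, or
partially wrong labels. Passing tests therefore demonstrate the
correctness and calibration of the machinery under clean planted
conditions, not classification performance on real cohorts.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` run the full pipeline on the
197-sample blueprint (seconds per fit), 1000-vector step-fit oracle
comparisons, the complete relation-call grid over all count tables with
total ≤ 60, null matrices up to 150 × 250, 200 + 50 survival replicates,
and 450–800-cell single-cell sets — sizes chosen so the whole study runs
on a laptop-class single core in well under an hour while every check
retains its statistical teeth. Floating-point tie-breaks: smallest step
`k`; cluster ordering by (size desc, first member); path ordering by
(objective desc, cluster ids). Degenerate inputs (constant genes, empty
quadrant margins, zero-variance scores, fully censored cohorts) are
flagged or warned, never silently dropped.

## Known limitations

- The relation caller needs tens of retained samples per pair; small
  cohorts yield empty networks (by design of the statistic).
- Path discovery is restricted to single-pivot (transitive) paths.
- The clustered-network edge orientation is evaluated from the lower
  cluster id only; heavily asymmetric noise between two clusters could in
  principle vote differently in the two directions.
- The circadian transform presumes at least two samples per group and
  nonzero dynamic ranges; groups violating this pass through untouched.
- The TPM transform `log2(TPM)` above 1 / `TPM − 1` below 1 is exposed
  alongside `log2(TPM+1)`; neither is declared a default — callers pick
  per platform.
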