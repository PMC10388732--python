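# binet — Boolean implication networks for gene expression

`binet` infers *Boolean implication relationships* between genes and
turns them into interpretable, weighted gene signatures. It was built
around the macrophage polarization problem — placing samples or single
cells on a continuum from "reactive" (M1-like, inflammatory) to
"tolerant" (M2-like, tissue-remodelling) states — but every stage is a
generic building block for systems biology: discretizing expression,
calling asymmetric pairwise logic between genes, clustering the
resulting network, and scoring samples along paths through it.

## The method in brief

**Discretization (StepMiner).** Each gene's values are sorted and a
one-step function is fitted by minimizing the residual sum of squares
over all step positions; the midpoint of the two segment means is the
gene's threshold, and a ±0.5 noise margin (2-fold on the log2 scale)
defines an intermediate band that is ignored downstream.

**Implication calls (BooleanNet statistics).** For a gene pair the
retained samples occupy four quadrants a00, a01, a10, a11. With
eᵢⱼ the expected count under independence, a quadrant is *sparse* when

    S_ij = (e_ij − a_ij) / √e_ij > sThr = 3     and
    p_ij = ½ (a_ij / row_i + a_ij / col_j) < pThr = 0.1

One sparse quadrant ⇒ an asymmetric implication (`A low ⇒ B low`,
`A high ⇒ B low`, ...); sparse diagonals ⇒ `EQUIVALENT` or `OPPOSITE`.
A permutation routine estimates the false discovery rate of the calls.

**Clustered network.** Genes are clustered over the EQUIVALENT subgraph
(minimum spanning forest pruned at Jaccard 0.5); inter-cluster edges
carry the majority relation between rank-sampled representative genes.

**Boolean paths and scoring.** A path is a cluster chain with exactly
one `high ⇒ low` / `OPPOSITE` pivot and integer weights (−1 | 1, 2 in
the three-node case). Per sample, each gene contributes a modified
z-score z = (expr − thr)/(3·sd); cluster means combine through the path
weights into a composite score — low = reactive, high = tolerant. The
best path is selected supervised, by the product of one-vs-rest ROC-AUCs
of the designated classes (M1 × M2). On top of the scores sit survival
stratification (log-rank at threshold ± margin), single-cell quadrant
enrichment (two-proportion z-tests), pseudobulk mixing, circadian
normalization and gene-set overlap statistics.

A synthetic module generates cohorts, single-cell sets and survival data
with planted Boolean structure, so the whole pipeline is testable without
any external download.

## Worked example

```python
from binet import BooleanPathModel
from binet.synthetic import GeneratorBlueprint, generate_polarized_matrix

ds = generate_polarized_matrix(GeneratorBlueprint(seed=1))   # 215 genes x 197 samples
res = BooleanPathModel(ds.matrix, ds.annotation).fit()
print(res.summary())
```

```
Boolean implication path model
================================================================
genes in network      : 215
implication edges     : 17020
equivalence clusters  : 3
cluster edges (CBIN)  : 3
candidate paths       : 3

path                           objective  AUC by class
----------------------------------------------------------------
2(-1) -> 1(+1) -> 3(+2)           1.0000  M0=0.619 M1=1.000 M2=1.000
2(-1) -> 3(+1)                    1.0000  M0=0.619 M1=1.000 M2=1.000
3(-2) -> 1(-1) -> 2(+1)           0.0000  M0=0.619 M1=0.000 M2=0.000
----------------------------------------------------------------
best path: 2(-1) -> 1(+1) -> 3(+2)  (objective = 1.0000, positives = M1xM2)
```

The fit recovered the three planted clusters (the 48-gene reactive block
and the 90/47-gene tolerant arm) and the planted path through them: the
reactive cluster carries weight −1, the tolerant chain weights +1 and +2.
The objective is the M1-AUC × M2-AUC of the path's composite score —
1.0 means both polarized classes separate perfectly. Scoring the cohort:

```python
cs = res.score(ds.matrix)          # recomputes thresholds on this cohort
print(cs.to_frame().loc[["M1_001", "M0_001", "M2_001"]])
```

```
           score          call
sample
M1_001 -1.386022      REACTIVE
M0_001 -0.158981  INTERMEDIATE
M2_001  1.488596      TOLERANT
```

M1 samples average −1.49, M0 −0.02 and M2 +1.52: low scores mark the
reactive end of the continuum, and calls follow the score's own step
threshold ± its propagated noise margin.

The same pipeline is available from a shell:

```sh
binet run --seed 1 --out-dir out/          # simulate -> fit -> score + manifest
binet discretize --matrix X.tsv --out codes.tsv
binet score --matrix X.tsv --signature c13.txt --signature c14.txt \
            --signature c3.txt --weights -1,1,2 --out scores.tsv
```

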