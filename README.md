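# combinet

Bipartite network modelling of single-drug response screens for combination
therapy design.

## The problem

Large ex vivo screens (patient-derived AML samples, cancer cell line panels)
measure how hundreds of drugs inhibit hundreds of biological samples, one
drug at a time. Which *pairs* of drugs are worth combining? `combinet`
implements a phenotype-only answer: it never looks at genomics to make the
prediction, only at the potency profiles themselves.

The pipeline:

1. **Potency read-out.** Each drug × sample dose-response series is reduced
   to its median cell viability (with AUC, absolute/relative IC50 from a
   four-parameter logistic fit, and relative inhibition computed alongside,
   plus MIC/MAS/MEV association diagnostics for choosing among them).
2. **Weighted bipartite network.** The complete-case drug × sample matrix of
   inverse medians is min–max normalised to \[0, 1\] and becomes the
   incidence matrix *W* of a weighted bipartite graph: *m* drugs + *n*
   samples, *m·n* edges.
3. **Projection.** The drug similarity network (DSN) and sample similarity
   network (PSN) are the one-mode projections with product-sum weights,
   *A* = *W Wᵀ* and *Wᵀ W* (off-diagonal).
4. **Communities.** Weighted Newman–Girvan modularity
   *Q* = (1/2m) Σᵢⱼ \[Aᵢⱼ − sᵢsⱼ/2m\] δ(cᵢ, cⱼ) is optimised by a
   deterministic fast-greedy agglomeration with local refinement (infomap /
   spinglass / leiden available as seeded igraph backends; the best *Q*
   wins).
5. **Homogeneity validation.** Cluster members are checked for coherence
   against independent evidence — Dice similarity 2c/(a+b) of circular
   fingerprints, shared primary/secondary targets, shared pathways, harmonic
   expression similarity 2·Σ PᵢQᵢ/(Pᵢ+Qᵢ), continuous Jaccard distance —
   each against a random-grouping permutation null with Kruskal–Wallis and
   pairwise Wilcoxon tests (Benjamini–Hochberg adjusted).
6. **Design + synergy.** The top-*k* most potent drugs per community define
   cross-cluster ("positive") and within-cluster ("negative") combination
   sets; dose-response combination matrices are scored with the four
   reference synergy models — HSA (max(y₁, y₂)), Bliss (y₁+y₂−y₁y₂), Loewe
   (solve d₁/D₁(y) + d₂/D₂(y) = 1), and ZIP (departure of
   partner-conditioned logistic refits from the fitted-monotherapy Bliss
   reference) — and the positive/negative δ distributions are compared.

A fully seeded synthetic-cohort generator (`combinet.synthetic`) plants
block structure in every layer, so the whole pipeline is testable offline.

## Worked example

```python
from combinet import BipartiteScreenModel
from combinet.synthetic import CohortSpec, generate_responses

spec = CohortSpec(seed=3)                  # 88 drugs × 88 samples, 2×2 blocks
responses, truth = generate_responses(spec)
results = BipartiteScreenModel(responses).fit(seed=3)
print(results.summary())
```

```
Bipartite screen model
==========================================================
Incidence matrix      88 drugs x 88 samples (complete)
Weight transform      reciprocal
Bipartite graph       176 nodes, 7744 edges

network  nodes  edges  heterogeneity  degree_centralization  mean_weighted_clustering      Q  n_clusters
    DSN     88   3828         0.0000                 0.0000                    1.0000 0.4039           2
    PSN     88   3828         0.0000                 0.0000                    1.0000 0.4039           2

Drug communities      2 (sizes [44, 44], Q=0.4039, fastgreedy)
Sample communities    2 (sizes [44, 44], Q=0.4039, fastgreedy)
```

The 176-node / 7744-edge bipartite graph projects to two 88-node, 3828-edge
similarity networks; community detection splits each into the two planted
44-member blocks (adjusted Rand index 1.0 against `truth`). From there:

```python
design = results.design(k=5)               # 25 positive + 20 negative pairs
len(design.positive_pairs), len(design.negative_pairs)   # (25, 20)
```

The command line mirrors the stages: `combinet simulate`, `measures`,
`build-net`, `project`, `cluster`, `homogeneity`, `design`, `synergy` and
`run-all` (see `combinet --help`).

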