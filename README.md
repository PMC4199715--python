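# grouprank

Disease-gene prioritization in protein–protein interaction (PPI) networks.

`grouprank` ranks candidate genes by how close they sit — under a random-walk
diffusion kernel on the PPI graph — to *groups* of coordinately
differentially expressed (DE) genes derived from case/control expression
data.  The premise: a strong candidate disease gene need not itself change
expression, but the downstream genes it perturbs tend to be differentially
expressed *and* mutually co-expressed, and they cluster around it in the
interaction network.  Scoring candidates against whole co-expressed groups,
rather than against individual DE genes, suppresses the false positives that
a single dramatically changed neighbor can induce.

It is written for computational biologists who have (a) a gene-level
expression matrix with two-class labels, (b) an undirected PPI edge list
(e.g. a HINT-style flat file), and optionally (c) a list of known disease
genes for evaluation.  A seeded synthetic-benchmark generator with planted
ground truth is included, so the entire pipeline and its evaluation protocol
run with no downloads.

## The method

1. **Differential expression.** Per-gene two-sample Student t-test with
   Bonferroni correction; genes with corrected p < 0.05 are DE.  Each gene
   also gets a log2 case/control ratio.
2. **Co-expression grouping.** Pairwise distance d_ij = (1 − r_ij)/2
   (Pearson r over all samples), average-linkage hierarchical clustering,
   tree cut at a threshold d ∈ [0, 1].  Each cluster is a gene group with
   size n and expression level e = geometric mean of member |log2 ratio|.
3. **Diffusion kernel.** From the adjacency matrix A and diagonal degree
   matrix D, the transition matrix W = D⁻¹A yields the discrete
   heat-diffusion kernel

       S = (I + (γ/N)(W − I))^N        (γ = 1, N = 5 by default)

   which approximates exp(γ(W − I)) after a few iterations.
4. **Group scoring.** A candidate gene with network degree k scores, against
   a group of size n,

       R_G = s · e · min(1, α/k) · min(1, β/n)

   where s is the geometric mean of kernel similarities from the candidate
   to each group member, and the multiplicative caps (α = 15, β = 20 by
   default) penalize hub candidates and super-sized groups.  The final score
   is the sum of R_G over all groups, with per-group contributions retained
   for attribution.
5. **Evaluation.** Known disease genes are scored as ordinary candidates;
   a gene ranked r among N_c candidates has rank ratio r/N_c, and the mean
   rank ratio (MRR, lower is better) is the headline metric, alongside
   midrank Mann–Whitney ROC/AUC.  A sweep of the clustering threshold
   (0 to 1, step 0.01) locates the optimal d, and a permutation null
   replaces each group with size-matched random gene sets (1000 resamples)
   to test whether co-expression structure actually helps.

The **SingleRank** baseline is the degenerate case in which every DE gene is
its own singleton group; `grouprank` at cut threshold d = 0 reproduces it
exactly.

## Worked example

Generate a synthetic benchmark (200-node scale-free network, 3 planted
disease genes, each adjacent to a planted module of 8 co-expressed DE genes;
10 cases vs 10 controls) and rank all network genes:

```
$ grouprank simulate --seed 42 --out demo
wrote 200-node instance with 3 planted disease genes -> demo/network.tsv,
demo/expression.tsv, demo/labels.tsv, demo/truth.json

$ python -c "import json; t = json.load(open('demo/truth.json')); \
    open('demo/known.txt', 'w').write('\n'.join(t['disease_genes']))"

$ grouprank rank --expr demo/expression.tsv --labels demo/labels.tsv \
    --ppi demo/network.tsv --known demo/known.txt --out results
ranked 200 candidates (0 off-network) -> results/
MRR=0.0217 AUC=0.9882

$ head -4 results/ranking.tsv
# grouprank schema_version=1
gene    score           rank  rank_ratio  top_group  top_group_pct
G0022   0.006706803445  1     0.005       group_1    100
G0030   0.006034549128  2     0.01        group_1    100
```

The two top-ranked genes are two of the three planted disease genes
(`demo/truth.json` lists G0022, G0030, G0072): although their own expression
is pure background noise, their kernel proximity to the planted co-expressed
modules drives the score.  MRR = 0.0217 means the known genes sit, on
average, in the top 2.2% of the ranking; `top_group_pct` shows which gene
group contributes their score.

Other commands: `grouprank single-rank` (baseline), `grouprank sweep`
(threshold curve + optimum), `grouprank null` (random-group permutation
test), `grouprank eval` (ROC export).  All parameters can also live in a
flat TOML config passed via `--config`; explicit flags override it, and the
effective configuration is serialized next to every output.

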