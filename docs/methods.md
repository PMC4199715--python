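# Methods

## Model and assumptions

`grouprank` scores a candidate gene by its random-walk proximity, in an
undirected PPI network, to clusters of coordinately differentially expressed
genes.  Three assumptions underlie the score:

* disease-relevant perturbations show up as *groups* of co-expressed DE
  genes rather than isolated hits, because functionally related and
  co-regulated genes move together;
* those groups sit near the causal gene in the interaction network, so
  diffusion-kernel similarity from a candidate to group members carries
  signal even when the candidate itself is not DE;
* hub genes and very large groups accrue spurious proximity, so both are
  penalized.

The network is treated as a simple undirected graph: self-loops are dropped,
duplicate edges collapsed, edge provenance (binary vs co-complex) ignored.
The expression matrix is assumed gene-level and log2-scale; duplicate gene
rows are collapsed by mean on load.

## Pipeline components

**Differential expression.** Equal-variance two-sample Student t per gene
(Welch behind `equal_var=False`), Bonferroni multiplier = number of genes
tested, DE flag = corrected p strictly below alpha (default 0.05).  A gene
with zero variance in both classes has an undefined t statistic and is
assigned p = 1 with a warning.  The per-gene log2 ratio is the difference of
class means (log2 data) or log2 of the ratio of class means (`--linear`).

**Distance and clustering.** d_ij = (1 − r_ij)/2, with Pearson r computed
over all samples; this maps the full correlation range onto [0, 1] so the
threshold sweep's grid covers it exactly, and anti-correlated genes are
maximally distant.  The unsigned alternative 1 − |r| (which treats
anti-correlated genes as tightly coupled) is available via
`--distance-mode abs`.  Clustering is agglomerative with average linkage
(UPGMA) — the conventional choice for correlation-based expression
clustering, whose cut heights stay commensurate with the pairwise
distances — cut at height d.  Genes are sorted lexicographically before
linkage, making the partition invariant to input order; a zero-variance
gene is pushed to maximal distance from all partners.  Singleton clusters
are retained and scored (the group-size penalty handles them naturally);
`drop_singletons` removes them.

**Diffusion kernel.** W = D⁻¹A row-normalized; isolated nodes keep an
all-zero row rather than an invented teleportation term, so their only
nonzero kernel entry is the self term.  The kernel is
S = (I + (γ/N)(W − I))^N with γ = 1, N = 5 — the standard discrete
approximation of exp(γ(W − I)); a handful of iterations is already close to
the limit, and the tests verify the monotone approach.  S is computed
densely up to 20k nodes and by sparse matrix powers above, with identical
results to 1e-10.  Tiny negative entries from floating-point cancellation
are clipped to 0.  S_ij is read as similarity *from* candidate i *to*
member j; with a symmetric adjacency the direction only matters near hubs,
and the convention is fixed.

**Scoring.** s = geometric mean over group members of max(S[candidate,
member], ε) with ε = 1e-12, so one unreachable member suppresses a group
without producing log(0).  e = geometric mean of member |log2 ratio|:
magnitudes are used because a coordinately down-regulated group is as
informative as an up-regulated one and a signed geometric mean is undefined
for mixed signs; the dominant sign is kept as group metadata.  Penalties are
multiplicative caps min(1, α/k) and min(1, β/n): inactive below the
thresholds, proportional damping above, stricter as α and β shrink.  The
defaults α = 15 and β = 20 are sized relative to the mean degree (~6.7) of
curated human PPI networks, so typical candidates are unpenalized.  An
exponential variant exp(−k/α)·exp(−n/β) sits behind `--penalty exp`.
Integration is plain summation over groups, which keeps per-group
contributions additive and exactly recoverable for attribution (the
contributions matrix rows sum to the score with no re-summation error).
Candidates or members absent from the network are excluded and reported
separately, since S is only defined on network nodes.  Ties in score get
average ranks, so rank ratios are order-independent.

**Evaluation.** Known disease genes are ranked as ordinary candidates —
the method uses no training set, so nothing is held out.  MRR is the
arithmetic mean of their rank ratios; unrankable known genes go to an
exclusion list, not into the mean.  AUC uses the midrank Mann–Whitney
formulation (positives = known genes, negatives = all other ranked
candidates), verified in the tests against a brute-force all-pairs oracle.
The threshold sweep evaluates MRR on the 101-point grid d = 0, 0.01, …, 1,
reusing the kernel and DE results across grid points; ties go to the
smallest d.  The random-group null redraws each group as a uniform sample
of network nodes of the same size (without replacement within a group,
groups independent) and uses the add-one empirical p-value
(b + 1)/(m + 1), so p is never exactly 0.  The GroupRank-vs-SingleRank
comparison is a two-sided paired Wilcoxon signed-rank test on per-replicate
(or per-gene) MRRs — exact distribution up to 25 informative pairs, normal
approximation with continuity correction above; the pairing unit is the
caller's choice and the synthetic benchmarks pair per replicate.

## Synthetic benchmark generator

`make_instance` builds a Barabási–Albert graph (m = 3, giving a heavy
degree tail and a mean degree near curated human PPI networks; a
configuration-model alternative keeps its largest component), picks disease
genes among mid-degree nodes (neighborhood large enough to host a module,
degree ≤ 15 so the planted signal is not confounded with the hub penalty),
and plants one module per disease gene inside its ≤ hop_radius neighborhood,
*excluding* the disease gene itself — by default the disease gene's own
expression is pure background, isolating the network-proximity signal the
score is designed to exploit (`disease_genes_de=True` flips this).

Expression is simulated on log2 scale: background genes are i.i.d.
normal(8, 0.5); module genes share a per-module standard-normal latent
factor weighted by √ρ plus independent noise weighted by √(1 − ρ), all
scaled by the noise SD, giving within-module equicorrelation ≈ ρ, and cases
receive a mean shift of `effect` log2 units with a random per-module sign.
The default conditions are a 200-node network, 3 disease genes, module size
8, hop radius 1, effect 2.0, ρ = 0.85, 10 cases + 10 controls.  The noise
SD of 0.5 reflects the within-group spread typical of curated log2
microarray intensities, so the default effect is a 4-SD separation.  One
master seed fans out through `numpy.random.SeedSequence` children so every
stage is independently reproducible.

What the generator does *not* emulate: probe-level noise, batch effects,
normalization artifacts, missing values, the true topology of curated PPI
networks beyond a heavy-tailed degree distribution, or overlapping /
hierarchical module structure.  Passing benchmarks therefore demonstrate
that the implementation recovers planted proximity signal under its own
generative assumptions — not that it will achieve comparable MRRs on real
case/control microarray cohorts, where effect sizes, correlation structure
and annotation error are all less favorable.

## Problem sizes and numerical choices

The replicated benchmarks use 200-node instances: 50 replicates for signal
recovery and chance-level controls, 20 for the paired method comparison,
1000 resamples for the random-group null, and the full 101-point threshold
sweep — sizes at which results are stable across seeds while a complete run
stays interactive.  Determinism is exact: fixed seeds and inputs give
byte-identical output files; scores are reproducible to 1e-10 and ranks
exactly.  Degenerate inputs are handled explicitly: no DE genes yields a
flat all-zero ranking (every candidate at the average rank ratio ≈ 0.5)
rather than an error, one DE gene yields a single singleton group, and
empty networks, empty candidate sets, invalid γ/N/ρ/d all raise named
errors.

## Known limitations

* The candidate universe defaults to all network genes; prioritization
  quality degrades for genes poorly covered by the interaction network, and
  off-network genes cannot be ranked at all.
* The equicorrelation module model makes within-module correlation and DE
  effect partially confounded through the shared class shift; the
  correlation-recovery tests therefore measure ρ with the effect switched
  off.
* Bonferroni correction is deliberately conservative; with weak effects the
  DE stage, not the network stage, is the pipeline's bottleneck.
* The optimal cut threshold found on tightly correlated synthetic modules
  is small (≈ 0.03); real expression data with looser co-expression push
  the optimum higher, and the sweep should always be inspected rather than
  trusting a single default d.
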