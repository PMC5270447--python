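# synmarker

Simultaneous identification of synergistic **subnetwork markers** for
two-class gene-expression classification (e.g. metastatic vs.
non-metastatic cancer prognosis), by affinity-propagation clustering of
genes on a protein–protein interaction (PPI) network.

Single-gene prognostic signatures transfer poorly between cohorts.
`synmarker` instead looks for *groups* of genes whose protein products
are close in the interactome and whose expression changes jointly carry
more class information than any member alone.  All candidate markers
are found **simultaneously** and are **mutually exclusive** (no gene
appears in two markers), so the resulting features can be combined in
one classifier without double-counting evidence.

## Method

Per gene *g<sub>i</sub>*, class-conditional Gaussians are fitted and the
per-sample **log-likelihood ratio** λ<sub>i</sub>(x) = log
f<sub>i</sub><sup>1</sup>(x)/f<sub>i</sub><sup>2</sup>(x) is scored by
its two-sample t-statistic t<sub>i</sub> (Welch by default).  For every
ordered gene pair within shortest-path distance 2 in the PPI network the
asymmetric similarity

```
s(i,k) = t_k + min(t_ik − t_i, t_ik − t_k) − α·|t_i − t_k|,   d(i,k) ≤ 2
s(i,k) = −∞                                                   otherwise
```

rewards a discriminative candidate exemplar (first term), synergy of the
summed LLRs (t<sub>ik</sub> is the t-score of λ<sub>i</sub>+λ<sub>k</sub>;
the min term is positive only when the pair beats both singles), and
penalises mismatched discriminative power with weight α ∈ [0,1].  The
self-similarity *c* (the affinity-propagation preference) is set so that
only 1% of the finite entries lie at or above it.

**Affinity propagation** then exchanges responsibility/availability
messages over the sparse finite entries until the exemplar set is
stable; each cluster of genes becomes a candidate marker.  Clusters are
post-processed by exact 1-D k-means on the member t-scores
(k = ⌊log n + 1⌋), removing the weakest group.  A marker's **activity**
for a sample is the sum of member LLRs, A(x) = Σ λ<sub>i</sub>(x<sup>i</sup>);
markers are ranked by |t| of this activity, and evaluated by top-K power
curves, AUC-driven greedy feature selection, and repeated stratified
5-fold LDA cross-validation — including a cross-dataset protocol in
which markers and features are frozen on a source cohort before an
independent target cohort is touched.

## Worked example

Generate a synthetic benchmark (500-gene scale-free interactome, three
planted 6–9-gene modules with effect size 1.5 and within-module
correlation 0.5, two replicate cohorts), identify markers on the first
replicate, and evaluate them on the second:

```
$ synmarker simulate --out-dir fix --n-genes 500 --n-modules 3 \
    --module-size-min 6 --module-size-max 9 --n-pos 40 --n-neg 80 \
    --replicates 2 --seed 7
wrote 6 files under fix

$ synmarker identify --expression fix/expression_rep1.tsv \
    --labels fix/labels_rep1.tsv --network fix/network.tsv \
    --alpha 0.5 --top-k 10 --seed 1 --out markers.tsv
identified 10 markers (439 clusters, converged=True) -> markers.tsv

$ head -4 markers.tsv
rank    exemplar    members                                             activity_t
1       G00017      G00017;G00052;G00104;G00133;G00193;G00236;G00342;G00356  14.14713169
2       G00456      G00029;G00142;G00204;G00278;G00456                  11.55231723
3       G00115      G00039;G00115;G00253;G00407                         10.94920446
```

The top markers recover the planted modules: their activity separates
the classes at |t| ≈ 11–14.  Re-evaluated on the independent replicate
(class models refitted there), the top-10 ranking keeps a mean |t| of
5.8 — weaker, as expected across "platforms", but far from the chance
level:

```
$ synmarker evaluate-power --markers markers.tsv \
    --expression fix/expression_rep2.tsv --labels fix/labels_rep2.tsv \
    --out curve.tsv
$ cat curve.tsv
K       mean_abs_t
10      5.815793179
...

$ synmarker classify --source-expression fix/expression_rep1.tsv \
    --source-labels fix/labels_rep1.tsv \
    --target-expression fix/expression_rep2.tsv \
    --target-labels fix/labels_rep2.tsv --network fix/network.tsv \
    --n-partitions 20 --seed 2 --out report.json
AUC 0.9738 +/- 0.0375 -> report.json
```

The cross-dataset AUC of 0.97 means markers and features chosen on the
first cohort classify the second almost perfectly at this signal level.
Identical seeds reproduce every output byte for byte.

Library use mirrors the CLI: `synmarker.identify_markers(dataset,
network, alpha=0.5)` returns ranked `SubnetworkMarker` objects plus the
cluster solution; see `docs/methods.md` for the model details.

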