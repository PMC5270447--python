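# Methods

## Model and procedure

`synmarker` treats subnetwork-marker discovery as exemplar-based
clustering under a purpose-built similarity.  The pipeline:

1. **Induced network.**  The PPI graph is restricted to genes measured
   in every supplied dataset, and the ordered pair set at shortest-path
   distance ≤ 2 is computed by depth-2 BFS.  This pair set is the
   sparsity pattern of everything downstream: pairs farther apart never
   interact, represented by *absence* from the sparse structure rather
   than by any large negative float, so forbidden links cannot be
   overcome by message magnitudes.
2. **Gene scoring.**  Expression of gene *i* under class *j* is modelled
   as Gaussian; the per-sample log-likelihood ratio (LLR)
   λᵢ(x) = log f¹ᵢ(x) − log f²ᵢ(x) is computed in log space.  A gene's
   discriminative power is the two-sample t-statistic of its LLR vector
   between classes; a pair's combined power t_ik is the t of the summed
   LLR vectors.  Absolute t values enter the similarity.
3. **Similarity.**  s(i,k) = t_k + min(t_ik−t_i, t_ik−t_k) − α|t_i−t_k|
   on the distance-≤2 support.  The asymmetry is deliberate: the
   identity s(i,k) − s(k,i) = t_k − t_i means similarity always points
   toward the stronger gene, so exemplars end up being the most
   discriminative members of their clusters.  The shared preference
   (self-similarity) c is the smallest finite entry value such that at
   most a fraction q (default 1%) of the finite entries are ≥ c.
4. **Affinity propagation.**  Damped responsibility/availability
   updates on the sparse support plus diagonal; exemplars are points
   with positive self-evidence a(k,k)+r(k,k); convergence is an
   exemplar set unchanged for a window of iterations.  Final assignment
   sends each non-exemplar to the reachable exemplar of maximal
   similarity (ties to the smaller gene id), which keeps cluster
   membership within network distance 2 of the exemplar and makes runs
   reproducible.
5. **Post-processing.**  Within each cluster, 1-D k-means over the
   members' |t| with k = ⌊ln n + 1⌋ groups; the group with the lowest
   mean is dropped (degenerate cases — n ≤ 2, k = 1, all scores tied —
   leave the cluster untouched, so a marker is never emptied).  If the
   exemplar is dropped, the surviving member with the highest |t| is
   promoted to represent the marker.
6. **Activity and ranking.**  Marker activity per sample is the sum of
   member LLRs; markers are ranked by |t| of activity between classes.
7. **Evaluation.**  Top-K power curves (mean |activity t| of the
   original top-K ranking on an evaluation dataset, class models
   refitted there); greedy forward selection keeping a marker only on a
   strict AUC increase of an LDA classifier on a held-out selection
   fold; repeated stratified 5-fold cross-validation reporting mean/SD
   AUC.  In the cross-dataset protocol the source cohort is split 3-fold
   (two folds rank markers, one selects features; class densities come
   from the full source), and the frozen marker/feature choice is then
   evaluated over random 5-fold partitions of an independent target
   whose class models are refitted on each partition's training folds.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| α | 0.5 | penalty weight on \|t_i − t_k\| in s(i,k); larger α → smaller, more homogeneous markers (0.2/0.5/0.8 are the conventional settings) |
| preference quantile q | 0.01 | fraction of finite entries ≥ c; larger q → lower preference → fewer, larger clusters |
| damping λ | 0.9 | message damping; escalates to 0.95/0.99 on restart after a non-converged run |
| max_iter / stable_iters | 2000 / 100 | iteration budget and convergence window, sized so desk-scale problems converge in seconds |
| tie_noise | 1e-8 | relative magnitude of the seeded jitter applied to similarities inside `run()` |
| t variant | welch | Welch two-sample t; pooled-variance available (`variant="pooled"`) |
| σ floor | 1e-6 × global SD | lower bound on class SDs so near-constant genes cannot yield unbounded LLRs |
| top_k | 50 | markers kept after ranking |

## Numerical and design choices

* **t-statistic variant.**  "t-test score" is underdetermined; Welch is
  the robust default (no equal-variance assumption across phenotype
  classes), pooled is a flag away.  Features with zero within-class
  variance in both classes score t = 0: a constant feature has no
  discriminative power.
* **Absolute vs. signed t in s(i,k).**  Absolute.  With signed t, an
  up-regulated and a down-regulated gene of equal strength would look
  maximally dissimilar, which is the wrong notion of "similar
  discriminative power" for marker building.  Configurable upstream by
  passing signed scores.
* **Preference quantile denominator.**  The 1% rule is applied over the
  *finite* entries.  Counting all n² ordered pairs would make the rule
  unattainable on sparse supports where fewer than 1% of pairs are
  within two hops; a flag (`all_pairs_denominator`) switches to the
  all-pairs reading.  Boundary ties resolve to the larger candidate c,
  keeping the covered fraction within budget.
* **Tie-breaking jitter.**  Exactly tied, symmetric similarities make
  the message equations degenerate: by symmetry, two identical points
  either both become exemplars or neither does, and no damping schedule
  can decide between them.  `run()` therefore adds a seeded Gaussian
  jitter of 1e-8 × the similarity span before iterating — the standard
  affinity-propagation remedy.  The jitter only influences which
  messages win ties; final assignment and the reported net similarity
  use the unperturbed entries, and the seed makes reruns bit-identical.
  `tie_noise=0` restores strictly unperturbed updates.
* **Empty competitor sets.**  A gene whose only finite entry is its own
  diagonal has an empty responsibility competition; its responsibility
  is defined as 0 and the gene is forced to be a singleton
  self-exemplar, so isolated genes cannot crash or distort the solver.
* **Exact 1-D k-means.**  Optimal scalar clusters are contiguous in
  sorted order, so the post-processing k-means is solved exactly by
  dynamic programming — no Lloyd initialisation randomness.  A seeded
  Lloyd fallback covers k > 12, which the ⌊ln n + 1⌋ rule only reaches
  for clusters of ~60k genes.
* **Natural log in k = ⌊log n + 1⌋.**  Gives k = 2 at n = 3 and k = 4
  at n = 55, a plausible granularity for observed cluster sizes;
  base-10 is configurable.
* **LDA.**  scikit-learn's SVD-solver LDA, which handles singular
  within-class scatter (marker counts can approach fold sizes) without
  an explicit ridge term.
* **Stratified partitioning.**  All CV folds are stratified by class;
  with cohorts of ~35 positives, unstratified folds can lose a class
  entirely.
* **Strict AUC increase** in forward selection (> not ≥) prevents
  unbounded accumulation of tied features.
* **Duplicate probe rows** collapse by per-sample mean at load time
  (configurable); missing values are rejected unless per-gene mean
  imputation is requested.  Identifier matching is exact string match
  after trimming — alias resolution is data preparation, not method.

## The synthetic generator

`synthetic_data` emulates the method's intended inputs at desk scale:
a Barabási–Albert preferential-attachment interactome (default 2,000
genes, attachment 2 — heavy-tailed degrees like a real interactome,
though sparser than the ~10-interactions-per-protein of curated human
PPI snapshots), five planted connected modules of 8–15 genes grown by
seeded BFS, a 1:2 positive:negative class imbalance (100/200) echoing
real metastasis cohorts, and replicate datasets sharing the planted
truth.  Module genes mix a shared latent factor (pairwise correlation
ρ = 0.5) with independent noise and receive a mean shift δ = 1.5 in
positive samples; each replicate gets an independent per-gene lognormal
scale jitter (sd 0.1) standing in for platform differences.

What passing tests on this generator do **not** show: robustness to
probe-level artifacts, batch effects richer than a scale factor,
non-Gaussian expression marginals, or survival/censoring structure —
none of which the generator produces.

A known property worth stating plainly: because every planted module
shifts the *same* positive samples, genes from different modules are
statistically synergistic too — the shared within-module factor
actually *raises* the variance of summed within-module LLRs, so a
cross-module pair often scores a higher combined t than a within-module
pair.  Together with the hubs of a preferential-attachment graph
(which place many genes within two hops of several modules), this lets
optimal clusterings mix genes across modules.  Planted-module recovery
as measured by Jaccard against single markers is therefore structurally
limited under these conditions (≈0.3 in our runs) even though the
solver is verifiably near-optimal and planted genes dominate the top
ranks; distinguishing co-regulated modules would require
module-specific sample heterogeneity the generator deliberately does
not model.

## Problem sizes used in tests and the acceptance script

Exhaustive-oracle checks run on ≤ 8-point instances (100 instances);
pipeline-level checks use the generator defaults above with 10 seeds
for recovery/retention and 100 random partitions for classification
nulls; unit tests use a 300-gene, 3-module instance.  These sizes are
chosen so the whole suite completes in a few minutes on one CPU while
keeping every estimate comfortably away from small-sample artifacts.

## Known limitations

* Marker identity depends on the PPI snapshot; no alias/probe mapping
  is attempted.
* The 1% preference rule is a heuristic; no model-selection criterion
  for the number of markers is provided.
* Within-dataset evaluation reuses markers identified on the full
  dataset (the standard shortcut given the cost of re-identifying
  markers per partition), which optimistically biases its absolute AUC;
  the cross-dataset protocol is the honest benchmark and keeps strict
  information hygiene.
* Affinity propagation is not guaranteed to reach the global optimum of
  the net-similarity objective; on small instances it does in the
  median (verified exhaustively), but symmetric or adversarial inputs
  can settle at slightly suboptimal solutions.
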