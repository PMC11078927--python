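# Methods

`mrgrn` implements a master-regulator discovery procedure for two-condition
bulk RNA-seq studies: differential expression on raw counts, restriction of
a curated transcription-factor→target network to the expressed regulators of
each condition, and identification of master-regulator candidates as the
transcription factors that survive an iterative lowest-out-degree pruning of
the differentially-expressed-gene neighborhood. This note records the model,
the defaults, the numerical choices, and what the synthetic benchmark does
and does not demonstrate.

## Differential expression

Counts K_gj for gene g in sample j are modeled as negative binomial with
mean s_j·q_gc (c the sample's condition) and variance μ + α_g·μ².

* **Size factors** are median-of-ratios: s_j = median_g K_gj / (∏_k K_gk)^(1/m),
  the median taken over genes with strictly positive counts in every sample.
  There is no pseudo-reference fallback; a matrix without a single
  all-positive gene is rejected explicitly.
* **Dispersions** α_g are per-gene method-of-moments estimates on
  size-factor-normalized counts: within each condition,
  α_c = (var − mean)/mean², pooled across the two conditions by their
  degrees of freedom and floored at 1e-8. Genes whose sample variance does
  not exceed the mean (including constant genes) sit at the floor. There is
  no dispersion trend, no shrinkage toward it, and no outlier refitting.
* **Wald test.** Group means q̂_c are fitted as means of normalized counts.
  The reported effect is log2fc = log2((q̂_case+0.5)/(q̂_ctrl+0.5)); the +0.5
  pseudocount keeps zero-count groups finite in the absence of shrinkage.
  SE(log2fc) comes from the NB information at the fitted means,
  Var(ȳ_c) = (Σ_j q̂_c/s_j + n_c·α·q̂_c²)/n_c², and the two-sided p-value is
  read off the **normal** reference. Genes with zero counts in all samples
  are reported `untested` (p undefined) rather than propagating NaNs.
* **Multiplicity.** Benjamini–Hochberg step-up with monotonicity
  enforcement, undefined p-values excluded from m. A gene is called up
  (down) iff padj < α and log2fc > fc_threshold (< −fc_threshold).

Defaults: α = 0.05; fc_threshold = 0 for the DEG set passed to the network
stage. The fold-change filter exists because volcano-style reporting
commonly applies one, but the network stage is defined on adjusted-p
significance alone; both cutoffs are parameters.

**Small-sample behavior.** The normal reference makes this a large-sample
test. With the study-scale 4 replicates per group the statistic behaves
like a t with ~6 degrees of freedom read off the normal table, i.e. raw
p-values are anti-conservative (the test suite measures ~11% null genes at
p < 0.05 at n=4 versus ~5.5% at n=50). Calibration properties (null
uniformity, FDR of BH calls) are therefore asserted in the n = 50/group
regime where the approximation holds; at n = 4 the pipeline still ranks
strong planted effects correctly, which is what the recovery benchmark
checks, but individual p-values should be read as scores, not calibrated
probabilities. No batch covariate is modeled; a matrix already corrected
for batch can be supplied in place of raw counts (the correction itself is
out of scope).

**Normalization identifiability.** Median-of-ratios assumes the majority
of genes are unchanged and roughly sign-balanced. If a large fraction of
the transcriptome shifts in one direction, the size factors absorb part of
the shift and unchanged genes acquire an opposite apparent fold change.
This is a property of global-scaling normalization generally, not of this
implementation; the FDR benchmark uses a sign-balanced planted mixture for
exactly this reason.

## Reference network and contextualization

The reference network is the union of user-supplied edge lists (TRRUST-like,
RegNetwork-like, DoRothEA-like, or generic three-column TSV dialects),
deduplicated per ordered pair. Sources are merged; an explicit
activation-vs-repression conflict across databases yields mode `ambiguous`,
while `unknown` is absorbed by any signed mode; the best (lexicographically
smallest) confidence grade is kept. Gene symbols are opaque and
case-sensitive — no identifier mapping is attempted, so all inputs must
share a symbol space.

Contextualization removes every outgoing edge of a transcription factor not
expressed in the condition, keeps incoming edges regardless of the target's
expression, and drops nodes left without any edge. "Expressed" means the
arithmetic mean of **raw** counts over the condition's replicates is ≥ τ,
boundary inclusive, with τ = 10 by default. The aggregation rule is
configurable (`mean`/`min`/`max`) because a per-condition cutoff can
reasonably be read against any of them; the mean is the default as the
least surprising summary of replicates. Raw rather than normalized counts
are used deliberately: the cutoff is an absolute detection threshold, not a
relative abundance statement. Contextualization is idempotent and
monotone in τ, and each condition is contextualized independently.

## Master-regulator inference

1. **Neighborhood.** From the contextualized network, keep the DEGs present
   in it plus every node with a directed path of length 1 or 2 to a DEG
   (first and second upstream neighbors), and take the induced subgraph.
2. **Core pruning.** Repeatedly select the node with minimal current
   out-degree — ties broken by minimal in-degree, then lexicographic id —
   tentatively delete it, and commit unless the remainder would have fewer
   than 2 nodes or be weakly disconnected, in which case the deletion is
   undone and pruning stops. The surviving dense core, by construction,
   contains the regulators with the highest residual edge density.
3. **Annotation.** Each surviving node that is a TF in the reference
   becomes a candidate, annotated with its in/out degree inside the core,
   DE status and direction, reciprocity (it both directs and is directed by
   other survivors), and, when a physical-interaction pair table is
   supplied, whether any surviving partner is a documented physical
   interactor. The differentially expressed candidates are the headline
   result set.

Design choices where the procedure is underdetermined:

* "Unconnected" is read as **weak** disconnection of the directed graph;
  a remainder of fewer than 2 nodes also stops pruning so that termination
  is well defined.
* The tie-break (in-degree, then id) exists only to make runs
  deterministic; the pruning trace records every committed removal and the
  blocking event so alternative policies can be compared offline.
* Stop-at-first-block is the default. A `skip_blockers` variant sets the
  blocking node aside and tries the next-lowest instead, pruning deeper; it
  never yields a larger survivor set.
* A weakly disconnected input is pruned one component at a time (components
  ordered by their smallest node id) and the surviving blocks merged.
* Self-loops count once toward each degree and never affect connectivity.
* All nodes are eligible for deletion; pure targets (out-degree 0) simply
  fall first under the rule.
* When the per-condition candidate sets differ, the report carries both
  sets and their intersection; the headline `de_mrs` is the case-condition
  set, since the disease context is the study subject.

## Enrichment

Overrepresentation of a DEG set against a GMT collection uses the exact
hypergeometric upper tail P(X ≥ k) for an overlap of k DEGs in a term of
size K within an N-gene universe, BH-adjusted across tested terms. The
universe defaults to the genes the DE stage actually tested (not the whole
annotation) to guard against annotation-composition bias; terms are
filtered to 5 ≤ K ≤ 500 after intersection with the universe, common
practice in the absence of a stated rule. No ontology topology or
redundancy trimming is attempted.

## qPCR quantification

Per animal, dCt = Ct_target − Ct_housekeeping; ddCt references the
arithmetic mean of the control group's dCt, so the control group's mean
relative expression is 1 by construction; rq = 2^(−ddCt). Animals missing a
housekeeping Ct are excluded with a warning. Group comparison is the
pooled-variance (Student) unpaired two-sided t-test, df = n₁+n₂−2, with the
degenerate zero-variance cases mapped to p = 1 (equal means) or p = 0 with
a warning (unequal means). No amplification-efficiency correction is
applied.

## Synthetic benchmark

The generator plants a known truth so the whole chain is testable without
any external dataset:

* A reference network of `n_tfs` TFs and `n_targets` targets. Each TF draws
  a Poisson out-degree (mean `targets_per_tf`; planted MRs draw 3× that, so
  they are hubs) and picks targets by preferential attachment (weight
  1 + current in-degree), which makes popular targets shared between TFs.
  Planted MRs additionally regulate each other pairwise, giving them the
  direct-and-be-directed reciprocity of the master-regulator definition.
  Edges carry a regulation mode (60% activation / 40% repression, the
  rough skew of curated databases).
* Counts for 2·`n_replicates` samples: every gene is NB(`baseline_mean`,
  `dispersion`) in controls; in cases, planted MRs shift by `mr_log2fc`,
  their direct non-MR targets by ±`cascade_log2fc` according to the net
  planted edge sign (ties favor activation), and a fraction
  `frac_low_expressed_tfs` of the non-MR TFs drops to a mean of 5 counts —
  below the contextualization cutoff — to exercise contextual edge removal.
  The mixed-sign cascade keeps the simulated transcriptome compositionally
  balanced, as real ones are; an all-up cascade at this desk scale (~30% of
  genes) would confound global-scaling normalization itself.
* qPCR Ct tables for the planted MRs: housekeeping Ct 20, target Ct 25 in
  controls, reduced by `mr_log2fc` cycles in cases, plus Gaussian noise
  (default sd 0.25 cycles); at zero noise the ddCt readout recovers
  2^`mr_log2fc` exactly.

Defaults (seed 1, 30 TFs, 300 targets, 5 planted MRs, mean out-degree 8,
4 replicates/condition, baseline mean 200, dispersion 0.1, mr_log2fc 1.5,
cascade_log2fc 2.0, 20% low-expressed TFs) mirror a 4-replicate
two-condition design with a handful of true master regulators at a size
where every stage runs in seconds. All draws come from integer-seeded
generators with a fixed draw order, so every output is reproducible from
the scenario seed.

What the benchmark does **not** emulate: library-size variation between
samples (size factors are exercised by dedicated scale-invariance tests
instead), batch structure, gene-length or GC effects, correlated
gene-gene noise, indirect (second-order) cascade effects, and annotation
databases with version drift. Passing the planted-recovery benchmark shows
the chain of contracts is implemented coherently, not that the procedure's
biological conclusions transfer to any particular real dataset.

## Known limitations

* At n = 4/group the raw p-values are anti-conservative (see above); the
  planted-recovery benchmark tolerates this because planted effects are
  large, but real marginal calls at this depth deserve skepticism.
* One-directional global expression shifts are partially absorbed by
  normalization and cannot be distinguished from reciprocal changes in the
  unaffected genes without spike-ins.
* Stop-at-first-block pruning is conservative: a single weakly attached
  peripheral node can freeze the survivor set early, enlarging the
  candidate list. The DE filter downstream is what keeps the headline set
  small; `skip_blockers` offers the aggressive alternative.
* The reference network is authoritative: no edges are inferred from
  expression, and nothing corrects for database coverage bias toward
  well-studied TFs.
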