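# Methods

This note records the statistical model behind each stage, the defaults
and why they were chosen, and the design choices made where the procedure
was genuinely open.

## The analysis in one paragraph

Given three genes × samples abundance matrices (mRNA, lncRNA, miRNA), a
sample table with condition and survival fields, an AGO-evidence-filtered
miRNA–target catalog and a GMT gene-set collection, the pipeline: filters
low-expressed genes, tests each gene tumor-vs-normal, builds a bipartite
miRNA–target network restricted to differentially expressed molecules with
correlation-supported edges and the shared-miRNA (ceRNA) constraint,
extracts tri-class modules, stratifies tumor samples on each module's
expression for a log-rank comparison, and scores gene sets per sample with
ssGSEA for module–pathway correlation and group comparisons.

## Differential expression

* The *t*-test runs on log₂(x + c), c = 0.01 by default. Abundance data
  are strongly right-skewed and heteroscedastic; the log transform
  stabilizes variance, and the pseudocount only matters for abundances
  near zero. Welch's form is used because group variances are not assumed
  equal (tumor cohorts are usually noisier than normals).
* The fold change is computed on linear-scale group means, so the FC > 2
  gate equals |log₂FC| > 1. Mixing scales (test on log, FC on linear) is
  the conventional reading of "fold change of group means".
* The 10% low-expression filter is inclusive at the boundary: a gene
  non-zero in exactly 10% of samples is retained ("less than 10% …
  ignored").
* No multiple-testing correction by default (the DE gate is a raw
  p < 0.05 plus the fold-change gate); Benjamini–Hochberg is available via
  `DeConfig(adjust="BH")`.
* Degenerate genes (zero variance in both groups) get the documented
  limits t = 0, p = 1 (equal means) or p → 0 (unequal means) rather than
  NaN.

## Network construction

* Edge correlations are computed on log₂(x + c) across **all** samples,
  tumor and normal pooled. Pooling inflates |r| for pairs that are
  differentially expressed in opposite directions — that is the
  dysregulation signal this design deliberately selects for, but it also
  means a pair of co-differential genes with independent noise can pass
  the gate; the planted-edge precision measured by the acceptance script
  quantifies how often that happens under the default conditions.
* Thresholds are strict inequalities: |r| > 0.3, p < 0.01, with p from
  the t transform of r on n − 2 degrees of freedom.
* Edge sign is not constrained by default (the gate is on |r|);
  `require_negative=True` restricts edges to the canonical repression
  sign.
* The shared-miRNA step removes every miRNA lacking either a passing
  lncRNA edge or a passing mRNA edge, then its edges, then any target
  left isolated. One pass suffices: removing a miRNA cannot invalidate
  another miRNA's edges.

## Module detection

Hierarchical clustering methods for protein-interaction networks score an
edge by the neighborhood overlap of its endpoints; on a bipartite
miRNA–target graph that score is degenerate (a miRNA and its target share
no neighbors), so module detection here uses the correlation weight
directly: edges sorted by |r| descending (ties broken lexicographically on
(miRNA, target)) are processed through a union–find that merges two
clusters only when the merged size stays ≤ `max_size` (default 20).
Clusters with ≥ `min_size` (default 6) nodes containing all three RNA
classes are emitted, ordered by descending mean |r|. The procedure is a
deterministic surrogate for the published plugin algorithms, not a port;
its properties — node-disjoint, connected, class-complete modules,
invariant to input order — are what the tests rely on. The defaults were
chosen so that a planted module (two bridged regulons, ~16 nodes) fits
under the cap while two planted modules cannot merge through a single
spurious edge.

## Survival analysis

* Features for k-means are per-gene z-scored log₂ abundances; without
  z-scoring the highest-abundance RNA class dominates the Euclidean
  metric. k = 2, ten restarts of seeded k-means++ initialization, best
  inertia (scikit-learn). Labels are canonicalized so group 1 always has
  the higher mean module expression, which makes output stable across
  seeds for separable data.
* Kaplan–Meier estimation and the log-rank test (hypergeometric variance
  with ties, χ² on 1 df) are delegated to lifelines; the test suite
  verifies both against hand-rolled product-limit and O−E/V accumulations.
* The tumor-vs-normal module test is a two-sided Wilcoxon rank-sum on the
  per-sample mean log₂ expression of the module RNAs; exact null for
  combined n ≤ 20 without ties, tie-corrected normal approximation
  otherwise.
* Samples missing survival fields are excluded from stratification with a
  logged count; condition is required for everyone.

## Gene-set machinery

* ORA: hypergeometric upper tail P(X ≥ k) with the gene set intersected
  with the stated universe; BH across the collection.
* Preranked GSEA: weighted Kolmogorov–Smirnov running sum — |w| normalized
  over set members as increments, uniform 1/(N−K) decrements at
  non-members; ES is the signed maximum deviation. The null permutes gene
  labels (sample permutation is impossible for preranked input); the
  p-value uses the +1-smoothed same-sign count and NES divides by the mean
  |null ES| of the same sign.
* ssGSEA: per sample, genes ranked by expression descending with
  tie-averaged ranks; the score sums, over the full walk, the rank^τ-
  weighted cumulative in-set fraction minus the unweighted out-of-set
  fraction. τ = 0.25 and division of the final matrix by its overall
  range follow the customary single-sample GSEA convention. Scores
  depend only on within-sample ranks, hence are invariant to any
  monotone within-sample transform.
* ncRNA annotation by co-expression: average Pearson r of each mRNA over
  the ncRNA set, top 500 by signed average (an `absolute` option exists);
  ties broken lexicographically.

## Synthetic cohort model

Expression is log-normal: log₂ x = baseline + δ·tumor + λᵀf + ε with
ε ~ N(0, σ²), per-gene baselines drawn around class-specific means (mRNA
2⁵, lncRNA 2³, miRNA 2⁶, spread 1.5 log₂ units) so the three classes live
on realistic, different dynamic ranges.

* **DE genes** (fraction 0.15 per class): |δ| ~ N(2, 0.25) log₂ units,
  random sign outside regulons. With σ = 0.5 and 60 vs 20 samples this
  puts planted genes far past both gates while null genes pass at < 5%,
  the regime the recovery criteria describe.
* **Regulons** (10): one miRNA + 5 mRNA + 2 lncRNA targets, all drawn
  from the planted DE pools so planted edges always join DE molecules.
  miRNA and targets load on a shared latent factor f ~ N(0,1) with
  opposite signs and magnitude a = σ·√(ρ/(1−ρ)), which gives
  within-condition correlation −ρ (default ρ = 0.8) between miRNA and
  target.
* **Modules** (2): pairs of regulons joined by a bridge edge and sharing
  one latent factor, ≈16 nodes each. Module regulons are oriented
  targets-up / miRNA-down so module expression is higher in tumors;
  standalone regulons use the canonical miRNA-up / targets-down
  orientation.
* **Decoys** (200): uniform random non-planted miRNA–target pairs with
  independent noise and 0–3 AGO sites. Decoys between two DE genes can
  pass the pooled-correlation gate (see the network caveat above); at the
  default DE fraction the expected number of such passes stays well below
  a tenth of the planted edge count.
* **Survival**: the first module's per-sample mean log₂ expression,
  standardized over tumor samples, drives an exponential hazard
  h ∝ exp(β z)/s with β = 1.5 and baseline scale s = 1000 days.
  Censoring is an independent uniform time on (0, k·s) with k solved so
  the expected censoring fraction under the baseline hazard matches
  `censor_rate` (default 0.3).
* **Gene sets**: one planted set per module (the module's mRNAs padded
  with other DE mRNAs to 25 members) plus 8 random background sets.

What the generator does **not** emulate: count noise (no negative-binomial
sampling), batch effects, tumor purity, copy-number confounding,
administrative censoring, and realistic library-size variation. Passing
recovery tests therefore demonstrates the pipeline's correctness and power
under a clean log-normal world, not robustness to those artifacts.

Determinism: one `numpy.random.default_rng(seed)` drives all draws in a
fixed order, so a config + seed reproduces every matrix and the truth
bit-identically. The pipeline derives per-stage seeds from its global seed
via `SeedSequence`, keeping stages independently rerunnable.

## Evaluation conventions

* Planted-module recovery is scored as the adjusted Rand index between
  detected and planted partitions restricted to planted-module nodes: the
  truth labels only those nodes, while the network legitimately contains
  additional stars (standalone regulons) the truth does not name.
* Log-rank power is measured on the planted prognostic module (simulate →
  stratify → test) across repeated cohorts with 100 tumor samples,
  isolating the survival machinery from upstream detection noise; the
  null rate repeats this with the hazard disabled.
* The default evaluation cohort is 500 mRNA / 200 lncRNA / 100 miRNA with
  60 tumor and 20 normal samples — large enough that every recovery
  statistic is measured on dozens-to-hundreds of decisions, small enough
  that the whole pipeline runs in seconds.

## Known limitations

* The pooled-correlation caveat above: co-differential decoys can enter
  the network; a within-condition correlation option would remove them at
  the cost of diverging from the published two-step filter.
* The module detector is a surrogate with its own size parameters; module
  boundaries on real data will differ from any specific plugin algorithm.
* ssGSEA normalization divides by the global score range, so scores are
  comparable within one run only.
* k-means stratification assumes two groups; modules whose expression is
  continuous rather than bimodal get an arbitrary-but-deterministic split.
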