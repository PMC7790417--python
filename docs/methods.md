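# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of the `irnet` pipeline, in the order data flows
through it. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Synthetic cohort model (`irnet.synth`)

The generator emulates a multi-clone iPSC expression study of insulin
resistance and provides the ground truth every downstream stage is
validated against.

**Cohort structure.** `n_donors` (default 100) donors, 48% insulin
sensitive, each contributing `clones_per_donor` (default 3) clone samples.
SSPG is drawn per donor from N(84, 20) mg/dl (IS) or N(210, 45) mg/dl (IR);
group membership is taken from the planted label, and the 140 mg/dl
classifier is exercised separately, so label noise near the cutoff cannot
corrupt recovery experiments. Donor covariates: sex, age N(58, 8), BMI
N(29, 4), three ethnicity levels, reprogramming source cell; sample
covariates: four sequencing batches, two RNA kits.

**Latent expression.** Each gene's log2-scale signal is built in
topological order of a planted DAG:

    z_g = lam_g * phi(z_hub) + sum_p w_pg * phi(z_p) + beta_e * (dos - mean)
          + noise_g

* **Modules as hub neighborhoods.** Five modules of 30–45 genes. The
  module "factor" is the hub regulator (key driver) itself: every module
  gene loads on the hub's expression with `lam = 0.6`, so all module pairs
  share ≈ lam² of their variance regardless of their distance in the
  planted tree. The factor is therefore an *observed* variable, and
  conditioning on the hub blocks within-module confounding during network
  learning — an early draft used a latent per-module Gaussian factor, which
  either left the modules incoherent (weak factor) or flooded structure
  learning with confounded edges (strong factor). This is also the
  biological reading of key driver analysis: the driver regulates its
  co-expression module. Modules without a planted driver (when
  `n_kd < n_modules`) keep a latent donor-level factor.
* **Layered trees.** Each hub feeds a layered subtree: layer-1 width drawn
  from `kd_out_degree` (11–16), subsequent widths decaying geometrically
  (×0.7), depth capped at six layers; each deeper node draws one (30%: two)
  parents from the previous layer only, so the planted layer equals the
  shortest directed distance from the hub. Edge weights scale with
  `intra_module_corr` (0.6). 20% of genes are "decoy" regulators with 1–3
  edges into random tree genes; the remainder is unstructured background
  (3% of it lowly expressed, to exercise the CPM filter).
* **Response curve.** `phi(x) = (x + c (clip(x)² − 1)/√2)/√(1 + c²)` with
  `c = nonlinearity = 0.4` and saturation at |x| = 3. A purely
  linear-Gaussian structural model leaves every non-root edge
  score-equivalent and no method could orient it; the mild quadratic
  component is the generative counterpart of the modeling assumption that
  biochemical perturb–response relations are nonlinear, which is what makes
  causal direction identifiable from observational data.
* **Noise calibration.** Each child's noise SD is set so the parent-signal
  fraction of its variance equals `intra_module_corr`, then the latent
  value is standardized to unit variance. Without the standardization,
  variance multiplies by 1/rho per layer and deep genes drown the planted
  group effect. Residual noise is 30% donor-level / 70% clone-level
  (clone-to-clone variability of iPSC lines is large); the hub factor and
  all genetic variance are donor-level, so clones of one donor still
  cluster together.
* **Genetics.** 25 cis-eQTL anchor genes — the five hubs first, the rest on
  exogenous (decoy/background) genes so planted roots are sources of the
  truth DAG — each with a biallelic marker (MAF U(0.2, 0.5)) within 1 Mb of
  its TSS and an allelic effect of `eqtl_beta = 1.0` log2 units, a strong
  cis signal detectable at 60 donors.
* **Group effect.** `group_effect_size` (1.0 log2 units, random sign per
  gene) is added to IR samples on genes strictly downstream of the planted
  hubs only, so the DE list genuinely points at the planted regulators and
  key-driver recovery is a meaningful test.
* **Counts.** Negative binomial around library-scaled relative abundances
  (`lib_size_range` 0.8–1.2 M for the default 800–5000 gene panels);
  gene-level dispersion log-normal around `dispersion = 0.04` (BCV ≈ 0.2,
  technical-scale overdispersion — biological variation is already carried
  by the latent signal).
* **Perturbation.** The in-silico inhibition shifts every gene downstream
  of the target by `−perturb_effect × attenuation^(layer−1)` (2.0 and 0.5
  by default), applied directly per layer on top of a paired latent state
  (same line with/without inhibitor). The treated/control arms are fresh
  draws from the stored generator state.

**What the generator does not emulate.** Read-level sequencing artifacts,
linkage disequilibrium beyond one causal marker per gene, isoforms,
GC/length biases, cross-module pathway overlap, and latent global expression
factors (PEER-style structure). Passing tests therefore show that the
pipeline recovers planted structure under a clean, factor-plus-DAG model of
expression — not that it would perform identically on a real cohort, where
unmodeled latent structure and weaker, more diffuse effects will reduce
power.

## Normalization and residualization (`irnet.normalize`)

Filtering keeps genes with ≥ 1 CPM in ≥ ceil(0.30 × n) samples (the
boundary count passes). TMM follows the trimmed mean of M-values exactly as
the reference implementation computes it — reference column by 75th
expression quantile closest to the mean, doubly trimmed M (30%) and A (5%)
ranks, inverse-asymptotic-variance weights, factors normalized to product
1 — and is cross-checked against edgeR in the test suite. log2-CPM uses a
prior count of 0.5: `log2((count + 0.5)/(lib × factor + 1) × 1e6)`.

Covariate adjustment fits, per gene, fixed-effect terms (OLS columns;
continuous covariates standardized) and random-effect terms (batch, RNA
kit) as ridge-shrunken level effects. The shared penalty is profiled per
gene by REML on a 81-point log-spaced grid after absorbing the fixed
design (SVD of the projected random design makes each evaluation O(q));
the final solve uses Henderson's equations, which makes the residuals
exactly orthogonal to the fixed-effect design and mean-zero. This is
partial pooling with the intent of a mixed model but deterministic and
dependency-light. ApP residuals are arithmetic means of each donor's clone
columns.

## Differential expression (`irnet.de`)

Two-group per-gene linear model on residuals with empirical-Bayes variance
moderation: gene variances are shrunk toward an inverse-gamma prior fitted
by matching moments of log s² (trigamma inversion by Newton), degrees of
freedom augmented by the prior df; the implementation matches limma's
moderated t to ~1e-12 on shared fixtures. Testing residuals with a
group-only design reproduces the study's two-stage scheme and is known to
be anti-conservative relative to a joint model; the ApP stream (donor-level
units) is the calibrated counterpart, and the pipeline follows the
convention of using the top 500 genes by p-value for ApP target lists when
nothing passes FDR. BH adjustment wraps statsmodels. Rank comparison takes
the union of each stream's top-500 genes (the union convention is a
documented choice) and reports Spearman's rho plus a paired Wilcoxon test.

## Co-expression modules (`irnet.coexpress`)

Unsigned adjacency |cor|^power; soft power chosen as the smallest candidate
(1–12 in half steps) whose signed scale-free R² (log-log regression of
binned connectivity frequency) reaches 0.8, with a plateau rule — accept a
lower power at R² ≥ 0.78 when the next increment improves by < 0.01 — and
an argmax fallback below 0.5 (warned). TOM as defined above; constant genes
get zero correlation with a warning.

Module detection is average-linkage clustering on 1 − TOM with a static
cut. The cut default is adaptive: candidate cuts between consecutive merge
heights are scanned and the *highest* cut maximizing the number of clusters
of size ≥ `min_module_size` (30) is used. A fixed quantile of merge
heights (an earlier default) fails on both tails — background-dominated
trees put every informative split below it, and it has no defense against
absorbing modules into the background. The adaptive rule finds the finest
stable level; its known limitation is that a module larger than twice
`min_module_size` may be split (an explicit `cut_height` overrides, and
dynamic tree cutting would be the full-strength alternative).

The permutation background shuffles every gene row independently (the
strongest null preserving gene marginals), pools permuted |correlations|
within each module across 10 permutations, and scores observed pairs as
`(1 + #{null ≥ obs})/(1 + #null)`. Module selection is one-sided
hypergeometric enrichment against GMT sets over the analyzed-gene universe,
BH across all module × set tests; a module is selected when any set whose
name matches a configured relevance list (glucose / hexose / glycolysis /
lipid / cholesterol / sterol / electron transport / mitochondrial /
insulin) passes FDR < 0.05. Set-overlap tests replace a running-sum
enrichment statistic because module membership is a plain set.

## Seed expansion (`irnet.expand`)

Multi-source BFS from the selected module genes over the prior network,
depth k = 3, edges traversed as undirected (interaction databases carry no
trusted direction); DE genes are unioned afterwards with provenance
priority module > DE > expanded. Missing seeds are kept with a warning.

## Causal networks (`irnet.causalnet`)

The cis-eQTL scan regresses donor-level residuals on every MAF-filtered
(≥ 0.01) marker within 1 Mb of the TSS (inclusive window), records each
gene's best marker and BH-corrects across genes; FDR < 0.05 genes become
root genes.

Structure learning is greedy hill climbing (add/delete/reverse, best move
first, cycle-blocked moves skipped per sweep) over candidate pairs adjacent
in the prior or sharing a co-expression module, under acyclicity, root
in-degree 0 and `max_parents = 3`. The family score is a Gaussian BIC in
which every parent contributes two regressors — its profile and its
standardized squared response — computed from a precomputed feature Gram
matrix and cached per (child, parent set). The quadratic feature is the
top-down face of bottom-up causality inference: when the data-generating
response is curved, regression functions are not symmetric under edge
reversal, so the score itself distinguishes orientations instead of leaving
entire equivalence classes to chance. The BIC complexity term carries a
multiplier (`penalty = 2.0`, extended-BIC style) because at n ≈ 30–90 units
over hundreds of nodes plain BIC admits many weak shortcut edges; planted
edges carry likelihood gains an order of magnitude above the stricter
penalty. Restarts (default 1) climb from random legal subgraphs.

`orient_equivalent_edges` then visits every edge whose reversal is legal
and changes the BIC by less than 2 (the conventional "not worth more than a
bare mention" band), fits cubic polynomials in both directions and keeps
the direction whose residuals have lower distance correlation with the
predictor; ties within 0.02 are declared unresolvable and keep the original
orientation (the linear-Gaussian identifiability limit). Genotypes enter
only through root constraints, not as network nodes. The module documents
its tested scale (≤ ~500 nodes); the contract is the stated invariants and
recovery properties, not equivalence to any proprietary engine.

## Key driver analysis (`irnet.kda`)

Candidate nodes come from the background sub-network (targets plus their
K = 6-step upstream neighborhoods). For each candidate and each h = 1..6, a
one-sided Fisher exact test compares |downstream_h ∩ targets| against the
whole network's node set; the candidate's own target membership is excluded
from its neighborhood, overlap and universe. The Fisher universe is the
network rather than the sub-network: when a network is learned well, the
background sub-network is nearly all targets and a sub-network universe
saturates every p-value toward 1 — the whole-network universe is also the
convention of published key-driver implementations (`universe="background"`
remains available). BH runs across all (node, h) tests jointly; key drivers
are significant at any h. Target lists smaller than 10 in-network genes are
refused (minimum-set-size convention of enrichment tools; tiny lists from
null cohorts otherwise yield formally significant but meaningless calls).

Appearances are counted per network (a gene "appears" when called for any
of that network's target lists); the final prioritized call keeps genes
with ≥ 3 appearances whose DE-proximity score reaches at least half of the
best candidate's — co-dominant hubs score within a factor of each other
while replicated pathway intermediates trail by an order of magnitude. DE
proximity uses downstream paths only (the score reads "from the key driver
to the DE genes"); both scores use shortest directed path lengths and are
exact against a Floyd–Warshall oracle in the tests.

## Perturbation validation (`irnet.validate`)

Layers are shortest directed path lengths from the perturbed node (diamonds
take the minimum); layers beyond `max_layer` pool into a final row. The
per-layer report gives %DE at FDR < 0.05, mean |log2FC| and mean −log10
FDR, with non-increase flags from layer 1. Treated-vs-control DE reuses the
de module in paired mode (the inhibition design is paired by cell line).
The downstream-enrichment Fisher test and the Venn-style overlap partition
complete the layer profile.

## Benchmark scales and determinism

The tested study conditions are 60 donors × 3 clones and 800 genes with 5
planted drivers (each ≥ 25 downstream group-DE targets) for the recovery,
null-calibration and module-recovery experiments, and 40 donors × 600 genes
for the demo; these sizes keep a full pipeline run in seconds while leaving
every stage's statistics in their intended operating regime. All
randomness flows from one global seed through named SHA-256-derived
substreams; reruns are byte-identical, including the demo manifest.

## Known limitations

* The AS stream treats clones as independent; with donor-level group
  assignment it is anti-conservative by design (documented above), which is
  why the pipeline carries the ApP stream alongside.
* Static tree cutting can split very large modules and has no merge step.
* The additive-noise orientation pass is reliable on clean bivariate
  relations; on confounded pairs inside modules its evidence is weak, which
  is why the quadratic-feature score, the eQTL roots and the prior-restricted
  search space carry most of the orientation burden.
* Network learning is tested to a few hundred nodes; the score cache and
  move arrays would need blocking for genome-scale seeding sets.
* Appearance counting assumes the four-network factorial design; other
  designs reuse `count_appearances` but the ≥ 3 threshold should be
  reconsidered.
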