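# irnet

Network modeling of insulin resistance from multi-clone iPSC expression
cohorts: co-expression modules, causal (predictive) networks with cis-eQTL
root constraints, and key driver analysis — plus a synthetic cohort
generator with planted ground truth so every stage can be validated without
access to patient data.

## The problem

Insulin resistance (IR) is polygenic; single-gene differential expression
rarely exposes the regulators that matter. A network strategy works instead
from a cohort of induced pluripotent stem cell (iPSC) lines — several
clones per donor, donors dichotomized into insulin-resistant and
insulin-sensitive (IS) by steady-state plasma glucose (SSPG ≥ 140 mg/dl) —
and asks which *key driver* genes sit causally upstream of the expression
programs that differ between the groups.

The pipeline implemented here:

1. **normalize** — filter genes below 1 CPM in 30% of samples, TMM
   library-size normalization, log2-CPM, then per-gene removal of technical
   covariates (sequencing batch, RNA kit — ridge-shrunken random effects)
   and biological covariates (reprogramming source cell, sex, ethnicity,
   age, BMI — fixed effects). Residuals are produced per sample (**AS**,
   all-samples) and averaged per donor (**ApP**, average-per-patient).
2. **de** — moderated-t differential expression (empirical-Bayes variance
   shrinkage) IR vs IS in both streams, with a rank-concordance comparison
   of the two.
3. **coexpress** — four weighted co-expression networks ({AS, ApP} ×
   {IR, IS}): soft threshold by the scale-free criterion
   (a_ij = |cor|^power), topological overlap

       TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

   average-linkage clustering with an adaptive static cut, a 10-permutation
   background for pairwise correlations, and hypergeometric module
   selection against metabolic gene sets (FDR < 0.05).
4. **expand** — pathFinder: breadth-first expansion of the selected module
   genes through a prior interaction network (k ≤ 3 steps), DE genes
   unioned in.
5. **causalnet** — Bayesian-network structure learning over the seed genes:
   greedy hill climbing maximizing a BIC score whose families include each
   parent's squared response (so nonlinear perturb–response relations make
   causal direction score-visible), candidate edges restricted to
   prior-adjacent or same-module pairs, cis-eQTL genes constrained to be
   roots (no parents), and an additive-noise orientation pass for
   score-equivalent edges.
6. **kda** — key driver analysis: for every candidate node and step size
   h = 1..6, a one-sided Fisher exact test of its downstream neighborhood's
   enrichment for the target list (module genes, DE genes), BH-corrected;
   appearance counting across the four networks; the two ranking scores

   * DE proximity  = Σ over reachable DE genes of 1/d(kd, gene),
   * KD dominance = Σ_downstream 1/d(kd, other KD) − Σ_upstream 1/d(other KD, kd),

   with shortest directed path lengths d.
7. **validate** — in-silico inhibition of a driver: per-layer %DE,
   mean |log2FC| and −log10 FDR decay with directed distance from the
   target, plus downstream Fisher enrichment and DE-list overlap partitions.

The **synth** module generates the whole study in silico: ~100 donors × ~3
clones, negative-binomial counts, planted covariate effects, five
co-expression modules each organised around a hub regulator with a layered
downstream tree, cis-eQTL anchors on the hubs, an IR-group effect placed
only on hub-downstream genes, and a perturbation experiment whose effect
attenuates geometrically with network layer.

## Worked example

```bash
irnet demo --seed 1
```

simulates a compact cohort (40 donors × 3 clones, 600 genes, 5 planted key
drivers), runs the full pipeline and prints:

```
planted key drivers:   G00025, G00035, G00144, G00328, G00410
recovered key drivers: G00025, G00035, G00144, G00235, G00328, G00410
recall=1.00 precision=0.83
```

All five planted hub regulators are recovered (recall 1.0); one extra
candidate survived the prioritization filter (precision 0.83). With
`--outdir` the demo also writes residual matrices, DE tables, learned
networks, KDA tables, the ranked key-driver score table and a JSON manifest
whose content is byte-identical across reruns with the same seed.

Individual stages run standalone on plain-text inputs (`irnet simulate`,
`normalize`, `de`, `coexpress`, `expand`, `learn-network`, `kda`,
`validate`), and `irnet run-all --config pipeline.yaml` drives the whole
flow from a YAML config.

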