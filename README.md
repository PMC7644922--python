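# dppn

Condition-specific prediction of protein subcellular locations — and of
disease-associated **mis-localization** — from diffusion kernels on
dynamically rewired protein–protein interaction (PPI) networks.

Proteins must be sorted to the right subcellular compartment to function, and
mis-sorted proteins are implicated in many cancers. Experimental localization
maps are expensive to build per condition, so `dppn` infers them
computationally: it combines a physical interaction network (whose local
density carries co-localization signal) with per-condition gene co-expression
(which carries the *difference* between disease and healthy cells), and asks,
for every protein, which compartments gain or lose it in disease.

## The model

For each condition θ ∈ {θ₀ control, θ₁ case}:

1. **Weighted network.** Each interaction {u, v} is weighted by
   a_{u,v} = ρ_{u,v}·η_{u,v}, the product of the Pearson correlation ρ of the
   two genes' expression in that condition and the edge clustering coefficient
   η_{u,v} = z_{u,v} / min(d_u−1, d_v−1) (triangles through the edge over the
   maximum possible; 0 when the denominator degrades to zero).
2. **Diffusion kernel.** K(τ) = exp(−τL) with L = D − A, D the diagonal of
   weighted degrees. K is symmetric positive definite and row-stochastic, a
   similarity that integrates all paths between proteins.
3. **Multi-label → single-label.** A protein with κ annotated locations is
   split into κ *virtual locative proteins* that inherit its edges and
   expression but never interact with each other.
4. **SVM scores.** A multi-class SVM on the precomputed kernel (one-vs-one
   with pairwise-coupled probability estimates) yields per-location
   probabilities p_{u,k} summing to 1; these are min–max rescaled per
   location across proteins (p̂) and renormalized per protein into adjusted
   scores q_{u,k}. The called location set is every k with
   q_{u,k} ≥ max_k q_u − α(max_k q_u − min_k q_u).

The **disease network** is not assumed identical to the control one: with
h_{u,v} = ρ_{u,v}(θ₁) − ρ_{u,v}(θ₀) over *all* measured pairs, and thresholds
t± = h̄ ± 3σ, interactions with h < t₋ are removed and non-interacting pairs
with h > t₊ become edges. Scores from the two conditions are compared through
the mis-localization score

φ_{u,k} = (q_{u,k}(θ₁) − q_{u,k}(θ₀)) / q_{u,k}(θ₀),

and proteins are ranked by sup_k φ_u (descending: "moves to") and
inf_k φ_u (ascending: "moves from"); the top 0.1% of each list are the
candidate mis-localized proteins. Defaults τ = 1.1, α = 0.3 are the
grid-search calibrated values.

## Worked example

Everything is runnable from the built-in synthetic benchmark, which plants
proteins whose co-expression partners switch compartments between
conditions:

```python
from dppn import (SyntheticConfig, generate, run_pipeline, RunConfig,
                  ground_truth_recovery)

inst = generate(SyntheticConfig(seed=7))          # 300 proteins, 4 locations
res = run_pipeline(inst.network, inst.annotations,
                   inst.expression0, inst.expression1, RunConfig(seed=7))
m = res.manifest
print(f"control network: {m['n_proteins']} proteins, {m['n_edges_theta0']} interactions")
print(f"rewiring: {m['edges_added']} interactions gained, {m['edges_removed']} lost in disease")
for r in res.report.moves_to[:3]:
    pct = "+Inf" if r.phi == float("inf") else f"{100*r.phi:+.2f}%"
    print(f"  {r.rank}. {r.protein}  +{r.location} ({pct})")
print("recall:", ground_truth_recovery(res.report, inst.planted).recall)
```

prints

```
control network: 300 proteins, 3428 interactions
rewiring: 451 interactions gained, 86 lost in disease
  1. P0138  +Golgi apparatus (+Inf)
  2. P0050  +Cell cortex (+Inf)
  3. P0021  +Cytosol (+Inf)
recall: 0.5
```

P0138 is one of the ten planted mis-localizations: its control-condition
Golgi score is 0, so gaining the compartment in disease gives φ = +Inf, rank
1\. Five of the ten planted proteins appear in the top-10 lists for this
seed (the mean over ten seeds is ≈0.7).

The same pipeline runs from files via the CLI — `dppn simulate`, `dppn run`,
and stage-by-stage subcommands (`filter`, `annotate`, `expand`, `coexpress`,
`rewire`, `kernel`, `predict`, `mislocalize`, `evaluate`, `calibrate`). See
`dppn --help`.

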