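# famturnover

Gene families grow and shrink by gene duplication (birth, rate β per gene
copy) and gene loss (death, rate δ), modelled as a linear birth–death
process running along the branches of a dated species tree.  Estimating
(β, δ) sounds routine, but the standard methods — ancestral-count parsimony,
full maximum likelihood on gene counts, and gene-tree/species-tree
reconciliation — can disagree severely, and a single lineage with its own
turnover regime (the *Drosophila sechellia* situation in the chemosensory
gene families) can bias global estimates badly.  `famturnover` implements
the whole toolkit plus an exact stochastic simulator so the estimators can
be benchmarked against known truth, for people studying multigene-family
evolution who need to know *which* estimate to trust.

## What's inside

* **Simulator** — exact event-by-event gene birth–death simulation of
  independent orthologous groups (OGs) on a dated tree, with per-branch-class
  rates; count tables, true per-branch event counts, and optionally the
  realized gene tree (duplication nodes, pruned extinct lineages).
* **Estimators**
  * `CSP` / `CWP`: Sankoff / Wagner parsimony ancestral family sizes →
    per-branch gains and losses → global ratio-of-sums rates
    β̂ = ΣG_i / ΣC_i·T_i;
  * `CWP-Av` and branch-average rates: β̂ = mean_i G_i/(C_i·T_i);
  * `CML`: maximum-likelihood (posterior-mode) ancestral counts under
    fitted rates, same event equations;
  * `BD-GR-ML` / `L-GR-ML`: full pruning likelihood of the counts (exact
    linear-BD transition kernel), global or branch-class rates, the L
    variant constraining β = δ = λ;
  * GT–ST reconciliation: LCA mapping of gene trees, duplication/loss
    inference, optional conservative curation rules.
* **Model selection** — branch models (global; internal/terminal; focal
  ecological lineages such as the sechellia model `Msec`), AIC ranking and
  nested LRTs.
* **Experiments** — the simulation studies comparing all of the above:
  estimator accuracy under homogeneous rates (Exp. 1, with a gene-tree
  variant), bias from ignored rate heterogeneity (Exp. 2.1), and the power
  of the LRT to detect a foreground lineage's distinctive rates (Exp. 2.2),
  on the packaged 11-species *Drosophila* chronogram.

See `docs/methods.md` for the model, the estimator definitions, numerical
choices, and what the simulations do and do not establish.

## Worked example

Simulate 50 OGs under a sechellia-specific death-rate excess and test for it:

```python
from famturnover import (
    BDParams, BranchModel, ExperimentConfig, fit, label_branches, lrt,
    fixture_drosophila_tree, simulate_counts,
)

tree = fixture_drosophila_tree()            # 11 species, root at 62.9 Mya
labels = label_branches(tree, "Msec")       # internal / sechellia / rest
params = BDParams({
    "internal":   (0.01, 0.01),
    "background": (0.02, 0.02),
    "foreground": (0.02, 0.2),              # sechellia loses genes 10x faster
})
counts, true_events = simulate_counts(tree, labels, params, n_og=50, rng=1)

null = fit(counts, tree, BranchModel.named(tree, "Mterm"), mode="totals", rng=0)
alt  = fit(counts, tree, BranchModel.named(tree, "Msec"),  mode="totals", rng=0)
fg_b, fg_d = alt.rate("foreground")
bg_b, bg_d = alt.rate("background")
print(f"foreground: beta = {fg_b:.4f}, delta = {fg_d:.4f}")
print(f"background: beta = {bg_b:.4f}, delta = {bg_d:.4f}")
print(f"LRT p-value = {lrt(null, alt):.4f}")
```

prints

```
foreground: beta = 0.0000, delta = 0.1448
background: beta = 0.0223, delta = 0.0206
LRT p-value = 0.0005
```

— the background rates land on their simulated value 0.02; the foreground
fit detects the strong excess loss (δ̂ = 0.14 against a simulated 0.2 — on
a single 2.3-Myr terminal branch β and δ are only weakly separable, so the
totals likelihood attributes the net contraction to δ and pushes β̂ to the
boundary); and the likelihood-ratio test (df = 2) flags the heterogeneity.

The experiment drivers wrap this per-replicate logic, e.g.

```bash
famturnover exp2.2 --scenario sBRhigh10 --reps 200 --seed 1 --out scratch/power
famturnover exp1 --scenario exp1_low --reps 500 --seed 1 --out scratch/exp1
```

write per-replicate TSVs plus a JSON summary (power, median estimates among
significant replicates, accuracy summaries per method).

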