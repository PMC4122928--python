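# Methods

## The model

Gene families evolve on a dated, rooted, ultrametric species tree by a
linear (per-copy) birth–death process: along a branch of duration *T* (Myr),
each extant gene copy independently duplicates with hazard β and is lost
with hazard δ (events per gene per Myr).  Zero copies is absorbing — all new
genes arise by duplication, never by de-novo innovation.  The unit of
evolution is the orthologous group (OG): every OG starts with one copy at
the root and evolves independently of all other OGs.  Branches are grouped
into *rate classes* by a branch model (all branches; internal vs. terminal;
internal / one focal terminal / remaining terminals; etc.), and each class
carries its own (β, δ).

For a branch of duration *t* the transition probability from *i* to *j*
copies has the classical closed form.  With

    α = δ(e^{(β−δ)t} − 1) / (βe^{(β−δ)t} − δ),   η = (β/δ)α

(α = η = βt/(1+βt) when β = δ), each initial copy leaves 0 descendants with
probability α and k ≥ 1 descendants with probability (1−α)(1−η)η^{k−1};
P(j|i) is the i-fold convolution.  We evaluate it either as the explicit
log-space sum over the number of surviving initial copies
(`transition_prob`) or, for whole transition matrices, by iterated
convolution of the single-lineage distribution, which the geometric tail
reduces to an O(N) recurrence per row.  Both are exact for the retained
states: truncating the state space at `n_max` does not perturb entries, it
only removes the probability of exceeding `n_max`.  Numerically, α and η are
computed via `expm1`, which keeps them (and hence derivative estimates used
by the optimizer) smooth through β ≈ δ; without this the cancellation in
e^{(β−δ)t} − 1 injects ~1e−7 noise exactly where equal-rates fits start.

## Estimators

* **CSP / CWP** — ancestral family sizes per OG by Sankoff parsimony
  (states 0..n_max, cost |a−b| per branch) or Wagner parsimony (Farris
  intervals on the ordered integer character; provably the same optimal
  cost).  Per-branch gains/losses are the one-signed count differences
  G_i = max(0, n_child − n_parent), L_i = max(0, n_parent − n_child); a gain
  and a loss on the same branch are invisible by construction — that is the
  method's definition, not a defect, and it drives the documented
  underestimation at high rates.
* **CML** — ancestral counts assigned at the mode of the marginal posterior
  (inside–outside over the truncated state space, point-mass root prior),
  under rates fitted by maximum likelihood; events derived the same way.
* **Global (ratio-of-sums) rates** — β̂ = Σ_i G_i / Σ_i C_i·T_i with C_i the
  copy number at the branch's ancestral node (summed over OGs), and the
  analogous δ̂.  The exact algebraic form of the originally cited global
  equations is not reprinted in the source describing them; the
  ratio-of-sums form is adopted as the natural counterpart of the
  branch-average equations and is the package's committed definition.
* **Branch-average rates** — β̂ = (1/n) Σ_i G_i/(C_i·T_i), excluding branches
  with C_i = 0 (no gene at risk; n shrinks accordingly).
* **BD-GR-ML / L-GR-ML** — full pruning likelihood of the counts under the
  branch model, maximized over log-rates; the L variant constrains
  β = δ = λ per class.  Input granularity is explicit: `per_og` mode sums
  independent per-OG likelihoods (root count 1 each); `totals` mode
  evaluates the per-species totals with root count equal to the number of
  OGs (the additivity of independent linear birth–death processes makes the
  totals of m root-1 families exactly a root-m family).  The totals carry
  strictly less information than the OG-resolved table; the global-rate ML
  methods are defined on totals and are treated that way here.
* **GT-ST reconciliation** — LCA mapping of a gene tree into the species
  tree; a node is a duplication iff it maps to the same species node as one
  of its children; losses are charged to the stem branch of each bypassed
  sister clade (the parsimony placement).  Because every OG is assumed
  present at the root, a gene-tree root mapping below the species root
  implies stem losses along the root path.  Losses of fully extinct
  sub-lineages are invisible to reconciliation by construction; this is the
  mechanism behind the 1.5–2× underestimation of high turnover rates and is
  deliberately left uncorrected.  Optional conservative curation rules
  (species-congruent regraft of single misplaced copies of unstable taxa;
  tip placement of scattered same-species copies) approximate manual
  curation of real gene trees; they are OFF for simulated trees, which are
  exact.

## Root prior

The likelihood conditions on the known root copy number (point mass): 1 per
OG in `per_og` mode, the number of OGs in `totals` mode.  This matches the
generative process of the simulation experiments.  A uniform root prior
would be the natural alternative for empirical data where the root state is
unknown; the point mass is the package default because every experiment
here controls the root state by design.

## Model selection and the heterogeneity LRT

Branch models are compared by AIC (2k − 2lnL) and nested pairs by the
likelihood-ratio test, 2(lnL_alt − lnL_null) (clamped at 0) against χ² with
df = Δk.  For the rate-heterogeneity power experiment the alternative is
the 6-parameter foreground model (internal / foreground terminal / other
terminals).  The null is configurable:

* `Mterm` (default): internal and terminal branches have separate rates
  (4 parameters, df = 2).  The internal-branch rates are nuisance
  parameters, so the test is specific to the foreground species.  This is
  the only reading under which the test has small size when the foreground
  terminal matches the other terminals, because the simulated scenarios
  deliberately give internal branches rates different from the terminals.
* `MGr`: all branches equal (2 parameters, df = 4).  Under the simulated
  scenarios this null is false even without any foreground effect, and the
  LRT then mostly detects the internal-vs-terminal difference (power near
  100% regardless of the foreground), which is not the question the
  experiment asks.  It is retained as a switch for homogeneous-background
  designs.

## Optimization

Rates are optimized on the log scale with L-BFGS-B, bounded to
[1e−8, 3] events/gene/Myr — the lower bound keeps gradients alive near the
β = 0 / δ = 0 boundary.  Multi-restart protocol: the first start is either
mid-range (0.01) or a caller-supplied warm start (the experiments warm-start
the 6-parameter model from the nested null's optimum), the rest are random
log-uniform draws; the best log-likelihood's *multiplicity* (restarts
reproducing it within 1e−4) is reported and convergence declared at ≥ 30%
of restarts.  An optional early-stop rule ends the restart loop once the
best optimum has been reproduced (`min_agreeing=2` in the experiments) —
the "clearly over-represented optimum" criterion.  The experiments default
to 3 restarts with this rule (the replicate-heavy LRT power runs use 2,
both warm-started: the null from Wagner-parsimony moment rates, the
alternative from the null's optimum); `fit` alone defaults to 10.  Impossible or
astronomically unlikely parameter regions return a finite penalty (−1e12)
rather than −inf/−1e300, which keeps the line search numerically sane.

State truncation: n_max = max(2 × max observed count, 10), enlarged to
cover the root count, with adaptive doubling (up to 256) whenever the
truncated space loses more than 1e−6 of transition mass for reachable
states at the current optimum.

## The synthetic-data generator

Simulation is exact and event-by-event (exponential waiting times per
lineage), not a draw from the analytic kernel, so the realized births and
deaths per branch — and in gene-tree mode the realized topology with
duplication nodes and pruned extinct lineages — are available as ground
truth.  The generator's defaults are the study conditions: 50 OGs per
family, one copy at the root, 500 replicates (scaled-down runs state their
sizes below), uniform rates 0.002 (low) or 0.02 (high) for the homogeneous
experiment, and the four heterogeneity scenarios

| scenario  | internal β=δ | background β=δ | foreground β | foreground δ |
|-----------|--------------|----------------|--------------|--------------|
| sBRlow5   | 0.01         | 0.002          | 0.002        | 0.01         |
| sBRlow10  | 0.01         | 0.002          | 0.002        | 0.02         |
| sBRhigh5  | 0.01         | 0.02           | 0.02         | 0.1          |
| sBRhigh10 | 0.01         | 0.02           | 0.02         | 0.2          |

with the foreground on the *D. sechellia* terminal branch.  Randomness
derives from one master seed through `SeedSequence(master, spawn_key=…)`
per replicate and OG, so any replicate is re-runnable in isolation and
results are independent of any parallelism.

What the generator emulates — and what it does not: independent OGs, known
root state, exact gene trees, and no annotation error.  Real data add OG
delimitation error, gene-tree reconstruction error (the curation rules
exist for that), pseudogene annotation (handled as a separate counting
mode: each annotated pseudogene is a death on its terminal branch, plus the
birth of the duplicate that later pseudogenized unless the species kept no
functional copy while others did), gene conversion, and assembly artifacts.
Passing tests therefore validate the estimators under the model's own
assumptions, not robustness to these empirical complications.

## Fixture tree

The 11-species *Drosophila* tree (melanogaster, simulans, sechellia,
yakuba, erecta, ananassae, pseudoobscura, willistoni, mojavensis, virilis,
grimshawi) ships as data with node ages transcribed from the standard
chronogram for the group: root 62.9 Mya, Sophophora crown 62.2,
pseudoobscura split 54.9, ananassae split 44.2, melanogaster group 12.8,
yakuba–erecta 10.4, melanogaster–(simulans,sechellia) 5.4,
simulans–sechellia 2.3, Drosophila-subgenus crown 36.6, mojavensis–virilis
32.1.  Divergence dates are data, not code; the source chronogram does not
print every node age to this precision and published estimates vary by a
few Myr, which shifts absolute LRT power values mildly (the
simulans–sechellia split duration scales the foreground signal linearly).

## Problem sizes used by the shipped runs

The full-size experiment is 500 replicates; the acceptance script and the
power-related tests run 200 replicates per scenario (binomial SE ≈ 1.5–3.5
percentage points depending on the true power) with 2 warm-started
restarts per fit, the
Exp. 1 accuracy summaries 500 replicates, the Exp. 2.1 distortion
comparison 100 replicates per scenario, and the gene-tree reconciliation
experiment 10 families of 50 OGs — the same family count the original
design used for its (manual) reconciliation arm.  These sizes are the
package's chosen compromise between Monte-Carlo error and a laptop-friendly
run; pass `--reps` / `ExperimentConfig.replicates` for full-size runs.

## Known limitations

* Innovation (de-novo gain), whole-cluster events, and gene conversion are
  out of scope; pseudogene columns are consumed, never simulated.
* Count-difference event derivation cannot see a gain and a loss on the
  same branch; reconciliation cannot see fully extinct sub-lineages.  Both
  are properties of the methods being studied, reproduced faithfully.
* The curation rules are a declared algorithmic approximation of
  case-by-case manual curation; anything beyond the two implemented filters
  is out of scope.
* The empirical chemosensory count tables are not distributed here; the
  empirical mode (arbitrary CountTable → branch-model AIC table) is
  exercised on synthetic data only.
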