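# Methods

## Model

Two binary traits are modelled jointly as a continuous-time Markov chain
on the four ordered pairs (0,0), (0,1), (1,0), (1,1), indexed 0–3 with
state = 2·trait1 + trait2. Instantaneous double transitions are
structurally impossible, leaving eight single-step rates
q01, q02, q10, q13, q20, q23, q31, q32 (named q⟨from⟩⟨to⟩). The
**dependent** model frees all eight; the **independent** model imposes the
four equalities q02=q13, q20=q31, q01=q23, q10=q32 (each trait's rates
ignore the other trait's state), which makes its generator the Kronecker
sum of the two single-trait 2×2 generators — an identity the tests verify
both algebraically and through the likelihood factorisation
lnL₄(pair) = lnL₂(trait1) + lnL₂(trait2).

**Restricted models** add exactly one equality to the dependent model
(7 free rates) and are tested against it with a 1-d.f. likelihood-ratio
test; the canonical four restrictions tie each trait's transition rate
across the two background states of the other trait. The dependent vs
independent comparison has 4 d.f. The χ² reference distribution is the
conventional choice for these tests; see Limitations for its
finite-sample behaviour.

## Likelihood

Felsenstein pruning with per-node rescaling (accumulated log-scalers), so
likelihoods are exact to machine precision on trees far larger than the
underflow limit of unscaled partials. Internal nodes are grouped by
topological level and each level is processed with vectorised matrix
products; when all branch lengths are equal a single matrix exponential
serves every branch. For heterogeneous branch lengths exp(Qt) is obtained
for all branches at once from one eigendecomposition of Q when the
eigenbasis is well conditioned (condition number < 1e8 and reconstructed
row sums within 1e-9 of 1), falling back to scaling-and-squaring
(`scipy.linalg.expm`) per unique branch length otherwise. The
eigendecomposition path is itself validated against `expm` in the tests.

Root treatments: `uniform` (default, ¼ per state), `stationary` (left
null vector of Q), `fitzjohn` (states weighted by their own root partial
likelihoods) and `fixed(state)`. The choice shifts log-likelihoods by a
bounded constant and is recorded in every report; both models in a
comparison always share the same treatment.

## Fitting

Rates are optimised in log space (bounds 1e-8 to 1e3 per unit branch
length) with L-BFGS-B, from `attempts` random starts with log₁₀-rates
uniform on [−3, 1] drawn from a seeded generator; the default 25 attempts
follows common practice for these mildly multimodal surfaces, and all
attempt log-likelihoods are retained for diagnosing multimodality.
Convergence uses a relative function tolerance of 1e-12 and at most 2000
function evaluations per attempt. If a fitted full model falls below its
nested restriction (nesting violation beyond 1e-6), the full fit is
retried with twice the attempts; the LRT statistic is clamped at zero.

## MCC trees

Clades are keyed by the frozenset of descendant tip labels; posterior
frequencies are exact counts over the post-burn-in sample. The MCC tree
is always a sampled tree maximising the **sum** of its clades' posterior
frequencies (default), with the log-product score available; ties break
to the lowest tree index. The posterior-probability limit (default 0.5)
controls which clades receive annotations on the selected tree and never
affects selection. Branch lengths of the selected tree are kept as
sampled (no height averaging); the analysis pipeline typically overrides
them with equal lengths anyway.

## Branch lengths

The pipeline default sets every branch to 1.0 ("equal" mode). Under this
transform a rate is "expected changes per branch"; the absolute value of
the equal length is absorbed by the rate scale, which is why 1.0 is
canonical. The `as-is` mode keeps the input (e.g. time-calibrated)
lengths. The rate–time confounding identity (scaling Q by c while
dividing lengths by c leaves the likelihood unchanged) is tested.

## Ancestral states and transition counts

Marginal reconstructions use the inside–outside scheme: one post-order
pass for subtree (inside) partials, one pre-order pass propagating the
outside contribution, per-node product renormalised to the "proportional
likelihoods". This equals brute-force enumeration (tested to 1e-8) and
the re-rooting construction at a single extra traversal's cost. Joint
(4-state) reconstructions can be collapsed to either trait by summing
over the other trait's states.

Transitions are counted per ordered state pair over edges, under two
rules: `argmax` (every node assigned its most probable state) and
`threshold(p)` (only nodes whose top state reaches proportional
likelihood ≥ p are assigned, p ∈ (0.5, 1]; edges with an unassigned
endpoint are skipped). The threshold rule is deliberately conservative —
a lower bound in the spirit of "at least N transitions" — and its counts
are non-increasing in p (tested).

A note on ground truth: the simulator's event log counts every realised
change, including same-edge reversals (A→B→A) that leave no trace in any
node-state assignment. Reconstruction-based counts therefore estimate the
*node-visible* change count (edges whose true endpoint states differ),
which the simulated datasets expose separately; at the default rates the
raw event count exceeds the visible count by roughly a third. Validation
compares against the visible count.

## Synthetic data

`simulate_tree` draws Yule (pure-birth) trees: lineage k waits
Exp(λk), a uniformly chosen lineage splits, and the process stops one
interval after reaching n lineages, giving ultrametric trees whose mean
root height is Σ_{k=2..n} 1/(λk) (tested against this closed form). The
simulator is hand-seeded through a single `numpy.random.Generator` so
datasets are bit-reproducible across platforms.

`simulate_traits` runs a Gillespie simulation along every branch
(exponential waiting times, competing transitions) and retains the full
event log; replaying the log reproduces the tip states exactly (tested),
and structural zeros in Q make dual transitions impossible by
construction. The master cross-validation check simulates tens of
thousands of histories on a fixed 3-tip tree and compares empirical
tip-pattern frequencies with exact pattern probabilities from the
likelihood engine.

The study-scale generator (`make_study_like_dataset`) defaults to 1582
tips — the complete-case sample size of the motivating nesting analysis —
with a dependent-model truth in which the bright→dark iris rate in
non-cavity nesters (q20 = 1.5) is ten times the baseline (0.15), matching
the inferred direction of selection away from bright eyes in open
nesters. Baseline 0.15 per unit time on a unit-birth-rate Yule tree
(height ≈ ln n ≈ 7) puts roughly one expected change per trait on a
root-to-tip path, inside the identifiability sweet spot of about 0.5–2.
Missingness is applied independently per trait and species (MCAR; iris
2%, nest 8% by default), yielding unequal per-analysis sample sizes as in
real trait compilations and matching the complete-case analysis
downstream. What this emulates — and what it does not: real data add
phylogenetic signal in sampling, non-random missingness, polymorphic and
misclassified states, and trait-dependent diversification; passing tests
on MCAR Markovian data say nothing about robustness to those.

## Validation experiment design

* **Size (type-I error):** 500 replicates of independent evolution
  (4 distinct rates, 0.08–0.16 per edge) on 100-tip unit-branch trees,
  root state drawn from the same uniform prior the models fit with, so
  the generating process lies inside the fitted null family. Rejection
  counts are compared with the exact central 95% binomial interval at
  α = 0.05.
* **Power:** both transition coefficients of trait 1 elevated ×10 in one
  background state of trait 2 (1.5 vs 0.15; the definitional form of
  dependence — a trait's coefficients differing between trait
  environments), 400-tip time trees, 50 replicates.
* **Recovery:** dependent truth with a ×3 elevation (0.45 vs 0.15) so all
  four joint states stay populated; pooled relative errors of all eight
  rates at 100/200/400 tips.

Simulation experiments fit with 2–3 optimisation attempts per model:
under these well-behaved conditions extra attempts were verified to leave
every statistic unchanged, and the reduced count keeps the full
validation affordable on one CPU.

## Known limitations

* The χ²(4) reference for the dependent-vs-independent LRT is
  anticonservative at moderate tree sizes: at 100 tips with ~1 expected
  change per trait per path the empirical size is ≈0.08 at nominal 0.05,
  with the inflation robust to more optimisation attempts and to the
  root-draw correction. This mirrors the long-standing observation that
  the test's null distribution is only asymptotically χ²; Monte-Carlo
  null calibration is the usual remedy and is straightforward with the
  simulator, but the package reports the conventional χ² p-values.
* Boundary estimates (true rates at or near zero) violate LRT regularity;
  statistics are clamped at zero and the χ² reference is used regardless,
  as is conventional.
* Polymorphic or uncertain tip states are not supported; the missing
  marker `?` drops a species from complete-case analyses.
* Hidden-rate, covarion and trait-dependent diversification models are
  out of scope.
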