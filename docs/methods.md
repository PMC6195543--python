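# Methods

## Model

A cohort is a binary matrix `D` (N samples × n genes).  Each sample is
generated by one of K latent components; component k is a Bayesian network
(G_k, θ_k) over the n mutation indicators with mixture weight τ_k.  Node X
with parents **Y** is Bernoulli(θ_Y) with a Beta(α, β) prior,
α = β = χ/2^(m+1) for m parents, so a single pseudocount mass χ controls
every prior in the model; a Dirichlet(χ) prior sits on τ.  Marginalising θ
gives the BDe score; because the score is decomposable, all search and
sampling work with per-node local scores.

The structure prior is edge-wise factorised:
log P(G) = −Σ_edges [ln κ_all + 1{edge ∉ prior network} ln κ_prior] + const.
Defaults: κ_prior = 2 (applied only when a prior network is supplied),
κ_all = 1 for inference and 16 when learning the displayed consensus
networks, where sparsity matters more than likelihood.

## EM MAP clustering

The frequency-only phase keeps all graphs empty, so each component is a
product of Bernoullis.  The updates

    τ_k = (χ + Σ_i T_ik)/(χK + N),
    θ_jk = (χ/2 + Σ_i D_ij T_ik)/(χ + Σ_i T_ik)

are posterior means.  Posterior means are the M-step *maximisers* of the
pseudocount-shifted objective

    F = Σ_i ln Σ_k τ_k P(D_i | θ_k)  +  χ Σ_k ln τ_k
        + (χ/2) Σ_jk [ln θ_jk + ln(1 − θ_jk)],

so F is monotone non-decreasing along the iteration and is what `em_fit`
records; a decrease beyond 1e-8 relative slack raises an error (bug trap).
With χ → 0 the procedure is exactly a plain Bernoulli mixture model, which
the tests verify against an independently coded reference EM.  Convergence
is declared at max |ΔT| < 1e-6 (max 1000 iterations); the exactly uniform
T is an unstable fixed point, so initial responsibilities are uniform plus
a ±1% multiplicative perturbation.  Restarts (default 240 at full scale,
24 at test scale) keep the highest objective.

## Structure-aware phase

Alternating loop: (1) per cluster, learn a MAP DAG by greedy hill climbing
(add/delete/reverse moves, skeleton-restricted, a few random restarts) on
BDe scores whose counts are weighted by the current responsibilities;
(2) with graphs fixed, iterate posterior-mean per-configuration θ̂ and the
responsibility update to convergence.  The outer loop stops when the hard
assignment repeats; since graph space is discrete the loop can orbit, and a
detected cycle is broken by letting each cluster carry the small collection
of graphs visited in the cycle, averaging their likelihoods.  Clusters
whose total responsibility drops below one sample-equivalent are dropped
with a warning.

Identical-marginals degeneracy.  When clusters share all marginal
frequencies, the converged empty-graph fit is an uninformative saddle:
responsibilities are near-uniform, each cluster's weighted data looks like
the pooled data, pooled pairs are (exactly) marginally independent, and the
weighted MAP graphs therefore never contain the discriminating edges — the
loop cannot bootstrap.  The loop therefore also restarts from frequency-EM
fits on the matrix augmented with pairwise *agreement* indicators
1{D_a = D_b} (whose frequencies are precisely the co-occurrence/exclusivity
signal, and which are marginally independent of the single-gene columns at
balanced margins, so the EM does not simply re-split on single genes).
Among all runs the final model with the lowest AIC wins; AIC rather than
raw likelihood, because an unseparated run can buy likelihood with richer
graphs (2^m parameters per node) and the comparison must charge for them.

## Structure search and sampling

* Skeleton: PC-style sweep with G² conditional-independence tests on binary
  data, α = 0.05, conditioning sets up to size 3, PC-stable neighbourhood
  snapshots; empty strata contribute neither G² nor degrees of freedom.  An
  optional score-based expansion admits a missing pair when it raises some
  node's best achievable local score (rescues edges the marginal tests
  miss).  Inside the clustering loop the complete skeleton is used for
  n ≤ 25: a skeleton estimated from pooled data can censor mixture-masked
  edges (see above), and at that size the full search is still cheap.
* MAP search: steepest-ascent hill climbing with restarts; deterministic
  given the seed, ties towards lexicographically smallest parent sets.
* Posterior sampling: Metropolis–Hastings over DAGs — toggle a uniformly
  chosen skeleton-allowed ordered pair (symmetric proposal) or, with
  probability 0.2, reverse an existing edge (edge count preserved, hence
  symmetric); invalid proposals (cycle, parent cap) reject in place.
  Burn-in 20%, thinning 10 by default.  The contract is a correct posterior
  rather than a particular sampler: on n = 4 the edge-inclusion frequencies
  match exhaustive enumeration over all 543 DAGs within 0.05 at M = 5000.
  Exact enumeration is available as a test oracle up to n = 5.

## Predictive scoring and the heterogeneity map

A profile's fit to one DAG multiplies posterior-mean probabilities
θ̂_Y = (α + a1_Y)/(α + a1_Y + β + a0_Y) over nodes (never exactly 0 or 1,
so log-likelihoods are finite); the group likelihood averages M posterior
DAGs via log-sum-exp.  Membership vectors use a uniform group prior unless
given.  The sample map computes all-pairs Jensen–Shannon divergences
(natural log; the base is a constant factor) and embeds them with classical
Torgerson MDS, top two components, per-axis sign fixed so the
largest-magnitude coordinate is positive.  The "average cluster
assignment" summary is the mean over samples of max_k P(k | D_i).

## Model selection

K: lowest AIC over a scan, ties to the smaller K.  AIC uses
p = (K − 1) + Σ_k Σ_j 2^(m_jk) free parameters (K·n for empty graphs); the
penalty form is pluggable — deliberately, as the exact penalty is the one
genuinely open design point of the procedure.  χ: each grid value
(default 0.25–8, powers of two) is clustered at its own best K; the χ whose
labelling has the highest mean NMI against the rest of the grid wins, ties
to the smallest.  NMI uses arithmetic-mean normalisation; hard assignments
are argmax responsibilities with ties to the lowest index.

## Consensus reporting

A gene pair is a consensus edge if it appears — in either orientation — in
at least half of the posterior DAGs (boundary inclusive).  Direction is
reported only when one orientation holds in ≥ 75% of the DAGs containing
the pair; DAGs in one Markov equivalence class can disagree on direction,
which is exactly the "cannot be inferred" case.  Edge sign is the sign of
the log odds ratio of the pair's 2×2 table with half-pseudocounts (a
model-based alternative comparing θ̂ across parent states is available).
Gene display ranking is connection count × mutation frequency, ties by
higher frequency then name.  The overlap between a learned union network
and a functional prior is tested by permuting the prior's gene labels;
the empirical p uses the add-one correction (1 + #{≥ observed})/(1 + n_perm).
The overlap count is highly discrete, so the p-values are conservative
(super-uniform): calibration checks must be one-sided.

## Survival evaluation

Cox proportional hazards (lifelines, Efron ties — the tie method is
configurable).  Stage keeps levels I–IV separate, with every
unclassifiable raw label pooled into a single level X; level I is the
reference.  The clustering's prognostic value is the likelihood-ratio
statistic between the models with and without the cluster indicator, both
adjusted for age, stage and cancer type, referred to χ² with
(#clusters − 1) degrees of freedom.  Exactly collinear design columns
(e.g. a cluster indicator duplicating an adjusted covariate) are dropped
with a warning rather than letting the partial likelihood go singular.
Proportional-hazards diagnostics are reported but never gate results; no
frailty terms for residual cancer-type-specific confounding are fitted.

## Synthetic data: what it emulates, what it does not

The generator plants a full ground truth — per-cluster DAGs with explicit
per-configuration θ tables, mixture weights, an imperfect prior network,
and clinical tables with exponential survival and cluster-specific log
hazard ratios.  Default test scales: a 3-component Bernoulli mixture with
N = 900, n = 20, weights (0.45, 0.35, 0.20) and five signature genes per
cluster at 0.75 vs 0.05 background; the separation is chosen so that the
Bayes-optimal classifier under the true parameters reaches ARI ≈ 0.98 —
recovery failures then indicate algorithmic faults rather than irreducible
class overlap.  The named opposing-dependence fixture has two equal
clusters, three gene pairs at P(child = parent) = 0.95 vs 0.05, and every
marginal exactly 0.5.  The strong-signal network fixture is a 10-gene DAG
with six edges and 0.1→0.9 conditional contrast.

Real mutation matrices are sparser (typical gene frequencies 1–20%), have
long-tailed frequency distributions, within-cluster heterogeneity, and
hypermutated samples; none of that is emulated.  Passing tests therefore
demonstrate correctness of the machinery and recoverability under honest
generative conditions, not expected effect sizes on cohort data.
Enumeration oracles run at n ≤ 4, clustering tests at n = 20, N = 900;
these sizes were chosen so exhaustive enumeration and repeated restarts
both stay at desk scale.

## Known limitations

* The sampler is plain structure MCMC; mixing degrades on dense skeletons
  with many near-equivalent DAGs.  The enumeration contract protects small
  n; large-n use should monitor the logged acceptance rate and score trace.
* AIC's penalty for mixtures of Bayesian networks is heuristic; the count
  is the number of free θ parameters, not an effective dimension.
* The co-mutation initialisation uses all pairs for moderate n (skeleton
  pairs otherwise); at n in the hundreds the augmented EM becomes the
  dominant cost of the structure phase.
* Survival simulation uses exponential times with independent censoring;
  time-varying effects and competing risks are out of scope.
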