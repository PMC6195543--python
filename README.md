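# mutclust

Bayesian-network modelling and mixture clustering of binary tumour mutation
profiles.

## The problem

A cohort of tumour samples is summarised as a binary matrix `D` (samples ×
genes), `D_ij = 1` iff sample *i* carries at least one non-silent mutation in
gene *j*.  Mutation *frequencies* alone miss much of the biology: genes can
be mutated together more often than chance (co-occurrence) or avoid each
other (mutual exclusivity), and such interaction patterns differ between
tumour groups.  `mutclust` models each group of samples as a Bayesian
network over the mutation indicators and clusters samples with a *mixture*
of such networks, so groups are defined by their mutational interactions and
not only by their mutation rates.  The intended users are computational
cancer-genomics groups working with MAF-derived gene-level mutation calls
and matched clinical follow-up.

## The model

Each node *X* with parent configuration **Y** (over its *m* parents) is
Bernoulli with parameter θ_Y under a conjugate Beta(α, β) prior with
α = β = χ/2^(m+1), a single pseudocount mass χ shared across the network.
Integrating the parameters out gives the decomposable BDe log marginal
likelihood

    score(X | Y) = Σ_Y ln B(α + a1_Y, β + a0_Y) − ln B(α, β),

with a1/a0 the per-configuration counts of X = 1 / X = 0.  An edge-wise
factorised structure prior penalises every edge by a global factor (16 for
the displayed consensus networks) and edges absent from a functional prior
network (e.g. STRING) by an extra factor 2.

* **Structure learning** — PC-style constraint-based skeleton (G² tests)
  optionally expanded by score-based search; greedy MAP search and
  Metropolis–Hastings posterior sampling over skeleton-restricted DAGs,
  validated against exact enumeration on small networks.
* **Predictive scoring** — posterior-mean per-configuration probabilities
  θ̂_Y = (α + a1_Y)/(α + a1_Y + β + a0_Y), model-averaged over M posterior
  DAGs; group-membership vectors P(k | D_i) ∝ P(D_i | k) P(k); pairwise
  Jensen–Shannon divergences embedded in 2D by classical MDS.
* **Clustering** — a K-component mixture: empty-graph (frequency-only)
  EM MAP phase with updates τ_k = (χ + Σ_i T_ik)/(χK + N) and
  θ_jk = (χ/2 + Σ_i D_ij T_ik)/(χ + Σ_i T_ik), then an alternating
  structure phase (learn per-cluster MAP DAGs from responsibility-weighted
  scores; re-run EM with structured likelihoods).  K by lowest AIC, χ by
  NMI stability across a grid.
* **Reporting** — consensus edges (≥ half of 100 posterior DAGs), edge
  direction and co-occurrence/exclusivity sign, gene ranking by
  connections × frequency, prior-network overlap permutation test.
* **Survival** — Cox proportional hazards (lifelines, Efron ties) with age,
  stage (unclassifiable stages pooled into X) and cancer type; the cluster
  indicator is evaluated by a likelihood-ratio test.

## Worked example

```python
import numpy as np
from mutclust.synthetic_data import opposing_dependence_truth, sample_mixture
from mutclust.mixture_em import best_of_restarts, em_with_structure, hard_assignment, ari

# two clusters: every gene mutated at 50% in both, but three gene pairs
# co-occur in cluster 0 and are mutually exclusive in cluster 1
truth = opposing_dependence_truth()
mm, labels = sample_mixture(truth, 600, seed=11)

init = best_of_restarts(mm.D, K=2, chi=1.0, n_restarts=8, master_seed=2)
print("frequency-only ARI:", round(ari(hard_assignment(init[1].T), labels), 3))

model, resp = em_with_structure(mm.D, K=2, chi=1.0, seed=2, init=init)
print("structure-aware ARI:", round(ari(hard_assignment(resp.T), labels), 3))
print("cluster-0 edges:", sorted(model.graphs[0][0].edges()))
```

Output:

```
frequency-only ARI: 0.003
structure-aware ARI: 0.98
cluster-0 edges: [(0, 1), (2, 3), (4, 5)]
```

Frequency-only clustering is blind here (every marginal is exactly 0.5 in
both clusters, ARI ≈ 0), while the structure-aware mixture recovers the
planted partition and the three planted interaction edges — interactions,
not frequencies, define these clusters.

A thin CLI covers the file-based workflow: `mutclust convert` (MAF →
matrix), `mutclust cluster` (mixture clustering), `mutclust report`
(consensus-network export).

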