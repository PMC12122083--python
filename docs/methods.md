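# Methods

## The model

`hdpmix` clusters paired omics measurements — a microbiome count table
`X1` (N samples x D taxa, row sums equal the sequencing depths `J_i`) and a
metabolome table `X2` (N x D' continuous features) — with a two-level
(hierarchical) Dirichlet-process mixture:

* **Global level.** Each sample i carries an indicator `W_ik` for its global
  cluster. Global weights follow a truncated stick-breaking construction
  `Psi_k = v_k prod_{k'<k}(1 - v_k')` with `v_k ~ Beta(1, gamma)` and the
  final stick fixed at 1, so the K_max truncated weights sum to one exactly.
* **Local level.** Each global cluster k is linked, per omics layer m, to a
  local mixture component through an indicator `Z_mkt`, with layer-specific
  truncated stick weights `Pi_mt` built the same way from `Beta(1, lambda)`
  sticks. Two global clusters may share a local component in one layer while
  differing in the other; this is how information is pooled across layers.
* **Observation models.** Count vectors follow Dirichlet-multinomial (DM)
  components; metabolite features follow independent Gaussians with
  per-feature precisions.
* **Per-observation feature selection.** A binary indicator `Phi_mij` says
  whether feature j of sample i is explained by its cluster's component
  (selected) or by a single layer-wide background component (rejected). The
  selection rate of each layer has a symmetric `Beta(s0, s0)` prior.

Priors and defaults follow the hyperparameters used throughout the package:
`K_max = T_max = 10`, `gamma = lambda = 0.1`, `s0 = 0.1`, symmetric
Dirichlet(1) priors on the DM concentration vectors, and Normal-Gamma
`(m0 = 0, kappa0 = 1, a0 = 1, b0 = 1)` priors per metabolite feature. The
metabolome is z-scored per feature by default, which is why the neutral
prior location is 0.

### The count likelihood under a simplex-valued concentration

The variational posterior over a DM concentration vector is a Dirichlet,
so the concentration lives on the simplex and `sum(alpha) = 1` almost
surely. Two useful consequences:

1. The shared normalising term of the DM log-pmf,
   `lgamma(sum alpha) - lgamma(sum alpha + J_i)`, is the deterministic
   constant `-lgamma(J_i + 1)` and cancels the multinomial coefficient's
   `J_i!`. The log-likelihood then decomposes exactly feature by feature,

       log p(x_i | alpha) = sum_j [ lgamma(alpha_j + x_ij) - lgamma(alpha_j)
                                    - lgamma(x_ij + 1) ],

   which is the decomposition the per-observation selection indicators act
   on: no approximation is needed to mix selected and background terms per
   feature.
2. A unit-total-mass DM is strongly overdispersed. Its per-feature term is
   approximately `log(alpha_j) + lgamma(x_ij)` for `x_ij >= 1`, so samples
   are discriminated mostly by *which* features are present and the log
   composition under each cluster, and only weakly by exact proportions.
   This matches the behaviour of the method on sparse taxonomic tables and
   explains why the synthetic-data generator encodes cluster signal partly
   through presence shifts (see below).

### Delta-method expectations

`E_q[lgamma(alpha_j + x) - lgamma(alpha_j)]` has no closed form under a
Dirichlet posterior. The term is split as

    log(alpha_j)                     (for x >= 1)
    + lgamma(alpha_j + x) - lgamma(alpha_j + 1),

where the singular first piece has the *exact* expectation
`digamma(u_j) - digamma(U)` (u = posterior shape, U = its sum), and the
smooth remainder is expanded to second order around the posterior mean with
the exact Beta-marginal variance. The remainder's curvature involves
trigammas at arguments >= 1, so the correction is bounded; an expansion of
the unsplit function is *not* used because its curvature diverges like
`1/alpha_j^2` for rare features and produces occupancy-dependent errors of
tens of nats. The approximation is exact for `x = 0` and in the
concentrated-posterior limit, and is validated against Monte-Carlo
integration in the test suite. Gaussian expectations are exact
(Normal-Gamma conjugacy).

## Inference

Mean-field variational inference with the factorisation over `W`, sticks,
`Z`, `Phi`, component parameters and selection rates. Per-sample variables
(`W`, `Phi`) are local; everything else is global. One epoch updates, in
order: `W -> Phi -> Z -> sticks -> components & selection rates`. Global
updates form the conjugate "hat" parameters from (scaled) batch statistics
and blend them with the current values on natural-parameter coordinates:

* Dirichlet: shape vectors;
* Normal-Gamma: `(kappa, kappa*m, a, b + kappa*m^2/2)`;
* Beta sticks and selection rates: `(a, b)` pseudo-counts;
* the linkage tables `q(Z)`: log-probabilities, renormalised.

In full-batch mode the step size is 1 and the algorithm is deterministic
coordinate ascent given the seed. In minibatch mode the step size follows
`rho_t = (tau0 + t)^(-kappa)` with defaults `tau0 = 64`, `kappa = 0.6`.

One refinement applies to the count components in full-batch mode. Their
conjugate accumulation (prior plus selection-weighted counts) is a
natural-gradient *direction* for the delta-approximated bound, not an exact
coordinate maximiser — the approximated expectations weight features by
presence while the accumulation weights them by counts — and taking the
full step can lower the bound by tens of nats per sweep. The step is
therefore backtracked (halved, up to six times) until the count-component
block of the bound does not decrease; since every other update is an exact
coordinate maximiser, each full-batch epoch is then monotone in the ELBO.

**Merge moves.** Coordinate ascent on this posterior landscape reliably
gets trapped in states where one true cluster stays fragmented across
several global clusters: each fragment's DM component overfits its own
samples (mean-field underestimates parameter uncertainty, so in-sample
likelihood advantages of ~10 nats per sample dwarf the ~1-2 nat
stick-prior penalty), and no single-sample reassignment can cross the
barrier — even though the merged configuration can be thousands of nats
better. `fit` therefore interleaves ELBO-guided merge moves, a standard
device for truncated variational Dirichlet-process mixtures: when the
stopping rule first fires, candidate cluster pairs (ranked by distance
between their linkage-weighted expected log-compositions) are merged one
at a time; the shared parameters are refreshed so the absorbed component
cannot recapture its samples, the trial relaxes for two sweeps, and the
merge is kept only if the bound improves. Accepted merges restart the
ascent; the run ends when the stopping rule fires and no merge is
accepted. Comparing at a fixed point matters: away from convergence, the
trial's relaxation sweeps would bias the comparison toward merging. The
whole procedure is monotone in the ELBO, and it is the package's concrete
realisation of "the truncation level is optimised automatically".

**Selection-rate handling.** Each layer's selection rate epsilon has a
symmetric `Beta(s0, s0)` prior with `s0 = 0.1`, which is bimodal. Under
mean field its posterior tracks the mean of `Phi`, a positive feedback
that, on otherwise identical data, drives a whole layer to all-selected or
all-rejected depending on the seed — and an all-or-nothing `Phi` carries no
feature ranking. By default the log-odds entering the `Phi` updates are
therefore pinned at the prior's symmetric centre (zero); `q(epsilon)` is
still tracked for the ELBO and reporting. With the pin, the per-feature
averaged selection probabilities centre near 0.5 and rank informative
features on top. `adapt_selection_rate=True` restores the full coordinate
update.

Initialisation: k-means (k = K_max) on the concatenation of
centred-log-ratio transformed counts (pseudocount 0.5) and the z-scored
metabolome, softened to 0.9 on the assigned cluster; identity-biased
linkage; `Phi = 0.5`; one conjugate update for all components. All
randomness flows from the single seed.

Stopping: relative ELBO change `< elbo_tol` (default 1e-3), evaluated on
the full data each epoch after a burn-in of `min_iter` epochs (default 30).
The burn-in exists because the relative criterion can fire during the early
epochs while the partition is still reorganising. Non-convergence at
`max_iter` flags the result rather than raising.

Cluster count: the expected global stick weights `E[Psi_k]` are computed
from the Beta posteriors; components with weight above `prune_threshold`
(default 0.01) are counted, with a floor of one. Hard labels are row-argmax
responsibilities (ties to the lowest index), re-indexed by descending
cluster size.

## The synthetic-data generator

The generator emulates paired 16S + metabolome studies:

* A shared concentration vector with log-normal magnitudes (log-sd 2)
  scaled to total mass `dm_base_concentration = 20`. The heavy tail gives a
  steep rank-abundance curve and, at depths of 5,000-50,000 reads, about
  75-85% zero entries — typical of species-level tables. Counts are DM
  draws: a Dirichlet composition per sample, then a multinomial at a
  uniformly drawn depth.
* A fraction (`informative_fraction`, default 0.3) of taxa are informative:
  per taxon, the clusters take a random permutation of log-multipliers
  spaced `separation` (default 3.0) apart and centred at zero. Centred
  levels keep the clusters' total concentration balanced — a systematically
  more concentrated cluster would bias the presence-driven likelihood — and
  the multiplicative shifts move borderline taxa across the detection
  threshold, producing the presence signal the model detects best.
* The same fraction of metabolite features are informative, with cluster
  means spaced `0.5 * separation` standard deviations apart (same permuted
  centred-level design) and unit precisions everywhere. The halved spacing
  keeps the two layers' per-sample evidence comparable, so integrative
  fitting is meaningfully better than either single layer rather than
  being carried by one of them.
* Scenario presets: I single cluster of 500; II two balanced clusters of
  200 drawn from a 1000-sample pool; III an unbalanced 100 + 300 selection
  of the same pool design; IV two clusters of 50; V three clusters of 200
  from a 1500-sample pool. Full-scale feature dimensions default to 614
  taxa and 161 metabolites and are overridden to desk scale (D = 200,
  D' = 80) in the tests and the acceptance script.

What the generator does **not** emulate: taxonomic correlation structure
(taxa are exchangeable given the concentration vector), depth-composition
coupling, batch effects, metabolite-metabolite correlation, non-Gaussian
metabolite tails, and zero-inflation beyond what the DM itself produces.
Passing tests on these data therefore show correctness and qualitative
behaviour of the inference machinery, not performance on any particular
real study.

## Numerical choices

* All Gamma-family evaluations via `gammaln` / `digamma` / `polygamma`; no
  factorials.
* Responsibilities and probability tables floored at 1e-12 before logs;
  all mixture normalisations via log-sum-exp.
* The fixed final stick contributes `(0, -inf)` to the stick expectations;
  the `-inf` never enters a weight.
* Normal-Gamma rate parameters are clipped at 1e-12 only to absorb
  floating-point cancellation at exactly zero weight.
* Ties in hard assignment go to the lowest cluster index; ranked feature
  tables break score ties by original feature order (stable sort).

## Known limitations

* The ELBO uses the delta-approximated DM expectations throughout; the
  backtracked count-component step keeps full-batch epochs monotone but can
  freeze those components for an epoch when no damped step ascends.
* Mean-field underestimates posterior uncertainty; cluster-number recovery
  depends on the merge moves as discussed above.
* Per-observation selection is strictly more flexible than per-sample
  clustering: a single global cluster plus the background can imitate a
  two-cluster structure by letting `Phi` switch feature-wise between two
  learned components. For small sample sizes (around 50 samples per
  cluster at desk-scale dimensions) the parameter-complexity saving of
  that configuration can outweigh its poorer data fit, and the ELBO then
  genuinely prefers merging weakly separated clusters — the counterpart of
  the known tendency of unbalanced designs to absorb small clusters. The
  scenario studies use sample sizes (at least 100 per cluster) and
  separations where the clustered configuration wins.
* Selection probabilities saturate for high-count observations (their
  evidence grows with the count), so the per-feature averaged scores are
  most informative on sparse tables.
* No missing-value handling; metabolome values must be finite.
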