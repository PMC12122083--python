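# hdpmix

Integrative Bayesian nonparametric clustering of paired microbiome count and
metabolome profile data, with per-observation feature selection.

## The problem

Microbiome studies increasingly measure several omics layers on the same
samples — typically a 16S (or shotgun) count table of taxonomic units and a
continuous table of metabolite abundances. The two layers carry shared and
complementary information about how samples group (disease vs control,
treatment vs baseline, environmental condition), and most features in either
layer are irrelevant noise for that grouping. `hdpmix` addresses both needs
at once: it jointly clusters the samples using both layers, infers how many
clusters the data support, and scores every taxon and metabolite by how much
it contributes to the clustering.

## The model

Samples are assigned to *global* clusters drawn from a truncated
stick-breaking (Dirichlet-process) prior, `Psi_k = v_k prod_{k'<k}(1-v_k')`
with `v_k ~ Beta(1, gamma)`. Each global cluster is linked, per omics layer,
to a *local* mixture component through a second stick-breaking process
(`Beta(1, lambda)` sticks), so layers can share or refuse structure. Counts
follow Dirichlet-multinomial components; metabolite features follow
independent Gaussians with per-feature precision. A binary indicator
`Phi_mij` per observation switches feature j of sample i between its
cluster's component and a layer-wide background component; the per-feature
average of its posterior is the feature's importance score.

Inference is mean-field variational with natural-gradient updates of the
global parameters (stochastic variational inference when a minibatch size is
set), Taylor/delta approximations for the Dirichlet-multinomial
expectations, and ELBO-guided merge moves that let redundant clusters be
absorbed once coordinate ascent has converged. Empty clusters' mixing
weights collapse toward zero, and the number of clusters is read off the
expected stick weights. See `docs/methods.md` for the full account.

## Worked example

```sh
# generate a balanced two-cluster paired dataset (desk scale)
hdpmix simulate II --n-taxa 200 --n-metab 80 --seed 7 --out-dir sim_ii

# fit the integrative model
hdpmix fit sim_ii/counts.csv sim_ii/metabolome.csv --seed 1 --out-dir fit_ii

# compare inferred labels with the simulator's truth
hdpmix evaluate sim_ii/truth.csv fit_ii/assignments.csv --out-json eval.json
```

The fit step prints

```
n_clusters=2 converged=True epochs=32 out=fit_ii
```

meaning the mixing weights support two clusters (the other eight truncation
slots decayed below the 1% pruning threshold) and the ELBO stopping rule
fired after 31 epochs. The evaluate step prints

```
ARI=1.0000 -> eval.json
```

the adjusted Rand index between true and inferred partitions (1 = identical
up to label names). `fit_ii/ranked_taxa.csv` and
`fit_ii/ranked_metabolites.csv` list features by their averaged selection
probability; on this synthetic dataset the simulator's informative features
fill the top of both tables (recovery AUC 0.95 for taxa against the
simulator's mask). The same
steps are available in Python:

```python
import hdpmix as hm

dataset, truth = hm.simulate_scenario("II", n_taxa=200, n_metab=80, seed=7)
result = hm.fit(dataset, hm.FitConfig(seed=1))
print(result.n_clusters, hm.adjusted_rand_index(truth.labels, result.labels))
```

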