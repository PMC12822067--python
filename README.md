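# mdrsmap

Inference of **time-varying species interaction networks** from community
time series, using multiview distance regularized (MDR) S-maps, together
with the downstream analyses that turn an interaction tensor into ecology:
strong-interaction classification, keystone-taxon detection, facilitation
statistics, and temperature-conditioned comparisons.

## The scientific problem

Microbial communities are not static: who affects whom, and how strongly,
changes through the seasons. Sequencing surveys give long abundance time
series, but pairwise correlations between abundances say little about
*interactions* — two taxa can covary because they respond to the same
environment, and real effects are state-dependent and fluctuate over time.

Empirical dynamic modeling treats the community as a deterministic dynamical
system observed through its time series. The S-map recovers, at every time
point, a local linear approximation of the system map — a time-varying
Jacobian matrix whose entry (i, j) is the effect of taxon j's abundance now
on taxon i's abundance at the next step. The MDR S-map extends this to
communities with many taxa, where a single embedding is unreliable:

1. **Multiview distances.** Many low-dimensional lag embeddings ("views")
   of the community are proposed per target taxon, ranked by leave-one-out
   simplex forecast skill, and the best views' state-space distances are
   averaged into one robust distance between any two time points.
2. **Regularized local regression.** At each time point, a weighted elastic
   net regression is fitted, with weights decaying exponentially in the
   multiview distance (locality parameter θ) and penalty λ chosen by
   cross-validated forecast skill.
3. **Coefficient extraction.** The local regression coefficients at each
   time point form the row of the time-varying interaction matrix.

The package also ships a **Ricker community simulator with analytic
Jacobians**, so every claim the inference makes can be checked against a
known ground truth, and a pipeline that runs the whole chain (filter → bin →
standardize → infer → metrics → temperature analyses) reproducibly from one
YAML config and one seed.

## Worked example

Simulate an 8-taxon community with known interactions, infer the network,
and compare against the truth:

```python
import numpy as np, pandas as pd
from mdrsmap import (CommunityParams, MDRSMap, MDRConfig,
                     simulate_community, random_interaction_matrix)

rng = np.random.default_rng(0)
params = CommunityParams(
    n_taxa=8,
    A=random_interaction_matrix(8, connectance=0.15, rng=rng),
    sigma_proc=0.05,
    seed=0,
)
ds = simulate_community(params, n_steps=300, burn_in=100)
data = pd.DataFrame(ds.N, columns=ds.taxon_ids)

model = MDRSMap(
    data,
    temperature=ds.temperature,
    config=MDRConfig(e_cap=5, n_candidate_views=50, k_top=7,
                     theta_grid=(0.0, 0.5, 2.0), lambda_grid=(1e-3, 1e-2, 1e-1),
                     cv_stride=4, seed=0),
)
results = model.fit()

keystones = results.keystones(thresholds=(0.05, 0.057))
print(keystones[["interactiveness", "facilitation_pct", "n_partners",
                 "rank", "keystone"]].round(3))

vt = results.interactions.valid_time_indices
J_hat = results.interactions.taxa_values[vt].mean(axis=0)
J_true = ds.standardized_true_jacobian()[vt].mean(axis=0)
off = ~np.eye(8, dtype=bool)
print("correlation with true Jacobian:",
      round(float(np.corrcoef(J_hat[off], J_true[off])[0, 1]), 3))
```

Output:

```
           interactiveness  facilitation_pct  n_partners  rank  keystone
taxon
taxon_000            0.469            32.267           4     5     False
taxon_001            0.113           100.000           1     7     False
taxon_002            0.289             0.000           2     6     False
taxon_003            0.956            25.344           4     2     False
taxon_004            0.578           100.000           2     4     False
taxon_005            1.401            16.537           5     1      True
taxon_006            0.610           100.000           1     3     False
taxon_007            0.000               NaN           0     8     False

correlation with true Jacobian: 0.938
```

`results.summary()` prints a plain-text fit report; `results.thresholds()`
derives data-driven strong-interaction thresholds (medians of the strength
and occurrence distributions). The example above passes explicit threshold
overrides because on densely nonzero tensors (no coefficient ever exactly
zero) the median occurrence is 1.0 and the strict `occurrence > threshold`
rule classifies every pair neutral — the data-driven defaults are designed
for sparse (lasso-zeroed) tensors.

### Command line

```sh
mdrsmap run-all -c config.yaml -o outdir/    # full pipeline
mdrsmap simulate -c config.yaml -o data/     # synthetic inputs only
mdrsmap preprocess -c config.yaml -i data/abundance.tsv -o z.tsv
```

A minimal synthetic config:

```yaml
seed: 0
synthetic:
  n_taxa: 12
  n_steps: 300
  burn_in: 100
mdr:
  e_cap: 5
  k_top: 7
```

Identical config + seed give bit-identical outputs, and `manifest.json`
records the config hash for traceability.

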