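# netgimme

Person-specific directed functional-connectivity analysis for resting-state
ROI time series, with subgroup discovery, stability validation, network
density profiling, and regression linkage to clinical outcomes.

## The problem

In a cohort of nicotine-dependent adults, resting-state fMRI signals from
eleven regions of interest spanning three large-scale networks — the default
mode network (DMN, 2 ROIs), salience network (SN, 5 ROIs), and frontoparietal
network (FPN, 4 ROIs) — carry both shared and person-specific connectivity
structure. The question this package addresses: which directed connections
are common to the whole group, which define subgroups, which are unique to
individuals — and do the person-specific features predict smoking-cessation
outcomes (slips, craving during treatment, cue-induced craving)?

## The model

Each subject's p-variate series η_t follows a unified structural equation
model (a lag-1 structural VAR):

    η_t = A η_t + Φ η_{t−1} + ζ_t,   ζ_t ~ N(0, diag(Ψ))

where A holds contemporaneous directed paths (zero diagonal), Φ lag-1 paths
(diagonal = autoregressive paths), and an edge *source → target* means the
target's equation regresses on the source. Estimation minimises the Gaussian
ML discrepancy F = ln|Σ(θ)| + tr(S Σ(θ)⁻¹) − ln|S| − 2p on the stacked
2p-variate covariance of [η_{t−1}; η_t], with the lagged block saturated.

The staged search (in the GIMME family) starts from autoregressive-only
person models and:

1. adds paths whose modification index (1-df score test) is significant for
   ≥ 75% of subjects (group level), then prunes and re-orients;
2. clusters subjects with Walktrap on a sign-aware count similarity matrix
   and repeats the search within subgroups (≥ 50% majority);
3. adds person-specific paths until the model reaches excellent fit on two
   of four indices (CFI ≥ .95, NNFI ≥ .95, RMSEA ≤ .05, SRMR ≤ .05).

The subgrouping is validated by edge-rewiring perturbation: the solution is
stable if ≥ 20% of edges must be rewired before the partition is as
different (variation of information) as randomly reassigning 20% of
subjects. Each final graph is reduced to 12 sign-split within/between-network
densities, which are linked to outcomes by negative-binomial (slips) and
log-scale OLS (craving) regressions with Bonferroni correction across the six
primary models (threshold 0.05/6 = 0.008).

## Worked example

```python
import numpy as np
from netgimme import GIMME, default_atlas
from netgimme.simulate import SimulationParams, make_true_structure, simulate_cohort

params = SimulationParams(n_subjects=12, T=300, seed=3,
                          subgroup_sizes=(8, 4), subgroup_n_paths=(3, 5),
                          individual_rate=1.0)
truth = make_true_structure(default_atlas(), params)
cohort = simulate_cohort(truth, params)

model = GIMME().fit(cohort)
print("group paths:", len(model.group_paths_))
print("subgroup sizes:", np.bincount(model.subgroup_labels_)[1:])
print("mean fit:", {k: round(v, 3) for k, v in model.mean_fit_.items()})
```

Output from this exact run:

```
group paths: 13
subgroup sizes: [8 4]
mean fit: {'CFI': 0.994, 'NNFI': 0.991, 'RMSEA': 0.02, 'SRMR': 0.032}
```

Thirteen directed paths pass the 75% majority — twelve of the thirteen
planted group paths (10 contemporaneous + 3 lagged; the 11 autoregressive
paths are free from the start and not counted); one weak lagged path is
missed and a spurious contemporaneous path absorbs its signal, the typical
failure mode at this sample size. The two planted blocks of 8 and
4 subjects are recovered exactly, and the cohort-average fit indices show
every person-specific model fitting well.
A command-line interface wraps the same stages:
`netgimme simulate|fit|validate|density|regress|run`, each taking
`--config <yaml> --seed <int> --out <dir>`.

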