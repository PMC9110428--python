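# faultmem

Bayesian estimation of visual change-detection performance over a circular
stimulus space, using an intrinsic Gaussian Markov random field (GMRF)
prior on a torus lattice.

## The problem

In a change-detection experiment an observer sees a *memory* stimulus, a
blank retention interval, and a *probe*, and reports whether they differ.
Here every stimulus is a geologic-fault scene described by one circular
parameter, its **rake angle** (0–360°, anticlockwise from horizontal), so
each trial lands on a memory × probe grid that wraps on both axes — a
torus.  At full scale the grid has 180 angles (2° steps) and 32,400
memory–probe combinations, of which an experiment can sample only a few
percent, mostly once.  The estimation target is the probability of a
"change" report at *every* combination, which is what lets one examine
category-boundary effects, mirror-image confusions, and the oblique
effect in visual working memory.

The package is aimed at psychophysicists and cognitive scientists with
sparsely sampled, binary-response designs over a structured (here,
circular × circular) stimulus space.

## The model

For node (x, y) with `n_xy` presentations and `k_xy` "change" reports:

    k_xy ~ Binomial(n_xy, θ_xy),      θ_xy = logistic(φ_xy)

with an intrinsic GMRF prior on the latent field — independent
Normal(0, σ) increments on each 4-neighbour edge `i ~ j` of the torus:

    log p(Φ) = − 1/(2σ²) · Σ_{i~j} (φ_i − φ_j)²  + const,   σ = 2.

Smoothing shares statistical strength between similar memory–probe pairs
and interpolates to unobserved combinations.  Inference is Hamiltonian
Monte Carlo preconditioned by a Laplace approximation at the posterior
mode (the posterior is strictly log-concave), validated against 1-D
quadrature oracles in the decoupled (σ→∞) and pooled (σ→0) limits.
Summaries — posterior mean surfaces, condition-difference maps,
category-boundary ("critical trial") aggregates, and marginal sensitivity
curves — carry 95% highest-density credible intervals (HDCIs).

A synthetic study generator reproduces the design (three training
conditions, ~100 participants each, 50 trials per participant, half
change trials) over a known ground-truth surface, so the full pipeline —
exclusions → aggregation → fit → summaries — is testable end to end and
parameter recovery is measurable.  See `docs/methods.md` for the complete
account.

## Worked example

```python
from faultmem import (ChangeDetectionGMRF, EffectConfig, GMRFSpec,
                      SamplerConfig, StudyDesign, aggregate_counts,
                      apply_exclusions, simulate_study)
from faultmem.geometry import BoundaryType

design = StudyDesign(participants={"control": 40, "train_left_right": 40},
                     lattice_L=18)                      # 20-degree grid
trials, truth = simulate_study(EffectConfig(), design, seed=7)

fits = {}
for condition, df in trials.items():
    kept, report = apply_exclusions(df)                 # study exclusion rules
    counts = aggregate_counts(kept, design.lattice)
    model = ChangeDetectionGMRF(counts, GMRFSpec(sigma=2.0),
                                condition=condition)
    fits[condition] = model.fit(SamplerConfig(chains=4, warmup_iters=800,
                                              samples_per_chain=400, seed=7))

print(fits["train_left_right"].summary().to_string(index=False))

diff, lo, hi = fits["train_left_right"].critical_trial_difference(
    fits["control"], BoundaryType.LEFT_RIGHT)
print(f"trained - control, left/right critical trials: "
      f"{diff:.3f} (95% HDCI {lo:.3f}, {hi:.3f})")
```

Output:

```
                       quantity                            value
                      condition                 train_left_right
                        lattice         18x18 torus, 20 deg step
                          sigma                              2.0
                         trials                             1728
                 observed nodes                              305
               chains x samples                          4 x 400
                 max split-Rhat                           1.0063
                        min ESS                            913.7
       converged (Rhat <= 1.01)                             True
mean theta (no-change diagonal)                           0.1208
     mean theta (change trials)                           0.7663
     critical mean [left_right] 0.9197 (95% HDCI 0.9000, 0.9398)
 critical mean [normal_reverse] 0.8730 (95% HDCI 0.8463, 0.9029)
trained - control, left/right critical trials: 0.150 (95% HDCI 0.121, 0.184)
```

Reading it: false alarms on no-change (diagonal) trials sit near the
generating 0.10; change trials are detected ~77% of the time overall; and
for observers trained on the left/right-lateral distinction, changes that
cross that category boundary are detected 15 percentage points more often
than in the untrained control group, with a 95% HDCI excluding zero.

The same pipeline is scriptable from a shell (`faultmem simulate`,
`preprocess`, `fit`, `summarize`, `report`); every stage takes an explicit
seed and a YAML config, and `summarize` emits tidy CSV tables (surface,
difference map, critical-trial means, marginal sensitivity curves).

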