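# Methods

## The problem

In a visual change-detection task, an observer sees a memory stimulus, a
blank retention interval, and a probe stimulus, and reports whether the two
differ.  Here each stimulus is a geologic-fault scene characterised by a
single circular parameter, the rake angle (degrees anticlockwise from the
horizontal, 0–360), so a trial is a point on a memory × probe grid that
wraps around on both axes — a torus.  With 180 grid angles there are 32,400
memory–probe combinations, and a realistic experiment samples only a few
percent of them.  The analysis problem is to estimate the probability of a
"change" report at *every* combination from sparse counts.

## Model

Let `n_xy` be the number of presentations of combination (x, y) and `k_xy`
the number of "change" reports.  The model places one latent value `phi_xy`
per node and assumes

    k_xy ~ Binomial(n_xy, theta_xy),     theta_xy = 1 / (1 + exp(-phi_xy))

with an intrinsic Gaussian Markov random field prior on the field:
independent Normal(0, sigma) increments on every 4-neighbour edge of the
torus lattice,

    log p(Phi) = - (1 / 2 sigma^2) * sum_{i~j} (phi_i - phi_j)^2 + const,

each undirected edge counted once.  The prior is translation-invariant
(improper along the constant direction); the likelihood identifies the
level as soon as one node is observed, and the lattice's connectivity then
makes the posterior proper and strictly log-concave.  `sigma` is fixed at 2
logit units, tied to the once-per-edge counting convention; estimating it
from data is out of scope.  The precision operator is `(1/sigma^2)` times
the torus graph Laplacian (row sums zero, rank deficiency one), which is
also the quantity that makes all gradients sparse and cheap.

## Stimulus-space geometry

Fault categories tile the rake-angle circle in overlapping half-circles:
reverse on (0°, 180°), normal on (180°, 360°), left-lateral on
(270°, 360°) ∪ [0°, 90°), right-lateral on (90°, 270°).  Membership is
decided by exact degree comparisons, not floating-point `sin`/`cos` signs,
so the cardinal prototypes 0/90/180/270 carry exactly one label (a 90°
fault has zero lateral displacement).  Consequence, deliberately exposed
rather than hidden: a stimulus at a cardinal angle never counts as crossing
the orthogonal category boundary.

Two reflections generate the mirror structure: `theta -> 180 - theta` swaps
left/right laterality and preserves dip; `theta -> 360 - theta` swaps
normal/reverse dip and preserves laterality.  Both are involutions and
their composition is the half-turn `theta -> theta + 180`.  A "critical"
trial is an off-diagonal node whose memory and probe angles carry opposite
labels of the named boundary pair.

## Exclusion rules

Four rules in order, strict inequalities throughout (a trial at exactly
2.5 s lag or 5 s response time is kept): (1) drop trials with lag > 2.5 s;
(2) drop trials with RT > 5 s; (3) drop participants with fewer than 25
remaining trials; (4) drop participants below 60% correct, where the
numerator counts correct responses among the participant's trials *as
given to the filter* and the denominator is the nominal session length
(50).  Rule 4's denominator convention means a participant with a short
session is penalised for the missing trials; it also means re-filtering
already-filtered data can, in contrived cases, remove a borderline
participant whose correct trials were eaten by rules 1–2.  The exclusion
report reconciles exactly: lag + RT + min-trials + accuracy removals +
retained = input trials.

## Sampling

The posterior is log-concave with a cheap analytic gradient, so the sampler
is plain Hamiltonian Monte Carlo, all chains advanced as one
(chains × dim) array.  Three ingredients matter:

* **Laplace preconditioning.**  Before sampling, a damped Newton iteration
  finds the posterior mode and the negative Hessian there,
  `P = Q + diag(n * theta * (1 - theta))`.  HMC runs in the whitened space
  `z = L^T (phi - mode)` with `P = L L^T` (dense Cholesky).  This is what
  makes a single step size work across smoothing regimes: with near-flat
  priors (large sigma) observed and unobserved nodes have wildly different
  scales, and with strong smoothing (small sigma) the neighbour-difference
  directions are thousands of times stiffer than the pooled level.  Above
  5000 latent dimensions the dense factor falls back to a diagonal
  `sqrt(diag(P))` preconditioner.
* **Adaptation.**  Dual averaging tunes per-chain step sizes to a 0.8
  acceptance target; warmup is split Stan-style (15% step-size-only, a long
  pooled-variance window for a diagonal mass refinement, 10% step-size
  re-adaptation).  Leapfrog path lengths are jittered uniformly in
  [max_leapfrog/2, max_leapfrog] to avoid resonances.
* **Initialisation.**  Chains start at the posterior mode plus whitened
  Gaussian jitter (scale 0.5), i.e. overdispersed around the
  empirical-logit solution.  (A raw empirical-logit start works too; the
  mode is available for free from the preconditioner.)

The full-scale protocol default is 5 chains × 2000 warmup × 500 kept
samples; validation work uses 2–4 chains and a few hundred iterations on
6×6 to 36×36 lattices, which keeps every check minutes-scale on one CPU.
Identical seeds give bit-identical draws.

Convergence is summarised by the classic split-chain potential scale
reduction (gate: max split-R̂ ≤ 1.01 across nodes) and bulk effective
sample size via arviz.  The rank-normalised R̂ variant is deliberately not
used for the gate: its folded scale component is noisy at a few hundred
draws per chain and flags well-mixed chains.  Reported ESS is capped at
chains × samples because antithetic HMC chains can push the bulk estimator
above the raw draw count.

### Validation oracles

The sampler is accepted only through independent oracles, not by
construction: with sigma = 10^3 the nodes decouple and the observed node's
posterior mean must match 1-D quadrature of the logistic-binomial
posterior (tolerance 0.02); with sigma = 10^-2 the field is forced
constant and every node must match the pooled-count quadrature; the
analytic gradient must match central finite differences to 1e-6 relative;
and under near-zero data the posterior SD of neighbour differences must
not exceed sigma (smoothing can only shrink increments).

## Posterior summaries

Probabilities are always transformed before averaging: every summary is a
functional of the `theta = logistic(phi)` draws, never the logistic of an
averaged `phi`.  The HDCI is the shortest contiguous window of the sorted
draws containing ceil(0.95 N) of them, ties resolved toward the lowest
lower bound; it reduces to brute-force window search and is checked against
it and against normal quantiles.

Condition fits are independent, so between-condition differences (surface
difference maps and critical-trial differences) pair draw streams by index
after truncation to equal length — the pairing is arbitrary by
independence, and index pairing keeps results reproducible.

Critical-trial aggregates average `theta` over the boundary-crossing,
off-diagonal node set.  The default weighting is cell-uniform — a property
of the estimated surface, stable when the raw design sparsely samples the
crossing set — with per-node trial counts available as an alternative
weighting.  Marginal sensitivity curves average the surface over one axis
per draw; the same-stimulus diagonal is included by default ("all possible
paired stimuli") and can be excluded.

## Synthetic study generator

The generator exists so the full pipeline is testable without any data
download, and so parameter recovery can be measured against known truth.
It emulates the study design: three conditions (control, train-left/right,
train-normal/reverse) with 100/118/115 participants by default, 50 trials
per participant, memory angles uniform on the grid, half change trials
with the probe uniform over the remaining angles.

The true surface is additive on the logit scale and smooth by
construction: false-alarm baseline 0.10 (the diagonal equals it exactly);
a saturating ramp in circular angular difference (0.03 logit/degree,
ceiling at probability 0.85); cosine-squared bumps of half-width 20° at
the four cardinal angles on either axis (amplitude 0.8 logit — the oblique
effect); condition-gated cosine ridges of half-width 15° where the probe
approximates the relevant mirror of the memory stimulus (amplitude 1.0
logit); and condition-gated boundary boosts.  Control observers keep a
small residual boundary sensitivity (0.2 / 0.4 logit for left-right /
normal-reverse); training raises the trained boundary's boost to 2.4 /
3.0 logit.  Those trained amplitudes look large because the probability
scale saturates near the ceiling: they are calibrated (analytically, from
the surface itself) so the trained-minus-control effect averaged over the
crossing set is at least 0.15 probability units, the regime the recovery
analysis targets.  Participant heterogeneity is a Normal(0, 0.5) logit
offset per participant.

Nuisance processes are sized to exercise every exclusion rule: 5% of
trials get 3–6 s lag spikes; 2% of participants are "laggy" (70% of their
trials contaminated, so the min-trials rule fires — isolated 5% spikes
alone can never remove 25 of 50 trials); 2% of trials get 5.5–8 s response
times; 5% of participants respond at chance (caught by the accuracy rule
most of the time — a chance responder clears 60% of 50 with probability
about 0.1, which is intended residual noise).

What the generator does *not* emulate: encoding-noise observer models,
sequential effects, learning within the session, response-time structure
tied to difficulty, and any dependence of lag on the stimulus.  Passing
recovery tests therefore shows the estimator recovers surfaces of this
smooth additive family under realistic sparsity — not that the model is
true of human observers.

## Scaled-down recovery replica

Full-scale inference (180×180, 32,400 nodes) is the deployment target, not
the validation target.  Recovery is measured on a 36×36 lattice (10° step)
with 3 × 100 participants × 50 trials, sigma = 2, 4 chains × 500 warmup ×
250 kept — sizes chosen so the complete replica, including three MCMC
fits, runs in minutes on one CPU while keeping per-cell occupancy (~1.7
trials per off-diagonal cell) comparable in sparsity to the real design.
Under these conditions the posterior-mean surface attains RMSE ≤ 0.10
against the generating truth (raw observed-cell proportions sit near
0.3), the trained-condition critical-trial aggregate exceeds control with
a 95% HDCI of the difference excluding zero, and all chains pass the
split-R̂ gate.  About 0.008 of the RMSE floor is attributable to
participant heterogeneity (the estimator targets the population-marginal
probability, which is slightly shrunk toward 0.5 relative to theta*), and
a further share to smoothing across the hard boundary-boost edges.

## Numerical choices and edge cases

* Logistic quantities go through `scipy.special.expit` / `log_expit`;
  |phi| = 745 saturates without overflow.
* Off-grid angles in trial data raise an error rather than snapping:
  silent rebinning would corrupt mirror-line diagnostics.
* `L >= 3` per axis so torus wrap-around creates no duplicate edges.
* All-zero count lattices are rejected (improper posterior), as is a
  single chain (no split-R̂).
* Empty trial sets are legal for the exclusion filter (empty output,
  all-zero report) but not for fitting.
* HDCI requires at least 20 samples; fewer is an error, not a wide
  interval.

## Known limitations

* The diagonal-preconditioner fallback above 5000 dimensions has not been
  validated against the quadrature oracles at full scale; full-scale runs
  should be checked with the R̂ gate and, ideally, longer warmup.
* The accuracy-rule denominator convention (nominal 50) makes the
  exclusion filter only empirically, not structurally, idempotent; see
  above.
* Critical-trial cell-uniform averaging weights every crossing cell
  equally regardless of how often the design sampled it; trial-weighted
  averaging is provided but shares draws with the surface estimate, so the
  two can differ materially on very sparse designs.
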