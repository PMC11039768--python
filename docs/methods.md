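# Methods

## Model and estimation

Each subject's p ROI series is modelled as a unified SEM (structural VAR
with contemporaneous effects): η_t = A η_t + Φ η_{t−1} + ζ_t with diagonal
Gaussian innovations. The convention throughout is that `A[target, source]`
(and `Phi`) holds the effect of *source on target*; lag 0 is contemporaneous
and lag 1 means t−1. Series are z-scored per ROI before fitting (the raw
scale is available via a flag); this makes coefficients comparable across
subjects and stabilises the optimisation.

The ML discrepancy F = ln|Σ(θ)| + tr(SΣ(θ)⁻¹) − ln|S| − 2p is defined on
the sample covariance S (denominator n−1) of the stacked vector
[η_{t−1}; η_t], built from the n_eff = T−1 usable pairs; the lagged block
is saturated and the innovation covariance diagonal. Because the likelihood
factorises into a marginal part for η_{t−1} (whose saturated estimate is the
sample lagged block) and a conditional part, and the optimal innovation
variances given (A, Φ) are the diagonal structural residual variances, F
concentrates to

F(A, Φ) = Σ_i ln R_ii − 2 ln|det(I − A)| + ln|S_LL| − ln|S|,  R = W S Wᵀ,
W = [−Φ, I − A].

Each R_ii involves only row i of (A, Φ); rows couple only through the
log-determinant. Gradient and Hessian are closed-form, so fitting uses a
trust-region Newton method (scipy `trust-exact`, gradient tolerance 1e−7,
max 500 iterations; convergence flagged at max-norm < 1e−5, and
non-convergence is flagged on the result rather than raised). Free
coefficients start at zero, AR paths at 0.3; searches warm-start from the
previous pattern's estimates. The concentrated minimum was verified against
a brute-force Nelder–Mead minimisation of the full stacked-covariance
discrepancy over (V, A, Φ, Ψ) to < 1e−12 on 3-ROI fixtures.

Standard errors come from the inverse of the observed profile information
(n_eff−1)/2 · ∇²F at the optimum. The model chi-square is (n_eff−1)·F with
df = p(2p+1) − [p(p+1)/2 + #free(A) + #free(Φ) + p]; the baseline for
CFI/NNFI treats all 2p variables as uncorrelated. With df = 0 the
conventions CFI = NNFI = 1, RMSEA = 0 apply. SRMR is the RMS of
correlation-metric residuals over the unique entries of the 2p × 2p matrix.
"Excellent fit" means at least two of CFI ≥ .95, NNFI ≥ .95, RMSEA ≤ .05,
SRMR ≤ .05 (boundaries inclusive). The multiplier (n_eff−1) rather than
n_eff is a fixed convention; at T = 500 the difference is negligible.

Modification indices are univariate score (Lagrange-multiplier) tests: the
gradient of the concentrated F at the sample covariance combined with the
expected information — the same analytic Hessian evaluated at the
model-implied covariance — with the free-parameter block profiled out by a
Schur complement. The expected-information form tracks the exact refit
Δχ² within ~10% for moderate single omitted effects; with several paths
omitted simultaneously, or very large misfit, the quadratic approximation
degrades (observed-information MIs were measurably worse, ~30% at
|a| = 0.4, which is why the expected form is used). The expected parameter
change is −g_c divided by the same Schur complement; its sign feeds the
similarity features. Wald tests are two-sided; the default α = 0.05 applies
to both MI counting and pruning and is configurable, as is a
Bonferroni-over-candidates mode.

## Staged search

The group stage starts from AR-only patterns (freeing all lag-1
self-paths from the start; a literal empty start is available via
`ar_start=False`) and repeatedly adds the candidate whose MI is significant
for the largest number of subjects, requiring ≥ γ_group = 0.75 of the
cohort; ties break by summed MI, then canonical (lag, target, source)
order, making the search invariant to subject order. Non-convergent
subjects are excluded from a round's numerator but stay in the denominator.
Added paths that are Wald-significant for fewer than γ_group of subjects
are pruned afterwards, worst first (AR paths protected); the same machinery
runs within subgroups at γ_sub = 0.50.

One deliberate extension of the plain greedy loop: after adding, the
orientation of each added ROI pair is re-examined by comparing the
equal-complexity direction variants (for a pair carrying one or two added
paths, 2 or 4 variants) on the cohort-summed discrepancy, sweeping until no
pair changes, and the add loop then runs once more before pruning. The
motivation is a reproducible failure mode of one-path-at-a-time search:
when a contemporaneous and a lagged path share an ROI pair, the first
(wrong-direction) addition absorbs both signals and the mirrored
parameterisation locks in, although the correctly oriented model fits
better by Δχ² ≈ 10–30 per subject at the population level. The refinement
is a pure model comparison among models of identical size and can be
disabled (`direction_refinement=False`). Under default synthetic
conditions it raises 20-replicate group-path recall from ≈ 0.89 to ≈ 0.93;
the residual misses are direction flips on weak (|a| ≈ 0.2)
contemporaneous paths, which at T = 500 sit close to the identification
limit.

Subgrouping builds a sparse count similarity matrix: per subject, features
are each non-AR group path tagged by the sign of that subject's estimate,
plus each still-fixed candidate with a significant MI tagged by the sign of
its expected parameter change; similarity counts shared (path, sign)
features. Walktrap (4 steps, raw counts as weights) is cut at maximal
modularity; an all-zero matrix yields flagged singletons. The individual
stage adds the single largest significant-MI path per iteration and stops
at excellent fit, no significant candidate, or the safety cap (default 60),
then prunes its own additions with group/subgroup/AR paths protected.

On clean synthetic data the group + subgroup model usually already meets
the 2-of-4 excellent-fit rule, so the individual stage adds little — a
direct consequence of the sparse stopping rule, and a caveat when
interpreting synthetic individual-path recovery: real fMRI data carry far
more misfit, so the individual stage is exercised harder there.

## Synthetic cohort

The generator emulates the study design: 49 subjects, 11 ROIs
(DMN 2 / SN 5 / FPN 4), T = 500 time points (6-minute scan at TR = 720 ms),
with a layered truth. The default group map matches the reported counts:
contemporaneous paths within SN (2), FPN (4), DMN (1) and between SN–FPN
(1) and SN–DMN (2); lagged paths within FPN (2) and DMN (1); AR paths on
all 11 ROIs. Two subgroups of 39 and 10 subjects carry 6 and 18 extra
paths; individual paths arrive at Poisson rate 2 per subject. Coefficient
magnitudes (no magnitudes are reported for the study itself) are AR ~
U(0.2, 0.6) and non-AR ±U(0.2, 0.4) with a 75% positive sign mix. Truth
draws exclude reciprocal contemporaneous pairs (s→t and t→s together),
which are nearly unidentifiable from a single stationary run; the search
still admits them as candidates. Draws are rejection-resampled until every
subject's reduced-form spectral radius is < 1. Series are generated from
η_t = (I−A)⁻¹(Φη_{t−1} + ζ_t) with unit diagonal noise and a 200-sample
burn-in; the sample stacked covariance was checked against the closed-form
discrete-Lyapunov solution (2% at T = 20,000).

Because the larger subgroup holds 39/49 ≈ 80% of the cohort — above the
75% group criterion — its six paths are legitimately detected at the group
level under default conditions; group-path recall is computed against the
true group set only, and subgroup recovery is still clean because the
similarity features separate the blocks.

Outcomes couple to the *true* density profiles: slips ~ NB(mean =
exp(−2.5 + 20·d(SN-SN,+) − 20·d(DMN-FPN,+) + 0.05·FTND), θ = 2), giving
realistic 0–30 two-week slip counts; craving during treatment is
log-normal with slopes −5 on d(DMN-SN,−) and +5 on d(SN-FPN,+) around a
0–10 scale; cue-induced craving is exp(·) − 1 (so post-minus-pre
differences can be negative) with slopes ∓2. Covariates draw from the
cohort descriptives (age ~ N(28.35, 6.36) truncated to 18–45, sex ~
Bernoulli(28/49), FTND ~ N(4.49, 1.86) clipped to 0–10, treatment ~
Bernoulli(29/49)). What passing tests show is therefore calibration and
recovery under a correctly specified, stationary, Gaussian world — not
robustness to scanner artefacts, motion, haemodynamics, or non-stationarity.

## Stability validation

Rewiring swaps the weights of ⌈α·m⌉ of the m nonzero dyads with uniformly
chosen other dyads, preserving the weight multiset, symmetry, and zero
diagonal (the published perturbation procedure does not pin down its exact
rewiring variant; this swap scheme is the package's documented, seedable
choice). For each α the rewired graph is re-clustered and compared with the
original partition by variation of information (in bits; ARI reported
alongside). The benchmark redraws move a random 20% of subjects to
different existing subgroups. The verdict: stable iff the smallest α whose
mean VI reaches the benchmark is ≥ 0.20 (never reached on a grid extending
past 0.20 also counts as stable; a grid that stops short is flagged not
assessable, as is a single-subgroup solution). Default grid 0.01–1.00 step
0.01 with 100 replicates per α; the validation studies use step 0.05 with
20 replicates, which preserves the verdict while staying desk-scale.

## Densities and outcome models

Every non-AR edge of a final graph belongs to the unordered pair of its
endpoint networks and to the sign of its estimate, giving 12 metrics. The
default denominator is the per-category count of admissible directed paths
(within size-n: 2n(n−1); between n₁, n₂: 4n₁n₂) — chosen because the
reported per-category values sum to ≈ 1.3, impossible under one shared
total-edge denominator; the "total" mode (12 values summing to 1) is also
shipped. AR paths never count: every subject has all of them by
construction. A metric enters regression models only if ≥ ⌈0.25·N⌉
subjects have a nonzero value (13 of 49 qualifies; 6 does not).

Slips are modelled by ML negative-binomial (NB2: var = μ + μ²/θ, θ
estimated jointly) with log link, reporting per-predictor Wald statistics
and the likelihood-ratio χ² against the covariate-only null; estimation
failures return flagged results. Craving outcomes are log-transformed —
log(y), or log(y − min(y) + 1) when any value is ≤ 0 (the shift is
recorded) — and fit by OLS, reporting unstandardized b, standardized β
(= b·SD(x)/SD(log y)), R², and the overall F with (k, n−k−1) df; listwise
deletion of missing outcomes explains df like F(10, 37) at N = 49 with one
incomplete subject. Model-level p-values (LR χ² for counts, F for linear)
are Bonferroni-corrected across the six primary models, threshold
0.05/6 ≈ 0.008.

## Validation problem sizes

The replicated studies are sized for a single CPU: 20 replicates for the
group-recovery, specificity, planted-subgroup, and stability studies; 200
replicates at n = 200 for regression coverage and familywise error. The
oracle comparisons (brute-force discrepancy, exact-refit Δχ², Lyapunov
covariance, max-modularity enumeration) run on 3–6-node fixtures where the
independent computation is exact.

## Known limitations

Direction recovery for weak contemporaneous paths is imperfect by nature
of the likelihood landscape, not estimation error. The similarity matrix
and the stability procedure are deterministic given a seed but depend on
Walktrap's resolution behaviour for very flat structures. No missing-data
estimation, higher-order lags, latent variables, or non-Gaussian
likelihoods; inputs begin at extracted ROI time series.
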