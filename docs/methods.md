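# Methods

## Drift model

A crypt's labeled-clone size n ∈ {0, …, N} performs a continuous-time
random walk: while 0 < n < N, replacement events arrive at rate 2λ and
move the size ±1 with equal probability; 0 (clone loss) and N
(monoclonal conversion) are absorbing. The generator's eigenvalues are
4λ sin²(πm/2N), m = 1…N−1, giving the closed forms in the README. The
extinct mass p_0 is defined by complement; values driven below zero by
floating cancellation are clamped at −10⁻⁹ tolerance, and anything worse
raises an internal-consistency error rather than being silently
repaired. The initial condition is fixed at one labeled cell (n₀ = 1):
the labeling experiment the model describes marks single cells, and no
general-n₀ interface is exposed.

Three observable classes map clone sizes to what a section scores:
any surviving clone (sizes 1…N, used for the small intestine, where
ribbon clones are not size-resolved), partly populated (1…N−1), and
wholly populated (N, used for the colon, where partial clones are
harder to call). All drift-level functions take pure drift time t; the
emergence delay τ is subtracted exactly once, as chase_day − τ, in the
simulation and fitting layer, so it cannot be applied twice.

Tissue constants are treated as known: (N, λ, τ) = (5, 0.1/d, 5 d)
proximal small intestine, (6, 0.2/d, 5 d) distal, (7, 0.3/d, 1 d)
colon. Estimating them from data is out of scope.

Two independent realisations of the same process serve as oracles for
the spectral formulas and for each other: the matrix exponential of the
tridiagonal generator, and exact event-driven (Gillespie) simulation
with exponential waiting times — chosen over time-discretised updates
so that oracle comparisons carry no step-size error.

## Hierarchical inference

The mixture Q_n(t) = (1−v) δ_{0,n} + v p_n(t) is taken at face value:
extinction is handled by the n = 0 mass, with no additional
survival-conditioning inside the mixture. This reading reproduces the
observed-4%-to-inferred-~44% relationship for the colon and keeps the
expected observable fraction exactly linear in v.

The fitted model, per mouse i:

    κ_i ~ Binomial(C_i, R_i)
    R_i ~ Student-t(η, Q_i, σ) truncated to [0, 1],  Q_i = v · P(observable at t_i)

Priors: η ~ Gamma(2, 0.1) (shape–rate; mean 20, a standard weakly
informative choice for degrees of freedom), σ ~ Gamma(0.01, 0.01)
(vague), v ~ Beta(½, ½) (Jeffreys). Each row carries its own observable
class and chase day, so mixed designs pool naturally. The truncation
normalisation of the Student-t depends on Q_i and hence on v; it is
included in the posterior — omitting it visibly biases v.

Two deliberate numerical bounds:

* The degrees of freedom are bounded below at η ≥ 1. Below η ≈ 1 the
  truncated-t renormalisation concentrates into a density spike at the
  location (almost all untruncated mass lies in the far tails), a
  pathological region that traps samplers at absurd values like
  η ~ 10⁻⁹ while carrying under 0.5% of the Gamma(2, 0.1) prior mass.
  Bounding dof at 1 is the common convention for Student-t dof priors
  in robust hierarchical models.
* σ = 0 is outside the sampler's support (log parameterisation);
  "no mouse effect" is represented by σ small against the binomial
  counting scale, which the data cannot distinguish from zero.

## Sampler

Adaptive Metropolis-within-Gibbs on transformed coordinates: logit v,
log η, log σ, and the standardised residuals u_i = (R_i − Q_i)/σ, with
exact Jacobians so the chain targets the natural-space posterior. The
residual coordinates are the load-bearing choice. Under the vague
Gamma(0.01, 0.01) prior, 84% of σ's prior mass lies below 10⁻⁶; when
the mice are homogeneous the posterior therefore drives σ across tens
of orders of magnitude. In centred coordinates this is a funnel in
which R_i must track Q_i to within σ — mixing stalls, and worse,
transported residuals round to exactly zero in double precision, which
silently breaks reversibility and measurably biases the σ marginal. In
u-coordinates the funnel is flat, every quantity stays O(1), and
prior-only runs reproduce all prior marginals across the full range
(the suite checks v's Beta moments; σ quantiles were verified over
twenty orders of magnitude during development of the move set).

Update blocks per sweep: random-walk steps on each coordinate (step
sizes adapted during warmup toward 0.35 acceptance by a decaying
Robbins–Monro rule, then frozen; 10% of proposals take a 10× step to
cross multi-scale marginals); two deterministic-coupling flows that
move v or σ while holding every centred R_i fixed (unit-Jacobian and
e^{−Mδ} determinants respectively); and prior-independence proposals
with full Hastings corrections for v (residuals riding along or held,
50/50), η (residuals carried through the Student-t quantile map, which
preserves each residual's tail mass), and σ (half prior draws — made in
log space, since the small-shape Gamma underflows — and half
log-uniform over the likelihood-relevant band [10⁻⁸, 1], so regime
switches remain frequent). Latent R_i are explicit in the model
(centred specification); the u-coordinates are a change of variables
inside the sampler only, and reported draws are the R_i.

Defaults: 4 chains, 2 000 warmup + 2 000 retained draws per chain.
Convergence is declared when every sampled quantity has split-R̂ < 1.01
and bulk ESS > 400 (computed with arviz); failure produces a warning
and a `converged=False` flag, never a silent result. All randomness
flows from one seed through `numpy.random.SeedSequence` spawning, so
fits, simulations and recovery batches are exactly reproducible,
including per-mouse streams that do not depend on cohort ordering.

## Synthetic cohorts and what passing tests show

`simulate_cohort` draws each mouse's R_i from the same truncated
Student-t family the inference assumes and κ_i binomially — parameter
recovery is therefore a well-posed check of the fitting machinery, not
of the model's adequacy for real tissue. Defaults emulate a colon
experiment: 6 mice × 900 crypts, chase day 30, η_true = 20 (the prior
mean) and σ_true = 0.005, a mouse-level spread comparable to the
binomial noise of ~900 scored crypts. Real data depart from this ideal
in ways the generator does not emulate: scoring error in calling a
crypt wholly populated, crypt fission, non-neutral behaviour of labeled
clones, and uncertainty in the fixed constants (N, λ, τ). Passing
recovery tests certify the estimator under the stated model, nothing
more.

The calibration harness (`recovery_experiment`) runs simulate-then-fit
replicates and reports 95%-interval coverage and the median absolute
error of posterior medians; replicate failures are recorded per row
rather than aborting the batch. The shipped suite uses 20 replicates
at 2 chains × 800 + 800 draws — enough that coverage below 0.8 would
flag miscalibration while keeping the run at desk scale.

## Deterministic companions

For quick checks without MCMC, `invert_point_estimate` divides a pooled
observed fraction by the observable probability (the mixture solved for
v), erroring informatively when the observable has probability zero or
the implied v exceeds 1. `stem_cell_equivalents` restates a crypt
fraction v as a per-stem-cell fraction v/N with a "1 in ⌊N/v⌋" report
(the exact ratio is returned alongside the floored integer), and
`fold_change` reports an exact ratio with a nearest-integer "-fold"
string. Full precision lives in return values; rounding happens only in
report strings.

## Known limitations

* The colon estimate uses wholly populated crypts only (the preset
  default); partly populated counts can be fitted by overriding the
  observable kind, but joint WPC+PPC multinomial fitting is not
  implemented.
* σ's posterior under the prescribed Gamma(0.01, 0.01) prior is
  extremely diffuse whenever between-mouse spread is not identified;
  its summaries (and occasionally its ESS at default chain lengths)
  reflect that genuine diffuseness rather than a sampler defect.
* N, λ and τ enter as exact constants; their uncertainty is not
  propagated into the posterior for v.
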