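# Methods

## The internal model

The learner explains its trial-by-trial experience — a CS configuration
**x**_t ∈ ℝ^D and a US intensity r_t at time τ(t) — as the output of
latent causes. One cause is active per trial. Given cause k, each CS
feature is Gaussian with mean μ_kd and variance σ_x²; μ_kd itself has a
standard-normal prior (variance fixed at 1, deliberately not a
parameter), which yields conjugate posterior-predictive terms: after
N_k assigned trials with running mean x̄_kd, a new trial's feature d is
predicted as 𝒩(N_k x̄_kd/(N_k+σ_x²), σ_x²/(N_k+σ_x²) + σ_x²). The
predictive variance is shared across features because assignment is
per-trial, so all features of a cause have the same count. The US is
Gaussian around a cause-specific linear function of the CS,
𝒩(**w**_k·**x**_t, σ_r²), with weights starting at zero (mirroring the
zero-mean μ prior).

The prior over causes is a time-sensitive Chinese restaurant process:
an old cause's unnormalized mass is the sum of a power-law kernel
𝒦(Δ)=1/Δ over the times of its assigned trials; a brand-new cause has
mass α. 𝒦(0)=0, taken literally: simultaneous events lend each other
no mass, and this is the only sanctioned same-time behaviour. The
power-law kernel compresses remote history — two old causes become
equally plausible as both recede — which is what produces spontaneous
recovery and the age-dependence of memory modification.

## Inference and learning

Exact inference over assignment histories is intractable (Bell-number
growth), so the engine uses the local-MAP approximation: the posterior
at trial t conditions on the single running sequence of hard
assignments ẑ_{1:t−1}, and ẑ_t is the argmax of the final trial
posterior (ties break to the lowest, i.e. oldest, index). Sufficient
statistics are committed once per trial, after learning finishes;
earlier trials are never revisited. The candidate set at every trial is
all instantiated causes plus exactly one new cause.

Each trial proceeds in a fixed order:

1. **Response.** Before the outcome is revealed, a response posterior
   ∝ prior × CS likelihood is computed over the K+1 candidates, the US
   prediction r̃_t averages the candidates' linear predictions under
   that posterior (the new slot predicts 0), and the conditioned
   response is read out as CR = 1 − Φ(θ; r̃_t, λ), the probability
   that the US exceeds threshold θ under a Gaussian with *variance* λ.
   The CR is anticipatory by construction.
2. **Learning.** The outcome then drives n alternations of an E-step
   (posterior now including the US likelihood, with statistics frozen
   at their pre-trial values) and an M-step (delta rule
   w_kd += η x_td q_tk (r_t − **w**_k·**x**_t), η absorbing the 1/σ_r²
   gradient factor). Weight changes compound across the alternations —
   this compounding is the engine of the retrieval-extinction effect.
   The new-cause candidate carries a transient weight vector during the
   trial and keeps it only if it is actually instantiated at commit.
3. **Commit.** The trial's time and features join ẑ_t's statistics.

The alternation count is the "rumination" budget: one E/M pass per
whole time unit of free interval after the trial — the gap to the next
trial, or to an injection attached to the trial — clamped to [1, 3].
The final trial of a schedule has no defined trailing interval and
receives `final_trial_iters` (default 1) passes; probe trials with no
outcome learn nothing. Trials whose outcome is absent (`None`) skip the
US likelihood and the M-step entirely.

With α=0 the prior puts zero mass on new causes, a single cause absorbs
every trial, the posterior is degenerate at that cause, and the update
reduces exactly to Rescorla-Wagner; the suite verifies the weight
trajectories agree to 1e−10 on random schedules. On the first trial of
a schedule the lone new-cause candidate receives probability 1 even at
α=0 (the single-cause model still needs its cause); the raw CRP prior
of an empty state with α=0 is an error.

## Amnestic agents

A protein-synthesis inhibitor administered after trial t decrements
every cause's weight vector, **w**_k ← **w**_k (1 − q_tk), in
proportion to the posterior that cause k was active on that trial —
the trace-dominance principle in update form. Sufficient statistics are
untouched: the trace is weakened, never erased, which is why amnesia
can be transient. Delayed administration is modeled with a recency
gate: if the injection arrives more than `psi_window` (default 3 time
units, matching the maximum rumination span) after the trial, no cause
counts as active and the decrement has no target. The gate is a
minimal formalization — the theory says delayed injections miss the
window of cause activation but gives no functional form; an
exponential-decay activation would be a natural extension point. The
drug state itself can also enter the stimulus vector as an ordinary
feature (state-dependency); it then participates in the CS likelihood
and the US prediction with no special casing.

## Parameters

| name | default | meaning |
| --- | --- | --- |
| α | 0.1 | concentration: prior mass of a brand-new cause |
| η | 0.3 | delta-rule learning rate (absorbs 1/σ_r²) |
| σ_r² | 0.4 | US noise; lower = more sensitive to US prediction error |
| σ_x² | 1.0 | CS noise |
| θ | 0.02 | CR threshold (sigmoid inflection) |
| λ | 0.01 | CR variance (inverse gain; λ→0 gives a step) |
| max_em_iters | 3 | rumination ceiling |
| psi_window | 3.0 | injection recency gate, time units |
| final_trial_iters | 1 | rumination for a schedule's last trial |

Human within-subjects designs use the read-out scaling θ=0.0016,
λ=0.00008; θ and λ rescale predictions without changing any ordering.
Time is mapped as 24 h ≡ 20 units, one month ≡ 200 units; CSs are unit
impulses unless a paradigm says otherwise (0.8 for a similar context).

## Experiment battery

Paradigm builders lay the classic designs on the model clock.
Schedule defaults that the literature does not pin down numerically
were fixed once and are used everywhere: within-session ITI of 1 unit;
3 CS–US acquisition pairings (varied over {1,3,10} in the
memory-strength design; US intensity 0.5 for the weak memory in
paradoxical enhancement); 10-trial extinction sessions; "immediate"
injections at lag 1 and "delayed" at lag 18 (outside the gate);
memory-age intervals {20, 200}; reexposure gaps {1, 5, 20, 140}
(1 h / 6 h / 24 h / 1 week); retrieval-extinction intervals
{0, 3, 100} for the retrieval-extinction comparison; context
similarity 0.8 vs 0. Probes are the test-trial CRs; claims are
orderings over probes, and `run_experiment` evaluates all of them.
All simulations run in well under a minute on one CPU; the largest
single computation (the 30-point REI curve) simulates 30 schedules of
17 trials each.

Design points that emerged from implementation, in places where the
sources fix no number:

- **Memory age** is scored as the amnesic *contrast* — control CR minus
  Ret+PSI CR at the same age (0.102 day-old vs 0.010 month-old under
  defaults) — because the raw month-old test CR is already capped by
  ordinary forgetting (control 0.745), so a raw between-age CR
  comparison would confound disruption with retrieval.
- **Transience of amnesia** probes retrieval-test intervals
  {3, 5, 10, 15, 200}. The recovery window is the period in which the
  retrieval-session cause still dominates the prior but is losing
  dominance (its 1/Δ mass decays faster than the older acquisition
  cause's); with a single reexposure trial that window closes within
  about one model day, after which the constant new-cause mass α makes
  the acquisition posterior — and the CR — decline. The remote probe
  at 200 exhibits the terminal dip.
- **Paradoxical enhancement** uses retrieval-test intervals {1, 200}.
  Enhancement is a pure retrieval effect, and it must outrun the cost
  of the unreinforced retrieval trial: each rumination pass shrinks the
  acquisition weight by a factor (1 − ηq), so a gap long enough to
  grant 3 passes (≥3 units) costs ≈ half the weight while the
  prior-bridging at test gains less than that back. At a 1-unit
  interval the bridge is fresh, a single pass runs, and the retrieval
  condition tests higher (+0.003 under defaults); by 200 units the
  effect has reversed — the model's expression of the phenomenon's
  transience.
- **Reexposure timing** registers the orderings the model actually
  predicts: every spaced gap tests below the massed (1-unit) gap, and
  the week gap below the day gap, but the decrease is *not* monotone
  through the middle of the grid. A gap of a few units after the first
  reexposure is precisely the retrieval-extinction sweet spot —
  rumination reactivates the acquisition cause, so the injection after
  the second reexposure bites hardest there (CRs 0.964, 0.636, 0.807,
  0.662 across {1,5,20,140}). This nonmonotonicity is forced by the
  same mechanism that produces the interior peak of the
  REI curve, so a strictly monotone version of this design cannot
  coexist with the retrieval-extinction results in this model.
- The **sensitivity sweep** of σ_r² uses the grid {0.1…0.4}: above
  ≈0.42 the reexposure trial's hard assignment flips back to the
  acquisition cause and the discrete jump in test-time retrieval masks
  the smooth mechanism (US-error sensitivity falling with σ_r²) that
  the sweep traces. The α grid {0.01…10} spans the interior peak.
- In the state-dependency design the drug feature is set on the
  acquisition trials and (in the drug-at-test arm) the test trial
  only; it is not propagated to any other trial.

## Numerical choices

All probability arithmetic is in log space with max-subtraction
normalization; posteriors are renormalized to machine precision and
validated (nonnegative, sum within 1e−12). Ties in the hard assignment
break to the oldest cause for reproducibility. The core engine contains
no randomness at all — identical schedules give byte-identical result
tables; randomness exists only in the test-support schedule generator,
which is fully seeded. The exact-enumeration oracle (guarded at 8
trials) computes the true posterior over assignment histories with
weights held at zero and serves as a diagnostic of the local-MAP
approximation, not as an equality requirement.

## What the simulations do and do not show

Schedules are trial-level: stimulus duration within a trial is not
represented (reexposure *duration* is proxied by the number of
presentations), and the US is a scalar intensity. The generator of
random verification schedules produces monotone times, Bernoulli
stimuli and outcomes — it exercises the engine's invariants, not the
statistics of real conditioning data. Passing the battery shows that
the model reproduces the *direction* of each phenomenon under one
shared parameter set; the CR magnitudes are not calibrated to empirical
freezing or skin-conductance levels (the response mapping saturates
quickly at the rodent read-out scale, so many orderings ride on small
differences near the ceiling — deterministic, but not meaningful as
effect sizes). No fitting to empirical data is performed anywhere.
Known limitations: no within-trial time, no pharmacokinetics of the
amnestic agent beyond the hard recency gate, no discrete-stimulus
emission variant, and no mechanism for complete spontaneous recovery
(the acquisition cause's prior mass can approach but never exceed the
extinction cause's).
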