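# latentcause

A simulator for the latent-cause theory of Pavlovian conditioning and
memory modification: an infinite-capacity mixture model in which an
animal's *structure learning* (Bayesian inference about which hidden
cause generated each trial) interleaves with *associative learning*
(Rescorla-Wagner-style updates of per-cause CS–US weights). The package
is aimed at computational-cognitive-neuroscience work on fear
conditioning, extinction, reconsolidation and the retrieval-extinction
effect: it turns the classic experimental designs (post-retrieval
amnesia and its boundary conditions, the Monfils-Schiller paradigm,
state-dependency, cue-specificity, paradoxical enhancement) into
runnable, deterministic simulations with testable ordering claims.

## The model

Each trial t carries a stimulus configuration **x**_t ∈ ℝ^D and an
outcome r_t. The internal model assumes a single latent cause z_t
generated both:

- CS emission: x_td | z_t=k ~ 𝒩(μ_kd, σ_x²), with a standard-normal
  prior on μ_kd (so the posterior predictive for cause k has mean
  N_k x̄_kd / (N_k + σ_x²) and shared variance σ_x²/(N_k+σ_x²) + σ_x²);
- US emission: r_t | z_t=k ~ 𝒩(**w**_k·**x**_t, σ_r²);
- a time-sensitive Chinese restaurant process prior over causes:
  P(z_t=k) ∝ Σ_{t′<t} 𝒦(τ(t)−τ(t′)) 𝕀[z_{t′}=k] for old causes and
  ∝ α for a new one, with power-law kernel 𝒦(Δ)=1/Δ, 𝒦(0)=0.

Inference is an online EM scheme: the E-step computes the posterior
over the K instantiated causes plus one new-cause candidate under a
local-MAP approximation of the assignment history; the M-step updates
every candidate's weights by the delta rule
w_kd ← w_kd + η x_td q_tk (r_t − **w**_k·**x**_t). The E/M alternation
("rumination") repeats once per whole time unit of free interval after
a trial, up to 3 times. The conditioned response is read out *before*
the outcome, CR = 1 − Φ(θ; r̃_t, λ) with
r̃_t = Σ_d x_td Σ_k w_kd q_tk. A protein-synthesis inhibitor given
within 3 time units of a trial multiplies each cause's weights by
(1 − q_tk). With α = 0 the model collapses exactly onto the
Rescorla-Wagner model.

Defaults (used in every simulation): α=0.1, η=0.3, σ_r²=0.4, σ_x²=1,
θ=0.02, λ=0.01; 24 h ≡ 20 time units, one month ≡ 200.

## Worked example

```python
import numpy as np
from latentcause import ModelParams, build_paradigm, run_experiment

report = run_experiment(build_paradigm("monfils_schiller"), ModelParams())
for probe, cr in report.probe_crs.items():
    print(f"{probe:10s} test CR = {cr:.3f}")
```

prints

```
no_ret     test CR = 0.679
ret_short  test CR = 0.449
ret_long   test CR = 0.509
```

Three retrieval-extinction conditions differ only in the interval
between a lone CS reexposure (24 h after 3 CS–US pairings) and the
10-trial extinction session. With no interval (`no_ret`) or a long one
(`ret_long`), extinction trials are assigned to a *new* latent cause,
the fear association survives untouched, and fear spontaneously
recovers at the test a day later. With a short interval (`ret_short`,
3 time units ≈ a half-hour to an hour), rumination during the gap
weakens the CS–US weight just enough that the extinction trials are
re-attributed to the original acquisition cause, which erases the fear
memory: the test CR stays at the lowest level of the three.

The same engine exposes every registered paradigm:

```bash
latentcause battery --out results/        # all paradigms + claim report
latentcause run --paradigm monfils_schiller --set rei=3 --out results/
latentcause sweep --param alpha=0.01,0.1,1,10 --out results/
```

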