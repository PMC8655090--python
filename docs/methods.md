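# Methods

## Model

Two independent unit-noise diffusions race on every trial, both on a
time axis in seconds relative to the *scheduled* stimulus onset of a
standard trial (fixation onset at −0.3 s).

**Action initiation (AI).**  A single-bound process with reduced drift
`V_A` (1/s) and reduced bound `θ_A`, total latency `t_A` (afferent +
motor, folded into one shift; negative values mean the bound can be
reached before stimulus onset, producing fixation breaks).  Its
first-passage law is the inverse Gaussian with mean `θ_A/V_A` and shape
`θ_A²`; the cdf is the standard Wald cdf, computed in log space so that
`exp(2 V_A θ_A)` never overflows and the defective mass
`exp(2 V_A θ_A) < 1` for negative drifts comes out exactly.

**Evidence accumulation (EA).**  A symmetric two-bound process with
drift `V_E = ν_E·S`, bounds `±θ_E`, starting offset `Z_E = z_E·b_k`,
latency `t_E` after the trial's actual stimulus onset (shifted by Δ on
onset-manipulated trials).  Per-bound exit densities use the large-time
Fourier series; the per-bound cdf is obtained term by term analytically
and anchored at the closed-form two-barrier absorption probability, so
both ends of the support are exact rather than quadrature-limited.  The
series is truncated per decade band of elapsed time (the required term
count falls as `1/√τ`), keeping the first dropped term below
`exp(−45)`; elapsed times under 10 µs are treated as zero support —
there the exact density is below 1e−40 for any parameters in the search
box while the series would need more terms than the cap.

**Race and read-out.**  `p = p_A(1−c_E) + p_E(1−c_A)`.  When the AI
wins, the stimulus stops at withdrawal and the EA finishes integrating
what was heard (total stimulus-driven integration time = withdrawal
time since stimulus onset), with sticky bounds; the choice is the sign
of the final EA state.  The split of `t_E` into afferent and motor
parts is unidentifiable from fits and the read-out is defined so it
does not depend on it.

**Contaminants.**  With probability `c`, the response comes from
`p_C = d·TruncExp(β) + (1−d)·Uniform` on the analysis window
[−0.3, 1.0] s, the exponential decaying from fixation onset (the
window's left edge) and renormalized on the window; contaminant choices
are fair coins.

## Likelihood and fitting

Only withdrawal times enter the likelihood — fixation breaks as
negative times, where the race density automatically reduces to the AI
branch.  Responses slower than 1 s are censored.  By default each
trial's mixture density is divided by its exact mass inside
(−0.3, 1] s (closed-form race cdf at the window edges): this is the
proper truncated likelihood and is consistent under the censoring,
whereas the raw censored density (available via `renormalize=False`)
systematically mis-estimates slow subjects — in our checks wrong
parameters could beat the truth by over a thousand log-likelihood
units once a few percent of the model mass lay beyond 1 s.

The 10 free parameters of the standard model (11 biased, 12 in the
reward model) are optimized by bounded Nelder–Mead through a logistic
transform onto the search box, with scipy's adaptive simplex
coefficients (the non-adaptive defaults stall in 10+ dimensions).  A
cheap screening stage evaluates a few dozen uniform draws and keeps the
best as coarse-pass starts; the two best coarse optima are polished to
1e−6 on the log-likelihood, and the winner gets a restarted
quasi-Newton (BFGS, numerical gradients) refinement — the likelihood
has a long narrow ridge among (θ_A, ν_A0, t_A) along which the simplex
crawls but a gradient method tracks.  Reward-model fits warm-start from a
standard-mode prefit, whose affine-in-trial drift approximates the
reward drift well.  Per-trial densities are floored at 1e−300 before
the log; floored trials are counted and reported.  Densities inside the
likelihood are tabulated on a geometric-then-linear elapsed-time grid
(dense near the EA onset where the density rises super-exponentially)
and linearly interpolated at the observed times; the Fourier decay
matrices depend only on the grid and the bound, so one workspace per
evaluation serves every strength/bias/shift condition.

Fitting bounds (the search box): ν_A0 [0,12] s⁻¹; ν_trial [−2,1]×10⁻²
s⁻¹·trial⁻¹; θ_A [0.1,10]; t_A [−600,300] ms; ν_E [2,10] s⁻¹; θ_E
[0.1,1.2]; t_E [35,75] ms; z_E [−1/2,1/3]; c [0,0.5]; d [0,1]; β
[0,50] s⁻¹.

## Simulation

Euler–Maruyama at 0.1 ms (default) with sticky absorbing bounds and a
per-step Brownian-bridge crossing probability
`exp(−2(θ−x₁)(θ−x₂)/σ²dt)`: plain end-point detection at 0.1 ms
carries an O(√dt) first-passage bias large enough to be visible against
the analytic densities (KS ≈ 0.01–0.04 for fast processes); the bridge
term removes it, and halving dt then changes nothing beyond Monte-Carlo
noise.  Same-step double crossings are broken by a fair coin.
Contaminant trials are drawn by inverse-cdf sampling.  Responses above
1 s are emitted but flagged invalid and dropped downstream without
renormalization; latent bound hits before fixation onset (possible when
`t_A < −0.3`) are flagged invalid too, since no withdrawal can be
observed before the animal has poked in.

## Extended-DDM baseline

A single accumulator integrates internal noise (drift 0, variance
σ_I²) from fixation onset plus latency, switching to drift `ν_E·S` and
unit variance once stimulus information arrives; absorbing bounds ±θ.
On the response-time axis the switch happens exactly at `t_E`, so the
model is at chance for any response faster than that.  The occupancy
density is evolved by Crank–Nicolson (default Δx = θ/200, Δt = 0.5 ms)
with Dirichlet ends; the first 16 steps are fully implicit to damp the
oscillations Crank–Nicolson develops on a point-mass start, and the
step straddling the stimulus switch uses time-averaged coefficients —
without these, grid refinement did not converge.  Mass lost per step is
attributed to the two boundaries in proportion to the one-sided
diffusive fluxes, so surviving + absorbed mass is conserved to machine
precision.  Fitting uses differential evolution (seeded, modest
population) on a coarser internal grid (Δx = θ/120, Δt = 1 ms).

## Synthetic data

`generate_sessions` emulates the task: 300 ms fixation, strengths drawn
from {0, 0.25, 0.5, 1} with a random rewarded side, a predetermined
target side for zero-strength and silent trials, 10% silent catch
trials or 5% + 5% advanced/delayed onsets (at full strength), reward
sizes 12/24/48 µL, 700 trials per session, and an optional blockwise
alternating expectation sign.  `generate_rat` draws each parameter
uniformly in the central 60% of its fitting bound and resamples until
the subject lies in the study's behavioral regime: analytic proactive
share in [0.15, 0.85], fixation-break probability in [0.04, 0.35]
(bracketing the observed ~16% FBs and ~35% express responses), AI drift
still positive at trial 700, and `t_A > −0.29 s` (the AI starts at
fixation onset after nonnegative latencies, and a latency outside the
observable window would leave `t_A` identified only by extrapolation).
Without the regime filter most draws never express one of the two
processes and its parameters are unrecoverable in principle.  Reward
weights default to signs (w_r > 0, w_t < 0, w_c < 0) and magnitudes
under which the reward-size effect on fast responses fades rather than
reverses across a 500-trial session.

What the generator does *not* emulate: serial choice dependencies and
the block structure behind the expectation sign (supplied as a plain
alternating sign), session-to-session drifts, stimulus acoustics, and
within-trial evidence fluctuations beyond white noise.  Passing tests
therefore show the estimator is correct under the model's own
assumptions, not that real data satisfy them.

## Behavioral statistics

Tachometric curves bin choice-bearing responses (fixation breaks and
invalid trials excluded) in 10 ms windows with normal-approximation
binomial intervals.  Time-delay curves invert both empirical cdfs with
linear interpolation between jump points, so a sample against itself is
identically zero; positive values mean the sample is faster at that
quantile.  The RT-modulation onset scans truncation times, comparing
strongest- vs weakest-stimulus RTs by a one-sided KS test (exact
p-values below 50 samples); the onset is where the comparison becomes
significant *and stays significant* to the end of the scan — anchoring
on the trailing run keeps the null detection rate at α despite the
nested multiple comparisons, while a first-momentary-dip rule false-
alarms on ~40% of null datasets.  The fast-response fraction counts
withdrawals faster than 50 ms after stimulus onset, fixation breaks
included, per 50-trial block.

## Problem sizes and numerical defaults

Oracle comparisons use 1e5 Euler trials at 0.1 ms (KS tolerance 0.01);
recovery experiments use 10 subjects × 20 000 trials with 5-start fits
and 0.2 ms simulation steps; the acceptance script scales to 4 subjects
and 5e4-trial oracles.  Density grids default to 1 ms over
[−0.3, 1.0] s; quadrature is trapezoidal.  All randomness flows from
explicit `numpy.random.Generator` seeds; simulation kernels take a
single integer seed and are bit-reproducible.

## Known limitations

The AI trio (ν_A0, θ_A, t_A) is weakly identified whenever proactive
responses are rare, and `t_A` specifically needs the AI onset edge
inside the observation window; fits near the regime boundary show
correlated errors among the three.  The large-time series cdf loses its
advantage for θ_E far above the search box (term counts grow with the
bound).  The eDDM boundary-flux split (not its total) is first-order
accurate.  Reward-mode simulation is sequential by construction
(consumed reward feeds back into the drift) and therefore slower than
the vectorized standard mode.
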