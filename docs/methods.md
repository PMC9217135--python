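# Methods

## Plant and controller

The plant is a discrete-time planar point mass (`m = 1` kg) with intrinsic
damping `b = 0.1` N·s/m, driven per axis by a force actuator that low-pass
filters the motor command with time constant `τ = 0.06` s; the timestep is
`δt = 0.01` s. Per axis the state is `[position, velocity, force]`; the
two-axis state is block ordered `[p_x, v_x, f_x, p_y, v_y, f_y]` with x the
lateral (perturbation) axis and y the forward (movement) axis. Units are SI
internally; centimetres appear only in reporting.

The controller is a finite-horizon linear-quadratic regulator: state costs
`ω_p` (squared position error relative to the target), `ω_v`, `ω_f` are
applied at the terminal step only, the activation cost `R` (default
`3·10⁻⁶`) at every step, and the optimal time-varying gains come from the
backward Riccati recursion in Joseph form, with each value matrix
symmetrised against roundoff and asserted positive semidefinite. The
regulator runs in target-relative coordinates, so the gains are independent
of the target and a target jump is a step change in the reference series.
The model assumes perfect state information and purely additive control
noise — no sensory noise, no state estimator, and no signal-dependent
noise. The additive noise `ξ` defaults to **off**: all model-prediction
profiles are deterministic. When enabled (for synthetic-data realism
studies) it is i.i.d. Gaussian per axis with configurable SD; nothing in
the packaged analyses depends on its distributional details.

Horizons are `N = round(duration/δt)`. Cost weights apply equally to both
axes; axis-specific weights are representable in `CostSchedule` but unused
by the built-in tasks.

## Tasks

| task | target | duration | ω_p | ω_v | ω_f | activation |
|---|---|---|---|---|---|---|
| stop | 25 cm | 700 ms | 1.5 | 1 | 0.1 | stationary `R` |
| hit | 25 cm | 620 ms | 1.5 | 1/50 | 0.1/50 | stationary `R` |
| long-stop | 28 cm | 800 ms | 1.5 | 1 | 0.1 | `R·C(t)`, mean(C) = 1 |

Long-stop is a control construction: the stop cost set aimed at a virtual
target 3 cm beyond the real one, so the movement is still travelling
(~32 cm/s) when it crosses 25 cm — a hit-like movement executed by the
stopping controller. Its activation-cost ramp is
`C(t) ∝ exp((p·t + q)/r)` with constants `p = 1, q = −1000, r = 65`,
normalised to mean one over the movement so the total activation budget is
unchanged. The time variable of this expression is, by default, the **step
index**. This is a deliberate interpretation choice: with `t` in
milliseconds the exponent ramps by `e^12` within one movement and the
simulated long-stop peaks near 124 cm/s, which defeats the ramp's purpose
(matching the ~60 cm/s hit-like velocity profile); with the step-index
reading the long-stop peaks at 59.8 cm/s, crosses 25 cm at ~605 ms at
31.6 cm/s, and matches the intended kinematics. The millisecond reading
and the literal form `exp(p·t + q·r)` remain available through
`activation_profile(..., time_unit=...)`; the additive constant in the
exponent cancels under normalisation in every reading.

The `universal` task is the generative embodiment of the
single-controller hypothesis: a controller built from the element-wise
blend of the stop and hit weight vectors (default weight 0.5, i.e. the
arithmetic mean; the blend weight is a parameter) with the mean of the two
durations.

## Perturbation sweeps and the three reference frames

A sweep simulates one movement per trigger step. The lateral target
reference shifts by the jump (default 2 cm, signed) 150 ms after the
trigger — the virtual analogue of human visuomotor latency, so that model
response timing aligns with responses measured 180–230 ms after a real
perturbation — and stays shifted to movement end (the measurement closes
60 ms after the shift, so a later return is immaterial here; the
experiment's 250 ms return is implemented in the data generator instead).
Intensity is the mean lateral force over 10–60 ms after the shift minus
the unperturbed run's lateral force over the identical absolute samples.
The window is earlier than the human 180–230 ms window because the
single-low-pass muscle makes model responses ramp immediately. Triggers
whose window overruns the horizon (the last 150 + 60 ms of triggers) are
dropped and counted.

Each record carries the trigger time, the time-to-target (first crossing
of the 25 cm measurement distance, linearly interpolated between samples;
movements that halt at the target without formally crossing it use the
movement end, making time-to-target and time-to-movement-end identical for
stop and hit), the time-to-movement-end, and the forward position and
velocity at the trigger. `profile_views` re-indexes the same records on the
three abscissae without resampling.

Channel mode clamps the lateral position and velocity to zero after every
transition — an infinitely stiff mechanical channel — while the commanded
lateral force state evolves and is recorded, mirroring how a force channel
measures corrective force without letting the hand deviate. Because the
axes are dynamically decoupled and the costs diagonal, the Riccati solution
is block-diagonal and the forward movement is unaffected.

Model geometry worth knowing when reading sweep output: gains of a
finite-horizon regulator depend only on steps-to-go, so two movements with
identical cost structure and stationary activation cost produce *exactly*
the same intensity at matched time-to-movement-end regardless of target or
duration (the stop/long-stop comparison exploits this; the test suite
asserts it to 1e-12 with the ramp disabled). The printed activation ramp
raises late-movement `R` by ~1.8x and perturbs the late gains, so with the
ramp enabled the stop and long-stop movement-end-frame curves deviate by
~20% of peak at short times-to-movement-end — the ramp trades frame
invariance for kinematic matching. Likewise, with the built-in 50-fold
cost reduction the hit simulation still brakes to 8.6 cm/s at its final
sample (the optimum was cross-checked by direct trajectory optimisation);
sustaining hitting-like terminal speeds above 20 cm/s within this
formulation requires either the long-stop construction or terminal-cost
reductions nearer 250–300-fold. Both facts are consequences of the
finite-horizon formulation and are asserted, at their measured values, in
the test suite.

The delay + window + actuator constant also impose a feasibility floor:
no intensity can be measured for triggers within 210 ms of movement end,
and profiles collapse toward zero as that floor approaches. The hit and
stop profiles pinch together in this collapse region; their separation
(hit above stop at matched time-to-target) is strict below ~0.35 s and the
curves cross at ~0.36 s.

## Experimental schedule

Blocks of 16 trials per condition: 10 directional perturbation trials
(5 onset locations × left/right), one zero-perturbation channel trial, and
5 free movements, fully randomised within the block. Onset locations are
exact fifths-of-six of the 25 cm distance (`k·25/6` cm, displayed rounded
to 4.2–20.8 cm). The blocked phase is 26 blocks of each condition back to
back (order configurable); the mixed phase is 26 blocks of 32 trials, each
merging one 16-trial set per condition under a fresh permutation. Run-length
statistics classify every mixed-phase trial after the first by the number
of immediately preceding same-condition trials, counting across block
boundaries because the sequence is presented continuously; expected
fractions over seeds are ≈52/26/12% for 0/1/2. A single seeded NumPy
generator drives all randomisation, making schedules byte-for-byte
reproducible.

## Synthetic participant recordings

Each trial is a 1 kHz recording: 200 ms at rest in the start circle, the
controller's movement (positions upsampled from the 10 ms model grid by
monotone cubic interpolation, velocities by differentiation), then 250 ms
holding the final position. Perturbed trials trigger at the first sample
the (noisy) forward position crosses the onset location; the lateral force
response is the assigned controller's channel-mode response to a 2 cm jump
that returns after 250 ms, delayed 150 ms plus per-trial Gaussian jitter
(SD 8 ms), scaled by the participant's response gain, and added to the
force trace. Channel trials also carry a small deterministic baseline
force proportional to forward velocity (0.15 N per m/s), identical in
perturbed and neutral trials so it cancels under neutral subtraction —
there to exercise that pipeline stage. Start-tone delays are
exponential(λ=0.7) truncated to 1–2 s.

Noise is smooth (low-pass-filtered white, rescaled to target SD):
kinematic noise SD 0.8 mm at 2.5 Hz, force noise SD 0.08 N at 6 Hz. The
kinematic bandwidth is deliberately slow: it represents trial-to-trial
planning/execution drift, keeps the differentiated velocity noise small
against the ±8 cm/s peak-speed compliance window, and leaves ~95% of
generated trials passing the peak-speed/peak-location criteria, as the
feedback-trained participants the generator emulates would. Response gains
across a generated cohort are log-normal (median 1, σ = 0.25).

`switching` participants use the task's own controller on every trial;
`universal` participants use the blended controller for every mixed-phase
trial. The experimental channel wall (printed stiffness 2 N/m, damping
4000 N·s/m) is so overdamped it is treated as rigid; the parameters are
carried in `ChannelWall`, whose `plausible` preset swaps the two numbers —
the transposed values are the usual regime for such an apparatus and the
printed pair is plausibly a transposition. Not modelled: EMG/muscle
detail, eye movements, aborted/timed-out trials, learning across blocks,
and any trial-to-trial intensity variability beyond gain, jitter and
additive noise — the true human variability structure is unknown, and all
defaults are parameters.

## Analysis pipeline

Filtering is a 5th-order Butterworth at 15 Hz run forward and backward
(`sosfiltfilt`) — a tenth-order zero-phase-lag response — after
re-gridding onto an exact 1 kHz axis if samples are missing. Movement
start is the last sample inside the 1.6 cm start circle before first exit;
movement end is the last sample before the cursor centre first enters the
1.2 cm target circle (for hit movements: entry, not rest). Intensity is
the mean lateral force 180–230 ms after the perturbation onset minus the
participant's neutral-profile mean over the matching window, with the
neutral (zero-perturbation channel) trials aligned to each onset location
by their own position crossing — mirroring how perturbations are
triggered; responses to leftward jumps are negated so positive means
"toward the shifted target". Time-to-target of an experimental record is
movement end minus perturbation onset.

Normalisation is per participant: cell means over
condition × schedule × onset location are min-max mapped to [0, 1] and
each record carries its cell's normalised mean; a participant with all
cells equal is flagged degenerate and dropped from normalised analyses.
The comparison stage fits OLS
`normalized ~ time_to_target + condition * schedule` on the cell means and
reports the type-II ANOVA table — raw p-values per term; sphericity
corrections, post-hoc tables and Bayesian model comparison are out of
scope. Profile summaries bin by onset-location index; continuous
time-to-target enters only the linear model. Every perturbed channel trial
ends up in the records or the exclusion log with a reason code.

## What synthetic-data tests do and do not show

Passing end-to-end tests show the pipeline correctly recovers what this
generative world contains: gain scaling (doubling the response gain doubles
extracted intensity), the mixed-vs-blocked equivalence under switching, and
the mixed-phase collapse under a universal controller. They do not show
that human data would behave likewise. One known divergence matters: the
finite-horizon model's intensity-vs-time-to-target profile is bell-shaped
with its peak near 0.35–0.40 s and a hit/stop crossover at ~0.36 s, so
over the five experimental onset locations the conditions separate in one
direction at the earliest onset and the other direction at later onsets,
and a covariate-adjusted linear model finds no net condition effect in
synthetic cohorts — whereas monotone profiles (as human cohorts produce
over this range) would separate cleanly. The profile-level comparisons,
not the ANCOVA condition term, are therefore the informative recovery
checks in this synthetic world.

## Numerical choices

Riccati solves guard the control Hessian (impossible to trigger for
`R > 0` but reported if degenerate) and symmetrise each value matrix.
Crossing times are linear interpolations between bracketing samples
(validated against a 10×-denser zero-order-hold re-simulation to within
one coarse step). Sweep windows are converted to steps by rounding.
Intensity extraction averages all 1 kHz samples inside the closed window;
window-mean discretisation (10 ms model grid vs 1 kHz recordings) is worth
a few percent on the curved response ramp and is accounted for where the
two are compared. The realized cost attached to a trajectory uses the
same index the solver minimises, with the position error taken against the
instantaneous reference.
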