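# Methods

## First-order thermal model

Each prosthetic layer is treated as a single lumped thermal capacitance:
heat flow from a constant source is proportional to the temperature
difference, giving dΔT/dt = −ΔT/τ with ΔT the deficit to the layer's own
steady state and τ = ρc_pV/(hA_s). No continuum conduction is modelled and
h, ρ, c_p are never estimated individually; τ is the only thermal parameter
and is stored in **minutes** (trace time axes are in seconds; conversions
happen at call boundaries).

Bench observations show the material surface plateaus *below* the heat-tape
set-point, with the deficit growing with the set-point. The simulator
therefore parameterises the response by its own asymptote

    T_ss = setpoint − k·(setpoint − ambient),   k = 0.15 by default,

a placeholder loss model (the magnitude of the real offset was not
characterised); the estimation procedure is insensitive to it because it
subtracts the *detected* steady state, never the source temperature.

Stacked liner+socket tests are simulated as two cascaded first-order nodes:
the liner interface T₂ relaxes with the *measured combination* time
constant (so estimation round-trips against the library), and the outer
socket surface T₃ is the second-stage lag (socket's individual τ, asymptote
attenuated to 85 % of T₂'s excess over ambient). Because a unit-gain lag of
a monotone signal never overtakes it, T₃ ≤ T₂ ≤ T₁ holds at every sample —
heat flows outward. No coupled-PDE physics is claimed; the cascade exists
to reproduce the measured interface behaviour.

Measurement noise is i.i.d. Gaussian per sample, default sd 0.05 °C
(typical K-thermocouple logger resolution); the heat-tape channel T₁ is
noiseless by construction (it is servo-controlled).

## Logarithmic-method τ estimation

The estimator follows the classical recipe — detect T_ss, form
ln(T_ss − T(t)), OLS, τ = −1/slope (the governing identity is
ln x(t) = ln x(0) − t/τ, so the slope is −1/τ, not τ itself) — with two
numerical safeguards:

* **Fit window.** The regression uses the contiguous prefix of samples
  whose deficit exceeds max(`min_delta_c` = 0.1 °C, 5 % of the initial
  step), and drops the first sample (contact transient). A per-sample
  threshold applied to *noisy* deficits would preferentially keep upward
  noise excursions near the asymptote and bias τ upward, growing with
  record length; the contiguous amplitude-based window avoids that
  selection effect and keeps the log-noise small (≤ 0.05 °C noise on
  ≥ 0.5 °C deficits for typical 10 °C steps).
* **Steady-state refinement.** The tail mean of a record truncated at
  4–5 τ understates the asymptote by ~1 % of the step, which curves the
  log-deficit and biases τ low by ~10 %. Since only the true asymptote
  makes the log-deficit exactly linear, the estimator refines T_ss by
  maximising the R² of the log-linear fit over T_ss ≥ tail-mean (bounded
  scalar search). On noiseless truncated data this recovers the exact
  asymptote and τ to < 10⁻⁶ min; on noisy data it tracks a direct
  nonlinear least-squares fit of the exponential to within a few percent.
  The refinement can be disabled (`refine_steady_state=False`) to get the
  textbook procedure.

Steady-state *detection* (the guard that a recording is usable) is the mean
of the final 10 % of samples, accepted only if the straight-line slope over
that tail is below 0.05 °C/min. Estimates are repeated across heat-source
set-points 30–40 °C and pooled by arithmetic mean with the sample sd as the
dispersion; a warning fires above 10 % relative dispersion. On noiseless
data the estimate is set-point-invariant to 10⁻⁹ min, as it must be for a
material property.

For stacked recordings the fit uses the liner-interface channel T₂ and its
own asymptote T₂ss — never the outer surface — because the predictive model
consumes liner temperature.

## GP regression with the length scale clamped to τ

Model: y = f(x) + ε with f ~ GP(0, θ₁ exp(−d²/2l²)) after subtracting the
training-target mean (skin sits near 30–34 °C; a zero-mean prior would
distort extrapolation, and the offset is restored at prediction).
Hyperparameters:

| parameter | meaning | default / treatment |
|---|---|---|
| l | kernel width | **clamped** to the stack's τ (5.4, 6.7, … — dimensionless numeric clamp; l multiplies squared °C differences while τ is in minutes, and the clamp is applied literally as the method prescribes) |
| θ₁ | signal variance (°C²) | fitted, init 1, bounds 10⁻⁶–10⁶ |
| σ_n² | noise variance (°C²) | fitted, init 0.01, same bounds |

θ₁ and σ_n² are optimised in log space by L-BFGS-B with analytic evidence
gradients (max 200 iterations, gradient tolerance 10⁻⁶); if the optimiser
returns a worse evidence than the initial point, the initial point is kept,
so the fitted evidence never falls below the starting value. Cholesky
factorisation uses a jitter ladder 10⁻¹⁰ → 10⁻⁸ → 10⁻⁶ before raising,
reporting the smallest eigenvalue on failure. The predictive variance is
(θ₁ + σ_n²) − k*ᵀC_N⁻¹k* — the *noisy-observation* variance — and the 95 %
band uses the Gaussian 1.96 multiplier. Lateral and medial sites are fitted
as separate models. The input is deliberately one-dimensional (liner
temperature): adding a second input such as elapsed time would require its
own length scale and break the single physical clamp l = τ that defines the
method.

## Synthetic trial generator

The generator emulates the 35-min chamber protocol: rest 10 min, treadmill
walk 10 min, rest 15 min, sampled at 0.5 Hz, four channels (skin and liner,
lateral + medial), chamber ambients 10/15/20/25 °C at 40 % humidity
(metadata). Within each phase the skin relaxes exponentially toward a phase
equilibrium with a physiological time constant of 8 min; walking raises the
equilibrium by 1.5 °C. Defaults, chosen once to keep traces in the observed
30–34 °C band:

* resting skin equilibrium 30.5 + 0.06·ambient °C (31.1 °C at 10 °C,
  32.0 °C at 25 °C);
* donning offset −0.3 °C (the limb starts marginally below its resting
  equilibrium);
* default ambient 20 °C (standard room temperature; all four chamber
  settings are supported);
* liner drive = 0.6·skin + 0.4·ambient (the liner-socket interface sits
  roughly midway between skin and surroundings), lagged first-order with
  the stack's combination τ, liner starting at ambient (the prosthesis was
  off before donning);
* lateral/medial offset 0.3 °C; i.i.d. Gaussian noise sd 0.1 °C on every
  channel.

Integration is exact per-sample exponential stepping with zero-order hold
of the coupling, so identical seeds give bit-identical recordings. The 5-s
time averaging applied to recordings uses non-overlapping blocks of
floor(window × rate) samples (2 samples at 0.5 Hz, so 1050 → 525), block
times being the mean of member times; the trailing partial block is
dropped.

Every generator parameter is recorded in the `truth` mapping and the
noise-free channels are kept alongside the noisy ones, which is what allows
model error to be measured against ground truth.

### What the generator does and does not show

The generator reproduces the qualitative structure of real trials — liner
follows skin with a positive lag, colder chambers give colder limbs,
activity raises skin temperature — so passing tests demonstrate that the
pipeline (τ estimation → clamped-l GP → intervals) is internally sound and
achieves ≤ 0.5 °C worst-case error and ~95 % coverage *under these
dynamics*. It does not emulate sweating/evaporation, gait oscillations,
sensor drift or inter-subject variability, so those numbers are not claims
about any particular subject population.

One structural property matters for interpretation: because the liner lags
the skin by the stack τ (≈ 5.4 min), the liner→skin relation is not exactly
a function — rising and falling branches differ (hysteresis), worst just
after activity stops. A single-input GP can only fit the central curve, so
~0.2 °C rms of branch separation is absorbed into the fitted σ_n (typically
0.21–0.23 °C against 0.1 °C of generator channel noise, i.e. slightly more
than twice the injected sd — the remainder being propagated input noise and
hysteresis). The intervals remain well calibrated (~95 % coverage) because
the inflated σ_n correctly prices the total predictive uncertainty. When
model accuracy is scored against the *noise-free* truth, the posterior mean
is evaluated at the noise-free liner inputs, so that measurement noise on
the test inputs is not charged to the model.

## Numerical conventions

* Trace CSVs: header `time_s,<channel>,...`, UTF-8, decimal point; floats
  written with 17 significant digits so round trips are exact; uniform time
  step enforced on read (10⁻⁹ relative).
* Model files: versioned JSON (hyperparameters, training data, mean
  offset); the factorisation is rebuilt deterministically on load, so
  reloaded models predict identically.
* Problem sizes used in the shipped checks: bench traces of 900–1800
  samples (30–60 min at 0.5 Hz), 20-seed noise ensembles, trials of 1050
  samples averaged to 525, and 10-trial coverage pools — sizes at which
  every quantity is stable to well inside its tolerance.
* Degenerate inputs fail loudly: constant training inputs, non-decaying
  deficits, tails still drifting, fewer than 3 usable samples, non-PD
  covariances after the jitter ladder.

## Known limitations

* The loss coefficient (0.15) and stack outer-node attenuation (0.85) are
  uncharacterised placeholders; they shape simulations only, not
  estimation.
* The numeric clamp l = τ mixes units (°C vs minutes) by construction; the
  method inherits this deliberately and it is documented rather than
  "fixed".
* Only two-layer stacks are modelled; three-layer builds (e.g. with a
  stump sock) are not.
* Cooling-phase (doffing) analysis and perspiration physiology are out of
  scope.
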