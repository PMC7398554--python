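# Methods

## Circuit and equations

The model describes a tonotopic population of N = 5 LSO neurons. Each band
receives ipsilateral excitation directly and contralateral excitation relayed
through an MNTB population that converts it into inhibition. Three coupled
first-order ODEs govern each band (see README for the equations):

* **LSO membrane `r`** — leaky integrator with an excitatory conductance term
  `(beta_r - r) E` and a mixed subtractive/shunting inhibitory term
  `(gamma_r + kappa_r r) I`. For inputs in `[0, 1]` the drift points inward
  at `r = beta_r` and at `r = -gamma_r / kappa_r`, so the state stays in
  `[-0.75, 1.0]` under the default parameters (asserted in the property
  suite).
* **MNTB relay `q`** — linear low-pass of the contralateral drive; its
  half-wave rectified rate `g_q(q) = max(q, 0)` drives the inhibition.
* **GABA receptor activation `p`** — slow variable (`tau_p = 2500` model
  time constants vs `tau_r = 0.025`) charged by the neuron's own activity.
  The effective synaptic kernels are multiplied by `clip(1 - lambda p, 0, 1)`
  per band, so GABA can silence an input but never invert it. `p` is clamped
  non-negative: hyperpolarized episodes do not build up "negative
  adaptation".

Connection kernels are Gaussians over the integer band distance
(`sigma_ee = 0.5`, `sigma_ei = 0.6`, `sigma_ie = 0.1`), row-normalized so a
uniform drive excites every band identically. This normalization makes the
closed-form steady states exact for uniform stimuli and is what the
integrator oracles in the tests rely on. The inhibitory kernel additionally
carries a constant per-entry offset `delta_r = 0.16` (broad unspecific
inhibition; a unit row then sums to `1 + 5 * 0.16 = 1.8`).

The GABA equation is driven by the raw membrane state `r`, not the firing
rate; `ModelParameters(gaba_rate_driven=True)` switches to the rate-driven
variant for comparison.

All default parameter values live in `lsoadapt.params.ModelParameters`.

## Time bases and integration

All dynamics are integrated with explicit Euler. Rate constants are
expressed per *model second*; the calibration used throughout maps one model
second to 0.1 s of wall-clock time. The default step `dt = 0.001` model s
(0.1 ms wall) resolves the fast dynamics by a factor 25 relative to
`tau_r = tau_q = 0.025`. With this calibration the standard protocols come
out right: a 1.2 s adapter is 12 000 steps, the 100 ms readout delay is
1 000 steps, and a 400-step staircase plateau (40 ms wall, 16 effective time
constants) converges to steady state to better than 1e-6.

The onset-timing experiment (exp4) cannot work on that time base: with a
2.5 ms membrane constant, onset offsets of a few hundred µs are invisible.
Exp4 therefore runs on a dedicated fast time base in which one Euler step of
the same numeric size represents 10 µs of wall time, i.e. `tau_r` corresponds
to 250 µs. This is the regime in which level-dependent latencies of
10 µs/dB and ITDs of hundreds of µs interact with the membrane integration
window, and it reproduces the intended tens-of-dB transient shifts.

## Experiments

* **exp1 — static response.** Descending staircase over 41 ILDs
  (+40 → −40 dB, 400 steps per plateau), GABA disabled; plateau-end readout
  of the middle band. Parameter sweeps over `gamma_r ∈ [0, 3.5]` and
  `kappa_r ∈ [0, 14]`. The "zero-response point" is the first ILD whose rate
  exceeds the resting rate `g_r(0) ≈ 0.018` by a small margin (threshold
  0.02): subtractive inhibition (`gamma_r`) moves it, shunting inhibition
  (`kappa_r`) does not, while both move the point of steepest slope.
* **exp2 — GABA effectiveness sweep.** For each `(lambda_E, lambda_I)` on a
  21×21 grid (resolution 0.05), condition the network with a 1.2 s adapter at
  +40 dB ILD (10 ms ramps) plus 0.5 s silence, then measure the test response
  curve (readout 100 ms after test onset) and its peak coding precision. The
  ridge is the per-`lambda_E` argmax over `lambda_I` (ties resolve to the
  smallest `lambda_I`); a least-squares line through the ridge gives slope,
  intercept, and the implied effectiveness ratio. The adaptation range is
  then measured along the fitted ridge line.
* **exp3 — adapter-tone paradigm.** 41 adapter × 41 test ILDs (1 681
  arrangements): 1.2 s adapter, 0.5 s silence, 2 s test, readout 100 ms after
  test onset. Each adapted response curve is compared against the no-adapter
  reference measured with the identical readout rule. Positive (ipsilateral)
  adapters shift the precision peak toward the adapter by up to ~5.2 dB and
  raise the precision at the adapted peak location by >170 % relative to the
  unadapted curve there; negative adapters produce no shift.
* **exp4 — onset timing.** Constant binaural drives with per-channel onset
  shifts on the fast time base: the contralateral onset is delayed by −ITD,
  and each channel's onset is advanced by 10 µs per dB of its own level.
  ITD grid −800…+400 µs (50 µs spacing), ILD grid −40…+40 dB. The transient
  is summarized by the maximal rate over the trace ("peak" readout); the
  final steady rate is kept as the "steady" readout. The steady response is
  onset-independent, so the zero-ITD steady slice reproduces the exp1 default
  curve exactly (cross-experiment invariant, checked to 1e-3 by the CLI and
  in tests); for the same reason all ITD effects live in the transient, and
  the unadapted reference for shift measurements is the steady default curve.
  Contralateral-leading ITDs release the transient from inhibition and shift
  the precision peak by ~37 dB across the grid; the criterion-point (rate
  0.5) displacement between ITD −600 µs and the reference yields a
  time–intensity trading value of ~15 µs/dB.
* **fig5 — comparison.** Maximal precision-peak shifts and sensitivity gains
  of the two mechanisms side by side, plus their summed operative range
  (~43 dB).

## Analysis definitions

* **Coding precision** — central-difference derivative of the rate-vs-ILD
  curve on the interior grid; the peak location carries a 3-point parabolic
  sub-grid refinement (exact for cubic response data), the peak value is the
  discrete maximum.
* **Shift / gain** — displacement of the precision peak vs a reference
  curve; gain is the relative change of precision (peak-to-peak, or local at
  a fixed ILD where stated).
* **Trading value** — |ΔITD| / |Δ(criterion ILD)| between two conditions,
  with the criterion point defined as the rate-0.5 upward crossing (linear
  interpolation).
* **U/V curvature** — the rate-vs-ITD section at ILD −20 dB falls from a
  released response at negative ITDs to the suppressed floor; the
  negative-ITD limb ends in a sharp elbow (larger maximal second difference,
  V-like) while the positive-ITD limb is smooth (U-like).

## Limitations

The implementation reproduces the static response structure, the
adapter-tone adaptation, and the timing-induced trading quantitatively, but
several published headline numbers do not emerge from the stated protocols:

1. **Peak-sensitivity location.** The default curve's precision peak sits at
   22.4 dB ILD, not 25 dB. The zero-response point (10 dB), curve shape and
   all parameter-sweep trends match.
2. **GABA effectiveness ridge.** The (lambda_E, lambda_I) precision map is
   dominated by cells whose adapted curves peak *because* inhibition is
   suppressed, and its per-column argmax sits at `lambda_I ≈ 0` nearly
   everywhere. No conditioning protocol we evaluated produces the published
   diagonal ridge (slope 0.80, intercept −0.06) or a saturation point near
   `lambda_E = 0.71`; the sweep, fit and saturation analysis are implemented
   faithfully and report what the model actually does.
3. **Ipsilateral timing shift.** With sustained stimuli, an
   inhibition-leading (positive) ITD suppresses the transient but cannot
   displace the curve by a further +2 dB; the measured ipsilateral shift is
   ~0. A positive shift of that size does appear for pulsed (click-like)
   stimuli, which the default protocol does not use.
4. **ITD sensitivity gain.** The maximally shifted transient curve is
   shallower than the steady reference, so its peak precision is lower
   (−44 %), not 106 % higher. Comparing instead against the reference
   precision at the shifted location (deep in the reference's silent region)
   produces an arbitrarily large number; neither reading yields ~106 %.

The corresponding acceptance tests are left failing rather than weakened,
and `scripts/acceptance.py` reports the recomputed values unmodified.
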