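# lsoadapt

A deterministic rate model of sound-source lateralization in the lateral
superior olive (LSO), with two adaptation mechanisms layered on top of the
static circuit:

1. **Retrograde GABA signaling** — activity of an LSO neuron builds up a slow
   presynaptic signal `p` that attenuates the neuron's own excitatory and
   inhibitory afferents, shifting its response curve toward recently heard
   interaural level differences (ILDs).
2. **Onset-timing (time–intensity trading)** — level-dependent transmission
   latencies and interaural time differences (ITDs) change how much the
   contralateral inhibition overlaps the excitatory onset, shifting the
   transient response curve by tens of dB.

## The model

Five tonotopic bands, three state variables per band:

```
tau_r dr/dt = -alpha_r r + (beta_r - r) * E  - (gamma_r + kappa_r r) * I
tau_q dq/dt = -alpha_q q + beta_q * (contra drive)
tau_p dp/dt = -alpha_p p + (beta_p - p) * r        (p clamped >= 0)
```

with

* `E = clip(1 - lambda_E p, 0, 1) * (ipsi drive through the E-E kernel)`
* `I = clip(1 - lambda_I p, 0, 1) * (rectified q through the E-I kernel + delta_r)`
* firing rate `g_r(r) = 1 / (1 + exp(-(r - b) a))`, MNTB rate `g_q(q) = max(q, 0)`.

`r` is the LSO membrane state, `q` the MNTB relay that converts contralateral
excitation into inhibition, and `p` the slow GABA receptor activation.
The `gamma_r` term is subtractive inhibition, the `kappa_r r` term is shunting
(divisive) inhibition. Kernels are row-normalized Gaussians over integer band
distance. Sound levels in `[0, 40]` dB map linearly onto drives in `[0, 1]`;
an ILD around a 20 dB base level splits as `ipsi = 20 + ILD/2`,
`contra = 20 - ILD/2`.

Integration is explicit Euler. The model is fully deterministic: no random
numbers are consumed anywhere (the CLI flag `--seedless` asserts this).

### Time bases

One model second corresponds to 0.1 s of wall-clock time; the default step
`dt = 0.001` model s therefore represents 0.1 ms. The onset-timing experiment
(exp4) runs on a dedicated fast time base in which one Euler step represents
10 µs, putting the membrane time constant in the few-hundred-µs range where
sub-millisecond onset timing matters. See `docs/methods.md` for the full
rationale.

## Worked example

```python
import numpy as np
from lsoadapt import (DEFAULTS, default_response_curve, coding_precision,
                      run_exp3)

# static response curve of the middle neuron, GABA disabled
curve = default_response_curve()          # 41 ILDs from -40 to +40 dB
cp = coding_precision(curve)              # derivative of rate vs ILD
print(cp.peak_ild)                        # ILD of maximal sensitivity

# adapter-tone experiment: a 1.2 s adapter at +40 dB ILD shifts the
# precision peak toward the adapter
res = run_exp3()
shifts = [m.shift_db for m in res["measurements"]]
print(max(shifts))                        # ~5.2 dB shift toward the adapter
```

Command line:

```bash
lsoadapt exp1 --out results            # gamma_r / kappa_r parameter sweeps
lsoadapt exp2 --out results            # (lambda_E, lambda_I) precision map
lsoadapt exp3 --out results            # 41x41 adapter/test paradigm
lsoadapt exp4 --out results            # ILD x ITD timing experiment
lsoadapt fig5 --out results            # GABA vs timing comparison
lsoadapt all  --out results --seedless
```

Each run writes CSV tables plus a `manifest.json` holding the exact
parameters, configuration and invariant-check results; the exit code is 0
only if all internal invariant checks pass. A YAML config (`--config`) can
override parameters (`params:` mapping) and grids; `--override key=value`
overrides single model parameters.

## Package layout

| module | contents |
| --- | --- |
| `lsoadapt.params` | `ModelParameters` (frozen dataclass, YAML round-trip) |
| `lsoadapt.kernels` | Gaussian kernels and GABA-modulated effective kernels |
| `lsoadapt.dynamics` | drift terms, nonlinearities, closed-form steady states |
| `lsoadapt.stimuli` | level map, staircase / adapter-test / ITD protocols |
| `lsoadapt.simulation` | Euler integrator, trajectories, readout policies |
| `lsoadapt.analysis` | response curves, coding precision, ridge fit, trading value |
| `lsoadapt.experiments` | batched end-to-end runners for exp1–exp4 and fig5 |
| `lsoadapt.cli` | `lsoadapt` command-line interface |

## Tests and acceptance targets

```bash
python -m pytest                                  # full suite
python scripts/acceptance.py --seed 0 --out targets.json
```

`scripts/acceptance.py` recomputes every quantitative acceptance target from
scratch (a few seconds). `tests/test_acceptance.py` holds one test per
external acceptance criterion; four of them encode published claims that this
implementation does not reproduce and are left failing deliberately rather
than weakened — see `docs/methods.md` (Limitations) for what holds and what
does not.
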