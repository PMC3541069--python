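# Methods

## The forward model

One heartbeat's worth of physics: the arterial pressure waveform sets the
transmural pressure across the compressed artery segment; the segment's
volume follows instantaneously from the bi-exponential pressure–volume law;
the volume pulse compresses the sealed air in the cuff, whose Boyle's-law
compliance converts it into the millimetre-of-mercury-scale oscillation a
device records.

The governing equation for gauge cuff pressure `P` during a deflation at
bleed rate `r` from starting pressure `P0` is

    dP/dt = −r + (P0 + 760 − r·t)/V0 · dVa/dt,
    dVa/dt = Ca(Pt) · (dPa/dt + r),      Pt = Pa(t) − (P0 − r·t),

where `Ca` is the artery's dynamic compliance (`a·Va0·e^{a·Pt}` collapsed,
`a·Va0·e^{−b·Pt}` distended) and `Pa` the Fourier waveform. Two closure
choices are deliberate:

* **The artery feels the ramp, not the oscillations.** Transmural pressure
  uses the smooth deflation `P0 − r·t`; the sub-mmHg oscillations the
  artery itself generates are neglected in its forcing. This makes the
  right-hand side a pure function of time, so the forward Euler recursion
  is an exact cumulative sum — fast and free of feedback stiffness.
* **The cuff-compliance factor uses the ramp pressure** (`P0 + 760 − r·t`)
  rather than the evolving `P`, consistent with the first choice.

A consequence worth knowing: because the artery slowly refills as the cuff
deflates (net `Ca·r` per unit time), the integrated cuff pressure ends a
40 s run about 3.6 mmHg *above* the nominal ramp. A real device does not
show this secular drift — its bleed valve is regulated against the measured
pressure — so the envelope extraction uses the deflation schedule, not the
drifted integral, as the beat's pressure coordinate whenever the recording
carries its scenario metadata. For external recordings (no schedule) the
per-beat mean of the measured pressure is used, which is correct for real
valves. Using the drifted coordinate on simulated runs would shift the
diastolic estimate by about +2 mmHg and the tail log-slope by +0.002/mmHg.

### Parameters and defaults

| parameter | meaning | default | unit | rationale |
|---|---|---|---|---|
| `a` | collapse-branch exponent | 0.11 | 1/mmHg | `ln(0.1)/(−20 mmHg)` |
| `b` | distension-branch exponent | 0.03 | 1/mmHg | from `Cn = 0.0016 ml/mmHg` at 100 mmHg |
| `Va0` | zero-pressure segment volume | 0.3 | ml | 0.1 cm radius × 10 cm cuff-width segment |
| `V0` | cuff air volume | 300 | ml | 30×10×1 cm bladder; scales amplitude only |
| `P0` | inflation pressure | 150 | mmHg | standard run start |
| `r` | bleed rate | 3 | mmHg/s | standard clinical deflation |
| `f` | heart rate | 4/3 | Hz | 80 beats/min |
| SBP/DBP | true pressures | 120/80 | mmHg | normal scenario |
| `dt` | Euler step | 5·10⁻⁴ | s | first-order method; resolves the stiff collapse exponential; halving it moves no sample by more than 0.01 mmHg |
| duration | run length | 40 | s | 150 mmHg down to 30 mmHg at 3 mmHg/s |

The waveform's nominal SBP/DBP label its construction; its true extremes
are `mean ± 0.4995·PP` (the three-harmonic shape's maximum is 1.3876, not
exactly 25/18), i.e. 119.98/80.02 for the normal case. No correction is
applied; estimation errors are quoted against the nominal labels.

## Oscillation extraction

The high-pass filter subtracts each pressure sample from the centered mean
over exactly one beat period (trapezoidal discrete mean, so an exactly
periodic signal and any linear trend are removed identically); samples
within half a beat of either end are undefined. Beats are consecutive
windows of one period — phase-aligned for simulated data, anchored at the
first oscillation zero-crossing for external data — and any beat touching
undefined filter samples is dropped.

Per-beat amplitude definitions (`extract_envelope(amp_method=...)`):

* `ptp` (default): max − min of the filtered oscillation in the beat. This
  is the definition used throughout the validation suite.
* `harmonic`: max − min after projecting the beat's oscillation onto the
  first 8 harmonics of the beat frequency. In the envelope's head and tail
  every beat's oscillation is a beat-constant times one fixed waveform
  shape, so any scale-equivariant amplitude leaves the semi-log slopes and
  the normalised envelope unchanged; projection merely rejects broadband
  noise. Noise-free it agrees with `ptp` to ~1 %; with 0.02 mmHg white
  measurement noise it keeps the recovered pressures within 1 mmHg of the
  noise-free result, whereas `ptp` (an extreme-value statistic) inflates
  the ~0.05 mmHg head amplitudes and shifts SBP by 5–6 mmHg.
* `area`: mean |oscillation| per beat (the pulse-area envelope), offered as
  the classical alternative; not used by default.
* `cuff_range`: max − min of the *raw* cuff pressure per beat. This
  includes the ramp's 2.25 mmHg fall across the beat and is how envelope
  figures are conventionally drawn; it is used only for the
  characteristic-ratio sweep, never for estimation.

## The inverse algorithm

1. **Stiffness regressions.** In the head of the envelope (cuff well above
   systolic) amplitude ∝ `e^{−aP}`; in the tail (cuff below diastolic)
   ∝ `e^{+bP}`. The head range runs from the first beat to the first beat
   reaching ⅓ of the peak height; the tail from the last beat above ⅔ of
   the peak to the end. These height rules keep both ranges inside the pure
   collapse/distension domains and are deterministic under noise; an
   inflection-point range detector is available behind
   `fit_stiffness(method="inflection")`. Both regressions are ordinary
   least squares of log amplitude on beat pressure; beats with
   non-positive amplitude are dropped and counted. The lumped intercepts
   (`ln k1`, `ln k3`) are reported as diagnostics only.

   Known bias: the true head/tail relations carry an extra factor
   `(P+760)` from the cuff compliance, tilting the fitted slopes by about
   `1/(P+760) ≈ 0.0012`/mmHg (`â` low, `b̂` high by that amount). The
   grid search, which includes the factor, absorbs most of it; no
   correction is applied to the regressions themselves.

2. **Envelope matching.** For candidates SBP > DBP on a 1 mmHg lattice
   (diastolic from 10 mmHg below the lowest beat pressure up to the
   envelope-peak pressure; systolic from the peak pressure to 10 mmHg
   above the highest beat pressure) the predicted envelope is evaluated at
   the observed beat pressures, both envelopes are normalised by their
   maxima over those beats, and the sum of squared differences is
   minimised. Ties break toward the smallest pulse pressure, then the
   smallest systolic value. A degenerate candidate whose predicted
   envelope underflows to zero scores +inf rather than raising. The
   surface, grids and regression diagnostics are returned with the
   estimate.

## Validation suite and characteristic ratios

Five noise-free scenarios: normal; both exponents ÷1.44 ("twice normal
stiffness") and ×1.44 ("half normal stiffness") at 120/80; and the normal
artery at 110/90 and 140/60. Across the suite the estimator recovers SBP
within 2 mmHg and DBP within 1 mmHg, and the exponents within 0.01 (`a`)
and 0.005 (`b`). The classical fixed-ratio baseline (50 % rising / 70 %
falling) is computed on the same envelopes for comparison and loses the
diastolic point by 4–12 mmHg as stiffness varies.

The characteristic-ratio sweep is a separate study: stiff (exponents ÷2),
normal, compliant (×2) arteries at 120/80, with the figure-style
`cuff_range` envelope against measured beat-mean pressure. Under that
convention the diastolic oscillation ratio falls from ≈95 % through ≈89 %
to ≈78 % — the stiffness sensitivity that motivates model-based
estimation. The ratio values depend visibly on the envelope convention
(filtered-oscillation envelopes give a narrower spread, ≈90/87/84 on the
schedule axis), which is worth remembering when comparing published ratio
figures extracted under unstated conventions; the sweep factor and
envelope mode are both arguments.

## What the simulator does and does not emulate

It emulates: the nonlinear collapse/distension mechanics that shape the
envelope, Boyle's-law cuff stiffening during deflation, deterministic beat
timing, and optional additive white Gaussian measurement noise. It does
not emulate: beat-to-beat variability or arrhythmia, respiratory
modulation, viscoelastic/hysteretic wall behaviour (the P–V law is
memoryless), motion artifact, analog device filtering beyond the
moving-average subtraction, or cuff–arm coupling losses (these scale
`Va0/V0` and cancel in the normalised fit). Passing tests therefore show
the algorithm is correct *under the model's physics*; they do not
establish clinical accuracy, which requires intra-arterial comparison
data.

## Numerical notes and limitations

* The branch point `Pt = 0` belongs to the distension branch; volume and
  compliance are continuous there, so the assignment is inconsequential.
* `derive_a`/`derive_b` keep full precision (`ln 0.1 = −2.302585…`);
  rounding happens only in display.
* Euler integration is first order; the default step gives ≤0.01 mmHg
  sample error (verified against a halved step). The integration is a
  cumulative sum, so runs are bitwise reproducible.
* The estimator needs at least 3 usable beats in each regression range;
  short runs, very slow heart rates, or envelopes whose peak sits at the
  edge of the pressure support raise informative errors.
* The grid search is the method; no continuous refinement is applied by
  default, so estimates are quantised to the grid step.
* With pulse pressures far above normal the head region shortens (fewer
  fully-collapsed beats) and `â` degrades first; the 140/60 scenario's
  2 mmHg systolic error is the suite's worst case.
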