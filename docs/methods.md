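# Methods

`hippoquant` quantifies the two experiment families of a typical hippocampal
slice study — whole-cell current-clamp measurements of intrinsic
excitability and extracellular field-potential measurements of synaptic
transmission and plasticity — together with the companion molecular assays
(qPCR relative expression, Western-blot densitometry, synaptic-marker
immunofluorescence). Every analysis stage has a synthetic counterpart with
known ground truth, so the whole pipeline is testable without recordings.

## Data model and units

Canonical internal units are mV (voltage), pA (current), ms (waveform
features) and s (epoch/stimulus times); readers convert on ingest
(V → mV, nA → pA, ms time columns → s). Sample `k` of a trace maps to
`t0 + k·dt`, and stimulus times refer to the onset of the stimulus
artifact. The shipped file dialect is delimited text plus a JSON sidecar
(sampling, units, channel roles, protocol); vendor episodic formats attach
through a reader registry and are otherwise out of scope. A time column,
when present, must agree with the declared sampling interval to within
1% of `dt` per step; larger jitter is treated as a resampled or corrupt
file and rejected.

## Model neuron

The synthetic cell is an adaptive-exponential integrate-and-fire (AdEx)
neuron integrated by fixed-step Euler at `dt = 0.05 ms` (a 20 kHz
acquisition rate):

    C dV/dt = −g_L (V − E_L) + g_L Δ_T exp((V − V_T)/Δ_T) − w + I(t)
    τ_w dw/dt = a (V − E_L) − w

with `g_L = 1/R`. When V crosses `V_peak` the crossing sample is drawn at
`V_peak`, V resets to `V_reset` and `w` increments by `b`. Defaults
(`E_L = −73 mV`, `R = 200 MΩ`, `C = 80 pF`, `V_T = −50 mV`,
`Δ_T = 2 mV`) approximate a CA1 pyramidal cell with `τ_m = 16 ms`. With
`a = b = 0` and small `Δ_T` the model is leaky integrate-and-fire; the
subthreshold step response then matches the analytic RC solution and the
quasi-static ramp rheobase is `(V_T − E_L)/R` plus a ramp-rate × τ_m lag.
The exponential argument is clipped at +30 to avoid overflow; an Euler
step that lands above `V_peak` is the (clipped) spike upstroke, not an
integration failure. Recording noise is added to the integrated trace
(not into the dynamics), so a seed controls the noise exactly and the
trajectory is identical across noise levels.

Note one boundary case of the standard ramp: a cell with
`(V_T − E_L)/R = 100 pA` reaches its quasi-static rheobase only at the
final sample of the 0→100 pA/2 s ramp, and the membrane lag then pushes
the first spike past the ramp end. Closure tests therefore use a cell
whose analytic rheobase (80 pA) sits comfortably inside the ramp; cells
that do not fire during the standard ramp report a spike count of zero
and an undefined rheobase, and rheobase values obtained with steeper
ramps may be pooled into rheobase summaries but never into spike-count
summaries.

## Intrinsic-excitability measurements

* **RMP** — mean voltage over a pre-stimulus window of at least 100 ms.
  The window must not overlap injected current, and spike-sized excursions
  (dV/dt criterion plus a 20 mV amplitude demand above the window median,
  so broadband noise alone cannot trigger it) mark the baseline as
  contaminated.
* **Spike detection** — upward crossings of a dV/dt criterion
  (default 20 mV/ms) with a 2 ms refractory period; requires
  `dt ≤ 0.1 ms`. Each detection yields a segment spanning
  [peak − 5 ms, peak + 20 ms].
* **AP threshold** — the phase-plane method: form dV/dt as a function of V
  on the upstroke (segment start to the dV/dt maximum) and take V at the
  maximum slope of that curve. Numerical choices: the segment is smoothed
  with a 5-sample Savitzky–Golay filter (order 3), spline-refined 10×
  before differencing (at 20 kHz the voltage advances several mV per
  sample mid-upstroke, so raw finite differences cannot localize the
  inflection), and the analysis stops once dV/dt exceeds a 50 mV/ms
  ceiling — beyond the initiation region the sample spacing in V no
  longer constrains the curve, and for an exponential-upstroke model the
  slope maximum would otherwise sit at a resolution-dependent edge. A
  phase plane whose dV/dt spans less than 10 mV/ms (e.g. a linear ramp)
  has no threshold and is reported as degenerate.
* **AP features** — amplitude is threshold-to-peak; half-width is the time
  between the two crossings of threshold + amplitude/2 with linear
  interpolation between samples; maximal rise slope is the dV/dt maximum
  on the upstroke; the fast afterhyperpolarization is the strict interior
  minimum within 20 ms after the peak, reported as depth below threshold
  and delay from the peak, and flagged absent when the trace decays
  monotonically through the window. Threshold-referenced amplitude and
  fAHP, and peak-referenced fAHP delay, are conventions chosen here; the
  alternatives (baseline-referenced amplitude, repolarization-referenced
  delay) are not exposed.
* **Ramp analysis** — spike count restricted to the ramp epoch; rheobase
  is the injected current at the first spike's dV/dt-criterion crossing
  under the linear time→current map. Features of the first AP in the
  ramp-evoked train are the per-cell defaults.
* **Passive properties** — from a subthreshold current step:
  `R_N = ΔV/ΔI` at steady state (last quarter of the step),
  `τ_m` from a single-exponential fit to the relaxation, `C_m = τ_m/R_N`.
  Capacitance from voltage-clamp membrane-test transients is deliberately
  not implemented; the amplifier's membrane-test algorithm is
  instrument-defined, whereas the τ/R route is fully specified by the
  trace.

## Short-term plasticity model

The synthetic synapse follows a Tsodyks–Markram-style recurrence with
utilization `u` (facilitation, decay `τ_f`) and resources `R`
(depression, recovery `τ_d`). The state-update order is fixed and
documented because conventions differ: read the response `u_n·R_n`,
facilitate `u ← u + U(1 − u)`, deplete `R` by the *read* fraction
`u_n·R_n`, then decay both toward rest until the next pulse. Amplitudes
are reported relative to the first pulse. With `U = 1` the train is
purely depressing; when the inter-stimulus interval is long against both
time constants every amplitude returns to 1. The biphasic envelopes seen
in some augmentation experiments are not parameterized; the renderer's
per-pulse amplitude vector is the hook for composing such shapes
externally.

## Field-potential rendering and measurement

Each stimulus renders a brief biphasic artifact (0.1 ms per phase), a
Gaussian fiber volley (default 0.5 mV trough, the amplitude conventionally
targeted during 0.1 Hz baseline stimulation of FV-isolated recordings)
and a negative difference-of-exponentials fPSP (rise 1.5 ms, decay 8 ms,
closed-form peak) scaled by the pulse's relative amplitude. Ground-truth
landmark times and amplitudes accompany every sweep. Gaps longer than 2 s
between stimuli split the render into separate sweeps.

Measurement conventions: FV amplitude is pre-stimulus baseline to trough
(magnitude positive); fPSP amplitude is baseline to extremum; the slope is
a least-squares line through the samples between 20% and 80% of the peak
on the rising phase of the response magnitude, exactly invariant to
vertical offset and time shift. The baseline is taken before the first
stimulus of a sweep (later pre-stimulus spans in a train are contaminated
by preceding responses), and the fPSP peak is the largest *interior*
local extremum of its window so that the decaying FV tail at the window
edge cannot masquerade as a tiny response. Overlapping responses at short
intervals are handled by sequentially subtracting a scaled template of
the measured response (template from a baseline average, scaled by each
pulse's measured amplitude); this is switchable to raw measurement.
Paired-pulse ratios use amplitudes, input–output curves use amplitudes,
and long-term plasticity time courses use slopes. Train facilitation is
normalized to the pre-train 0.1 Hz baseline mean, not to the first pulse
of the train; both choices appear in the literature and the baseline
reference keeps first responses near 100%.

Plasticity time courses normalize to the baseline-epoch mean (the
baseline is then 100% by construction), summarize configured post-
induction windows (e.g. 51–60 min after high-frequency stimulation,
41–50 min after a 5 Hz train, 35–40 min after low-frequency stimulation)
as mean ± SEM over sweeps, and summarize induction-period responses
separately. A baseline whose linear drift exceeds 5% per 10 min is
flagged unstable rather than rejected. Fiber-volley trajectories
normalize the same way, excluding (and counting) sweeps below a noise
floor; their summary windows (last 5 min of LFS, 35–40 min post-LFS) may
lie inside the induction epoch, so they are checked against the full
recording span.

## Molecular and imaging quantification

* **2^−ΔΔCq** — technical replicates average on the Cq scale before any
  exponentiation; ΔCq = target − reference gene per sample; ΔΔCq is
  anchored to the mean ΔCq of a named reference group (a group-level
  anchor, so the reference group's folds have geometric mean 1); 100%
  amplification efficiency is assumed throughout. The estimate is
  invariant to any global Cq offset.
* **Densitometry** — per-lane ratio of background-corrected target OD to
  background-corrected β-actin OD; technical replicates average per
  sample before group statistics. The documented contract: the ratio is
  invariant to rescaling all four ODs of a lane together.
* **VGLUT1/MAP2 ratio** — total VGLUT1 intensity over pixels above the
  VGLUT1 threshold, divided by the count of pixels above the MAP2
  threshold. Thresholds are operator-chosen (blinded to condition) and
  recorded in the output; an automatic between-class-variance fallback
  exists for unattended runs and tests but is never the default. An
  option restricts the VGLUT1 sum to MAP2-positive pixels (puncta on
  identified neurites); the default takes the above-threshold sum over
  the whole frame. Any DAPI channel is ignored.

The image generator draws dilated random-walk dendrite skeletons as the
MAP2 channel and Gaussian puncta (σ = 1.5 px) centred on the mask as the
VGLUT1 channel, plus additive Gaussian background; the noiseless channels
are kept so above-threshold sums are exact for any threshold. It emulates
the intensity structure the ratio depends on, not optical realism: no
point-spread blur across channels, no uneven illumination, no
out-of-focus haze. Passing closure tests therefore validate the
arithmetic and threshold logic, not robustness to microscope artifacts.

## Statistics

Group values are reported as mean ± SEM with n, where the experimental
unit is the cell/slice/sample, never the sweep. Two-group comparisons use
the unpaired two-tailed Student t test with pooled variance at α = 0.05
(Welch behind a flag); three or more groups use one-way ANOVA followed by
Tukey's HSD. Degenerate zero-variance inputs follow explicit conventions
(equal means → p = 1; unequal → p = 0, flagged). Significance stars map
0.05/0.01/0.001. No multiplicity correction is applied across separate
comparisons by default, mirroring the per-comparison α convention of the
analyses this package serves; a Holm step-down helper is available.

## Determinism and problem sizes

Every stochastic routine takes an explicit seed; nothing touches global
RNG state, and the manifest runner records the configuration hash and
seed in its run log, so re-runs are byte-identical. The verification
suite uses desk-scale problem sizes chosen to exercise the protocols at
their stated settings: an 18-cell parameter-recovery grid, 24 synthetic
AP shapes for the threshold oracle, paired pulses at five ISIs and
100-pulse trains at five frequencies for two synapse types, hour-long
0.1 Hz plasticity series, 128×128 image pairs, and 10,000-replicate null
simulations for test calibration.

## Known limitations

* The AdEx spike is drawn as a clipped sample at `V_peak`; spike shape
  above the initiation region (and hence half-width of simulated APs) is
  not physiological. Constructed waveforms cover waveform-feature tests.
* Template subtraction assumes the response waveform scales linearly with
  its amplitude; strongly nonlinear overlap (e.g. population-spike
  contamination) is out of scope.
* The I-O curve uses monotone linear interpolation, not a sigmoid fit.
* qPCR efficiency correction, gel-band segmentation, puncta counting and
  colocalization are out of scope; ODs and Cq values are inputs.
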