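# Methods

## Scope and model overview

`neurotact` models a soft biomimetic fingertip scanning fine textures at
constant speed and the neuromorphic pipeline that turns its three sensor
channels into afferent activity and texture/speed classifications. All
data are synthetic: the simulator is a first-class, tested component that
emulates the statistical structure such a rig records, not a measurement
of any particular hardware.

## Texture and scan simulator

A texture is a 1-D height profile: a sum of sinusoidal components with
spatial periods 0.4–2.8 mm plus Gaussian broadband roughness. Ten default
textures (S1–S10) carry distinct period/amplitude/noise signatures;
single-period gratings, two- and three-component mixtures and one
noise-dominated surface. These are stand-ins with plausible fine-texture
geometry, not reproductions of physical samples. Periods below 0.4 mm are
avoided because at the fastest scan (90 mm/s) they would induce vibrations
above the 250 Hz analysis band-edge (and approach the 500 Hz Nyquist limit
of the 1 kHz acquisition).

Scanning at speed `v` maps spatial period `p` to temporal frequency `v/p`;
the simulator enforces the Nyquist condition per component and raises an
error naming the offending period otherwise.

Channel models:

* **Taxels** — each of the 64 taxels reads
  `indentation + contact_gain · profile(x_taxel(t))`, with taxel columns
  trailing along the scan axis by the 1.5 mm pitch and rows offset by a
  small fixed lateral jitter (≤ 15 % of the coarsest period) that emulates
  2-D surface irregularity while keeping the rows largely coherent, as
  naturalistic surfaces are across a 10.5 mm contact patch. The contact
  signal is low-pass filtered at 50 Hz (2nd-order Butterworth, zero-phase)
  to represent mechanical dispersion by the soft elastomer layer, then
  clipped to the sensor range [0, 1].
* **Piezo** — the time derivative of the aperture-weighted sum of the raw
  (unfiltered) contact signals, plus white noise at 1 % of signal RMS.
  The aperture is a Gaussian (σ = 2 taxels) slightly off the array centre;
  a perfectly centred symmetric aperture would cancel exactly any spatial
  period that divides twice the pitch (e.g. 3.0 mm), an artifact of
  perfect symmetry no physical mounting has.
* **Proprio** — a linear voltage ramp proportional to displacement
  (0.1 V/mm) with additive Gaussian noise at 0.5 % of range.

Per-trial seeds are SHA-256 hashes of (master seed, texture, speed,
repetition), so any trial is reproducible in isolation and datasets are
fully deterministic.

The default protocol mirrors the acquisition design the pipeline targets:
10 textures × 6 speeds (40–90 mm/s) × 10 repetitions at 1 kHz, 40 mm scan
length, baseline indentation 0.4 (normalised units; real contact forces
are not modelled, only controlled indentation).

## Innervation

`build_innervation` wires 12 SA-I and 24 RA-I afferents (1:2 ratio) to
connected neighborhoods of the 8×8 array. The total number of positive
weights is `round(target_mean × 36)`, split as evenly as integers allow,
so the realized mean density tracks the target; receptive fields grow by
seeded 8-neighborhood expansion from a random centre, preferring
not-yet-covered taxels. Orphan taxels are appended to the nearest (then
least-loaded) afferent so every taxel is innervated; at densities below
64/36 ≈ 1.78 this coverage guarantee necessarily lifts the realized mean
above the target — an arithmetic fact, not a tuning choice.

Weights are `max(0.001, u · min(1, m/4) · exp(−d/λ))` with `u ~ U(0.5, 1)`,
`d` the Chebyshev distance from the field centre, `λ = max(1, √m/2)` and
`m` the field size. The `min(1, m/4)` factor couples weight amplitude to
innervation density: sparse wiring produces dim, low-gain fields near the
0.001 floor, dense wiring bright high-gain centres. This coupling is what
makes very sparse innervation weakly informative (sub-rheobase drives) and
produces the interior optimum of classification accuracy versus density.

Drives: SA-I currents are the weighted raw taxel sums (static pressure);
RA-I currents are weighted sums of a dynamic component — the temporal
derivative band-passed 5–250 Hz and normalised by 2π·12.5 Hz, so vibration
amplitude in the drive grows linearly with frequency. A `ra_pathway="raw"`
switch feeds RA-I the same static signal as SA-I for ablation studies,
since how rapidly-adapting units derive their dynamic sensitivity from a
shared pressure array is a genuinely open modelling choice.

## Spike encoding

All tactile afferents use the Izhikevich neuron in regular-spiking mode
(a = 0.02, b = 0.2, c = −65 mV, d = 8 mV, spike at 30 mV) with the state
equations in the standard per-millisecond form, per-receptor gains
G = 1.3 / 17 / 2 kΩ for SA-I / RA-I / RA-II and Cm = 1 absorbing units.
Integration starts at the resting fixed point (−70 mV, −14), the solution
of `0.04v² + (5−b)v + 140 = 0` on its stable branch.

The integrator is an explicit-midpoint (RK2) scheme with 0.25 ms substeps
(input held constant within each 1 kHz sample). Threshold crossings are
located by linear interpolation inside the step and the post-reset
remainder of the step is integrated from the reset state; this keeps
spike-time error against a 10×-finer-step reference near 1 ms over 1 s
test currents, where a plain first-order step accumulates ~0.5 ms of phase
drift per spike. A divergence guard (|v| > 1000 mV) raises with advice to
reduce the step.

Unit seam: normalised channel values are interpreted against the 5 V
supply rail of a typical readout circuit before the receptor gains apply.
The piezo channel is normalised by a fixed 2.5 V reference (dataset-level)
rather than per-trial min–max, so vibration amplitude — which grows with
scanning speed and differs across textures — remains informative; the
per-trial min–max mode is also available. These scale constants are
calibration choices of the sensor-to-model interface, set so drives cross
the model's rheobase (G·I > 4) at moderate stimuli and firing rates land
in the tens-to-hundreds of spikes/s range.

Preprocessing contracts: piezo 5–250 Hz band-pass is an 8th-order
Butterworth (4 poles per band edge), applied zero-phase; −3 dB sits at
each corner of the designed filter, and DC rejection exceeds 60 dB. The
proprio channel is noise-filtered and affinely mapped so its minimum is
exactly 0.95 and maximum exactly 1.08 (normalised fascicle length). The
default noise filter is a 20 Hz low-pass (`smooth_only`): a literal 1 Hz
first-order high-pass (`highpass` mode, also provided) removes the slow
position trend that the spindle model needs, so the two requirements —
high-pass noise removal and absolute length preservation — cannot both be
met; the low-pass default resolves the tension in favour of the spindle's
input contract.

## Muscle spindle

Three intrafusal fibers share one rectified polynomial rate law

    rate = max(0, k_f·f + k_L·(L − 0.95) + k_V·sign(L̇)·|L̇|^0.3)

with fusimotor drive f = 70 spikes/s for both the dynamic (bag1) and
static (bag2, chain) systems. Bag1 carries the velocity term
(k_f = 0.15, k_L = 200, k_V = 100); bag2 and chain are length-only
(k_f = 0.10, k_L = 150, k_V = 0 each). L̇ is estimated by central
differences followed by a 20 Hz low-pass, since raw differencing at 1 kHz
amplifies sensor noise. The exponent 0.3 gives the familiar saturating
velocity sensitivity of primary endings. These fiber constants are
stand-ins chosen for plausible rate ranges on ramp-and-hold stretches
(tens of spikes/s at rest, ~100 spikes/s at fast stretch); the fiber law
is a pluggable `FiberParams` interface so a full differential-equation
intrafusal model can be substituted.

Afferent combination uses partial occlusion with S = 0.156:
`prim = max(b1, b2c) + S·min(b1, b2c)`, `sec = b2c`, elementwise in time.
Both outputs are instantaneous firing rates; they are deliberately not
converted to spike trains.

## Features and classification

Each trial yields 39 features: the spike count of each tactile afferent
divided by the analysis window (full trial by default, or the window
covering the first X mm of the scan), plus the time-means of the MS-Prim
and MS-Sec rate traces. Speed classes split the sorted speed list into
thirds ({40,50} low, {60,70} medium, {80,90} high).

The canonical protocol is stratified five-fold cross-validation,
deterministic given a seed. KNN uses Euclidean distance on z-scored
features with the scaler fit on training folds only (k = 1 default;
k = 3 is a common alternative); Random Forest uses 1000 trees. Modality
ablations reuse identical fold splits so subset comparisons are paired.

## Experiments and problem sizes

* Innervation sweep: 6 textures at 90 mm/s, 10 repetitions, KNN k=1 on
  SA-I-only and RA-I-only features, densities {1.3, 4.3, 7.2, 10.5, 12.5},
  5 generator seeds.
* Fusion ablation: the full 600-trial protocol, 8 feature subsets × both
  classifiers, 5 seeds.
* Displacement sweep: windows of {5, 10, 20, 30, 40} mm (the grid is a
  plausible default, not a measured one), flagging the smallest window
  within 2 points of the best accuracy.
* Rate-vs-speed: mean class rates for three textures at 40 vs 90 mm/s
  with 90/40 ratio columns.

Default seed counts (5 for sweeps and fusion, 3 for displacement) balance
standard-deviation estimation against simulation cost; each experiment
embeds its config snapshot and seeds in the report so any table can be
regenerated exactly.

## What the synthetic data can and cannot show

The simulator reproduces the *structure* that makes speed-invariant
texture recognition hard and fusion useful: speed-scaled vibration
spectra, texture-specific spatial signatures, amplitude growth with speed,
and a proprioceptive channel encoding position and velocity. Tests
therefore assert ordering and shape claims — dynamic-afferent rates
non-decreasing in speed while SA-I and MS-Sec stay nearly constant;
all-modality fusion beating the SA-I+RA-I tactile pair on paired folds;
an interior optimum of innervation density; chance-level behaviour under
permuted labels — rather than absolute accuracy values, which on clean
synthetic surfaces run higher than on real recordings with motor noise,
row/column crosstalk and contact-force variability, none of which are
modelled. Passing these tests shows the pipeline is implemented correctly
and behaves as the underlying theory predicts; it does not certify
performance on physical sensor data.

## Numerical and degenerate-input conventions

* Zero-phase (forward–backward) filtering throughout preprocessing; the
  effective stop-band attenuation is therefore doubled relative to the
  designed single-pass magnitude, which is what the corner contracts are
  stated against.
* Traces shorter than the filter warm-up (3× filter order) are rejected;
  constant proprio traces raise "degenerate proprio signal" since the
  [0.95, 1.08] mapping is undefined at zero range.
* Spike times are clamped to the trial duration against 1-ulp float
  overshoot; half-open windows [t0, t1) count spikes.
* Ties in orphan-taxel assignment resolve to the nearest, then
  least-loaded, then lowest-index afferent — fully deterministic.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; no global RNG state is touched.

## Known limitations

* The RA-I dynamic-extraction pathway and all sensor-to-current scale
  factors are modelling choices; only the neuron parameters, receptor
  gains, filter specifications, spindle combination rule and fusimotor
  drives are fixed by the underlying theory.
* Intrafusal fiber gains are qualitative stand-ins, not fits to
  physiological recordings.
* No contact mechanics, no row/column readout crosstalk, no closed-loop
  fusimotor control, and no spike-distance (Victor–Purpura / van Rossum)
  features — spike rate is the only feature family.
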