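# Methods

## Model

The network has three populations:

* **Tactile map** — 41 × 21 neurons on a 0.5 cm lattice covering a
  20 cm × 10 cm hand surface.
* **Auditory map** — 101 × 16 neurons on a 2 cm lattice covering
  200 cm × 30 cm of space on and around the hand; the hand occupies
  [0, 20] × [0, 10] cm of that frame, so a sound "at distance d" sits at
  x = 20 + d cm, y = 5 cm. Distances from the hand are Euclidean
  distances to the hand rectangle.
* **Multisensory (PPS) unit** — a single unit receiving excitatory
  feedforward input from both maps and returning excitatory feedback.

Every neuron is a leaky integrator with a logistic output,

    tau dz/dt = -z + u(t),    y = 1 / (1 + exp(-s (z - theta))),

integrated with explicit Euler (dt = 0.5 ms; a guard rejects
dt > min(tau)/5). Unisensory input `u` sums (i) the external stimulus
filtered through the neuron's Gaussian receptive field, (ii) Mexican-hat
lateral input, and (iii) feedback `B · y_m` from the multisensory unit;
the multisensory input is `Σ W_t y_t + Σ W_a y_a`. A stimulus of spatial
width σ_s acting through RFs of width σ_rf drives neuron j as
`I · exp(-‖c_j - c_stim‖² / 2(σ_rf² + σ_s²))`: the same physical
stimulus therefore activates a much wider patch (in cm²) of the auditory
map (σ_rf = 6 cm) than of the tactile map (σ_rf = 0.5 cm), the model's
rendering of coarse auditory spatial resolution.

The lateral kernel `w(d) = L_ex exp(-d²/2σ_ex²) - L_in exp(-d²/2σ_in²)`
excludes the self-connection. Because the kernel is a difference of
Gaussians it factorizes along the grid axes; the runtime computes the
lateral field with four small matrix products (exact, no truncation),
which also lets independent noisy repetitions of one trial be integrated
as a single batched tensor.

Steady state is declared when the largest per-neuron activity change
falls below 1e-5 per ms after the last stimulus onset/offset event;
non-convergence within the simulated window is flagged, never silent.

## Synaptic organization

`W_t` is uniform at the ceiling `W_max = 1` (touch on the hand always
drives the unit). `B_t`, `B_a` mirror the feedforward arrangements and
are fixed. The basal auditory profile is a normalized-logistic plateau
of hand distance,

    W_a(d) = W_max · s((d0 − d)/w) / s(d0/w),     s = logistic,

with half-decay d0 = 54 cm and width w = 4 cm: exactly `W_max` for RF
centers touching the hand, ~1 over the near field, and a smooth drop to
~0 by 70 cm. A plateau (rather than a decay starting at the hand edge)
keeps the entire near field at saturation, so Hebbian potentiation is a
no-op there and training cannot distort the basal field — which is also
why near-distance reaction times are unchanged by training.

Two constraints fixed the multisensory unit's parameters
(theta = 35 input units, slope = 0.12):

* **Rest activity.** The logistic never reaches zero, so the unit's rest
  output is `1/(1 + exp(s·theta))` ≈ 0.015. Rest activity must stay well
  below 10% of the driven response (basal far-field silence) and, more
  stringently, low enough that sound-alone phases of the asynchronous
  protocol — where the "post-synaptic" factor of the Hebbian rule is the
  rest output — cannot accumulate potentiation over 30 presentations.
  Configurations with s·theta ≲ 3 visibly fail both.
* **Subthreshold feedback.** Feedback gains (2.0) are set so that
  feedback alone cannot ignite either map: with stronger feedback the
  unit becomes self-sustaining after stimulus offset, and a sound
  arriving after the touch has ended is paired with a still-active unit,
  turning the asynchronous control into de-facto synchronous training.

## Training protocols

One presentation = a 300 ms tactile stimulus at the hand center plus a
300 ms auditory stimulus at (100, 5) cm, both of intensity 10;
30 presentations, each from rest (activity fully decays in the
inter-presentation gap, and a silent multisensory unit drives no
plasticity, so the gap is not integrated). Synchronous mode: equal
onsets and durations. Asynchronous mode: a signed onset asynchrony drawn
uniformly from ±[250, 750] ms, so the stimuli are randomly partially
superimposed (|SOA| < 300 ms, p ≈ 0.1) or completely separated. The
Hebbian rates are γ_pot = 2.4e-4 /ms and γ_forget = 1e-6 /ms: 30
synchronous presentations drive the far-space weights near the ceiling,
while the asynchronous protocol's brief overlaps leave them within ~10%
of the synchronous change, and the slow forgetting term erodes untouched
weights by < 1% over a whole training run.

## Test batteries

* **RF mapping** — unimodal auditory probe (intensity 60, ±10%
  multiplicative intensity noise drawn once per presentation) at
  10-cm-spaced distances from 0 to 140 cm, 30 repetitions each, fresh
  rest state per repetition; the settled multisensory activation is
  recorded. The field extent is the largest tested distance whose mean
  activation reaches half the maximum mean.
* **Network RT** — simultaneous tactile (intensity 10) and auditory
  probes; RT = first time the tactile map's summed activity covers 90%
  of its rise above rest (linear interpolation between Euler steps);
  runs that fail to settle are flagged censored, and a trial whose
  aggregate never rises (e.g. zero-intensity probes) raises an error
  rather than returning a number. 15 distances, 140 → 0 cm, 30
  repetitions.

The probe intensities are deliberately asymmetric to the training
stimuli: RT probes are strong (fast, reliable responses with small
per-trial jitter), the training sound is moderate, which keeps the
potentiated band compact around the trained location. All were
calibrated once, against the deterministic (noise-free) curves first and
then verified under noise, to place the basal half-activation boundary
near 55 cm and the trained band at 85–115 cm; they are ordinary config
values and can be overridden per run.

## Boundary estimation

`y(x) = ymin + ymax·e^((x−xc)/b)/(1 + e^((x−xc)/b))` is fitted by
least squares (scipy `curve_fit`) to pooled repetition-level points;
`xc` — where the curve passes `ymin + ymax/2` — is the operational PPS
boundary. Initialization: `ymin = min`, `ymax = range`, `xc` at the
steepest slope of a 3-point moving average of the per-x means,
`|b| = x-range/10` with the sign of the overall trend; five
deterministically jittered restarts on failure; non-convergence returns
a flagged result. The 95% CI on `xc` is t-based from the Jacobian
covariance (df = n − 4); a case-resampling bootstrap is available as an
option. The fit record also carries the abscissa of the alternative
midpoint convention (where y = (ymin + ymax)/2), which coincides with
`xc` only for ymin = 0 — the two conventions circulate in the RT
literature and the report keeps both explicit. A flat response raises a
degenerate-fit error; fewer than four distinct x values is an error.

On the five published pre-training group means (517, 497, 464, 459,
455 ms at delays 300–2700 ms) this procedure gives xc = 912.9 ms. The
originally reported midpoint for that condition, 1055 ms, is not a
least-squares optimum of those five printed values under this equation
(the residual profile is ~5× higher there than at 913 ms); it evidently
derives from trial- or subject-level data that were never printed. The
package reports what the printed numbers yield. With five points and
four parameters the midpoint is in any case weakly identified — the CI
spans several hundred ms — which is why the simulation batteries use 15
distances with 30 repetitions.

## Behavioral pipeline

Trial tables carry subject, training condition, session, sound direction
(IN = looming, OUT = receding), delay label (T1..T5 = 300, 800, 1500,
2200, 2700 ms from sound onset), RT, and a catch flag (catch trials are
sound-only and carry no RT; tactile trials are 77% of trials). Delay
labels are recoded to perceived-distance bins D1 (farthest) … D5
(closest): identity order for IN, reversed for OUT, so equal bins share
an expected RT. Catch trials and missed detections are dropped first;
then RTs beyond two SDs of their subject × training-condition cell mean
are trimmed in a single pass (mean/SD computed once; the grouping
granularity is configurable since finer cells are equally defensible).
Summaries are balanced: subject means first, then the across-subject
mean ± SEM (NaN-flagged for single subjects). Boundary fits per session
use RT against touch-delivery time on the IN-sound axis; the two
post-training blocks are pooled into one "after" curve by default. No
ANOVA machinery is included — the inferential surface is the boundary
comparison.

## Synthetic data

`ppsnet.fixtures` bundles the published group summary tables (missing
cells — the post-synchronous D1 IN mean and the whole post-asynchronous
IN row — are NaN and flagged) and a trial-level generator: RT = boundary
sigmoid of touch-delivery time (defaults ymin 455 ms, amplitude 60 ms,
xc 1055 ms, b −150 ms) + a per-subject Gaussian intercept (SD 20 ms) +
trial noise (SD 50 ms), 16 subjects × 8 trials per cell, 2% large
positive outliers (+400 ms, attentional lapses), 23% catch trials.
The generator emulates the *structure* the analysis assumes — sigmoidal
distance dependence, subject offsets, heavy right outliers — but not
sequential effects, fatigue, direction asymmetries or lapse-rate
heterogeneity; recovery tests therefore validate the pipeline's
arithmetic and robustness to the modeled nuisances, not its behavior on
every pathology of real RT data. Parameter-recovery studies (200
replicates through trim → fit) recover the generating midpoint with
< 5% median bias.

## Known limitations

* After synchronous training the mean RT curve carries a ~4 ms
  non-monotone ripple between the native field edge (~60 cm) and the
  trained band's center (~80 cm): the remapped band is strongest where
  the training sound sat, slightly weaker at its seam with the basal
  field. Monotonicity tests allow 5 ms there (strict within-noise
  tolerance for the untrained and asynchronously trained curves).
* One multisensory unit means no spatial gradient within the far band
  and no head/trunk fields; no visual modality; no spiking dynamics.
* The asynchronous null depends on rare stimulus overlap under the
  chosen SOA range; protocols whose overlap exposure approaches the
  synchronous one will show intermediate potentiation, as the Hebbian
  rule has no explicit coincidence window beyond the network's own time
  constants.
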