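# Methods

## Signal model and simulator

A trot stride is modelled as four extrema per cycle — `min1, max1, min2,
max2` at phases (0, 0.25, 0.5, 0.75) of the stride by default — joined by
cosine half-waves, so the noiseless curve attains the configured extrema
exactly and with zero slope. The stride is anchored at a displacement
minimum; the first half-cycle holds (`min1`, `max1`), the second (`min2`,
`max2`). Default stride time is 720 ms (a typical trot value; the
configurable default matters only for the simulator, all analysis stages
estimate timing from the data) at 100 Hz sampling, so the default extrema
fall on exact samples.

Closed-form single-stride metrics, with the first half labelled *left*:

* `Dmin = min1 − min2`, `Dmax = max1 − max2`
* `Dup = (max1 − min1) − (max2 − min2)`
* `ROM = max(max1, max2) − min(min1, min2)`

Note the identity `Dup = Dmax − Dmin` within a stride under
minimum-anchored halves: the upward amplitude of a half is its maximum
minus its anchoring minimum. Consequently the simulator realises
signal-level Dup effects implicitly through the Dmin/Dmax effects; the
D\*Dup columns of an effect table drive only the summary-level simulations
used for statistical calibration. Medians across strides do not inherit
the identity exactly (a median of differences is not a difference of
medians), matching the behaviour of real tabulated data.

Noise components (all optional, seeded, reproducible): per-stride
per-extremum value jitter (`sigma_stride`), additive white measurement
noise (`sigma_meas`), a slow sinusoidal baseline drift (bounded and
reproducible, unlike a random walk; default period 10 s), and extremum-time
jitter. The simulator emulates the statistical structure the analysis
assumes — periodic two-per-stride oscillation, stride-half-specific
extrema, per-horse baselines, condition-wise effect shifts. It does not
emulate sensor orientation error, gait irregularity (breaks, transitions)
beyond duration outliers, autocorrelated noise, or soft-tissue artefact;
passing tests therefore demonstrate correctness of the computational
chain, not robustness to every artefact of field recordings.

The full-study simulator reproduces the limb-by-limb design: per horse, a
randomly assigned (or fixed) first forelimb; sessions pre / between /
post; the first limb's intervention shifts every condition measured from
'between' onward, the second limb's from 'post' onward, so each
adjacent-session difference isolates one limb. Effects are specified on
the side-normalized difference scale per variable as cell means over
(surface, direction) plus horse, limb-within-horse and residual SDs; raw
(un-normalized) shifts follow by undoing the sign convention for
right-limb interventions. Ground-truth condition summaries and normalized
differences are returned with the signals, and with all noise terms zero
the full pipeline reproduces them to numerical precision (< 1e-9 mm)
given the true boundaries. One master seed drives deterministic
substreams (design, effects, baselines, signals).

## Displacement from acceleration

Twofold numerical integration (trapezoidal) with a zero-phase 4th-order
Butterworth high-pass applied before and after each integration stage.
The cutoff is 0.5 × the stride-frequency hint (≈ 0.7 Hz for trot), which
suppresses integration drift while leaving the 2-per-stride oscillation
(≈ 2.8 Hz) essentially untouched. Sampling below 4 × the stride frequency
is rejected. The combined filter/integration transient settles on the
scale of the cutoff period, not the stride, so three cutoff cycles are
discarded at each end of the output (≈ 4.3 s at trot defaults); with this
trim a pure-sinusoid closed-form check recovers the displacement
amplitude to < 0.5%. Output is zero-mean displacement in mm. Input is
assumed to be gravity-free vertical acceleration; orientation estimation
is out of scope.

## Stride segmentation

The dominant oscillation frequency is estimated from a Welch spectrum
(segment length n/4, minimum 256), searched within 1–6 Hz, and refined by
parabolic interpolation of the log-PSD. A flat or noise-only spectrum
(peak < 10 × the band's median power) raises an explicit segmentation
failure. If comparable power exists at twice the peak (an asymmetric gait
whose stride fundamental dominates), the harmonic is taken as the
oscillation frequency; the stride frequency is half the oscillation
frequency.

Minima are detected on a band-pass filtered copy (0.4–1.6 × the
oscillation frequency) and refined to the raw-signal minimum within
±0.15 oscillation periods (earliest index on ties). Strides run between
alternate minima; the intervening minimum splits the halves. Strides
whose duration deviates more than 25% from the median stride time
(turns, transitions) are discarded and logged. The pelvis signal is the
stride clock for all three landmarks of a trial (trot timing is shared
across the upper body).

Which half belongs to which forelimb is not identifiable from a single
vertical trace; `label_halves` attaches the limb attribution from an
explicit convention or an external label source, and the choice is
recorded in the output. Flipping the reference negates the nine asymmetry
metrics and leaves ROM unchanged.

## Symmetry metrics and summaries

Per stride, each half's minimum is its anchoring boundary sample and its
maximum the interior extremum (earliest sample on ties); halves without
an interior maximum exclude the stride (logged). Metrics follow the
closed forms above with left/right taken from the half labels. Conditions
are summarised by component-wise medians (numpy midpoint convention for
even counts) together with the median stride time and the stride count;
fewer than 25 strides triggers a warning, zero valid strides an explicit
error.

## Normalization

Post-minus-pre differences are formed per horse, surface and exercise
condition for the two adjacent session pairs, attributed to the limb
re-shod in the later session. Right-limb interventions invert the nine
asymmetry differences (multiplication by −1); the three ROM differences
carry no left/right sign and are exempt. Lunge direction is recoded
*inside*/*outside* by whether the re-shod limb is on the inside of the
circle; straight-line records keep *straight* on both surfaces (circles
exist only on the soft surface in the observed design). After
normalization, negative asymmetry differences indicate reduced force
production with the re-shod limb. The inversion is an involution, and the
full design yields exactly 80 records.

## Pooling check

Left- and right-intervention records are paired per horse within each
(surface, direction) cell on the side-normalized scale (the scale on
which pooling is the hypothesis under test; the source description does
not state the pairing scale). Per variable, the paired differences are
tested for normality with a Lilliefors test whose null distribution is
simulated (10 000 seeded standard-normal samples, avoiding table
interpolation); the centre is the mean when normality is not rejected at
5%, otherwise the median. A variable passes when |centre| does not exceed
its repeatability threshold — 6 mm for head variables, 3 mm for withers
and pelvis (the stricter pelvic value stands in for withers, which has no
published threshold). Pooling is permitted iff all twelve variables pass;
otherwise the analysis proceeds with the side of intervention as a fixed
covariate and logs the deviation.

## Mixed models

Per difference variable: `D ~ surface + direction` with reference coding
(hard, inside) and random intercepts for horse and limb-within-horse,
estimated by REML. The three variance components are profiled directly
through the closed-form REML criterion (optimised over log-variances,
L-BFGS-B, three starts); this makes the observed information over the
variance parameters available, which the Satterthwaite approximation
needs. A limb-within-horse component estimated at the zero boundary
(< 1e-6 × the outcome variance) triggers a refit without the nested term,
with a logged warning.

Fixed factors are tested with F statistics using Satterthwaite
denominator degrees of freedom (delta-method variance of the contrast
variance, numerically differentiated; multi-row contrasts combine
per-eigenvector one-df values as in standard mixed-model software). EMMs
are model predictions at each level of one factor averaged with equal
weights over the levels of the other — the design's empty cell
(hard × circles) is handled by additive-model prediction, so hard-surface
EMMs extrapolate into the unobserved hard-circle cells exactly as
standard EMM semantics prescribe; this is the main structural caveat of
the design. 95% CIs use the per-contrast Satterthwaite t quantile. The
three pairwise direction contrasts are Bonferroni-adjusted (×3, capped at
1); the omnibus p is reported unadjusted. A surface × direction
interaction is not estimable under the empty cell and is not modelled.
The implementation agrees with independent mixed-model software
(REML + Satterthwaite + equal-weight marginal means) to ~1e-7 on EMMs and
CIs and ~1e-5 on p-values on a frozen test dataset, and with
statsmodels' MixedLM on estimates and variance components.

## Calibration experiments

`experiments.default_effect_table` turns the published per-variable EMM
table into a generative effect structure: cell means from the additive
decomposition `cell(s, d) = EMM(s) + EMM(d) − grand mean` (the published
rows are additive-consistent), and the residual SD chosen per variable so
the model-based hard-surface EMM CI matches the published half-width
(t quantile at 60 df; horse and limb SDs fixed at half the residual SD).
Replicate synthetic studies then measure estimator bias (mean EMM error
over replicates), CI coverage, and — with all effects zeroed — type-I
error of the surface and direction F tests. At the study's size (N = 80)
the acceptance runs use 150–200 replicates; head variables carry roughly
3× the EMM standard error of withers/pelvis variables, so the bias check
is asserted on withers/pelvis variables where 200 replicates give it
adequate power, and coverage (pooled over 1000 intervals) on a head
variable as well.

## Defaults

| parameter | default | note |
| --- | --- | --- |
| sampling rate | 100 Hz | study acquisition rate |
| stride time (simulator) | 720 ms | typical trot; configurable |
| strides per condition | 30 | ≥ 25-stride target, warning below 25 |
| stride-duration outlier | 25% of median | discard + log |
| repeatability thresholds | 6 / 3 / 3 mm | head / withers / pelvis |
| significance / confidence | 0.05 / 0.95 | |
| high-pass cutoff | 0.5 × stride frequency | integration stage |

## Known limitations

* Limb identity of stride halves requires an external reference; the
  package never guesses it.
* The exact filter chain and degrees-of-freedom method of the commercial
  processing software behind the original tabulated data are unpublished;
  equivalence is demonstrated on simulated round trips and against
  independent mixed-model software, not bit-for-bit.
* Satterthwaite degrees of freedom at a variance boundary are
  approximate; the boundary triggers the documented reduced refit.
* The simulator's noise is white and its drift sinusoidal; field
  recordings contain structured artefacts outside this model.
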