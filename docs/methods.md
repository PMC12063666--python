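# Methods

This note documents the models, estimators, defaults and numerical
choices behind `sarcokit`, and what the synthetic-data tests do and do
not demonstrate.

## 1. Biomechanical feedback model (`sarcokit.feedback`)

### Dynamics

State: three lengths per half-sarcomere — actin `L_actin(t)`, A-band
`L_A(t)`, I-band titin `L_I(t)` — evolving through alternating
relaxation (duration `T_r`) and contraction (duration `T_c`) phases.
A cycle starts with relaxation.

Relaxation (`L_I = L_I_max`):

* actin grows at `v_actin_r`, capped at `L_I_max + alpha`
  (`alpha = N_c·l`: once the actomyosin overlap recruits the critical
  motor number, strong contractions block further recruitment);
* the A-band grows at `v_A_r` and halts once `L_A ≥ L_actin − L_I_min`
  (a contracted sarcomere would then be fully overlapped). When a cap is
  a moving target (actin at the midline wall while the A-band still
  grows; the A-band on its halt line while actin still grows), the
  constrained length tracks it at the minimum of the two speeds.

Contraction (`L_I = L_I_min = L_I_max − T_motor/K_titin`):

* the A-band is frozen; actin grows at `v_actin_c` capped at
  `L_I_min + L_A`, which is exactly the midline wall condition
  `L_actin ≤ L_I + L_A` with the compressed I-band. If the phase switch
  itself violates that cap (the I-band shortens instantaneously), actin
  is clamped to the wall at the switch; the recorded state at a phase
  boundary is the state at the start of the new phase.

### Integration

All dynamics are piecewise linear, so the simulator is event-driven and
exact: phase boundaries come from an integer cycle counter (no float
drift), and cap/constraint activation times are solved in closed form.
There is no time-stepping error; recorded lengths are exact up to float
rounding (~1e-15), which is why the fixed-point agreement tests can use
a 1e-9 tolerance.

### Fixed points and valid region

For positive relaxation growth rates and a periodic schedule the system
converges to

    L_actin(∞) = L_I_max + alpha
    L_A(∞)     = L_I_max + alpha − L_I_min

independently of the rates and of initial conditions *within the valid
region*: initial lengths must satisfy the wall condition and sit at or
below their fixed-point values (`L_actin_0 ≤ L_I_max + alpha`,
`L_A_0 ≤ alpha + T_motor/K_titin`). The model has no shrink dynamics, so
states started above the fixed point stay there; we treat that region as
unphysical for a growing myofibril. `time_to_converge()` returns a total
time that provably suffices (worst-case growth at the minimum rate,
during relaxation fractions only, plus a few cycles of margin).

### Conventions and parameters

* `sarcomere_length = 2·(L_I + L_A)` under a half-sarcomere reading of
  the state variables; the factor is a parameter (`sarcomere_factor`)
  since the mapping of model lengths to a full sarcomere is a
  convention.
* Units: μm for lengths and arbitrary (hours recommended) for time; the
  dynamics are scale-free.
* Presets (`scenario()`): a shared base (L_I_max 2.0, L_I_min 0.5,
  alpha 1.5, T_r = T_c = 1, growth 0.02 μm per unit time in relaxation,
  no growth in contraction, initial lengths 0.6/0.3, total time 100)
  modified one mechanism at a time: `silenced` removes contractions,
  `hypercontractile` shortens relaxation to 0.25 of the cycle,
  `flight_development` stops contractions at half time,
  `stiff_cuticle` shortens the relaxed I-band to 1.2 μm at the same
  compressed length. The base was chosen so that at the shared total
  time all presets are still far from their caps — the finite-time
  ordering (silenced > wild type > hypercontractile) is then a pure
  consequence of relaxation-time budget, not of different caps.
* Phase-diagram classification thresholds (configurable): flight-like
  if I-band/half-sarcomere < 0.1 and overlap/actin > 0.9;
  crawling-like if I-band fraction > 0.5; otherwise intermediate.

### Interpretation choices

Two symbols in the phase equations are used without definition in their
source formulation; we identify the relaxation cap constant with
`L_I_max` (so the cap is `L_I_max + alpha`, consistent with the maximal
actin length the narrative model states) and the contraction cap
constant with `L_I_min` (so the cap equals the wall condition). The
printed relaxation cap appears as a lower bound (`max[...]`); we
implement it as the upper cap, treating the printed form as a sign
inversion — a lower bound on a monotonically growing length would be
inert and could not produce the stated final lengths. Narratively,
contraction "blocks recruitment"; the equations still carry an actin
growth speed `v_actin_c` in contraction, so both are supported and
`v_actin_c = 0` (the preset default) reproduces full blocking.

## 2. Striation quantification (`sarcokit.profiles`)

Four steps: declared pattern → autocorrelation period → reference
sarcomere and cross-correlation segmentation → per-segment sub-pixel
feature fits.

* **Period**: linear detrend, biased autocorrelation, peaks above a
  significance floor (default 0.2 of the zero-lag value) beyond a
  minimum lag (half of the smallest plausible period, default 1 μm);
  among peaks within 80% of the strongest, the smallest lag is taken
  (rejects band-pair sub-structure below and period multiples above)
  and refined by a 3-point parabola. Constant or noise-only profiles
  raise an "aperiodic input" error.
* **Reference**: one period cut around the global intensity maximum
  (clipped at the ends). For block-with-bands patterns the anchor pixel
  is chosen on a *band* by first subtracting a wide median filter
  (window = period/4), so segments are Z-disc-anchored and each block
  lies between consecutive anchors.
* **Segmentation**: cross-correlation of the detrended profile with the
  mean-subtracted reference, zero-padded so end repeats surface as
  interior peaks; peaks ≥ 0.3 of the strongest at ≥ 0.7 periods
  spacing; one refinement pass re-estimates the template as the mean of
  all aligned repeats (suppressing single-sarcomere noise). Anchors are
  coarse alignment: interior anchors are sub-pixel, the two boundary
  repeats only pixel-accurate; final precision comes from the feature
  fits below.
* **Bands**: least-squares Gaussian (+ offset) in a window of ±25% of
  the period around the nearest local maximum (narrowed to half the
  pair separation for band pairs); fits that fail or run to the window
  edge are reported missing, never imputed. Ties between equal peaks
  resolve leftmost (stable sort).
* **Block edges**: a cubic smoothing spline (smoothing set from the
  first-difference noise estimate) crossed at half of
  plateau-minus-baseline; levels are estimated globally (medians above/
  below the mid-level), then refined per edge from local flanking
  windows, which insulates the crossing from other features in the
  segment. For a Gaussian-blurred step the half-crossing sits exactly
  on the true edge, so the estimator is unbiased under symmetric blur.
  A plateau indistinguishable from baseline (< 4 noise SD) reports the
  block missing. A sigmoid-fit alternative was considered and not
  needed: the spline route is already exact for blurred steps.
* **Metrics**: sarcomere length = consecutive Z-band spacing; A-band =
  block length; I-band = sarcomere − A-band; titin (Sls) span = N-to-C
  band-pair separation across the Z-disc; ratios of each to sarcomere
  length. Positions are continuous μm, pixel-center convention, profile
  start at 0.

## 3. PEVK scanning and curation (`sarcokit.domains`)

A window of 250 residues (default) slides one residue at a time;
each window's P/E/V/K proportion is counted case-insensitively, with
non-standard residues ('X') in the denominator only (conservative).
Windows strictly above the 40% threshold are merged — union of their
residue spans, adjacent spans coalesced — into PEVK intervals (1-based
inclusive). The strict inequality follows the "more than 40%" rule;
whether qualifying windows should be merged is not specified anywhere,
so union-merge is our choice (it is idempotent and
threshold-monotone: lowering the threshold never shrinks any call).
Sequences shorter than the window yield an empty profile plus a
warning. Curation of external annotation tables keeps Ig, Fn3, kinase
and Z-repeat rows (alias-normalized), skips malformed rows with a
logged warning, and sorts by start. `contour_length()` uses 0.35 nm per
residue for a fully extended chain.

## 4. FLIM-FRET (`sarcokit.flim`)

Tail-only fitting (default tail start: two bins past the histogram
maximum) avoids instrument-response modelling. The model is
`a·exp(−t/τ) (+ b·exp(−t/τ₂)) + c`; weights are Poisson
(`1/sqrt(counts)`), with a second pass reweighted by the fitted model —
weighting by observed counts biases τ low in sparse tail bins, and the
model-weighted refit removes most of that (residual bias ≈ −0.3% at
1e5 photons, within the 1% contract). The constant background is fitted
by default and allowed to go slightly negative so noise does not
rectify into a downward τ bias. "Average lifetime" is
amplitude-weighted, `Σaᵢτᵢ/Σaᵢ` (the photon-number-weighted mean is
available behind `intensity_weighted=True`); the weighting convention
is a choice, as is the tail window — both are stated here because the
reference analysis software's internal settings are not public.
Efficiencies use `E = 1 − τ_DA/τ_D` exactly; cohort analysis takes
τ_D as the median of the donor-only fits.

## 5. Wing beat (`sarcokit.wingbeat`)

Defaults: 10 kHz sampling (so the 10,000-sample Hann window gives 1 Hz
bins; the recording rate of the original hardware is not reported and
is configurable), 150–350 Hz band, 0% overlap, first 2 s skipped ("the
first seconds" made concrete). The bandpass is an order-6 elliptic SOS
run forward-backward (zero phase): passband ripple doubles to ≈0.4 dB
and stopband attenuation to ≈90 dB, comfortably meeting the ≥40 dB
harmonic-rejection / ≤1 dB passband contract verified spectrally in the
tests. Window peaks are accepted only if in-band peak power exceeds 30×
the in-band median power (a scale-free criterion, so the estimate is
amplitude-invariant); with no accepted window the trace reports "no
flight detected". Sub-bin refinement is a parabola on log power; the
per-fly statistic is the median over windows (median vs mean over
windows is unspecified at the source; the median is robust to bout
onsets/offsets).

## 6. Synthetic data (`sarcokit.synth`)

What the generators emulate — and what they do not:

* **Sequences**: exact-count composition blocks (planted P/E/V/K
  fraction matched to rounding) in filler whose P/E/V/K fraction is
  fixed at 0.15, drawn from an alphabet excluding P/E/V/K plus an
  explicit P/E/V/K quota. Real titins have PPAK-type repeat structure
  and compositional gradients; none of that is modelled — these
  fixtures test window counting and thresholding, not biological motif
  structure.
* **Profiles**: sums of Gaussian-blurred features (bands: Gaussians of
  the PSF width; blocks: erf-blurred plateaus) in continuous
  coordinates, sampled at pixel centers, plus i.i.d. Gaussian noise.
  Real myofibrils add varying band intensities, background gradients,
  out-of-focus light and curvature of the traced line; passing the
  recovery tests shows estimator correctness under the stated noise
  model, not robustness to every imaging artifact.
* **Decays**: exponential mixtures integrated exactly over uniform
  bins, Poisson counts, flat background; mixture fractions are decay
  *amplitude* fractions, so the amplitude-weighted mean lifetime of the
  truth is `Σfᵢτᵢ`. No instrument response convolution, afterpulsing or
  pile-up.
* **Audio**: harmonic sinusoids (optionally a linear chirp) in Gaussian
  noise. No amplitude modulation, bout structure, or room acoustics.

All generators are deterministic under a fixed seed
(`numpy.random.default_rng`).

## 7. Problem sizes in tests and the acceptance script

The recovery checks use 40-sarcomere profiles, 1e5–1e6-photon
histograms, 10-second audio traces, 50-seed repetition for lifetime
bias, and 100 random parameter sets / sequences for the property
checks — sizes at which the estimators' asymptotic behaviour is already
visible while the whole suite runs in seconds.

## 8. Known limitations

* The feedback model is deterministic and mean-field: no stochastic
  motor binding, force-velocity relations, 3D lattice geometry or
  stretch-activation dynamics.
* Convergence guarantees (and the fixed-point tests) require positive
  relaxation growth rates and initial conditions below the fixed point.
* The profile pipeline is strictly 1D: ROI selection and myofibril
  tracing are upstream manual steps, and multi-channel data are
  analyzed channel by channel.
* Boundary sarcomeres (first/last repeat of a profile) have reduced
  anchor accuracy; length statistics should rely on interior repeats
  when profiles are short.
* FLIM fitting assumes tail bins free of instrument-response effects;
  decays with lifetimes comparable to the bin width are rejected rather
  than deconvolved.
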