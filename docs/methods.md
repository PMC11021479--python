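# Methods

This note documents the models, the analysis conventions, and the design
choices behind `obpc`, in the spirit of a methods appendix: what each
component assumes, which parameters matter, and what the synthetic-data
results do and do not establish.

## Response classification and ROI filtering

Inputs are ΔF/F response amplitudes (one number per ROI, stimulus, and
trial — e.g. the mean signal in a fixed window after odor onset) plus blank
(no-odorant) trials per ROI. Classification thresholds are
`blank mean ± n_sd × blank SD` with `n_sd = 3` by default, computed **per
ROI** from that ROI's own blank trials, because noise levels differ across
ROIs; pooled-blank thresholds are available via `threshold_mode="pooled"`,
and ROIs with degenerate (zero-variance) blanks automatically fall back to
the pooled SD and are flagged. The label compares the **across-trial mean**
against the thresholds with strict inequalities; a trial mean exactly at a
threshold is nonresponsive.

Two operating characteristics follow from this definition and are verified
in the test suite. When the compared statistic has the same noise scale as a
single blank trial, the false-positive rate per ROI-stimulus entry is
2Φ(−3) ≈ 0.27%. Averaging over three trials shrinks the statistic's noise by
√3, so a planted response 5 blank-SDs above baseline is detected with
probability 1 − Φ((3 − 5)√3) ≈ 99.97%, at the cost of a much lower (not the
nominal 0.27%) false-positive rate. Both effects are properties of the
3-SD-of-single-trials convention itself, not of this implementation. The
threshold estimate also inherits sampling noise from the number of blank
trials: with few blanks the realized false-positive rate is inflated
t-like, which is why operating-characteristic checks use generously sized
blank sets.

Only ROIs with at least one significant response (enhanced **or**
suppressed) are retained for population analyses. Polarity classes are
defined per ROI over the panel: pure-enhanced (≥1 enhanced, 0 suppressed),
pure-suppressed (symmetric), mixed (≥1 of each), silent.

## Sparseness

Population sparseness of stimulus j over n ROIs is the activity ratio
`PS_j = (mean r)² / mean(r²)`; lifetime sparseness is the same functional
across stimuli for one ROI. Values lie in (0, 1]: 1 for uniform activity,
1/n for one-hot. Sparseness inputs are **absolute** trial-mean magnitudes by
default so suppressed responses count toward breadth (a signed mode exists
for all-positive data); an all-zero vector returns NaN with a warning. The
measure is invariant to positive rescaling and satisfies the transpose
duality (PS of a matrix's columns = LS of the transposed matrix's rows),
both asserted as properties.

## Representational similarity

Population vectors are the retained ROIs' amplitudes per stimulus-trial
column (trial level) or per trial-averaged stimulus (stimulus-mean level);
similarity is the Pearson correlation between columns. Zero-variance columns
yield NaN sentinel entries that are excluded from averages and warned about.
Trial-to-trial reliability is the mean off-diagonal entry of each stimulus's
trial block. Matrix ordering uses average-linkage agglomerative clustering
on the distance 1 − r (linkage choice is a package convention; the leaf
order is scipy's default dendrogram traversal), and an ordering derived from
one population can be applied verbatim to another population's matrix.

Mixture overlap between component sets is `|a ∩ b| / max(|a|, |b|)` by
default. With a single 75% criterion this reads "≥6 shared of 8" for 8-vs-8
pairs and "≥9 of 12" for 12-vs-12 pairs, and it is conservative for
mixed-size pairs; Jaccard overlap is available behind a flag.

## Polarity null model

Given per-odorant category probabilities (p_N, p_E, p_S), each simulated
bouton draws n = 16 independent labels; fractions of pure-enhanced,
pure-suppressed, mixed, and silent boutons are reported over 10,000
simulated boutons with 99% binomial half-widths 2.576·√(p(1−p)/n_boutons).
The exact closed form (silent = p_N^n, pure-enhanced = (p_N+p_E)^n − p_N^n,
etc.) serves as an independent oracle, itself validated against exhaustive
enumeration of all 3³ outcomes at n = 3. At the observed probabilities
(0.722, 0.124, 0.154) the closed form gives 6.34% / 11.48% / 81.64% / 0.55%.
Note the binomial 99% half-width at n = 10,000 for the pure-suppressed
category is ±0.82 percentage points; comparisons of a single Monte-Carlo
run against the exact value should use that scale. Silent boutons (~0.5%)
are reported as their own category rather than folded into the other three.

## Circuit model

Times are expressed in units of the membrane time constant τ. Glomerular
output follows receptor occupancy (affinities log-normal with natural-log SD
3, i.e. spanning roughly three orders of magnitude; binary efficacies at
activation probability 0.2); a sparse half-normal projection (density 0.1,
scale 0.5) maps 400 glomeruli to 5000 cortical neurons; a global interneuron
integrates the summed rectified cortical output and feeds back
`w_inh · σ(β(v − v_thr))` with defaults (1, 2, 2000). Conventions the model
statement leaves open, fixed here:

* σ is the standard logistic `1/(1+e^(−z))` — bounded activation in (0, 1).
* Integration is forward Euler with dt = 0.01τ over 20τ from zero initial
  conditions, with the odor input stepped on at t = 0 and held constant.
  `CircuitSpec` rejects dt > 0.1τ (Euler stability margin), and the
  integrator aborts with a divergence error if |u| ever exceeds 1e8.
  Halving dt changes steady states by < 1e-3 relative (test-verified), and
  with the inhibitory gate frozen at any constant g the integrator's steady
  state matches the analytic fixed point `u* = Σ W x − w_inh·g` to 1e-3.
* The steady-state response is the mean rectified output over the final 20%
  of the trace (robust to residual ringing of the inhibitory loop); response
  latency is the first crossing of 50% of that steady state, which gives the
  closed-form τ·ln 2 for the inhibition-free step response and NaN for
  silent neurons.
* Heterogeneous inhibition: 500 interneurons whose three parameters are each
  scaled by independent 1 + ε factors (ε ~ N(0, 0.2²), negatives clipped at
  zero — a ~5·10⁻⁷ event per draw); each integrates its own voltage from the
  same summed cortical drive, and the cortical inhibition is the population
  mean of the individual `w_inh·σ(·)` terms. This reduces exactly to the
  homogeneous model at zero jitter.
* The default concentration grid is 24 log-spaced points over 10⁻³–10³ in
  affinity-relative units, bracketing the affinity spread on both sides.

Under the defaults roughly a quarter of cortical neurons have nonmonotonic
dose-response curves (rise, dip when the inhibition threshold is crossed,
recovery as input overcomes the fixed inhibitory weight), no neuron is
nonmonotonic with w_inh = 0, and the population-median half-max latency
falls from 0.69τ at low concentration to ~0.2τ before creeping back up as
steady states recover — monotone as a trend (Spearman ρ < 0) though not
point-by-point. Population-mean dose-response curves are reported both over
all neurons and over responsive neurons only. With heterogeneous
interneurons the population-mean curve is smoother than in the homogeneous
model; because the homogeneous mean curve plateaus rather than dips under
the defaults, smoothness is best quantified by the maximum absolute second
difference of the mean curve (0.073 heterogeneous vs 0.103 homogeneous at
the default grid) rather than by the maximum single-step drop (zero for
both).

One consistency note: the claim that cortical input at saturating
concentration has unit magnitude on average does not follow from the stated
parameter distributions, which give a mean saturating drive of
400·0.1·0.2·(0.5·√(2/π)) ≈ 3.19 (Monte-Carlo confirmed). The parameters are
kept as stated — only the ratio of drive to w_inh matters for the
phenomenology — and the test suite asserts the derived 3.19.

## Synthetic-data generators

The generators encode the population contrasts as ground truth so the
pipeline's recovery of them is a genuine end-to-end test.

**Stimulus panels.** The mixture panel is 16 monomolecular odorants plus 84
mixtures (24 of size 2, 20 each of sizes 4, 8, 12), component sets sampled
uniformly without replacement within each size class. The concentration
panel is 8 log-spaced steps spanning a 10³ concentration ratio, matching the
delivered 0.08%–80% (v/v) range.

**OSN tensors.** Each ROI is sensitive to each of the 16 components with
probability 0.12, with log-normal drive magnitudes (log-median 0.5, log-SD
1). A mixture's drive is the component sum passed through the saturating
`s/(1+s)` (default), so response density and amplitude grow sublinearly with
mixture size and overlapping mixtures correlate through shared components;
an antagonistic alternative passes partial efficacies through a
competitive-binding rule (weaker responses for large mixtures, same
sublinearity). Concentration responses are Hill curves (slope 2) with
per-ROI midpoints log-uniform over the panel range. A random 10% of ROIs
carry sign-flipped (suppressed) tuning — a phenomenological stand-in, not a
mechanism. Trials add i.i.d. Gaussian noise; blanks are pure noise.

**Bouton tensors.** Direct mode draws an independent responder subset per
stimulus at density 0.278 (the observed per-odorant responsive fraction),
log-normal amplitudes signed enhanced with probability 0.446 (the observed
12.4:15.4 balance); tuning independence across stimuli makes sparseness and
correlation profiles flat by construction (a fixed-responder mode exists for
correlated tuning). Circuit mode instead simulates the rate model on
per-component glomerular input — per-component affinities and efficacies
sampled from the circuit's distributions and combined by competitive binding
at each glomerulus, `x_i = Σ_k η_ik κ_ik c / (1 + Σ_k κ_ik c)`, which
reduces to single-odor occupancy for one component — then rescales the
steady-state outputs so the population maximum is one amplitude unit
(trial-noise settings should be scaled accordingly). Circuit-derived bouton
responses are non-negative and inherit nonmonotonic concentration tuning.

**Noise calibration.** Trial-noise SDs were set once, by a one-dimensional
sweep, to place the mean within-odorant trial-to-trial population-vector
correlation at the levels observed for the two populations: 0.12 ΔF/F for
OSNs (reliability ≈ 0.77, target ≈ 0.78) and 0.39 for boutons (≈ 0.53).
Default population sizes are 400 OSN and 800 bouton ROIs with 3 trials and 6
blank trials — the scale of the study populations while staying fast on a
single CPU (the full suite runs in under a minute; the full-size circuit
dose-response sweep takes ~10 s per 24-point grid).

**What passing tests show — and don't.** The generators produce independent
Gaussian trial noise, no correlated (respiration- or state-driven)
variability, no amplitude drift, no photon/indicator nonlinearity, and no
temporal structure; real imaging data violate all of these to some degree
(the study corrected correlated variability before analysis; that correction
is deliberately not implemented here, and a simple per-trial blank-drift
subtraction is available but off by default). Recovery of the designed
contrasts therefore validates the analysis logic, not the generators'
realism, and the study's real-data values (e.g. lifetime sparseness 0.46 vs
0.65, tuning widths 3.15 vs 4.45 odorants) are reproduced only as
qualitative orderings, never as numbers.

## Degenerate inputs and sentinels

All-zero response vectors: NaN sparseness / ranked curves with warnings.
Zero-variance population vectors: NaN similarity entries, excluded from
averages. Silent neurons: NaN latency. Empty overlap groups: NaN means.
Empty ROI filters are permitted with a warning. Configuration files reject
unknown keys by name; tensor files round-trip bitwise through HDF5 + JSON.
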