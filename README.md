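# obpc — feedforward vs. feedback odor coding

`obpc` is a Python package for analysing and modelling the two information
streams that meet in the mouse olfactory bulb: the feedforward input from
olfactory sensory neurons (OSNs) and the feedback projections ("boutons")
that piriform-cortex neurons send back to the bulb. It is aimed at systems
neuroscientists working with odor-evoked calcium-imaging response amplitudes
(ΔF/F), and provides four things:

1. **A response-analysis pipeline** for ROI × stimulus × trial amplitude
   tensors: significance classification against a per-ROI 3-SD blank-trial
   threshold, enhanced/suppressed/mixed polarity classes, effective-odorant
   counts, population and lifetime sparseness, ranked-normalized tuning
   curves, Pearson representational-similarity matrices with hierarchical
   ordering, trial-to-trial reliability, and mixture-overlap group
   comparisons.
2. **An exact + Monte-Carlo null model** for response polarity: if a
   bouton's 16 odorant responses were drawn independently from the observed
   per-odorant category distribution, what fraction of boutons would look
   purely enhanced, purely suppressed, or mixed?
3. **A rate model of the bulb→cortex circuit** with a sparse random
   expansion and global activity-dependent inhibition, which produces
   nonmonotonic single-neuron dose-response curves while response latency
   falls with concentration.
4. **Synthetic-data generators** that emulate the statistical structure of
   both populations (density scaling with mixture size in OSNs, flat density
   in boutons, different trial reliabilities, sigmoidal vs. nonmonotonic
   concentration tuning), so every stage of the pipeline is testable without
   imaging data.

## The models in brief

**Sparseness** (per stimulus *j* over *n* ROIs; the lifetime version swaps
the roles of ROIs and stimuli):

```
PS_j = (Σ_i r_ij / n)² / Σ_i (r_ij² / n)
```

1 for uniform population activity, 1/n for a one-hot pattern.

**Polarity null.** With per-odorant probabilities (p_N, p_E, p_S) and
independent draws over n odorants,

```
P(silent) = p_N^n,   P(pure enhanced) = (p_N + p_E)^n − p_N^n,
P(pure suppressed) = (p_N + p_S)^n − p_N^n,   P(mixed) = the rest.
```

**Circuit model.** Glomerular input follows receptor occupancy
`x_i(c) = η_i κ_i c / (1 + κ_i c)` with log κ_i ~ N(0, 3²) and
η_i ~ Bernoulli(0.2); a sparse non-negative matrix W (density 0.1,
half-normal 0.5 entries) projects 400 glomeruli onto 5000 cortical neurons:

```
τ du_j/dt = −u_j − w_inh σ(β (v − v_thr)) + Σ_i W_ji x_i
τ dv/dt   = −v + Σ_j max(u_j, 0)
```

with defaults w_inh = 1, β = 2, v_thr = 2000, and σ the logistic function.

## Worked example

```python
from obpc import (OBSERVED_PROBS, analytic_polarity_null,
                  simulate_polarity_null)

res = simulate_polarity_null(OBSERVED_PROBS, n_odors=16, n_boutons=10_000,
                             seed=1)
exact = analytic_polarity_null(OBSERVED_PROBS, 16)
for cat in ("pure_enhanced", "pure_suppressed", "mixed"):
    print(f"{cat:16s} {100 * res.fractions[cat]:5.2f}% "
          f"± {100 * res.ci99[cat]:.2f}  (exact {100 * exact[cat]:5.2f}%)")
```

```
pure_enhanced     6.11% ± 0.62  (exact  6.34%)
pure_suppressed  12.10% ± 0.84  (exact 11.48%)
mixed            81.30% ± 1.00  (exact 81.64%)
```

Reading: if bouton-odorant responses were independent across odorants, ~82%
of boutons would show both enhanced and suppressed responses. Observed
populations show far more single-polarity boutons than that, i.e. response
polarity is a conserved property of a bouton, not an accident of sampling.

The same contrast logic runs end-to-end on synthetic tensors:

```python
from obpc import (BoutonGeneratorParams, OsnGeneratorParams,
                  classify_responses, filter_rois, make_mixture_panel,
                  simulate_bouton_tensor, simulate_osn_tensor,
                  sparseness_report)

panel = make_mixture_panel(seed=0)           # 16 odorants + 84 mixtures
osn = simulate_osn_tensor(panel, OsnGeneratorParams(seed=0))
bouton = simulate_bouton_tensor(panel, BoutonGeneratorParams(seed=0))
for t in (osn, bouton):
    mask = filter_rois(classify_responses(t))
    ps = sparseness_report(t, roi_mask=mask).population_sparseness
    by_size = [round(float(ps[panel.sizes == s].mean()), 2)
               for s in (1, 2, 4, 8, 12)]
    print(t.population_label, "PS by mixture size:", by_size)
```

```
OSN PS by mixture size: [0.29, 0.35, 0.5, 0.72, 0.86]
bouton PS by mixture size: [0.48, 0.47, 0.47, 0.47, 0.48]
```

Population sparseness climbs with mixture size in the feedforward population
and stays flat in the feedback population — the normalization signature the
pipeline is built to detect.

A CLI exposes the same functionality
(`obpc simulate-circuit | dose-response | make-synthetic | analyze |
polarity-null`); every run writes a provenance record with the resolved
configuration and seed.

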