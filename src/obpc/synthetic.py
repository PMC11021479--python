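"""Synthetic ΔF/F response tensors with the statistical structure of
feedforward (OSN) and feedback (cortical bouton) odor representations.

The generators are the test bed for the analysis pipeline: they produce
ROI × stimulus × trial amplitude tensors (plus blank trials) whose design
mirrors the contrasts the analyses are meant to detect:

* OSN tensors — per-component receptor sensitivities drive responses through
  a saturating nonlinearity, so response density and population sparseness
  grow sublinearly with mixture size, shared components make overlapping
  mixtures correlated, and concentration series follow Hill (sigmoidal)
  curves.  A minority of ROIs carries sign-flipped (suppressed) tuning.
* Bouton tensors — response density is stimulus-independent and tuning is
  (by default) independent across stimuli, so sparseness and mixture-mixture
  correlation profiles are flat.  The enhanced:suppressed balance and the
  higher trial-to-trial variability of feedback axons are built in.
  Optionally, bouton responses are produced by simulating the bulb-to-cortex
  circuit model on per-component glomerular input, which inherits
  nonmonotonic concentration tuning from the global-inhibition loop.

Stimulus panels reproduce the study design: 16 monomolecular odorants plus
84 mixtures (24/20/20/20 of sizes 2/4/8/12), and an 8-step concentration
series spanning a 10^3 concentration ratio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .circuit import CircuitSpec, simulate_drive
from .pipeline import N_COMPONENTS, ResponseTensor, Stimulus, StimulusPanel

__all__ = [
    "OsnGeneratorParams",
    "BoutonGeneratorParams",
    "MIXTURE_SIZE_COUNTS",
    "make_mixture_panel",
    "make_concentration_panel",
    "simulate_osn_tensor",
    "simulate_bouton_tensor",
]

#: Mixture panel composition: {mixture size: number of mixtures}.
MIXTURE_SIZE_COUNTS = {2: 24, 4: 20, 8: 20, 12: 20}

#: Concentration series: 8 log-spaced steps over the delivered 0.08%-80% (v/v) range.
CONC_MIN = 8e-4
CONC_MAX = 0.8
N_CONC_STEPS = 8


# ---------------------------------------------------------------------------
# Stimulus panels
# ---------------------------------------------------------------------------

def make_mixture_panel(seed: int | None = None) -> StimulusPanel:
    """16 monomolecular odorants + 84 mixtures (sizes 2, 4, 8, 12).

    Component sets are sampled uniformly without replacement within each size
    class, all distinct; reproducible under a fixed seed.
    """
    rng = np.random.default_rng(seed)
    stimuli = [Stimulus(id=f"od{c + 1:02d}", kind="odorant",
                        components=frozenset({c})) for c in range(N_COMPONENTS)]
    for size, count in MIXTURE_SIZE_COUNTS.items():
        seen: set = set()
        while len(seen) < count:
            comps = frozenset(rng.choice(N_COMPONENTS, size=size, replace=False).tolist())
            seen.add(comps)
        # sort for a deterministic ordering independent of draw history
        for k, comps in enumerate(sorted(seen, key=sorted)):
            stimuli.append(Stimulus(id=f"mix{size:02d}_{k + 1:02d}", kind="mixture",
                                    components=comps))
    return StimulusPanel(tuple(stimuli))


def make_concentration_panel(n_steps: int = N_CONC_STEPS,
                             c_min: float = CONC_MIN, c_max: float = CONC_MAX,
                             component: int = 0) -> StimulusPanel:
    """One odorant at ``n_steps`` log-spaced relative concentrations."""
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    if not 0 < c_min < c_max:
        raise ValueError("need 0 < c_min < c_max")
    levels = np.logspace(np.log10(c_min), np.log10(c_max), n_steps)
    return StimulusPanel(tuple(
        Stimulus(id=f"conc{k + 1}", kind="concentration_step",
                 components=frozenset({component}),
                 concentration_level=k + 1, concentration=float(c))
        for k, c in enumerate(levels)))


# ---------------------------------------------------------------------------
# OSN generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class OsnGeneratorParams:
    """Parameters of the feedforward (OSN) tensor generator.

    ``component_response_prob`` sets how many ROIs are sensitive to each of
    the 16 components; drives of sensitive pairs are log-normal.  Mixture
    responses pass the summed component drive through ``s/(1+s)``
    (``additive_saturating``) or a competitive-binding rule
    (``antagonistic``); both are sublinear in mixture size.  Concentration
    responses are Hill curves with per-ROI midpoints log-uniform over the
    panel range.  ``trial_noise_sd`` is calibrated so that trial-to-trial
    population-vector correlation sits near the feedforward level (~0.78).
    """

    n_rois: int = 400
    component_response_prob: float = 0.12
    drive_logmean: float = 0.5   # natural-log median of component drives
    drive_logsd: float = 1.0
    mixture_rule: str = "additive_saturating"
    hill_slope: float = 2.0
    suppressed_fraction: float = 0.1
    amp_scale: float = 1.0       # ΔF/F units of a saturating response
    trial_noise_sd: float = 0.12
    n_trials: int = 3
    n_blank_trials: int = 6
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_rois < 1 or self.n_trials < 1 or self.n_blank_trials < 1:
            raise ValueError("counts must be >= 1")
        for name in ("component_response_prob", "suppressed_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.trial_noise_sd <= 0:
            raise ValueError("trial_noise_sd must be > 0")
        if self.mixture_rule not in ("additive_saturating", "antagonistic"):
            raise ValueError("mixture_rule must be 'additive_saturating' or 'antagonistic'")
        if self.hill_slope <= 0 or self.drive_logsd <= 0 or self.amp_scale <= 0:
            raise ValueError("hill_slope, drive_logsd and amp_scale must be > 0")


def _noiseless_osn(panel: StimulusPanel, p: OsnGeneratorParams,
                   rng_struct: np.random.Generator) -> np.ndarray:
    """Noise-free ROI × stimulus response matrix for an OSN population."""
    mask = rng_struct.random((p.n_rois, N_COMPONENTS)) < p.component_response_prob
    drives = np.exp(rng_struct.normal(p.drive_logmean, p.drive_logsd,
                                      size=(p.n_rois, N_COMPONENTS)))
    sens = np.where(mask, drives, 0.0)
    efficacy = rng_struct.uniform(0.2, 1.0, size=(p.n_rois, N_COMPONENTS))
    sign = np.where(rng_struct.random(p.n_rois) < p.suppressed_fraction, -1.0, 1.0)
    # Hill midpoints for concentration stimuli, log-uniform over the panel range
    conc_values = [s.concentration for s in panel if s.kind == "concentration_step"]
    if conc_values:
        lo, hi = np.log10(min(conc_values)), np.log10(max(conc_values))
        midpoints = 10.0 ** rng_struct.uniform(lo, hi, size=p.n_rois)

    r0 = np.zeros((p.n_rois, len(panel)))
    for j, stim in enumerate(panel):
        comps = sorted(stim.components)
        if stim.kind == "concentration_step":
            sat = sens[:, comps[0]]
            a = sat / (1.0 + sat)
            c, h = stim.concentration, p.hill_slope
            r0[:, j] = a * c ** h / (c ** h + midpoints ** h)
        else:
            s = sens[:, comps].sum(axis=1)
            if p.mixture_rule == "additive_saturating":
                r0[:, j] = s / (1.0 + s)
            else:  # antagonistic: competitive binding with partial efficacies
                num = (efficacy[:, comps] * sens[:, comps]).sum(axis=1)
                r0[:, j] = num / (1.0 + s)
    return p.amp_scale * sign[:, None] * r0


def simulate_osn_tensor(panel: StimulusPanel,
                        params: OsnGeneratorParams | None = None,
                        return_truth: bool = False):
    """Generate an OSN ResponseTensor (optionally with the noise-free truth).

    Per-trial amplitudes are the noiseless response plus i.i.d. Gaussian trial
    noise; blank trials are pure noise.  With ``return_truth=True`` the
    noiseless matrix and the ground-truth responsive mask are returned
    alongside the tensor.
    """
    p = params or OsnGeneratorParams()
    ss = np.random.SeedSequence(p.seed)
    rng_struct, rng_noise = (np.random.default_rng(c) for c in ss.spawn(2))
    r0 = _noiseless_osn(panel, p, rng_struct)
    amplitudes = r0[:, :, None] + rng_noise.normal(
        0.0, p.trial_noise_sd, size=(p.n_rois, len(panel), p.n_trials))
    blanks = rng_noise.normal(0.0, p.trial_noise_sd,
                              size=(p.n_rois, p.n_blank_trials))
    tensor = ResponseTensor(amplitudes, blanks, panel, population_label="OSN")
    if return_truth:
        return tensor, {"noiseless": r0, "responsive": np.abs(r0) > 0}
    return tensor


# ---------------------------------------------------------------------------
# Bouton generator
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BoutonGeneratorParams:
    """Parameters of the feedback (cortical bouton) tensor generator.

    Direct mode: every stimulus activates an independently drawn ROI subset
    at the target ``density`` (stimulus-independent, matching the observed
    72.2% per-odorant unresponsive rate), signed enhanced/suppressed at the
    observed balance.  ``decorrelate=False`` fixes a single responder set
    across stimuli instead.  ``trial_noise_sd`` is calibrated to the higher
    trial-to-trial variability of feedback axons (~0.53 population-vector
    reliability).  Circuit mode (``derive_from_circuit``) replaces the direct
    draw with steady-state output of the bulb-to-cortex model on
    per-component glomerular input.
    """

    n_rois: int = 800
    density: float = 0.278
    enhanced_fraction: float = 0.446  # 12.4 : 15.4 enhanced:suppressed balance
    amp_logmean: float = -0.5
    amp_logsd: float = 0.5
    amp_scale: float = 1.0
    trial_noise_sd: float = 0.39
    decorrelate: bool = True
    derive_from_circuit: CircuitSpec | None = None
    mixture_concentration: float = 1.0  # odor concentration used in circuit mode
    n_trials: int = 3
    n_blank_trials: int = 6
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_rois < 1 or self.n_trials < 1 or self.n_blank_trials < 1:
            raise ValueError("counts must be >= 1")
        if not 0.0 < self.density < 1.0:
            raise ValueError("density must be in (0, 1)")
        if not 0.0 <= self.enhanced_fraction <= 1.0:
            raise ValueError("enhanced_fraction must be in [0, 1]")
        if self.trial_noise_sd <= 0 or self.amp_scale <= 0:
            raise ValueError("trial_noise_sd and amp_scale must be > 0")


def _noiseless_bouton_direct(panel: StimulusPanel, p: BoutonGeneratorParams,
                             rng: np.random.Generator) -> np.ndarray:
    n_stim = len(panel)
    if p.decorrelate:
        mask = rng.random((p.n_rois, n_stim)) < p.density
    else:
        mask = np.broadcast_to((rng.random(p.n_rois) < p.density)[:, None],
                               (p.n_rois, n_stim)).copy()
    amp = np.exp(rng.normal(p.amp_logmean, p.amp_logsd, size=(p.n_rois, n_stim)))
    sign = np.where(rng.random((p.n_rois, n_stim)) < p.enhanced_fraction, 1.0, -1.0)
    return p.amp_scale * np.where(mask, sign * amp, 0.0)


def _noiseless_bouton_circuit(panel: StimulusPanel, p: BoutonGeneratorParams,
                              rng: np.random.Generator) -> np.ndarray:
    """Bouton responses from steady states of the bulb-to-cortex model.

    A per-component affinity/efficacy table is sampled (same distributions as
    the circuit's single-odor panel); a stimulus's glomerular drive combines
    its components by competitive binding,
    ``x_i = sum_k eta_ik kappa_ik c / (1 + sum_k kappa_ik c)``,
    which reduces to the single-odor occupancy curve for one component.
    Steady-state rectified outputs of the first ``n_rois`` cortical neurons
    are rescaled to ΔF/F-like units (population maximum -> amp_scale).
    """
    spec = p.derive_from_circuit
    if p.n_rois > spec.n_cortical:
        raise ValueError("n_rois exceeds the circuit's cortical population")
    n_glom = spec.panel.n_glomeruli
    sd = np.std(spec.panel.log_affinities) or 3.0
    prob = float(np.mean(spec.panel.efficacies)) or 0.2
    kappa = np.exp(rng.normal(0.0, sd, size=(n_glom, N_COMPONENTS)))
    eta = (rng.random((n_glom, N_COMPONENTS)) < prob).astype(float)
    r0 = np.zeros((p.n_rois, len(panel)))
    for j, stim in enumerate(panel):
        comps = sorted(stim.components)
        c = stim.concentration if stim.concentration is not None else p.mixture_concentration
        kc = kappa[:, comps] * c
        x = (eta[:, comps] * kc).sum(axis=1) / (1.0 + kc.sum(axis=1))
        trace = simulate_drive(spec, x)
        r0[:, j] = trace.steady_state()[: p.n_rois]
    peak = r0.max()
    if peak > 0:
        r0 *= p.amp_scale / peak
    return r0


def simulate_bouton_tensor(panel: StimulusPanel,
                           params: BoutonGeneratorParams | None = None,
                           return_truth: bool = False):
    """Generate a bouton ResponseTensor (direct or circuit-derived)."""
    p = params or BoutonGeneratorParams()
    ss = np.random.SeedSequence(p.seed)
    rng_struct, rng_noise = (np.random.default_rng(c) for c in ss.spawn(2))
    if p.derive_from_circuit is not None:
        r0 = _noiseless_bouton_circuit(panel, p, rng_struct)
    else:
        r0 = _noiseless_bouton_direct(panel, p, rng_struct)
    amplitudes = r0[:, :, None] + rng_noise.normal(
        0.0, p.trial_noise_sd, size=(p.n_rois, len(panel), p.n_trials))
    blanks = rng_noise.normal(0.0, p.trial_noise_sd,
                              size=(p.n_rois, p.n_blank_trials))
    tensor = ResponseTensor(amplitudes, blanks, panel, population_label="bouton")
    if return_truth:
        return tensor, {"noiseless": r0, "responsive": np.abs(r0) > 0}
    return tensor
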