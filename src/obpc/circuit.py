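"""Rate model of the olfactory bulb → piriform cortex feedback loop.

The model has three stages:

1. Glomerular input.  Each odorant binds the receptors feeding glomerulus
   ``i`` with affinity ``kappa_i`` and activates it with binary efficacy
   ``eta_i``; the steady glomerular output at concentration ``c`` is the
   receptor-occupancy curve ``x_i(c) = eta_i * kappa_i c / (1 + kappa_i c)``.
2. Sparse random expansion.  A non-negative sparse matrix ``W`` projects the
   ``N_g`` glomerular signals onto ``N_p`` cortical neurons.
3. Global activity-dependent inhibition.  One interneuron (or a heterogeneous
   population) sums rectified cortical output and, above a threshold, feeds
   back a non-specific inhibitory drive:

       tau du_j/dt = -u_j - w_inh * sigma(beta (v - v_thr)) + sum_i W_ji x_i
       tau dv/dt   = -v + sum_j max(u_j, 0)

   with ``sigma`` the logistic function.  The loop makes individual cortical
   dose-response curves nonmonotonic (rise, dip when inhibition engages,
   recovery at saturating input) while response latency still falls
   monotonically with concentration.

All times (``dt``, ``duration``, latencies) are expressed in units of the
membrane time constant ``tau``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

__all__ = [
    "GlomerularPanel",
    "ProjectionMatrix",
    "InterneuronPopulation",
    "CircuitSpec",
    "SimulationTrace",
    "DoseResponseCurve",
    "CircuitDivergenceError",
    "sample_glomerular_panel",
    "glomerular_output",
    "sample_projection",
    "make_heterogeneous_interneurons",
    "simulate",
    "simulate_drive",
    "dose_response",
    "response_latency",
    "detect_nonmonotonicity",
    "nonmonotonic_flags",
    "default_spec",
]

# Default parameters of the cortical circuit.
N_GLOMERULI = 400
N_CORTICAL = 5000
LOG_AFFINITY_SD = 3.0
ACTIVATION_PROB = 0.2
PROJECTION_DENSITY = 0.1
PROJECTION_SCALE = 0.5
W_INH = 1.0
BETA = 2.0
V_THR = 2000.0
N_HETERO_INTERNEURONS = 500
JITTER_SD = 0.2
DT = 0.01           # integration step, units of tau
DURATION = 20.0     # simulated time, units of tau
STEADY_FRACTION = 0.2   # final fraction of the trace averaged for steady state
DIVERGENCE_GUARD = 1e8  # |u| beyond this aborts the integration


class CircuitDivergenceError(RuntimeError):
    """Raised when the forward-Euler integration blows up."""


# ---------------------------------------------------------------------------
# Glomerular input (receptor occupancy)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GlomerularPanel:
    """Per-glomerulus binding affinities and binary activation efficacies.

    ``log_affinities`` holds natural logs of the affinities ``kappa_i``
    (units: log inverse concentration); ``efficacies`` is the 0/1 vector
    ``eta_i``.
    """

    log_affinities: np.ndarray
    efficacies: np.ndarray
    seed: int | None = None

    def __post_init__(self) -> None:
        la = np.asarray(self.log_affinities, dtype=float)
        eta = np.asarray(self.efficacies)
        if la.ndim != 1 or eta.shape != la.shape:
            raise ValueError("log_affinities and efficacies must be 1-D and equal length")
        if not np.isin(eta, (0, 1)).all():
            raise ValueError("efficacies must be binary (0 or 1)")
        object.__setattr__(self, "log_affinities", la)
        object.__setattr__(self, "efficacies", eta.astype(np.int8))

    @property
    def n_glomeruli(self) -> int:
        return self.log_affinities.size

    @property
    def affinities(self) -> np.ndarray:
        """Affinities ``kappa_i = exp(log_affinities)``."""
        return np.exp(self.log_affinities)


def sample_glomerular_panel(
    n_glomeruli: int = N_GLOMERULI,
    log_affinity_sd: float = LOG_AFFINITY_SD,
    activation_prob: float = ACTIVATION_PROB,
    seed: int | None = None,
) -> GlomerularPanel:
    """Draw a random odor: log-affinities ~ N(0, sd²), efficacies ~ Bernoulli(p).

    With the default sd the affinities span roughly three orders of magnitude,
    and about 20% of glomeruli are activated at saturating concentration.
    """
    if n_glomeruli < 1:
        raise ValueError("n_glomeruli must be >= 1")
    if log_affinity_sd <= 0:
        raise ValueError("log_affinity_sd must be > 0")
    if not 0.0 <= activation_prob <= 1.0:
        raise ValueError("activation_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    log_kappa = rng.normal(0.0, log_affinity_sd, size=n_glomeruli)
    eta = rng.random(n_glomeruli) < activation_prob
    return GlomerularPanel(log_kappa, eta.astype(np.int8), seed=seed)


def glomerular_output(panel: GlomerularPanel, concentration: float) -> np.ndarray:
    """Steady glomerular activity ``x_i(c) = eta_i * kappa_i c / (1 + kappa_i c)``."""
    if concentration < 0:
        raise ValueError("concentration must be non-negative")
    kc = panel.affinities * concentration
    return panel.efficacies * (kc / (1.0 + kc))


# ---------------------------------------------------------------------------
# Bulb-to-cortex projection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProjectionMatrix:
    """Sparse non-negative feedforward weights W (n_cortical × n_glomeruli)."""

    weights: np.ndarray
    density: float = PROJECTION_DENSITY
    scale: float = PROJECTION_SCALE
    seed: int | None = None

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2:
            raise ValueError("weights must be a 2-D matrix")
        if (w < 0).any():
            raise ValueError("projection weights must be non-negative")
        object.__setattr__(self, "weights", w)

    @property
    def shape(self) -> tuple[int, int]:
        return self.weights.shape


def sample_projection(
    n_cortical: int = N_CORTICAL,
    n_glomeruli: int = N_GLOMERULI,
    density: float = PROJECTION_DENSITY,
    scale: float = PROJECTION_SCALE,
    seed: int | None = None,
) -> ProjectionMatrix:
    """Entries non-zero with probability ``density``, drawn half-normal(scale).

    The default scale sets the mean cortical drive at saturating
    concentration (20% of 400 glomeruli fully on) to
    400 · 0.1 · 0.2 · 0.5 · sqrt(2/pi) ≈ 3.19; only its ratio to the
    inhibitory weight matters for the circuit's phenomenology.
    """
    if n_cortical < 1 or n_glomeruli < 1:
        raise ValueError("matrix dimensions must be >= 1")
    if not 0.0 < density <= 1.0:
        raise ValueError("density must be in (0, 1]")
    if scale <= 0:
        raise ValueError("scale must be > 0")
    rng = np.random.default_rng(seed)
    mask = rng.random((n_cortical, n_glomeruli)) < density
    magnitudes = np.abs(rng.normal(0.0, scale, size=(n_cortical, n_glomeruli)))
    return ProjectionMatrix(np.where(mask, magnitudes, 0.0), density, scale, seed)


# ---------------------------------------------------------------------------
# Inhibitory interneurons
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InterneuronPopulation:
    """Global inhibitory units, each with (w_inh, beta, v_thr).

    The homogeneous model is the single triple (1, 2, 2000).  Each neuron
    integrates its own voltage ``v_k`` from the summed rectified cortical
    output; the inhibition delivered to every cortical neuron is the
    population mean of ``w_inh_k * sigma(beta_k (v_k - v_thr_k))``.
    """

    w_inh: np.ndarray
    beta: np.ndarray
    v_thr: np.ndarray

    def __post_init__(self) -> None:
        w = np.atleast_1d(np.asarray(self.w_inh, dtype=float))
        b = np.atleast_1d(np.asarray(self.beta, dtype=float))
        t = np.atleast_1d(np.asarray(self.v_thr, dtype=float))
        if not (w.shape == b.shape == t.shape):
            raise ValueError("w_inh, beta, v_thr must have equal length")
        if (w < 0).any():
            raise ValueError("w_inh must be non-negative")
        if (b <= 0).any():
            raise ValueError("beta must be positive")
        object.__setattr__(self, "w_inh", w)
        object.__setattr__(self, "beta", b)
        object.__setattr__(self, "v_thr", t)

    @property
    def n_interneurons(self) -> int:
        return self.w_inh.size

    @classmethod
    def homogeneous(cls, w_inh: float = W_INH, beta: float = BETA,
                    v_thr: float = V_THR) -> "InterneuronPopulation":
        return cls(np.array([w_inh]), np.array([beta]), np.array([v_thr]))


def make_heterogeneous_interneurons(
    base: tuple[float, float, float] = (W_INH, BETA, V_THR),
    n_interneurons: int = N_HETERO_INTERNEURONS,
    jitter_sd: float = JITTER_SD,
    seed: int | None = None,
) -> InterneuronPopulation:
    """Population with each parameter scaled by 1 + eps, eps ~ N(0, jitter_sd²).

    Independent jitter per parameter per neuron.  Negative results (vanishingly
    rare at sd 0.2) are clipped at 0; beta is kept strictly positive.
    """
    if n_interneurons < 1:
        raise ValueError("n_interneurons must be >= 1")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    base_arr = np.asarray(base, dtype=float)
    factors = 1.0 + rng.normal(0.0, jitter_sd, size=(n_interneurons, 3))
    params = np.clip(base_arr[None, :] * factors, 0.0, None)
    params[:, 1] = np.maximum(params[:, 1], np.finfo(float).tiny)
    return InterneuronPopulation(params[:, 0], params[:, 1], params[:, 2])


# ---------------------------------------------------------------------------
# Circuit specification and simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CircuitSpec:
    """Full model specification: input panel, projection, inhibition, integration."""

    panel: GlomerularPanel
    projection: ProjectionMatrix
    interneurons: InterneuronPopulation = field(
        default_factory=InterneuronPopulation.homogeneous)
    tau: float = 1.0
    dt: float = DT
    duration: float = DURATION

    def __post_init__(self) -> None:
        if self.projection.shape[1] != self.panel.n_glomeruli:
            raise ValueError(
                f"projection shape {self.projection.shape} does not match "
                f"{self.panel.n_glomeruli} glomeruli")
        if not 0.0 < self.dt <= 0.1:
            raise ValueError("dt must be in (0, 0.1] (units of tau)")
        if self.duration < 10.0:
            raise ValueError("duration must be >= 10 (units of tau)")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    @property
    def n_cortical(self) -> int:
        return self.projection.shape[0]


def default_spec(seed: int = 0, heterogeneous: bool = False, **overrides) -> CircuitSpec:
    """Build the standard circuit (N_g=400, N_p=5000, w_inh=1, beta=2, v_thr=2000).

    Randomness is split into independent named streams (panel, projection,
    interneurons) spawned from ``seed`` so components can be regenerated
    independently.
    """
    ss = np.random.SeedSequence(seed)
    s_panel, s_proj, s_inter = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    n_glomeruli = overrides.pop("n_glomeruli", N_GLOMERULI)
    n_cortical = overrides.pop("n_cortical", N_CORTICAL)
    panel = sample_glomerular_panel(
        n_glomeruli,
        overrides.pop("log_affinity_sd", LOG_AFFINITY_SD),
        overrides.pop("activation_prob", ACTIVATION_PROB),
        seed=s_panel,
    )
    projection = sample_projection(
        n_cortical, n_glomeruli,
        overrides.pop("density", PROJECTION_DENSITY),
        overrides.pop("scale", PROJECTION_SCALE),
        seed=s_proj,
    )
    base = (overrides.pop("w_inh", W_INH), overrides.pop("beta", BETA),
            overrides.pop("v_thr", V_THR))
    if heterogeneous:
        inter = make_heterogeneous_interneurons(
            base, overrides.pop("n_interneurons", N_HETERO_INTERNEURONS),
            overrides.pop("jitter_sd", JITTER_SD), seed=s_inter)
    else:
        inter = InterneuronPopulation.homogeneous(*base)
    return CircuitSpec(panel=panel, projection=projection, interneurons=inter,
                       **overrides)


@dataclass(frozen=True)
class SimulationTrace:
    """Forward-Euler trajectories for one constant odor stimulus.

    ``u``: cortical voltages (n_cortical × n_timepoints); ``v``: interneuron
    voltages; ``x``: the constant glomerular input.  Rectified output ``y``
    is derived on access.
    """

    time_grid: np.ndarray
    u: np.ndarray
    v: np.ndarray
    x: np.ndarray

    @property
    def y(self) -> np.ndarray:
        return np.maximum(self.u, 0.0)

    def steady_state(self, fraction: float = STEADY_FRACTION) -> np.ndarray:
        """Per-neuron mean rectified output over the final ``fraction`` of the trace."""
        n_tail = max(1, int(np.ceil(fraction * self.time_grid.size)))
        return self.y[:, -n_tail:].mean(axis=1)


def _inhibition(pop: InterneuronPopulation, v: np.ndarray) -> float:
    """Population-mean inhibitory drive w_inh * sigma(beta (v - v_thr))."""
    return float(np.mean(pop.w_inh * expit(pop.beta * (v - pop.v_thr))))


def simulate(
    spec: CircuitSpec,
    concentration: float,
    freeze_inhibition: float | None = None,
) -> SimulationTrace:
    """Integrate the circuit for a step stimulus switched on at t = 0.

    The glomerular input ``x`` is computed once from the spec's panel and held
    constant; see :func:`simulate_drive` for arbitrary glomerular inputs.
    ``freeze_inhibition`` pins the sigmoidal gate at a constant value ``g`` in
    [0, 1] (inhibition term ``mean(w_inh) * g``), which is useful for checking
    analytic fixed points.
    """
    x = glomerular_output(spec.panel, concentration)
    return simulate_drive(spec, x, freeze_inhibition)


def simulate_drive(
    spec: CircuitSpec,
    x: np.ndarray,
    freeze_inhibition: float | None = None,
) -> SimulationTrace:
    """Integrate the circuit for an arbitrary constant glomerular input ``x``.

    Forward-Euler from zero initial conditions; ``u`` and ``v`` trajectories
    are recorded at every step.
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (spec.panel.n_glomeruli,):
        raise ValueError("x must have one entry per glomerulus")
    drive = spec.projection.weights @ x
    n_steps = int(round(spec.duration / spec.dt))
    time_grid = np.linspace(0.0, n_steps * spec.dt, n_steps + 1)
    pop = spec.interneurons

    u = np.zeros(spec.n_cortical)
    v = np.zeros(pop.n_interneurons)
    u_hist = np.empty((spec.n_cortical, n_steps + 1))
    v_hist = np.empty((pop.n_interneurons, n_steps + 1))
    u_hist[:, 0] = u
    v_hist[:, 0] = v

    frozen_inh = None
    if freeze_inhibition is not None:
        frozen_inh = float(np.mean(pop.w_inh)) * freeze_inhibition

    dt = spec.dt
    for step in range(1, n_steps + 1):
        y = np.maximum(u, 0.0)
        inh = frozen_inh if frozen_inh is not None else _inhibition(pop, v)
        sum_y = y.sum()
        u = u + dt * (-u - inh + drive)
        v = v + dt * (-v + sum_y)
        if not np.isfinite(u).all() or np.abs(u).max() > DIVERGENCE_GUARD:
            raise CircuitDivergenceError(
                f"integration diverged at t = {step * dt:.3f} tau "
                f"(dt = {dt}); reduce the step size")
        u_hist[:, step] = u
        v_hist[:, step] = v

    return SimulationTrace(time_grid=time_grid, u=u_hist, v=v_hist, x=x)


# ---------------------------------------------------------------------------
# Dose-response extraction
# ---------------------------------------------------------------------------

LATENCY_FRACTION = 0.5
RESPONSE_EPS = 1e-12


@dataclass(frozen=True)
class DoseResponseCurve:
    """Steady-state responses and latencies over a concentration grid.

    ``responses``: n_neurons × n_concentrations rectified steady states.
    ``latencies``: time (units of tau) to reach half of steady state; NaN
    where the neuron never responds.
    """

    concentrations: np.ndarray
    responses: np.ndarray
    latencies: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.concentrations, dtype=float)
        if c.ndim != 1 or (np.diff(c) <= 0).any():
            raise ValueError("concentrations must be strictly increasing")
        if (np.asarray(self.responses) < 0).any():
            raise ValueError("responses must be non-negative")
        object.__setattr__(self, "concentrations", c)


def _latencies_from_trace(trace: SimulationTrace,
                          fraction: float = LATENCY_FRACTION) -> np.ndarray:
    """Vectorized first-crossing latency for every neuron of a trace."""
    steady = trace.steady_state()
    y = trace.y
    thresh = fraction * steady
    crossed = y >= thresh[:, None]
    # exclude t=0 where y=0 would trivially cross a zero threshold
    crossed[:, 0] = False
    first = crossed.argmax(axis=1)
    lat = trace.time_grid[first].astype(float)
    lat[~crossed.any(axis=1)] = np.nan
    lat[steady <= RESPONSE_EPS] = np.nan
    return lat


def response_latency(trace: SimulationTrace, neuron: int,
                     fraction: float = LATENCY_FRACTION) -> float:
    """Time for neuron ``neuron`` to first reach ``fraction`` of steady state.

    Returns NaN (the "no response" sentinel) when the steady state is zero.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must be in (0, 1)")
    return float(_latencies_from_trace(trace, fraction)[neuron])


def dose_response(spec: CircuitSpec, concentrations) -> DoseResponseCurve:
    """Run ``simulate`` at each concentration; collect steady states and latencies."""
    c = np.asarray(concentrations, dtype=float)
    if c.ndim != 1 or c.size < 1 or (c <= 0).any():
        raise ValueError("concentrations must be positive")
    if (np.diff(c) <= 0).any():
        raise ValueError("concentrations must be sorted increasing")
    responses = np.empty((spec.n_cortical, c.size))
    latencies = np.empty((spec.n_cortical, c.size))
    for k, conc in enumerate(c):
        trace = simulate(spec, conc)
        responses[:, k] = trace.steady_state()
        latencies[:, k] = _latencies_from_trace(trace)
    return DoseResponseCurve(c, responses, latencies)


def detect_nonmonotonicity(curve, rel_tol: float = 0.1):
    """Flag a dose-response curve that dips below an earlier value.

    A curve is nonmonotonic when some response falls short of the running
    maximum at a lower concentration by more than ``rel_tol`` times the curve
    maximum.  Returns ``(flag, dip_index)`` with the index of the deepest dip
    (or -1 when monotone).
    """
    r = np.asarray(curve, dtype=float)
    if r.ndim != 1 or r.size < 3:
        raise ValueError("curve must be 1-D with at least 3 points")
    running_max = np.maximum.accumulate(r)
    dips = running_max - r
    peak = r.max()
    if peak <= 0 or dips.max() <= rel_tol * peak:
        return False, -1
    return True, int(dips.argmax())


def nonmonotonic_flags(responses: np.ndarray, rel_tol: float = 0.1) -> np.ndarray:
    """Vectorized ``detect_nonmonotonicity`` flag over rows of a response matrix."""
    r = np.asarray(responses, dtype=float)
    if r.ndim != 2 or r.shape[1] < 3:
        raise ValueError("responses must be n_neurons × >=3 concentrations")
    running_max = np.maximum.accumulate(r, axis=1)
    dips = (running_max - r).max(axis=1)
    peak = r.max(axis=1)
    with np.errstate(invalid="ignore"):
        return (peak > 0) & (dips > rel_tol * peak)
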