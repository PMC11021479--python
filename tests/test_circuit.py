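"""Circuit-model tests: input stage, projection, integrator, dose-response."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from obpc import circuit as cc


def small_spec(seed=2, **overrides):
    """Desk-scale circuit keeping the default parameter ratios."""
    overrides.setdefault("n_cortical", 300)
    overrides.setdefault("n_glomeruli", 80)
    overrides.setdefault("v_thr", 120.0)  # v_thr/n_cortical as in the full model
    return cc.default_spec(seed=seed, **overrides)


# ---------------------------------------------------------------------------
# Glomerular panel
# ---------------------------------------------------------------------------

class TestGlomerularPanel:
    def test_default_sampling_statistics(self):
        panel = cc.sample_glomerular_panel(400, seed=0)
        frac = panel.efficacies.mean()
        # binomial 99% CI around 0.2 at n=400
        half = 2.576 * np.sqrt(0.2 * 0.8 / 400)
        assert abs(frac - 0.2) < half
        # affinities span ~3 orders of magnitude (sd 3 in natural log)
        spread = np.percentile(panel.log_affinities, 97.5) - \
            np.percentile(panel.log_affinities, 2.5)
        assert spread / np.log(10) > 3.0

    def test_large_sample_sd_matches_parameter(self):
        panel = cc.sample_glomerular_panel(10000, 3.0, 0.2, seed=1)
        assert abs(panel.log_affinities.std() - 3.0) / 3.0 < 0.03

    def test_zero_activation_prob(self):
        panel = cc.sample_glomerular_panel(10, 3.0, 0.0, seed=0)
        assert (panel.efficacies == 0).all()

    def test_seed_reproducibility(self):
        a = cc.sample_glomerular_panel(100, seed=7)
        b = cc.sample_glomerular_panel(100, seed=7)
        np.testing.assert_array_equal(a.log_affinities, b.log_affinities)
        np.testing.assert_array_equal(a.efficacies, b.efficacies)

    @pytest.mark.parametrize("kwargs", [
        {"n_glomeruli": 0}, {"log_affinity_sd": 0.0},
        {"log_affinity_sd": -1.0}, {"activation_prob": 1.5},
    ])
    def test_invalid_arguments(self, kwargs):
        defaults = dict(n_glomeruli=10, log_affinity_sd=3.0, activation_prob=0.2)
        defaults.update(kwargs)
        with pytest.raises(ValueError):
            cc.sample_glomerular_panel(**defaults, seed=0)


class TestGlomerularOutput:
    def test_zero_concentration_is_silent(self):
        panel = cc.sample_glomerular_panel(50, seed=0)
        assert (cc.glomerular_output(panel, 0.0) == 0).all()

    def test_occupancy_midpoint(self):
        panel = cc.GlomerularPanel(np.zeros(3), np.array([1, 1, 0]))
        x = cc.glomerular_output(panel, 1.0)  # kappa = 1
        np.testing.assert_allclose(x, [0.5, 0.5, 0.0])

    def test_negative_concentration_rejected(self):
        panel = cc.sample_glomerular_panel(5, seed=0)
        with pytest.raises(ValueError):
            cc.glomerular_output(panel, -1.0)

    @settings(deadline=None, derandomize=True)
    @given(st.floats(min_value=0, max_value=1e6),
           st.floats(min_value=0, max_value=1e6))
    def test_bounded_and_monotone_in_concentration(self, c1, c2):
        panel = cc.sample_glomerular_panel(40, seed=3)
        lo, hi = sorted((c1, c2))
        x_lo, x_hi = (cc.glomerular_output(panel, c) for c in (lo, hi))
        assert (x_lo >= 0).all() and (x_hi <= panel.efficacies).all()
        assert (x_hi >= x_lo).all()


# ---------------------------------------------------------------------------
# Projection matrix
# ---------------------------------------------------------------------------

class TestProjection:
    def test_density_and_nonnegativity(self):
        proj = cc.sample_projection(5000, 400, seed=0)
        assert (proj.weights >= 0).all()
        frac = (proj.weights > 0).mean()
        half = 2.576 * np.sqrt(0.1 * 0.9 / (5000 * 400))
        assert abs(frac - 0.1) < half

    def test_degenerate_scale_gives_near_zero_entries(self):
        proj = cc.sample_projection(50, 20, density=1.0, scale=1e-12, seed=0)
        assert (proj.weights > 0).all() and proj.weights.max() < 1e-10

    def test_mean_saturating_input(self):
        # Mean cortical drive with 20% of glomeruli fully on:
        # n_g * density * activation_prob * half-normal mean = 3.19
        proj = cc.sample_projection(4000, 400, seed=9)
        panel = cc.sample_glomerular_panel(400, seed=10)
        drive = proj.weights @ panel.efficacies.astype(float)
        expected = 400 * 0.1 * 0.2 * 0.5 * np.sqrt(2 / np.pi)
        assert abs(drive.mean() - expected) / expected < 0.1

    def test_invalid_density(self):
        with pytest.raises(ValueError):
            cc.sample_projection(10, 10, density=0.0, seed=0)


# ---------------------------------------------------------------------------
# Interneurons
# ---------------------------------------------------------------------------

class TestInterneurons:
    def test_jitter_cv_matches_parameter(self):
        pop = cc.make_heterogeneous_interneurons(n_interneurons=500, seed=0)
        for values in (pop.w_inh, pop.beta, pop.v_thr):
            cv = values.std() / values.mean()
            assert abs(cv - 0.2) < 0.03

    def test_zero_jitter_replicates_base(self):
        pop = cc.make_heterogeneous_interneurons((1.0, 2.0, 2000.0), 5, 0.0, seed=0)
        np.testing.assert_array_equal(pop.w_inh, np.ones(5))
        np.testing.assert_array_equal(pop.beta, np.full(5, 2.0))
        np.testing.assert_array_equal(pop.v_thr, np.full(5, 2000.0))

    def test_single_unjittered_neuron_is_homogeneous(self):
        pop = cc.make_heterogeneous_interneurons((1.0, 2.0, 2000.0), 1, 0.0, seed=0)
        hom = cc.InterneuronPopulation.homogeneous()
        np.testing.assert_array_equal(pop.w_inh, hom.w_inh)
        np.testing.assert_array_equal(pop.v_thr, hom.v_thr)

    def test_validation(self):
        with pytest.raises(ValueError):
            cc.InterneuronPopulation(np.array([-1.0]), np.array([2.0]),
                                     np.array([0.0]))
        with pytest.raises(ValueError):
            cc.make_heterogeneous_interneurons(n_interneurons=0, seed=0)


# ---------------------------------------------------------------------------
# Integrator
# ---------------------------------------------------------------------------

class TestSimulate:
    def test_zero_input_stays_at_fixed_point(self):
        # u = v = 0 is the fixed point up to the sigmoid's far tail
        # (sigma(-beta*v_thr) ~ 1e-105 leaks an immeasurably small inhibition)
        spec = small_spec()
        trace = cc.simulate(spec, 0.0)
        assert np.abs(trace.u).max() < 1e-50
        assert np.abs(trace.v).max() < 1e-50

    def test_rectification_and_initial_conditions(self):
        spec = small_spec()
        trace = cc.simulate(spec, 1.0)
        np.testing.assert_array_equal(trace.y, np.maximum(trace.u, 0.0))
        assert (trace.u[:, 0] == 0).all() and (trace.v[:, 0] == 0).all()

    def test_subthreshold_steady_state_is_feedforward_drive(self):
        # with sigma frozen off, u* = sum_i W_ji x_i
        spec = small_spec()
        drive = spec.projection.weights @ cc.glomerular_output(spec.panel, 1.0)
        trace = cc.simulate(spec, 1.0, freeze_inhibition=0.0)
        assert np.abs(trace.u[:, -1] - drive).max() < 1e-3

    def test_saturated_inhibition_steady_state(self):
        # sigma forced to 1 via v_thr = -inf: u* = drive - w_inh
        spec = small_spec(v_thr=-np.inf)
        drive = spec.projection.weights @ cc.glomerular_output(spec.panel, 1.0)
        trace = cc.simulate(spec, 1.0)
        assert np.abs(trace.u[:, -1] - (drive - 1.0)).max() < 1e-3

    def test_frozen_inhibition_matches_analytic_fixed_point(self):
        spec = small_spec()
        drive = spec.projection.weights @ cc.glomerular_output(spec.panel, 1.0)
        for g in (0.25, 0.8):
            trace = cc.simulate(spec, 1.0, freeze_inhibition=g)
            assert np.abs(trace.u[:, -1] - (drive - g)).max() < 1e-3

    def test_halving_dt_converges(self):
        spec = small_spec(dt=0.01)
        spec_half = small_spec(dt=0.005)
        r1 = cc.simulate(spec, 10.0).steady_state()
        r2 = cc.simulate(spec_half, 10.0).steady_state()
        scale = max(r1.max(), 1e-12)
        assert np.abs(r1 - r2).max() / scale < 1e-3

    def test_heterogeneous_jitterless_population_matches_homogeneous(self):
        hom = small_spec()
        het_pop = cc.make_heterogeneous_interneurons((1.0, 2.0, 120.0), 1, 0.0,
                                                     seed=0)
        het = cc.CircuitSpec(panel=hom.panel, projection=hom.projection,
                             interneurons=het_pop, dt=hom.dt,
                             duration=hom.duration)
        t_hom = cc.simulate(hom, 10.0)
        t_het = cc.simulate(het, 10.0)
        np.testing.assert_array_equal(t_hom.u, t_het.u)  # bit-for-bit at n=1
        many = cc.CircuitSpec(
            panel=hom.panel, projection=hom.projection,
            interneurons=cc.make_heterogeneous_interneurons(
                (1.0, 2.0, 120.0), 500, 0.0, seed=0),
            dt=hom.dt, duration=hom.duration)
        np.testing.assert_allclose(cc.simulate(many, 10.0).u, t_hom.u,
                                   rtol=0, atol=1e-9)

    def test_spec_validation(self):
        spec = small_spec()
        with pytest.raises(ValueError):
            cc.CircuitSpec(panel=spec.panel, projection=spec.projection, dt=0.5)
        with pytest.raises(ValueError):
            cc.CircuitSpec(panel=spec.panel, projection=spec.projection,
                           duration=5.0)
        with pytest.raises(ValueError):
            cc.simulate_drive(spec, np.zeros(3))


# ---------------------------------------------------------------------------
# Dose-response and latency
# ---------------------------------------------------------------------------

class TestDoseResponse:
    def test_no_inhibition_curves_are_monotone(self):
        spec = small_spec(w_inh=0.0)
        curve = cc.dose_response(spec, np.logspace(-2, 2, 8))
        assert (np.diff(curve.responses, axis=1) >= -1e-9).all()
        assert not cc.nonmonotonic_flags(curve.responses).any()

    def test_inhibition_produces_nonmonotonic_neurons(self):
        curve = cc.dose_response(small_spec(), np.logspace(-3, 3, 12))
        assert cc.nonmonotonic_flags(curve.responses).sum() > 0

    def test_heterogeneous_inhibition_smooths_mean_curve(self):
        grid = np.logspace(-3, 3, 12)
        hom = cc.dose_response(small_spec(seed=1), grid).responses.mean(axis=0)
        het = cc.dose_response(small_spec(seed=1, heterogeneous=True),
                               grid).responses.mean(axis=0)
        kink = lambda m: np.abs(np.diff(m, 2)).max()
        drop = lambda m: float(np.maximum(np.maximum.accumulate(m) - m, 0).max())
        assert drop(het) <= drop(hom) + 1e-9
        assert kink(het) < kink(hom)

    def test_unsorted_concentrations_rejected(self):
        with pytest.raises(ValueError):
            cc.dose_response(small_spec(), [1.0, 0.5, 2.0])


class TestLatency:
    def test_first_order_relaxation_half_time(self):
        # without inhibition u(t) = a(1 - e^{-t}); half-max at ln 2
        spec = small_spec(w_inh=0.0)
        trace = cc.simulate(spec, 100.0)
        neuron = int(np.argmax(trace.steady_state()))
        lat = cc.response_latency(trace, neuron, fraction=0.5)
        assert abs(lat - np.log(2)) <= spec.dt + 1e-12

    def test_silent_neuron_returns_sentinel(self):
        spec = small_spec()
        trace = cc.simulate(spec, 0.0)
        assert np.isnan(cc.response_latency(trace, 0))

    def test_fraction_validation(self):
        trace = cc.simulate(small_spec(), 1.0)
        with pytest.raises(ValueError):
            cc.response_latency(trace, 0, fraction=1.5)


class TestNonmonotonicity:
    @pytest.mark.parametrize("curve,expected_flag,expected_dip", [
        ([0.1, 0.5, 0.9], False, -1),
        ([0.1, 0.5, 0.2, 0.6, 0.9], True, 2),
        ([0.0, 0.0, 0.0], False, -1),
    ])
    def test_examples(self, curve, expected_flag, expected_dip):
        flag, dip = cc.detect_nonmonotonicity(curve, rel_tol=0.1)
        assert flag == expected_flag
        assert dip == expected_dip

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError):
            cc.detect_nonmonotonicity([1.0, 2.0])

    def test_vectorized_flags_match_scalar(self, rng):
        curves = rng.random((20, 7))
        flags = cc.nonmonotonic_flags(curves)
        scalar = [cc.detect_nonmonotonicity(c)[0] for c in curves]
        np.testing.assert_array_equal(flags, scalar)
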