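"""Tail-current analysis: isochronal amplitudes, normalization, the γ/P_o
decomposition, instantaneous I–V, and the fitting routines."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

import cngrectify as cg
from cngrectify.errors import AlignmentError, NormalizationError, ParameterError
from cngrectify.tail_analysis import CurveTable


@pytest.fixture(scope="module")
def cs_recording(cs_model, tail_protocol):
    return cg.simulate_macroscopic(cs_model, tail_protocol, cg.NoiseSpec(1.0), seed=42)


class TestIsochronalTails:
    def test_flat_for_voltage_independent_gating(self, flat_po_model, tail_protocol):
        rec = cg.simulate_macroscopic(flat_po_model, tail_protocol, cg.NoiseSpec(1.0), seed=7)
        tails = cg.isochronal_tails(rec, mode="extrapolate")
        spread = tails.y.max() - tails.y.min()
        assert spread < 0.01 * np.abs(tails.y).mean()

    def test_monotone_for_monotone_po(self, cs_recording):
        tails = cg.isochronal_tails(cs_recording, mode="extrapolate")
        rho = stats.spearmanr(tails.V, np.abs(tails.y)).statistic
        assert rho > 0.95

    def test_latency_outside_tail_rejected(self, cs_recording):
        with pytest.raises(ParameterError):
            cg.isochronal_tails(cs_recording, t_iso=-1.0)
        with pytest.raises(ParameterError):
            cg.isochronal_tails(cs_recording, t_iso=50.0)

    def test_point_and_peak_modes_run(self, cs_recording):
        for mode in ("point", "peak"):
            tails = cg.isochronal_tails(cs_recording, mode=mode)
            assert len(tails) == cs_recording.n_sweeps


class TestNormalizeTails:
    def test_minsub_construction(self, cs_recording):
        tails = cg.isochronal_tails(cs_recording, mode="extrapolate")
        norm = cg.normalize_tails(tails, mode="minsub")
        assert norm.y.min() == 0.0
        assert norm.value_at(200.0) == pytest.approx(1.0, abs=1e-12)

    def test_plain_on_constant_curve(self):
        V = np.arange(-100.0, 201.0, 50.0)
        curve = CurveTable(V, np.full(V.size, 3.3))
        assert np.allclose(cg.normalize_tails(curve, mode="plain").y, 1.0)

    def test_missing_anchor_rejected(self):
        curve = CurveTable(np.array([-100.0, 0.0, 100.0]), np.array([0.1, 0.5, 1.0]))
        with pytest.raises(NormalizationError):
            cg.normalize_tails(curve, mode="minsub")

    @given(
        gain=st.floats(min_value=0.05, max_value=50.0),
        sign=st.sampled_from([-1.0, 1.0]),
        offset=st.floats(min_value=-100.0, max_value=100.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_minsub_invariant_to_affine_maps(self, gain, sign, offset):
        V = np.arange(-200.0, 201.0, 20.0)
        rng = np.random.default_rng(0)
        y = np.sort(rng.uniform(0, 10, V.size))
        base = cg.normalize_tails(CurveTable(V, y), mode="minsub")
        mapped = cg.normalize_tails(CurveTable(V, sign * gain * y + offset), mode="minsub")
        assert np.allclose(mapped.y, base.y, atol=1e-9)

    def test_dma_like_tail_curve_shows_plateau(self):
        # between the two gating transitions the normalized curve is locally flat
        model = cg.load_preset("dma_like")
        prot = cg.build_tail_protocol(0, -200, 200, 20, 100.0, -200, 5.0)
        rec = cg.simulate_macroscopic(model, prot, cg.NoiseSpec(1.0), seed=13)
        norm = cg.normalize_tails(cg.isochronal_tails(rec, mode="extrapolate"), mode="minsub")
        slopes = np.abs(np.gradient(norm.y, norm.V))
        inside = (norm.V > -50) & (norm.V < 50)
        assert slopes[inside].min() < 0.10 * slopes.max()


class TestSteadyConductance:
    def test_flat_for_ohmic_constant_po(self, flat_po_model, tail_protocol):
        rec = cg.simulate_macroscopic(flat_po_model, tail_protocol, cg.NoiseSpec(1.0), seed=3)
        G = cg.steady_conductance(rec, window=20.0)
        assert np.allclose(G.y, 1.0, atol=0.02)
        assert 0.0 not in G.V

    def test_cs_like_is_inwardly_rectifying(self, cs_recording):
        G = cg.steady_conductance(cs_recording, window=20.0)
        assert G.value_at(-200.0) > 1.0
        assert G.value_at(200.0) == pytest.approx(1.0, abs=1e-12)

    def test_ea_like_is_outwardly_rectifying(self):
        model = cg.load_preset("ea_like")
        prot = cg.build_tail_protocol(0, -200, 200, 20, 100.0, -200, 5.0)
        rec = cg.simulate_macroscopic(model, prot, cg.NoiseSpec(1.0), seed=5)
        G = cg.steady_conductance(rec, window=20.0)
        assert G.value_at(-200.0) < 0.5
        assert G.value_at(200.0) == pytest.approx(1.0, abs=1e-12)

    def test_window_overrun_rejected(self, cs_recording):
        with pytest.raises(ParameterError):
            cg.steady_conductance(cs_recording, window=150.0)


class TestGammaRatio:
    def test_identity_quotient(self):
        V = np.arange(-200.0, 201.0, 20.0)
        y = np.linspace(0.2, 1.0, V.size)
        out = cg.gamma_ratio(CurveTable(V, y), CurveTable(V, y))
        assert np.allclose(out.y, 1.0)

    def test_zero_po_point_masked_not_divided(self):
        V = np.array([-200.0, 0.0, 200.0])
        G = CurveTable(V, np.array([0.5, 0.7, 1.0]))
        Po = CurveTable(V, np.array([0.0, 0.5, 1.0]))
        out = cg.gamma_ratio(G, Po)
        assert -200.0 not in out.V
        assert -200.0 in out.flags

    def test_grid_mismatch_rejected(self):
        G = CurveTable(np.array([-100.0, 0.0, 100.0]), np.ones(3))
        Po = CurveTable(np.array([-100.0, 100.0]), np.ones(2))
        with pytest.raises(AlignmentError):
            cg.gamma_ratio(G, Po)


class TestFullPipeline:
    @pytest.mark.parametrize(
        "name", ["na_like", "rb_like", "cs_like", "ma_like", "dma_like", "wt_dma", "r2q_dma"]
    )
    def test_round_trip_recovers_generator_laws(self, name):
        """Simulate → tails/G/γ analysis must reproduce the model's own
        P_o(V) and γ(V) ratio curves (the EA-like preset deactivates faster
        than the recording bandwidth at −200 mV and is checked for
        conductance shape only, below)."""
        model = cg.load_preset(name)
        prot = cg.build_tail_protocol(0, -200, 200, 20, 100.0, -200, 5.0)
        rec = cg.simulate_macroscopic(model, prot, cg.NoiseSpec(1.0), seed=42)
        tails = cg.isochronal_tails(rec, mode="extrapolate")
        po = cg.normalize_tails(tails, mode="plain")
        G = cg.steady_conductance(rec, window=20.0)
        common = np.intersect1d(G.V, po.V)
        gam = cg.gamma_ratio(G.restrict(common), po.restrict(common))
        po_true = model.po(po.V) / model.po(200.0)
        gam_true = model.gamma(gam.V) / model.gamma(200.0)
        assert np.all(np.abs(po.y - po_true) <= np.maximum(0.10 * po_true, 0.04))
        assert np.all(np.abs(gam.y / gam_true - 1) <= 0.10)

    def test_cs_like_rectification_sign_structure(self, cs_model, cs_recording):
        # inwardly rectifying current while P_o still grows with depolarization
        G = cg.steady_conductance(cs_recording, window=20.0)
        i_m200 = G.value_at(-200.0)  # ∝ |I(−200)|/200 over G(+200)
        assert i_m200 > 1.0  # |I(−200)| > |I(+200)|
        assert cs_model.po(200.0) > cs_model.po(-200.0)


class TestInstantaneousIV:
    def _analytic_tail_set(self, model, prot, dt=0.02):
        """Deterministic (noise-free ensemble) tail family from the model laws."""
        n = prot.n_samples(dt)
        t = (np.arange(n) + 0.5) * dt
        onset = prot.epoch_start(1)
        traces = np.empty((prot.n_sweeps, n))
        p0 = model.po(prot.epochs[0].level)
        for s, V in enumerate(prot.sweep_levels):
            pre = t < onset
            traces[s, pre] = model.N * p0 * model.isc(prot.epochs[0].level)
            tt = t[~pre] - onset
            p_inf, tau = model.po(V), model.tau(V)
            occ = p_inf + (p0 - p_inf) * np.exp(-tt / tau)
            traces[s, ~pre] = model.N * occ * model.isc(V)
        return cg.SweepSet(dt=dt, traces=traces, protocol=prot,
                           meta={"signal_filtered": False})

    def test_noiseless_tau_recovery_within_2_percent(self, rb_model):
        prot = cg.build_instantaneous_iv_protocol(0, 200, 50.0, -200, 200, 20, 20.0)
        rec = self._analytic_tail_set(rb_model, prot)
        _, tau = cg.instantaneous_iv(rec)
        # exclude the prepulse voltage (no relaxation) and 0 mV (no current)
        keep = (np.abs(tau.V - 200.0) > 1) & (np.abs(tau.V) > 1)
        errs = np.abs(tau.y[keep] / rb_model.tau(tau.V[keep]) - 1)
        assert errs.max() < 0.02

    def test_deactivation_faster_at_hyperpolarized_potentials(self, rb_model):
        prot = cg.build_instantaneous_iv_protocol(0, 200, 50.0, -200, 200, 20, 20.0)
        rec = cg.simulate_macroscopic(rb_model, prot, cg.NoiseSpec(1.0), seed=21)
        _, tau = cg.instantaneous_iv(rec)
        neg = tau.V <= -60
        assert stats.spearmanr(tau.V[neg], tau.y[neg]).statistic > 0.9

    def test_recovered_instantaneous_iv_matches_generator(self, rb_model):
        prot = cg.build_instantaneous_iv_protocol(0, 200, 50.0, -200, 200, 20, 20.0)
        rec = cg.simulate_macroscopic(rb_model, prot, cg.NoiseSpec(1.0), seed=21)
        iv, _ = cg.instantaneous_iv(rec)
        keep = np.abs(iv.V) > 1
        truth = rb_model.isc(iv.V[keep]) / rb_model.isc(200.0)
        assert np.abs(iv.y[keep] / truth - 1).max() < 0.10


class TestFitTwoBoltzmann:
    def _wt_curve(self, noise_sd=0.0, reps=1, seed=0):
        model = cg.load_preset("wt_dma")
        V = np.arange(-180.0, 201.0, 20.0)
        y = cg.eval_two_boltzmann(V, model.po_law)
        if noise_sd == 0:
            return CurveTable(V, y), model.po_law
        rng = np.random.default_rng(seed)
        draws = y + rng.normal(0, noise_sd, (reps, V.size))
        sem = draws.std(axis=0, ddof=1) / np.sqrt(reps)
        return CurveTable(V, draws.mean(axis=0), sem=sem, n=np.full(V.size, reps)), model.po_law

    def test_noiseless_parameters_recovered_to_a_tenth_percent(self):
        curve, truth = self._wt_curve()
        fit = cg.fit_two_boltzmann(curve)
        assert fit.A == pytest.approx(truth.A, rel=1e-3)
        assert fit.V_mid1 == pytest.approx(truth.c1.V_mid, rel=1e-3)
        assert fit.k1 == pytest.approx(truth.c1.k, rel=1e-3)
        assert fit.V_mid2 == pytest.approx(truth.c2.V_mid, rel=1e-3)
        assert fit.k2 == pytest.approx(truth.c2.k, rel=1e-3)
        assert not fit.degenerate

    def test_estimates_converge_as_noise_shrinks(self):
        errs = []
        for sd in (0.05, 0.02, 0.005):
            curve, truth = self._wt_curve(noise_sd=sd, reps=6, seed=1)
            fit = cg.fit_two_boltzmann(curve)
            errs.append(abs(fit.z1 - truth.c1.z()) + abs(fit.z2 - truth.c2.z()))
        assert errs[0] > errs[2]
        assert errs[1] > errs[2]

    def test_single_boltzmann_data_flagged_degenerate(self):
        V = np.arange(-180.0, 201.0, 20.0)
        y = 1.0 / (1.0 + np.exp((-20.0 - V) / 25.0))
        fit = cg.fit_two_boltzmann(CurveTable(V, y))
        assert fit.degenerate

    def test_too_few_points_rejected(self):
        V = np.arange(-60.0, 61.0, 20.0)
        with pytest.raises(ParameterError):
            cg.fit_two_boltzmann(CurveTable(V, np.linspace(0, 1, V.size)))


class TestActivationKinetics:
    def test_noiseless_biexponential_recovery(self):
        t = np.arange(0, 15, 0.02)
        y = 5.0 - 2.0 * np.exp(-t / 0.08) - 3.0 * np.exp(-t / 1.5)
        fit = cg.fit_activation(t, y)
        assert fit.tau_f == pytest.approx(0.08, rel=0.01)
        assert fit.tau_s == pytest.approx(1.5, rel=0.01)
        assert fit.tau_f < fit.tau_s

    def test_single_exponential_input_flagged(self):
        t = np.arange(0, 10, 0.02)
        y = 4.0 - 4.0 * np.exp(-t / 1.2)
        fit = cg.fit_activation(t, y)
        assert "single-exponential" in fit.flags or "tau-overlap" in fit.flags

    def test_close_time_constants_raise_identifiability_flag(self):
        t = np.arange(0, 10, 0.02)
        rng = np.random.default_rng(0)
        y = 5 - 2 * np.exp(-t / 0.9) - 2 * np.exp(-t / 1.1) + rng.normal(0, 0.01, t.size)
        fit = cg.fit_activation(t, y)
        assert "tau-overlap" in fit.flags

    def test_tau_bell_recovers_equivalent_charge(self):
        # τ(V) generated with z_eq = 0.88 plus multiplicative scatter
        law = cg.load_preset("ea_like").rate_law
        V = np.arange(-180.0, 201.0, 20.0)
        tau = cg.relaxation(V, law)[2]
        rng = np.random.default_rng(2)
        noisy = np.mean([tau * rng.lognormal(0, 0.10, tau.size) for _ in range(5)], axis=0)
        fit = cg.fit_tau_bell(CurveTable(V, noisy))
        assert fit.z_eq == pytest.approx(law.za + law.zb, rel=0.10)

    def test_bell_fit_needs_five_voltages(self):
        with pytest.raises(ParameterError):
            cg.fit_tau_bell(CurveTable(np.array([-40.0, 0.0, 40.0]), np.ones(3)))
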