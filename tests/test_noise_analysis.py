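"""Stationary noise analysis and Gaussian-mixture channel counting."""

import numpy as np
import pytest

import cngrectify as cg
from cngrectify.errors import ParameterError
from conftest import make_counting_model


def _steady_protocol(V, dur=200.0):
    return cg.build_tail_protocol(V, V, V, 20, dur, V, 1.0)


class TestVarianceToMean:
    def test_matches_hidden_state_oracle(self, cs_model):
        # brute-force oracle: variance/mean computed directly from the
        # simulator's hidden n_open path (noise off)
        V = -120.0
        prot = _steady_protocol(V, dur=300.0)
        rec = cg.simulate_macroscopic(
            cs_model, prot, cg.NoiseSpec(0.0), seed=17, store_states=True
        )
        seal = cg.simulate_background(prot, cg.NoiseSpec(0.0), seed=18)
        table = cg.variance_to_mean(rec, seal, window=250.0)
        sel = rec.time() >= prot.epochs[0].duration - 250.0
        sel &= rec.time() < prot.epochs[0].duration
        n_open = rec.meta["n_open"][0, sel]
        isc = cs_model.isc(V)
        oracle = (n_open * isc).var(ddof=1) / (n_open * isc).mean()
        assert table.ratio[0] == pytest.approx(oracle, rel=0.02)

    def test_saturated_gating_gives_zero_ratio(self, na_model):
        law = cg.TwoBoltzmann(
            1.0, cg.BoltzmannComponent(-3000.0, 20.0), cg.BoltzmannComponent(-3000.0, 20.0)
        )
        model = cg.ChannelModel(po_law=law, rate_law=na_model.rate_law,
                                perm=na_model.perm, N=10000, name="saturated")
        V = 100.0
        prot = _steady_protocol(V)
        rec = cg.simulate_macroscopic(model, prot, cg.NoiseSpec(1.0), seed=6)
        seal = cg.simulate_background(prot, cg.NoiseSpec(1.0), seed=7)
        table = cg.variance_to_mean(rec, seal, window=150.0)
        assert abs(table.ratio[0]) < 0.05

    def test_ratio_tracks_gating_noise_law_across_voltages(self, cs_model):
        prot = cg.build_tail_protocol(0, -200, 200, 20, 200.0, -200, 2.0)
        vc, vs, im = [], [], []
        for r in range(8):
            rec = cg.simulate_macroscopic(cs_model, prot, cg.NoiseSpec(1.0), seed=300 + r)
            seal = cg.simulate_background(prot, cg.NoiseSpec(1.0), seed=800 + r)
            t = cg.variance_to_mean(rec, seal, window=150.0)
            vc.append(t.var_cgmp), vs.append(t.var_seal), im.append(t.I_mean)
        ratio = (np.mean(vc, 0) - np.mean(vs, 0)) / np.mean(im, 0)
        V = t.V
        pred = cs_model.isc(V) * (1 - cs_model.po(V))
        ok = V != 0
        assert np.abs(ratio[ok] / pred[ok] - 1).max() < 0.12

    def test_subtraction_removes_any_seal_level(self, cs_model):
        V = -160.0
        prot = _steady_protocol(V, dur=300.0)
        ratios = []
        for rms in (0.5, 2.0):
            rec = cg.simulate_macroscopic(cs_model, prot, cg.NoiseSpec(rms), seed=9)
            seal = cg.simulate_background(prot, cg.NoiseSpec(rms), seed=10)
            ratios.append(cg.variance_to_mean(rec, seal, window=250.0).ratio[0])
        assert ratios[0] == pytest.approx(ratios[1], rel=0.10)

    def test_low_current_points_masked(self, cs_model):
        prot = cg.build_tail_protocol(0, -20, 20, 20, 200.0, -20, 2.0)
        rec = cg.simulate_macroscopic(cs_model, prot, cg.NoiseSpec(1.0), seed=1)
        seal = cg.simulate_background(prot, cg.NoiseSpec(1.0), seed=2)
        table = cg.variance_to_mean(rec, seal, window=100.0, floor=1e6)
        assert np.all(np.isnan(table.ratio))
        assert len(table.masked) == 3


class TestPredictedRatio:
    def test_saturated_po_is_identically_zero(self, na_model):
        law = cg.TwoBoltzmann(
            1.0, cg.BoltzmannComponent(-5000.0, 10.0), cg.BoltzmannComponent(-5000.0, 10.0)
        )
        model = cg.ChannelModel(po_law=law, rate_law=na_model.rate_law,
                                perm=na_model.perm, N=1, name="sat")
        curve = cg.predicted_ratio(model, np.arange(-200.0, 201.0, 40.0))
        assert np.allclose(curve.y, 0.0, atol=1e-9)

    def test_half_open_ohmic_arithmetic(self, na_model):
        law = cg.TwoBoltzmann(
            1.0, cg.BoltzmannComponent(160.0, 25.0), cg.BoltzmannComponent(160.0, 25.0)
        )
        model = cg.ChannelModel(
            po_law=law, rate_law=na_model.rate_law,
            perm=cg.PermeationLaw(30.0, 30.0, 60.0), N=1, name="half",
        )
        curve = cg.predicted_ratio(model, [160.0])
        # P_o = 0.5, i_sc(+160) = 4.8 pA → ratio 2.4 pA
        assert curve.y[0] == pytest.approx(2.4, rel=1e-9)

    def test_simulation_agrees_with_prediction(self, cs_model):
        V = -100.0
        prot = _steady_protocol(V, dur=400.0)
        ratios = []
        for r in range(4):
            rec = cg.simulate_macroscopic(cs_model, prot, cg.NoiseSpec(1.0), seed=30 + 2 * r)
            seal = cg.simulate_background(prot, cg.NoiseSpec(1.0), seed=31 + 2 * r)
            ratios.append(cg.variance_to_mean(rec, seal, window=350.0).ratio[0])
        predicted = cg.predicted_ratio(cs_model, [V]).y[0]
        assert np.mean(ratios) == pytest.approx(predicted, rel=0.10)


class TestAbsolutePo:
    def test_limiting_values(self):
        assert cg.absolute_po_from_noise(0.0, 4.8)[0] == 1.0
        assert cg.absolute_po_from_noise(4.8, 4.8)[0] == 0.0
        with pytest.raises(ParameterError):
            cg.absolute_po_from_noise(1.0, 0.0)

    def test_recovers_generator_open_probability(self, na_model):
        # P_o = 0.8 channel; noise-measured ratio inverted for absolute P_o
        vt = cg.CONSTANTS.thermal_mV
        vmid = 60.0 - vt * np.log(4.0)  # P_o(+60) = 0.8
        law = cg.TwoBoltzmann(
            1.0, cg.BoltzmannComponent(vmid, vt), cg.BoltzmannComponent(vmid, vt)
        )
        model = cg.ChannelModel(po_law=law, rate_law=na_model.rate_law,
                                perm=cg.PermeationLaw(30.0, 30.0, 60.0),
                                N=10000, name="po08")
        assert model.po(60.0) == pytest.approx(0.8, abs=1e-9)
        prot = _steady_protocol(60.0, dur=400.0)
        rec = cg.simulate_macroscopic(model, prot, cg.NoiseSpec(1.0), seed=60)
        seal = cg.simulate_background(prot, cg.NoiseSpec(1.0), seed=61)
        ratio = cg.variance_to_mean(rec, seal, window=350.0).ratio[0]
        po, flagged = cg.absolute_po_from_noise(ratio, model.isc(60.0))
        assert abs(po - 0.8) < 0.05
        assert not flagged


class TestOpenNoiseInflation:
    def test_worst_case_bound_is_25_percent(self):
        # σ_o/i_sc = 0.5 at P_o = 0.5 → sqrt(1.5) − 1 ≈ 22.5%, below 25%
        val = cg.open_noise_inflation(0.5, 0.5)
        assert val == pytest.approx(np.sqrt(1.5) - 1.0, rel=1e-12)
        assert val <= 0.25

    def test_typical_ratio_inflates_about_one_percent(self):
        assert cg.open_noise_inflation(0.1, 0.5) == pytest.approx(0.00995, abs=5e-4)

    def test_vanishes_without_open_noise(self):
        assert cg.open_noise_inflation(0.0, 0.7) == 0.0

    def test_undefined_at_full_opening(self):
        with pytest.raises(ParameterError):
            cg.open_noise_inflation(0.1, 1.0)

    def test_monotone_in_both_arguments(self):
        ratios = np.linspace(0.0, 1.0, 11)
        pos = np.linspace(0.0, 0.95, 11)
        for po in pos:
            vals = [cg.open_noise_inflation(r, po) for r in ratios]
            assert np.all(np.diff(vals) >= 0)
        for r in ratios[1:]:
            vals = [cg.open_noise_inflation(r, po) for po in pos]
            assert np.all(np.diff(vals) >= 0)


@pytest.fixture(scope="module")
def counting_protocol():
    return cg.build_tail_protocol(100, 100, 100, 20, 1500.0, 100, 10.0)


class TestAmplitudeHistogram:
    def test_two_channel_recording_counted(self, counting_protocol, na_model):
        model = make_counting_model(2, na_model.perm)
        rec, _ = cg.simulate_single_channel(model, counting_protocol, cg.NoiseSpec(1.0), seed=5)
        fit = cg.count_channels_from_histogram(rec, seed=0)
        assert fit.channel_count == 2
        assert fit.weights.sum() == pytest.approx(1.0, abs=1e-6)

    def test_single_channel_recording_counted(self, counting_protocol, na_model):
        model = make_counting_model(1, na_model.perm)
        rec, _ = cg.simulate_single_channel(model, counting_protocol, cg.NoiseSpec(1.0), seed=8)
        assert cg.count_channels_from_histogram(rec, seed=0).channel_count == 1

    def test_seal_only_recording_counts_zero(self, counting_protocol):
        rec = cg.simulate_background(counting_protocol, cg.NoiseSpec(1.0), seed=4)
        assert cg.count_channels_from_histogram(rec, seed=0).channel_count == 0

    def test_two_channel_counting_reliability(self, counting_protocol, na_model):
        # ≥95% correct over 100 seeded runs at well-separated levels
        model = make_counting_model(2, na_model.perm)
        correct = 0
        for s in range(100):
            rec, _ = cg.simulate_single_channel(
                model, counting_protocol, cg.NoiseSpec(1.0), seed=2000 + s
            )
            correct += cg.count_channels_from_histogram(rec, seed=0).channel_count == 2
        assert correct >= 95

    def test_empty_recording_rejected(self):
        rec = cg.SweepSet(dt=0.02, traces=np.zeros((1, 0)))
        with pytest.raises(ParameterError):
            cg.amplitude_histogram(rec)


class TestDmaNoiseGrowth:
    def test_noise_grows_more_than_linearly_at_negative_voltages(self):
        """σ²/I of the DMA-like preset more than doubles from −100 to −200 mV
        while P_o changes by less than 0.05 — open-pore rectification, not
        gating, drives the extra noise."""
        model = cg.load_preset("dma_like")
        assert abs(model.po(-100.0) - model.po(-200.0)) < 0.05
        ratios = {}
        for V in (-100.0, -200.0):
            prot = _steady_protocol(V, dur=300.0)
            rec = cg.simulate_macroscopic(model, prot, cg.NoiseSpec(1.0), seed=int(-V))
            seal = cg.simulate_background(prot, cg.NoiseSpec(1.0), seed=int(-V) + 1)
            ratios[V] = abs(cg.variance_to_mean(rec, seal, window=250.0).ratio[0])
        assert ratios[-200.0] > 2.0 * ratios[-100.0]
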