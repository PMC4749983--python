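import numpy as np
import pytest

import bulbsparse as bs
from bulbsparse.dynamics import (
    SimConfig,
    read_raster_csv,
    simulate_isolated_mitral,
    write_raster_csv,
)

CFG = SimConfig()
FAST = bs.REDUCED_SIM


class TestSigmoid:
    def test_midpoint_is_half(self):
        assert bs.sigmoid_S(25) == pytest.approx(0.5)

    def test_fully_depressed_weight_is_negligible(self):
        assert bs.sigmoid_S(0) < 1e-3

    def test_fully_potentiated_matches_direct_evaluation(self):
        # independent evaluation of 1 / (1 + exp((25 - 50) / 3))
        expected = 1.0 / (1.0 + np.exp((25.0 - 50.0) / 3.0))
        assert bs.sigmoid_S(50) == pytest.approx(expected, rel=1e-12)
        assert expected > 0.999

    def test_strictly_increasing(self):
        p = np.linspace(0, 50, 101)
        assert (np.diff(bs.sigmoid_S(p)) > 0).all()


class TestClassifyISI:
    @pytest.mark.parametrize(
        "isi_ms,delta",
        [(20, 1), (33, 1), (33.001, -1), (100, -1), (249.999, -1), (250, 0), (300, 0)],
    )
    def test_partition_with_closed_boundaries(self, isi_ms, delta):
        assert bs.classify_isi(isi_ms) == delta

    def test_nonpositive_isi_rejected(self):
        with pytest.raises(ValueError):
            bs.classify_isi(0.0)
        with pytest.raises(ValueError):
            bs.classify_isi(-5.0)


class TestApplyPlasticity:
    def test_ltd_at_floor_is_ignored(self):
        c = bs.SynapseComponent(g_max=1.0)
        bs.apply_plasticity(c, 0.0)
        w0 = c.w
        bs.apply_plasticity(c, 0.1)  # ISI 100 ms -> LTD, but p=0 stays
        assert c.p == 0.0
        assert c.w == w0

    def test_fifty_ltp_spikes_reach_full_potentiation(self):
        c = bs.SynapseComponent(g_max=2.0)
        t = 0.0
        bs.apply_plasticity(c, t)  # reference spike, no ISI yet
        changes = 0
        while c.p < 50.0:
            t += 0.020
            bs.apply_plasticity(c, t)
            changes += 1
        assert changes == 50
        assert c.w == pytest.approx(2.0 * float(bs.sigmoid_S(50)))
        # further LTP spikes are ignored at the ceiling
        bs.apply_plasticity(c, t + 0.020)
        assert c.p == 50.0

    def test_slow_train_changes_nothing(self):
        c = bs.SynapseComponent(p=10.0, w=1.0 * float(bs.sigmoid_S(10)), g_max=1.0)
        bs.apply_plasticity(c, 0.0)
        bs.apply_plasticity(c, 0.3)  # ISI 300 ms -> delta 0
        assert c.p == 10.0

    def test_interior_ltd_decrements_by_one(self):
        c = bs.SynapseComponent(p=10.0, w=1.0 * float(bs.sigmoid_S(10)), g_max=1.0)
        bs.apply_plasticity(c, 0.0)
        bs.apply_plasticity(c, 0.1)
        assert c.p == 9.0

    def test_time_regression_rejected(self):
        c = bs.SynapseComponent(g_max=1.0)
        bs.apply_plasticity(c, 1.0)
        with pytest.raises(ValueError):
            bs.apply_plasticity(c, 0.5)

    @pytest.mark.parametrize("rate_hz,expected_dp", [(4.0, 0), (2.0, 0), (30.5, 20)])
    def test_constant_rate_boundary_property(self, rate_hz, expected_dp):
        """Rates <= 4 Hz never change p; >= ~30.4 Hz gain +1 per spike."""
        c = bs.SynapseComponent(p=20.0, w=float(bs.sigmoid_S(20)), g_max=1.0)
        isi = 1.0 / rate_hz
        for k in range(21):
            bs.apply_plasticity(c, k * isi)
        assert c.p - 20.0 == expected_dp


class TestRunEpoch:
    def test_quiescence_without_input_or_background(self, tiny_network, tiny_panel):
        cfg = SimConfig(
            dt_ms=0.5, background_rate_hz=0.0, granule_background_rate_hz=0.0
        )
        res = bs.run_epoch(tiny_network, [], tiny_panel, cfg, duration=1.0, seed=0)
        assert sum(s.size for s in res.mitral.spikes) == 0
        assert sum(s.size for s in res.granule.spikes) == 0
        assert tiny_network.w_exc.sum() == 0
        assert tiny_network.w_inh.sum() == 0

    def test_seed_determinism_of_epochs(self, tiny_config, tiny_panel):
        rasters = []
        for _ in range(2):
            net = bs.build_network(tiny_config, seed=3)
            stim = bs.StimulusSpec(odor_id=0, onset=0.2, duration=1.0)
            res = bs.run_epoch(net, [stim], tiny_panel, FAST, duration=1.3, seed=42)
            rasters.append(res)
        a, b = rasters
        for ra, rb in ((a.mitral, b.mitral), (a.granule, b.granule)):
            assert all(np.array_equal(x, y) for x, y in zip(ra.spikes, rb.spikes))

    def test_plasticity_closure_in_debug_mode(self, tiny_config, tiny_panel):
        net = bs.build_network(tiny_config, seed=3)
        cfg = bs.SimConfig(dt_ms=0.5, debug_checks=True)
        stim = bs.StimulusSpec(odor_id=0, onset=0.1, duration=0.8)
        bs.run_epoch(net, [stim], tiny_panel, cfg, duration=1.0, seed=1)
        assert ((net.p_exc >= 0) & (net.p_exc <= 50)).all()
        # untouched components keep their exact-zero initial weight, which
        # coincides with g_max * S(0) up to the ~1e-3 depressed floor
        assert np.allclose(
            net.w_exc, net.config.g_max_exc * bs.sigmoid_S(net.p_exc), atol=2e-3
        )
        assert np.allclose(
            net.w_inh, net.config.g_max_inh * bs.sigmoid_S(net.p_inh), atol=2e-3
        )

    def test_replay_equivalence_with_offline_rule(self, tiny_config, tiny_panel):
        """p trajectories reconstructed from logged presynaptic event times
        must equal the simulator's final state exactly."""
        net = bs.build_network(tiny_config, seed=3)
        stim = bs.StimulusSpec(odor_id=0, onset=0.1, duration=1.5)
        res = bs.run_epoch(
            net, [stim], tiny_panel, FAST, duration=1.8, seed=5, record_events=True
        )
        for events, p_final, g_max in (
            (res.events_exc, net.p_exc, net.config.g_max_exc),
            (res.events_inh, net.p_inh, net.config.g_max_inh),
        ):
            p = np.zeros(net.n_synapses)
            last = np.full(net.n_synapses, np.nan)
            for t, idx in events:
                isi_ms = (t - last[idx]) * 1e3
                has = np.isfinite(last[idx])
                delta = np.zeros(idx.size)
                with np.errstate(invalid="ignore"):
                    delta[has] = np.array(
                        [bs.classify_isi(v) for v in isi_ms[has]], dtype=float
                    )
                cand = p[idx] + delta
                ok = (cand >= 0) & (cand <= 50)
                p[idx[ok]] = cand[ok]
                last[idx] = t
            assert np.array_equal(p, p_final)

    def test_column_formation_proximal_exceeds_distal(self, small_panel):
        """One strong odor for 5 s concentrates potentiated inhibition on
        the proximal dendrite halves of the driven mitral cells."""
        net = bs.build_network(bs.REDUCED_PRESET, seed=1)
        stim = bs.StimulusSpec(odor_id=0, onset=0.5, duration=5.0)
        bs.run_epoch(net, [stim], small_panel, FAST, duration=5.5, seed=3)
        strengths = net.strengths_per_mitral(small_panel.odor_strengths(0))
        driven = np.isin(net.syn_mc, np.flatnonzero(strengths >= 3))
        seg = net.seg_index[net.syn_seg]
        half = net.config.segments_per_dendrite // 2
        prox = net.w_inh[driven & (seg < half)].mean()
        dist = net.w_inh[driven & (seg >= half)].mean()
        assert prox > dist


class TestCalibration:
    def test_default_config_separates_strong_from_weak(self):
        cfg = bs.calibrate_thresholds(FAST)
        n_sniffs = 10
        for s in (3, 4):
            assert simulate_isolated_mitral(s, cfg, 2.0).size >= n_sniffs
        for s in (0, 1, 2):
            assert simulate_isolated_mitral(s, cfg, 2.0).size == 0

    def test_firing_gap_between_strengths_two_and_three(self):
        r2 = simulate_isolated_mitral(2, FAST, 4.0, background=True, seed=1).size / 4
        r3 = simulate_isolated_mitral(3, FAST, 4.0, background=True, seed=1).size / 4
        assert r3 > 3 * r2

    def test_infeasible_threshold_recovered_by_bisection(self):
        # absurdly low threshold makes weak inputs fire; calibration fixes it
        bad = bs.SimConfig(dt_ms=0.5, mitral_threshold_mv=-58.0)
        fixed = bs.calibrate_thresholds(bad)
        assert simulate_isolated_mitral(2, fixed, 2.0).size == 0
        assert simulate_isolated_mitral(3, fixed, 2.0).size >= 10


def test_raster_csv_round_trip(tmp_path):
    raster = bs.SpikeRaster(
        population="mitral",
        spikes=[[0.01, 0.5], [], [0.2]],
        t_start=0.0,
        t_stop=1.0,
    )
    path = tmp_path / "raster.csv"
    write_raster_csv(raster, path)
    back = read_raster_csv(path, n_cells=3, t_stop=1.0)
    assert back.population == "mitral"
    assert all(np.array_equal(a, b) for a, b in zip(back.spikes, raster.spikes))
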