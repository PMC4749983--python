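import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bulbsparse as bs
from bulbsparse import metrics as M


class TestSparseness:
    def test_uniform_population_is_zero(self):
        assert bs.sparseness([3.0] * 17) == pytest.approx(0.0, abs=1e-12)

    def test_one_hot_population_is_one(self):
        r = np.zeros(50)
        r[13] = 7.5
        assert bs.sparseness(r) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # r = (2, 4, 6, 8): mean^2 = 25, mean square = 30
        # S = (1 - 25/30) / (1 - 1/4) = (1/6) / (3/4) = 2/9
        assert bs.sparseness([2, 4, 6, 8]) == pytest.approx(2.0 / 9.0)

    def test_all_zero_rates_yield_sentinel(self):
        assert np.isnan(bs.sparseness([0.0, 0.0, 0.0]))

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            bs.sparseness([1.0, -0.1])

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        rates=st.lists(st.floats(0.0, 100.0), min_size=2, max_size=30).filter(
            lambda r: sum(r) > 0
        ),
        scale=st.floats(0.01, 50.0),
    )
    def test_bounds_scale_and_permutation_invariance(self, rates, scale):
        s = bs.sparseness(rates)
        assert -1e-9 <= s <= 1.0 + 1e-9
        assert bs.sparseness(np.array(rates) * scale) == pytest.approx(s, abs=1e-9)
        assert bs.sparseness(sorted(rates)) == pytest.approx(s, abs=1e-9)


class TestPerSniffSparseness:
    def _raster(self, rows, t_stop=1.0):
        return bs.SpikeRaster("mitral", rows, 0.0, t_stop)

    def test_homogeneous_raster_gives_flat_zero_trace(self):
        times = list(np.arange(0.005, 1.0, 0.01))
        raster = self._raster([times, times, times])
        trace = bs.per_sniff_sparseness(raster, np.arange(0.0, 1.0, 0.2))
        assert np.allclose(trace.values, 0.0, atol=1e-12)

    def test_concentrating_activity_gives_nondecreasing_trace(self):
        # three cells; cells 1 and 2 fall silent over time
        sniffs = np.arange(0.0, 1.0, 0.25)
        c0 = list(np.arange(0.01, 1.0, 0.02))
        c1 = list(np.arange(0.01, 0.6, 0.04))
        c2 = list(np.arange(0.01, 0.3, 0.04))
        raster = self._raster([c0, c1, c2])
        trace = bs.per_sniff_sparseness(raster, sniffs)
        direct = [
            bs.sparseness(raster.rates(t, t + 0.25)) for t in sniffs
        ]  # independent per-window evaluation
        assert np.allclose(trace.values, direct, equal_nan=True)
        assert (np.diff(trace.values) >= -1e-12).all()

    def test_cumulative_variant_uses_growing_window(self):
        raster = self._raster([[0.05], [0.3, 0.55], [0.8]])
        sniffs = np.array([0.0, 0.25, 0.5, 0.75])
        cum = bs.per_sniff_sparseness(raster, sniffs, cumulative=True)
        direct = [bs.sparseness(raster.rates(0.0, t + 0.25)) for t in sniffs]
        assert np.allclose(cum.values, direct, equal_nan=True)

    def test_sniffs_outside_epoch_rejected(self):
        with pytest.raises(ValueError):
            bs.per_sniff_sparseness(self._raster([[0.1]]), [2.0])


class TestCoherence:
    def test_identical_trains_have_unit_coherence(self):
        t = [0.01, 0.21, 0.55]
        assert bs.coherence_pair(t, t, epoch=(0, 1)) == pytest.approx(1.0)

    def test_disjoint_bins_have_zero_coherence(self):
        assert bs.coherence_pair([0.005], [0.125], epoch=(0, 0.2)) == 0.0

    def test_four_bin_hand_example(self):
        # X bins (1,1,0,1), Y bins (1,0,0,1): sum XY = 2, sums 3 and 2
        tau = 20.0
        x = [0.001, 0.021, 0.061]
        y = [0.002, 0.062]
        k = bs.coherence_pair(x, y, tau_ms=tau, epoch=(0.0, 0.08))
        assert k == pytest.approx(2.0 / np.sqrt(6.0))
        # brute-force bin oracle
        edges = np.arange(0.0, 0.08 + 1e-9, tau * 1e-3)
        bx = (np.histogram(x, edges)[0] > 0).astype(float)
        by = (np.histogram(y, edges)[0] > 0).astype(float)
        assert k == pytest.approx(bx @ by / np.sqrt(bx.sum() * by.sum()))

    def test_symmetry_and_empty_train_convention(self):
        x, y = [0.01, 0.05], [0.03]
        assert bs.coherence_pair(x, y, epoch=(0, 0.1)) == pytest.approx(
            bs.coherence_pair(y, x, epoch=(0, 0.1))
        )
        assert bs.coherence_pair(x, [], epoch=(0, 0.1)) == 0.0

    def test_network_mean_matches_pairwise_values(self, fixtures):
        raster = fixtures["raster3"]
        epoch = (raster.t_start, raster.t_stop)
        pairs = [
            bs.coherence_pair(raster.spikes[i], raster.spikes[j], epoch=epoch)
            for i, j in ((0, 1), (0, 2), (1, 2))
        ]
        assert bs.network_coherence(raster) == pytest.approx(np.mean(pairs))
        # fixture construction: cells 0,1 identical; cell 2 disjoint
        assert pairs[0] == pytest.approx(1.0)
        assert pairs[1] == 0.0

    def test_identical_population_coherence_is_one(self):
        t = [0.01, 0.13, 0.29]
        raster = bs.SpikeRaster("mitral", [t, t, t, t], 0.0, 0.4)
        assert bs.network_coherence(raster) == pytest.approx(1.0)


class TestResponseCorrelation:
    def test_self_comparison_is_one(self):
        counts = np.array([[1, 2, 3], [4, 1, 2]], float)
        c, n = bs.response_correlation_from_counts(counts, counts)
        assert c == pytest.approx(1.0)
        assert n == 2

    def test_perfect_anticorrelation(self):
        x = np.tile([1.0, 2.0, 3.0], (4, 1))
        y = np.tile([3.0, 2.0, 1.0], (4, 1))
        c, _ = bs.response_correlation_from_counts(x, y)
        assert c == pytest.approx(-1.0)

    def test_two_cell_hand_oracle_and_zero_variance_skip(self):
        x = np.array([[1.0, 2.0, 4.0], [5.0, 5.0, 5.0]])
        y = np.array([[2.0, 2.0, 5.0], [1.0, 2.0, 3.0]])
        c, n = bs.response_correlation_from_counts(x, y)
        assert n == 1  # constant cell skipped
        assert c == pytest.approx(np.corrcoef(x[0], y[0])[0, 1])

    def test_raster_interface_with_per_sniff_bins(self):
        edges = np.array([0.0, 0.25, 0.5, 0.75, 1.0])
        ra = bs.SpikeRaster("mitral", [[0.1], [0.1, 0.3, 0.6, 0.9]], 0.0, 1.0)
        c, n = bs.response_correlation(ra, ra, edges)
        assert c == pytest.approx(1.0)

    def test_no_valid_cells_yields_sentinel(self):
        flat = np.ones((3, 4))
        c, n = bs.response_correlation_from_counts(flat, flat)
        assert np.isnan(c) and n == 0


class TestFitSHalf:
    @staticmethod
    def _sigmoid(t, a1, a2, x0, h):
        return a2 + (a1 - a2) / (1.0 + (t / x0) ** h)

    def test_parameter_recovery_on_noiseless_sigmoid(self):
        t = np.linspace(0.2, 10, 40)
        y = self._sigmoid(t, 0.1, 0.9, 2.5, 3.0)
        fit = bs.fit_S_half(bs.SparsenessTrace(t, y))
        assert fit.converged
        assert fit.S_half == pytest.approx(2.5, rel=0.02)
        assert fit.r_squared > 0.999

    def test_recovery_within_five_percent_under_noise(self):
        rng = np.random.default_rng(0)
        t = np.linspace(0.2, 10, 40)
        truth = 3.0
        hits = 0
        for _ in range(100):
            y = self._sigmoid(t, 0.15, 0.85, truth, 2.0) + rng.normal(0, 0.004, t.size)
            fit = bs.fit_S_half(bs.SparsenessTrace(t, y))
            if abs(fit.S_half - truth) / truth <= 0.05:
                hits += 1
        assert hits >= 95

    def test_constant_trace_flagged_degenerate(self):
        fit = bs.fit_S_half(bs.SparsenessTrace(np.arange(6.0), np.full(6, 0.4)))
        assert not fit.converged
        assert "degenerate" in fit.message

    def test_monotone_trace_yields_s_half_inside_span(self):
        t = np.linspace(0.2, 5, 25)
        y = np.tanh(t / 1.5) * 0.5 + 0.3
        fit = bs.fit_S_half(bs.SparsenessTrace(t, y))
        assert 0 < fit.S_half <= t[-1] * 1.5

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            bs.fit_S_half(bs.SparsenessTrace(np.arange(3.0), np.arange(3.0)))


class TestOdorSimilarity:
    def test_self_similarity_is_one(self, small_panel):
        assert bs.odor_similarity(small_panel, 0, 0) == pytest.approx(1.0)

    def test_complement_pattern_is_anticorrelated(self):
        strengths = np.array([[4, 4, 3, 0, 0, 0], [0, 0, 0, 4, 4, 3]])
        panel = bs.OdorPanel(strengths, ("a", "b"))
        r = bs.odor_similarity(panel, "a", "b")
        assert r == pytest.approx(-1.0, abs=0.2)

    def test_network_expansion_matches_textbook_formula(self, small_panel):
        net = bs.build_network(bs.REDUCED_PRESET, seed=0)
        r = bs.odor_similarity(small_panel, 0, 1, network=net)
        x = net.strengths_per_mitral(small_panel.odor_strengths(0)).astype(float)
        y = net.strengths_per_mitral(small_panel.odor_strengths(1)).astype(float)
        cov = np.mean((x - x.mean()) * (y - y.mean()))
        assert r == pytest.approx(cov / (x.std() * y.std()))

    def test_zero_variance_yields_sentinel(self):
        panel = bs.OdorPanel(np.array([[4, 4], [4, 0]]), ("flat", "other"))
        assert np.isnan(bs.odor_similarity(panel, "flat", "other"))


class TestWeightSummary:
    def test_untrained_network_all_zero(self, tiny_network, tiny_panel):
        ws = bs.weight_summary(tiny_network, tiny_panel, 0)
        assert (ws["G_ex"].fillna(0) == 0).all()
        assert (ws["G_in"].fillna(0) == 0).all()

    def test_class_partition_covers_all_mitral_cells(self, tiny_network, tiny_panel):
        ws = bs.weight_summary(tiny_network, tiny_panel, 0)
        assert ws.loc["strong", "n_cells"] + ws.loc["weak", "n_cells"] == ws.loc[
            "all", "n_cells"
        ]
        assert ws.loc["all", "n_cells"] == tiny_network.n_mitral
        assert (
            ws.loc["strong", "n_components"] + ws.loc["weak", "n_components"]
            == tiny_network.n_synapses
        )
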