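"""Calcium-fluorescence simulator: rates, events, spikes, kernel, ΔF/F."""

import math

import numpy as np
import pytest

import assemblybench as ab
from assemblybench.arrays import Assembly, AssemblyConfiguration
from assemblybench.simulate import (
    SimulationParams,
    _kernel_length,
    assign_background_rates,
    build_rate_matrix,
    compute_dff,
    place_spikes,
    sample_events,
    sample_spike_counts,
    synthesize_fluorescence,
)


def _tiny_config(rings=2, sets=({0, 1, 2}, {2, 3, 4})):
    array = ab.build_hex_array(rings)
    return AssemblyConfiguration(
        assemblies=[Assembly(frozenset(s)) for s in sets], array=array
    )


class TestBackgroundRates:
    def test_degenerate_interval(self):
        assert np.all(assign_background_rates(20, (3.0, 3.0), 0) == 3.0)

    def test_range_and_mean(self):
        r = assign_background_rates(20000, (1.0, 6.0), 0)
        assert r.min() >= 1.0 and r.max() <= 6.0
        assert r.mean() == pytest.approx(3.5, abs=0.05)

    def test_seeded_determinism(self):
        a = assign_background_rates(50, (1.0, 6.0), 42)
        b = assign_background_rates(50, (1.0, 6.0), 42)
        np.testing.assert_array_equal(a, b)

    def test_invalid_interval(self):
        with pytest.raises(ValueError):
            assign_background_rates(5, (6.0, 1.0), 0)


class TestEvents:
    def test_zero_frequency_no_events(self):
        params = SimulationParams(T=100.0, f_event=0.0)
        am, lm = sample_events(_tiny_config(), params, 0)
        assert not any(m.any() for m in am)
        assert not any(m.any() for m in lm.values())

    def test_event_duration_one_bin(self):
        # dT_event == dT: every onset occupies exactly one bin
        params = SimulationParams(T=50.0, f_event=0.1, dT_event=0.5, dT=0.5)
        am, _ = sample_events(_tiny_config(), params, 1)
        onsets_expected = params.f_event * params.T
        total = sum(m.sum() for m in am)
        # with single-bin events, active-bin count == onset count, which is
        # Binomial(n_bins, f*dT); allow 5 sigma
        n_bins = params.n_bins
        p = params.f_event * params.dT
        sd = math.sqrt(n_bins * p * (1 - p)) * len(am)
        assert abs(total - onsets_expected * len(am)) < 5 * sd + 1

    def test_onset_rate_matches_f_event(self):
        params = SimulationParams(T=2000.0, f_event=0.01)
        am, _ = sample_events(_tiny_config(), params, 2)
        p = params.f_event * params.dT
        n_bins = params.n_bins
        for mask in am:
            assert abs(mask.sum() - n_bins * p) < 5 * math.sqrt(n_bins * p)

    def test_lone_neurons_get_their_own_events(self):
        cfg = _tiny_config(rings=2, sets=({0, 1},))
        params = SimulationParams(T=100.0, f_event=0.01)
        _, lm = sample_events(cfg, params, 3)
        assert set(lm) == set(range(2, cfg.array.n_neurons))


class TestRateMatrix:
    def test_no_events_constant_background(self):
        cfg = _tiny_config()
        params = SimulationParams(T=10.0, f_event=0.0)
        bg = assign_background_rates(cfg.array.n_neurons, (1.0, 6.0), 0)
        events = sample_events(cfg, params, 0)
        rates = build_rate_matrix(bg, events, cfg, params)
        np.testing.assert_array_equal(rates, np.tile(bg[:, None], rates.shape[1]))

    def test_overlapping_assemblies_single_multiplier(self):
        # neuron 2 sits in both assemblies; simultaneous events give lam once
        cfg = _tiny_config()
        params = SimulationParams(T=2.0, lam=6.0)
        bg = np.full(cfg.array.n_neurons, 2.0)
        n_bins = params.n_bins
        masks = [np.ones(n_bins, bool), np.ones(n_bins, bool)]
        rates = build_rate_matrix(bg, (masks, {}), cfg, params, n_bins=n_bins)
        assert rates[2, 0] == pytest.approx(6.0 * 2.0)

    def test_event_elevates_all_members_coordinately(self):
        cfg = _tiny_config()
        params = SimulationParams(T=5.0, lam=4.0)
        bg = np.full(cfg.array.n_neurons, 1.0)
        n_bins = params.n_bins
        mask = np.zeros(n_bins, bool)
        mask[3] = True
        rates = build_rate_matrix(bg, ([mask, np.zeros(n_bins, bool)], {}), cfg,
                                  params, n_bins=n_bins)
        assert np.all(rates[[0, 1, 2], 3] == 4.0)
        assert np.all(rates[[0, 1, 2], 2] == 1.0)


class TestSpikes:
    def test_zero_rate_zero_counts(self):
        params = SimulationParams(T=10.0)
        counts = sample_spike_counts(np.zeros((3, 20)), params, 0)
        assert counts.sum() == 0

    def test_poisson_mean_and_fano(self):
        params = SimulationParams(T=10.0, dT=0.5)
        rates = np.full((1, 100_000), 4.0)
        counts = sample_spike_counts(rates, params, 0)
        assert counts.mean() == pytest.approx(2.0, abs=0.03)
        assert counts.var() / counts.mean() == pytest.approx(1.0, abs=0.05)

    def test_placement_conserves_counts(self):
        params = SimulationParams(T=10.0, dT=0.5, ddT=0.01)
        rng = np.random.default_rng(0)
        counts = rng.poisson(3.0, size=(5, 20))
        train = place_spikes(counts, params, 1)
        np.testing.assert_array_equal(train.counts(), counts)

    def test_saturated_bin_fills_every_slot(self):
        params = SimulationParams(T=1.0, dT=0.5, ddT=0.1)
        counts = np.full((1, 2), params.slots_per_bin)
        train = place_spikes(counts, params, 0)
        assert train.to_dense().all()

    def test_excess_counts_clipped_with_warning(self):
        params = SimulationParams(T=0.5, dT=0.5, ddT=0.1)
        with pytest.warns(UserWarning, match="clip"):
            train = place_spikes(np.array([[99]]), params, 0)
        assert train.counts()[0, 0] == params.slots_per_bin


class TestFluorescence:
    def test_kernel_truncation_length(self):
        assert _kernel_length(SimulationParams(tau_half=1.0, ddT=0.001)) == 6644

    def test_saturation_midpoint(self):
        from assemblybench.simulate import _saturate

        assert _saturate(np.array([1000.0]), 1000.0)[0] == pytest.approx(500.0)
        assert _saturate(np.array([7.0]), math.inf)[0] == 7.0

    def test_single_spike_kernel_shape(self):
        # sigma=0, kappa=inf: peak 1 at the spike, halving every tau_half
        params = SimulationParams(
            T=2.0, dT=0.5, ddT=0.1, tau_half=0.2, sigma_noise=0.0
        )
        counts = np.zeros((1, params.n_bins + params.warmup_bins), dtype=int)
        counts[0, params.warmup_bins] = 1
        train = place_spikes(counts, params, 0)
        fluo = synthesize_fluorescence(train, params, 0, dense=True)
        fine = fluo.fine[0]
        spike_at = int(np.argmax(fine))
        assert fine[spike_at] == pytest.approx(1.0)
        half_life_samples = round(params.tau_half / params.ddT)
        assert fine[spike_at + half_life_samples] == pytest.approx(0.5, rel=1e-6)

    def test_warmup_removal_leaves_T_over_ddT_samples(self):
        params = SimulationParams(T=3.0, dT=0.5, ddT=0.1, tau_half=0.5)
        n_total = params.n_bins + params.warmup_bins
        counts = np.ones((2, n_total), dtype=int)
        train = place_spikes(counts, params, 0)
        fluo = synthesize_fluorescence(train, params, 0, dense=True)
        assert fluo.fine.shape[1] == round(params.T / params.ddT)
        assert fluo.F.shape[1] == params.n_bins

    def test_fast_path_matches_dense_at_zero_noise(self):
        params = SimulationParams(T=20.0, dT=0.5, ddT=0.01, tau_half=1.0)
        rng = np.random.default_rng(3)
        n_total = params.n_bins + params.warmup_bins
        counts = rng.poisson(1.5, size=(4, n_total))
        train = place_spikes(counts, params, 5)
        fast = synthesize_fluorescence(train, params, 0)
        dense = synthesize_fluorescence(train, params, 0, dense=True)
        np.testing.assert_allclose(fast.F, dense.F, rtol=0, atol=1e-12)


class TestDff:
    def test_constant_trace_zero_dff(self):
        params = SimulationParams(T=100.0)
        F = np.full((1, 200), 5.0)
        out = compute_dff(F, params)
        np.testing.assert_allclose(out.dff, 0.0, atol=1e-9)

    def test_pure_noise_trace_unbiased(self, rng):
        params = SimulationParams(T=500.0)
        F = 5.0 + rng.standard_normal((1, 1000))
        out = compute_dff(F, params)
        se = out.dff.std() / math.sqrt(out.dff.size)
        assert abs(out.dff.mean()) < 3 * se

    def test_transient_gives_positive_excursion(self):
        params = SimulationParams(T=500.0)
        F = np.full((1, 1000), 4.0)
        F[0, 500:504] += 8.0
        out = compute_dff(F, params)
        assert out.dff[0, 500:504].max() > 1.0
        assert abs(out.dff[0, :450]).max() < 0.2

    def test_all_zero_trace_warns(self):
        params = SimulationParams(T=100.0)
        with pytest.warns(UserWarning, match="all-zero"):
            out = compute_dff(np.zeros((1, 200)), params)
        np.testing.assert_array_equal(out.dff, 0.0)


def test_full_pipeline_bit_reproducible():
    array = ab.build_hex_array(3)
    cfg = ab.sample_configuration(
        array, ab.GeneratorParams(k=2, centre_radius=1.5), 0
    )
    params = SimulationParams(T=120.0)
    a, _ = ab.simulate_dataset(cfg, params, 9)
    b, _ = ab.simulate_dataset(cfg, params, 9)
    np.testing.assert_array_equal(a.dff, b.dff)


def test_invalid_event_probability_rejected():
    with pytest.raises(ValueError):
        SimulationParams(f_event=3.0, dT=0.5)
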