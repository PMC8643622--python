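"""Simulator physics: stationary laws, emission statistics, determinism."""

import numpy as np
import pytest

from zmwfccs.correlator import multitau_correlate, stream_to_traces
from zmwfccs.simkit import (SimulationConfig, detection_weight, emit_photons,
                            simulate_binding_trajectory, simulate_binned_traces,
                            simulate_diffusion, simulate_photon_stream,
                            titration_condition, _telegraph_bins)


class TestConfigValidation:
    def test_fret_ordering_enforced(self):
        with pytest.raises(ValueError, match="E2 < E1"):
            SimulationConfig(E1=0.1, E2=0.3)

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError, match="k_off"):
            SimulationConfig(k_off=-1.0)

    def test_underresolved_kinetics_rejected(self):
        with pytest.raises(ValueError, match="under-resolved kinetics"):
            SimulationConfig(k_off=50.0, dt=4.0)

    def test_underresolved_diffusion_rejected(self):
        with pytest.raises(ValueError, match="under-resolved diffusion"):
            SimulationConfig(diffusion_R=30.0, dt=4.0)

    def test_box_must_hold_50_volumes(self):
        with pytest.raises(ValueError, match="50 effective"):
            SimulationConfig(box_lengths=(150.0, 150.0, 150.0))

    def test_effective_volume_matches_paper_scale(self):
        # default geometry reproduces the ~1.2e-18 l nanoaperture volume
        assert SimulationConfig().v_eff_liters == pytest.approx(1.2e-18,
                                                                rel=0.01)

    def test_titration_condition_splits_populations(self):
        cfg = titration_condition(40.0, k_on=0.07, k_off=3.61)
        b = cfg.bound_occupancy
        assert cfg.conc_GR == pytest.approx(b)
        assert cfg.conc_R == pytest.approx(1 - b)
        assert cfg.conc_G + cfg.conc_GR == pytest.approx(40.0)


class TestBindingTrajectory:
    def test_absorbing_bound_state(self):
        cfg = SimulationConfig(k_on=0.05, k_off=0.0, ligand_conc=40.0,
                               duration=0.2)
        states = simulate_binding_trajectory(cfg, 50, seed=3)
        assert states[:, -1].all()
        assert states[:, -1000:].all()

    def test_stationary_occupancy(self):
        # k1 = 2.8, k2 = 3.61 -> occupancy 0.43682
        cfg = SimulationConfig(k_on=0.07, k_off=3.61, ligand_conc=40.0,
                               duration=0.5, dt=4.0)
        states = simulate_binding_trajectory(cfg, 200, seed=7)
        occ = states.mean()
        # ~200*0.5s/156us correlation-time samples -> MC se ~ 0.002
        assert occ == pytest.approx(0.436817, abs=3 * 0.002)

    def test_indicator_autocorrelation_decay(self):
        cfg = SimulationConfig(k_on=0.07, k_off=3.61, ligand_conc=40.0,
                               duration=0.5, dt=4.0)
        states = simulate_binding_trajectory(cfg, 100, seed=11).astype(float)
        lam = (0.07 * 40 + 3.61)                    # ms^-1; tau = 156 us
        d = states - states.mean()
        lags_bins = np.array([5, 10, 25, 39, 60, 100])
        acf = np.array([
            (d[:, :-k] * d[:, k:]).mean() for k in lags_bins])
        var = d.var()
        expected = var * np.exp(-lam * lags_bins * 0.004)
        assert np.allclose(acf, expected, atol=0.015 * var + 0.002)

    def test_underresolved_rates_rejected(self):
        cfg = SimulationConfig(duration=0.01)
        object.__setattr__(cfg, "k_off", 30.0)  # bypass construction check
        with pytest.raises(ValueError, match="< 0.1"):
            simulate_binding_trajectory(cfg, 5, seed=1)

    def test_exact_dwell_path_matches_stationary_law(self, rng):
        k1, k2 = 2.0, 5.0
        st = np.concatenate([
            _telegraph_bins(rng, 100_000, 0.01, k1, k2, k1 / (k1 + k2))
            for _ in range(5)])
        assert st.mean() == pytest.approx(k1 / (k1 + k2), abs=0.01)


class TestDiffusion:
    def test_zero_diffusion_is_static(self, small_config):
        pos = simulate_diffusion(small_config, 4, seed=2, diffusion=0.0)
        assert np.all(pos == pos[0])

    def test_msd_is_2dt_per_axis(self):
        cfg = SimulationConfig(duration=0.02, dt=4.0,
                               box_lengths=(2000.0, 2000.0, 2000.0))
        d = 0.5                                     # um^2/s == nm^2/us
        pos = simulate_diffusion(cfg, 400, seed=5, diffusion=d)
        for k_steps, t_us in ((25, 100.0), (100, 400.0)):
            disp = pos[k_steps] - pos[0]
            disp = (disp + 1000.0) % 2000.0 - 1000.0   # minimum image
            msd = (disp ** 2).mean(axis=0)
            assert np.allclose(msd, 2 * d * t_us, rtol=0.25)

    def test_positions_stay_in_box(self, small_config):
        pos = simulate_diffusion(small_config, 10, seed=8)
        box = np.asarray(small_config.box_lengths)
        assert pos.min() >= 0.0 and np.all(pos.max(axis=(0, 1)) < box)

    def test_uniform_occupancy_of_subvolume(self, small_config):
        # stationary density is uniform: an octant holds 1/8 of positions
        pos = simulate_diffusion(small_config, 50, seed=9)
        box = np.asarray(small_config.box_lengths)
        frac = np.all(pos < box / 2, axis=2).mean()
        n = pos.shape[0] * pos.shape[1]
        # correlated samples: generous binomial-style tolerance
        assert frac == pytest.approx(1 / 8, abs=0.05)


class TestEmitPhotons:
    def test_background_only_is_homogeneous_poisson(self):
        cfg = SimulationConfig(brightness_G=0.0, brightness_R=0.0,
                               background_G=5.0, background_R=4.0,
                               conc_GR=0.1, duration=2.0, dt=10.0,
                               diffusion_stride=1)
        n_steps = int(round(cfg.duration / (cfg.dt * 1e-6)))
        states = np.zeros((3, n_steps), dtype=bool)
        pos = simulate_diffusion(cfg, 3, seed=1)
        stream = emit_photons(states, pos, cfg, seed=2)
        rate_dd = len(stream.microtimes[(stream.channels == 0)
                                        & (stream.microtimes < 12.5)]) / 2.0
        # donor detector green gate carries background_G = 5000/s
        assert rate_dd == pytest.approx(5000.0, rel=0.05)

    def test_immobile_center_molecule_without_fret(self):
        cfg = SimulationConfig(conc_GR=0.1, background_G=0.0,
                               background_R=0.0, brightness_G=80.0,
                               brightness_R=0.0, E1=0.5, E2=0.0,
                               duration=2.0, dt=10.0)
        n_steps = int(round(cfg.duration / (cfg.dt * 1e-6)))
        states = np.zeros((1, n_steps), dtype=bool)   # unbound: E = E2 = 0
        pos = np.tile(np.asarray(cfg.box_lengths) / 2.0,
                      (n_steps, 1, 1))
        stream = emit_photons(states, pos, cfg, seed=3)
        donor = (stream.channels == 0).sum()
        acceptor = (stream.channels == 1).sum()
        assert donor / cfg.duration == pytest.approx(80_000.0, rel=0.05)
        assert acceptor == 0

    def test_energy_partition_at_half_transfer(self):
        cfg = SimulationConfig(conc_GR=0.1, background_G=0.0,
                               background_R=0.0, brightness_R=0.0,
                               E1=0.5, E2=0.02, duration=2.0, dt=10.0)
        n_steps = int(round(cfg.duration / (cfg.dt * 1e-6)))
        states = np.ones((1, n_steps), dtype=bool)    # bound: E = 0.5
        pos = np.tile(np.asarray(cfg.box_lengths) / 2.0, (n_steps, 1, 1))
        stream = emit_photons(states, pos, cfg, seed=4)
        sel = stream.microtimes < 12.5
        frac = (stream.channels[sel] == 1).mean()
        assert frac == pytest.approx(0.5, abs=0.02)

    def test_pileup_rejected(self):
        cfg = SimulationConfig(conc_GR=0.1, brightness_G=500.0,
                               duration=0.01, dt=10.0)
        n_steps = int(round(cfg.duration / (cfg.dt * 1e-6)))
        states = np.ones((1, n_steps), dtype=bool)
        pos = np.tile(np.asarray(cfg.box_lengths) / 2.0, (n_steps, 1, 1))
        with pytest.raises(ValueError, match="pile-up"):
            emit_photons(states, pos, cfg, seed=5)

    def test_microtimes_respect_pie_windows(self, small_config):
        stream = simulate_photon_stream(small_config, seed=6)
        donor = stream.microtimes[stream.channels == 0]
        assert np.all(donor < small_config.red_pulse_delay)


class TestStatisticalEquivalence:
    def test_total_count_rate_matches_expectation(self):
        cfg = SimulationConfig(conc_G=0.5, conc_R=0.5, conc_GR=0.0,
                               duration=4.0, dt=8.0, diffusion_stride=4,
                               background_G=0.5, background_R=0.5)
        traces = simulate_binned_traces(cfg, seed=13)
        box_v = float(np.prod(np.asarray(cfg.box_lengths)))
        mean_w = cfg.v_eff_nm3 / (2 ** 1.5 * box_v)
        n_g = cfg.n_molecules(0.5)
        expect_dd = (cfg.brightness_G * n_g * mean_w + cfg.background_G)
        rate_dd = traces.DexDem.mean() / (cfg.dt * 1e-3)
        assert rate_dd == pytest.approx(expect_dd, rel=0.10)

    def test_same_seed_identical_different_seeds_not(self):
        cfg = SimulationConfig(conc_GR=0.3, duration=0.5)
        a = simulate_binned_traces(cfg, seed=21)
        b = simulate_binned_traces(cfg, seed=21)
        c = simulate_binned_traces(cfg, seed=22)
        assert np.array_equal(a.DexDem, b.DexDem)
        assert np.array_equal(a.AexAem, b.AexAem)
        assert not np.array_equal(a.DexDem, c.DexDem)

    def test_photon_and_binned_paths_agree_statistically(self):
        """The fast binned path and the photon-record path produce
        correlation curves that agree within their joint noise."""
        kw = dict(conc_G=0.0, conc_R=0.0, conc_GR=0.4, k_on=0.07,
                  k_off=3.61, duration=2.5, dt=4.0, diffusion_stride=2,
                  brightness_G=40.0, brightness_R=40.0)
        curves = {}
        for name, sim in (("binned", lambda c: simulate_binned_traces(c, 31)),
                          ("photon", lambda c: stream_to_traces(
                              simulate_photon_stream(c, 32), 4.0))):
            traces = sim(SimulationConfig(**kw))
            curves[name] = multitau_correlate(
                traces.channel("Dex"), traces.channel("Dex"), 4.0,
                max_lag_s=5e-3)
        ga, gb = curves["binned"].G, curves["photon"].G
        scale = max(ga.max(), 1e-3)
        # independent realizations: require same curve within noise
        assert np.median(np.abs(ga - gb)) < 0.15 * scale

    def test_triplet_blinking_adds_fast_bunching(self):
        kw = dict(conc_G=0.4, conc_R=0.0, conc_GR=0.0, duration=3.0,
                  dt=2.0, diffusion_stride=2, brightness_G=120.0,
                  triplet_tau=20.0)
        quiet = simulate_binned_traces(SimulationConfig(**kw), seed=41)
        blink = simulate_binned_traces(
            SimulationConfig(**kw, triplet_frac=0.35), seed=41)
        def short_lag_excess(traces):
            c = multitau_correlate(traces.DexDem.astype(float),
                                   traces.DexDem.astype(float), 2.0,
                                   max_lag_s=2e-3)
            early = c.G[c.lags <= 10e-6].mean()
            late = c.G[(c.lags >= 100e-6) & (c.lags <= 300e-6)].mean()
            return early / late
        assert short_lag_excess(blink) > 1.15 * short_lag_excess(quiet)
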