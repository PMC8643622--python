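"""Correlator estimators: gating, oracle agreement, statistical behaviour."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from zmwfccs.correlator import (DegenerateTraceError, direct_correlate,
                                multitau_correlate, photon_correlate,
                                pie_gate, split_and_average, stream_to_traces)
from zmwfccs.simkit import PhotonStream


def _stream(micro, channels, macro=None, sync=25.0, duration=1.0):
    micro = np.asarray(micro, dtype=float)
    if macro is None:
        macro = np.arange(len(micro), dtype=np.int64) * 1000
    return PhotonStream(np.asarray(macro, dtype=np.int64), micro,
                        np.asarray(channels, dtype=np.uint8),
                        sync_period=sync, duration=duration)


class TestPieGate:
    def test_partition_conserves_photons(self, rng):
        n = 5000
        stream = _stream(rng.random(n) * 25.0, rng.integers(0, 2, n),
                         macro=np.sort(rng.integers(0, 10 ** 7, n)))
        gated = pie_gate(stream)
        assert sum(len(v) for v in gated.values()) == n

    def test_red_window_empty_when_all_photons_early(self):
        stream = _stream([1.0, 5.0, 11.0], [1, 1, 1])
        gated = pie_gate(stream)
        assert len(gated["AexAem"]) == 0
        assert len(gated["DexAem"]) == 3

    def test_known_counts_per_window(self):
        micro = [2.0] * 100 + [20.0] * 50       # donor detector photons
        stream = _stream(micro, [0] * 150)
        gated = pie_gate(stream)
        assert len(gated["DexDem"]) == 100
        assert len(gated["AexDem"]) == 50

    def test_overlapping_windows_rejected(self):
        stream = _stream([1.0], [0])
        spec = {"a": (0, 0.0, 15.0), "b": (0, 10.0, 25.0)}
        with pytest.raises(ValueError, match="overlap"):
            pie_gate(stream, spec)

    def test_window_outside_sync_period_rejected(self):
        stream = _stream([1.0], [0])
        with pytest.raises(ValueError, match="within"):
            pie_gate(stream, {"a": (0, 10.0, 30.0)})


class TestMultitau:
    def test_constant_trace_has_zero_correlation(self):
        trace = np.full(5000, 7.0)
        curve = multitau_correlate(trace, trace, 10.0)
        assert np.allclose(curve.G, 0.0, atol=1e-12)

    def test_independent_poisson_traces_uncorrelated(self, rng):
        a = rng.poisson(5.0, 200_000).astype(float)
        b = rng.poisson(3.0, 200_000).astype(float)
        curve = split_and_average(a, b, 10.0, n_chunks=10, max_lag_s=0.02)
        ok = np.abs(curve.G) < 4.0 * np.maximum(curve.stderr, 1e-12)
        assert ok.mean() > 0.95

    def test_telegraph_decay_matches_closed_form(self, telegraph_trace):
        trace, k1, k2, (lo, hi), bin_ms = telegraph_trace
        curve = multitau_correlate(trace, trace, bin_ms * 1e3,
                                   max_lag_s=3e-3)
        lam = (k1 + k2) * 1e3                  # s^-1
        p1 = k1 / (k1 + k2)
        mean = lo + p1 * (hi - lo)
        g0 = p1 * (1 - p1) * (hi - lo) ** 2 / mean ** 2
        model = g0 * np.exp(-lam * curve.lags)
        sel = curve.lags < 1.5e-3
        resid = curve.G[sel] - model[sel]
        assert np.max(np.abs(resid)) < 0.15 * g0    # MC error budget

    def test_scale_invariance(self, telegraph_trace):
        trace = telegraph_trace[0]
        c1 = multitau_correlate(trace, trace, 10.0)
        c2 = multitau_correlate(7.3 * trace, 7.3 * trace, 10.0)
        assert np.allclose(c1.G, c2.G, rtol=1e-12, atol=1e-14)

    def test_cross_of_identical_inputs_equals_auto(self, telegraph_trace):
        trace = telegraph_trace[0]
        auto = multitau_correlate(trace, trace, 10.0)
        cross = multitau_correlate(trace.copy(), trace.copy(), 10.0)
        assert np.array_equal(auto.G, cross.G)

    def test_zero_mean_channel_raises(self):
        with pytest.raises(DegenerateTraceError):
            multitau_correlate(np.zeros(1000), np.ones(1000), 10.0)

    @given(st.integers(600, 10_000), st.integers(1, 10 ** 6))
    @settings(deadline=None, max_examples=12)
    def test_agrees_with_direct_estimator_everywhere(self, n, seed):
        """Multi-tau == brute-force direct estimator at every lag,
        including rebinned octaves, to 1e-10 relative."""
        rng = np.random.default_rng(seed)
        base = rng.poisson(4.0, n).astype(float) \
            + np.sin(np.arange(n) / 50.0) ** 2
        other = np.roll(base, 3) + rng.poisson(1.0, n)
        mt = multitau_correlate(base, other, 5.0, m=8)
        # independent rebin + direct summation per octave
        a, b = base.copy(), other.copy()
        width, i = 5.0, 0
        first, last = 1, 8
        while i < len(mt):
            ks = [k for k in range(first, last + 1)
                  if i + k - first < len(mt)
                  and abs(mt.lags[i + k - first] - k * width * 1e-6) < 1e-15]
            if not ks:
                break
            ref = direct_correlate(a, b, width, ks)
            for j, _ in enumerate(ks):
                # 1e-10 relative, with an absolute floor for G ~ 0 where
                # a relative criterion is ill-posed
                assert abs(mt.G[i + j] - ref.G[j]) <= \
                    1e-10 * abs(ref.G[j]) + 1e-13
            i += len(ks)
            n2 = len(a) // 2 * 2
            a = a[:n2].reshape(-1, 2).sum(axis=1)
            b = b[:n2].reshape(-1, 2).sum(axis=1)
            width *= 2
            first, last = 5, 8

    def test_rebinning_invariance_at_long_lags(self, telegraph_trace):
        trace = telegraph_trace[0]
        fine = multitau_correlate(trace, trace, 10.0, max_lag_s=5e-3)
        n2 = len(trace) // 2 * 2
        coarse_trace = trace[:n2].reshape(-1, 2).sum(axis=1)
        coarse = multitau_correlate(coarse_trace, coarse_trace, 20.0,
                                    max_lag_s=5e-3)
        shared = np.intersect1d(np.round(fine.lags, 12),
                                np.round(coarse.lags, 12))
        shared = shared[shared >= 10 * 10e-6]
        gf = fine.G[np.isin(np.round(fine.lags, 12), shared)]
        gc = coarse.G[np.isin(np.round(coarse.lags, 12), shared)]
        assert np.max(np.abs(gf - gc)) < 0.1 * np.max(np.abs(fine.G))


class TestPhotonCorrelate:
    def test_insufficient_events_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            photon_correlate([0.5], [0.2], np.array([0, 1e-3]), 1.0)

    def test_homogeneous_poisson_is_flat(self, rng):
        ta = np.sort(rng.random(20_000))
        tb = np.sort(rng.random(20_000))
        edges = np.geomspace(1e-5, 0.05, 25)
        curve = photon_correlate(ta, tb, edges, 1.0)
        assert np.max(np.abs(curve.G)) < 0.1

    def test_matches_binned_estimator_on_bunched_stream(self, rng):
        # bunched events: Poisson with a slowly switching rate
        n_bins = 100_000
        bin_s = 1e-5
        state = np.cumsum(rng.normal(0, 1, n_bins))
        rate = 2.0 + 1.5 * (state - state.min()) / np.ptp(state)
        counts_a = rng.poisson(rate)
        counts_b = rng.poisson(rate)
        t = (np.arange(n_bins) + 0.5) * bin_s
        ta = np.repeat(t, counts_a)
        tb = np.repeat(t, counts_b)
        binned = multitau_correlate(counts_a.astype(float),
                                    counts_b.astype(float), 10.0,
                                    max_lag_s=5e-3)
        edges = np.concatenate([[binned.lags[0] / 2],
                                np.sqrt(binned.lags[1:] * binned.lags[:-1]),
                                [binned.lags[-1] * 1.4]])
        event = photon_correlate(ta, tb, edges, n_bins * bin_s)
        # same statistical object within binning error
        scale = np.max(np.abs(binned.G))
        match = np.interp(event.lags, binned.lags, binned.G)
        assert np.median(np.abs(event.G - match)) < 0.1 * scale


class TestSplitAndAverage:
    def test_periodic_chunks_give_zero_stderr(self):
        chunk = np.tile([1.0, 4.0, 2.0, 7.0], 500)
        trace = np.tile(chunk, 4)
        curve = split_and_average(trace, trace, 10.0, n_chunks=4,
                                  max_lag_s=1e-4)
        assert np.allclose(curve.stderr, 0.0, atol=1e-12)

    def test_stderr_consistent_across_chunk_counts(self, rng):
        # the split-based SE estimates the full-trace uncertainty, so it
        # must not depend on how many chunks estimate it: per-chunk
        # scatter grows as sqrt(n) while averaging shrinks it by sqrt(n)
        trace = rng.poisson(10.0, 160_000).astype(float)
        se = {}
        for n in (4, 16):
            curve = split_and_average(trace, trace, 10.0, n_chunks=n,
                                      max_lag_s=5e-4)
            se[n] = np.median(curve.stderr)
        assert se[16] == pytest.approx(se[4], rel=0.6)
        # and the per-chunk scatter itself scales as 1/sqrt(chunk length)
        assert se[16] * np.sqrt(16) == pytest.approx(
            2.0 * se[4] * np.sqrt(4), rel=0.6)

    def test_chunk_too_short_for_max_lag(self):
        with pytest.raises(ValueError, match="chunk duration"):
            split_and_average(np.ones(1000), np.ones(1000), 10.0,
                              n_chunks=4, max_lag_s=1.0)

    def test_values_come_from_full_trace(self, rng):
        a = rng.poisson(6.0, 50_000).astype(float)
        full = multitau_correlate(a, a, 10.0, max_lag_s=1e-3)
        split = split_and_average(a, a, 10.0, n_chunks=5, max_lag_s=1e-3)
        n = len(split)
        assert np.array_equal(split.G, full.G[:n])


class TestStreamToTraces:
    def test_binned_counts_conserve_photons(self, rng):
        n = 4000
        stream = _stream(rng.random(n) * 25.0, rng.integers(0, 2, n),
                         macro=np.sort(rng.integers(0, 39_999_999, n)),
                         duration=1.0)
        traces = stream_to_traces(stream, bin_width_us=100.0)
        total = sum(int(traces.channel(c).sum())
                    for c in ("DexDem", "DexAem", "AexAem", "AexDem"))
        assert total == n
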