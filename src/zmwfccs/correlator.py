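"""PIE-gated auto- and cross-correlation on a quasi-logarithmic lag grid.

The estimator is the normalized intensity covariance

    G(tau) = <dF_a(t) dF_b(t + tau)> / (<F_a> <F_b>)

computed with *symmetric* normalization: for every lag the two means are
recomputed over the overlapping segments of the traces, which suppresses
bias from slow drifts.  Successive octaves of the multi-tau scheme are
evaluated on pairwise-rebinned traces (``m`` lag points per octave),
spanning microsecond to second lags at O(N log N) cost.  Zero lag is
never part of a curve (it is shot-noise dominated); "G(0)" downstream
always means a fitted amplitude.

:func:`direct_correlate` is the brute-force reference implementation of
the same estimator, kept deliberately independent of the multi-tau code
path so the two can be cross-checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .simkit import PhotonStream, IntensityTraces, DET_DONOR, DET_ACCEPTOR


class DegenerateTraceError(ValueError):
    """Raised when a correlation is mathematically undefined (zero mean)."""


@dataclass
class CorrelationCurve:
    """Correlation amplitudes on a strictly increasing positive lag grid."""

    lags: np.ndarray                    # s
    G: np.ndarray
    stderr: Optional[np.ndarray] = None
    channel_pair: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        if self.lags.ndim != 1 or self.G.shape != self.lags.shape:
            raise ValueError("lags and G must be 1-D arrays of equal length")
        if len(self.lags) and self.lags[0] <= 0:
            raise ValueError("lags must be > 0")
        if len(self.lags) > 1 and np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if not np.all(np.isfinite(self.G)):
            raise ValueError("G must be finite")
        if self.stderr is not None:
            self.stderr = np.asarray(self.stderr, dtype=float)
            if self.stderr.shape != self.lags.shape:
                raise ValueError("stderr must match lags in length")
            if np.any(self.stderr < 0):
                raise ValueError("stderr must be >= 0")

    def __len__(self) -> int:
        return len(self.lags)


# ---------------------------------------------------------------------------
# PIE gating


def default_gates(stream: PhotonStream) -> dict:
    """Microtime windows of the four logical channels under 40 MHz PIE."""
    cfg = stream.metadata.get("config") or {}
    delay = cfg.get("red_pulse_delay", stream.sync_period / 2.0)
    sync = stream.sync_period
    return {
        "DexDem": (DET_DONOR, 0.0, delay),
        "DexAem": (DET_ACCEPTOR, 0.0, delay),
        "AexAem": (DET_ACCEPTOR, delay, sync),
        "AexDem": (DET_DONOR, delay, sync),
    }


def pie_gate(stream: PhotonStream, gate_spec: Optional[dict] = None) -> dict:
    """Split a photon stream into gated per-channel event-time lists.

    ``gate_spec`` maps logical channel names to ``(detector, lo_ns,
    hi_ns)`` microtime windows; windows must be disjoint per detector and
    lie within ``[0, sync_period)``.  Returns absolute event times in
    seconds per logical channel; a window retaining no photons yields an
    empty array (never an error).
    """
    gates = default_gates(stream) if gate_spec is None else gate_spec
    per_det = {}
    for name, (det, lo, hi) in gates.items():
        if not (0.0 <= lo < hi <= stream.sync_period):
            raise ValueError(
                f"gate {name!r}: window [{lo}, {hi}) must lie within "
                f"[0, {stream.sync_period})")
        per_det.setdefault(det, []).append((lo, hi, name))
    for det, wins in per_det.items():
        wins = sorted(wins)
        for (lo1, hi1, n1), (lo2, hi2, n2) in zip(wins, wins[1:]):
            if lo2 < hi1:
                raise ValueError(
                    f"gates {n1!r} and {n2!r} overlap on detector {det}")
    times = stream.times_s
    out = {}
    for name, (det, lo, hi) in gates.items():
        sel = ((stream.channels == det)
               & (stream.microtimes >= lo) & (stream.microtimes < hi))
        out[name] = times[sel]
    return out


def bin_events(times_s: np.ndarray, bin_width_us: float,
               duration_s: float) -> np.ndarray:
    """Histogram event times onto a regular grid of ``bin_width_us`` bins."""
    n_bins = int(round(duration_s / (bin_width_us * 1e-6)))
    idx = np.floor(np.asarray(times_s) / (bin_width_us * 1e-6)).astype(
        np.int64)
    idx = idx[(idx >= 0) & (idx < n_bins)]
    return np.bincount(idx, minlength=n_bins).astype(np.int64)


def stream_to_traces(stream: PhotonStream, bin_width_us: float,
                     gate_spec: Optional[dict] = None) -> IntensityTraces:
    """Gate a photon stream and bin each logical channel."""
    gated = pie_gate(stream, gate_spec)
    binned = {name: bin_events(t, bin_width_us, stream.duration)
              for name, t in gated.items()}
    return IntensityTraces(
        bin_width=bin_width_us,
        DexDem=binned.get("DexDem", 0),
        DexAem=binned.get("DexAem", 0),
        AexAem=binned.get("AexAem", 0),
        AexDem=binned.get("AexDem", 0),
        duration=stream.duration,
        metadata=dict(stream.metadata))


# ---------------------------------------------------------------------------
# estimators


def _symnorm_corr(a: np.ndarray, b: np.ndarray, k: int) -> float:
    """Symmetric-normalization correlation of two traces at integer lag k."""
    n = len(a) - k
    ma = a[:n].mean()
    mb = b[k:].mean()
    if ma <= 0 or mb <= 0:
        raise DegenerateTraceError(
            "correlation undefined: zero-mean channel over the overlap")
    return float(np.dot(a[:n], b[k:]) / n / (ma * mb) - 1.0)


def _rebin2(x: np.ndarray) -> np.ndarray:
    n = len(x) // 2 * 2
    return x[:n].reshape(-1, 2).sum(axis=1)


def multitau_correlate(trace_a: np.ndarray, trace_b: np.ndarray,
                       bin_width_us: float, m: int = 16,
                       max_lag_s: float = 1.0,
                       channel_pair: str = "") -> CorrelationCurve:
    """Multi-tau correlation of two equal-length binned traces.

    The first octave evaluates lags ``1..m`` at the native bin width;
    each subsequent octave pairwise-rebins both traces and evaluates
    lags ``m/2+1..m`` at the doubled width, until ``max_lag_s`` or the
    trace length is exhausted.
    """
    a = np.asarray(trace_a, dtype=np.float64)
    b = np.asarray(trace_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("traces must be 1-D and of equal length")
    if len(a) < 2 * m:
        raise ValueError("trace too short for the requested lag scheme")
    if a.mean() <= 0 or b.mean() <= 0:
        raise DegenerateTraceError("correlation undefined: zero-mean channel")

    width = bin_width_us * 1e-6
    lags, G = [], []
    first, last = 1, m
    while True:
        stop = False
        for k in range(first, last + 1):
            lag = k * width
            if lag > max_lag_s or len(a) - k < max(m, 8):
                stop = True
                break
            lags.append(lag)
            G.append(_symnorm_corr(a, b, k))
        if stop or len(a) // 2 < 2 * m:
            break
        a = _rebin2(a)
        b = _rebin2(b)
        width *= 2.0
        first, last = m // 2 + 1, m
    return CorrelationCurve(np.array(lags), np.array(G),
                            channel_pair=channel_pair,
                            meta={"m": m, "bin_width_us": bin_width_us,
                                  "max_lag_s": max_lag_s,
                                  "normalization": "symmetric"})


def multitau_lag_bins(n_bins: int, m: int = 16,
                      max_lag_bins: Optional[int] = None) -> list:
    """The (octave_level, lag_in_rebinned_bins) schedule of the multi-tau grid.

    Exposed so reference implementations can evaluate the identical grid.
    """
    out = []
    level, first, last = 0, 1, m
    n = n_bins
    while True:
        stop = False
        for k in range(first, last + 1):
            lag_native = k * (2 ** level)
            if (max_lag_bins is not None and lag_native > max_lag_bins) \
                    or n - k < max(m, 8):
                stop = True
                break
            out.append((level, k))
        if stop or n // 2 < 2 * m:
            break
        n //= 2
        level += 1
        first, last = m // 2 + 1, m
    return out


def direct_correlate(trace_a: np.ndarray, trace_b: np.ndarray,
                     bin_width_us: float, lag_bins: Sequence[int],
                     channel_pair: str = "") -> CorrelationCurve:
    """Brute-force direct estimator at explicit integer lags (reference).

    Computes the symmetric-normalization estimator by explicit
    summation, independent of the multi-tau code path.  O(N) per lag,
    intended for traces of at most ~1e4 bins.
    """
    a = np.asarray(trace_a, dtype=np.float64)
    b = np.asarray(trace_b, dtype=np.float64)
    lags, G = [], []
    for k in sorted(set(int(k) for k in lag_bins)):
        if k < 1 or k >= len(a):
            raise ValueError(f"lag {k} outside the trace")
        n = len(a) - k
        ma = a[:n].sum() / n
        mb = b[k:].sum() / n
        if ma <= 0 or mb <= 0:
            raise DegenerateTraceError("zero-mean channel")
        s = 0.0
        for i in range(n):
            s += a[i] * b[i + k]
        lags.append(k * bin_width_us * 1e-6)
        G.append(s / n / (ma * mb) - 1.0)
    return CorrelationCurve(np.array(lags), np.array(G),
                            channel_pair=channel_pair,
                            meta={"estimator": "direct"})


def photon_correlate(events_a: np.ndarray, events_b: np.ndarray,
                     lag_edges_s: np.ndarray, duration_s: float,
                     min_events: int = 10,
                     channel_pair: str = "") -> CorrelationCurve:
    """Event-mode correlation of two photon arrival-time lists.

    For each lag bin ``[e_i, e_{i+1})`` counts ordered pairs with that
    separation and normalizes by the expectation for independent
    homogeneous streams, giving the same quantity as the binned
    estimator at matching resolution.
    """
    ta = np.sort(np.asarray(events_a, dtype=float))
    tb = np.sort(np.asarray(events_b, dtype=float))
    if len(ta) < min_events or len(tb) < min_events:
        raise ValueError(
            f"insufficient events for correlation (need >= {min_events} "
            f"per channel, got {len(ta)} and {len(tb)})")
    edges = np.asarray(lag_edges_s, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0) \
            or edges[0] < 0:
        raise ValueError("lag_edges_s must be increasing and non-negative")
    rate_b = len(tb) / duration_s
    lags, G = [], []
    lo_idx = np.searchsorted(tb, ta[:, None] + edges[None, :])
    for i in range(len(edges) - 1):
        width = edges[i + 1] - edges[i]
        mid = 0.5 * (edges[i] + edges[i + 1])
        pairs = int((lo_idx[:, i + 1] - lo_idx[:, i]).sum())
        # effective observation window shrinks by the lag
        n_a_eff = int(np.searchsorted(ta, duration_s - mid))
        if n_a_eff <= 0:
            continue
        expected = n_a_eff * rate_b * width
        lags.append(mid)
        G.append(pairs / expected - 1.0)
    return CorrelationCurve(np.array(lags), np.array(G),
                            channel_pair=channel_pair,
                            meta={"estimator": "photon"})


def split_and_average(trace_a: np.ndarray, trace_b: np.ndarray,
                      bin_width_us: float, n_chunks: int = 8, m: int = 16,
                      max_lag_s: float = 1.0,
                      channel_pair: str = "") -> CorrelationCurve:
    """Full-trace multi-tau correlation with split-based standard errors.

    The curve values come from the full-length trace (the mean-
    normalization bias of the estimator scales as 1/T, so the longest
    stretch gives the least biased amplitudes); the per-lag standard
    error is estimated from the scatter of ``n_chunks`` contiguous
    segments correlated separately.  Chunks must comfortably exceed the
    longest lag.
    """
    if n_chunks < 3:
        raise ValueError("need n_chunks >= 3 for a standard error")
    a = np.asarray(trace_a, dtype=np.float64)
    b = np.asarray(trace_b, dtype=np.float64)
    chunk = len(a) // n_chunks
    chunk_dur = chunk * bin_width_us * 1e-6
    if chunk_dur < 4.0 * max_lag_s:
        raise ValueError(
            f"chunk duration {chunk_dur:.3g}s too short for max lag "
            f"{max_lag_s:.3g}s (need >= 4x)")
    full = multitau_correlate(a, b, bin_width_us, m=m, max_lag_s=max_lag_s)
    curves = []
    for c in range(n_chunks):
        sl = slice(c * chunk, (c + 1) * chunk)
        curves.append(multitau_correlate(a[sl], b[sl], bin_width_us, m=m,
                                         max_lag_s=max_lag_s))
    n_lag = min(min(len(c) for c in curves), len(full))
    lags = full.lags[:n_lag]
    stack = np.stack([c.G[:n_lag] for c in curves])
    se = stack.std(axis=0, ddof=1) / np.sqrt(n_chunks)
    return CorrelationCurve(lags, full.G[:n_lag], stderr=se,
                            channel_pair=channel_pair,
                            meta={"m": m, "bin_width_us": bin_width_us,
                                  "max_lag_s": max_lag_s,
                                  "n_chunks": n_chunks,
                                  "normalization": "symmetric",
                                  "values": "full-trace",
                                  "stderr_from": "chunk scatter"})


def correlate_traces(traces: IntensityTraces, pair: str, m: int = 16,
                     max_lag_s: float = 1.0,
                     n_chunks: int = 0) -> CorrelationCurve:
    """Correlate a named channel pair of an :class:`IntensityTraces`.

    ``pair`` is one of ``GG`` (species green autocorrelation, all
    donor-excited photons), ``RR`` (red autocorrelation, AexAem),
    ``GR`` (species cross-correlation, all donor-excited x AexAem),
    ``FRET`` (donor-acceptor anticorrelation, DexDem x DexAem),
    ``FA`` (FRET-acceptor autocorrelation, DexAem) or
    ``DD`` (donor-channel autocorrelation, DexDem).  With ``n_chunks``
    >= 3 the split-based standard error is attached.
    """
    pairs = {
        "GG": ("Dex", "Dex"),
        "DD": ("DexDem", "DexDem"),
        "RR": ("AexAem", "AexAem"),
        "GR": ("Dex", "AexAem"),
        "FRET": ("DexDem", "DexAem"),
        "FA": ("DexAem", "DexAem"),
    }
    if pair not in pairs:
        raise KeyError(f"unknown channel pair {pair!r}; expected one of "
                       f"{sorted(pairs)}")
    ca, cb = pairs[pair]
    a = traces.channel(ca)
    b = traces.channel(cb)
    if n_chunks >= 3:
        curve = split_and_average(a, b, traces.bin_width, n_chunks=n_chunks,
                                  m=m, max_lag_s=max_lag_s,
                                  channel_pair=pair)
    else:
        curve = multitau_correlate(a, b, traces.bin_width, m=m,
                                   max_lag_s=max_lag_s, channel_pair=pair)
    curve.meta["channels"] = (ca, cb)
    return curve
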