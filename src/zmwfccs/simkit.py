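"""Synthetic PIE dual-color photon streams and binned intensity traces.

The generator emulates the statistical structure that downstream
correlation analysis assumes: point-like molecules diffusing through a
small 3D-Gaussian observation volume (the stand-in for a zero-mode
waveguide near field), a mixture of green-only, red-only and
dual-labelled species, reversible two-state binding of the dual-labelled
species modelled as a telegraph process with pseudo-first-order rates
``k_on * [ligand]`` and ``k_off``, FRET switching between a bound
efficiency ``E1`` and an unbound residual ``E2``, optional triplet
blinking of each dye, pulsed interleaved excitation (PIE) timing, and
uncorrelated detector background.

Two generation paths exist:

* a fine-grained, fully inspectable path
  (:func:`simulate_binding_trajectory`, :func:`simulate_diffusion`,
  :func:`emit_photons`) that produces time-tagged photon records, used
  for small problems and validation, and
* a fast binned path (:func:`simulate_binned_traces`) that draws Poisson
  counts per bin directly from the instantaneous detection rates,
  skipping individual photon records.

Both paths share the same physical model and are statistically
indistinguishable for matched configurations.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np

AVOGADRO = 6.02214076e23

# logical channel order used everywhere: donor-excited donor, donor-excited
# acceptor (FRET), red-excited acceptor, red-excited donor
CHANNELS = ("DexDem", "DexAem", "AexAem", "AexDem")

# detector indices in photon records
DET_DONOR = 0
DET_ACCEPTOR = 1


@dataclass
class SimulationConfig:
    """Physical and numerical parameters of a synthetic PIE-FCCS measurement.

    Units follow the repo-wide convention: lengths in nm, diffusion
    coefficients in um^2/s, concentrations in uM, rate constants in
    uM^-1 ms^-1 (association) and ms^-1 (dissociation), brightnesses and
    backgrounds in counts/ms, PIE timing in ns, duration in s, the
    simulation time step ``dt`` in us.
    """

    # geometry
    box_lengths: tuple = (392.0, 392.0, 392.0)   # nm
    detection_waist_xy: float = 47.6             # nm, 1/e^2 lateral radius
    kappa: float = 2.0                           # axial/lateral aspect ratio

    # species: diffusion (um^2/s) and concentrations (uM)
    diffusion_G: float = 0.60
    diffusion_R: float = 0.65
    diffusion_GR: float = 0.55
    conc_G: float = 1.0
    conc_R: float = 1.0
    conc_GR: float = 0.0

    # binding kinetics of the dual-labelled species
    k_on: float = 0.07          # uM^-1 ms^-1
    k_off: float = 3.61         # ms^-1
    ligand_conc: float = 40.0   # uM, un-depleted ligand bath

    # FRET efficiencies of the bound / unbound state
    E1: float = 0.40
    E2: float = 0.02

    # triplet blinking (per dye, independent donor/acceptor)
    triplet_frac: float = 0.0   # dark-state occupancy
    triplet_tau: float = 2.0    # us, correlation time

    # photophysics / detection
    brightness_G: float = 100.0  # counts/ms per molecule at volume centre
    brightness_R: float = 100.0
    background_G: float = 0.2   # counts/ms, donor detector
    background_R: float = 0.2   # counts/ms, acceptor detector
    crosstalk: float = 0.0      # donor photons leaking into the acceptor channel
    direct_excitation: float = 0.0  # acceptor excited by the green laser

    # PIE timing
    sync_period: float = 25.0       # ns (40 MHz)
    red_pulse_delay: float = 12.5   # ns

    # acquisition / numerics
    duration: float = 8.0       # s
    dt: float = 4.0             # us, emission bin / state-update step
    diffusion_stride: int = 16  # positions updated every dt * stride
    seed: int = 0

    def __post_init__(self):
        if not (0.0 <= self.E2 < self.E1 <= 1.0):
            raise ValueError(
                f"FRET efficiencies must satisfy 0 <= E2 < E1 <= 1, "
                f"got E1={self.E1}, E2={self.E2}")
        for name in ("k_on", "k_off", "ligand_conc", "conc_G", "conc_R",
                     "conc_GR", "brightness_G", "brightness_R",
                     "background_G", "background_R", "triplet_frac",
                     "diffusion_G", "diffusion_R", "diffusion_GR"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.dt <= 0 or self.duration <= 0:
            raise ValueError("dt and duration must be > 0")
        if self.diffusion_stride < 1:
            raise ValueError("diffusion_stride must be >= 1")
        if not (0 < self.red_pulse_delay < self.sync_period):
            raise ValueError("red_pulse_delay must lie inside the sync period")
        # spatial resolution: rms displacement per dt well below the waist
        d_max = max(self.diffusion_G, self.diffusion_R, self.diffusion_GR)
        if np.sqrt(2.0 * d_max * self.dt) >= self.detection_waist_xy / 5.0:
            raise ValueError(
                f"under-resolved diffusion: rms step per dt "
                f"{np.sqrt(2.0 * d_max * self.dt):.2f} nm must stay below "
                f"waist/5 = {self.detection_waist_xy / 5.0:.2f} nm; "
                f"decrease dt or the diffusion coefficients")
        # positions advance every dt*stride; a coarser limit applies there:
        # amplitudes are exact for any step (stationary distribution is
        # uniform) but correlation shape below the update interval degrades
        step_rms = np.sqrt(2.0 * d_max * self.dt * self.diffusion_stride)
        if step_rms >= self.detection_waist_xy / 2.0:
            raise ValueError(
                f"position-update step {step_rms:.2f} nm exceeds waist/2: "
                f"reduce diffusion_stride or dt")
        # temporal resolution of the binding kinetics
        k_tot = self.k_on * self.ligand_conc + self.k_off   # ms^-1
        if self.dt * 1e-3 * k_tot >= 0.1:
            raise ValueError(
                f"under-resolved kinetics: dt*(k_on*[ligand]+k_off) = "
                f"{self.dt * 1e-3 * k_tot:.3f} must be < 0.1")
        if np.prod(np.asarray(self.box_lengths)) < 50.0 * self.v_eff_nm3:
            raise ValueError(
                "simulation box must hold at least 50 effective detection "
                "volumes so boundary effects are negligible")

    # -- derived geometry ------------------------------------------------
    @property
    def v_eff_nm3(self) -> float:
        """Effective detection volume pi^{3/2} w^2 z0 of the 3D Gaussian."""
        w = self.detection_waist_xy
        return np.pi ** 1.5 * w * w * (self.kappa * w)

    @property
    def v_eff_liters(self) -> float:
        return self.v_eff_nm3 * 1e-24

    def n_molecules(self, conc_uM: float) -> int:
        """Number of molecules of a species at ``conc_uM`` in the box."""
        box_l = float(np.prod(np.asarray(self.box_lengths))) * 1e-24
        return int(round(conc_uM * 1e-6 * AVOGADRO * box_l))

    @property
    def bound_occupancy(self) -> float:
        """Stationary bound-state occupancy k1/(k1+k2) of the telegraph."""
        k1 = self.k_on * self.ligand_conc
        tot = k1 + self.k_off
        if tot == 0:
            return 0.0
        return k1 / tot

    def digest(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["box_lengths"] = list(self.box_lengths)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "box_lengths" in d:
            d["box_lengths"] = tuple(d["box_lengths"])
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        return cls(**d)


def titration_condition(ligand_conc: float, rgg_conc: float = 1.0,
                        k_on: float = 0.07, k_off: float = 3.61,
                        min_dual_molecules: int = 10,
                        **overrides) -> SimulationConfig:
    """Config for one titration point: green-labelled ligand in excess.

    The red-labelled species (the peptide, total ``rgg_conc``) is split
    between free (red-only) and complexed (dual-labelled) populations
    according to the stationary bound fraction k1/(k1+k2); the
    dual-labelled population additionally carries the two-state FRET
    switching with the same rates.

    When the dual-labelled population would round to fewer than
    ``min_dual_molecules`` molecules in the default box (low ligand
    concentration), the box is enlarged so integer molecule counts do
    not distort the realized population fraction.
    """
    b = k_on * ligand_conc / (k_on * ligand_conc + k_off)
    conc_gr = rgg_conc * b
    kwargs = dict(overrides)
    if "box_lengths" not in kwargs and conc_gr > 0:
        default_box = SimulationConfig.__dataclass_fields__[
            "box_lengths"].default
        v_box_l = float(np.prod(np.asarray(default_box))) * 1e-24
        need_l = min_dual_molecules / (conc_gr * 1e-6 * AVOGADRO)
        if need_l > v_box_l:
            side = (need_l * 1e24) ** (1.0 / 3.0)
            kwargs["box_lengths"] = (side, side, side)
    return SimulationConfig(
        ligand_conc=ligand_conc,
        conc_G=max(ligand_conc - conc_gr, 0.0),
        conc_R=rgg_conc * (1.0 - b),
        conc_GR=conc_gr,
        k_on=k_on, k_off=k_off,
        **kwargs)


# ---------------------------------------------------------------------------
# containers


@dataclass
class PhotonStream:
    """Time-tagged photon records, the stand-in for TTTR acquisition data.

    ``macrotimes`` count sync ticks (period ``sync_period`` ns) and are
    non-decreasing; ``microtimes`` are ns within the sync period and
    identify the exciting laser under PIE; ``channels`` index the two
    detectors (0 donor, 1 acceptor).
    """

    macrotimes: np.ndarray      # int64, sync ticks
    microtimes: np.ndarray      # float64, ns in [0, sync_period)
    channels: np.ndarray        # uint8
    sync_period: float          # ns
    duration: float             # s
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.macrotimes = np.asarray(self.macrotimes, dtype=np.int64)
        self.microtimes = np.asarray(self.microtimes, dtype=np.float64)
        self.channels = np.asarray(self.channels, dtype=np.uint8)
        n = len(self.macrotimes)
        if len(self.microtimes) != n or len(self.channels) != n:
            raise ValueError("photon record arrays must have equal length")
        if n and np.any(np.diff(self.macrotimes) < 0):
            raise ValueError("macrotimes must be non-decreasing")
        if n and (self.microtimes.min() < 0
                  or self.microtimes.max() >= self.sync_period):
            raise ValueError("microtimes must lie in [0, sync_period)")
        if n and not np.isin(self.channels,
                             [DET_DONOR, DET_ACCEPTOR]).all():
            raise ValueError("channels restricted to the two detectors {0,1}")

    def __len__(self) -> int:
        return len(self.macrotimes)

    @property
    def times_s(self) -> np.ndarray:
        """Absolute photon times in seconds."""
        return self.macrotimes * (self.sync_period * 1e-9)


@dataclass
class IntensityTraces:
    """Binned counts of the four PIE-gated logical channels on one time base."""

    bin_width: float            # us
    DexDem: np.ndarray
    DexAem: np.ndarray
    AexAem: np.ndarray
    AexDem: np.ndarray
    duration: float             # s
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.DexDem)
        for ch in CHANNELS:
            arr = np.asarray(getattr(self, ch))
            if len(arr) != n:
                raise ValueError("all channels must share one time base")
            if arr.size and arr.min() < 0:
                raise ValueError(f"counts in {ch} must be non-negative")
            setattr(self, ch, arr.astype(np.int64))

    def __len__(self) -> int:
        return len(self.DexDem)

    def channel(self, name: str) -> np.ndarray:
        if name == "Dex":       # all donor-excited photons, FRET-independent
            return self.DexDem + self.DexAem
        if name not in CHANNELS:
            raise KeyError(f"unknown channel {name!r}; expected one of "
                           f"{CHANNELS + ('Dex',)}")
        return getattr(self, name)

    @property
    def time_s(self) -> np.ndarray:
        return np.arange(len(self)) * self.bin_width * 1e-6


# ---------------------------------------------------------------------------
# seeding helpers


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Deterministically split one seed into n independent 31-bit seeds."""
    ss = np.random.SeedSequence(int(seed))
    return (ss.generate_state(n, dtype=np.uint64) % (2 ** 31 - 1)).astype(
        np.int64)


# ---------------------------------------------------------------------------
# fine-grained path


def simulate_binding_trajectory(cfg: SimulationConfig, n_molecules: int,
                                seed: int) -> np.ndarray:
    """Two-state bound/unbound paths of ``n_molecules`` on the dt grid.

    Fixed-step telegraph updates with per-step flip probability
    ``1 - exp(-k dt)``; the initial states are drawn from the stationary
    occupancy so the ensemble is at equilibrium from the first step.
    Returns a boolean array of shape ``(n_molecules, n_steps)``;
    ``True`` marks the bound (high-FRET) state.
    """
    k1 = cfg.k_on * cfg.ligand_conc     # ms^-1, association (pseudo-1st-order)
    k2 = cfg.k_off                      # ms^-1
    dt_ms = cfg.dt * 1e-3
    if not np.isfinite(k1) or not np.isfinite(k2):
        raise ValueError("rates must be finite")
    if dt_ms * (k1 + k2) >= 0.1:
        raise ValueError("dt*(k_on*[ligand]+k_off) must be < 0.1")
    n_steps = int(round(cfg.duration / (cfg.dt * 1e-6)))
    rng = np.random.default_rng(seed)
    p_bind = 1.0 - np.exp(-k1 * dt_ms)
    p_unbind = 1.0 - np.exp(-k2 * dt_ms)
    p0 = 1.0 if (k1 > 0 and k2 == 0) else cfg.bound_occupancy
    states = np.empty((n_molecules, n_steps), dtype=bool)
    cur = rng.random(n_molecules) < p0
    for t in range(n_steps):
        u = rng.random(n_molecules)
        flip = np.where(cur, u < p_unbind, u < p_bind)
        cur = cur ^ flip
        states[:, t] = cur
    return states


def simulate_diffusion(cfg: SimulationConfig, n_molecules: int, seed: int,
                       diffusion: Optional[float] = None) -> np.ndarray:
    """Brownian positions on the dt grid in a periodic box.

    ``diffusion`` (um^2/s) defaults to the dual-labelled species value.
    Returns positions in nm, shape ``(n_steps, n_molecules, 3)``, wrapped
    into ``[0, box)`` per axis; the detection volume sits at the box centre.
    """
    d = cfg.diffusion_GR if diffusion is None else diffusion
    if d < 0:
        raise ValueError("diffusion coefficient must be >= 0")
    n_steps = int(round(cfg.duration / (cfg.dt * 1e-6)))
    box = np.asarray(cfg.box_lengths, dtype=float)
    rng = np.random.default_rng(seed)
    sigma = np.sqrt(2.0 * d * cfg.dt)   # nm; d in um^2/s == nm^2/us, dt in us
    pos = np.empty((n_steps, n_molecules, 3))
    pos[0] = rng.random((n_molecules, 3)) * box
    if sigma > 0:
        steps = rng.normal(0.0, sigma, size=(n_steps - 1, n_molecules, 3))
        pos[1:] = pos[0] + np.cumsum(steps, axis=0)
        pos[:] = np.mod(pos, box)
    else:
        pos[1:] = pos[0]
    return pos


def detection_weight(positions: np.ndarray, cfg: SimulationConfig
                     ) -> np.ndarray:
    """3D-Gaussian detection profile exp(-2r^2/w^2) exp(-2z^2/(kappa w)^2).

    ``positions`` are absolute box coordinates (nm); the profile is
    centred on the box centre.
    """
    box = np.asarray(cfg.box_lengths, dtype=float)
    rel = positions - box / 2.0
    w2 = cfg.detection_waist_xy ** 2
    z02 = (cfg.kappa * cfg.detection_waist_xy) ** 2
    return np.exp(-2.0 * (rel[..., 0] ** 2 + rel[..., 1] ** 2) / w2
                  - 2.0 * rel[..., 2] ** 2 / z02)


def _channel_rates(states: np.ndarray, weights: np.ndarray,
                   cfg: SimulationConfig, species: np.ndarray) -> np.ndarray:
    """Per-step expected counts/ms in the four logical channels.

    ``states`` (n_mol, n_steps) bool, ``weights`` (n_steps, n_mol),
    ``species`` (n_mol,) with 0 = green-only, 1 = red-only,
    2 = dual-labelled.
    """
    e = np.where(states, cfg.E1, cfg.E2).T          # (n_steps, n_mol)
    is_g = species == 0
    is_r = species == 1
    is_gr = species == 2
    w_g = weights[:, is_g].sum(axis=1)
    w_r = weights[:, is_r].sum(axis=1)
    w_gr = weights[:, is_gr]
    e_gr = e[:, is_gr]
    bG, bR = cfg.brightness_G, cfg.brightness_R
    dd = bG * (w_g + (w_gr * (1.0 - e_gr)).sum(axis=1))
    da = bG * (w_gr * e_gr).sum(axis=1)
    aa = bR * (w_r + w_gr.sum(axis=1))
    if cfg.direct_excitation > 0:   # green laser exciting the acceptor
        da = da + cfg.direct_excitation * bG * (w_r + w_gr.sum(axis=1))
    if cfg.crosstalk > 0:           # donor emission in the acceptor channel
        da = da + cfg.crosstalk * dd
        dd = dd * (1.0 - cfg.crosstalk)
    ad = np.zeros_like(dd)
    rates = np.stack([dd + cfg.background_G,
                      da + 0.5 * cfg.background_R,
                      aa + 0.5 * cfg.background_R,
                      ad], axis=0)
    return rates    # (4, n_steps)


def emit_photons(states: np.ndarray, positions: np.ndarray,
                 cfg: SimulationConfig, seed: int,
                 species: Optional[np.ndarray] = None) -> PhotonStream:
    """Draw photon records from state and position paths.

    Expected counts per molecule and step are brightness times the
    Gaussian detection weight, partitioned between donor and acceptor by
    the molecule's current FRET efficiency.  Donor-excited photons get
    micro-times in ``[0, red_pulse_delay)``, directly red-excited
    acceptor photons in ``[red_pulse_delay, sync_period)``; arrival
    times are uniform within each dt step.  Background enters both
    detectors as homogeneous Poisson.
    """
    n_mol = states.shape[0]
    if positions.shape[1] != n_mol or positions.shape[0] != states.shape[1]:
        raise ValueError("states and positions must share the dt grid")
    if species is None:
        species = np.full(n_mol, 2, dtype=np.int64)
    weights = detection_weight(positions, cfg)
    rates = _channel_rates(states, weights, cfg, species)   # counts/ms
    dt_ms = cfg.dt * 1e-3
    if rates.max() * dt_ms > 1.0:
        raise ValueError(
            "expected counts per dt exceed 1 (pile-up): reduce brightness "
            "or dt")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rates * dt_ms)     # (4, n_steps)
    n_steps = states.shape[1]
    dt_s = cfg.dt * 1e-6
    delay, sync = cfg.red_pulse_delay, cfg.sync_period

    rec_t, rec_micro, rec_ch = [], [], []
    for ci, (det, lo, hi) in enumerate([
            (DET_DONOR, 0.0, delay),        # DexDem
            (DET_ACCEPTOR, 0.0, delay),     # DexAem
            (DET_ACCEPTOR, delay, sync),    # AexAem
            (DET_DONOR, delay, sync)]):     # AexDem
        c = counts[ci]
        total = int(c.sum())
        if total == 0:
            continue
        step_idx = np.repeat(np.arange(n_steps), c)
        t = (step_idx + rng.random(total)) * dt_s
        rec_t.append(t)
        rec_micro.append(lo + rng.random(total) * (hi - lo))
        rec_ch.append(np.full(total, det, dtype=np.uint8))

    if rec_t:
        t = np.concatenate(rec_t)
        micro = np.concatenate(rec_micro)
        ch = np.concatenate(rec_ch)
        order = np.argsort(t, kind="stable")
        t, micro, ch = t[order], micro[order], ch[order]
        macro = np.floor(t / (sync * 1e-9)).astype(np.int64)
    else:
        macro = np.empty(0, dtype=np.int64)
        micro = np.empty(0)
        ch = np.empty(0, dtype=np.uint8)
    return PhotonStream(macro, micro, ch, sync_period=sync,
                        duration=n_steps * dt_s,
                        metadata={"config_digest": cfg.digest(),
                                  "seed": int(seed)})


def simulate_photon_stream(cfg: SimulationConfig,
                           seed: Optional[int] = None) -> PhotonStream:
    """Full fine-grained simulation of the configured mixture."""
    seed = cfg.seed if seed is None else seed
    s = _child_seeds(seed, 5)
    n_g = cfg.n_molecules(cfg.conc_G)
    n_r = cfg.n_molecules(cfg.conc_R)
    n_gr = cfg.n_molecules(cfg.conc_GR)
    n_steps = int(round(cfg.duration / (cfg.dt * 1e-6)))
    species = np.concatenate([np.zeros(n_g), np.ones(n_r),
                              np.full(n_gr, 2)]).astype(np.int64)
    pos = np.concatenate([
        simulate_diffusion(cfg, n_g, s[0], cfg.diffusion_G),
        simulate_diffusion(cfg, n_r, s[1], cfg.diffusion_R),
        simulate_diffusion(cfg, n_gr, s[2], cfg.diffusion_GR)], axis=1)
    states = np.zeros((n_g + n_r + n_gr, n_steps), dtype=bool)
    if n_gr:
        states[n_g + n_r:] = simulate_binding_trajectory(cfg, n_gr, s[3])
    stream = emit_photons(states, pos, cfg, s[4], species)
    stream.metadata["config"] = cfg.to_dict()
    return stream


# ---------------------------------------------------------------------------
# fast binned path


def _telegraph_bins(rng, n_bins: int, bin_ms: float, k1: float, k2: float,
                    p0: float) -> np.ndarray:
    """Exact two-state Markov path sampled at bin starts.

    Dwell times follow the exact exponential laws (rate ``k1`` ms^-1 out
    of the unbound state, ``k2`` out of the bound state), so the path
    carries no time-discretization error; the state is read out at the
    start of each of ``n_bins`` bins of width ``bin_ms``.  Returns a
    boolean array, True = bound.
    """
    start_bound = bool(rng.random() < p0)
    if (start_bound and k2 <= 0) or (not start_bound and k1 <= 0):
        return np.full(n_bins, start_bound)
    total = n_bins * bin_ms
    cycle_rate = k1 * k2 / (k1 + k2)
    chunks = []
    t_end = 0.0
    while t_end < total:
        remaining = total - t_end
        m = int(remaining * cycle_rate
                + 10.0 * np.sqrt(remaining * cycle_rate + 1.0) + 8)
        # one batch = m full cycles, so the alternation pattern repeats
        d_first = rng.exponential(1.0 / (k2 if start_bound else k1), m)
        d_second = rng.exponential(1.0 / (k1 if start_bound else k2), m)
        dw = np.column_stack([d_first, d_second]).ravel()
        chunks.append(dw)
        t_end += float(dw.sum())
    trans = np.cumsum(np.concatenate(chunks))
    bin_starts = np.arange(n_bins) * bin_ms
    n_flips = np.searchsorted(trans, bin_starts, side="right")
    odd = (n_flips % 2).astype(bool)
    return odd ^ start_bound


def _species_sigmas(cfg: SimulationConfig, n_g: int, n_r: int,
                    n_gr: int) -> np.ndarray:
    dt_pos = cfg.dt * cfg.diffusion_stride  # us; D in um^2/s == nm^2/us
    return np.concatenate([
        np.full(n_g, np.sqrt(2.0 * cfg.diffusion_G * dt_pos)),
        np.full(n_r, np.sqrt(2.0 * cfg.diffusion_R * dt_pos)),
        np.full(n_gr, np.sqrt(2.0 * cfg.diffusion_GR * dt_pos)),
    ]).astype(np.float32)


def _coarse_weights(cfg: SimulationConfig, rng, n_coarse: int,
                    n_g: int, n_r: int, n_gr: int, keep_all: bool):
    """Brownian paths at the coarse (position-update) resolution.

    Returns the per-step detection-weight sums of the green-only and
    red-only populations plus the per-molecule weights of the
    dual-labelled population — or the full per-molecule weight matrix
    when ``keep_all`` (needed for triplet blinking).  Arrays are laid
    out coordinate-major so the cumulative sums and the wrap run on
    contiguous memory.
    """
    n_mol = n_g + n_r + n_gr
    box = np.asarray(cfg.box_lengths, dtype=np.float32)
    half = box / np.float32(2.0)
    inv_w2 = np.float32(2.0 / cfg.detection_waist_xy ** 2)
    inv_z2 = np.float32(2.0 / (cfg.kappa * cfg.detection_waist_xy) ** 2)
    sig = _species_sigmas(cfg, n_g, n_r, n_gr)
    pos = (rng.random((3, n_mol)) * box[:, None]).astype(np.float32)

    s_g = np.empty(n_coarse)
    s_r = np.empty(n_coarse)
    w_gr = np.empty((n_coarse, n_gr), dtype=np.float32)
    w_all = np.empty((n_coarse, n_mol), dtype=np.float32) if keep_all \
        else None
    chunk = max(256, int(12e6 // max(n_mol, 1)))
    for s0 in range(0, n_coarse, chunk):
        ln = min(chunk, n_coarse - s0)
        steps = rng.standard_normal((3, n_mol, ln), dtype=np.float32)
        steps *= sig[None, :, None]
        np.cumsum(steps, axis=2, out=steps)
        steps += pos[:, :, None]
        for ax in range(3):
            np.mod(steps[ax], box[ax], out=steps[ax])
        pos = np.ascontiguousarray(steps[:, :, -1])
        r2 = (steps[0] - half[0]) ** 2
        r2 += (steps[1] - half[1]) ** 2
        r2 *= inv_w2
        zz = (steps[2] - half[2]) ** 2
        zz *= inv_z2
        r2 += zz
        r2 *= np.float32(-1.0)
        w = np.exp(r2, out=r2)                  # (n_mol, ln)
        s_g[s0:s0 + ln] = w[:n_g].sum(axis=0)
        s_r[s0:s0 + ln] = w[n_g:n_g + n_r].sum(axis=0)
        w_gr[s0:s0 + ln] = w[n_g + n_r:].T
        if keep_all:
            w_all[s0:s0 + ln] = w.T
    return s_g, s_r, w_gr, w_all


def simulate_binned_traces(cfg: SimulationConfig,
                           seed: Optional[int] = None) -> IntensityTraces:
    """Fast path: Poisson counts per bin drawn directly from the model rates.

    Positions (and detection weights) advance every
    ``dt * diffusion_stride``; binding and triplet states are exact
    continuous-time telegraph paths read out per bin.  Statistically
    equivalent to binning the photon path at the same resolution, at a
    fraction of the cost.
    """
    seed = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(int(seed))
    s_diff, s_kin, s_emit = ss.spawn(3)
    rng_diff = np.random.Generator(np.random.SFC64(s_diff))
    rng_kin = np.random.default_rng(s_kin)
    rng_emit = np.random.default_rng(s_emit)
    n_bins = int(round(cfg.duration / (cfg.dt * 1e-6)))
    stride = int(cfg.diffusion_stride)
    n_coarse = -(-n_bins // stride)
    n_g = cfg.n_molecules(cfg.conc_G)
    n_r = cfg.n_molecules(cfg.conc_R)
    n_gr = cfg.n_molecules(cfg.conc_GR)
    dt_ms = cfg.dt * 1e-3
    k1 = cfg.k_on * cfg.ligand_conc
    k2 = cfg.k_off
    triplet = cfg.triplet_frac > 0
    if triplet:
        if cfg.dt > cfg.triplet_tau / 2.0:
            raise ValueError(
                "resolving triplet blinking requires dt <= triplet_tau/2")
        if (n_g + n_r + n_gr) * n_bins > 5e8:
            raise ValueError(
                "triplet path is per-molecule; problem too large — reduce "
                "duration, concentrations or the box")

    s_g, s_r, w_gr, w_all = _coarse_weights(cfg, rng_diff, n_coarse,
                                            n_g, n_r, n_gr,
                                            keep_all=triplet)
    idx = np.arange(n_bins) // stride      # bin -> coarse step

    tt_ms = cfg.triplet_tau * 1e-3
    k_dark = cfg.triplet_frac / tt_ms
    k_bright = (1.0 - cfg.triplet_frac) / tt_ms

    def dark_path():
        return _telegraph_bins(rng_kin, n_bins, dt_ms, k_dark, k_bright,
                               cfg.triplet_frac)

    if not triplet:
        w_gg = np.repeat(s_g, stride)[:n_bins]
        w_rr = np.repeat(s_r, stride)[:n_bins]
    else:
        w_gg = np.zeros(n_bins)
        for i in range(n_g):
            w_gg += w_all[:, i][idx] * ~dark_path()
        w_rr = np.zeros(n_bins)
        for i in range(n_r):
            w_rr += w_all[:, n_g + i][idx] * ~dark_path()

    w_don = np.zeros(n_bins)    # GR weight into the donor channel
    w_fret = np.zeros(n_bins)   # GR weight into the FRET acceptor channel
    w_dir = np.zeros(n_bins)    # GR weight under direct red excitation
    if n_gr and not triplet:
        wmat = np.repeat(w_gr, stride, axis=0)[:n_bins]     # (n_bins, n_gr)
        emat = np.empty_like(wmat)
        for i in range(n_gr):
            bound = _telegraph_bins(rng_kin, n_bins, dt_ms, k1, k2,
                                    cfg.bound_occupancy)
            emat[:, i] = np.where(bound, np.float32(cfg.E1),
                                  np.float32(cfg.E2))
        w_dir = wmat.sum(axis=1, dtype=np.float64)
        w_fret = (wmat * emat).sum(axis=1, dtype=np.float64)
        w_don = w_dir - w_fret
    elif n_gr:
        for i in range(n_gr):
            wi = w_gr[:, i][idx].astype(np.float64)
            bound = _telegraph_bins(rng_kin, n_bins, dt_ms, k1, k2,
                                    cfg.bound_occupancy)
            e = np.where(bound, cfg.E1, cfg.E2)
            d_ok = ~dark_path()
            a_ok = ~dark_path()
            # acceptor dark: no transfer, donor keeps its full yield
            w_don += wi * np.where(d_ok & a_ok, 1.0 - e, d_ok * 1.0)
            w_fret += wi * e * (d_ok & a_ok)
            w_dir += wi * a_ok

    b_g = cfg.brightness_G * dt_ms
    b_r = cfg.brightness_R * dt_ms
    r_dd = b_g * (w_gg + w_don)
    r_da = b_g * w_fret
    r_aa = b_r * (w_rr + w_dir)
    if cfg.direct_excitation > 0:
        r_da = r_da + cfg.direct_excitation * b_g * (w_rr + w_dir)
    if cfg.crosstalk > 0:
        r_da = r_da + cfg.crosstalk * r_dd
        r_dd = r_dd * (1.0 - cfg.crosstalk)
    r_dd += cfg.background_G * dt_ms
    r_da += 0.5 * cfg.background_R * dt_ms
    r_aa += 0.5 * cfg.background_R * dt_ms

    out_dd = rng_emit.poisson(r_dd)
    out_da = rng_emit.poisson(r_da)
    out_aa = rng_emit.poisson(r_aa)
    out_ad = np.zeros(n_bins, dtype=np.int64)
    return IntensityTraces(
        bin_width=cfg.dt,
        DexDem=out_dd, DexAem=out_da, AexAem=out_aa, AexDem=out_ad,
        duration=n_bins * cfg.dt * 1e-6,
        metadata={"config_digest": cfg.digest(), "seed": int(seed),
                  "config": cfg.to_dict()})
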