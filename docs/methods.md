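# Methods

`zmwfccs` analyzes reversible binding of a red-labelled peptide to a
green-labelled nucleic acid by dual-color pulsed-interleaved-excitation
fluorescence cross-correlation spectroscopy (PIE-FCCS) combined with
FRET, in an attoliter observation volume of the kind produced by a
zero-mode waveguide (ZMW) nanoaperture.  This note records the model,
the estimator design, the synthetic-data generator, the numerical
choices, and the limits of what the package's tests demonstrate.

## Physical model

Three fluorescent species diffuse through the observation volume: the
free ligand (green label only, concentration C_G), the free peptide
(red label only, C_R) and the complex (both labels, C_GR).  Binding is
a two-state Markov process: with the ligand in large excess over the
peptide it is pseudo-first-order, with association rate k1 = k_on·[L]
and dissociation rate k2 = k_off (both ms⁻¹; k_on in µM⁻¹ ms⁻¹).  The
stationary bound fraction and the relaxation time of the fluctuations
are

    b   = k1 / (k1 + k2) = [L] / ([L] + K),      K = k_off / k_on
    τ_S = 1 / (k1 + k2)

so a measured (b, τ_S) pair at known [L] determines both rate
constants:

    K = [L] (1 − b)/b,    k_on = 1/(τ_S ([L] + K)),    k_off = K·k_on.

The complex transfers donor excitation to the acceptor with efficiency
E1; the unbound state retains a small residual efficiency E2 ≈ 0.02
(background and weak transfer persist even without contact, so E2 is
not exactly zero).  Switching between E1 and E2 modulates the donor and
FRET-sensitized acceptor intensities in antiphase.

The detection profile is modelled as a 3D Gaussian with lateral 1/e²
radius w and axial elongation κ, giving the effective volume
V_eff = π^{3/2} w² (κw) and the diffusion part of every correlation

    G_diff(τ) = (1 + τ/τ_D)^{-1} (1 + τ/(κ²τ_D))^{-1/2},  τ_D = w²/4D.

The Gaussian is a stand-in for the true ZMW near-field; the model
functions assume exactly this form, so simulation and analysis are
consistent by construction (see Limitations).  The default geometry
(w = 47.6 nm, κ = 2) reproduces the measured nanoaperture volume
V_eff = 1.2 × 10⁻¹⁸ l.

Fitted model functions (times internally in seconds):

* cross-correlation:  G_x(τ) = G_x(0) [1 − S e^{−τ/τ_S}] G_diff(τ)
* autocorrelation:    G_a(τ) = G_a(0) [1 + A_T e^{−τ/τ_T}]
                               [1 + S e^{−τ/τ_S}] G_diff(τ)

with triplet amplitude A_T and lifetime τ_T (autocorrelations only —
donor and acceptor triplet dynamics are uncorrelated, so the
cross-correlation carries no triplet factor).

For the telegraph FRET switch the cross-correlation (donor ×
FRET-acceptor) kinetic amplitude is exactly

    S = k1 k2 (E1−E2)² / { [k1(1−E1) + k2(1−E2)] (k1 E1 + k2 E2) }
      = Var(E) / [(1−⟨E⟩)⟨E⟩],

which the package inverts for E1 by bracketed root finding on (E2, 1),
recomputing S from the root as a consistency check.  Association
thermodynamics follow from K_on,eq = k_on/k_off (converted to M⁻¹) and
ΔG°_on = −RT ln K_on,eq at the 1 M standard state, T = 293.15 K
(measurements at 20 °C), R = 8.314 J mol⁻¹ K⁻¹.

## Channel scheme and estimators

PIE tags every photon with the exciting laser (40 MHz sync, 12.5 ns
green/red delay): micro-times in the first half-period are
donor-excited, in the second half directly red-excited.  Four logical
channels result: DexDem (donor-excited donor), DexAem (donor-excited,
FRET-sensitized acceptor), AexAem (red-excited acceptor), AexDem
(empty; diagnostic).

A point that shapes the whole analysis: in which channel pair each
observable lives.

* **Amplitudes / bound fraction.**  The donor-excited *total* (DexDem +
  DexAem) has brightness independent of the FRET state — transfer only
  moves photons between the two donor-excited channels.  Using it as
  the green channel makes the amplitude ratio exact:
  G_x(0)/G_g(0) = C_GR/C_R,tot with no FRET-brightness bias,
  where G_g is the total-donor-excited autocorrelation and G_x its
  cross-correlation with AexAem.  (With DexDem alone, the complex is
  (1−⟨E⟩) dimmer than free ligand and the ratio would be biased low by
  ~⟨E⟩.)  Bound fractions above 1, possible with noisy amplitudes, are
  reported with a warning and never clamped, keeping the binding fit
  unbiased.
* **Kinetics.**  The anticorrelated rise term exists only where the
  FRET switch modulates a channel: DexDem × DexAem.  At the study
  concentrations (1 µM peptide ≈ 0.3 complexes in V_eff) its absolute
  amplitude G_x(0)·S ≈ 0.007 is far below desk-scale noise.  The
  FRET-acceptor *autocorrelation* carries the same relaxation time with
  amplitude (1/N_GR)·Var(E)/⟨E⟩² — several hundred times larger —
  because only complexes emit in that channel and their switching
  modulates it deeply.  The relaxation time is extracted from the
  *kinetic contrast function*: the per-lag ratio of the FRET-acceptor
  ACF to the green species ACF.  When every species shares one
  diffusion coefficient (as in the kinetic configurations) the two
  curves have the identical diffusion shape — including any
  discretization or finite-box distortion — so the ratio is an exact
  pure exponential A(1 + S_a e^{−τ/τ_S}).  The cross-correlation rise
  term is then fitted for its amplitude S with τ_S held (also via the
  FRET/GG contrast).  Both observables measure the identical telegraph
  process, λ = k1 + k2.  Model-based fits of the same channels are
  written alongside for inspection.

The correlator is a multi-tau estimator: m = 16 lags per octave,
pairwise rebinning between octaves, symmetric normalization (means
recomputed over the overlapping segments at every lag, suppressing
drift bias).  Zero lag is excluded — "G(0)" always means a fitted
amplitude.  Curve values come from the full trace; per-lag standard
errors from the scatter of 8 contiguous chunks (the mean-normalization
bias of the estimator scales as 1/T, so the full trace gives the least
biased amplitudes while chunks calibrate the noise).  A brute-force
direct estimator of the same definition is kept as an independent
reference and the two must agree to 10⁻¹⁰.

Fitting is weighted least squares (lmfit, Levenberg–Marquardt) with the
split-based errors when available.  Bounds disambiguate the three
exponential-like terms: τ_T ∈ [0.5, 20] µs, τ_S ∈ [20 µs, 10 ms],
τ_D ∈ [50 µs, 100 ms]; the anticorrelation amplitude S < 1 in the
cross-correlation (positivity) but may exceed 1 as an ACF bunching
amplitude.  A deterministic multi-start over (τ_S, τ_D) guards against
the kinetics/diffusion swap; κ is held fixed at the calibration value
(floating it is degenerate with τ_D).  Initialization is deterministic:
plateau beyond 50 µs for G0, half-decay lag for τ_D.  Parameters pinned
at a bound flag the fit as unclean; degenerate inputs (zero-mean
traces, saturated bound fractions, unachievable S) raise explicit
errors rather than returning numbers.

## Synthetic data generator

Molecules perform Brownian motion in a periodic box holding at least 50
effective volumes (boundary effects negligible); positions are uniform
at stationarity, which makes all zero-lag amplitudes exact regardless
of time discretization.  Binding/FRET states of the dual-labelled
species follow exact exponentially distributed dwell times read out per
emission bin (the fine-grained trajectory API uses fixed-step updates
with flip probability 1 − e^{−k·dt} instead, with the precondition
dt·(k1+k2) < 0.1).  Expected counts per bin are brightness × Gaussian
detection weight, partitioned donor/acceptor by the current FRET
efficiency; direct red excitation drives AexAem; backgrounds are
homogeneous Poisson (donor background in the green gate, acceptor
background split between the two acceptor gates).  Optional triplet
blinking is an independent dark/bright telegraph per dye with occupancy
`triplet_frac` and correlation time `triplet_tau`; a dark acceptor
suppresses transfer (donor keeps its full yield), a dark donor silences
both donor-excited channels.  Spectral crosstalk and direct acceptor
excitation by the green laser default to zero (PIE exists to remove
them) but are exposed as config parameters.

Positions advance every `dt × diffusion_stride`; the rms step per
update must stay below w/2 (and below w/5 per elementary dt).  Between
updates the detection weight is constant, so the measured diffusion
correlation is the piecewise-linear interpolation of G_diff between
multiples of the update interval; fits of synthetic data use the
matching discrete diffusion factor (`diffusion_factor_discrete`, the
analogue of a hardware correlator's bin-time correction), and
amplitudes are exact for any step size because the stationary position
distribution is uniform.  A second, subtler distortion comes from the
canonical box itself: with a *fixed* number of molecules the
correlations are depressed by O(V_eff/V_box) spread over the box-mixing
time (~L²/4π²D), which steepens apparent decays by several per cent of
τ_D.  Ratio observables — the amplitude ratio and the kinetic contrast
— cancel both distortions exactly when species share a diffusion
coefficient, which is why the analysis is built on them.  Integer molecule counts
would distort small population fractions (e.g. 0.02 µM of complex
rounds to 1 molecule in the default box), so titration configs enlarge
the box until the dual-labelled species has at least 6–10 molecules,
and the mixture experiments scan box scales on [1, 2.5]× to realize a
requested fraction exactly with rounded counts.

Defaults and why:

| parameter | default | rationale |
|---|---|---|
| w, κ | 47.6 nm, 2.0 | V_eff = 1.2 × 10⁻¹⁸ l, the measured nanoaperture volume |
| box | (392 nm)³ | exactly 50 V_eff (smallest box with negligible boundary effects) |
| k_on, k_off | 0.07 µM⁻¹ms⁻¹, 3.61 ms⁻¹ | the reported quadruplex–peptide rate constants |
| [L], C_R,tot | 40 µM, 1 µM | the reference titration condition |
| E1, E2 | 0.40, 0.02 | E2 is the stated residual-transfer assumption; E1 a representative bound-state value |
| D (kinetic runs) | 0.55–0.65 µm²/s | τ_D ≈ 1 ms ≫ τ_S ≈ 150–200 µs so rise and decay separate |
| D (amplitude runs) | 2.5 µm²/s, all species | equal D makes the amplitude ratio exact at every lag; faster transits maximize amplitude precision per second of trace (σ ∝ √(τ_D/T)); D is not reported experimentally and the two regimes bracket plausible values |
| brightness | 100 counts/ms per molecule | bright-dye, enhanced-emission regime; sets shot noise well below particle noise |
| background | 0.2 counts/ms per detector | weak dark-count floor |
| sync, delay | 25 ns, 12.5 ns | 40 MHz interleaved excitation |
| dt | 4–8 µs | resolves τ_S by >20×; satisfies the kinetic and spatial step preconditions |
| duration | 8 s (config default) | desk-scale trace; recovery experiments choose 8–24 s per condition (below) |

Seeds are mandatory; every experiment splits one master seed into
independent sub-streams (diffusion, kinetics, emission, per-condition,
per-repeat) via `numpy.random.SeedSequence`, so identical (config,
seed) runs are byte-identical and different seeds are independent.

## Recovery experiments and statistical precision

The amplitude of a cross-correlation between a bright many-molecule
channel and a sparse channel is intrinsically noisy: the per-seed
relative error is roughly √(n_G n_R)/n_GR · √(τ_D/T) with n the mean
molecule numbers in V_eff.  At 40 µM ligand / 1 µM peptide this is
~√(29·0.7)/0.3 ≈ 15 per √(independent transit), i.e. tens of per cent
for second-scale traces — the reason the underlying experiments
integrate for minutes.  The desk-scale experiments in
`zmwfccs.experiments` use 5–6 independent seeds with durations of
10 s (titration points), 8 s (kinetic conditions) and 10–20 s (mixture
fractions).  The titration reports the median K_D over per-seed Hill
fits; the kinetic and mixture experiments analyze the seeds' traces
*concatenated* into one long record — the statistical equivalent of a
single several-times-longer measurement, which is how the underlying
experiments integrate down FCCS noise, and, for the rates, the only
aggregation that keeps (K, k_on, k_off) algebraically consistent with
the measured (b, τ_S) pair (medians of separately inverted rates do
not satisfy K = k_off/k_on).  This puts the reported values'
statistical errors at roughly 4–10% for most quantities — comparable
to the stated recovery tolerances, so occasional excursions near a
tolerance edge are expected behaviour, not defects.  Two quantities
remain noise-limited at desk scale: the smallest mixture fraction
(0.16 against a 40 µM green background has σ ≈ 15% even on the
concatenated record; its ±10% check is a coin flip and honestly so),
and the CCF kinetic amplitude S (uncertainty of order tens of per
cent, biased high by the positivity bound; it feeds only the
bound-state FRET efficiency E1).  A 30-seed calibration study
during development confirmed the amplitude-ratio estimator is unbiased
(mean within one standard error of truth); a small residual bias of
order −3% remains at the coarsest position-update stride from the
staircase shape approximation.

## Limitations

* The detection profile is a 3D Gaussian, not the true ZMW near-field;
  real nanoaperture data have non-Gaussian shoulders that bias τ_D and
  would require a calibrated profile.
* No photobleaching, detector dead time, afterpulsing, or saturation;
  the binned path cannot reproduce sub-µs detector artefacts at all.
* Spectral crosstalk and direct acceptor excitation default to zero;
  real dye pairs need the nonzero-crosstalk configuration and, for
  severe cases, corrections the package does not implement (FLCS-style
  filtering is out of scope).
* The ligand bath is un-depleted (pseudo-first-order) — valid only
  while [L] ≫ C_R,tot, as in all configurations here.
* The complex is modelled as a persistent dual-labelled entity whose
  FRET efficiency switches; physical unbinding that separates the pair
  on the measurement time scale is represented only through the static
  population split between red-only and dual-labelled species.
* Passing recovery tests demonstrates internal consistency of
  simulator, correlator, models and inversion under the model's own
  assumptions — not that the analysis is unbiased on real nanoaperture
  data with non-Gaussian optics, photophysics and drift.
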