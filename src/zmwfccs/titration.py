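"""From fitted correlation amplitudes to binding constants and kinetics.

Observables per titration condition:

* bound fraction  b = G_x(0) / G_g(0) = C_GR / C_R,tot — the fraction of
  red-labelled molecules in complex, from the ratio of the
  cross-correlation and green autocorrelation zero-lag amplitudes;
* relaxation time tau_S and amplitude S of the anticorrelated kinetic
  term of the cross-correlation.

For a two-state binding equilibrium with pseudo-first-order association
rate ``k_on [L]`` and dissociation rate ``k_off``:

    b      = [L] / ([L] + K),        K = k_off / k_on
    tau_S  = 1 / (k_on [L] + k_off)

so one (b, tau_S) pair at known ligand concentration determines both
rate constants.  The kinetic amplitude of the donor-acceptor
cross-correlation for a telegraph FRET switch between efficiencies E1
(bound) and E2 (unbound) is

    S = k1 k2 (E1 - E2)^2 /
        { [k1 (1-E1) + k2 (1-E2)] (k1 E1 + k2 E2) }

with k1 = k_on [L] and k2 = k_off, which is inverted for E1 given the
measured S and the rates (E2 fixed at a small residual, 0.02 by
default).  The association equilibrium constant and standard free
energy follow as K_on,eq = k_on/k_off (in M^-1) and
dG0_on = -RT ln K_on,eq at the 1 M standard state.
"""

from __future__ import annotations

import warnings as _warnings
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import lmfit
from scipy.optimize import brentq

from .fcs_models import FcsFit

R_GAS = 8.314           # J mol^-1 K^-1
T_DEFAULT = 293.15      # K, measurements at 20 C
E2_DEFAULT = 0.02       # residual unbound FRET efficiency


class UnidentifiableError(ValueError):
    """Raised when the requested quantity is not determined by the data."""


# ---------------------------------------------------------------------------
# result containers


@dataclass
class TitrationPoint:
    """Per-condition observables feeding the binding and kinetic analysis."""

    ligand_conc: float              # uM
    bound_fraction: float
    S: float = float("nan")
    tau_S_ms: float = float("nan")
    salt_mM: float = 100.0
    label: str = ""
    gg_fit: Optional[FcsFit] = None
    gr_fit: Optional[FcsFit] = None
    warnings: tuple = ()

    def __post_init__(self):
        if self.ligand_conc < 0:
            raise ValueError("ligand_conc must be >= 0")


class KineticRates(NamedTuple):
    K: float        # uM
    k_on: float     # uM^-1 ms^-1
    k_off: float    # ms^-1


class AmplitudeInversion(NamedTuple):
    E1: float
    S_residual: float   # |S recomputed from the root - S measured|


class Thermodynamics(NamedTuple):
    K_on_eq: float      # M^-1
    dG_on: float        # kJ/mol


@dataclass
class BindingCurveFit:
    """Hill-model fit (coefficient fixed at 1) of bound fraction vs ligand."""

    K_D: float                  # uM
    K_D_stderr: float           # uM
    residuals: np.ndarray
    n_points: int
    hill_coefficient: float = 1.0

    def __post_init__(self):
        if self.K_D <= 0:
            raise ValueError("K_D must be > 0")


@dataclass
class KineticResult:
    """Kinetics, bound-state FRET efficiency and association thermodynamics."""

    ligand_conc: float          # uM
    K: float                    # uM
    k_on: float                 # uM^-1 ms^-1
    k_off: float                # ms^-1
    E1: float = float("nan")
    E2: float = E2_DEFAULT
    S_residual: float = float("nan")
    K_on_eq: float = float("nan")   # M^-1
    dG_on: float = float("nan")     # kJ/mol
    T: float = T_DEFAULT
    tau_S_ms: float = float("nan")          # measured
    tau_S_implied_ms: float = float("nan")  # 1/(k_on*[L]+k_off) re-derived
    label: str = ""

    def __post_init__(self):
        if self.k_on < 0 or self.k_off < 0:
            raise ValueError("rates must be >= 0")


@dataclass
class TitrationResult:
    points: list
    hill: Optional[BindingCurveFit]
    kinetics: list
    mean_k_on: float = float("nan")
    mean_k_off: float = float("nan")
    warnings: tuple = ()


# ---------------------------------------------------------------------------
# operations


def bound_fraction(ccf_fit: FcsFit, acf_fit: FcsFit,
                   strict: bool = True) -> float:
    """Amplitude ratio G_x(0)/G_g(0) = C_GR/C_R,tot.

    Values above 1 (possible with noisy amplitudes) are *reported* with
    a warning, not clamped, so downstream binding fits stay unbiased.
    """
    if strict and not (ccf_fit.success and acf_fit.success):
        raise ValueError("bound fraction requires converged fits")
    if acf_fit.G0 <= 0 or ccf_fit.G0 < 0:
        raise ValueError("amplitudes must be positive")
    b = ccf_fit.G0 / acf_fit.G0
    if b > 1.0:
        _warnings.warn(f"bound fraction {b:.3f} exceeds 1; reported "
                       f"unclamped", stacklevel=2)
    return b


def hill_curve(ligand_conc, K_D):
    """Bound fraction 1/(1 + K_D/[L]) with Hill coefficient 1."""
    c = np.asarray(ligand_conc, dtype=float)
    return 1.0 / (1.0 + K_D / c)


def fit_hill(points: Sequence) -> BindingCurveFit:
    """Least-squares dissociation constant from (ligand_conc, bound_fraction).

    The Hill coefficient is fixed at 1 (1:1 stoichiometry).  Raises
    :class:`UnidentifiableError` when every fraction sits at 0 or 1.
    """
    pts = [(float(c), float(b)) for c, b in points]
    if not pts:
        raise ValueError("no titration points")
    if len(pts) < 3:
        _warnings.warn("fewer than 3 titration points; K_D poorly "
                       "constrained", stacklevel=2)
    c = np.array([p[0] for p in pts])
    b = np.array([p[1] for p in pts])
    if np.any(c <= 0):
        raise ValueError("ligand concentrations must be > 0")
    if np.all(b <= 0.02) or np.all(b >= 0.98):
        raise UnidentifiableError(
            "all bound fractions saturate at 0 or 1; K_D unidentifiable")
    informative = (b > 0.0) & (b < 1.0)
    kd0 = float(np.median(c[informative] * (1.0 / b[informative] - 1.0)))
    kd0 = min(max(kd0, 1e-6), 1e6)
    pars = lmfit.Parameters()
    pars.add("K_D", value=kd0, min=1e-9, max=1e9)
    res = lmfit.minimize(lambda p: hill_curve(c, p["K_D"].value) - b, pars,
                         method="leastsq")
    kd = float(res.params["K_D"].value)
    se = res.params["K_D"].stderr
    return BindingCurveFit(
        K_D=kd,
        K_D_stderr=float(se) if se is not None else float("nan"),
        residuals=np.asarray(res.residual),
        n_points=len(pts))


def kinetic_rates(bound_frac: float, tau_S_ms: float,
                  ligand_conc: float) -> KineticRates:
    """Invert b = [L]/([L]+K) and tau_S = 1/(k_on([L]+K)) for the rates.

    The returned triple satisfies both relations exactly on
    re-substitution; K = k_off/k_on by construction.
    """
    if not 0.0 < bound_frac < 1.0:
        raise UnidentifiableError(
            f"bound fraction must lie strictly between 0 and 1, got "
            f"{bound_frac}")
    if tau_S_ms <= 0:
        raise ValueError("tau_S must be > 0")
    if ligand_conc <= 0:
        raise ValueError("ligand_conc must be > 0")
    K = ligand_conc * (1.0 - bound_frac) / bound_frac
    k_on = 1.0 / (tau_S_ms * (ligand_conc + K))
    k_off = K * k_on
    return KineticRates(K=K, k_on=k_on, k_off=k_off)


def fret_amplitude(k1: float, k2: float, E1: float, E2: float) -> float:
    """Kinetic amplitude of the donor-acceptor cross-correlation.

    ``k1`` is the pseudo-first-order association rate (k_on [L]) and
    ``k2`` the dissociation rate, both ms^-1.  Equals
    Var(E)/((1-<E>)<E>) for the telegraph FRET switch; zero iff E1 = E2;
    invariant under common rescaling of the rates.
    """
    if k1 <= 0 or k2 <= 0:
        raise ValueError("rates must be > 0")
    if not (0.0 <= E2 <= E1 < 1.0):
        raise ValueError("need 0 <= E2 <= E1 < 1")
    num = k1 * k2 * (E1 - E2) ** 2
    den = (k1 * (1.0 - E1) + k2 * (1.0 - E2)) * (k1 * E1 + k2 * E2)
    if den == 0.0:
        raise ValueError("degenerate FRET amplitude (zero denominator)")
    return num / den


def invert_amplitude(S: float, k1: float, k2: float,
                     E2: float = E2_DEFAULT) -> AmplitudeInversion:
    """Bound-state FRET efficiency E1 from the measured kinetic amplitude.

    Finds the root of the amplitude relation in ``(E2, 1)`` by bracketed
    bisection and validates it by recomputing S from the root (the
    residual is reported alongside).  Raises when no root exists, i.e.
    the measured S exceeds what any E1 < 1 can produce for these rates.
    """
    if S < 0:
        raise ValueError("S must be >= 0")
    if S == 0.0:
        return AmplitudeInversion(E1=E2, S_residual=0.0)

    def f(e1):
        return fret_amplitude(k1, k2, e1, E2) - S

    lo, hi = E2 + 1e-12, 1.0 - 1e-9
    f_lo, f_hi = f(lo), f(hi)
    if f_lo > 0:
        raise UnidentifiableError("S inconsistent with E1 > E2")
    if f_hi < 0:
        # S monotone increasing in E1 on (E2, 1); no achievable root
        raise UnidentifiableError(
            f"S = {S:.4g} not achievable for k1 = {k1:.4g}, k2 = {k2:.4g}, "
            f"E2 = {E2:.3g} with any E1 < 1")
    e1 = brentq(f, lo, hi, xtol=1e-14, rtol=1e-14)
    return AmplitudeInversion(E1=float(e1),
                              S_residual=abs(fret_amplitude(k1, k2, e1, E2)
                                             - S))


def thermodynamics(k_on: float, k_off: float,
                   T: float = T_DEFAULT) -> Thermodynamics:
    """Association equilibrium constant (M^-1) and standard free energy.

    k_on in uM^-1 ms^-1 and k_off in ms^-1 give K_on,eq = k_on/k_off in
    uM^-1, converted to M^-1; dG0 = -RT ln(K_on,eq * 1 M), kJ/mol.
    """
    if k_on <= 0 or k_off <= 0:
        raise ValueError("rates must be > 0")
    k_on_eq = k_on / k_off * 1e6    # M^-1
    dg = -R_GAS * T * np.log(k_on_eq) / 1e3
    return Thermodynamics(K_on_eq=float(k_on_eq), dG_on=float(dg))


def analyze_point(point: TitrationPoint, E2: float = E2_DEFAULT,
                  T: float = T_DEFAULT) -> KineticResult:
    """Rates, E1 and thermodynamics for one titration condition."""
    rates = kinetic_rates(point.bound_fraction, point.tau_S_ms,
                          point.ligand_conc)
    k1 = rates.k_on * point.ligand_conc
    e1, resid = float("nan"), float("nan")
    if np.isfinite(point.S) and point.S > 0:
        try:
            inv = invert_amplitude(point.S, k1, rates.k_off, E2=E2)
            e1, resid = inv.E1, inv.S_residual
        except UnidentifiableError:
            pass
    thermo = thermodynamics(rates.k_on, rates.k_off, T=T)
    return KineticResult(
        ligand_conc=point.ligand_conc, K=rates.K, k_on=rates.k_on,
        k_off=rates.k_off, E1=e1, E2=E2, S_residual=resid,
        K_on_eq=thermo.K_on_eq, dG_on=thermo.dG_on, T=T,
        tau_S_ms=point.tau_S_ms,
        tau_S_implied_ms=1.0 / (k1 + rates.k_off),
        label=point.label)


def analyze_titration(points: Sequence[TitrationPoint],
                      E2: float = E2_DEFAULT,
                      T: float = T_DEFAULT) -> TitrationResult:
    """Binding curve plus per-condition kinetics for a titration series.

    The Hill fit uses every point; kinetics are computed per point where
    (b, tau_S) are informative, with the across-condition means attached.
    """
    notes = []
    hill = None
    try:
        hill = fit_hill([(p.ligand_conc, p.bound_fraction) for p in points])
    except (UnidentifiableError, ValueError) as exc:
        notes.append(f"Hill fit failed: {exc}")
    kinetics = []
    for p in points:
        if not np.isfinite(p.tau_S_ms) or not (0.0 < p.bound_fraction < 1.0):
            continue
        try:
            kinetics.append(analyze_point(p, E2=E2, T=T))
        except (UnidentifiableError, ValueError) as exc:
            notes.append(f"kinetics at {p.ligand_conc} uM failed: {exc}")
    k_on = np.array([k.k_on for k in kinetics])
    k_off = np.array([k.k_off for k in kinetics])
    return TitrationResult(
        points=list(points), hill=hill, kinetics=kinetics,
        mean_k_on=float(k_on.mean()) if k_on.size else float("nan"),
        mean_k_off=float(k_off.mean()) if k_off.size else float("nan"),
        warnings=tuple(notes))
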