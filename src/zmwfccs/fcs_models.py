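"""FCS/FCCS model functions and weighted least-squares curve fitting.

The correlation of a freely diffusing species through a 3D-Gaussian
observation volume decays as

    G_diff(tau) = (1 + tau/tau_D)^-1 (1 + tau/(kappa^2 tau_D))^-1/2

with diffusion time ``tau_D`` and axial/lateral aspect ratio ``kappa``.
The cross-correlation of a dual-labelled species undergoing two-state
FRET switching carries an *anticorrelated* kinetic factor,

    G_x(tau) = G0 [1 - S exp(-tau/tau_S)] G_diff(tau),

whose amplitude ``S`` and relaxation time ``tau_S`` encode the binding
kinetics, while the autocorrelation carries *bunching* factors for the
triplet state and the same kinetics,

    G_a(tau) = G0 [1 + A_T exp(-tau/tau_T)] [1 + S exp(-tau/tau_S)]
               G_diff(tau).

Amplitudes extrapolated to zero lag measure concentrations through the
effective volume: G(0) = 1 / (V_eff C N_A).

All model times are seconds internally; :class:`FcsFit` exposes the
conventional units (tau_T in us, tau_S and tau_D in ms).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import lmfit

from .correlator import CorrelationCurve
from .simkit import AVOGADRO

# fitting bounds chosen to disambiguate the three bunching/antibunching
# terms; they bracket the reported time scales by a wide margin
DEFAULT_BOUNDS = {
    "tau_T": (0.5e-6, 20e-6),       # s
    "tau_S": (20e-6, 10e-3),        # s
    "tau_D": (50e-6, 100e-3),       # s
    "S": (0.0, 0.95),               # ccf: anticorrelation amplitude < 1
    "S_acf": (0.0, 10.0),           # acf: bunching amplitude may exceed 1
    "A_T": (0.0, 10.0),
}

ACF_PARAMS = ("G0", "A_T", "tau_T", "S", "tau_S", "tau_D", "kappa")
CCF_PARAMS = ("G0", "S", "tau_S", "tau_D", "kappa")


def diffusion_factor(tau, tau_D, kappa):
    """Normalized 3D diffusion decay; 1 at tau = 0, monotone decreasing."""
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise ValueError("tau must be >= 0")
    if tau_D <= 0 or kappa <= 0:
        raise ValueError("tau_D and kappa must be > 0")
    x = tau / tau_D
    return 1.0 / (1.0 + x) / np.sqrt(1.0 + x / kappa ** 2)


def diffusion_factor_discrete(tau, tau_D, kappa, interval):
    """Diffusion factor of a process whose positions advance every
    ``interval`` seconds (piecewise-constant detection weight).

    Between updates the weight is frozen, so the exact correlation is
    the linear interpolation of the continuous factor between integer
    multiples of the update interval; it converges to
    :func:`diffusion_factor` as ``interval`` goes to zero.  Used to fit
    synthetic data generated on a coarse position grid without shape
    bias (the analogue of a hardware correlator's bin-time correction).
    """
    tau = np.asarray(tau, dtype=float)
    if interval <= 0:
        return diffusion_factor(tau, tau_D, kappa)
    m = np.floor(tau / interval)
    frac = tau / interval - m
    lo = diffusion_factor(m * interval, tau_D, kappa)
    hi = diffusion_factor((m + 1) * interval, tau_D, kappa)
    return (1.0 - frac) * lo + frac * hi


def kinetic_factor(tau, S, tau_S, sign=-1.0):
    """FRET-switching factor: 1 + sign*S*exp(-tau/tau_S).

    ``sign=-1`` gives the cross-correlation rise term (S < 1 so the
    correlation stays positive); ``sign=+1`` the autocorrelation
    bunching term, whose amplitude may exceed 1.
    """
    tau = np.asarray(tau, dtype=float)
    if tau_S <= 0:
        raise ValueError("tau_S must be > 0")
    if S < 0:
        raise ValueError("S must be >= 0")
    if sign < 0 and S >= 1.0:
        raise ValueError("anticorrelation amplitude S must be < 1")
    return 1.0 + sign * S * np.exp(-tau / tau_S)


def triplet_factor(tau, A_T, tau_T):
    tau = np.asarray(tau, dtype=float)
    if tau_T <= 0:
        raise ValueError("tau_T must be > 0")
    if A_T < 0:
        raise ValueError("A_T must be >= 0")
    return 1.0 + A_T * np.exp(-tau / tau_T)


def ccf_model(tau, G0, S, tau_S, tau_D, kappa, position_interval=0.0):
    """Cross-correlation model: anticorrelated kinetics times diffusion."""
    if G0 <= 0:
        raise ValueError("G0 must be > 0")
    return (G0 * kinetic_factor(tau, S, tau_S, sign=-1.0)
            * diffusion_factor_discrete(tau, tau_D, kappa,
                                        position_interval))


def acf_model(tau, G0, A_T, tau_T, S, tau_S, tau_D, kappa,
              position_interval=0.0):
    """Autocorrelation model: triplet x kinetics x diffusion."""
    if G0 <= 0:
        raise ValueError("G0 must be > 0")
    return (G0 * triplet_factor(tau, A_T, tau_T)
            * kinetic_factor(tau, S, tau_S, sign=+1.0)
            * diffusion_factor_discrete(tau, tau_D, kappa,
                                        position_interval))


@dataclass
class ObservationVolume:
    """Effective detection volume and aspect ratio of the Gaussian profile."""

    v_eff_liters: float
    kappa: float = 2.0

    def __post_init__(self):
        if self.v_eff_liters <= 0:
            raise ValueError("V_eff must be > 0")

    @classmethod
    def from_waist(cls, waist_nm: float, kappa: float) -> "ObservationVolume":
        v_nm3 = np.pi ** 1.5 * waist_nm ** 2 * (kappa * waist_nm)
        return cls(v_eff_liters=v_nm3 * 1e-24, kappa=kappa)

    def concentration_uM(self, G0: float) -> float:
        """Total concentration implied by a fitted zero-lag amplitude."""
        if G0 <= 0:
            raise ValueError("G0 must be > 0")
        return 1.0 / (G0 * self.v_eff_liters * AVOGADRO) * 1e6


def amplitude_to_totals(G0_GG: float, G0_RR: float,
                        v_eff_liters: float) -> tuple:
    """Total green/red concentrations (uM) from fitted ACF amplitudes."""
    vol = ObservationVolume(v_eff_liters)
    return vol.concentration_uM(G0_GG), vol.concentration_uM(G0_RR)


@dataclass
class FcsFit:
    """Result of fitting an FCS model to a correlation curve.

    ``params`` holds the fitted values with times in seconds; unit
    properties provide the conventional scales.  ``at_bounds`` lists
    free parameters pinned at a bound at the solution — such a fit is
    flagged, never silently reported as clean.
    """

    model: str                          # 'acf' | 'ccf'
    params: dict
    stderr: dict
    fixed: tuple
    redchi: float
    success: bool
    at_bounds: tuple = ()
    warnings: tuple = ()
    meta: dict = field(default_factory=dict)

    @property
    def G0(self) -> float:
        return self.params["G0"]

    @property
    def S(self) -> float:
        return self.params["S"]

    @property
    def tau_S_ms(self) -> float:
        return self.params["tau_S"] * 1e3

    @property
    def tau_D_ms(self) -> float:
        return self.params["tau_D"] * 1e3

    @property
    def A_T(self) -> float:
        return self.params.get("A_T", 0.0)

    @property
    def tau_T_us(self) -> float:
        return self.params.get("tau_T", 0.0) * 1e6

    @property
    def clean(self) -> bool:
        return self.success and not self.at_bounds

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "params": dict(self.params),
            "stderr": dict(self.stderr),
            "fixed": list(self.fixed),
            "redchi": self.redchi,
            "success": self.success,
            "at_bounds": list(self.at_bounds),
            "warnings": list(self.warnings),
            "units": {"tau_T": "s", "tau_S": "s", "tau_D": "s",
                      "G0": "dimensionless"},
            "meta": dict(self.meta),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FcsFit":
        return cls(model=d["model"], params=dict(d["params"]),
                   stderr=dict(d["stderr"]), fixed=tuple(d["fixed"]),
                   redchi=d["redchi"], success=d["success"],
                   at_bounds=tuple(d.get("at_bounds", ())),
                   warnings=tuple(d.get("warnings", ())),
                   meta=dict(d.get("meta", {})))


@dataclass
class ContrastFit:
    """Fit of a kinetic contrast function A (1 +/- S exp(-tau/tau_S)).

    The ratio of two correlation curves that share their diffusion
    (and any instrumental shape distortion) cancels everything except
    the kinetic factor, leaving a pure exponential — the most robust
    route to the relaxation time.
    """

    A: float
    S: float
    tau_S: float        # s
    sign: float
    stderr: dict
    redchi: float
    success: bool
    at_bounds: tuple = ()

    @property
    def tau_S_ms(self) -> float:
        return self.tau_S * 1e3


def ratio_curve(num: CorrelationCurve, den: CorrelationCurve,
                min_snr: float = 3.0,
                max_lag_s: float = 5e-3) -> CorrelationCurve:
    """Per-lag ratio of two curves on the same lag grid, with propagated
    errors; keeps lags where the denominator is significant."""
    n = min(len(num), len(den))
    if n == 0 or not np.allclose(num.lags[:n], den.lags[:n]):
        raise ValueError("curves must share their lag grid")
    g_n, g_d = num.G[:n], den.G[:n]
    keep = (den.lags[:n] <= max_lag_s) & (g_d > 0)
    if den.stderr is not None:
        keep &= g_d > min_snr * den.stderr[:n]
    if keep.sum() < 8:
        raise ValueError("too few usable lags for a ratio curve")
    r = g_n[keep] / g_d[keep]
    se = None
    if num.stderr is not None and den.stderr is not None:
        se = np.abs(r) * np.sqrt(
            (num.stderr[:n][keep] / np.where(g_n[keep] == 0, np.inf,
                                             g_n[keep])) ** 2
            + (den.stderr[:n][keep] / g_d[keep]) ** 2)
    return CorrelationCurve(num.lags[:n][keep], r, stderr=se,
                            channel_pair=f"{num.channel_pair}/"
                                         f"{den.channel_pair}")


def fit_kinetic_contrast(curve: CorrelationCurve, sign: float = +1.0,
                         fixed_tau_S: Optional[float] = None,
                         bounds: Optional[dict] = None) -> ContrastFit:
    """Least-squares fit of A (1 + sign * S exp(-tau/tau_S)) to a ratio
    curve; weighted by the propagated per-lag errors when present."""
    if sign not in (+1.0, -1.0):
        raise ValueError("sign must be +1 or -1")
    bnds = dict(DEFAULT_BOUNDS)
    bnds.update(bounds or {})
    s_hi = bnds["S_acf"][1] if sign > 0 else bnds["S"][1]
    lags, g = curve.lags, curve.G
    tail = g[lags >= 4 * (fixed_tau_S or 300e-6)]
    a0 = float(tail.mean()) if tail.size else float(g[-4:].mean())
    if not np.isfinite(a0) or a0 <= 0:
        a0 = max(float(np.median(g)), 1e-8)
    head = float(g[:4].mean())
    s0 = np.clip(sign * (head / a0 - 1.0), 0.05, 0.9 * s_hi)
    weights = None
    if curve.stderr is not None and np.all(curve.stderr > 0):
        weights = 1.0 / curve.stderr
    pars = lmfit.Parameters()
    pars.add("A", value=a0, min=a0 * 1e-3, max=max(a0 * 1e3, 1.0))
    pars.add("S", value=float(s0), min=0.0, max=s_hi)
    pars.add("tau_S", value=fixed_tau_S or 200e-6, min=bnds["tau_S"][0],
             max=bnds["tau_S"][1], vary=fixed_tau_S is None)

    def resid(p):
        model = p["A"].value * (1.0 + sign * p["S"].value
                                * np.exp(-lags / p["tau_S"].value))
        r = model - g
        return r * weights if weights is not None else r

    best = None
    for ts0 in ((fixed_tau_S,) if fixed_tau_S is not None
                else (50e-6, 200e-6, 1e-3)):
        p = lmfit.Parameters()
        for k in pars:
            p.add(k, value=pars[k].value, min=pars[k].min, max=pars[k].max,
                  vary=pars[k].vary)
        p["tau_S"].set(value=ts0)
        try:
            res = lmfit.minimize(resid, p, method="leastsq")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("kinetic-contrast fit failed")
    at_bounds = []
    for k, par in best.params.items():
        if not par.vary:
            continue
        span = par.max - par.min
        if abs(par.value - par.min) < 1e-6 * span                 or abs(par.value - par.max) < 1e-6 * span:
            at_bounds.append(k)
    return ContrastFit(
        A=float(best.params["A"].value), S=float(best.params["S"].value),
        tau_S=float(best.params["tau_S"].value), sign=sign,
        stderr={k: (float(v.stderr) if v.stderr is not None else
                    float("nan")) for k, v in best.params.items()},
        redchi=float(best.redchi), success=bool(best.success),
        at_bounds=tuple(at_bounds))


def _model_eval(model: str, tau, p, position_interval=0.0) -> np.ndarray:
    if model == "ccf":
        return ccf_model(tau, p["G0"], p["S"], p["tau_S"], p["tau_D"],
                         p["kappa"], position_interval)
    return acf_model(tau, p["G0"], p["A_T"], p["tau_T"], p["S"], p["tau_S"],
                     p["tau_D"], p["kappa"], position_interval)


def _initial_guesses(curve: CorrelationCurve, model: str) -> dict:
    """Deterministic initialization from the curve shape.

    G0 from the plateau just beyond 50 us (where triplet and most of the
    kinetic rise have relaxed but diffusion has not), tau_D from the
    half-decay lag, S small, A_T from the short-lag excess.
    """
    lags, g = curve.lags, curve.G
    plateau = g[(lags >= 50e-6) & (lags <= 300e-6)]
    g0 = float(plateau.mean()) if plateau.size else float(g[:4].mean())
    if not np.isfinite(g0) or g0 <= 0:
        g0 = max(float(np.max(g)), 1e-6)
    below = lags[g < g0 / 2.0]
    tau_d = float(below[0]) if below.size else float(lags[-1] / 4.0)
    tau_d = float(np.clip(tau_d, *DEFAULT_BOUNDS["tau_D"]))
    init = {"G0": g0, "S": 0.1, "tau_S": 200e-6, "tau_D": tau_d}
    if model == "acf":
        excess = float(g[0] / g0 - 1.0) if g0 > 0 else 0.1
        init["A_T"] = float(np.clip(excess, 0.01, 5.0))
        init["tau_T"] = 2e-6
    return init


def fit_curve(curve: CorrelationCurve, model: str = "ccf",
              kappa: float = 2.0,
              init: Optional[dict] = None,
              bounds: Optional[dict] = None,
              fixed: Optional[dict] = None,
              multistart: bool = True,
              position_interval: float = 0.0,
              offset: bool = False) -> FcsFit:
    """Weighted least-squares fit of the ACF/CCF model to a curve.

    Split-based standard errors weight the residuals when present
    (zero/absent errors fall back to unweighted).  A deterministic
    multi-start over (tau_S, tau_D) guards against the kinetics/diffusion
    swap ambiguity; the best chi-square solution wins.  ``fixed`` maps
    parameter names to frozen values (kappa is always fixed unless
    explicitly given in ``fixed`` as None-free via ``bounds``).
    """
    if model not in ("acf", "ccf"):
        raise ValueError("model must be 'acf' or 'ccf'")
    names = ACF_PARAMS if model == "acf" else CCF_PARAMS
    free_names = [n for n in names if n != "kappa"]
    n_free = len(free_names) - len(fixed or {})
    if len(curve) < 5 * max(n_free, 1):
        raise ValueError(
            f"curve has {len(curve)} lags; need >= 5x the {n_free} free "
            f"parameters")
    fixed = dict(fixed or {})
    bnds = dict(DEFAULT_BOUNDS)
    if model == "acf":
        bnds["S"] = bnds["S_acf"]
    bnds.update(bounds or {})
    guesses = _initial_guesses(curve, model)
    guesses.update(init or {})

    weights = None
    warnings = []
    if curve.stderr is not None:
        se = curve.stderr.copy()
        if np.all(se > 0):
            weights = 1.0 / se
        elif np.any(se > 0):
            se[se == 0] = se[se > 0].min()
            weights = 1.0 / se
            warnings.append("zero stderr values replaced by the smallest "
                            "positive one")
        else:
            warnings.append("all stderr zero; unweighted fit")
    else:
        warnings.append("no stderr available; unweighted fit")

    def build_params(start: dict) -> lmfit.Parameters:
        p = lmfit.Parameters()
        g0 = start["G0"]
        p.add("G0", value=g0, min=g0 * 1e-3, max=max(g0 * 1e3, 10.0))
        p.add("S", value=start["S"], min=bnds["S"][0], max=bnds["S"][1])
        p.add("tau_S", value=start["tau_S"], min=bnds["tau_S"][0],
              max=bnds["tau_S"][1])
        p.add("tau_D", value=start["tau_D"], min=bnds["tau_D"][0],
              max=bnds["tau_D"][1])
        p.add("kappa", value=kappa, vary=False)
        if offset:
            span = abs(start["G0"])
            p.add("c0", value=0.0, min=-0.5 * span, max=0.5 * span)
        if model == "acf":
            p.add("A_T", value=start["A_T"], min=bnds["A_T"][0],
                  max=bnds["A_T"][1])
            p.add("tau_T", value=start["tau_T"], min=bnds["tau_T"][0],
                  max=bnds["tau_T"][1])
        for name, val in fixed.items():
            if name not in p:
                raise KeyError(f"cannot fix unknown parameter {name!r}")
            p[name].set(value=val, vary=False)
        return p

    def residual(p):
        vals = {k: p[k].value for k in p}
        r = _model_eval(model, curve.lags, vals, position_interval) \
            - curve.G
        if "c0" in p:
            r = r + p["c0"].value
        return r * weights if weights is not None else r

    starts = [guesses]
    if multistart:
        for ts in (50e-6, 200e-6, 1e-3):
            for td in (0.3e-3, 1e-3, 3e-3):
                s = dict(guesses)
                s["tau_S"], s["tau_D"] = ts, td
                starts.append(s)

    best = None
    for start in starts:
        start = {k: float(np.clip(v, *bnds[k])) if k in bnds else v
                 for k, v in start.items()}
        try:
            res = lmfit.minimize(residual, build_params(start),
                                 method="leastsq")
        except Exception:
            continue
        if best is None or res.chisqr < best.chisqr:
            best = res
    if best is None:
        raise RuntimeError("all fit attempts failed")

    params = {k: float(best.params[k].value) for k in best.params}
    stderr = {k: (float(best.params[k].stderr)
                  if best.params[k].stderr is not None else float("nan"))
              for k in best.params}
    at_bounds = []
    for k, par in best.params.items():
        if not par.vary:
            continue
        span = (par.max - par.min) if np.isfinite(par.max - par.min) else 1.0
        if (np.isfinite(par.min) and abs(par.value - par.min) < 1e-6 * span) \
                or (np.isfinite(par.max)
                    and abs(par.value - par.max) < 1e-6 * span):
            at_bounds.append(k)
    if params["tau_S"] > params["tau_D"] and params["S"] > 1e-3 \
            and "tau_S" not in fixed:
        warnings.append("fitted tau_S exceeds tau_D: kinetics/diffusion "
                        "assignment may be swapped")
    fixed_names = tuple(k for k in best.params if not best.params[k].vary)
    return FcsFit(model=model, params=params, stderr=stderr,
                  fixed=fixed_names, redchi=float(best.redchi),
                  success=bool(best.success), at_bounds=tuple(at_bounds),
                  warnings=tuple(warnings),
                  meta={"nfev": int(best.nfev), "ndata": int(best.ndata),
                        "channel_pair": curve.channel_pair,
                        "position_interval": position_interval})
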