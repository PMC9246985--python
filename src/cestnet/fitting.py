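"""Least-squares fitting of CEST profiles against the spin-dynamics model.

The classical counterpart of the network pipeline: minimize the squared
residuals of the simulator's forward model over the exchange parameters.
Floated parameters are the chemical shifts, branch exchange rates,
excited-state populations and excited-state R2 offsets; the base relaxation
rates are fixed through tau_M, as is the scalar coupling.  Several profiles
(e.g. two B1 fields) may be fitted jointly, sharing all kinetic and
thermodynamic parameters.

Uncertainties come from the covariance matrix at the optimum,
cov = (J^T J)^-1 * s^2 with s^2 the residual variance, the standard
Gauss-Newton estimate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .profiles import CESTProfile
from .scenarios import AcquisitionConfig, ExchangeScenario, ValidationError
from .spin_dynamics import simulate_ap_profile, simulate_ip_profile

__all__ = ["FitResult", "least_squares_fit"]


@dataclass
class FitResult:
    scenario: ExchangeScenario  # best-fit parameters
    shifts: np.ndarray  # ppm, ground first
    shift_sigmas: np.ndarray  # ppm, covariance-based
    params: dict  # all floated parameters by name
    param_sigmas: dict
    cost: float
    success: bool
    message: str
    n_iterations: int


def _config_for(profile: CESTProfile) -> AcquisitionConfig:
    meta = profile.meta
    missing = [k for k in ("b0", "b1", "t_ex") if k not in meta]
    if missing:
        raise ValidationError(f"profile lacks metadata for fitting: {missing}")
    return AcquisitionConfig(
        b0=meta["b0"], b1=meta["b1"], offsets=profile.offsets, t_ex=meta["t_ex"]
    )


def least_squares_fit(
    profiles: CESTProfile | list[CESTProfile],
    n_states: int,
    initial: ExchangeScenario,
    inept: str = "ideal",
    max_nfev: int = 200,
) -> FitResult:
    """Fit shifts, kinetics and excited-state R2 offsets to one or more profiles.

    ``initial`` provides both the starting guesses for the floated parameters
    and the fixed spin parameters (tau_M, J_HN, R_ex).  All profiles must
    derive from the same exchanging system; per-profile acquisition settings
    are taken from each profile's metadata.
    """
    if isinstance(profiles, CESTProfile):
        profiles = [profiles]
    if n_states not in (2, 3):
        raise ValidationError("least_squares_fit supports 2 or 3 states")
    if initial.n_states != n_states:
        raise ValidationError("initial scenario does not match n_states")
    configs = [_config_for(p) for p in profiles]
    lo = min(p.offset_min for p in profiles)
    hi = max(p.offset_min + p.span for p in profiles)

    names = ["w_g", "w_e1"] + (["w_e2"] if n_states == 3 else [])
    names += ["kex_ge1"] + (["kex_ge2"] if n_states == 3 else [])
    names += ["p_e1"] + (["p_e2"] if n_states == 3 else [])
    names += ["dr2_e1"] + (["dr2_e2"] if n_states == 3 else [])
    x0 = np.array([getattr(initial, n) for n in names])
    bounds_lo, bounds_hi = [], []
    for n in names:
        if n.startswith("w_"):
            bounds_lo.append(lo - 0.5), bounds_hi.append(hi + 0.5)
        elif n.startswith("kex"):
            bounds_lo.append(0.0), bounds_hi.append(2000.0)
        elif n.startswith("p_"):
            bounds_lo.append(1e-4), bounds_hi.append(0.3)
        else:  # dR2
            bounds_lo.append(-20.0), bounds_hi.append(100.0)

    def build(x: np.ndarray) -> ExchangeScenario:
        kw = dict(zip(names, x))
        p_e1 = kw.get("p_e1", 0.0)
        p_e2 = kw.get("p_e2", 0.0)
        return initial.replace(p_g=1.0 - p_e1 - p_e2, **kw)

    def residuals(x: np.ndarray) -> np.ndarray:
        sc = build(x)
        out = []
        for prof, cfg in zip(profiles, configs):
            if prof.phase == "ap":
                sim = simulate_ap_profile(sc, cfg, inept=inept)
            else:
                sim = simulate_ip_profile(sc, cfg)
            out.append(sim.intensities - prof.intensities)
        return np.concatenate(out)

    res = least_squares(
        residuals, x0, bounds=(bounds_lo, bounds_hi), max_nfev=max_nfev, xtol=1e-12
    )
    m, k = res.fun.size, x0.size
    s2 = 2.0 * res.cost / max(m - k, 1)
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj) * s2
        sigmas = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        sigmas = np.full(k, np.nan)
    params = dict(zip(names, res.x))
    param_sigmas = dict(zip(names, sigmas))
    n_shift = n_states
    return FitResult(
        scenario=build(res.x),
        shifts=res.x[:n_shift],
        shift_sigmas=sigmas[:n_shift],
        params=params,
        param_sigmas=param_sigmas,
        cost=float(res.cost),
        success=bool(res.success),
        message=res.message,
        n_iterations=int(res.nfev),
    )
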