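"""Liouvillian construction and propagation for amide-proton CEST.

Model
-----
For the anti-phase (AP) experiment each exchanging state carries six
magnetization components, {Hx, Hy, Hz} in each of the two 15N longitudinal
manifolds (alpha/beta).  The 15N spin shifts the 1H precession by +pi*J
(alpha) or -pi*J (beta), producing the scalar-coupling doublet, and 15N
longitudinal relaxation interchanges the manifolds at rate R1_N/2 in each
direction.  The in-phase (IP) experiment is the hypothetical J = 0 spin: three
components {Hx, Hy, Hz} per state.

The Liouvillian L is defined such that the state evolves as exp(-L t); with B1
applied along x and an offset Omega (rad/s) the one-manifold Bloch block is::

    d/dt [Hx]   [ R2   Omega  0   ] [Hx]
         [Hy] = -[-Omega  R2  w1  ] [Hy]
         [Hz]   [ 0    -w1    R1  ] [Hz]

Chemical exchange couples corresponding components across states with the
rate matrix of :func:`cestnet.scenarios.build_rate_matrix`.

Dephasing propagator
--------------------
Experimental CEST profiles are smooth because B1 inhomogeneity dephases
coherent nutation.  Instead of averaging over a distribution of B1 fields,
propagation keeps only the real-eigenvalue part of the spectrum: after the
eigendecomposition L V = V D, the propagator is
``V_re exp(-t D_re) V_re^-1`` where "real" means |Im(lambda)| <= 1e-3 s^-1.

Signal conventions
------------------
IP profiles start from equilibrium (Hz = p_s per state) and detect
ground-state Hz.  AP profiles start from the anti-phase order created by the
first INEPT (Hz_alpha = +a_s, Hz_beta = -a_s; a_s = p_s for an ideal INEPT,
or attenuated amplitudes from an explicit delay-180-delay element) and detect
the ground-state manifold difference <Hz_alpha> - <Hz_beta>.  Both are
normalized by the same propagation with B1 = 0, which is equivalent to the
far off-resonance (-12 kHz) reference experiment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .profiles import CESTProfile
from .scenarios import (
    AcquisitionConfig,
    ExchangeScenario,
    ValidationError,
    build_rate_matrix,
    relaxation_rates,
)

__all__ = [
    "Liouvillian",
    "build_liouvillian",
    "real_eig_propagator",
    "simulate_ip_profile",
    "simulate_ap_profile",
    "REAL_EIG_IMAG_TOL",
]

#: eigenvalues with |Im| above this (s^-1) are dropped from the propagator
REAL_EIG_IMAG_TOL = 1e-3


@dataclass
class Liouvillian:
    """A real evolution-rate matrix (s^-1); the state evolves as exp(-L t)."""

    matrix: np.ndarray
    basis: list[str]

    @property
    def dim(self) -> int:
        return self.matrix.shape[0]


def _state_rates(scenario: ExchangeScenario, b0: float) -> tuple[np.ndarray, float, float]:
    """Per-state R2 values plus (R1_H, R1_N) for a scenario at field b0."""
    base = relaxation_rates(scenario.tau_m, b0)
    dr2 = [0.0, scenario.dr2_e1, scenario.dr2_e2][: scenario.n_states]
    r2 = np.array([base["R2_H"] + scenario.r_ex + d for d in dr2])
    # guard against pathological negative totals from the sampled dR2 offsets
    r2 = np.maximum(r2, 1e-3)
    return r2, base["R1_H"], base["R1_N"]


def _liouvillian_stack(
    scenario: ExchangeScenario,
    config: AcquisitionConfig,
    offsets: np.ndarray,
    phase: str,
    b1: float | None = None,
) -> np.ndarray:
    """Stack of Liouvillians, one per offset: shape (n_offsets, d, d)."""
    if phase not in ("ap", "ip"):
        raise ValidationError(f"unknown phase tag {phase!r}")
    offsets = np.atleast_1d(np.asarray(offsets, dtype=float))
    n = scenario.n_states
    n_man = 2 if phase == "ap" else 1
    d = 3 * n_man * n
    r2, r1_h, r1_n = _state_rates(scenario, config.b0)
    w1 = 2.0 * np.pi * (config.b1 if b1 is None else b1)
    nu0 = config.larmor  # Hz per ppm
    shifts = scenario.shifts
    K = build_rate_matrix(scenario)

    L = np.zeros((offsets.size, d, d))
    for s in range(n):
        for m in range(n_man):
            i = 3 * (n_man * s + m)
            # offset of this doublet component in rad/s; alpha takes +pi*J
            sign = 1.0 if m == 0 else -1.0
            j_term = sign * np.pi * scenario.j_hn if phase == "ap" else 0.0
            omega = 2.0 * np.pi * (shifts[s] - offsets) * nu0 + j_term
            L[:, i, i] = r2[s]
            L[:, i + 1, i + 1] = r2[s]
            L[:, i + 2, i + 2] = r1_h
            L[:, i, i + 1] = omega
            L[:, i + 1, i] = -omega
            L[:, i + 1, i + 2] = w1
            L[:, i + 2, i + 1] = -w1
        if n_man == 2:
            # 15N spin flips interchange the manifolds at R1_N/2 each way
            a, b = 6 * s, 6 * s + 3
            for k in range(3):
                L[:, a + k, a + k] += 0.5 * r1_n
                L[:, b + k, b + k] += 0.5 * r1_n
                L[:, a + k, b + k] -= 0.5 * r1_n
                L[:, b + k, a + k] -= 0.5 * r1_n
    # chemical exchange: L -= K (x) I
    block = 3 * n_man
    for si in range(n):
        for sj in range(n):
            if K[si, sj] != 0.0:
                idx_i, idx_j = block * si, block * sj
                for k in range(block):
                    L[:, idx_i + k, idx_j + k] -= K[si, sj]
    return L


def build_liouvillian(
    scenario: ExchangeScenario,
    config: AcquisitionConfig,
    offset: float,
    phase: str = "ap",
) -> Liouvillian:
    """Liouvillian at a single B1 carrier position (ppm)."""
    L = _liouvillian_stack(scenario, config, np.array([offset]), phase)[0]
    comps = ("Hx", "Hy", "Hz")
    labels = []
    for s in range(scenario.n_states):
        state = ["G", "E1", "E2"][s]
        if phase == "ap":
            labels += [f"{c}^{m}({state})" for m in ("a", "b") for c in comps]
        else:
            labels += [f"{c}({state})" for c in comps]
    return Liouvillian(L, labels)


def real_eig_propagator(L: Liouvillian | np.ndarray, duration: float) -> np.ndarray:
    """Dephasing propagator V_re exp(-duration D_re) V_re^-1.

    Only eigenvalues with |Im(lambda)| <= 1e-3 s^-1 are retained; the result
    is the projection of exp(-L t) onto the real eigensystem and is real.
    """
    A = L.matrix if isinstance(L, Liouvillian) else np.asarray(L, dtype=float)
    try:
        lam, V = np.linalg.eig(A)
        Vinv = np.linalg.inv(V)
    except np.linalg.LinAlgError as err:  # pragma: no cover - measure zero
        raise np.linalg.LinAlgError(f"eigendecomposition failed for L={A!r}") from err
    mask = np.abs(lam.imag) <= REAL_EIG_IMAG_TOL
    P = (V[:, mask] * np.exp(-duration * lam[mask])) @ Vinv[mask, :]
    if P.size and np.max(np.abs(P.imag)) > 1e-8 * max(1.0, np.max(np.abs(P.real))):
        warnings.warn("real-eigenvalue propagator has a large imaginary residue")
    return P.real


def _propagate_signal(
    L_stack: np.ndarray, m0: np.ndarray, detect: np.ndarray, duration: float
) -> np.ndarray:
    """Detected signal after real-eigenvalue propagation, per offset."""
    try:
        lam, V = np.linalg.eig(L_stack)
        b = np.broadcast_to(m0.astype(complex)[:, None], (L_stack.shape[0],) + (m0.size, 1))
        coef = np.linalg.solve(V, b)[..., 0]
    except np.linalg.LinAlgError:
        # degenerate/defective for this exact parameter set: perturb and retry
        raise
    mask = np.abs(lam.imag) <= REAL_EIG_IMAG_TOL
    amp = np.einsum("j,ojk->ok", detect, V)
    sig = np.sum(amp * np.where(mask, np.exp(-duration * lam), 0.0) * coef, axis=1)
    return sig.real


def _simulate(
    scenario: ExchangeScenario,
    config: AcquisitionConfig,
    phase: str,
    m0: np.ndarray,
    detect: np.ndarray,
) -> np.ndarray:
    offsets = config.offsets
    try:
        L = _liouvillian_stack(scenario, config, offsets, phase)
        sig = _propagate_signal(L, m0, detect, config.t_ex)
    except np.linalg.LinAlgError:
        warnings.warn("degenerate Liouvillian; perturbing offsets by 1e-6 ppm")
        L = _liouvillian_stack(scenario, config, offsets + 1e-6, phase)
        sig = _propagate_signal(L, m0, detect, config.t_ex)
    # reference: same propagation with B1 = 0 (offset-independent)
    L0 = _liouvillian_stack(scenario, config, offsets[:1], phase, b1=0.0)
    ref = _propagate_signal(L0, m0, detect, config.t_ex)[0]
    return sig / ref


def simulate_ip_profile(
    scenario: ExchangeScenario, config: AcquisitionConfig
) -> CESTProfile:
    """In-phase CEST profile: J = 0, equilibrium start, ground-state Hz detected."""
    n = scenario.n_states
    m0 = np.zeros(3 * n)
    m0[2::3] = scenario.populations
    detect = np.zeros(3 * n)
    detect[2] = 1.0
    ratio = _simulate(scenario, config, "ip", m0, detect)
    return CESTProfile(
        config.offsets.copy(), ratio, phase="ip", provenance="simulated",
        meta={"b0": config.b0, "b1": config.b1, "t_ex": config.t_ex},
    )


def _inept_amplitudes(
    scenario: ExchangeScenario, config: AcquisitionConfig
) -> np.ndarray:
    """Per-state anti-phase amplitudes after an explicit delay-180-delay INEPT.

    Free evolution under the full (B1 = 0) Liouvillian during the two
    1/(4|J|) delays, with ideal simultaneous 180(H, N) pulses in between;
    exchange and relaxation act throughout.  The carrier sits at the centre
    of the offset window.
    """
    n = scenario.n_states
    carrier = config.offset_min + 0.5 * config.span
    L = _liouvillian_stack(scenario, config, np.array([carrier]), "ap", b1=0.0)[0]
    tau = 1.0 / (4.0 * abs(scenario.j_hn))
    U = expm(-L * tau)
    # 180x on 1H (Hx, -Hy, -Hz) combined with 180 on 15N (manifold swap)
    R = np.zeros_like(L)
    flip = np.diag([1.0, -1.0, -1.0])
    for s in range(n):
        a, b = 6 * s, 6 * s + 3
        R[a : a + 3, b : b + 3] = flip
        R[b : b + 3, a : a + 3] = flip
    m0 = np.zeros(6 * n)
    for s in range(n):
        m0[6 * s] = scenario.populations[s]  # in-phase Hx
        m0[6 * s + 3] = scenario.populations[s]
    m = U @ (R @ (U @ m0))
    # anti-phase component per state: (Hy_beta - Hy_alpha) / 2
    return np.array([(m[6 * s + 4] - m[6 * s + 1]) / 2.0 for s in range(n)])


def simulate_ap_profile(
    scenario: ExchangeScenario, config: AcquisitionConfig, inept: str = "ideal"
) -> CESTProfile:
    """Anti-phase CEST profile.

    The CEST element starts from Hz_alpha = +a_s, Hz_beta = -a_s per state;
    with ``inept="ideal"`` the amplitudes a_s equal the populations, with
    ``inept="explicit"`` they carry the relaxation/exchange losses of the
    delay-180-delay INEPT element.  Detection is the ground-state manifold
    difference <Hz_alpha> - <Hz_beta>, normalized by the B1 = 0 propagation.
    """
    if inept not in ("ideal", "explicit"):
        raise ValidationError(f"unknown INEPT mode {inept!r}")
    n = scenario.n_states
    if inept == "ideal":
        amps = scenario.populations.astype(float)
    else:
        amps = _inept_amplitudes(scenario, config)
    m0 = np.zeros(6 * n)
    m0[2::6] = amps  # Hz alpha
    m0[5::6] = -amps  # Hz beta
    detect = np.zeros(6 * n)
    detect[2] = 1.0
    detect[5] = -1.0
    ratio = _simulate(scenario, config, "ap", m0, detect)
    return CESTProfile(
        config.offsets.copy(), ratio, phase="ap", provenance="simulated",
        meta={"b0": config.b0, "b1": config.b1, "t_ex": config.t_ex},
    )
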