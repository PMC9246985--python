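"""Exchange scenarios, acquisition settings and amide relaxation rates.

The exchange model is the forked three-site scheme E1 <=> G <=> E2: a major
("ground") conformer G interconverting with up to two sparsely populated
("excited") conformers.  A two-site system is the special case p_E2 = 0 and a
single isolated spin the case p_E1 = p_E2 = 0.

Exchange rates follow the usual CEST convention: for each branch the reported
rate is the sum of forward and backward rate constants,

    kex_GEi = k(G->Ei) + k(Ei->G),

with detailed balance  k(G->Ei) * p_G = k(Ei->G) * p_Ei  computed from the
global state populations.  For a two-site system this reduces to the familiar
k(G->E) = kex * p_E.

Ground-state relaxation rates are computed from a single rotational
correlation time tau_M assuming rigid isotropic tumbling, the one-bond H-N
dipolar interaction (r_HN = 1.02 A) and the 15N CSA (-164 ppm); remote-proton
contributions are neglected, appropriate for perdeuterated samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ExchangeScenario",
    "AcquisitionConfig",
    "B0_FIELDS",
    "GAMMA_H",
    "GAMMA_N",
    "build_rate_matrix",
    "relaxation_rates",
    "larmor_MHz",
]

#: Static fields (T) used when sampling training data.
B0_FIELDS = (14.1, 16.4, 18.8, 21.1, 23.5)

# Physical constants (SI)
GAMMA_H = 2.6752218744e8  # rad s^-1 T^-1
GAMMA_N = -2.7126e7  # rad s^-1 T^-1
HBAR = 1.054571817e-34  # J s
MU0 = 4.0e-7 * np.pi
R_HN = 1.02e-10  # m, amide H-N bond length
CSA_N = -164.0e-6  # 15N chemical shift anisotropy


class ValidationError(ValueError):
    """Raised when a scenario or configuration violates its invariants."""


@dataclass
class ExchangeScenario:
    """Spin-system and kinetic parameters of one exchanging amide proton.

    Populations are global fractions that must sum to one.  Shifts are in ppm
    on the 1H axis; ``j_hn`` is the one-bond 1H-15N scalar coupling in Hz
    (negative for amides).  ``r_ex`` is a microsecond-exchange contribution
    added to R2 of every state; ``dr2_e1``/``dr2_e2`` are excited-state R2,H
    offsets relative to the ground state.
    """

    p_g: float = 1.0
    p_e1: float = 0.0
    p_e2: float = 0.0
    kex_ge1: float = 0.0
    kex_ge2: float = 0.0
    w_g: float = 8.3
    w_e1: float = 8.3
    w_e2: float = 8.3
    tau_m: float = 10.0  # ns
    j_hn: float = -93.0  # Hz
    r_ex: float = 0.0  # s^-1
    dr2_e1: float = 0.0  # s^-1
    dr2_e2: float = 0.0  # s^-1

    def __post_init__(self) -> None:
        pops = (self.p_g, self.p_e1, self.p_e2)
        if any(p < 0 for p in pops):
            raise ValidationError(f"negative population: {pops}")
        if abs(sum(pops) - 1.0) > 1e-8:
            raise ValidationError(f"populations must sum to 1, got {sum(pops)}")
        if self.kex_ge1 < 0 or self.kex_ge2 < 0:
            raise ValidationError("exchange rates must be non-negative")
        if self.tau_m <= 0:
            raise ValidationError("tau_m must be positive")

    @property
    def n_states(self) -> int:
        """Number of populated states (1-3)."""
        return 1 + (self.p_e1 > 0) + (self.p_e2 > 0)

    @property
    def populations(self) -> np.ndarray:
        return np.array([self.p_g, self.p_e1, self.p_e2][: max(self.n_states, 1)])

    @property
    def shifts(self) -> np.ndarray:
        return np.array([self.w_g, self.w_e1, self.w_e2][: self.n_states])

    def replace(self, **kwargs) -> "ExchangeScenario":
        return replace(self, **kwargs)


@dataclass
class AcquisitionConfig:
    """Spectrometer and CEST-experiment settings.

    ``offsets`` is the regular grid of B1 carrier positions in ppm; ``b1`` the
    saturation field in Hz; ``t_ex`` the CEST delay and ``d1`` the inter-scan
    delay in seconds.
    """

    b0: float = 18.8  # T
    b1: float = 30.0  # Hz
    offsets: np.ndarray = field(default_factory=lambda: np.linspace(6.6, 10.0, 90))
    t_ex: float = 0.4  # s
    d1: float = 0.5  # s

    def __post_init__(self) -> None:
        self.offsets = np.asarray(self.offsets, dtype=float)
        if self.offsets.ndim != 1 or self.offsets.size < 2:
            raise ValidationError("offsets must be a 1-D grid with >= 2 points")
        steps = np.diff(self.offsets)
        if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
            raise ValidationError("offsets must form a regular grid")
        if self.b1 < 0:
            raise ValidationError("b1 must be non-negative")
        if self.t_ex <= 0:
            raise ValidationError("t_ex must be positive")

    @property
    def n_offsets(self) -> int:
        return self.offsets.size

    @property
    def offset_min(self) -> float:
        return float(self.offsets.min())

    @property
    def span(self) -> float:
        """Offset range max - min in ppm."""
        return float(self.offsets.max() - self.offsets.min())

    @property
    def larmor(self) -> float:
        """1H Larmor frequency in MHz (== Hz per ppm)."""
        return larmor_MHz(self.b0)


def larmor_MHz(b0: float) -> float:
    """1H Larmor frequency in MHz for a static field ``b0`` in tesla."""
    return GAMMA_H * b0 / (2.0 * np.pi) * 1e-6


def build_rate_matrix(scenario: ExchangeScenario) -> np.ndarray:
    """Exchange rate matrix K over the populated states, ground state first.

    ``K[i, j]`` is the rate constant j -> i for i != j and columns sum to
    zero, so populations evolve as dp/dt = K p and the stationary vector of K
    is the input population vector.  Branch rates obey detailed balance,
    k(G->Ei) p_G = k(Ei->G) p_Ei, with kex_GEi = k(G->Ei) + k(Ei->G).
    """
    n = scenario.n_states
    pops = scenario.populations
    kex = [scenario.kex_ge1, scenario.kex_ge2]
    K = np.zeros((n, n))
    # forked topology: every excited state exchanges with G (index 0) only
    for i in range(1, n):
        p_sum = pops[0] + pops[i]
        k_g_to_e = kex[i - 1] * pops[i] / p_sum
        k_e_to_g = kex[i - 1] * pops[0] / p_sum
        K[i, 0] += k_g_to_e
        K[0, 0] -= k_g_to_e
        K[0, i] += k_e_to_g
        K[i, i] -= k_e_to_g
    return K


def _j_spectral(omega: np.ndarray | float, tau: float) -> np.ndarray | float:
    """Rigid isotropic spectral density J(w) = (2/5) tau / (1 + (w tau)^2)."""
    return 0.4 * tau / (1.0 + (omega * tau) ** 2)


def relaxation_rates(tau_m: float, b0: float) -> dict[str, float]:
    """Ground-state relaxation rates {R1_H, R2_H, R1_N} from tau_M and B0.

    Standard amide expressions: H-N dipolar interaction for both spins plus
    the 15N CSA for 15N; the 1H CSA and remote protons are neglected
    (perdeuterated samples).  ``tau_m`` is in ns, ``b0`` in T, rates in s^-1.
    """
    if tau_m <= 0:
        raise ValidationError("tau_m must be positive")
    tau = tau_m * 1e-9
    w_h = GAMMA_H * b0
    w_n = abs(GAMMA_N) * b0
    d = MU0 * HBAR * GAMMA_H * abs(GAMMA_N) / (4.0 * np.pi * R_HN**3)
    c_n = w_n * CSA_N / np.sqrt(3.0)

    j0 = _j_spectral(0.0, tau)
    jh = _j_spectral(w_h, tau)
    jn = _j_spectral(w_n, tau)
    jhmn = _j_spectral(w_h - w_n, tau)
    jhpn = _j_spectral(w_h + w_n, tau)

    r1_h = d**2 / 4.0 * (jhmn + 3.0 * jh + 6.0 * jhpn)
    r2_h = d**2 / 8.0 * (4.0 * j0 + 3.0 * jh + jhmn + 6.0 * jn + 6.0 * jhpn)
    r1_n = d**2 / 4.0 * (jhmn + 3.0 * jn + 6.0 * jhpn) + c_n**2 * jn
    return {"R1_H": float(r1_h), "R2_H": float(r2_h), "R1_N": float(r1_n)}
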