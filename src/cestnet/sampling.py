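"""On-the-fly sampling of training scenarios and examples.

The sampler draws the stated training-data world: five static fields, B1
uniform in 15-50 Hz, 50-128 sampled points over a 3.4 ppm window, T_ex =
0.4 s, tau_M uniform in 3-20 ns, 1J_HN uniform in -95 to -91 Hz, R_ex the
absolute value of N(1, 2) s^-1, excited-state dR2 offsets N(0, 2) s^-1,
chemical shifts uniform over the sweep width, branch exchange rates uniform
in 10-300 s^-1, excited-state populations uniform in 0.01-0.15, and the
forked three-site model E1 <=> G <=> E2 with probability 25% (otherwise
p_E2 = 0, two-site exchange).

A transformation-network example packs a noisy anti-phase profile
(sigma = 0.01 of the profile maximum) and targets the clean in-phase profile
resampled to 128 offsets; a shift-network example maps a 128-point in-phase
profile to the normalized true shifts and the two/three-state indicator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .processing import N_UPSAMPLED, pack_input, pack_profile, upsampled_grid
from .profiles import CESTProfile
from .scenarios import B0_FIELDS, AcquisitionConfig, ExchangeScenario, ValidationError
from .spin_dynamics import simulate_ap_profile, simulate_ip_profile

__all__ = [
    "TrainingExample",
    "sample_scenario",
    "add_noise",
    "make_tr_example",
    "make_cs_example",
    "true_fractions",
    "tr_batch",
    "DEFAULT_OFFSET_MIN",
    "DEFAULT_SPAN",
    "THREE_SITE_PROB",
    "TR_NOISE",
    "CS_NOISE_RANGE",
]

DEFAULT_OFFSET_MIN = 6.6  # ppm, amide 1H window start
DEFAULT_SPAN = 3.4  # ppm, range of offset points for training data
THREE_SITE_PROB = 0.25
TR_NOISE = 0.01  # sigma as fraction of max for the transformation network
CS_NOISE_RANGE = (0.001, 0.04)  # noise range for the shift network


@dataclass
class TrainingExample:
    """One (noisy packed AP input -> clean IP target) training pair."""

    input_coeffs: np.ndarray  # 130 reals: Re | Im of the packed AP spectrum
    input_times: np.ndarray  # 130 reals: aligned time points
    target_ip: np.ndarray  # 128 reals: clean in-phase profile
    f_true: np.ndarray  # normalized shifts of the three slots, in (0, 1)
    indicator: np.ndarray  # {1,1,1} three-state, {1,1,0} two-state, {1,0,0} one-state
    scenario: ExchangeScenario = None
    config: AcquisitionConfig = None
    ap_clean: CESTProfile = None
    ap_noisy: CESTProfile = None
    extra: dict = field(default_factory=dict)


def sample_scenario(
    rng: np.random.Generator,
    offset_min: float = DEFAULT_OFFSET_MIN,
    span: float = DEFAULT_SPAN,
) -> tuple[ExchangeScenario, AcquisitionConfig]:
    """Draw one (scenario, acquisition) pair from the training distribution."""
    b0 = float(rng.choice(B0_FIELDS))
    b1 = float(rng.uniform(15.0, 50.0))
    n_points = int(rng.integers(50, 129))
    offsets = np.linspace(offset_min, offset_min + span, n_points)
    tau_m = float(rng.uniform(3.0, 20.0))
    j_hn = float(rng.uniform(-95.0, -91.0))
    r_ex = float(abs(rng.normal(1.0, 2.0)))
    dr2_e1 = float(rng.normal(0.0, 2.0))
    dr2_e2 = float(rng.normal(0.0, 2.0))
    w_g, w_e1, w_e2 = rng.uniform(offset_min, offset_min + span, size=3)
    three_site = bool(rng.random() < THREE_SITE_PROB)
    kex1 = float(rng.uniform(10.0, 300.0))
    kex2 = float(rng.uniform(10.0, 300.0))
    p_e1 = float(rng.uniform(0.01, 0.15))
    p_e2 = float(rng.uniform(0.01, 0.15))
    if not three_site:
        p_e2, kex2 = 0.0, 0.0
    scenario = ExchangeScenario(
        p_g=1.0 - p_e1 - p_e2,
        p_e1=p_e1,
        p_e2=p_e2,
        kex_ge1=kex1,
        kex_ge2=kex2,
        w_g=float(w_g),
        w_e1=float(w_e1),
        w_e2=float(w_e2),
        tau_m=tau_m,
        j_hn=j_hn,
        r_ex=r_ex,
        dr2_e1=dr2_e1,
        dr2_e2=dr2_e2,
    )
    config = AcquisitionConfig(b0=b0, b1=b1, offsets=offsets, t_ex=0.4, d1=0.5)
    return scenario, config


def add_noise(
    profile: CESTProfile, sigma_frac: float, rng: np.random.Generator
) -> CESTProfile:
    """Additive i.i.d. Gaussian noise with sigma = sigma_frac * max(profile)."""
    if sigma_frac < 0:
        raise ValidationError("sigma_frac must be non-negative")
    if sigma_frac == 0:
        return profile
    sigma = sigma_frac * float(np.max(profile.intensities))
    noisy = profile.intensities + rng.normal(0.0, sigma, size=profile.n_offsets)
    return CESTProfile(
        profile.offsets.copy(), noisy, phase=profile.phase,
        provenance=profile.provenance, noise=sigma_frac, meta=dict(profile.meta),
    )


def true_fractions(
    scenario: ExchangeScenario, offset_min: float, span: float
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized slot shifts and state indicator for a scenario.

    Slot 0 is the ground state; slots 1-2 hold the excited states ordered by
    population (descending).  Absent slots get f = 0.5 (irrelevant during
    training: the indicator leaves their uncertainty unpenalized) and
    indicator 0.
    """
    f = np.full(3, 0.5)
    ind = np.zeros(3)
    shifts = [scenario.w_g, scenario.w_e1, scenario.w_e2]
    pops = [scenario.p_g, scenario.p_e1, scenario.p_e2]
    order = [0] + sorted((i for i in (1, 2) if pops[i] > 0), key=lambda i: -pops[i])
    for slot, state in enumerate(order):
        fval = (shifts[state] - offset_min) / span
        if not 0.0 <= fval <= 1.0:
            raise ValidationError(f"shift {shifts[state]} outside the offset window")
        f[slot] = fval
        ind[slot] = 1.0
    return f, ind


def make_tr_example(
    scenario: ExchangeScenario,
    config: AcquisitionConfig,
    rng: np.random.Generator,
    noise: float = TR_NOISE,
    inept: str = "ideal",
) -> TrainingExample:
    """Simulate, noise, and pack one transformation-network training pair.

    The anti-phase profile is simulated on the sampled grid, noised at
    ``noise`` of its maximum, dip-transformed, real-FT'd, zero-filled and
    packed.  The target is the clean in-phase profile simulated directly on
    the 128-point upsampled grid (noise is never applied to the target).
    """
    ap = simulate_ap_profile(scenario, config, inept=inept)
    ap_noisy = add_noise(ap, noise, rng)
    ptd = pack_profile(ap_noisy, config.larmor)
    vec, tvec = pack_input(ptd)

    target_offsets = upsampled_grid(config.offset_min, config.span, config.n_offsets)
    target_cfg = AcquisitionConfig(
        b0=config.b0, b1=config.b1, offsets=target_offsets,
        t_ex=config.t_ex, d1=config.d1,
    )
    ip = simulate_ip_profile(scenario, target_cfg)
    f_true, indicator = true_fractions(scenario, config.offset_min, config.span)
    return TrainingExample(
        input_coeffs=vec, input_times=tvec, target_ip=ip.intensities,
        f_true=f_true, indicator=indicator, scenario=scenario, config=config,
        ap_clean=ap, ap_noisy=ap_noisy, extra={"ip": ip},
    )


def make_cs_example(
    tr_output: np.ndarray,
    scenario: ExchangeScenario,
    offset_min: float = DEFAULT_OFFSET_MIN,
    span: float = DEFAULT_SPAN,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Shift-network pair from a 128-point in-phase profile.

    ``tr_output`` is normally the transformation network's output for a noisy
    anti-phase profile; passing the clean simulated in-phase profile instead
    is a unit-test bypass, not the training route.
    """
    x = np.asarray(tr_output, dtype=float)
    if x.size != N_UPSAMPLED:
        raise ValidationError(f"expected {N_UPSAMPLED}-point profile, got {x.size}")
    f_true, indicator = true_fractions(scenario, offset_min, span)
    return x, f_true, indicator


def tr_batch(
    n: int,
    rng: np.random.Generator,
    noise: float = TR_NOISE,
    two_site_only: bool = False,
    **sample_kwargs,
) -> list[TrainingExample]:
    """Draw ``n`` transformation-network examples from the Table-1 world."""
    out = []
    while len(out) < n:
        scenario, config = sample_scenario(rng, **sample_kwargs)
        if two_site_only and scenario.n_states != 2:
            continue
        out.append(make_tr_example(scenario, config, rng, noise=noise))
    return out
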