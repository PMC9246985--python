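"""Liouvillian structure, the real-eigenvalue propagator, and profile physics."""

import numpy as np
import pytest
from scipy.linalg import expm

from cestnet import (
    AcquisitionConfig,
    ExchangeScenario,
    ValidationError,
    build_liouvillian,
    real_eig_propagator,
    simulate_ap_profile,
    simulate_ip_profile,
)
from cestnet.spin_dynamics import _liouvillian_stack


def _b1_averaged_profile(scenario, config, n_quad=21, width=0.1):
    """Oracle: full matrix-exponential propagation averaged over a Gaussian
    B1 distribution (fractional width 10%), the classical dephasing route."""
    b1_grid = config.b1 * (1.0 + width * np.linspace(-3, 3, n_quad))
    w = np.exp(-0.5 * ((b1_grid / config.b1 - 1) / width) ** 2)
    w /= w.sum()
    n = scenario.n_states
    m0 = np.zeros(6 * n)
    m0[2::6] = scenario.populations
    m0[5::6] = -scenario.populations
    detect = np.zeros(6 * n)
    detect[2], detect[5] = 1.0, -1.0
    sig = np.zeros(config.n_offsets)
    for b1, wt in zip(b1_grid, w):
        L = _liouvillian_stack(scenario, config, config.offsets, "ap", b1=b1)
        for i in range(config.n_offsets):
            sig[i] += wt * detect @ expm(-L[i] * config.t_ex) @ m0
    L0 = _liouvillian_stack(scenario, config, config.offsets[:1], "ap", b1=0.0)[0]
    ref = detect @ expm(-L0 * config.t_ex) @ m0
    return sig / ref


class TestLiouvillianStructure:
    def test_free_precession_block(self, single_site):
        """One state, B1 = 0, J = 0: 2x2 transverse block with eigenvalues
        R2 +- i*Omega and a 1x1 longitudinal block with eigenvalue R1."""
        cfg = AcquisitionConfig(b0=18.8, b1=0.0, offsets=np.linspace(6.6, 10.0, 5))
        L = build_liouvillian(single_site, cfg, offset=8.0, phase="ip")
        assert L.dim == 3
        lam = np.linalg.eigvals(L.matrix)
        from cestnet import relaxation_rates

        rates = relaxation_rates(8.0, 18.8)
        r2 = rates["R2_H"] + 1.0  # + R_ex
        omega = 2 * np.pi * (8.3 - 8.0) * cfg.larmor
        expected = {r2 + 1j * omega, r2 - 1j * omega, rates["R1_H"]}
        for e in expected:
            assert min(abs(lam - e)) < 1e-8 * max(abs(e), 1.0)

    def test_ap_degenerate_doublet_at_j_zero(self, single_site, config):
        sc = single_site.replace(j_hn=0.0)
        L = build_liouvillian(sc, config, offset=8.0, phase="ap")
        np.testing.assert_allclose(L.matrix[:3, :3], L.matrix[3:6, 3:6])

    def test_two_site_ap_dimension(self, two_site, config):
        L = build_liouvillian(two_site, config, offset=8.0, phase="ap")
        assert L.matrix.shape == (12, 12)
        assert len(L.basis) == 12

    def test_unknown_phase(self, two_site, config):
        with pytest.raises(ValidationError):
            build_liouvillian(two_site, config, 8.0, phase="xy")


class TestRealEigPropagator:
    def test_full_real_spectrum_is_exact_exponential(self):
        L = np.diag([11.0, 11.0, 0.03])
        P = real_eig_propagator(L, 0.4)
        np.testing.assert_allclose(P, expm(-L * 0.4), rtol=1e-12)

    def test_free_spin_keeps_only_longitudinal(self, single_site):
        """Offset != 0, B1 = 0: transverse components map to 0, Hz decays
        with R1 (only one real eigenvalue in the 3x3 Bloch matrix)."""
        cfg = AcquisitionConfig(b0=18.8, b1=0.0, offsets=np.linspace(6.6, 10.0, 5))
        L = build_liouvillian(single_site, cfg, offset=9.0, phase="ip")
        P = real_eig_propagator(L, 0.4)
        from cestnet import relaxation_rates

        r1 = relaxation_rates(8.0, 18.8)["R1_H"]
        expected = np.zeros((3, 3))
        expected[2, 2] = np.exp(-r1 * 0.4)
        np.testing.assert_allclose(P, expected, atol=1e-10)

    def test_semigroup_on_projected_subspace(self, two_site, config):
        L = build_liouvillian(two_site, config, offset=8.3, phase="ap")
        P1, P2 = real_eig_propagator(L, 0.1), real_eig_propagator(L, 0.3)
        P3 = real_eig_propagator(L, 0.4)
        np.testing.assert_allclose(P1 @ P2, P3, atol=1e-8)

    def test_propagator_is_real(self, three_site, config):
        L = build_liouvillian(three_site, config, offset=8.0, phase="ap")
        P = real_eig_propagator(L, 0.4)
        assert P.dtype == float and np.all(np.isfinite(P))


class TestProfiles:
    def test_j_zero_ap_equals_ip(self, two_site, config):
        sc = two_site.replace(j_hn=0.0)
        ap = simulate_ap_profile(sc, config, inept="ideal")
        ip = simulate_ip_profile(sc, config)
        np.testing.assert_allclose(ap.intensities, ip.intensities, atol=1e-10)

    def test_b1_zero_reference_consistency(self, two_site):
        cfg = AcquisitionConfig(b0=18.8, b1=0.0, offsets=np.linspace(6.6, 10.0, 40))
        for sim in (simulate_ip_profile, simulate_ap_profile):
            prof = sim(two_site, cfg)
            np.testing.assert_allclose(prof.intensities, 1.0, atol=1e-8)

    def test_far_off_resonance_no_saturation(self, single_site):
        cfg = AcquisitionConfig(b0=18.8, b1=30.0, offsets=np.linspace(20.0, 23.4, 20))
        prof = simulate_ip_profile(single_site, cfg)
        np.testing.assert_allclose(prof.intensities, 1.0, atol=1e-2)

    def test_on_resonance_dip(self, single_site, config):
        prof = simulate_ip_profile(single_site, config)
        i = np.argmin(prof.intensities)
        assert abs(prof.offsets[i] - 8.3) < config.span / config.n_offsets
        assert prof.intensities[i] < 0.2

    def test_dip_depth_monotone_in_population(self, two_site, config):
        deep = simulate_ip_profile(two_site.replace(p_g=0.90, p_e1=0.10), config)
        shallow = simulate_ip_profile(two_site.replace(p_g=0.98, p_e1=0.02), config)
        idx = np.argmin(np.abs(config.offsets - 9.2))
        assert deep.intensities[idx] < shallow.intensities[idx]

    def test_ip_bounded(self, three_site, config):
        prof = simulate_ip_profile(three_site, config)
        assert np.all(prof.intensities >= -1e-10)
        assert np.all(prof.intensities <= 1.0 + 1e-8)

    def test_ap_doublet_separation_matches_j(self, single_site):
        """At weak B1 the anti-phase dip resolves into two lobes whose
        separation tracks |J_HN| (93 Hz here)."""
        cfg = AcquisitionConfig(
            b0=18.8, b1=5.0, offsets=np.linspace(6.6, 10.0, 800), t_ex=0.4
        )
        ap = simulate_ap_profile(single_site, cfg)
        dip = np.max(ap.intensities) - ap.intensities
        order = np.argsort(dip)[::-1]
        first = order[0]
        # second extremum: deepest point at least 5 grid steps away
        second = next(i for i in order if abs(i - first) > 5)
        sep_hz = abs(cfg.offsets[first] - cfg.offsets[second]) * cfg.larmor
        assert sep_hz == pytest.approx(93.0, rel=0.15)

    def test_explicit_inept_attenuates_but_preserves_shape(self, two_site, config):
        ideal = simulate_ap_profile(two_site, config, inept="ideal")
        explicit = simulate_ap_profile(two_site, config, inept="explicit")
        # normalized profiles nearly identical: INEPT losses largely cancel in I/I0
        assert np.max(np.abs(ideal.intensities - explicit.intensities)) < 0.02

    def test_invalid_inept_mode(self, two_site, config):
        with pytest.raises(ValidationError):
            simulate_ap_profile(two_site, config, inept="magic")


class TestDephasingOracle:
    def test_matches_b1_distribution_average(self, two_site):
        """Real-eigenvalue projection vs. Gaussian B1-inhomogeneity averaging
        of the full matrix exponential (three spot checks; the twenty-scenario
        sweep lives in the acceptance suite)."""
        rng = np.random.default_rng(11)
        for _ in range(3):
            sc = two_site.replace(
                w_e1=float(rng.uniform(6.8, 9.8)),
                kex_ge1=float(rng.uniform(20, 250)),
                p_g=1 - 0.08, p_e1=0.08,
            )
            cfg = AcquisitionConfig(
                b0=18.8, b1=float(rng.uniform(20, 45)),
                offsets=np.linspace(6.6, 10.0, 60), t_ex=0.4,
            )
            fast = simulate_ap_profile(sc, cfg).intensities
            oracle = _b1_averaged_profile(sc, cfg)
            rms = np.sqrt(np.mean((fast - oracle) ** 2))
            assert rms < 0.01
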