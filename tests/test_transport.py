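"""Kramers permeability, Smoluchowski oracle, MFPT, Markov rates and currents."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import gaussian_profile
from porinflux import (
    FES1D,
    RateSet,
    TransportConfig,
    current_curve,
    markov_current,
    mfpt,
    permeability,
    rates_from_fes,
    reference_to_bulk,
    smoluchowski_flux,
    splitting_probability,
)
from porinflux.constants import MOLAR_TO_PER_A3, kT
from porinflux.ctmc import discrete_mfpt


def make_flat(L=40.0, n=401):
    z = np.linspace(-L / 2, L / 2, n)
    return reference_to_bulk(FES1D(z, np.zeros_like(z)))


def square_barrier(height, width, L=40.0, n=4001):
    """Flat channel with a centered square barrier (sharp but grid-resolved)."""
    z = np.linspace(-L / 2, L / 2, n)
    F = np.where(np.abs(z) <= width / 2, height, 0.0)
    return FES1D(z, F, channel=(-L / 2, L / 2),
                 bulk_windows=((-L / 2, -L / 2), (L / 2, L / 2)))


class TestPermeability:
    def test_flat_profile_closed_form(self):
        """Free diffusion: P = D σ γ / L, current ≈ 1.37e3 /s at 1 µM."""
        fes = make_flat()
        cfg = TransportConfig(D=1.0, sigma_ref=math.pi * 17**2, channel=(-20, 20))
        P = permeability(fes, cfg)
        closed = 100.0 * math.pi * 17**2 * MOLAR_TO_PER_A3 / 40.0 * 1e9
        assert P == pytest.approx(closed, rel=1e-3)
        assert P * 1e-6 == pytest.approx(1.37e3, rel=0.01)

    def test_square_barrier_attenuation(self):
        """P ratio vs flat ≈ L / ((L−w) + w e^{βΔF}) → (L/w) e^{−βΔF}."""
        cfg = TransportConfig(D=1.0, channel=(-20, 20))
        L, w, dF = 40.0, 4.0, 5.0
        beta = 1 / kT(300.0)
        P_flat = permeability(make_flat(), cfg)
        P_bar = permeability(square_barrier(dF, w), cfg)
        exact = L / ((L - w) + w * math.exp(beta * dF))
        assert P_bar / P_flat == pytest.approx(exact, rel=5e-3)
        assert P_bar / P_flat == pytest.approx((L / w) * math.exp(-beta * dF), rel=0.05)

    def test_huge_barrier_no_overflow(self):
        fes = square_barrier(500.0, 4.0)
        P = permeability(fes, TransportConfig(channel=(-20, 20)))
        assert P == 0.0  # underflows cleanly in log-space

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_smoluchowski_oracle(self, seed):
        rng = np.random.default_rng(seed)
        fes = gaussian_profile(barrier=rng.uniform(0, 8),
                               wells=[(rng.uniform(0, 2), rng.uniform(-8, 8))])
        cfg = TransportConfig()
        c = 1e-6
        J_kramers = permeability(fes, cfg) * c
        J_fd = smoluchowski_flux(fes, cfg, c, 0.0, n_grid=2000)
        assert J_kramers == pytest.approx(J_fd, rel=0.01)


class TestSmoluchowski:
    def test_flat_matches_closed_form(self):
        fes = make_flat()
        cfg = TransportConfig(D=1.0, channel=(-20, 20))
        J = smoluchowski_flux(fes, cfg, 1e-6, 0.0, n_grid=2000)
        closed = 100.0 * math.pi * 17**2 * MOLAR_TO_PER_A3 / 40.0 * 1e9 * 1e-6
        assert J == pytest.approx(closed, rel=1e-3)

    def test_equilibrium_zero_flux(self, barrier_well_profile):
        cfg = TransportConfig()
        J = smoluchowski_flux(barrier_well_profile, cfg, 1e-3, 1e-3)
        scale = smoluchowski_flux(barrier_well_profile, cfg, 1e-3, 0.0)
        assert abs(J) < 1e-10 * abs(scale)

    def test_antisymmetry_on_symmetric_profile(self):
        fes = gaussian_profile(barrier=3.0)
        cfg = TransportConfig()
        assert smoluchowski_flux(fes, cfg, 1e-4, 0.0) == pytest.approx(
            -smoluchowski_flux(fes, cfg, 0.0, 1e-4), rel=1e-9)

    def test_small_grid_rejected(self, flat_profile):
        with pytest.raises(ValueError):
            smoluchowski_flux(flat_profile, TransportConfig(), 1e-6, 0, n_grid=50)


class TestMfpt:
    def test_flat_midpoint_matches_discrete_oracle(self):
        fes = make_flat()
        cfg = TransportConfig(D=1.0, channel=(-20, 20))
        T = mfpt(fes, cfg, 0.0)
        assert T == pytest.approx(40**2 / (8 * 100.0), rel=1e-6)  # L²/8D
        T_disc = discrete_mfpt(fes, cfg, 0.0, n_sites=801)
        assert T == pytest.approx(T_disc, rel=0.02)

    def test_oracle_agreement_with_barrier_and_well(self, barrier_well_profile):
        cfg = TransportConfig()
        z_w = 5.0
        T = mfpt(barrier_well_profile, cfg, z_w)
        T_disc = discrete_mfpt(barrier_well_profile, cfg, z_w, n_sites=1601)
        assert T == pytest.approx(T_disc, rel=0.02)

    def test_infinite_barrier_reduces_to_single_absorbing_end(self):
        # 20 kcal/mol wall between the start and the cis end
        z = np.linspace(-20, 20, 2001)
        F = 20.0 * np.exp(-((z + 10) ** 2) / 2)
        fes = FES1D(z, F, channel=(-20, 20))
        cfg = TransportConfig(channel=(-20, 20))
        both = mfpt(fes, cfg, 5.0)
        single = mfpt(fes, cfg, 5.0, reflecting="cis")
        assert both == pytest.approx(single, rel=1e-3)

    def test_inverse_diffusion_scaling(self, barrier_well_profile):
        t1 = mfpt(barrier_well_profile, TransportConfig(D=1.0), 5.0)
        t4 = mfpt(barrier_well_profile, TransportConfig(D=4.0), 5.0)
        assert t1 == pytest.approx(4 * t4, rel=1e-12)

    def test_start_outside_boundaries_rejected(self, flat_profile):
        with pytest.raises(ValueError, match="outside"):
            mfpt(flat_profile, TransportConfig(), 35.0, boundaries=(-20, 20))


class TestRates:
    def test_symmetric_profile_symmetric_rates(self):
        fes = gaussian_profile(barrier=4.0, wells=[(1.5, -6.0), (1.5, 6.0)])
        # two symmetric wells: pick either; koffs must mirror
        with pytest.warns(UserWarning, match="wells within"):
            rates = rates_from_fes(fes, TransportConfig())
        assert rates.phi_cis + rates.phi_trans == pytest.approx(1.0, abs=1e-9)
        # centered well between symmetric flanks: exits split evenly
        fes_c = gaussian_profile(barrier=0.0, wells=[(2.0, 0.0)])
        rates_c = rates_from_fes(fes_c, TransportConfig())
        assert rates_c.phi_cis == pytest.approx(0.5, abs=1e-6)
        assert rates_c.koff_cis == pytest.approx(rates_c.koff_trans, rel=1e-6)
        # barrier-only profile: fallback occupied state, flagged
        rates_b = rates_from_fes(gaussian_profile(barrier=4.0), TransportConfig())
        assert rates_b.flags == ["no_well:deepest_interior_point"]

    def test_dwell_time_identity(self):
        rates = RateSet(kon_cis=1e9, kon_trans=1e9, koff_cis=6e6, koff_trans=4e6,
                        tau_b=1.0 / (6e6 + 4e6), phi_cis=0.6, phi_trans=0.4,
                        well_z=0.0)
        assert rates.tau_b == pytest.approx(1e-7, rel=1e-12)

    @pytest.mark.parametrize("seed", range(3))
    def test_eq1_identity_and_slope_consistency(self, seed):
        rng = np.random.default_rng(seed + 100)
        fes = gaussian_profile(barrier=rng.uniform(1, 5),
                               wells=[(rng.uniform(1, 4), rng.uniform(-6, 6))])
        cfg = TransportConfig()
        rates = rates_from_fes(fes, cfg)
        assert rates.tau_b * (rates.koff_trans + rates.koff_cis) == pytest.approx(
            1.0, rel=1e-12)
        # Markov slope at c→0 equals the Kramers permeability by construction
        c = 1e-15
        assert markov_current(rates, c) / c == pytest.approx(
            permeability(fes, cfg), rel=1e-9)

    def test_splitting_probability_flat(self, default_config):
        fes = make_flat()
        phi = splitting_probability(fes, default_config, 10.0, boundaries=(-20, 20))
        assert phi == pytest.approx(0.75, abs=1e-6)  # linear in position


class TestMarkovCurrent:
    def test_saturation_limit_is_koff_trans(self, barrier_well_profile):
        rates = rates_from_fes(barrier_well_profile, TransportConfig())
        k_half = (rates.koff_cis + rates.koff_trans) / rates.kon_cis
        I = markov_current(rates, 1e6 * k_half)
        assert abs(I / rates.koff_trans - 1) < 1e-5
        assert I <= rates.koff_trans

    def test_equal_concentrations_symmetric_channel_zero(self):
        rates = RateSet(kon_cis=2e9, kon_trans=2e9, koff_cis=5e6, koff_trans=5e6,
                        tau_b=1e-7, phi_cis=0.5, phi_trans=0.5, well_z=0.0)
        assert markov_current(rates, 1e-3, 1e-3) == pytest.approx(0.0, abs=1e-20)

    def test_all_zero_input(self):
        rates = RateSet(kon_cis=0, kon_trans=0, koff_cis=0, koff_trans=0,
                        tau_b=np.inf, phi_cis=0.5, phi_trans=0.5, well_z=0.0)
        assert markov_current(rates, 0.0, 0.0) == 0.0

    @settings(deadline=None, derandomize=True, max_examples=30)
    @given(st.floats(1e-9, 1e-1), st.floats(1e3, 1e12), st.floats(1e3, 1e12))
    def test_bounded_and_positive_with_empty_trans(self, c, kofft, koffc):
        rates = RateSet(kon_cis=1e9, kon_trans=1e9, koff_cis=koffc,
                        koff_trans=kofft, tau_b=1 / (kofft + koffc),
                        phi_cis=koffc / (kofft + koffc),
                        phi_trans=kofft / (kofft + koffc), well_z=0.0)
        I = markov_current(rates, c)
        assert 0.0 <= I <= kofft


class TestCurrentCurve:
    def test_deeper_well_saturates_earlier(self):
        cfg = TransportConfig()
        shallow = gaussian_profile(barrier=3.0, wells=[(2.0, 5.0)])
        deep = gaussian_profile(barrier=3.0, wells=[(4.0, 5.0)])
        c = np.geomspace(1e-6, 1e-1, 10)
        cc_s = current_curve(shallow, cfg, c)
        cc_d = current_curve(deep, cfg, c)
        assert cc_d.k_half < cc_s.k_half

    def test_barrier_ordering_sets_current_ordering(self):
        cfg = TransportConfig()
        c = np.geomspace(1e-6, 1e-3, 5)
        currents = {}
        for name, barrier in (("A", 4.5), ("B", 3.5), ("C", 2.5)):
            fes = gaussian_profile(barrier=barrier)
            currents[name] = current_curve(fes, cfg, c).current[0]
        assert currents["C"] > currents["B"] > currents["A"]

    def test_flat_profile_linear_then_saturating(self, default_config):
        fes = make_flat()
        cfg = TransportConfig(channel=(-20, 20))
        c = np.geomspace(1e-8, 1e3, 40)
        cc = current_curve(fes, cfg, c)
        assert cc.imax == pytest.approx(cc.rates.koff_trans)
        assert np.all(np.diff(cc.current) >= -1e-9)  # nondecreasing
        assert np.all(cc.current <= cc.imax * (1 + 1e-12))
        lin = cc.current / cc.concentration
        assert lin[0] == pytest.approx(cc.permeability, rel=1e-6)
        assert cc.c_sat90 == pytest.approx(9 * cc.k_half, rel=1e-12)

    def test_bad_grid_rejected(self, flat_profile, default_config):
        with pytest.raises(ValueError):
            current_curve(flat_profile, default_config, np.array([1e-3, 1e-4]))


class TestProperties:
    def test_arrhenius_square_barriers(self):
        """ln P vs barrier height: linear with slope −β, R² > 0.999."""
        cfg = TransportConfig(channel=(-20, 20))
        heights = np.arange(4.0, 10.1, 1.0)  # barrier-dominated regime
        logP = np.array([math.log(permeability(square_barrier(h, 4.0), cfg))
                         for h in heights])
        slope, intercept = np.polyfit(heights, logP, 1)
        resid = logP - (slope * heights + intercept)
        r2 = 1 - resid.var() / logP.var()
        assert r2 > 0.999
        assert slope == pytest.approx(-1 / kT(300.0), rel=0.02)

    def test_gauge_invariance_downstream(self):
        z = np.linspace(-25, 25, 501)
        F = 3.0 * np.exp(-z**2 / 18) - 2.0 * np.exp(-(z - 5) ** 2 / 8)
        t = np.clip((25 - np.abs(z)) / 5, 0, 1)
        m = t * t * (3 - 2 * t)
        a = reference_to_bulk(FES1D(z, F * m))
        b = reference_to_bulk(FES1D(z, F * m + 12.3))
        cfg = TransportConfig()
        assert permeability(a, cfg) == pytest.approx(permeability(b, cfg), rel=1e-9)
        assert rates_from_fes(a, cfg).koff_trans == pytest.approx(
            rates_from_fes(b, cfg).koff_trans, rel=1e-9)

    def test_near_barrierless_current_decade(self):
        """At 1 µM with default D, a low-barrier channel passes 10²–10⁴ /s."""
        fes = gaussian_profile(barrier=1.0)
        I = permeability(fes, TransportConfig()) * 1e-6
        assert 1e2 < I < 1e4

    def test_sub_4kcal_barriers_dwell_below_microsecond(self):
        for barrier, well in ((4.0, None), (3.0, (1.0, 5.0))):
            fes = gaussian_profile(barrier=barrier, wells=[well] if well else None)
            rates = rates_from_fes(fes, TransportConfig())
            assert rates.tau_b < 1e-6
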