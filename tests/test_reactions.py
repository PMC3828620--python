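"""Kinetics classes: mass action, direct rates, multi-compartment scaling."""

import numpy as np
import pytest

import dendrochem as dc


@pytest.fixture
def single_compartment():
    morph = dc.Morphology()
    sec = morph.create_section("s", L=1.0, diam=1.0, nseg=1)
    return dc.Region([sec], name="r"), sec


def hwo_model(region, kf, kb, mass_action=True, h0=0.3, o0=0.2, w0=0.1):
    H = dc.Species(region, name="H", initial=h0)
    O = dc.Species(region, name="O", initial=o0)
    W = dc.Species(region, name="W", initial=w0)
    rxn = dc.Reaction(2 * H + O, W, kf, kb, mass_action=mass_action)
    model = dc.Model(species=[H, O, W], reactions=[rxn])
    model.initialize()
    return model, H, O, W


class TestMassAction:
    @pytest.mark.parametrize("seed", range(5))
    def test_hydrogen_rate_formula(self, single_compartment, seed):
        """2H+O<->W: d[H]/dt = -2 kf H^2 O + 2 kb W, exactly."""
        region, _ = single_compartment
        rng = np.random.default_rng(seed)
        h, o, w = rng.uniform(0.05, 2.0, size=3)
        kf, kb = rng.uniform(0.1, 5.0, size=2)
        model, H, O, W = hwo_model(region, kf, kb, h0=h, o0=o, w0=w)
        rhs = model.rhs_full(model.state)
        flux = kf * h * h * o - kb * w
        assert rhs[H.nodes[0].index] == pytest.approx(-2 * flux, abs=1e-14)
        assert rhs[O.nodes[0].index] == pytest.approx(-flux, abs=1e-14)
        assert rhs[W.nodes[0].index] == pytest.approx(flux, abs=1e-14)

    def test_explicit_rates_variant(self, single_compartment):
        """mass_action=False: d[O]/dt = kb - kf and d[H]/dt = 2(kb - kf)."""
        region, _ = single_compartment
        kf, kb = 2.0, 0.5
        model, H, O, W = hwo_model(region, kf, kb, mass_action=False)
        rhs = model.rhs_full(model.state)
        assert rhs[O.nodes[0].index] == pytest.approx(kb - kf, abs=1e-14)
        assert rhs[H.nodes[0].index] == pytest.approx(2 * (kb - kf), abs=1e-14)
        assert rhs[W.nodes[0].index] == pytest.approx(kf - kb, abs=1e-14)

    def test_zero_state_zero_flux(self, single_compartment):
        region, _ = single_compartment
        model, H, O, W = hwo_model(region, 3.0, 0.0, h0=0.0, o0=0.0, w0=0.0)
        assert not np.any(model.rhs_full(model.state))

    def test_equilibrium_is_fixed_point(self, single_compartment):
        """kf·H²·O = kb·W gives exactly zero flux."""
        region, _ = single_compartment
        h, o = 0.5, 0.8
        kf, kb = 2.0, 4.0
        w = kf * h * h * o / kb
        model, *_ = hwo_model(region, kf, kb, h0=h, o0=o, w0=w)
        assert np.max(np.abs(model.rhs_full(model.state))) < 1e-14

    def test_mass_conservation_under_integration(self, single_compartment):
        """2·[W] + [H] and [W] + [O] are invariants of the closed scheme."""
        region, _ = single_compartment
        model, H, O, W = hwo_model(region, 5.0, 1.0)
        def moieties():
            return (
                H.nodes[0].concentration + 2 * W.nodes[0].concentration,
                O.nodes[0].concentration + W.nodes[0].concentration,
            )
        before = moieties()
        model.run_fixed(5.0, dt=0.01)
        after = moieties()
        assert after == pytest.approx(before, rel=1e-8)


class TestRate:
    def test_direct_rhs_contribution(self, single_compartment):
        region, _ = single_compartment
        kd = dc.Parameter(0.5, name="kd")
        ip3 = dc.Species(region, name="ip3", initial=1.0)
        deg = dc.Rate(ip3, -ip3 / (kd + ip3))
        model = dc.Model(species=[ip3], reactions=[deg])
        model.initialize()
        rhs = model.rhs_full(model.state)
        assert rhs[ip3.nodes[0].index] == pytest.approx(-1.0 / 1.5, rel=1e-14)

    def test_two_rates_sum(self, single_compartment):
        region, _ = single_compartment
        s = dc.Species(region, name="s", initial=2.0)
        model = dc.Model(
            species=[s], reactions=[dc.Rate(s, -s), dc.Rate(s, 3.0)]
        )
        model.initialize()
        rhs = model.rhs_full(model.state)
        assert rhs[s.nodes[0].index] == pytest.approx(1.0, rel=1e-14)

    def test_catalyst_has_zero_net_contribution(self, single_compartment):
        region, _ = single_compartment
        e = dc.Species(region, name="e", initial=0.4)
        s = dc.Species(region, name="s", initial=0.9)
        p = dc.Species(region, name="p", initial=0.0)
        rxn = dc.Reaction(e + s, e + p, 2.0)
        model = dc.Model(species=[e, s, p], reactions=[rxn])
        model.initialize()
        rhs = model.rhs_full(model.state)
        assert rhs[e.nodes[0].index] == 0.0
        assert rhs[s.nodes[0].index] == pytest.approx(-2.0 * 0.4 * 0.9)


class TestLocalization:
    def test_defaults_to_shared_regions(self, simple_cable):
        """A reaction activates exactly where all of its actors coexist."""
        _, sec, cyt = simple_cable
        er = dc.Region([sec], name="er", geometry=dc.FractionalVolume(0.2))
        a = dc.Species([cyt, er], name="a", initial=1.0)
        b = dc.Species([cyt], name="b", initial=1.0)
        rxn = dc.Reaction(a, b, 1.0)
        model = dc.Model(species=[a, b], reactions=[rxn])
        model.initialize()
        rhs = model.rhs_full(model.state)
        a_cyt = [n.index for n in a[cyt].nodes]
        a_er = [n.index for n in a[er].nodes]
        assert np.all(rhs[a_cyt] != 0.0)
        assert not np.any(rhs[a_er])

    def test_regions_override(self, simple_cable):
        _, sec, cyt = simple_cable
        er = dc.Region([sec], name="er", geometry=dc.FractionalVolume(0.2))
        a = dc.Species([cyt, er], name="a", initial=1.0)
        rxn = dc.Rate(a, -a, regions=[er])
        model = dc.Model(species=[a], reactions=[rxn])
        model.initialize()
        rhs = model.rhs_full(model.state)
        assert not np.any(rhs[[n.index for n in a[cyt].nodes]])
        assert np.all(rhs[[n.index for n in a[er].nodes]] != 0.0)


@pytest.fixture
def er_cyt():
    morph = dc.Morphology()
    sec = morph.create_section("s", L=5.0, diam=1.0, nseg=3)
    cyt = dc.Region([sec], nrn_region="i", name="cyt",
                    geometry=dc.FractionalVolume(0.8))
    er = dc.Region([sec], name="er", geometry=dc.FractionalVolume(0.2))
    mem = dc.Membrane(radius_fraction=0.4)
    return sec, cyt, er, mem


class TestMultiCompartment:
    def test_requires_region_qualification(self, er_cyt):
        _, cyt, er, mem = er_cyt
        ca = dc.Species([cyt, er], name="ca", initial=0.001)
        with pytest.raises(dc.ReactionError):
            dc.MultiCompartmentReaction(ca, ca, 1.0, membrane=mem)

    def test_volume_scaling_ratio(self, er_cyt):
        """Equal molecular flux into compartments of volume V and 4V gives
        concentration rates in ratio 4:1."""
        sec, cyt, er, mem = er_cyt
        ca = dc.Species([cyt, er], name="ca", initial=0.001)
        pump = dc.MultiCompartmentReaction(ca[cyt], ca[er], 10.0,
                                           membrane=mem)
        model = dc.Model(species=[ca], reactions=[pump])
        model.initialize()
        rhs = model.rhs_full(model.state)
        r_cyt = rhs[ca[cyt].nodes[0].index]
        r_er = rhs[ca[er].nodes[0].index]
        assert r_er == pytest.approx(-4.0 * r_cyt, rel=1e-12)

    def test_scale_by_area_disabled(self, er_cyt):
        sec, cyt, er, mem = er_cyt
        ca = dc.Species([cyt, er], name="ca", initial=0.001)
        thin = dc.Membrane(radius_fraction=0.1)
        def rate_with(membrane):
            pump = dc.MultiCompartmentReaction(
                ca[cyt], ca[er], 10.0, membrane=membrane, scale_by_area=False
            )
            model = dc.Model(species=[ca], reactions=[pump])
            model.initialize()
            return model.rhs_full(model.state)[ca[er].nodes[0].index]
        assert rate_with(mem) == pytest.approx(rate_with(thin), rel=1e-14)

    def test_moles_conserved_per_step(self, er_cyt):
        """V_A·Δc_A + V_B·Δc_B = 0 each step, to 1e-12 of the transfer."""
        sec, cyt, er, mem = er_cyt
        ca = dc.Species([cyt, er], name="ca", initial=0.001)
        pump = dc.MultiCompartmentReaction(ca[cyt], ca[er], 5.0e4, 2.0e4,
                                           membrane=mem)
        model = dc.Model(species=[ca], reactions=[pump])
        model.initialize()
        ca[er].concentration = 0.0009
        Vc = np.array([n.volume for n in ca[cyt].nodes])
        Ve = np.array([n.volume for n in ca[er].nodes])
        for _ in range(20):
            c0 = ca[cyt].concentration
            e0 = ca[er].concentration
            model.advance(0.05)
            dc_ = ca[cyt].concentration - c0
            de = ca[er].concentration - e0
            transfer = np.max(np.abs(Vc * dc_))
            assert transfer > 0
            assert np.max(np.abs(Vc * dc_ + Ve * de)) <= 1e-12 * transfer

    def test_area_volume_interplay_with_diameter(self):
        """Doubling the diameter doubles membrane area but quadruples the
        full-cross-section volume, halving the concentration rate."""
        rates = {}
        for diam in (1.0, 2.0):
            morph = dc.Morphology()
            sec = morph.create_section("s", L=2.0, diam=diam, nseg=1)
            cyt = dc.Region([sec], nrn_region="i", name="cyt")
            er = dc.Region([sec], name="er",
                           geometry=dc.FractionalVolume(0.5))
            # membrane spans the full radius so its area tracks the diameter
            mem = dc.Membrane()
            ca = dc.Species([cyt, er], name="ca", initial=0.001)
            pump = dc.MultiCompartmentReaction(ca[cyt], ca[er], 10.0,
                                               membrane=mem)
            model = dc.Model(species=[ca], reactions=[pump])
            model.initialize()
            rates[diam] = model.rhs_full(model.state)[ca[cyt].nodes[0].index]
        assert rates[2.0] == pytest.approx(0.5 * rates[1.0], rel=1e-12)


class TestMembraneCurrent:
    def test_unit_conversion(self):
        """1 molecule/(µm²·ms) of a z=+1 species is 1.602177e-5 mA/cm²."""
        # recompute independently from physical constants
        e = 1.602176634e-19  # C
        expected = e * 1e3 * 1e8 * 1e3  # per-ms -> per-s, µm² -> cm², A -> mA
        assert dc.membrane_current_density(1.0, 1) == pytest.approx(
            expected, rel=1e-12
        )
        assert expected == pytest.approx(1.602177e-5, rel=1e-6)

    def test_zero_flux_zero_current(self):
        assert dc.membrane_current_density(0.0, 2) == 0.0

    def test_linearity_in_charge(self):
        assert dc.membrane_current_density(0.7, 2) == pytest.approx(
            2 * dc.membrane_current_density(0.7, 1), rel=1e-14
        )

    def test_uncharged_moving_species_rejected(self, er_cyt):
        _, cyt, er, mem = er_cyt
        glc = dc.Species([cyt, er], name="glc", initial=0.001)  # no charge
        with pytest.raises(dc.ReactionError, match="charge"):
            dc.MultiCompartmentReaction(glc[cyt], glc[er], 1.0, membrane=mem,
                                        membrane_flux=True)

    def test_observable_current(self, er_cyt):
        sec, cyt, er, mem = er_cyt
        ca = dc.Species([cyt, er], name="ca", charge=2, initial=0.001)
        pump = dc.MultiCompartmentReaction(ca[cyt], ca[er], 10.0,
                                           membrane=mem, membrane_flux=True)
        model = dc.Model(species=[ca], reactions=[pump])
        model.initialize()
        currents = model.membrane_currents()
        assert set(currents) == {pump}
        flux = 10.0 * 0.001  # kf * [ca[cyt]] in molecules/µm²/ms
        expected = abs(2 * flux * dc.CURRENT_PER_MOLECULAR_FLUX)
        assert np.allclose(np.abs(currents[pump]), expected, rtol=1e-12)
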