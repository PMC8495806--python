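"""Length-mass conversion, metabolic scaling, and node-loss assembly."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import trophicflux as tf
from trophicflux.allometry import MeanMassFallbackWarning


class TestLengthToMass:
    def test_identity_regression(self):
        reg = tf.LengthMassRegression("id", "log10", intercept=0.0, exp_length=1.0)
        assert tf.length_to_mass(10.0, reg) == pytest.approx(10.0)

    def test_length_width_regression(self):
        reg = tf.LengthMassRegression("lw", "log10", 0.0, 1.0, exp_width=1.0)
        assert tf.length_to_mass(10.0, reg, width=2.0) == pytest.approx(20.0)

    @pytest.mark.parametrize("scale,base", [("log10", 10.0), ("ln", math.e)])
    def test_power_law_matches_hand_evaluation(self, scale, base):
        # independent oracle: evaluate the power law directly
        a, b, L = -0.85, 2.52, 5.0
        reg = tf.LengthMassRegression("t", scale, a, b)
        expected = base ** a * L ** b
        assert tf.length_to_mass(L, reg) == pytest.approx(expected, rel=1e-12)

    def test_dry_output_is_converted(self):
        reg = tf.LengthMassRegression("d", "log10", 0.0, 1.0, mass_basis="dry")
        assert tf.length_to_mass(10.0, reg, dry_to_fresh_factor=4.0) == pytest.approx(40.0)

    def test_errors(self):
        reg_w = tf.LengthMassRegression("lw", "log10", 0.0, 1.0, exp_width=1.0)
        reg = tf.LengthMassRegression("l", "log10", 0.0, 1.0)
        with pytest.raises(ValueError, match="width"):
            tf.length_to_mass(10.0, reg_w)
        with pytest.raises(ValueError, match="length"):
            tf.length_to_mass(0.0, reg)
        with pytest.raises(tf.WebBuildError, match="exponent"):
            tf.LengthMassRegression("bad", "log10", 0.0, exp_length=-1.0)


class TestDryToFresh:
    @pytest.mark.parametrize("dry,factor,expected", [(2.0, 4.0, 8.0), (0.0, 3.0, 0.0)])
    def test_factor_form(self, dry, factor, expected):
        assert tf.dry_to_fresh(dry, factor) == expected

    def test_regression_form_matches_direct_evaluation(self):
        reg = tf.DryFreshRegression("log10", 0.3, 1.1)
        assert tf.dry_to_fresh(2.0, regression=reg) == pytest.approx(
            10 ** (0.3 + 1.1 * math.log10(2.0)), rel=1e-12
        )

    def test_nonpositive_factor_rejected(self):
        with pytest.raises(ValueError):
            tf.dry_to_fresh(1.0, factor=0.0)


class TestMetabolicRate:
    def test_identity_parameters(self, identity_metabolic_regression):
        assert tf.metabolic_rate(2.0, 20.0, identity_metabolic_regression) == pytest.approx(2.0)

    def test_three_quarter_scaling(self):
        reg = tf.MetabolicRegression("q", ln_x0=0.0, mass_exp=0.75)
        assert tf.metabolic_rate(16.0, 20.0, reg) == pytest.approx(8.0)

    def test_increases_with_temperature(self):
        reg = tf.MetabolicRegression("arr", ln_x0=0.0, mass_exp=0.75, activation_energy_eV=0.69)
        assert tf.metabolic_rate(5.0, 25.0, reg) > tf.metabolic_rate(5.0, 15.0, reg)

    def test_arrhenius_form_matches_hand_evaluation(self):
        reg = tf.MetabolicRegression("arr", ln_x0=21.0, mass_exp=0.71, activation_energy_eV=0.69)
        expected = math.exp(21.0 + 0.71 * math.log(3.0) - 0.69 / (tf.BOLTZMANN_EV * 293.15))
        assert tf.metabolic_rate(3.0, 20.0, reg) == pytest.approx(expected, rel=1e-12)

    @given(c=st.floats(0.1, 10.0))
    @settings(max_examples=25, deadline=None)
    def test_scale_consistency(self, c):
        # shifting ln_x0 by ln(c) multiplies X by c exactly
        base = tf.MetabolicRegression("b", ln_x0=1.0, mass_exp=0.75)
        shifted = tf.MetabolicRegression("s", ln_x0=1.0 + math.log(c), mass_exp=0.75)
        assert tf.metabolic_rate(7.0, 20.0, shifted) == pytest.approx(
            c * tf.metabolic_rate(7.0, 20.0, base), rel=1e-12
        )


def two_node_web(**herb_fields):
    nodes = [
        dict(node_id="plant", guild="plant", resource_type="plant", biomass=100.0),
        dict(node_id="herb", guild="herbivore", resource_type="animal", biomass=10.0, **herb_fields),
    ]
    links = [dict(resource_id="plant", consumer_id="herb")]
    return tf.build_web(nodes, links, options=dict(losses_per_unit_biomass=False))


class TestNodeLosses:
    def test_additivity_over_individuals(self, identity_metabolic_regression):
        web = two_node_web(body_masses=(1.0, 1.0))
        out = tf.node_losses(web, {"herbivore": identity_metabolic_regression})
        assert out.node("herb").loss == pytest.approx(2.0)
        assert out.node("plant").loss == 0.0
        assert out.losses_per_unit_biomass is False

    def test_individual_vs_mean_mass_fallback_hand_values(self):
        # X ~ M^0.75: individuals {1, 3} vs fallback mean 2, n=2
        reg = tf.MetabolicRegression("q", ln_x0=0.0, mass_exp=0.75)
        web_ind = two_node_web(body_masses=(1.0, 3.0))
        web_mean = two_node_web(mean_body_mass=2.0, abundance=2.0)
        ind = tf.node_losses(web_ind, {"herbivore": reg}).node("herb").loss
        with pytest.warns(MeanMassFallbackWarning):
            fb = tf.node_losses(web_mean, {"herbivore": reg}).node("herb").loss
        assert ind == pytest.approx(1.0 ** 0.75 + 3.0 ** 0.75, rel=1e-12)
        assert fb == pytest.approx(2.0 * 2.0 ** 0.75, rel=1e-12)
        # concave scaling: the fallback overstates the demand of unequal masses
        assert fb > ind

    def test_fmr_multiplier_scales_losses_exactly(self, identity_metabolic_regression):
        web = two_node_web(body_masses=(1.0, 2.0, 3.0))
        base = tf.node_losses(web, {"herbivore": identity_metabolic_regression})
        fmr = tf.node_losses(web, {"herbivore": identity_metabolic_regression}, fmr_multiplier=3.0)
        assert fmr.node("herb").loss == pytest.approx(3.0 * base.node("herb").loss, rel=1e-12)

    def test_presupplied_loss_kept_and_basis_resolved(self, identity_metabolic_regression):
        nodes = [
            dict(node_id="plant", guild="plant", resource_type="plant", biomass=100.0),
            dict(node_id="herb", guild="herbivore", resource_type="animal", biomass=10.0, loss=0.5),
        ]
        links = [dict(resource_id="plant", consumer_id="herb")]
        web = tf.build_web(nodes, links, options=dict(losses_per_unit_biomass=True))
        out = tf.node_losses(web, {"herbivore": identity_metabolic_regression})
        assert out.node("herb").loss == pytest.approx(0.5 * 10.0)  # per-biomass x biomass

    def test_no_route_to_loss_raises(self, identity_metabolic_regression):
        web = two_node_web()
        with pytest.raises(tf.LossDerivationError, match="herb"):
            tf.node_losses(web, {"herbivore": identity_metabolic_regression})

    def test_missing_regression_raises(self):
        web = two_node_web(body_masses=(1.0,))
        with pytest.raises(tf.LossDerivationError, match="herbivore"):
            tf.node_losses(web, {})

    def test_individual_list_equals_fallback_for_equal_masses(self):
        reg = tf.MetabolicRegression("q", ln_x0=0.3, mass_exp=0.75, activation_energy_eV=0.2)
        web_ind = two_node_web(body_masses=(2.0, 2.0, 2.0))
        web_mean = two_node_web(mean_body_mass=2.0, abundance=3.0)
        ind = tf.node_losses(web_ind, {"herbivore": reg}).node("herb").loss
        with pytest.warns(MeanMassFallbackWarning):
            fb = tf.node_losses(web_mean, {"herbivore": reg}).node("herb").loss
        assert ind == pytest.approx(fb, rel=1e-12)


class TestSizeStructureProperties:
    @given(
        masses=st.lists(st.floats(0.1, 100.0), min_size=2, max_size=12),
        a=st.floats(0.1, 0.95),
    )
    @settings(max_examples=50, deadline=None)
    def test_subdividing_fixed_biomass_raises_joint_demand(self, masses, a):
        # many small individuals demand more than one holding all the biomass
        reg = tf.MetabolicRegression("q", ln_x0=0.0, mass_exp=a)
        total = sum(masses)
        joint = float(np.sum(tf.metabolic_rate(np.asarray(masses), 20.0, reg)))
        lumped = tf.metabolic_rate(total, 20.0, reg)
        assert joint >= lumped * (1 - 1e-12)

    @given(
        masses=st.lists(st.floats(0.1, 100.0), min_size=2, max_size=12, unique=True),
        a=st.floats(0.1, 0.95),
    )
    @settings(max_examples=50, deadline=None)
    def test_mean_mass_fallback_never_understates_at_fixed_count(self, masses, a):
        # Jensen: E[M^a] <= (E[M])^a for concave a, so n * mean^a >= sum M_i^a
        reg = tf.MetabolicRegression("q", ln_x0=0.0, mass_exp=a)
        n = len(masses)
        individual = float(np.sum(tf.metabolic_rate(np.asarray(masses), 20.0, reg)))
        fallback = n * tf.metabolic_rate(float(np.mean(masses)), 20.0, reg)
        assert fallback >= individual * (1 - 1e-12)
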