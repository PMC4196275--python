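import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cisclock.grn_model import (
    CANONICAL_INITIAL_STATE, GrnModel, NeighborSummary, ParameterSet,
    canonical_initial_state, cis_loss_rate, compute_canonical_initial_state,
    hes7_promoter_activity, hill_act, hill_rep, nicd_production_rate,
    rescale_time, species_names,
)


class TestHillFunctions:
    @pytest.mark.parametrize("c,H,h,expected", [
        (0.0, 1.0, 2.0, 1.0),      # no repressor: full activity
        (1.0, 1.0, 2.0, 0.5),      # threshold: half-inhibition
        (4.5, 4.5, 7.0, 0.5),
        (2.0, 1.0, 2.0, 0.2),      # 1/(1+4)
    ])
    def test_repression_values(self, c, H, h, expected):
        assert hill_rep(c, H, h) == pytest.approx(expected)

    @pytest.mark.parametrize("c,H,h,expected", [
        (0.0, 1.0, 2.0, 0.0),
        (4.5, 4.5, 2.0, 0.5),
        (3.0, 1.0, 2.0, 0.9),      # 9/10
    ])
    def test_activation_values(self, c, H, h, expected):
        assert hill_act(c, H, h) == pytest.approx(expected)

    @given(c=st.floats(0, 1e6), H=st.floats(0.01, 100), h=st.floats(1, 8))
    @settings(max_examples=200, deadline=None)
    def test_rep_act_sum_to_one(self, c, H, h):
        assert hill_rep(c, H, h) + hill_act(c, H, h) == pytest.approx(1.0)

    def test_monotonicity(self):
        c = np.linspace(0, 10, 200)
        assert np.all(np.diff(hill_rep(c, 1.0, 2.0)) <= 0)
        assert np.all(np.diff(hill_act(c, 1.0, 2.0)) >= 0)

    @pytest.mark.parametrize("bad", [-1.0, np.nan, np.inf])
    def test_rejects_bad_concentration(self, bad):
        with pytest.raises(ValueError):
            hill_rep(bad, 1.0, 2.0)
        with pytest.raises(ValueError):
            hill_act(bad, 1.0, 2.0)

    def test_rejects_bad_threshold_and_coefficient(self):
        with pytest.raises(ValueError):
            hill_rep(1.0, 0.0, 2.0)
        with pytest.raises(ValueError):
            hill_act(1.0, 1.0, 0.5)


class TestPromoterAndReactions:
    def test_promoter_needs_activator(self):
        # AND logic: without nuclear NICD the Hes7 promoter is silent
        p = ParameterSet()
        assert hes7_promoter_activity(0.0, 0.0, p) == 0.0
        assert hes7_promoter_activity(0.0, 1e9, p) == pytest.approx(1.0, abs=1e-6)

    def test_promoter_half_half(self):
        p = ParameterSet({"hes7": {"h_A": 2.0}})
        assert hes7_promoter_activity(1.0, 4.5, p) == pytest.approx(0.25)

    def test_trans_rate_zero_without_ligand(self):
        p = ParameterSet()
        assert nicd_production_rate(1.0, 0.0, 0.0, p) == 0.0

    def test_trans_rate_unaided_weight(self):
        # without Lfng the reaction runs at the unaided weight r0
        p = ParameterSet()
        expected = p["nicd"]["rDN"] * p["nicd"]["r0"]
        assert nicd_production_rate(1.0, 1.0, 0.0, p) == pytest.approx(expected)

    def test_lfng_promotes_reaction_about_fourfold(self):
        p = ParameterSet()
        unaided = nicd_production_rate(1.0, 1.0, 0.0, p, lfng_enabled=True)
        promoted = nicd_production_rate(1.0, 1.0, 1e9, p, lfng_enabled=True)
        boost = promoted / unaided - 1.0  # LFNG-added : unaided
        assert boost == pytest.approx(1.0 / p["nicd"]["r0"], rel=1e-6)
        assert 3.5 < boost < 4.5

    def test_cis_loss_rate(self):
        assert cis_loss_rate(0.0, 5.0, 0.01) == 0.0
        assert cis_loss_rate(2.0, 3.0, 0.01) == pytest.approx(0.06)
        assert cis_loss_rate(3.0, 2.0, 0.01) == cis_loss_rate(2.0, 3.0, 0.01)


class TestParameterSet:
    def test_defaults_match_standard_constants(self):
        p = ParameterSet()
        assert p["hes7"]["dmC"] == 0.067
        assert p["nicd"]["rDN"] == 0.05
        assert p["dll1"]["k"] == 1.25
        assert p["notch1"]["dm"] == 0.02
        assert p["coupling"]["rDNcis"] == 0.01

    def test_unknown_keys_rejected(self):
        with pytest.raises(KeyError):
            ParameterSet({"hes7": {"bogus": 1.0}})
        with pytest.raises(KeyError):
            ParameterSet({"nogene": {"k": 1.0}})

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            ParameterSet({"hes7": {"k": -1.0}})

    def test_rescale_identity_and_factor(self):
        p = ParameterSet()
        assert rescale_time(p, 1.0) == p
        p2 = rescale_time(p, 2.0)
        assert p2["hes7"]["dmC"] == pytest.approx(2 * p["hes7"]["dmC"])
        assert p2["hes7"]["G"] == pytest.approx(2 * p["hes7"]["G"])
        # denominators and dimensionless weights untouched
        for key in ("H_R", "H_A", "h_R", "h_A", "F"):
            assert p2["hes7"][key] == p["hes7"][key]
        assert p2["nicd"]["r0"] == p["nicd"]["r0"]
        assert p2["nicd"]["raLfng"] == p["nicd"]["raLfng"]

    def test_rescale_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            rescale_time(ParameterSet(), 0.0)
        with pytest.raises(ValueError):
            rescale_time(ParameterSet(), -2.0)


class TestDerivatives:
    def test_zero_state_bootstrap(self, model):
        nb = NeighborSummary(0.0, 0.0, 0)
        d = model.cell_derivatives(dict.fromkeys(model.species, 0.0), nb)
        # Dll1 and Notch1 transcribe at full rate; Hes7 is gated by NICD
        assert d["dll1.mN"] == pytest.approx(1.25)
        assert d["notch1.m"] == pytest.approx(0.5)
        for sp in ("hes7.mN", "hes7.mC", "hes7.pC", "hes7.pN"):
            assert d[sp] == 0.0

    def test_saturated_nuclear_decay_approaches_G(self):
        p = ParameterSet({"hes7": {"epC": 0.0, "epN": 0.0}})
        m = GrnModel(p)
        state = dict.fromkeys(m.species, 0.0)
        state["hes7.pN"] = 1e9
        d = m.cell_derivatives(state, NeighborSummary(0.0, 0.0, 0))
        assert d["hes7.pN"] == pytest.approx(-p["hes7"]["G"], rel=1e-6)

    def test_layout_mismatch_rejected(self, model):
        with pytest.raises(ValueError):
            model.cell_derivatives({"hes7.mN": 1.0}, NeighborSummary(0, 0, 0))
        with pytest.raises(ValueError):
            model.derivatives(np.zeros((3, 5)), np.zeros(3), np.zeros(3))

    def test_cis_loss_shared_between_ligand_and_receptor(self):
        # turning cis on changes dll1 and notch1 pools by the same flux
        base = np.tile(canonical_initial_state(GrnModel()), (1, 1))
        nb = np.zeros(1)
        m_on = GrnModel(ParameterSet({"coupling": {"rDNcis": 0.02}}))
        m_off = GrnModel(ParameterSet({"coupling": {"rDNcis": 0.0}}))
        diff = m_on.derivatives(base, nb, nb) - m_off.derivatives(base, nb, nb)
        ix = m_on.index
        assert diff[0, ix["dll1.pC"]] == pytest.approx(diff[0, ix["notch1.pC"]])
        assert diff[0, ix["dll1.pM"]] == pytest.approx(diff[0, ix["notch1.pM"]])

    def test_trans_reaction_mass_coupling(self, model):
        # the trans flux leaves sender DLL1 and receiver NOTCH1 and enters
        # receiver NICD with identical magnitude
        S = np.tile(canonical_initial_state(model), (2, 1))
        S[1] *= 0.6
        nb_d = S[::-1, model.index["dll1.pM"]].copy()
        nb_n = S[::-1, model.index["notch1.pM"]].copy()
        m_off = GrnModel(ParameterSet({"nicd": {"rDN": 0.0}}))
        diff = model.derivatives(S, nb_d, nb_n) - m_off.derivatives(S, nb_d, nb_n)
        ix = model.index
        flux_in_0 = diff[0, ix["nicd.pC"]]
        assert flux_in_0 > 0
        assert diff[0, ix["notch1.pM"]] == pytest.approx(-flux_in_0)
        assert diff[1, ix["dll1.pM"]] == pytest.approx(-flux_in_0)

    def test_cis_free_reduction(self, model):
        # rDNcis=0 reduces term-by-term to the cis-free coupled system
        S = np.tile(canonical_initial_state(model), (2, 1))
        S[1] *= 0.3
        nb_d = S[::-1, model.index["dll1.pM"]].copy()
        nb_n = S[::-1, model.index["notch1.pM"]].copy()
        m0 = GrnModel(ParameterSet({"coupling": {"rDNcis": 0.0}}))
        d0 = m0.derivatives(S, nb_d, nb_n)
        d1 = model.derivatives(S, nb_d, nb_n)
        ix = model.index
        cis_C = 0.01 * S[:, ix["dll1.pC"]] * S[:, ix["notch1.pC"]]
        cis_M = 0.01 * S[:, ix["dll1.pM"]] * S[:, ix["notch1.pM"]]
        expected = d0.copy()
        for sp, term in (("dll1.pC", cis_C), ("notch1.pC", cis_C),
                         ("dll1.pM", cis_M), ("notch1.pM", cis_M)):
            expected[:, ix[sp]] -= term
        np.testing.assert_allclose(d1, expected, rtol=1e-12)


class TestCanonicalState:
    def test_species_layout(self):
        assert len(species_names()) == 13
        assert len(species_names(lfng_enabled=True)) == 17

    def test_frozen_constants_match_regeneration(self):
        regen = compute_canonical_initial_state()
        for key, val in CANONICAL_INITIAL_STATE.items():
            assert regen[key] == pytest.approx(val, rel=1e-6), key

    def test_lfng_species_start_at_zero(self):
        m = GrnModel(lfng_enabled=True)
        vec = canonical_initial_state(m)
        assert vec.shape == (17,)
        for sp in ("lfng.mN", "lfng.mC", "lfng.pC", "lfng.pN"):
            assert vec[m.index[sp]] == 0.0
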