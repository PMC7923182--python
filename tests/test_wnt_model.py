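"""Extended Wnt model: variants, conservation, promoter competition."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wntrho import (
    NetworkModel,
    PromoterCompetitionParams,
    RateLaw,
    ReactionDef,
    SpeciesDef,
    WntVariantConfig,
    adipogenic_transcription_rate,
    build_wnt_model,
    find_steady_state,
)
from wntrho.wnt import default_wnt_schedule, wnt_conserved_totals


def test_config_requires_tcf_initial_without_feedback():
    with pytest.raises(ValueError, match="tcf_initial"):
        WntVariantConfig("double", tcf_feedback=False)
    with pytest.raises(ValueError, match="competition mode"):
        WntVariantConfig("triple")
    with pytest.raises(ValueError, match="pg_initial"):
        WntVariantConfig("double", pg_initial=-1.0)


def test_conserved_moieties_along_trajectory(wnt_sim):
    """Total APC, GSK3, Dsh and PG stay constant through the Wnt step."""
    y0 = wnt_sim.state_vector({"PG": 200.0})
    traj = wnt_sim.simulate(default_wnt_schedule(), y0=y0, n_out=80)
    t0 = wnt_conserved_totals(dict(zip(traj.species, traj.values[0])))
    for row in traj.values[1:]:
        tk = wnt_conserved_totals(dict(zip(traj.species, row)))
        for key, ref in t0.items():
            assert tk[key] == pytest.approx(ref, rel=1e-6)


def test_tcf_conserved_without_feedback():
    model = build_wnt_model(WntVariantConfig("double", False, tcf_initial=15.0, pg_initial=100.0))
    ss = find_steady_state(model, inputs={"Wnt": 1.0})
    total = ss["TCF"] + ss["Bcat_TCF"] + ss["PG_TCF"]
    assert total == pytest.approx(15.0, rel=1e-6)


def test_wnt_off_steady_state_reference_level(wnt_sim):
    """With PG = 0 and Wnt off, the adipogenic mRNA sits near 0.3 nM."""
    ss = wnt_sim.steady_state(inputs={"Wnt": 0.0})
    assert ss["AdipomRNA"] == pytest.approx(0.3, rel=1e-3)


def test_beta_catenin_rises_under_wnt_step(wnt_sim):
    off = wnt_sim.steady_state(inputs={"Wnt": 0.0})
    on = wnt_sim.steady_state(y0=off.vector(wnt_sim.species), inputs={"Wnt": 1.0})
    assert on["Bcat"] > 2 * off["Bcat"]


def test_tcf_insensitive_to_pg(wnt_sim):
    """With the regulatory loop, steady-state free TCF moves < 1% over the PG grid."""
    levels = []
    for pg in (0.0, 250.0, 500.0):
        ss = wnt_sim.steady_state(y0=wnt_sim.state_vector({"PG": pg}), inputs={"Wnt": 0.0})
        levels.append(ss["TCF"])
    assert max(levels) / min(levels) - 1 < 0.01


class TestVariantContrasts:
    def test_double_competition_monotone_in_pg(self, titration):
        s = titration.summary
        assert s["adipo_off"].is_monotonic_increasing
        assert s["adipo_on"].is_monotonic_increasing

    def test_single_competition_flat_in_pg(self, titration_single):
        s = titration_single.summary
        for col in ("adipo_off", "adipo_on"):
            rel_spread = s[col].max() / s[col].min() - 1
            assert rel_spread < 0.05

    def test_no_feedback_rises_in_both_wnt_states(self, titration_nofeedback):
        s = titration_nofeedback.summary
        assert s["adipo_off"].is_monotonic_increasing
        assert s["adipo_on"].is_monotonic_increasing
        assert s["adipo_on"].iloc[-1] > 1.2 * s["adipo_on"].iloc[0]

    def test_variant_separation(self, titration, titration_single, titration_nofeedback):
        def spread(res, col):
            return res.summary[col].max() - res.summary[col].min()

        for col in ("adipo_off", "adipo_on"):
            assert spread(titration, col) > spread(titration_single, col)
            assert spread(titration_nofeedback, col) > 0


class TestPromoterCompetition:
    def test_empty_promoter_gives_basal(self):
        params = PromoterCompetitionParams(basal=2.0, act=5.0, K_act=1.0, K_rep=1.0)
        assert adipogenic_transcription_rate(0.0, 0.0, params) == pytest.approx(2.0)

    def test_saturating_activator_limit(self):
        params = PromoterCompetitionParams(basal=2.0, act=5.0, K_act=1.0, K_rep=1.0)
        assert adipogenic_transcription_rate(3.0, 1e9, params) == pytest.approx(5.0, rel=1e-6)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            adipogenic_transcription_rate(-1.0, 0.0)

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(
        b=st.floats(0.0, 200.0),
        p=st.floats(0.0, 200.0),
        db=st.floats(0.1, 50.0),
        dp=st.floats(0.1, 50.0),
    )
    def test_monotonicity(self, b, p, db, dp):
        """Increasing PG/TCF raises the rate; increasing beta-catenin/TCF lowers it
        (defaults have act > basal)."""
        r = adipogenic_transcription_rate(b, p)
        assert adipogenic_transcription_rate(b, p + dp) > r
        assert adipogenic_transcription_rate(b + db, p) < r

    @pytest.mark.parametrize("b, p", [(0.0, 0.0), (40.0, 10.0), (5.0, 120.0), (200.0, 1.0)])
    def test_closed_form_matches_three_state_micromodel(self, b, p):
        """The occupancy law equals the steady state of an explicit
        free/B-bound/P-bound promoter micro-model."""
        params = PromoterCompetitionParams(basal=1.0, act=4.0, K_act=3.0, K_rep=20.0)
        kon = 10.0  # fast binding; K values set the off-rates
        micro = NetworkModel(
            "promoter",
            [
                SpeciesDef("E", 1.0),
                SpeciesDef("EB", 0.0),
                SpeciesDef("EP", 0.0),
                SpeciesDef("B", b, is_boundary=True),
                SpeciesDef("P", p, is_boundary=True),
            ],
            [
                ReactionDef("bon", [("E", 1), ("B", 1)], [("EB", 1), ("B", 1)],
                            RateLaw("mass_action", {"k": kon}, {"substrates": ["E", "B"]})),
                ReactionDef("boff", [("EB", 1)], [("E", 1)],
                            RateLaw("mass_action", {"k": kon * params.K_rep})),
                ReactionDef("pon", [("E", 1), ("P", 1)], [("EP", 1), ("P", 1)],
                            RateLaw("mass_action", {"k": kon}, {"substrates": ["E", "P"]})),
                ReactionDef("poff", [("EP", 1)], [("E", 1)],
                            RateLaw("mass_action", {"k": kon * params.K_act})),
            ],
        )
        ss = find_steady_state(micro)
        micro_rate = params.basal * ss["E"] + params.act * ss["EP"]
        assert adipogenic_transcription_rate(b, p, params) == pytest.approx(
            micro_rate, rel=1e-6
        )
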