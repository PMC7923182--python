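"""Rate-law evaluation, ODE compilation and model validation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wntrho import (
    NetworkModel,
    RateLaw,
    ReactionDef,
    SpeciesDef,
    compile_odes,
    eval_rate,
    validate_model,
)
from wntrho.wnt import WntVariantConfig, build_wnt_model


def law(kind, params, refs=None):
    return RateLaw(kind, params, refs or {})


class TestEvalRate:
    @pytest.mark.parametrize(
        "rate_law, conc, expected",
        [
            # phosphorylation law: k*Signal*Substrate/(K+Substrate)
            (
                law("saturating_signal", {"k": 0.06, "K": 100.0},
                    {"signal": "S", "substrate": "X"}),
                {"S": 10.0, "X": 100.0},
                0.3,
            ),
            (
                law("saturating_signal", {"k": 0.06, "K": 100.0},
                    {"signal": "S", "substrate": "X"}),
                {"S": 10.0, "X": 0.0},
                0.0,
            ),
            # bilinear actin-assembly law: k*m*gActin
            (
                law("modifier_mass_action", {"k": 0.1},
                    {"modifier": "ROCK", "substrate": "gActin"}),
                {"ROCK": 5.0, "gActin": 20.0},
                10.0,
            ),
            # unimolecular mass action
            (
                law("mass_action", {"k": 0.1}, {"substrates": ["X"]}),
                {"X": 10.0},
                1.0,
            ),
            (law("constant_synthesis", {"k": 0.42}), {}, 0.42),
        ],
    )
    def test_catalogue_values(self, rate_law, conc, expected):
        assert eval_rate(rate_law, conc) == pytest.approx(expected, rel=1e-12)

    def test_promoter_law_occupancy_form(self):
        promoter = law(
            "competitive_promoter",
            {"basal": 1.0, "act": 5.0, "K_act": 2.0, "K_rep_B": 4.0},
            {"activator": "P", "repressors": ["B"]},
        )
        # (1 + 5*(4/2)) / (1 + 4/2 + 8/4)
        assert eval_rate(promoter, {"P": 4.0, "B": 8.0}) == pytest.approx(11.0 / 5.0)

    def test_unknown_kind_rejected(self):
        with pytest.raises(ValueError, match="unknown rate-law kind"):
            eval_rate(law("hill", {"k": 1.0}), {})

    def test_missing_species_rejected(self):
        ma = law("mass_action", {"k": 1.0}, {"substrates": ["X"]})
        with pytest.raises(KeyError, match="X"):
            eval_rate(ma, {"Y": 1.0})

    def test_negative_concentration_rejected(self):
        ma = law("mass_action", {"k": 1.0}, {"substrates": ["X"]})
        with pytest.raises(ValueError, match="negative"):
            eval_rate(ma, {"X": -1.0})


class TestCompile:
    def test_no_reactions_zero_derivative(self):
        model = NetworkModel("still", [SpeciesDef("A", 3.0), SpeciesDef("B", 1.0)])
        compiled = compile_odes(model)
        assert np.all(compiled.rhs(0.0, model.initial_state(), compiled.p0) == 0.0)

    def test_unimolecular_stoichiometry(self):
        model = NetworkModel(
            "ab",
            [SpeciesDef("A", 10.0), SpeciesDef("B", 0.0)],
            [ReactionDef("r", [("A", 1)], [("B", 1)],
                         RateLaw("mass_action", {"k": 0.1}))],
        )
        compiled = compile_odes(model)
        dy = compiled.rhs(0.0, np.array([10.0, 0.0]), compiled.p0)
        assert dy == pytest.approx([-1.0, 1.0])

    def test_boundary_species_clamped(self):
        model = NetworkModel(
            "boundary",
            [SpeciesDef("Wnt", 1.0, is_boundary=True), SpeciesDef("B", 0.0)],
            [ReactionDef("r", [("Wnt", 1)], [("B", 1)],
                         RateLaw("mass_action", {"k": 0.5}))],
        )
        compiled = compile_odes(model)
        dy = compiled.rhs(0.0, np.array([1.0, 0.0]), compiled.p0)
        assert dy[0] == 0.0
        assert dy[1] == pytest.approx(0.5)

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(st.data())
    def test_mass_action_brute_force_oracle(self, data):
        """Compiled derivatives equal the stoichiometry-times-rate sum built
        directly from eval_rate, for random small mass-action networks."""
        n_species = data.draw(st.integers(2, 3))
        names = [f"S{i}" for i in range(n_species)]
        n_rxn = data.draw(st.integers(1, 3))
        reactions = []
        for j in range(n_rxn):
            reactants = data.draw(
                st.lists(
                    st.tuples(st.sampled_from(names), st.integers(1, 2)),
                    min_size=0, max_size=2, unique_by=lambda t: t[0],
                )
            )
            products = data.draw(
                st.lists(
                    st.tuples(st.sampled_from(names), st.integers(1, 2)),
                    min_size=0, max_size=2, unique_by=lambda t: t[0],
                )
            )
            k = data.draw(st.floats(0.0, 10.0, allow_nan=False))
            reactions.append(
                ReactionDef(f"r{j}", reactants, products,
                            RateLaw("mass_action", {"k": k}))
            )
        model = NetworkModel(
            "random", [SpeciesDef(n, 1.0) for n in names], reactions
        )
        compiled = compile_odes(model)
        y = np.array(
            [data.draw(st.floats(0.0, 5.0, allow_nan=False)) for _ in names]
        )
        conc = dict(zip(names, y))
        expected = np.zeros(n_species)
        for r in reactions:
            rate = eval_rate(r.rate_law, conc)
            for name, stoich in r.reactants:
                expected[names.index(name)] -= stoich * rate
            for name, stoich in r.products:
                expected[names.index(name)] += stoich * rate
        np.testing.assert_allclose(
            compiled.rhs(0.0, y, compiled.p0), expected, rtol=1e-10, atol=1e-12
        )


class TestValidate:
    def test_duplicate_species_named(self):
        model = NetworkModel("dup", [SpeciesDef("A"), SpeciesDef("A")])
        violations = validate_model(model)
        assert len(violations) == 1 and "A" in violations[0]

    def test_negative_initial_concentration(self):
        model = NetworkModel("neg", [SpeciesDef("A", -1.0)])
        assert any("negative initial" in v for v in validate_model(model))

    def test_unknown_species_in_reaction(self):
        model = NetworkModel(
            "bad", [SpeciesDef("A")],
            [ReactionDef("r", [("Z", 1)], [], RateLaw("mass_action", {"k": 1.0}))],
        )
        assert any("unknown species Z" in v for v in validate_model(model))

    def test_wellformed_wnt_model_clean(self):
        model = build_wnt_model(WntVariantConfig("double", True))
        assert validate_model(model) == []
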