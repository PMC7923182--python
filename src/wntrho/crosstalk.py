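"""Integrated Wnt / RhoA-ROCK crosstalk model.

The integrated network is the union of the extended Wnt model
(double-competition, TCF-feedback variant) and the Rho model, joined by three
crosstalk mechanisms:

1. *Receptor-level Dishevelled competition.* Canonical Wnt drives inactive
   Dishevelled (Dshi) to its canonical active form cDsh, the noncanonical
   ligand Wnt5b drives the same pool to ncDsh; both draw on the shared Dshi
   pool. ncDsh activates Daam1, which acts as a GEF-like signal on the RhoA
   exchange step.
2. *Desmosomal plakoglobin sequestration.* Active Rho kinase (pROK) drives
   free PG into the desmosome-bound pool dPG (saturating kinetics with pROK
   as the signal); release back to the free pool is first order, so the
   partition follows pROK.
3. *Siah2-APC beta-catenin degradation.* Wnt5b activates Siah2; active Siah2
   binds APC and the Siah2-APC complex routes free cytoplasmic beta-catenin
   to degradation (TCF- or complex-bound pools are untouched).

With the ``wnt5b_feedback`` option the Wnt5b input becomes a state variable:
its transcript gWnt5b is repressed by nuclear MKL1 and translated into the
ligand, closing the negative feedback loop in which active RhoA-ROCK
suppresses Wnt5b expression.

The PPARgamma readout uses the shared-promoter law with the PG/TCF dimer
activating and both the beta-catenin/TCF dimer and nuclear MKL1 repressing.
Its constants were calibrated once, at model construction, to the printed
condition-matrix steady states (2, 11, 4 and 16 nM for conditions 1, 4, 6
and 8).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .reaction_network import NetworkModel, RateLaw, ReactionDef, SpeciesDef
from .rho import RHO_PARAMS, build_rho_model, set_dominant_negative
from .simulation import Simulator
from .wnt import LEE_PARAMS, WntVariantConfig, build_wnt_model, wnt_parameter_groups

__all__ = [
    "CROSSTALK_PARAMS",
    "INTEGRATED_READOUT",
    "InputCondition",
    "ConditionMatrixResult",
    "DEFAULT_CONDITIONS",
    "build_integrated_model",
    "run_condition_matrix",
    "run_feedback_experiment",
    "crosstalk_conserved_totals",
]

CROSSTALK_PARAMS = {
    # Noncanonical ligand engagement saturates (receptor occupancy): both the
    # Dishevelled activation by Wnt5b and the Siah2 activation scale as
    # Wnt5b/(K_ligand + Wnt5b). Wnt5b works at ~100x the concentration scale
    # of canonical Wnt (100 nM vs 1 nM inputs).
    "k_ncdsh_act": 0.24,   # min^-1 at ligand saturation
    "K_ligand": 30.0,      # nM, Wnt5b half-saturation
    # Daam1 activation by ncDsh and first-order deactivation
    "daam1_total": 50.0,
    "k_daam1_act": 0.04,   # nM^-1 min^-1
    "k_daam1_deact": 0.5,  # min^-1
    # Siah2 branch
    "siah2_total": 50.0,
    "k_siah2_act": 0.065,  # min^-1 at ligand saturation
    "k_siah2_deact": 0.05,
    "k_siah2_apc_on": 0.01,   # nM^-1 min^-1
    "k_siah2_apc_off": 0.1,   # min^-1
    "k_siah2_bcat_deg": 1.0e-5,  # nM^-1 min^-1, Siah2-APC-mediated degradation
    # desmosomal PG sequestration (pROK-catalysed) and first-order release
    "k_dpg_seq": 0.06,
    "K_dpg_seq": 100.0,
    "k_dpg_rel": 0.002,
    # gWnt5b feedback loop
    "v_gwnt5b": 4.0,        # nM/min, unrepressed transcription
    "K_gwnt5b_rep": 5.0,    # nM, MKL1n repression scale
    "k_gwnt5b_deg": 0.02,
    "k_wnt5b_translate": 0.02,
    "k_wnt5b_deg": 0.02,
}

#: PPARgamma readout (calibrated; see module docstring). The PG/TCF promoter
#: binding scale is inherited from the Wnt-model readout.
INTEGRATED_READOUT = {
    "basal": 2.1092203e00,        # nM/min
    "act": 4.2439786e-01,         # nM/min
    "K_act": 3.3858408e00,        # nM (as in the Wnt model readout)
    "K_rep_Bcat_TCF": 1.6183436e00,  # nM
    "K_rep_MKL1n": 1.8663123e01,     # nM
    "k_deg": 0.02,                # min^-1
}

DEFAULT_PG_TOTAL = 300.0
DEFAULT_WNT5B_LEVEL = 100.0


def _sat(label, reactants, products, signal, k, K):
    substrate = reactants[0][0]
    return ReactionDef(
        label, reactants, products,
        RateLaw("saturating_signal", {"k": k, "K": K}, {"signal": signal, "substrate": substrate}),
        [signal],
    )


def _ma(label, reactants, products, k, refs=None, modifiers=()):
    return ReactionDef(
        label, reactants, products, RateLaw("mass_action", {"k": k}, refs or {}), list(modifiers)
    )


def build_integrated_model(
    *,
    wnt5b_feedback: bool = False,
    dn_rhok: bool = False,
    pg_total: float = DEFAULT_PG_TOTAL,
    wnt5b_boundary: bool | None = None,
    readout: dict | None = None,
) -> NetworkModel:
    """Assemble the integrated Wnt + Rho crosstalk network.

    Without feedback, Wnt5b is a boundary input (set per condition); with
    ``wnt5b_feedback`` it becomes a state variable fed by the MKL1n-repressed
    gWnt5b transcript. ``dn_rhok`` applies the dominant-negative Rho-kinase
    parameter changes. Requesting feedback while forcing Wnt5b to stay a
    boundary input is contradictory and rejected.
    """
    if wnt5b_boundary is None:
        wnt5b_boundary = not wnt5b_feedback
    if wnt5b_feedback and wnt5b_boundary:
        raise ValueError("wnt5b_feedback requires Wnt5b to be a state variable, not a boundary input")
    X = CROSSTALK_PARAMS
    R = dict(INTEGRATED_READOUT, **(readout or {}))

    model = build_wnt_model(WntVariantConfig("double", True, pg_initial=pg_total))
    model.name = "wnt-rho-crosstalk" + ("+wnt5b_feedback" if wnt5b_feedback else "")
    # canonical active Dishevelled becomes cDsh; ncDsh is added alongside
    model.rename_species("Dsha", "cDsh")
    # the generic adipogenic readout is replaced by the PPARgamma readout
    model.remove_reaction("r20")
    model.remove_reaction("r25")
    model.remove_species("AdipomRNA")

    rho = build_rho_model()
    for s in rho.species:
        if s.name != "PPARg":
            model.species.append(s)
    model.species.append(SpeciesDef("PPARg", 0.0))
    for r in rho.reactions:
        if r.label not in ("rp1", "rp2"):
            model.reactions.append(r)

    model.species += [
        SpeciesDef("Wnt5b", 0.0, is_boundary=wnt5b_boundary),
        SpeciesDef("ncDsh", 0.0),
        SpeciesDef("Daam1i", X["daam1_total"]),
        SpeciesDef("Daam1a", 0.0),
        SpeciesDef("Siah2i", X["siah2_total"]),
        SpeciesDef("Siah2a", 0.0),
        SpeciesDef("Siah2_APC", 0.0),
        SpeciesDef("dPG", 0.0),
    ]

    model.reactions += [
        # (1) receptor-level competition for the shared Dshi pool; the rate is
        # linear in Dshi (the "signal" slot) and saturates in the ligand
        ReactionDef(
            "rn1", [("Dshi", 1)], [("ncDsh", 1)],
            RateLaw("saturating_signal", {"k": X["k_ncdsh_act"], "K": X["K_ligand"]},
                    {"signal": "Dshi", "substrate": "Wnt5b"}),
            ["Wnt5b"],
        ),
        _ma("rn2", [("ncDsh", 1)], [("Dshi", 1)], LEE_PARAMS["k2"]),
        ReactionDef(
            "rd1", [("Daam1i", 1)], [("Daam1a", 1)],
            RateLaw("modifier_mass_action", {"k": X["k_daam1_act"]},
                    {"modifier": "ncDsh", "substrate": "Daam1i"}),
            ["ncDsh"],
        ),
        _ma("rd2", [("Daam1a", 1)], [("Daam1i", 1)], X["k_daam1_deact"]),
        _sat("rg1b", [("RhoGDP", 1)], [("RhoGTP", 1)], "Daam1a",
             RHO_PARAMS["k_phos"], RHO_PARAMS["K_phos"]),
        # (2) pROK-driven desmosomal sequestration of PG
        _sat("rq1", [("PG", 1)], [("dPG", 1)], "pROK", X["k_dpg_seq"], X["K_dpg_seq"]),
        _ma("rq2", [("dPG", 1)], [("PG", 1)], X["k_dpg_rel"]),
        # (3) Wnt5b -> Siah2 -> APC-mediated beta-catenin degradation; Siah2
        # activation is linear in the inactive pool and saturates in Wnt5b
        ReactionDef(
            "rs1", [("Siah2i", 1)], [("Siah2a", 1)],
            RateLaw("saturating_signal", {"k": X["k_siah2_act"], "K": X["K_ligand"]},
                    {"signal": "Siah2i", "substrate": "Wnt5b"}),
            ["Wnt5b"],
        ),
        _ma("rs2", [("Siah2a", 1)], [("Siah2i", 1)], X["k_siah2_deact"]),
        _ma("rs3", [("Siah2a", 1), ("APC", 1)], [("Siah2_APC", 1)], X["k_siah2_apc_on"]),
        _ma("rs4", [("Siah2_APC", 1)], [("Siah2a", 1), ("APC", 1)], X["k_siah2_apc_off"]),
        ReactionDef(
            "rs5", [("Bcat", 1)], [],
            RateLaw("modifier_mass_action", {"k": X["k_siah2_bcat_deg"]},
                    {"modifier": "Siah2_APC", "substrate": "Bcat"}),
            ["Siah2_APC"],
        ),
        # PPARgamma readout under three-way promoter competition
        ReactionDef(
            "rp1", [], [("PPARg", 1)],
            RateLaw(
                "competitive_promoter",
                {
                    "basal": R["basal"],
                    "act": R["act"],
                    "K_act": R["K_act"],
                    "K_rep_Bcat_TCF": R["K_rep_Bcat_TCF"],
                    "K_rep_MKL1n": R["K_rep_MKL1n"],
                },
                {"activator": "PG_TCF", "repressors": ["Bcat_TCF", "MKL1n"]},
            ),
            ["PG_TCF", "Bcat_TCF", "MKL1n"],
        ),
        _ma("rp2", [("PPARg", 1)], [], R["k_deg"]),
    ]

    if wnt5b_feedback:
        model.species.append(SpeciesDef("gWnt5b", 0.0))
        model.reactions += [
            ReactionDef(
                "rw1", [], [("gWnt5b", 1)],
                RateLaw(
                    "competitive_promoter",
                    {"basal": X["v_gwnt5b"], "K_rep_MKL1n": X["K_gwnt5b_rep"]},
                    {"activator": None, "repressors": ["MKL1n"]},
                ),
                ["MKL1n"],
            ),
            _ma("rw2", [("gWnt5b", 1)], [], X["k_gwnt5b_deg"]),
            _ma("rw3", [], [("Wnt5b", 1)], X["k_wnt5b_translate"],
                {"substrates": ["gWnt5b"]}, ["gWnt5b"]),
            _ma("rw4", [("Wnt5b", 1)], [], X["k_wnt5b_deg"]),
        ]

    if dn_rhok:
        model = set_dominant_negative(model)
    return model


@dataclass(frozen=True)
class InputCondition:
    """One column of the condition matrix: the four boundary-input levels."""

    label: int
    wnt: float
    wnt5b: float
    rhogef: float
    rhogap: float

    def __post_init__(self):
        if min(self.wnt, self.wnt5b, self.rhogef, self.rhogap) < 0:
            raise ValueError("input levels must be >= 0")


def default_conditions(
    wnt_level: float = 1.0, wnt5b_level: float = DEFAULT_WNT5B_LEVEL
) -> list[InputCondition]:
    """The eight-condition input matrix.

    Conditions 1-4 have the Rho pathway driven on (RhoGEF = 100 nM, RhoGAP =
    0); conditions 5-8 have it driven off (RhoGAP = 100 nM, RhoGEF = 0).
    Within each panel the four combinations of canonical Wnt (on/off) and
    Wnt5b (present/absent) are scanned. Condition 7 includes Wnt5b (both
    pathways nominally off, with residual Rho activity through the
    Wnt5b-Daam1 route).
    """
    rows = [
        (1, wnt_level, 0.0, 100.0, 0.0),
        (2, wnt_level, wnt5b_level, 100.0, 0.0),
        (3, 0.0, wnt5b_level, 100.0, 0.0),
        (4, 0.0, 0.0, 100.0, 0.0),
        (5, wnt_level, 0.0, 0.0, 100.0),
        (6, wnt_level, wnt5b_level, 0.0, 100.0),
        (7, 0.0, wnt5b_level, 0.0, 100.0),
        (8, 0.0, 0.0, 0.0, 100.0),
    ]
    return [InputCondition(*r) for r in rows]


DEFAULT_CONDITIONS = default_conditions()


@dataclass
class ConditionMatrixResult:
    """Steady states of the eight-condition scan plus the normalised colormap."""

    steady_states: pd.DataFrame  # rows: conditions, columns: species
    pparg: pd.Series             # steady-state PPARgamma per condition
    colormap: pd.DataFrame       # column-normalised (each column max = 1)
    converged: pd.Series


def run_condition_matrix(
    conditions: list[InputCondition] | None = None,
    wnt_level: float = 1.0,
    *,
    model: NetworkModel | None = None,
    simulator: Simulator | None = None,
) -> ConditionMatrixResult:
    """Equilibrate the integrated model under each input condition.

    The model is built without the Wnt5b feedback (Wnt5b is an input here).
    Each column of the colormap is normalised to its maximum over conditions;
    all-zero columns are left at zero.
    """
    conditions = conditions if conditions is not None else default_conditions(wnt_level)
    sim = simulator or Simulator(model or build_integrated_model())
    rows, ok = {}, {}
    for c in conditions:
        ss = sim.steady_state(
            inputs={"Wnt": c.wnt, "Wnt5b": c.wnt5b, "RhoGEF": c.rhogef, "RhoGAP": c.rhogap},
            raise_on_failure=False,
        )
        rows[c.label] = ss.concentrations
        ok[c.label] = ss.converged
    states = pd.DataFrame.from_dict(rows, orient="index")
    states.index.name = "condition"
    colmax = states.max(axis=0)
    colormap = states.divide(colmax.where(colmax > 0, 1.0), axis=1)
    return ConditionMatrixResult(
        steady_states=states,
        pparg=states["PPARg"],
        colormap=colormap,
        converged=pd.Series(ok, name="converged"),
    )


FEEDBACK_SCENARIOS = ("DN-RhoK", "RKP_up", "RKP_down")


def run_feedback_experiment(
    scenarios=FEEDBACK_SCENARIOS,
    wnt_level: float = 1.0,
    pg_total: float = DEFAULT_PG_TOTAL,
) -> pd.DataFrame:
    """Steady states of the gWnt5b feedback model under the three Rho regimes.

    ``RKP_up`` drives the pathway with RhoGEF (100 nM), ``RKP_down`` shuts it
    down with RhoGAP (100 nM), and ``DN-RhoK`` applies the dominant-negative
    Rho-kinase parameter set under the RKP_up inputs. Canonical Wnt is held
    at ``wnt_level`` (1 nM) in every scenario. Returns raw steady states of
    the reporting species plus fraction-of-total normalisations (pROK, active
    Daam1 and RhoA-GTP over their conserved totals; the TCF dimers over their
    maximum across scenarios).
    """
    base = build_integrated_model(wnt5b_feedback=True, pg_total=pg_total)
    sim = Simulator(base)
    # the DN model has the same reactions, only rescaled constants, so it can
    # reuse the compiled system with a substituted parameter vector
    dn_params = set_dominant_negative(base).parameters()
    p_dn = np.array([dn_params[name] for name in sim.compiled.param_names])
    rows = {}
    for name in scenarios:
        if name == "DN-RhoK":
            p, gef, gap = p_dn, 100.0, 0.0
        elif name == "RKP_up":
            p, gef, gap = sim.compiled.p0, 100.0, 0.0
        elif name == "RKP_down":
            p, gef, gap = sim.compiled.p0, 0.0, 100.0
        else:
            raise ValueError(f"unknown scenario {name!r}")
        ss = sim.steady_state(
            inputs={"Wnt": wnt_level, "RhoGEF": gef, "RhoGAP": gap}, p=p
        )
        rows[name] = {
            k: ss[k]
            for k in ("Wnt5b", "PPARg", "pROK", "Daam1a", "RhoGTP", "Bcat_TCF", "PG_TCF")
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "scenario"
    out["pROK_frac"] = out["pROK"] / RHO_PARAMS["rock_total"]
    out["Daam1a_frac"] = out["Daam1a"] / CROSSTALK_PARAMS["daam1_total"]
    out["RhoGTP_frac"] = out["RhoGTP"] / RHO_PARAMS["rhoa_total"]
    for col in ("Bcat_TCF", "PG_TCF"):
        out[f"{col}_norm"] = out[col] / out[col].max()
    return out


def crosstalk_conserved_totals(state: dict[str, float]) -> dict[str, float]:
    """Conserved moieties of the integrated network on a state map."""
    complexes = ["DCi", "DCa", "Bcat_DCa", "BcatP_DCa", "PG_DCa"]
    return {
        "APC": state["APC"] + state["APC_Axin"] + state["Bcat_APC"] + state["Siah2_APC"]
        + sum(state[c] for c in complexes),
        "GSK3": state["GSK3"] + sum(state[c] for c in complexes),
        "Dsh": state["Dshi"] + state["cDsh"] + state["ncDsh"],
        "PG": state["PG"] + state["PG_DCa"] + state["PG_TCF"] + state["dPG"],
        "RhoA": state["RhoGDP"] + state["RhoGTP"],
        "ROCK": state["ROCK"] + state["pROK"],
        "MKL1": state["MKL1c"] + state["MKL1n"] + state["MKL1_gActin"],
        "actin": state["gActin"] + state["fActin"] + state["MKL1_gActin"],
        "Daam1": state["Daam1i"] + state["Daam1a"],
        "Siah2": state["Siah2i"] + state["Siah2a"] + state["Siah2_APC"],
    }


def crosstalk_parameter_groups(model: NetworkModel) -> dict[str, str]:
    """Reaction-group label per flat parameter for the integrated model."""
    groups = wnt_parameter_groups(model)
    table = {
        "rp": "readout_synthesis_degradation",
        "rm": "mkl1_transport_binding",
        "ra": "actin_dynamics",
        "rg": "rho_gtpase_cycle",
        "rk": "rock_activation",
        "rn": "dsh_competition",
        "rd": "daam1",
        "rq": "pg_desmosome",
        "rs": "siah2",
        "rw": "wnt5b_feedback",
    }
    for key in list(groups):
        label = key.split(".", 1)[0]
        if label[:2] in table and not label.startswith("r1") and not label.startswith("r2"):
            groups[key] = table[label[:2]]
    return groups
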