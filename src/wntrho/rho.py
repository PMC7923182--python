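"""RhoA-ROCK / actin / MKL1 pathway model.

The network covers the GTPase cycle (GEF-driven GDP->GTP exchange, GAP-driven
and intrinsic hydrolysis), ROCK activation by both RhoA forms, F-actin
assembly catalysed by active Rho kinase (pROK), G-actin sequestration of the
transcriptional co-activator MKL1 (MRTFA), MKL1 nucleocytoplasmic shuttling,
and the PPARgamma readout repressed by nuclear MKL1.

Kinetic conventions follow the phosphorylation law v = k*Signal*Substrate /
(K + Substrate) with K = 100 nM and k = 0.06 min^-1 for every
enzyme-mediated activation step (overridable per reaction), the bilinear
actin-assembly law v = k*pROK*gActin with k = 0.1 nM^-1 min^-1, and
first-order F-actin turnover at 0.1 min^-1. RhoA-GDP also activates ROCK in
the physiological state, at one tenth of the RhoA-GTP rate (the relative
strength is a modelling choice; only the existence of both routes is given).
The dominant-negative Rho-kinase condition (DN-RhoK) abolishes ROCK
activation by either RhoA form and halves every pROK-catalysed rate
constant; the two switches are independently toggleable.
"""

from __future__ import annotations

from dataclasses import dataclass

from .reaction_network import NetworkModel, RateLaw, ReactionDef, SpeciesDef

__all__ = [
    "RhoModeConfig",
    "RHO_PARAMS",
    "build_rho_model",
    "set_dominant_negative",
    "prok_catalyzed_parameters",
    "rho_conserved_totals",
    "rho_parameter_groups",
]

RHO_PARAMS = {
    "k_phos": 0.06,    # min^-1, shared phosphorylation-law rate constant
    "K_phos": 100.0,   # nM, shared phosphorylation-law half-saturation
    "gdp_rock_fraction": 0.1,  # RhoA-GDP activates ROCK at 1/10 the GTP rate
    "k_hydrolysis": 0.025,     # min^-1, intrinsic RhoA-GTP hydrolysis
    "k_rock_off": 0.05,        # min^-1, pROK dephosphorylation
    "k_actin_poly": 0.1,       # nM^-1 min^-1, pROK-catalysed F-actin assembly
    "k_actin_depoly": 0.1,     # min^-1, F-actin turnover
    "k_mkl_actin_on": 0.01,    # nM^-1 min^-1, MKL1 + gActin binding
    "k_mkl_actin_off": 0.1,    # min^-1 (K_d = 10 nM)
    "k_mkl_import": 0.1,       # min^-1, nuclear import of free cytoplasmic MKL1
    "k_mkl_export": 0.05,      # min^-1, nuclear export
    # totals (nM)
    "rhoa_total": 100.0,
    "rock_total": 100.0,
    "actin_total": 500.0,
    "mkl1_total": 100.0,
}

#: PPARgamma readout constants shared with the integrated crosstalk model
#: (calibrated there against the printed condition-matrix steady states).
RHO_READOUT = {
    "basal": 6.8730723e-01,   # nM/min
    "K_rep_MKL1n": 1.8663123e01,  # nM
    "k_deg": 0.02,            # min^-1
}


@dataclass(frozen=True)
class RhoModeConfig:
    """Pathway mode and input (boundary) levels for the Rho model."""

    mode: str = "physiological"
    rhogef_level: float = 100.0
    rhogap_level: float = 0.0

    def __post_init__(self):
        if self.mode not in ("physiological", "dominant_negative"):
            raise ValueError(f"invalid mode {self.mode!r}")
        if self.rhogef_level < 0 or self.rhogap_level < 0:
            raise ValueError("input levels must be >= 0")


def _sat(label, reactants, products, signal, k, K):
    substrate = reactants[0][0]
    return ReactionDef(
        label,
        reactants,
        products,
        RateLaw("saturating_signal", {"k": k, "K": K}, {"signal": signal, "substrate": substrate}),
        [signal],
    )


def _ma(label, reactants, products, k, refs=None, modifiers=()):
    return ReactionDef(
        label, reactants, products, RateLaw("mass_action", {"k": k}, refs or {}), list(modifiers)
    )


def build_rho_model(
    config: RhoModeConfig | None = None,
    *,
    readout: dict | None = None,
    mkl1_repression: bool = True,
) -> NetworkModel:
    """Assemble the RhoA-ROCK network.

    ``mkl1_repression=False`` ablates the capacity of nuclear MKL1 to inhibit
    PPARgamma transcription (its term is dropped from the promoter law),
    leaving every upstream reaction intact.
    """
    config = config or RhoModeConfig()
    P = RHO_PARAMS
    R = dict(RHO_READOUT, **(readout or {}))
    species = [
        SpeciesDef("RhoGEF", config.rhogef_level, is_boundary=True),
        SpeciesDef("RhoGAP", config.rhogap_level, is_boundary=True),
        SpeciesDef("RhoGDP", P["rhoa_total"]),
        SpeciesDef("RhoGTP", 0.0),
        SpeciesDef("ROCK", P["rock_total"]),
        SpeciesDef("pROK", 0.0),
        SpeciesDef("gActin", P["actin_total"]),
        SpeciesDef("fActin", 0.0),
        SpeciesDef("MKL1c", P["mkl1_total"]),
        SpeciesDef("MKL1n", 0.0),
        SpeciesDef("MKL1_gActin", 0.0),
        SpeciesDef("PPARg", 0.0),
    ]
    reactions = [
        _sat("rg1", [("RhoGDP", 1)], [("RhoGTP", 1)], "RhoGEF", P["k_phos"], P["K_phos"]),
        _sat("rg2", [("RhoGTP", 1)], [("RhoGDP", 1)], "RhoGAP", P["k_phos"], P["K_phos"]),
        _ma("rg3", [("RhoGTP", 1)], [("RhoGDP", 1)], P["k_hydrolysis"]),
        _sat("rk1", [("ROCK", 1)], [("pROK", 1)], "RhoGTP", P["k_phos"], P["K_phos"]),
        _sat(
            "rk2",
            [("ROCK", 1)],
            [("pROK", 1)],
            "RhoGDP",
            P["k_phos"] * P["gdp_rock_fraction"],
            P["K_phos"],
        ),
        _ma("rk3", [("pROK", 1)], [("ROCK", 1)], P["k_rock_off"]),
        ReactionDef(
            "ra1",
            [("gActin", 1)],
            [("fActin", 1)],
            RateLaw(
                "modifier_mass_action",
                {"k": P["k_actin_poly"]},
                {"modifier": "pROK", "substrate": "gActin"},
            ),
            ["pROK"],
        ),
        _ma("ra2", [("fActin", 1)], [("gActin", 1)], P["k_actin_depoly"]),
        _ma("rm1", [("MKL1c", 1), ("gActin", 1)], [("MKL1_gActin", 1)], P["k_mkl_actin_on"]),
        _ma("rm2", [("MKL1_gActin", 1)], [("MKL1c", 1), ("gActin", 1)], P["k_mkl_actin_off"]),
        _ma("rm3", [("MKL1c", 1)], [("MKL1n", 1)], P["k_mkl_import"]),
        _ma("rm4", [("MKL1n", 1)], [("MKL1c", 1)], P["k_mkl_export"]),
        ReactionDef(
            "rp1",
            [],
            [("PPARg", 1)],
            RateLaw(
                "competitive_promoter",
                {"basal": R["basal"]}
                | ({"K_rep_MKL1n": R["K_rep_MKL1n"]} if mkl1_repression else {}),
                {"activator": None, "repressors": ["MKL1n"] if mkl1_repression else []},
            ),
            ["MKL1n"] if mkl1_repression else [],
        ),
        _ma("rp2", [("PPARg", 1)], [], R["k_deg"]),
    ]
    model = NetworkModel(name=f"rho[{config.mode}]", species=species, reactions=reactions)
    if config.mode == "dominant_negative":
        model = set_dominant_negative(model)
    return model


def prok_catalyzed_parameters(model: NetworkModel) -> list[str]:
    """Flat names of rate constants in reactions catalysed by active Rho kinase."""
    keys = []
    for r in model.reactions:
        refs = r.rate_law.species_refs
        if refs.get("modifier") == "pROK" or refs.get("signal") == "pROK":
            keys.extend(f"{r.label}.{p}" for p in r.rate_law.parameters if p == "k")
    return keys


def set_dominant_negative(
    model: NetworkModel,
    *,
    disable_rock_activation: bool = True,
    halve_prok_rates: bool = True,
) -> NetworkModel:
    """Copy of the model in the dominant-negative Rho-kinase state.

    ``disable_rock_activation`` zeroes ROCK activation by both RhoA-GTP and
    RhoA-GDP; ``halve_prok_rates`` reduces two-fold every rate constant of a
    pROK-catalysed reaction. Repeated application keeps halving (the
    operation is deliberately not idempotent: it encodes a parameter scaling,
    not a state).
    """
    updates: dict[str, float] = {}
    params = model.parameters()
    if disable_rock_activation:
        for key in ("rk1.k", "rk2.k"):
            if key in params:
                updates[key] = 0.0
    out = model.with_parameters(updates) if updates else model.copy()
    if halve_prok_rates:
        keys = prok_catalyzed_parameters(out)
        if keys:
            out = out.scale_parameters(keys, 0.5)
    out.name = model.name + "+DN" if not model.name.endswith("+DN") else model.name
    return out


def rho_conserved_totals(state: dict[str, float]) -> dict[str, float]:
    """Conserved moieties of the Rho network on a state map."""
    return {
        "RhoA": state["RhoGDP"] + state["RhoGTP"],
        "ROCK": state["ROCK"] + state["pROK"],
        "MKL1": state["MKL1c"] + state["MKL1n"] + state["MKL1_gActin"],
        "actin": state["gActin"] + state["fActin"] + state["MKL1_gActin"],
    }


def rho_parameter_groups(model: NetworkModel) -> dict[str, str]:
    """Reaction-group label per flat parameter name (for the MPSA)."""
    table = {
        "rp": "readout_synthesis_degradation",
        "rm": "mkl1_transport_binding",
        "ra": "actin_dynamics",
        "rg": "rho_gtpase_cycle",
        "rk": "rock_activation",
    }
    groups = {}
    for key in model.parameters():
        label = key.split(".", 1)[0]
        groups[key] = table.get(label[:2], "other")
    return groups
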