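"""Shared fixtures: models and steady-state scans reused across test modules.

The heavier objects (compiled models, the PG titration, the eight-condition
matrix) are session-scoped — they are deterministic, and recomputing them per
test would dominate the suite's runtime.
"""

import pytest

from wntrho import (
    Simulator,
    WntVariantConfig,
    build_integrated_model,
    build_rho_model,
    build_wnt_model,
    pg_titration,
    predict_treatment_effects,
    run_condition_matrix,
    run_feedback_experiment,
)
from wntrho.wnt import FIG_PG_GRID


@pytest.fixture(scope="session")
def wnt_sim():
    """Compiled reference Wnt model (double competition, TCF feedback)."""
    return Simulator(build_wnt_model(WntVariantConfig("double", True)))


@pytest.fixture(scope="session")
def rho_sim():
    return Simulator(build_rho_model())


@pytest.fixture(scope="session")
def integrated_sim():
    return Simulator(build_integrated_model())


@pytest.fixture(scope="session")
def titration():
    """Full-grid PG titration of the reference Wnt variant."""
    return pg_titration(WntVariantConfig("double", True), FIG_PG_GRID)


@pytest.fixture(scope="session")
def titration_single():
    """Three-point titration of the single-competition variant."""
    return pg_titration(WntVariantConfig("single", True), (0.0, 250.0, 500.0))


@pytest.fixture(scope="session")
def titration_nofeedback():
    """Three-point titration of the no-feedback variant (TCF0 = 15 nM)."""
    return pg_titration(
        WntVariantConfig("double", False, tcf_initial=15.0), (0.0, 250.0, 500.0)
    )


@pytest.fixture(scope="session")
def condition_matrix():
    return run_condition_matrix()


@pytest.fixture(scope="session")
def feedback_table():
    return run_feedback_experiment()


@pytest.fixture(scope="session")
def treatment_predictions():
    """Model-predicted treatment effects for both genotypes."""
    return {
        genotype: predict_treatment_effects(genotype=genotype)
        for genotype in ("WT", "PKP2mut")
    }
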