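"""Synthetic qRT-PCR-like expression data and trend-concordance testing.

The wet-lab validation this module emulates treats cardiomyocytes (healthy
"WT" and desmosome-mutant "PKP2mut") with small-molecule pathway modulators
for days and reads out adipogenic gene expression as fold changes versus the
untreated (NT) condition, n = 3 replicates. Here the drugs are mapped to
model-level interventions rather than pharmacokinetics:

- CHIR99021 (Wnt activator): the canonical Wnt input is raised to its "on"
  level (1 nM);
- XAV939 (tankyrase/Wnt inhibitor): the Wnt input is zeroed and Axin is
  stabilised (its turnover halved), mimicking degradation-complex
  stabilisation;
- Y27632 (ROCK inhibitor): every pROK-catalysed rate constant is scaled by
  0.1;
- combinations compose; the composition is order-independent.

The genotype convention is PG = 0 for WT and PG > 0 (default 300 nM) for
PKP2mut. Replicate fold changes are lognormal around the model-predicted
fold change with a chosen coefficient of variation (multiplicative noise,
matching qRT-PCR error structure after housekeeping normalisation); the
generating means are recorded so that recovery of the predicted trend
directions can be tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crosstalk import build_integrated_model
from .rho import prok_catalyzed_parameters
from .simulation import Simulator

__all__ = [
    "Intervention",
    "DEFAULT_TREATMENTS",
    "NT_INPUTS",
    "SyntheticExpressionSet",
    "ConcordanceReport",
    "predict_treatment_effects",
    "generate_replicates",
    "concordance",
]

#: untreated-condition inputs: endogenous canonical Wnt tone, Rho pathway
#: driven on (healthy cardiomyocytes maintain stress fibres), no Wnt5b.
NT_INPUTS = {"Wnt": 0.2, "Wnt5b": 0.0, "RhoGEF": 100.0, "RhoGAP": 0.0}

GENOTYPE_PG = {"WT": 0.0, "PKP2mut": 300.0}


@dataclass(frozen=True)
class Intervention:
    """A model-level treatment: input overrides and parameter scalings.

    ``wnt`` overrides the canonical Wnt input level; ``axin_stabilization``
    divides the Axin turnover constant (degradation-complex stabilisation);
    ``prok_scale`` multiplies every pROK-catalysed rate constant. ``compose``
    merges two interventions; scalings multiply (hence order-independent) and
    conflicting level overrides are rejected.
    """

    wnt: float | None = None
    axin_stabilization: float = 1.0
    prok_scale: float = 1.0

    def compose(self, other: "Intervention") -> "Intervention":
        if self.wnt is not None and other.wnt is not None and self.wnt != other.wnt:
            raise ValueError("conflicting Wnt level overrides in composed treatments")
        return Intervention(
            wnt=self.wnt if self.wnt is not None else other.wnt,
            axin_stabilization=self.axin_stabilization * other.axin_stabilization,
            prok_scale=self.prok_scale * other.prok_scale,
        )


_CHIR = Intervention(wnt=1.0)
_XAV = Intervention(wnt=0.0, axin_stabilization=2.0)
_Y = Intervention(prok_scale=0.1)

DEFAULT_TREATMENTS: dict[str, Intervention] = {
    "NT": Intervention(),
    "CHIR99021": _CHIR,
    "XAV939": _XAV,
    "Y27632": _Y,
    "XAV939+Y27632": _XAV.compose(_Y),
    "CHIR99021+Y27632": _CHIR.compose(_Y),
}


def predict_treatment_effects(
    treatments: dict[str, Intervention] | None = None,
    genotype: str = "PKP2mut",
    *,
    pg_total: float | None = None,
    readout: str = "PPARg",
    simulator: Simulator | None = None,
) -> pd.DataFrame:
    """Steady-state readout and fold change versus NT per treatment.

    The integrated crosstalk model (Wnt5b as an input, zero here) is
    equilibrated under each treatment's inputs and parameter scalings.
    Returns a frame indexed by treatment with columns ``pparg``,
    ``fold_change`` and ``converged``.
    """
    treatments = treatments or DEFAULT_TREATMENTS
    if "NT" not in treatments:
        raise ValueError("treatment map must include the untreated reference 'NT'")
    if pg_total is None:
        try:
            pg_total = GENOTYPE_PG[genotype]
        except KeyError:
            raise ValueError(f"unknown genotype {genotype!r}") from None
    sim = simulator or Simulator(build_integrated_model(pg_total=pg_total))
    prok_keys = prok_catalyzed_parameters(sim.model)
    nominal = dict(zip(sim.compiled.param_names, sim.compiled.p0))

    rows = {}
    for label, tr in treatments.items():
        overrides = {}
        if tr.axin_stabilization != 1.0:
            overrides["r15.k"] = nominal["r15.k"] / tr.axin_stabilization
        if tr.prok_scale != 1.0:
            for key in prok_keys:
                overrides[key] = nominal[key] * tr.prok_scale
        p = sim.compiled.param_vector(overrides)
        inputs = dict(NT_INPUTS)
        inputs["PG"] = pg_total  # PG is a conserved pool; reset per run
        if tr.wnt is not None:
            inputs["Wnt"] = tr.wnt
        boundary = {k: v for k, v in inputs.items() if k != "PG"}
        y0 = sim.state_vector({"PG": pg_total})
        ss = sim.steady_state(y0=y0, inputs=boundary, p=p, raise_on_failure=False)
        rows[label] = {"pparg": ss[readout], "converged": ss.converged}
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "treatment"
    out["fold_change"] = out["pparg"] / out.loc["NT", "pparg"]
    return out


@dataclass
class SyntheticExpressionSet:
    """Replicate fold changes with their recorded generating means."""

    genotype: str
    data: pd.DataFrame  # columns: treatment, replicate, fold_change
    generating_means: dict[str, float]
    cv: float
    n: int
    seed: int

    def replicates(self, treatment: str) -> np.ndarray:
        return self.data.loc[self.data["treatment"] == treatment, "fold_change"].to_numpy()


def generate_replicates(
    means: dict[str, float],
    cv: float = 0.15,
    n: int = 3,
    seed: int = 0,
    genotype: str = "PKP2mut",
) -> SyntheticExpressionSet:
    """Lognormal replicate fold changes around the given geometric means.

    The lognormal shape parameter is sigma^2 = ln(1 + cv^2), so the requested
    ``cv`` is the coefficient of variation of the multiplicative noise and
    each treatment's geometric mean equals its generating mean. Reproducible
    under ``seed``.
    """
    if cv <= 0:
        raise ValueError("cv must be > 0")
    if n < 2:
        raise ValueError("need at least 2 replicates per condition")
    for label, mean in means.items():
        if mean <= 0:
            raise ValueError(f"generating mean for {label!r} must be > 0")
    rng = np.random.default_rng(seed)
    sigma = float(np.sqrt(np.log1p(cv**2)))
    rows = []
    for label, mean in means.items():
        draws = mean * np.exp(rng.normal(0.0, sigma, size=n))
        rows += [(label, i + 1, fc) for i, fc in enumerate(draws)]
    data = pd.DataFrame(rows, columns=["treatment", "replicate", "fold_change"])
    return SyntheticExpressionSet(
        genotype=genotype, data=data, generating_means=dict(means), cv=cv, n=n, seed=seed
    )


@dataclass
class ConcordanceReport:
    """Direction agreement between model predictions and a synthetic dataset."""

    table: pd.DataFrame  # treatment, model_direction, data_direction, agree
    fraction_agreeing: float


def _model_direction(fold: float, threshold: float) -> str:
    if abs(np.log(fold)) <= np.log1p(threshold):
        return "no_change"
    return "up" if fold > 1 else "down"


def concordance(
    predictions: dict[str, float],
    dataset: SyntheticExpressionSet,
    n_boot: int = 200,
    seed: int = 0,
    threshold: float = 0.05,
) -> ConcordanceReport:
    """Compare predicted fold-change directions with the synthetic data.

    The data direction per treatment comes from a percentile bootstrap
    interval (2.5-97.5%) of the mean log fold change over replicates: "up" or
    "down" requires the interval to clear the minimal effect size
    ``log(1 + threshold)`` on the corresponding side (significance plus a
    floor on magnitude), otherwise "no_change". The model direction is the
    sign of the predicted log fold change, with changes below ``threshold``
    (relative) treated as "no_change". Treatments present on one side only
    raise ``KeyError``.
    """
    labels = set(predictions)
    data_labels = set(dataset.data["treatment"])
    if labels != data_labels:
        raise KeyError(
            f"treatment labels differ: predictions only {sorted(labels - data_labels)}, "
            f"data only {sorted(data_labels - labels)}"
        )
    rng = np.random.default_rng(seed)
    rows = []
    for label in sorted(labels):
        reps = np.log(dataset.replicates(label))
        idx = rng.integers(0, len(reps), size=(n_boot, len(reps)))
        boot_means = reps[idx].mean(axis=1)
        lo, hi = np.percentile(boot_means, [2.5, 97.5])
        eps = np.log1p(threshold)
        if lo > eps:
            data_dir = "up"
        elif hi < -eps:
            data_dir = "down"
        else:
            data_dir = "no_change"
        model_dir = _model_direction(predictions[label], threshold)
        rows.append((label, model_dir, data_dir, model_dir == data_dir))
    table = pd.DataFrame(rows, columns=["treatment", "model_direction", "data_direction", "agree"])
    return ConcordanceReport(table=table, fraction_agreeing=float(table["agree"].mean()))
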