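"""Multi-parametric sensitivity analysis (MPSA) of steady-state readouts.

The normalised sensitivity of output y_i to parameter p_j is

    S_ij = (dy_i/dp_j) * (p_j / y_i),

evaluated at steady state by central finite differences with a relative
parameter step (default 1e-4). The multi-parametric ensemble draws N
parameter sets from independent normals centred on the nominal values with a
standard deviation of 10% of each nominal value (non-positive draws are
resampled so the marginal shape is preserved), recomputes the steady state
for each set, and evaluates the sensitivity of the readout to every
parameter there. Distributions of S_ij across the ensemble are summarised
per parameter and aggregated by reaction group.

Parameters whose nominal value is zero have S_ij = 0 identically (the
normalisation carries a factor p_j), so they are reported with zero
sensitivity without being perturbed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .reaction_network import NetworkModel
from .simulation import SS_FLOOR, Simulator

__all__ = [
    "EnsembleSpec",
    "MPSAResult",
    "sample_parameter_sets",
    "steady_state_sensitivity",
    "run_mpsa",
    "group_summary",
]


@dataclass(frozen=True)
class EnsembleSpec:
    """Size, dispersion and seed of the sampled parameter ensemble."""

    n: int = 100
    sd_fraction: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("ensemble size must be >= 1")
        if self.sd_fraction < 0:
            raise ValueError("sd_fraction must be >= 0")


def sample_parameter_sets(
    nominal: dict[str, float], spec: EnsembleSpec
) -> list[dict[str, float]]:
    """Draw ``spec.n`` parameter maps around ``nominal``.

    Each entry is drawn independently from N(nominal, (sd_fraction*nominal)^2);
    non-positive draws are resampled. Requires every nominal value > 0.
    """
    for name, value in nominal.items():
        if value <= 0:
            raise ValueError(f"nominal value for parameter {name!r} must be > 0, got {value}")
    rng = np.random.default_rng(spec.seed)
    names = list(nominal)
    means = np.array([nominal[k] for k in names])
    sds = spec.sd_fraction * means
    out = []
    for _ in range(spec.n):
        draw = rng.normal(means, sds)
        while np.any(draw <= 0):
            bad = draw <= 0
            draw[bad] = rng.normal(means[bad], sds[bad])
        out.append(dict(zip(names, draw)))
    return out


def _relaxed_output(sim: Simulator, y0, p, output_idx, inputs, tol):
    ss = sim.steady_state(y0=y0, p=p, inputs=inputs, tol=tol, t_chunk=5e4,
                          raise_on_failure=False)
    if not ss.converged:
        return None
    return ss.vector(sim.species)[output_idx], ss


def steady_state_sensitivity(
    model: NetworkModel | Simulator,
    parameter: str,
    output: str,
    delta: float = 1e-4,
    *,
    inputs: dict[str, float] | None = None,
    p: np.ndarray | None = None,
    base_state: np.ndarray | None = None,
    tol: float = 1e-9,
) -> float:
    """Normalised steady-state sensitivity S of ``output`` to ``parameter``.

    Central difference: the steady state is recomputed at p*(1 +/- delta)
    (warm-started from the base steady state) and S = (y+ - y-)/(2*delta*y0).
    Raises ``ValueError`` if the output steady state is at the solver floor
    (the normalisation 1/y_i is then meaningless).
    """
    sim = model if isinstance(model, Simulator) else Simulator(model)
    pvec = sim.compiled.p0.copy() if p is None else np.array(p, dtype=float)
    try:
        j = sim.compiled.param_names.index(parameter)
    except ValueError:
        raise KeyError(f"unknown parameter {parameter!r}") from None
    out_idx = sim.species.index(output)
    if pvec[j] == 0.0:
        return 0.0

    if base_state is None:
        base = sim.steady_state(p=pvec, inputs=inputs, tol=tol)
        base_state = base.vector(sim.species)
    y0 = base_state[out_idx]
    if y0 <= SS_FLOOR:
        raise ValueError(
            f"steady-state output {output!r} = {y0:.3g} nM is at the solver floor; "
            "the normalised sensitivity is undefined"
        )
    values = []
    for sign in (+1.0, -1.0):
        pj = pvec.copy()
        pj[j] = pvec[j] * (1.0 + sign * delta)
        res = _relaxed_output(sim, base_state, pj, out_idx, inputs, tol)
        if res is None:
            raise RuntimeError(f"steady state did not converge at perturbed {parameter!r}")
        values.append(res[0])
    return (values[0] - values[1]) / (2.0 * delta * y0)


@dataclass
class MPSAResult:
    """Ensemble sensitivities: per-sample records and per-parameter summary."""

    records: pd.DataFrame   # columns: sample, parameter, group, sensitivity
    summary: pd.DataFrame   # per parameter: group, quantiles, median |S|
    failures: int           # parameter sets excluded for non-convergence
    condition: str


def run_mpsa(
    model: NetworkModel,
    spec: EnsembleSpec,
    output: str,
    *,
    inputs: dict[str, float] | None = None,
    groups: dict[str, str] | None = None,
    delta: float = 1e-4,
    condition: str = "",
    tol: float = 1e-8,
) -> MPSAResult:
    """MPSA of ``output`` for every model parameter under one condition.

    For each of the ``spec.n`` sampled parameter sets the steady state is
    recomputed (warm-started from the nominal steady state) and the
    normalised sensitivity to each parameter is evaluated by central
    differences. Sets whose steady state does not converge are excluded and
    counted in ``failures``.
    """
    sim = Simulator(model)
    pnames = sim.compiled.param_names
    nominal = dict(zip(pnames, sim.compiled.p0))
    positive = {k: v for k, v in nominal.items() if v > 0}
    zero_params = [k for k, v in nominal.items() if v == 0]
    groups = groups or {k: "all" for k in pnames}
    out_idx = sim.species.index(output)

    nominal_ss = sim.steady_state(inputs=inputs, tol=tol)
    nominal_state = nominal_ss.vector(sim.species)

    sets = sample_parameter_sets(positive, spec)
    rows = []
    failures = 0
    for k, sample in enumerate(sets):
        pvec = np.array([sample.get(name, nominal[name]) for name in pnames])
        res = _relaxed_output(sim, nominal_state, pvec, out_idx, inputs, tol)
        if res is None:
            failures += 1
            continue
        y0, base = res
        base_state = base.vector(sim.species)
        if y0 <= SS_FLOOR:
            failures += 1
            continue
        for j, name in enumerate(pnames):
            if pvec[j] == 0.0:
                rows.append((k, name, groups[name], 0.0))
                continue
            vals = []
            bad = False
            for sign in (+1.0, -1.0):
                pj = pvec.copy()
                pj[j] = pvec[j] * (1.0 + sign * delta)
                r = _relaxed_output(sim, base_state, pj, out_idx, inputs, tol)
                if r is None:
                    bad = True
                    break
                vals.append(r[0])
            if bad:
                rows.append((k, name, groups[name], np.nan))
                continue
            rows.append((k, name, groups[name], (vals[0] - vals[1]) / (2 * delta * y0)))

    records = pd.DataFrame(rows, columns=["sample", "parameter", "group", "sensitivity"])
    summary = (
        records.groupby(["parameter", "group"], sort=False)["sensitivity"]
        .agg(
            median="median",
            q25=lambda s: s.quantile(0.25),
            q75=lambda s: s.quantile(0.75),
            median_abs=lambda s: s.abs().median(),
        )
        .reset_index()
    )
    # zero-valued parameters that never entered the ensemble still appear once
    for name in zero_params:
        if name not in summary["parameter"].values:
            summary.loc[len(summary)] = [name, groups[name], 0.0, 0.0, 0.0, 0.0]
    return MPSAResult(records=records, summary=summary, failures=failures,
                      condition=condition)


def group_summary(result: MPSAResult) -> pd.Series:
    """Median |S| per reaction group, sorted descending."""
    return (
        result.records.dropna(subset=["sensitivity"])
        .assign(abs_s=lambda df: df["sensitivity"].abs())
        .groupby("group")["abs_s"]
        .median()
        .sort_values(ascending=False)
    )
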