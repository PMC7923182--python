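# Methods

This note documents the models, their parameters, the numerical machinery and
the design decisions behind `wntrho`. Units are nM and minutes everywhere;
"nmol/L" values from the source literature are read as nM.

## Reaction-network representation

Every model is a `NetworkModel`: species (with initial concentrations and a
boundary flag), reactions over a closed catalogue of five rate-law kinds
(mass action, saturating signal-driven conversion, bilinear modifier mass
action, quasi-equilibrium competitive-promoter occupancy, zeroth-order
synthesis), global constants and timed events. The catalogue is closed on
purpose: every kinetic term in the shipped networks can be audited against
one of five formulas, and the SBML writer/reader can round-trip them exactly.

Boundary species (Wnt, Wnt5b, RhoGEF, RhoGAP) represent experimental inputs:
their derivative is clamped to zero and they change only through events,
which are realised as hard integrator restarts (the protocols are stepwise
set/reset of inputs, not smooth ramps). Compilation builds symbolic rates
with sympy and lambdifies both the right-hand side and its Jacobian; with the
analytic Jacobian the stiff solvers take milliseconds per steady state on the
40-species integrated model, which is what makes the ensemble sensitivity
analysis cheap.

### Numerical settings

- Integration: LSODA, rtol 1e-8, atol 1e-10 nM (both overridable).
- Steady state: integrate in growing chunks until
  max_i |dy_i/dt| / max(y_i, 1e-6 nM) ≤ 1e-9 min⁻¹, horizon cap 1e6 min.
  The 1e-6 nM floor avoids division blow-ups for near-zero species.
  Non-convergence is reported (flag or exception), never silently truncated;
  a non-decaying residual is flagged as possibly oscillatory.
- Sensitivities: central differences with relative step 1e-4; perturbed
  steady states are warm-started from the base steady state. Halving the step
  moves sensitivities on the shipped models by well under 1% (tested).
- Tightening the integration tolerances tenfold moves steady states by less
  than 0.1% (tested on the Rho model).

## Wnt/β-catenin module

Reactions r1–r17 are the published degradation-complex model built on
Xenopus-egg kinetics: Wnt activates Dishevelled (k1 = 0.182 nM⁻¹min⁻¹,
k2 = 0.0182 min⁻¹), active Dishevelled releases GSK3 from the APC·Axin·GSK3
complex, the phosphorylated complex binds β-catenin (K₈ = 120 nM),
phosphorylates it (k9 = k10 = 206 min⁻¹) and routes it to degradation
(k11 = 0.417 min⁻¹); β-catenin is synthesised at 0.423 nM/min and partitions
onto TCF (K₁₆ = 30 nM) and APC (K₁₇ = 1200 nM); Axin turns over at
0.167 min⁻¹. The original rapid-equilibrium binding steps (r7, r8, r16, r17)
are explicit mass-action pairs with the published dissociation constants and
fast on-rates chosen here (0.1, 0.05, 0.1, 0.01 nM⁻¹min⁻¹). Two core
constants were adapted from the published values: the
Dishevelled catalysis constant k3 (0.05 → 0.8 nM⁻¹min⁻¹) and the Axin
synthesis term, which becomes β-catenin-induced (r14a/r14b,
4e-5 min⁻¹ each on free and TCF-bound β-catenin) — the negative feedback on
the pathway. Together these set the Wnt-off β-catenin level near the
published reference scale (≈35 nM) and give the sustained-Wnt response
(≈9-fold in β-catenin/TCF) required for the readout contrast below; with the
literal original values the printed 0.3 → 0.1 nM readout swing is
algebraically unreachable under the shared-site promoter law.

Extensions:

- **PG pools.** PG binds TCF and the active degradation complex with
  β-catenin's binding constants (stated assumption). PG is treated as a
  conserved pool (free / complex-bound / TCF-bound / desmosomal in the
  integrated model): the titration protocol prescribes fixed PG levels with
  no PG source, so the phospho-degradation branch is not applied to PG.
- **TCF regulatory loop.** TCF mRNA synthesis is saturably driven by the
  β-catenin/TCF dimer (half-saturation 0.05 nM — deeply saturated at
  physiological dimer levels), with first-order mRNA and free-TCF turnover
  tuned so free TCF rests at 15 nM. Saturation is what makes free TCF
  insensitive to PG sequestration (synthesis replenishes the free pool at a
  fixed rate); this is the mechanism behind the flat single-competition
  variant. The no-feedback variant instead conserves total TCF at 15 nM.
- **Readout.** Adipogenic mRNA is transcribed under shared-promoter-site
  competition, rate = (basal + act·p/K_act)/(1 + p/K_act + b/K_rep) with
  p = [PG/TCF], b = [β-catenin/TCF], and decays at 0.02 min⁻¹. This is the
  quasi-equilibrium reduction of a three-state promoter (empty / B-bound /
  P-bound); the tests verify it against an explicit promoter micro-model
  integrated to steady state. The four constants (basal 7.99e-3 nM/min,
  act 8.97e-3 nM/min, K_act 3.39 nM, K_rep 52.8 nM) were solved exactly, at
  construction time, from four reference steady states: 0.3 / 0.1 nM (Wnt
  off/on at PG = 0) and a Wnt-state difference of 45% at PG = 0 falling to 5%
  at PG = 500 nM. The percent difference is computed under two conventions,
  since the normalisation is not uniquely determined by those figures:
  off-referenced, (off − on)/off; and range-referenced, (off − on) divided by
  the maximal readout over the titration (the Wnt-off state at 500 nM PG).
  The 45%/5% pair is consistent with the 0.3/0.1 steady states only under the
  range-referenced convention (off-referenced, 0.3 vs 0.1 is a 67%
  difference); both numbers are reported everywhere.

## RhoA-ROCK module

RhoA (100 nM total) cycles between GDP- and GTP-bound forms: GEF-driven
exchange and GAP-driven hydrolysis both follow the saturating signal law
(k = 0.06 min⁻¹, K = 100 nM) and an intrinsic hydrolysis of 0.025 min⁻¹
keeps the cycle defined when both inputs are zero. ROCK (100 nM) is activated
by RhoA-GTP and, in the physiological state, by RhoA-GDP at one tenth of the
rate — the relative strength is a design choice (only the existence of both
routes is given); it is what distinguishes a GAP-inhibited pathway (residual
pROK of a few nM) from the dominant-negative kinase (none), and that
distinction carries the feedback-experiment ordering. pROK dephosphorylates
at 0.05 min⁻¹. F-actin assembles at k·[pROK]·[gActin] (k = 0.1 nM⁻¹min⁻¹)
and disassembles at 0.1 min⁻¹, so the F:G ratio tracks pROK. G-actin binds
MKL1 (K_d = 10 nM); only free cytoplasmic MKL1 shuttles into the nucleus
(import 0.1, export 0.05 min⁻¹); nuclear MKL1 represses the PPARγ readout
through the single-repressor promoter law. Totals: 500 nM actin, 100 nM MKL1.

`set_dominant_negative` zeroes both ROCK-activation constants and halves
every pROK-catalysed rate constant; the two switches are independent flags
(both on by default), and halving composes (applying it twice quarters the
constants) because it encodes a parameter scaling, not a state.

## Integrated crosstalk model

Union of the two networks (double-competition, feedback-on Wnt variant;
PPARγ replaces the generic adipogenic mRNA as the readout, with PG/TCF
activating and both β-catenin/TCF and nuclear MKL1 repressing). Crosstalk:

1. **Dishevelled competition.** Wnt drives Dshi → cDsh (the canonical branch
   keeps the core model's constants); Wnt5b drives Dshi → ncDsh with
   saturating ligand engagement, rate = 0.24 min⁻¹ · [Dshi] ·
   Wnt5b/(30 nM + Wnt5b). ncDsh activates Daam1 (50 nM total, activation
   0.04 nM⁻¹min⁻¹, deactivation 0.5 min⁻¹), and active Daam1 acts as an
   additional GEF-like signal on the exchange step.
2. **Desmosomal PG.** pROK drives PG → dPG by the saturating law
   (k = 0.06 min⁻¹, K = 100 nM); release is first order (0.002 min⁻¹), so
   the dPG fraction follows Rho activity: with the pathway driven on, most
   PG is desmosomal and the nuclear competition is disarmed.
3. **Siah2.** Wnt5b activates Siah2 (50 nM pool, 0.065 min⁻¹ at ligand
   saturation, same 30 nM ligand constant), active Siah2 binds APC
   (K_d = 10 nM) and the Siah2·APC complex degrades free cytoplasmic
   β-catenin (1e-5 nM⁻¹min⁻¹); TCF- and complex-bound pools are untouched.

The ligand saturation constant (30 nM) is a structural requirement, not a
tuning nicety: the condition-matrix orderings must hold over a 10–200 nM
Wnt5b sweep, and with linear ligand engagement the Daam1 pool saturates by
10 nM while the Siah2 branch keeps growing to 200 nM, which provably breaks
the ordering at one end of the sweep or the other.

The readout constants (basal 2.11 nM/min, act 0.424 nM/min, K_act inherited
from the Wnt readout, K_rep 1.62 nM for β-catenin/TCF and 18.7 nM for
nuclear MKL1) were solved exactly against the four printed condition-matrix
steady states (conditions 1, 4, 6, 8 → 2, 11, 4, 16 nM PPARγ) at the default
inputs (Wnt 1 nM, Wnt5b 100 nM, GEF/GAP 100 nM); conditions 2, 3, 5, 7 are
then genuine predictions of the calibrated model (2.39, 9.42, 4.38,
12.72 nM). The Wnt5b input level for conditions 2, 3, 6, 7 is not fixed by the
reference scenarios and defaults to 100 nM; all qualitative orderings are tested
across 10–200 nM. Condition 7 is run with Wnt5b present (the scenario is described with
residual Wnt5b-mediated Rho activity); the alternative
without Wnt5b is a one-line change to the scenario file. Total PG defaults to
300 nM in the integrated model (the mutant-genotype convention fixes only
PG ≠ 0).

With `wnt5b_feedback`, gWnt5b is transcribed under single-repressor control
by nuclear MKL1 (4 nM/min unrepressed, repression scale 5 nM) and translated
into Wnt5b (0.02 min⁻¹ each for transcript decay, translation and ligand
decay), closing the loop in which active RhoA-ROCK suppresses Wnt5b. The
three feedback scenarios are RKP_up (GEF 100 nM), RKP_down (GAP 100 nM) and
DN-RhoK (dominant-negative parameters under the RKP_up inputs), all at
Wnt = 1 nM.

## Sensitivity analysis

N = 100 parameter sets are drawn from independent normals (mean = nominal,
sd = 10% of nominal; non-positive draws are resampled to preserve the
marginal shape — with a 10% sd this is a <1e-23 event per draw, but the
contract must be defined). For each set the steady state is recomputed and
the normalised sensitivity of the readout to every parameter evaluated by
central differences. "Time" in the sensitivity definition is resolved to
steady state; the Wnt model is evaluated at the post-step state (Wnt = 1 nM)
at PG = 0 ("low") and 500 nM ("high" — the titration-grid endpoints), the
Rho model in the driven-on state (GEF 100 nM). Parameters with nominal value
zero have S ≡ 0 by the p/y normalisation and are reported without being
perturbed. Results are summarised per parameter (quantiles across the
ensemble) and aggregated by reaction group; the reference comparison is
ordinal (group rankings), so that is what the tests assert.

## Synthetic validation data

The generator emulates qRT-PCR fold-change experiments: drugs map to model
interventions (CHIR99021 → Wnt input 1 nM; XAV939 → Wnt 0 plus twofold Axin
stabilisation, mimicking tankyrase inhibition; Y27632 → pROK-catalysed rates
× 0.1), untreated cells get a basal canonical tone (Wnt 0.2 nM) with the Rho
pathway driven on, and the genotype convention is PG = 0 (WT) versus 300 nM
(PKP2-mutant). Replicates are lognormal around the model-predicted fold
change with σ² = ln(1 + cv²) (default cv 0.15, n = 3), so the geometric mean
equals the generating mean; ΔΔCt normalisation is emulated by working
directly in fold-change space, with housekeeping noise folded into the cv.
Concordance calls a data direction from a percentile bootstrap of the mean
log fold change, requiring the interval to clear a minimal effect size
(default 5%) — significance plus magnitude — and compares it with the
predicted direction.

What the generator does *not* emulate: amplification-efficiency artefacts,
between-batch effects, drug dose–response and pharmacokinetics, or any
transcriptional readout beyond the single PPARγ proxy. Passing
trend-concordance tests therefore shows that the pipeline recovers directions
the model itself generates under multiplicative noise — a self-consistency
property — not that the model fits real qRT-PCR data.

## Known limitations

- Appendix-level parameter values of the source models were not available;
  extension and crosstalk constants were calibrated once, at construction
  time, against the printed steady states and orderings (the source's own
  stated procedure), and are frozen as package defaults. Quantities not used
  in calibration (conditions 2, 3, 5, 7; the feedback-experiment levels) are
  predictions and carry that caveat.
- PG is a single well-mixed pool per compartment role; nuclear/cytoplasmic
  shuttling is not compartmentalised.
- The Wnt-inhibitor intervention raises WT PPARγ under XAV939 more than real
  healthy cardiomyocytes appear to respond; only the mutant-genotype trends
  are asserted.
- No stochastic simulation, no delays, no spatial structure; the SBML reader
  accepts only the package's own closed rate-law subset (documents must carry
  the structured kinetic-law annotation the writer emits).
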