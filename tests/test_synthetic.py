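"""Synthetic qRT-PCR generator, treatment predictions, trend concordance."""

import numpy as np
import pytest

from wntrho import concordance, generate_replicates, predict_treatment_effects
from wntrho.synthetic import DEFAULT_TREATMENTS, Intervention


class TestInterventions:
    def test_composition_order_independent(self):
        xav, y = DEFAULT_TREATMENTS["XAV939"], DEFAULT_TREATMENTS["Y27632"]
        assert xav.compose(y) == y.compose(xav)

    def test_conflicting_levels_rejected(self):
        with pytest.raises(ValueError, match="conflicting"):
            Intervention(wnt=1.0).compose(Intervention(wnt=0.0))

    def test_scalings_multiply(self):
        a = Intervention(prok_scale=0.5).compose(Intervention(prok_scale=0.5))
        assert a.prok_scale == pytest.approx(0.25)


class TestGenerator:
    def test_same_seed_identical(self):
        means = {"NT": 1.0, "T": 2.0}
        a = generate_replicates(means, cv=0.2, n=5, seed=9)
        b = generate_replicates(means, cv=0.2, n=5, seed=9)
        assert a.data.equals(b.data)

    def test_vanishing_cv_recovers_means(self):
        means = {"NT": 1.0, "T": 2.0}
        ds = generate_replicates(means, cv=1e-12, n=3, seed=0)
        for label, mean in means.items():
            np.testing.assert_allclose(ds.replicates(label), mean, rtol=1e-9)

    def test_nonpositive_cv_rejected(self):
        with pytest.raises(ValueError, match="cv"):
            generate_replicates({"NT": 1.0}, cv=0.0)
        with pytest.raises(ValueError, match="replicates"):
            generate_replicates({"NT": 1.0}, cv=0.1, n=1)
        with pytest.raises(ValueError, match="mean"):
            generate_replicates({"NT": 0.0}, cv=0.1)

    def test_geometric_mean_recovery(self):
        ds = generate_replicates({"T": 2.0}, cv=0.2, n=10_000, seed=4)
        gm = np.exp(np.mean(np.log(ds.replicates("T"))))
        assert gm == pytest.approx(2.0, rel=0.01)

    def test_nt_generating_mean_is_one(self, treatment_predictions):
        folds = treatment_predictions["PKP2mut"]["fold_change"].to_dict()
        ds = generate_replicates(folds, cv=0.15, n=3, seed=0)
        assert ds.generating_means["NT"] == pytest.approx(1.0)


class TestTreatmentPredictions:
    def test_double_inhibition_upregulates_pparg(self, treatment_predictions):
        folds = treatment_predictions["PKP2mut"]["fold_change"]
        assert folds["XAV939+Y27632"] > 1.0

    def test_chir_downregulates_in_mutant(self, treatment_predictions):
        assert treatment_predictions["PKP2mut"]["fold_change"]["CHIR99021"] < 1.0

    def test_wt_chir_y_closer_to_untreated_than_mutant(self, treatment_predictions):
        wt = treatment_predictions["WT"]["fold_change"]["CHIR99021+Y27632"]
        mut = treatment_predictions["PKP2mut"]["fold_change"]["CHIR99021+Y27632"]
        assert abs(np.log(wt)) < abs(np.log(mut))

    def test_mutant_expresses_more_pparg_untreated(self, treatment_predictions):
        assert (
            treatment_predictions["PKP2mut"].loc["NT", "pparg"]
            > treatment_predictions["WT"].loc["NT", "pparg"]
        )

    def test_genotype_contrast_across_pg_sweep(self):
        """PKP2mut (PG > 0) shows higher untreated PPARgamma than WT over a
        50-500 nM PG sweep."""
        wt_nt = predict_treatment_effects(
            {"NT": Intervention()}, genotype="WT"
        ).loc["NT", "pparg"]
        for pg in (50.0, 200.0, 500.0):
            mut_nt = predict_treatment_effects(
                {"NT": Intervention()}, genotype="PKP2mut", pg_total=pg
            ).loc["NT", "pparg"]
            assert mut_nt > wt_nt


class TestConcordance:
    def test_all_means_one_all_no_change(self):
        preds = {"A": 1.0, "B": 1.0}
        ds = generate_replicates(preds, cv=0.05, n=8, seed=21)
        report = concordance(preds, ds, n_boot=200, seed=0)
        assert (report.table["data_direction"] == "no_change").all()
        assert report.fraction_agreeing == 1.0

    def test_flipped_directions_zero_agreement(self):
        preds = {"A": 4.0, "B": 0.25}
        flipped = generate_replicates({"A": 0.25, "B": 4.0}, cv=0.05, n=6, seed=2)
        report = concordance(preds, flipped, n_boot=200, seed=0)
        assert report.fraction_agreeing == 0.0

    def test_mismatched_labels_rejected(self):
        ds = generate_replicates({"A": 1.0}, cv=0.1, n=3, seed=0)
        with pytest.raises(KeyError, match="labels differ"):
            concordance({"B": 1.0}, ds, n_boot=10, seed=0)

    def test_recovery_of_strong_effects_at_small_n(self, treatment_predictions):
        """Data generated from the model's own fold changes (cv = 0.1, n = 3)
        recovers the direction of every effect larger than 3 cv."""
        folds = treatment_predictions["PKP2mut"]["fold_change"].to_dict()
        ds = generate_replicates(folds, cv=0.1, n=3, seed=13)
        report = concordance(folds, ds, n_boot=200, seed=5)
        strong = {k for k, v in folds.items() if abs(np.log(v)) > 3 * 0.1}
        assert strong  # the scenario has well-separated effects
        table = report.table.set_index("treatment")
        assert table.loc[sorted(strong), "agree"].all()

    def test_full_recovery_at_large_n(self, treatment_predictions):
        """Self-consistency: at n = 10^4 replicates and cv = 0.1 the dataset is
        fully concordant with the generating predictions."""
        folds = treatment_predictions["PKP2mut"]["fold_change"].to_dict()
        ds = generate_replicates(folds, cv=0.1, n=10_000, seed=17)
        report = concordance(folds, ds, n_boot=200, seed=3)
        assert report.fraction_agreeing == 1.0
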