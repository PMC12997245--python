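"""Fit statistics, cross-validation, Y-scrambling and external metrics."""

import numpy as np
import pandas as pd
import pytest

from conftest import make_table
from ilqsar.descriptors import DescriptorTable
from ilqsar.mlr import fit_ols, predict
from ilqsar.validation import (
    concordance_ccc,
    cross_validate,
    external_metrics,
    loo_predictions,
    regression_metrics,
    y_scramble,
)


def brute_force_loo(table, names):
    """Independent LOO oracle: literally refit with each row held out."""
    ids = list(table.response.index)
    preds = {}
    for held in ids:
        keep = [i for i in ids if i != held]
        sub = DescriptorTable(data=table.data.loc[keep],
                              response=table.response.loc[keep])
        model = fit_ols(sub, names)
        preds[held] = predict(model, table.data.loc[[held]]).iloc[0]
    return pd.Series(preds)


class TestRegressionMetrics:
    def test_hand_computed_three_point_example(self):
        # y=(0,1,2), yhat=(0,1,1), p=1: SSres=1, SStot=2 -> R2=0.5;
        # RMSE=sqrt(1/3); S=sqrt(1/1)=1; SSreg/p / (SSres/dof) = 1; AAD=1/3
        m = regression_metrics([0, 1, 2], [0, 1, 1], p=1)
        assert m.r2 == pytest.approx(0.5)
        assert m.rmse == pytest.approx(np.sqrt(1 / 3))
        assert m.s == pytest.approx(1.0)
        assert m.fisher_f == pytest.approx(1.0)
        assert m.aad == pytest.approx(1 / 3)

    def test_perfect_fit(self):
        y = [-3.0, -2.0, -1.0, -2.5]
        m = regression_metrics(y, y, p=2)
        assert m.r2 == 1.0 and m.rmse == 0.0 and m.aad == 0.0 and m.aard_pct == 0.0

    def test_s_rmse_consistency_identity(self):
        rng = np.random.default_rng(0)
        y = rng.normal(size=20)
        yh = y + rng.normal(scale=0.3, size=20)
        m = regression_metrics(y, yh, p=3)
        assert m.s ** 2 * (m.n - m.p - 1) == pytest.approx(m.rmse ** 2 * m.n, abs=1e-10)

    def test_aard_positive_for_negative_responses(self):
        m = regression_metrics([-2.0, -3.0, -4.0], [-2.2, -2.7, -4.4], p=1)
        assert m.aard_pct > 0

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            regression_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0], p=1)


class TestCrossValidation:
    def test_noiseless_linear_data_gives_q2_of_one(self):
        table = make_table(15, ["C0.000", "C0.001"], seed=1,
                           beta=np.array([1.0, -2.0]), intercept=0.5)
        q2, _ = cross_validate(table, table.descriptor_names, "LOO")
        assert q2 == pytest.approx(1.0, abs=1e-9)

    def test_press_shortcut_equals_explicit_refits(self):
        table = make_table(15, ["C0.000", "C0.001"], seed=9,
                           beta=np.array([0.4, 0.8]), noise_sd=1.5)
        names = table.descriptor_names
        shortcut = loo_predictions(table, names)
        brute = brute_force_loo(table, names)
        np.testing.assert_allclose(shortcut.loc[brute.index], brute, atol=1e-10)

    def test_lmo_close_to_loo(self):
        table = make_table(60, ["C0.000", "C0.001", "C0.002"], seed=21,
                           beta=np.array([0.5, -0.5, 0.3]), noise_sd=1.0)
        names = table.descriptor_names
        q2_loo, _ = cross_validate(table, names, "LOO")
        q2_lmo, _ = cross_validate(table, names, "LMO", frac=0.2,
                                   iterations=1000, seed=0)
        assert q2_lmo == pytest.approx(q2_loo, abs=0.02)

    def test_q2_never_beats_resubstitution_r2(self):
        for seed in range(8):
            table = make_table(25, ["C0.000", "C0.001"], seed=seed,
                               beta=np.array([1.0, 1.0]), noise_sd=2.0)
            names = table.descriptor_names
            model = fit_ols(table, names)
            yh = predict(model, table.data)
            r2 = regression_metrics(table.response, yh, p=2).r2
            q2, _ = cross_validate(table, names, "LOO")
            assert q2 <= r2 + 1e-12

    def test_fold_too_small_rejected(self):
        table = make_table(8, ["C0.000", "C0.001", "C0.002"], seed=2,
                           beta=np.ones(3))
        with pytest.raises(ValueError, match="fold"):
            cross_validate(table, table.descriptor_names, "LMO", frac=0.45,
                           iterations=10, seed=0)


class TestExternalMetrics:
    def test_hand_computed_four_point_example(self):
        y_train = np.array([0.0, 1.0, 2.0, 3.0])  # mean 1.5
        y = np.array([0.0, 1.0, 2.0, 3.0])
        yh = np.array([0.1, 0.9, 2.2, 2.8])
        rep = external_metrics(y_train, y, yh)
        ssres = ((y - yh) ** 2).sum()
        assert rep.q2_f1 == pytest.approx(1 - ssres / ((y - 1.5) ** 2).sum())
        assert rep.q2_f2 == pytest.approx(1 - ssres / ((y - y.mean()) ** 2).sum())
        assert rep.q2_f3 == pytest.approx(
            1 - (ssres / 4) / (((y_train - 1.5) ** 2).sum() / 4))
        sxy = ((y - y.mean()) * (yh - yh.mean())).sum()
        ccc = 2 * sxy / (((y - y.mean()) ** 2).sum() + ((yh - yh.mean()) ** 2).sum()
                         + 4 * (y.mean() - yh.mean()) ** 2)
        assert rep.ccc == pytest.approx(ccc)

    def test_perfect_external_prediction(self):
        y = np.array([-3.0, -2.0, -1.0, -2.5])
        rep = external_metrics(np.array([-2.0, -1.5, -3.0]), y, y)
        assert rep.ccc == pytest.approx(1.0)
        assert rep.q2_f1 == pytest.approx(1.0)
        assert rep.q2_f2 == pytest.approx(1.0)
        assert rep.q2_f3 == pytest.approx(1.0)
        assert rep.r2m_delta == pytest.approx(0.0, abs=1e-12)

    def test_q2f1_dominates_q2f2(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            ytr = rng.normal(size=30)
            y = rng.normal(size=10)
            yh = y + rng.normal(scale=0.5, size=10)
            rep = external_metrics(ytr, y, yh)
            assert rep.q2_f1 >= rep.q2_f2 - 1e-12

    def test_ccc_bounded_by_pearson(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            y = rng.normal(size=15)
            yh = 0.5 * y + rng.normal(scale=0.7, size=15) + 0.3
            assert abs(concordance_ccc(y, yh)) <= abs(np.corrcoef(y, yh)[0, 1]) + 1e-12


class TestYScramble:
    def _table(self):
        return make_table(50, ["C0.000", "C0.001", "C0.002"], seed=3,
                          beta=np.array([1.0, -1.0, 0.5]), noise_sd=1.0)

    def test_zero_iterations_flagged_empty(self):
        res = y_scramble(self._table(), ["C0.000", "C0.001", "C0.002"], n_iter=0, seed=1)
        assert res.r2_values == [] and res.mean_r2 is None

    def test_seed_reproducibility(self):
        table = self._table()
        names = table.descriptor_names
        a = y_scramble(table, names, n_iter=50, seed=7)
        b = y_scramble(table, names, n_iter=50, seed=7)
        assert a.r2_values == b.r2_values

    def test_mean_matches_chance_expectation(self):
        """Scrambled R2 averages p/(n-1): pure chance correlation level."""
        table = make_table(80, [f"C0.00{i}" for i in range(5)], seed=8,
                           beta=np.ones(5), noise_sd=1.0)
        res = y_scramble(table, table.descriptor_names, n_iter=500, seed=0)
        expect = 5 / 79
        se = np.std(res.r2_values) / np.sqrt(len(res.r2_values))
        assert res.mean_r2 == pytest.approx(expect, abs=max(3 * se, 0.01))
        assert all(r <= 1.0 for r in res.r2_values)
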