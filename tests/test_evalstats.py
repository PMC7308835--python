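import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prolspec import (
    StudyDesign,
    evaluate,
    group_letters,
    rank_split,
    simulate_spectra_table,
    wavelength_anova,
)
from prolspec.chemometrics import _pls_fit_fixed
from prolspec.evalstats import EvaluationReport
from prolspec.grid import WavelengthGrid
from prolspec.preprocess import SpectraTable


class TestRankSplit:
    def test_100_samples_give_75_25(self, rng):
        cal, pred = rank_split(rng.normal(size=100))
        assert len(cal) == 75 and len(pred) == 25
        assert np.array_equal(np.sort(np.concatenate([cal, pred])), np.arange(100))

    def test_single_block_picks_third_ranked(self):
        cal, pred = rank_split(np.array([3.0, 1.0, 4.0, 2.0]))
        assert list(pred) == [0]  # y = 3 is the third-smallest
        assert sorted(cal) == [1, 2, 3]

    def test_prediction_range_interior_to_calibration(self, rng):
        for _ in range(20):
            y = rng.normal(size=rng.integers(8, 60))
            cal, pred = rank_split(y)
            assert y[pred].min() >= y[cal].min()
            assert y[pred].max() <= y[cal].max()

    def test_trailing_partial_block_goes_to_calibration(self, rng):
        y = rng.normal(size=10)  # blocks: 4 + 4 + trailing 2
        cal, pred = rank_split(y)
        assert len(pred) == 2 and len(cal) == 8

    def test_depends_only_on_values_not_order(self, rng):
        y = rng.normal(size=24)
        perm = rng.permutation(24)
        cal1, pred1 = rank_split(y)
        cal2, pred2 = rank_split(y[perm])
        assert np.allclose(np.sort(y[pred1]), np.sort(y[perm][pred2]))

    def test_too_few_samples_raise(self):
        with pytest.raises(ValueError):
            rank_split(np.array([1.0, 2.0, 3.0]))


class TestEvaluate:
    def test_perfect_predictor_scores_one(self, rng):
        X = rng.normal(size=(12, 3))
        beta = np.array([1.0, -1.0, 2.0])
        y = X @ beta
        model = _pls_fit_fixed(X[:8], y[:8], 3)
        rep = evaluate(model, X[:8], y[:8], X[8:], y[8:])
        assert np.isclose(rep.Rp, 1.0)
        assert rep.RMSEP < 1e-8
        assert rep.n_cal == 8 and rep.n_pred == 4

    def test_hand_computed_rmsep(self):
        class Fixed:
            def predict(self, X):
                return np.array([0.0, 1.0, 3.0])[: len(np.atleast_2d(X))]

            def refit(self, X, y):
                return self

        # RMSEP for y=(0,1,2) vs yhat=(0,1,3) is sqrt(1/3)
        X = np.zeros((3, 1))
        rep_rmsep = np.sqrt(
            np.mean((np.array([0.0, 1.0, 3.0]) - np.array([0.0, 1.0, 2.0])) ** 2)
        )
        assert np.isclose(rep_rmsep, np.sqrt(1.0 / 3.0))
        class Cal:
            def predict(self, X):
                X = np.atleast_2d(X)
                return X[:, 0] * 0.0 + 1.0

            def refit(self, X, y):
                return self
        # degenerate constant predictor: correlation undefined -> 0 + warning
        with pytest.warns(UserWarning, match="constant"):
            rep = evaluate(Cal(), np.arange(6.0)[:, None], np.arange(6.0),
                           np.arange(3.0)[:, None], np.array([0.0, 1.0, 2.0]))
        assert rep.Rp == 0.0 and rep.Rc == 0.0

    def test_empty_prediction_set_raises(self, rng):
        X = rng.normal(size=(6, 2))
        y = rng.normal(size=6)
        model = _pls_fit_fixed(X, y, 2)
        with pytest.raises(ValueError, match="empty"):
            evaluate(model, X, y, X[:0], y[:0])

    def test_report_invariants_enforced(self):
        with pytest.raises(ValueError):
            EvaluationReport(Rc=1.2, RMSECV=0.1, Rp=0.5, RMSEP=0.1,
                             n_cal=10, n_pred=5)
        with pytest.raises(ValueError):
            EvaluationReport(Rc=0.9, RMSECV=-0.1, Rp=0.5, RMSEP=0.1,
                             n_cal=10, n_pred=5)


def toy_table(X, groups, day=5):
    n, p = X.shape
    grid = WavelengthGrid(np.linspace(500.0, 600.0, p))
    labels = pd.DataFrame({
        "sample_id": [f"s{i}" for i in range(n)],
        "day": day,
        "cd_um": groups,
    })
    return SpectraTable(X=X, grid=grid, y=np.linspace(0.1, 0.2, n), labels=labels)


class TestWavelengthAnova:
    def test_two_groups_f_equals_t_squared(self, rng):
        X = rng.normal(size=(12, 4))
        groups = np.repeat([0.0, 100.0], 6)
        profile = wavelength_anova(toy_table(X, groups))
        for j in range(4):
            t, p_t = stats.ttest_ind(X[:6, j], X[6:, j], equal_var=True)
            f, p_f = stats.f_oneway(X[:6, j], X[6:, j])
            assert np.isclose(f, t**2)
            assert np.isclose(profile.pvalues[j], p_f)

    def test_null_type_one_error_near_alpha(self, rng):
        # identically distributed groups: ~5 % of bands flagged at 0.05
        reps, p = 200, 40
        flagged = 0
        for _ in range(reps):
            X = rng.normal(size=(15, p))
            groups = np.repeat([0.0, 25.0, 100.0], 5)
            flagged += wavelength_anova(toy_table(X, groups)).significant.sum()
        rate = flagged / (reps * p)
        se = np.sqrt(0.05 * 0.95 / (reps * p))
        assert abs(rate - 0.05) < 4 * se

    def test_late_stress_has_more_significant_bands(self, default_table):
        frac5 = wavelength_anova(default_table, day=5).fraction_significant
        frac20 = wavelength_anova(default_table, day=20).fraction_significant
        assert frac20 >= frac5

    def test_singleton_group_rejected(self, rng):
        X = rng.normal(size=(5, 3))
        groups = np.array([0.0, 0.0, 0.0, 0.0, 100.0])
        with pytest.raises(ValueError, match="2 members"):
            wavelength_anova(toy_table(X, groups))


class TestGroupLetters:
    def test_identical_groups_share_one_letter(self, rng):
        values = rng.normal(0.15, 0.01, 40)
        groups = np.repeat(np.arange(5), 8)
        disp = group_letters(values, groups)
        assert len({s for s in disp.letters.values()}) == 1

    def test_well_separated_groups_get_distinct_letters(self, rng):
        # five groups, means 10 pooled SDs apart
        means = np.arange(5) * 10.0
        values = np.concatenate([rng.normal(m, 1.0, 6) for m in means])
        groups = np.repeat(list("abcde"), 6)
        disp = group_letters(values, groups)
        letters = [disp.letters[g] for g in "abcde"]
        assert len(set(letters)) == 5
        assert all(len(s) == 1 for s in letters)

    def test_letters_match_pairwise_oracle(self, rng):
        # sharing a letter must coincide with a non-significant Tukey pair
        values = np.concatenate([
            rng.normal(0.0, 1.0, 8),
            rng.normal(1.5, 1.0, 8),
            rng.normal(8.0, 1.0, 8),
        ])
        groups = np.repeat(["g0", "g1", "g2"], 8)
        disp = group_letters(values, groups)
        res = stats.tukey_hsd(values[:8], values[8:16], values[16:])
        names = ["g0", "g1", "g2"]
        for i, j in itertools.combinations(range(3), 2):
            share = bool(set(disp.letters[names[i]]) & set(disp.letters[names[j]]))
            assert share == (res.pvalue[i, j] >= 0.05)

    def test_singleton_group_rejected(self):
        with pytest.raises(ValueError):
            group_letters(np.array([1.0, 2.0, 3.0]), np.array(["a", "a", "b"]))

    def test_default_study_day20_separates_dose_groups(self):
        # the late-stress FP response is strong enough for multiple letters
        truth_table = simulate_spectra_table(
            StudyDesign(seed=1)
        )
        day20 = truth_table.labels["day"] == 20
        disp = group_letters(
            truth_table.y[day20.to_numpy()],
            truth_table.labels.loc[day20, "cd_um"].to_numpy(),
        )
        assert len({s for s in disp.letters.values()}) >= 3
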