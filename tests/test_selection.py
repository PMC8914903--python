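"""Correlation screening and wavelet sensitivity-coefficient selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from npkspec.features import feature_table
from npkspec.selection import (
    correlation_table,
    pearson_r,
    select_sensitivity_coefficients,
    significance,
)
from npkspec.wavelet import detail_bank


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)
        assert pearson_r(x, -x) == pytest.approx(-1.0)

    def test_matches_direct_summation_oracle(self, rng):
        x = rng.normal(size=50)
        y = rng.normal(size=50)
        xc, yc = x - x.mean(), y - y.mean()
        oracle = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
        assert pearson_r(x, y) == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_r(np.ones(5), np.arange(5.0))

    @given(st.permutations(list(range(12))))
    def test_permutation_invariance(self, perm):
        rng = np.random.default_rng(0)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        p = np.asarray(perm)
        assert pearson_r(x[p], y[p]) == pytest.approx(pearson_r(x, y), abs=1e-12)


class TestSignificance:
    def test_zero_correlation_is_insignificant(self):
        p, flag = significance(0.0, 30)
        assert p == pytest.approx(1.0)
        assert flag == ""

    def test_strong_correlation_at_trial_size_flagged_001(self):
        # r = 0.905 at n = 72 is far beyond the 0.01 threshold
        p, flag = significance(0.905, 72)
        assert p < 1e-10
        assert flag == "0.01"

    def test_perfect_correlation_gives_zero_p(self):
        p, flag = significance(1.0, 10)
        assert p == 0.0 and flag == "0.01"

    def test_flags_monotone_in_abs_r(self):
        order = {"": 0, "0.05": 1, "0.01": 2}
        flags = [order[significance(r, 20)[1]] for r in np.linspace(0, 0.99, 40)]
        assert flags == sorted(flags)


class TestCorrelationTable:
    def test_feature_equal_to_response_scores_one(self):
        df = pd.DataFrame({"a": [1.0, 2, 3, 4], "b": [4.0, 1, 3, 2]},
                          index=list("wxyz"))
        y = pd.Series([1.0, 2, 3, 4], index=list("wxyz"))
        tab = correlation_table(df, y)
        assert tab.loc["a", "r"] == pytest.approx(1.0)

    def test_one_record_per_feature_on_trial_data(self, default_dataset):
        feats = feature_table(default_dataset.spectra.iloc[:20])
        tab = correlation_table(feats, default_dataset.samples["N"].iloc[:20])
        assert len(tab) == 24

    def test_matches_per_variable_pearson_loop(self, default_dataset):
        feats = feature_table(default_dataset.spectra.iloc[:15])
        y = default_dataset.samples["P"].iloc[:15]
        tab = correlation_table(feats, y)
        for col in feats.columns:
            assert tab.loc[col, "r"] == pytest.approx(
                pearson_r(feats[col], y), abs=1e-12)

    def test_constant_variable_flagged_not_crashing(self):
        df = pd.DataFrame({"const": np.ones(6), "ok": np.arange(6.0)})
        tab = correlation_table(df, pd.Series(np.arange(6.0)))
        assert np.isnan(tab.loc["const", "r"])
        assert tab.loc["const", "flag"] == "undefined"


def small_bank(rng, n_samples=20, n_bands=40):
    return {
        (basis, level): rng.normal(size=(n_samples, n_bands))
        for basis in ("db2", "db3")
        for level in (4, 5)
    }


class TestSelectSensitivityCoefficients:
    def test_planted_signal_recovered_first(self, rng):
        bank = small_bank(rng)
        y = 3.0 * bank[("db3", 5)][:, 17] + 1.0
        picked = select_sensitivity_coefficients(bank, y, k=3)
        top = picked[0]
        assert (top.basis, top.level, top.band_index) == ("db3", 5, 17)
        assert abs(top.r) > 0.9999

    def test_contract_k_records_sorted_by_abs_r(self, default_dataset):
        bank = detail_bank(default_dataset.spectra)
        y = default_dataset.samples["N"].to_numpy()
        picked = select_sensitivity_coefficients(bank, y, k=3)
        assert len(picked) == 3
        mags = [abs(c.r) for c in picked]
        assert mags == sorted(mags, reverse=True)

    def test_matches_brute_force_enumeration(self, rng):
        bank = small_bank(rng, n_samples=15, n_bands=12)
        y = rng.normal(size=15)
        picked = select_sensitivity_coefficients(bank, y, k=5)
        brute = []
        for (basis, level), mat in bank.items():
            for band in range(mat.shape[1]):
                xc = mat[:, band] - mat[:, band].mean()
                yc = y - y.mean()
                r = np.sum(xc * yc) / np.sqrt(np.sum(xc**2) * np.sum(yc**2))
                brute.append((abs(r), basis, level, band))
        brute.sort(reverse=True)
        best = {(b, l, band) for _, b, l, band in brute[:5]}
        assert {(c.basis, c.level, c.band_index) for c in picked} == best
        # no unselected candidate beats any selected one
        min_sel = min(abs(c.r) for c in picked)
        assert all(absr <= min_sel + 1e-12 for absr, *_ in brute[5:])

    def test_sample_order_invariance(self, rng):
        bank = small_bank(rng, n_samples=18, n_bands=10)
        y = rng.normal(size=18)
        perm = rng.permutation(18)
        shuffled = {k: m[perm] for k, m in bank.items()}
        a = select_sensitivity_coefficients(bank, y, k=4)
        b = select_sensitivity_coefficients(shuffled, y[perm], k=4)
        assert [(c.basis, c.level, c.band_index) for c in a] == \
               [(c.basis, c.level, c.band_index) for c in b]

    def test_k_beyond_candidates_rejected(self, rng):
        bank = {("db2", 1): rng.normal(size=(8, 3))}
        with pytest.raises(ValueError, match="exceeds"):
            select_sensitivity_coefficients(bank, rng.normal(size=8), k=10)
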