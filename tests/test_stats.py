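"""Descriptives, Spearman, exact Mann-Whitney and the comparison table."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from spinefe.stats import (
    build_table3,
    correlation_table,
    descriptives,
    mann_whitney_exact,
    spearman,
)

from test_densitometry import HC_BMD, OP_BMD


class TestDescriptives:
    def test_printed_healthy_cohort(self):
        mean, sd = descriptives(HC_BMD)
        assert round(mean, 2) == 100.77
        assert round(sd, 2) == 9.25  # population (divisor n) convention

    def test_single_value(self):
        assert descriptives([3.2]) == (3.2, 0.0)

    def test_all_equal(self):
        mean, sd = descriptives([7.0] * 5)
        assert (mean, sd) == (7.0, 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            descriptives([])

    def test_sample_convention_option(self):
        _, sd = descriptives(HC_BMD, ddof=1)
        assert round(sd, 2) == 10.13


class TestSpearman:
    def test_identity_and_antisymmetry(self):
        x = np.arange(12.0)
        assert spearman(x, x).rho == pytest.approx(1.0)
        assert spearman(x, -x).rho == pytest.approx(-1.0)

    def test_exact_p_matches_bruteforce(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0, 2.6])
        y = np.array([2.0, 7.0, 1.0, 8.0, 2.8, 5.0])
        res = spearman(x, y)
        rx, ry = sps.rankdata(x), sps.rankdata(y)
        ref_rho = np.corrcoef(rx, ry)[0, 1]
        assert res.rho == pytest.approx(ref_rho)
        hits = total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, perm)[0, 1]
            total += 1
            hits += abs(r) >= abs(ref_rho) - 1e-12
        assert res.method == "exact"
        assert res.p == pytest.approx(hits / total)

    def test_constant_vector_flagged(self):
        with pytest.warns(UserWarning, match="constant"):
            res = spearman([1.0, 1.0, 1.0, 1.0], [1, 2, 3, 4])
        assert np.isnan(res.rho)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=10), rng.normal(size=10)
        a = spearman(x, y, mc_seed=7)
        b = spearman(np.exp(x), y**3, mc_seed=7)
        assert a.rho == pytest.approx(b.rho)
        assert a.p == pytest.approx(b.p)


class TestMannWhitney:
    def test_complete_separation_6v6(self):
        res = mann_whitney_exact([1, 2, 3, 4, 5, 6], [10, 11, 12, 13, 14, 15])
        assert res.u == 0
        assert res.p == pytest.approx(2 / 924)

    def test_identical_groups(self):
        res = mann_whitney_exact([5.0] * 6, [5.0] * 6)
        assert res.p == pytest.approx(1.0)

    def test_critical_value_6v6(self):
        # two-sided exact p at U = 5 is below 0.05, at U = 6 above (the
        # textbook critical value for n1 = n2 = 6 at alpha = 0.05 is U = 5)
        a5 = [1, 2, 3, 4, 5, 11]
        b5 = [6, 7, 8, 9, 10, 12]
        r5 = mann_whitney_exact(a5, b5)
        assert r5.u == 5
        assert r5.p < 0.05
        a6 = [1, 2, 3, 4, 5, 12]
        b6 = [6, 7, 8, 9, 10, 11]
        r6 = mann_whitney_exact(a6, b6)
        assert r6.u == 6
        assert r6.p > 0.05

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=6), rng.normal(1.0, 1.0, size=7)
        ours = mann_whitney_exact(a, b)
        ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_monotone_transform_invariance(self):
        a = [3.0, 9.0, 1.0, 7.0, 4.0, 8.0]
        b = [2.0, 6.0, 5.0, 10.0, 11.0, 0.5]
        p1 = mann_whitney_exact(a, b).p
        p2 = mann_whitney_exact(np.exp(a), np.exp(b)).p
        assert p1 == pytest.approx(p2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_exact([], [1.0])


def synthetic_records(separated=True):
    rng = np.random.default_rng(0)
    rows = []
    for i in range(6):
        rows.append({
            "cohort": "healthy", "bmd_qct_l1_3": 100 + rng.normal(0, 5),
            "fl": (1500 if separated else 1000) + rng.normal(0, 100),
            "theta_f": 11 + rng.normal(0, 2), "theta_e": 12 + rng.normal(0, 2),
            "theta_l": 12 + rng.normal(0, 2), "theta_t": 9 + rng.normal(0, 2),
        })
        rows.append({
            "cohort": "osteoporotic", "bmd_qct_l1_3": 60 + rng.normal(0, 3),
            "fl": 1000 + rng.normal(0, 100),
            "theta_f": 11 + rng.normal(0, 2), "theta_e": 14 + rng.normal(0, 2),
            "theta_l": 14 + rng.normal(0, 2), "theta_t": 12 + rng.normal(0, 2),
        })
    return pd.DataFrame(rows)


class TestTable3:
    def test_structure(self):
        table = build_table3(synthetic_records())
        assert len(table) == 6
        assert table["p_value"].between(0, 1).all()

    def test_identical_cohorts_no_markers(self):
        df = synthetic_records()
        for col in ("bmd_qct_l1_3", "fl", "theta_f", "theta_e", "theta_l",
                    "theta_t"):
            df[col] = 1.0
        table = build_table3(df)
        assert (table["p_value"] == 1.0).all()
        assert not table["significant"].any()

    def test_separated_fl_marked(self):
        table = build_table3(synthetic_records(separated=True))
        fl_row = table[table["parameter"].str.startswith("Failure")].iloc[0]
        assert fl_row["significant"]

    def test_missing_outcome_omitted_with_warning(self, caplog):
        df = synthetic_records().drop(columns=["theta_t"])
        import logging

        with caplog.at_level(logging.WARNING):
            table = build_table3(df)
        assert len(table) == 5
        assert any("theta_t" in r.message for r in caplog.records)

    def test_correlation_table_reports_both_coefficients(self):
        corr = correlation_table(synthetic_records())
        fl_row = corr[corr["parameter"].str.startswith("Failure")].iloc[0]
        assert {"spearman_rho", "pearson_r", "r_squared"} <= set(corr.columns)
        assert -1 <= fl_row["spearman_rho"] <= 1
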