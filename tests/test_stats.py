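"""Correlation, association models, p-value adjustment, validation stats."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from cytofeat.errors import ConfigurationError
from cytofeat.phenotyping import PopulationTable
from cytofeat.stats import (
    ExternalMeasure,
    adjust_pvalues,
    associate,
    attach_adjusted,
    group_compare,
    population_correlation,
    validate_against_manual,
)

MARKERS = ("A", "B")


def _population_table(percents: dict[str, dict[str, float]]) -> PopulationTable:
    """percents: phenotype -> {sample -> percent}."""
    rows = []
    samples = sorted(next(iter(percents.values())))
    for pheno, per in percents.items():
        for s in samples:
            rows.append((s, pheno, int(per[s] * 10), per[s]))
    df = pd.DataFrame(rows, columns=["sample_id", "phenotype", "count", "percent"])
    return PopulationTable(
        df=df,
        marker_order=MARKERS,
        denominators={s: 1000 for s in samples},
    )


class TestCorrelation:
    def test_diagonal_one_and_symmetry(self):
        rng = np.random.default_rng(40)
        table = _population_table(
            {
                "00": {f"S{i}": float(rng.uniform(1, 10)) for i in range(5)},
                "01": {f"S{i}": float(rng.uniform(1, 10)) for i in range(5)},
                "11": {f"S{i}": float(rng.uniform(1, 10)) for i in range(5)},
            }
        )
        corr = population_correlation(table)
        m = corr.matrix.to_numpy()
        np.testing.assert_allclose(np.diag(m), 1.0)
        np.testing.assert_allclose(m, m.T, atol=1e-15)

    def test_exact_anticorrelation(self):
        y = {"S1": 1.0, "S2": 4.0, "S3": 2.5, "S4": 9.0}
        table = _population_table(
            {"00": y, "11": {s: 10.0 - v for s, v in y.items()}}
        )
        corr = population_correlation(table, "pearson")
        assert corr.matrix.iloc[0, 1] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_textbook_formula(self):
        grid = {
            "00": {"S1": 2.0, "S2": 5.0, "S3": 3.0, "S4": 8.0},
            "01": {"S1": 1.0, "S2": 7.0, "S3": 2.0, "S4": 4.0},
            "11": {"S1": 9.0, "S2": 1.0, "S3": 5.0, "S4": 2.0},
        }
        corr = population_correlation(_population_table(grid), "pearson")
        phenos = ["00", "01", "11"]
        ids = {p: corr.population_ids[i] for i, p in enumerate(sorted(phenos))}
        for a in phenos:
            for b in phenos:
                x = np.array([grid[a][s] for s in ("S1", "S2", "S3", "S4")])
                y = np.array([grid[b][s] for s in ("S1", "S2", "S3", "S4")])
                expected = (
                    ((x - x.mean()) * (y - y.mean())).sum()
                    / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
                )
                assert corr.matrix.loc[ids[a], ids[b]] == pytest.approx(
                    expected, abs=1e-12
                )

    def test_zero_variance_population_flagged_missing(self):
        table = _population_table(
            {
                "00": {"S1": 5.0, "S2": 5.0, "S3": 5.0},
                "11": {"S1": 1.0, "S2": 2.0, "S3": 3.0},
            }
        )
        corr = population_correlation(table)
        assert corr.matrix.iloc[0].isna().all()
        assert corr.matrix.iloc[1, 1] == 1.0

    def test_requires_three_samples(self):
        table = _population_table({"00": {"S1": 1.0, "S2": 2.0}})
        with pytest.raises(ConfigurationError, match=">=3"):
            population_correlation(table)


class TestAssociate:
    def test_constant_measure_gives_zero_slope(self):
        table = _population_table({"00": {"S1": 1.0, "S2": 2.0, "S3": 3.0}})
        measure = ExternalMeasure({"S1": 4.0, "S2": 4.0, "S3": 4.0})
        (res,) = associate(table, measure)
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_perfect_fit(self):
        table = _population_table({"00": {"S1": 1.0, "S2": 2.0, "S3": 3.0}})
        measure = ExternalMeasure({"S1": 2.0, "S2": 4.0, "S3": 6.0})
        (res,) = associate(table, measure)
        assert res.slope == pytest.approx(2.0, abs=1e-12)
        assert res.intercept == pytest.approx(0.0, abs=1e-12)
        assert res.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_matches_closed_form_ols(self):
        rng = np.random.default_rng(41)
        x = rng.uniform(1, 20, 10)
        y = 5.0 - 0.8 * x + rng.normal(0, 0.1, 10)
        table = _population_table(
            {"00": {f"S{i:02d}": float(v) for i, v in enumerate(x)}}
        )
        measure = ExternalMeasure(
            {f"S{i:02d}": float(v) for i, v in enumerate(y)}
        )
        (res,) = associate(table, measure)
        # closed forms
        sxx = ((x - x.mean()) ** 2).sum()
        slope = ((x - x.mean()) * (y - y.mean())).sum() / sxx
        intercept = y.mean() - slope * x.mean()
        resid = y - intercept - slope * x
        se = np.sqrt(resid @ resid / (len(x) - 2) / sxx)
        r2 = 1 - (resid @ resid) / (((y - y.mean()) ** 2).sum())
        from scipy.stats import t as tdist

        tstat = slope / se
        p = 2 * tdist.sf(abs(tstat), len(x) - 2)
        assert res.slope == pytest.approx(slope, abs=1e-10)
        assert res.intercept == pytest.approx(intercept, abs=1e-10)
        assert res.r_squared == pytest.approx(r2, abs=1e-10)
        assert res.p_value == pytest.approx(p, abs=1e-10)
        lo, hi = res.confint(0.95)
        half = tdist.ppf(0.975, 8) * se
        assert (lo, hi) == pytest.approx((slope - half, slope + half), abs=1e-10)

    def test_zero_variance_predictor_flagged(self):
        table = _population_table(
            {
                "00": {"S1": 5.0, "S2": 5.0, "S3": 5.0},
                "11": {"S1": 1.0, "S2": 2.0, "S3": 3.0},
            }
        )
        measure = ExternalMeasure({"S1": 1.0, "S2": 2.0, "S3": 4.0})
        results = associate(table, measure)
        flat = next(r for r in results if r.phenotype == "00")
        assert not flat.defined
        assert np.isnan(flat.p_value)

    def test_planted_slope_recovered_within_ci(self):
        rng = np.random.default_rng(42)
        x = rng.normal(20, 3, 10)
        y = 5.0 - 0.8 * x + rng.normal(0, 0.1, 10)
        table = _population_table(
            {"00": {f"S{i:02d}": float(v) for i, v in enumerate(x)}}
        )
        measure = ExternalMeasure({f"S{i:02d}": float(v) for i, v in enumerate(y)})
        (res,) = associate(table, measure)
        lo, hi = res.confint(0.95)
        assert lo <= -0.8 <= hi


def _bh_oracle(p: np.ndarray) -> np.ndarray:
    """Exhaustive step-up: sort, scale by m/i, cumulative min from largest."""
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


class TestAdjustPvalues:
    def test_single_p_unchanged(self):
        np.testing.assert_allclose(adjust_pvalues([0.03], "bh"), [0.03])

    def test_bh_worked_example(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.02, 0.04], "bh"), [0.03, 0.03, 0.04], atol=1e-12
        )

    def test_bonferroni_worked_example(self):
        np.testing.assert_allclose(
            adjust_pvalues([0.01, 0.5, 0.9], "bonferroni"), [0.03, 1.0, 1.0],
            atol=1e-12,
        )

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        st.lists(
            st.floats(min_value=1e-9, max_value=1.0, exclude_min=False),
            min_size=1, max_size=8,
        )
    )
    def test_bh_matches_oracle_and_orderings(self, p):
        p = np.asarray(p)
        bh = adjust_pvalues(p, "bh")
        np.testing.assert_allclose(bh, _bh_oracle(p), atol=1e-12)
        bonf = adjust_pvalues(p, "bonferroni")
        np.testing.assert_allclose(bonf, np.minimum(p * len(p), 1.0), atol=1e-12)
        assert np.all(bh >= p - 1e-15)
        assert np.all(bonf >= bh - 1e-12)

    def test_out_of_range_rejected(self):
        for bad in ([0.0], [1.5], [-0.1], [float("nan")]):
            with pytest.raises(ConfigurationError):
                adjust_pvalues(bad)

    def test_attach_adjusted_skips_undefined(self):
        table = _population_table(
            {
                "00": {"S1": 5.0, "S2": 5.0, "S3": 5.0},
                "11": {"S1": 1.0, "S2": 2.0, "S3": 3.0},
            }
        )
        measure = ExternalMeasure({"S1": 1.0, "S2": 2.0, "S3": 4.0})
        results = attach_adjusted(associate(table, measure), "bh")
        flat = next(r for r in results if r.phenotype == "00")
        good = next(r for r in results if r.phenotype == "11")
        assert flat.p_adjusted is None
        assert good.p_adjusted == pytest.approx(good.p_value)  # m=1 defined test


class TestGroupCompare:
    def test_identical_groups(self):
        measure = ExternalMeasure(
            {"a1": 1.0, "a2": 2.0, "a3": 3.0, "b1": 1.0, "b2": 2.0, "b3": 3.0}
        )
        groups = {s: s[0] for s in measure.values}
        out = group_compare(measure, groups)
        assert out.loc[0, "t"] == pytest.approx(0.0, abs=1e-12)
        assert out.loc[0, "p"] == pytest.approx(1.0, abs=1e-12)
        assert not out.loc[0, "significant"]

    def test_welch_closed_form(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])
        measure = ExternalMeasure(
            {f"a{i}": v for i, v in enumerate(a)} | {f"b{i}": v for i, v in enumerate(b)}
        )
        groups = {s: s[0] for s in measure.values}
        out = group_compare(measure, groups)
        va, vb = a.var(ddof=1) / 3, b.var(ddof=1) / 3
        t = (a.mean() - b.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / 2 + vb**2 / 2)
        from scipy.stats import t as tdist

        p = 2 * tdist.sf(abs(t), df)
        assert out.loc[0, "t"] == pytest.approx(t, abs=1e-12)
        assert out.loc[0, "df"] == pytest.approx(df, abs=1e-9)
        assert out.loc[0, "p"] == pytest.approx(p, abs=1e-12)
        assert bool(out.loc[0, "significant"]) == (p < 0.05)

    def test_single_group_errors(self):
        measure = ExternalMeasure({"a1": 1.0, "a2": 2.0})
        with pytest.raises(ConfigurationError, match="two groups"):
            group_compare(measure, {"a1": "x", "a2": "x"})


class TestValidation:
    def _pipeline(self):
        return _population_table(
            {"00": {"S1": 1.0, "S2": 2.0}, "11": {"S1": 3.0, "S2": 4.0}}
        )

    def test_exact_agreement(self):
        manual = pd.DataFrame(
            {
                "sample_id": ["S1", "S2", "S1", "S2"],
                "phenotype": ["00", "00", "11", "11"],
                "percent": [1.0, 2.0, 3.0, 4.0],
            }
        )
        result = validate_against_manual(self._pipeline(), manual)
        assert result.rho == pytest.approx(1.0)
        assert result.mean_abs_diff_percent == 0.0
        assert result.n_pairs == 4

    def test_scaled_manual_keeps_rank_order(self):
        manual = pd.DataFrame(
            {
                "sample_id": ["S1", "S2", "S1", "S2"],
                "phenotype": ["00", "00", "11", "11"],
                "percent": [2.0, 4.0, 6.0, 8.0],
            }
        )
        result = validate_against_manual(self._pipeline(), manual)
        assert result.rho == pytest.approx(1.0)
        assert result.mean_abs_diff_percent == pytest.approx(2.5)

    def test_unmatched_rows_reported_and_excluded(self):
        manual = pd.DataFrame(
            {
                "sample_id": ["S1", "S2", "S1", "S2", "S1"],
                "phenotype": ["00", "00", "11", "11", "10"],
                "percent": [1.0, 2.0, 3.0, 4.0, 9.0],
            }
        )
        result = validate_against_manual(self._pipeline(), manual)
        assert result.n_pairs == 4
        assert result.unmatched == ("S1:10",)
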