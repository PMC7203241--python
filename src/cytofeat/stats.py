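"""Population correlation, outcome association models, and validation stats.

The association stage regresses an external per-sample measurement (the
motivating case: log10 colony-forming units of *M. tuberculosis* per lung)
on each population's percentage by ordinary least squares, testing the null
of zero slope with the usual two-sided t test and reporting r² as the squared
sample correlation. Multiple-testing correction (Benjamini-Hochberg by
default) is available but opt-in; raw and adjusted p values are both kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError
from .phenotyping import PopulationTable

__all__ = [
    "CorrelationMatrix",
    "ExternalMeasure",
    "AssociationResult",
    "ValidationResult",
    "population_correlation",
    "associate",
    "adjust_pvalues",
    "group_compare",
    "validate_against_manual",
]


@dataclass
class CorrelationMatrix:
    population_ids: list[str]
    matrix: pd.DataFrame  # symmetric; NaN flags undefined (zero-variance) pairs
    method: str

    def to_csv(self, path) -> None:
        self.matrix.to_csv(path)


@dataclass(frozen=True)
class ExternalMeasure:
    """Per-sample numeric outcome, e.g. log10 CFU (transform applied upstream)."""

    values: Mapping[str, float]
    name: str = "outcome"
    transform: str = "log10"

    @classmethod
    def from_csv(cls, path, name: str | None = None, transform: str = "log10"):
        frame = pd.read_csv(path, comment="#", float_precision="round_trip")
        value_col = name or [c for c in frame.columns if c != "sample_id"][0]
        return cls(
            values=dict(zip(frame["sample_id"].astype(str), frame[value_col])),
            name=value_col,
            transform=transform,
        )


@dataclass(frozen=True)
class AssociationResult:
    population_id: int
    phenotype: str
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    p_adjusted: float | None = None
    stderr: float = float("nan")

    @property
    def defined(self) -> bool:
        return np.isfinite(self.slope)

    def confint(self, level: float = 0.95) -> tuple[float, float]:
        """Two-sided confidence interval for the slope."""
        half = sps.t.ppf(0.5 + level / 2, self.n - 2) * self.stderr
        return (self.slope - half, self.slope + half)


@dataclass(frozen=True)
class ValidationResult:
    rho: float
    rho_p: float
    mean_abs_diff_percent: float
    n_pairs: int
    unmatched: tuple[str, ...] = ()


def population_correlation(
    table: PopulationTable, method: str = "pearson"
) -> CorrelationMatrix:
    """Pairwise correlation of per-sample percent vectors across populations.

    Zero-variance populations yield undefined (NaN) entries rather than an
    imputed 0; the diagonal is 1 wherever it is defined.
    """
    if method not in ("pearson", "spearman"):
        raise ConfigurationError(f"unknown correlation method {method!r}")
    grid = table.percent_matrix()
    if grid.shape[0] < 3:
        raise ConfigurationError(
            f"population correlation needs >=3 samples, got {grid.shape[0]}"
        )
    if table.population_ids:
        grid = grid.rename(columns=lambda p: table.population_ids[p])
        grid = grid[sorted(grid.columns)]
    corr = grid.corr(method=method, min_periods=3)
    degenerate = grid.std(ddof=1) == 0
    corr.loc[degenerate.values, :] = np.nan
    corr.loc[:, degenerate.values] = np.nan
    np.fill_diagonal(corr.values, np.where(degenerate.values, np.nan, 1.0))
    return CorrelationMatrix(
        population_ids=list(corr.columns), matrix=corr, method=method
    )


def associate(
    table: PopulationTable, measure: ExternalMeasure
) -> list[AssociationResult]:
    """OLS of the external measure on each population's percent.

    One fit per population over the samples present in both tables; returns
    results sorted by population id. A zero-variance predictor yields a
    result flagged undefined (NaN estimates) instead of an error.
    """
    grid = table.percent_matrix()
    samples = [s for s in grid.index if str(s) in measure.values]
    if len(samples) < 3:
        raise ConfigurationError(
            f"association needs >=3 samples with outcome values, got {len(samples)}"
        )
    y = np.array([measure.values[str(s)] for s in samples], dtype=float)
    ids = table.population_ids or {
        p: i + 1 for i, p in enumerate(sorted(grid.columns))
    }
    results = []
    for phenotype in grid.columns:
        x = grid.loc[samples, phenotype].to_numpy(dtype=float)
        pid = ids[phenotype]
        if np.ptp(x) == 0:
            results.append(
                AssociationResult(
                    population_id=pid, phenotype=phenotype,
                    slope=float("nan"), intercept=float("nan"),
                    r_squared=float("nan"), p_value=float("nan"), n=len(x),
                )
            )
            continue
        if np.ptp(y) == 0:
            # Constant outcome: the flat line fits exactly, no association.
            results.append(
                AssociationResult(
                    population_id=pid, phenotype=phenotype,
                    slope=0.0, intercept=float(y[0]), r_squared=0.0,
                    p_value=1.0, n=len(x), stderr=0.0,
                )
            )
            continue
        fit = sps.linregress(x, y)
        results.append(
            AssociationResult(
                population_id=pid,
                phenotype=phenotype,
                slope=float(fit.slope),
                intercept=float(fit.intercept),
                r_squared=float(fit.rvalue) ** 2,
                p_value=float(fit.pvalue),
                n=len(x),
                stderr=float(fit.stderr),
            )
        )
    return sorted(results, key=lambda r: r.population_id)


def adjust_pvalues(p: Sequence[float], method: str = "bh") -> np.ndarray:
    """Multiple-testing adjusted p values, aligned with the input order.

    ``bh`` is Benjamini-Hochberg step-up, ``by`` Benjamini-Yekutieli,
    ``bonferroni`` the plain Bonferroni bound; all clipped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.size and (np.any(~np.isfinite(p)) or np.any(p <= 0) or np.any(p > 1)):
        raise ConfigurationError("p values must lie in (0, 1]")
    codes = {"bh": "fdr_bh", "by": "fdr_by", "bonferroni": "bonferroni"}
    if method not in codes:
        raise ConfigurationError(f"unknown adjustment method {method!r}")
    if p.size == 0:
        return p
    return multipletests(p, method=codes[method])[1]


def attach_adjusted(
    results: Sequence[AssociationResult], method: str = "bh"
) -> list[AssociationResult]:
    """Return results with p_adjusted filled in (undefined fits left NaN)."""
    defined = [r for r in results if np.isfinite(r.p_value)]
    adjusted = adjust_pvalues([r.p_value for r in defined], method)
    lookup = {id(r): a for r, a in zip(defined, adjusted)}
    from dataclasses import replace as _replace

    return [
        _replace(r, p_adjusted=float(lookup[id(r)])) if id(r) in lookup else r
        for r in results
    ]


def associations_frame(results: Sequence[AssociationResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "population_id": r.population_id,
                "phenotype": r.phenotype,
                "slope": r.slope,
                "intercept": r.intercept,
                "r_squared": r.r_squared,
                "p": r.p_value,
                "p_adj": r.p_adjusted,
                "n": r.n,
            }
            for r in results
        ]
    )


def group_compare(
    measure: ExternalMeasure,
    groups: Mapping[str, str],
    timepoints: Mapping[str, str] | None = None,
    variant: str = "welch",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group comparison of the external measure, per timepoint.

    Welch's unequal-variance t test by default (Student's available); returns
    one row per timepoint with t, df, p and a significance flag at *alpha*.
    """
    if variant not in ("welch", "student"):
        raise ConfigurationError(f"unknown t-test variant {variant!r}")
    samples = [s for s in measure.values if s in groups]
    frame = pd.DataFrame(
        {
            "sample_id": samples,
            "value": [measure.values[s] for s in samples],
            "group": [groups[s] for s in samples],
            "timepoint": [
                (timepoints or {}).get(s, "all") for s in samples
            ],
        }
    )
    rows = []
    for timepoint, sub in frame.groupby("timepoint"):
        labels = sorted(sub["group"].unique())
        if len(labels) != 2:
            raise ConfigurationError(
                f"timepoint {timepoint!r}: need exactly two groups, got {labels}"
            )
        a = sub.loc[sub["group"] == labels[0], "value"].to_numpy()
        b = sub.loc[sub["group"] == labels[1], "value"].to_numpy()
        if min(a.size, b.size) < 2:
            raise ConfigurationError(
                f"timepoint {timepoint!r}: each group needs n>=2"
            )
        res = sps.ttest_ind(a, b, equal_var=(variant == "student"))
        rows.append(
            {
                "timepoint": timepoint,
                "group_a": labels[0],
                "group_b": labels[1],
                "n_a": a.size,
                "n_b": b.size,
                "t": float(res.statistic),
                "df": float(res.df),
                "p": float(res.pvalue),
                "significant": bool(res.pvalue < alpha),
            }
        )
    return pd.DataFrame(rows)


def slope_ci_coverage(
    n_sims: int = 200,
    n_samples: int = 10,
    n_null: int = 7,
    slope: float = -0.8,
    intercept: float = 5.0,
    noise_sd: float = 0.1,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """Calibration of the association stage on planted linear models.

    Each simulated experiment has one population whose percent drives the
    outcome through ``intercept + slope * percent + noise`` and ``n_null``
    populations unrelated to it. Runs :func:`associate` per experiment and
    reports the planted slope's 95% CI coverage plus the mean false-discovery
    proportion among the null populations under BH at *alpha*.
    """
    rng = np.random.default_rng(seed)
    n_pop = n_null + 1
    markers = tuple(f"M{i}" for i in range(max(1, int(np.ceil(np.log2(n_pop + 1))))))
    bitstrings = [format(k + 1, f"0{len(markers)}b") for k in range(n_pop)]
    covered = 0
    fdp = []
    from .phenotyping import PopulationTable

    for _ in range(n_sims):
        x = rng.normal(20.0, 3.0, size=(n_samples, n_pop))
        y = intercept + slope * x[:, 0] + rng.normal(0.0, noise_sd, n_samples)
        rows = []
        for i in range(n_samples):
            for k in range(n_pop):
                rows.append((f"S{i:02d}", bitstrings[k], 0, x[i, k]))
        table = PopulationTable(
            df=pd.DataFrame(
                rows, columns=["sample_id", "phenotype", "count", "percent"]
            ),
            marker_order=markers,
            denominators={f"S{i:02d}": 1 for i in range(n_samples)},
        )
        measure = ExternalMeasure(
            {f"S{i:02d}": float(v) for i, v in enumerate(y)}
        )
        results = {r.phenotype: r for r in associate(table, measure)}
        lo, hi = results[bitstrings[0]].confint(1 - alpha)
        covered += lo <= slope <= hi
        adjusted = adjust_pvalues(
            [results[b].p_value for b in bitstrings], "bh"
        )
        discoveries = adjusted < alpha
        false = discoveries[1:].sum()
        fdp.append(false / discoveries.sum() if discoveries.any() else 0.0)
    fdp = np.asarray(fdp)
    return {
        "coverage": covered / n_sims,
        "mean_fdp": float(fdp.mean()),
        "fdp_se": float(fdp.std(ddof=1) / np.sqrt(n_sims)),
        "n_sims": n_sims,
    }


def validate_against_manual(
    pipeline: PopulationTable, manual: pd.DataFrame
) -> ValidationResult:
    """Compare pipeline percentages with an externally supplied manual-gating
    table of (sample_id, phenotype, percent).

    Matched (sample, phenotype) pairs enter a Spearman rank correlation and a
    mean absolute difference in percentage points; unmatched manual rows are
    reported, not imputed.
    """
    required = {"sample_id", "phenotype", "percent"}
    if not required <= set(manual.columns):
        raise ConfigurationError(
            f"manual table needs columns {sorted(required)}, got {list(manual.columns)}"
        )
    merged = manual.merge(
        pipeline.df[["sample_id", "phenotype", "percent"]],
        on=["sample_id", "phenotype"],
        how="left",
        suffixes=("_manual", "_pipeline"),
    )
    unmatched = merged[merged["percent_pipeline"].isna()]
    matched = merged.dropna(subset=["percent_pipeline"])
    if len(matched) < 3:
        raise ConfigurationError(
            f"validation needs >=3 matched pairs, got {len(matched)}"
        )
    rho, rho_p = sps.spearmanr(
        matched["percent_pipeline"], matched["percent_manual"]
    )
    diff = float(
        np.mean(np.abs(matched["percent_pipeline"] - matched["percent_manual"]))
    )
    return ValidationResult(
        rho=float(rho),
        rho_p=float(rho_p),
        mean_abs_diff_percent=diff,
        n_pairs=int(len(matched)),
        unmatched=tuple(
            f"{r.sample_id}:{r.phenotype}" for r in unmatched.itertuples()
        ),
    )
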