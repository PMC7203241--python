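"""Figures and their underlying tables: phenotype heatmap, correlation
heatmap, time-series grid, association scatter grid, FMO threshold panels.

Figures are pure functions of pipeline outputs; every figure writes its
numbers as a CSV table next to it, and only the tables are contractual —
colors and layout are presentation defaults.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .fcs_io import EventTable
from .phenotyping import PopulationTable
from .stats import AssociationResult, CorrelationMatrix, ExternalMeasure
from .thresholds import ThresholdSet

__all__ = [
    "phenotype_heatmap",
    "correlation_heatmap",
    "timeseries_grid",
    "association_grid",
    "fmo_panels",
]

_BINARY_CMAP = matplotlib.colors.ListedColormap(["#3b6fb6", "#2ca05a"])  # -,+


def _save(fig, path_base: Path, formats=("png",), dpi=300) -> list[Path]:
    written = []
    for fmt in formats:
        out = path_base.with_suffix(f".{fmt}")
        fig.savefig(out, dpi=dpi, bbox_inches="tight")
        written.append(out)
    plt.close(fig)
    return written


def phenotype_heatmap(
    table: PopulationTable, outdir, name: str = "phenotype_heatmap"
) -> pd.DataFrame:
    """Populations x markers binary expression heatmap, grouped by lineage.

    Returns (and writes) the underlying 0/1 matrix with lineage/subset/
    resident side columns; re-reading the CSV reproduces the phenotype bits.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    phenos = table.df.drop_duplicates("phenotype").copy()
    if table.population_ids:
        phenos["population_id"] = phenos["phenotype"].map(table.population_ids)
        phenos = phenos.sort_values("population_id")
    rows = []
    for r in phenos.itertuples(index=False):
        key = table.key(r.phenotype)
        row = {"population_id": getattr(r, "population_id", None)}
        row.update(dict(zip(table.marker_order, key.bits)))
        for label in ("lineage", "subset", "resident"):
            if hasattr(r, label):
                row[label] = getattr(r, label)
        rows.append(row)
    matrix = pd.DataFrame(rows)
    matrix.to_csv(outdir / f"{name}.csv", index=False)

    if matrix.empty:
        warnings.warn("phenotype heatmap: empty population table, empty figure")
        fig, _ = plt.subplots(figsize=(4, 2))
        _save(fig, outdir / name)
        return matrix
    bits = matrix[list(table.marker_order)].to_numpy()
    fig, ax = plt.subplots(
        figsize=(0.5 * len(table.marker_order) + 2, 0.28 * len(matrix) + 1.5)
    )
    ax.imshow(bits, cmap=_BINARY_CMAP, vmin=0, vmax=1, aspect="auto")
    ax.set_xticks(range(len(table.marker_order)))
    ax.set_xticklabels(table.marker_order, rotation=90, fontsize=7)
    labels = []
    for r in matrix.itertuples(index=False):
        pid = getattr(r, "population_id", None)
        lineage = getattr(r, "lineage", "")
        labels.append(f"{pid if pid is not None else ''} {lineage}".strip())
    ax.set_yticks(range(len(matrix)))
    ax.set_yticklabels(labels, fontsize=7)
    ax.set_title("Phenotypes (green = positive, blue = negative)")
    _save(fig, outdir / name)
    return matrix


def correlation_heatmap(
    corr: CorrelationMatrix, outdir, name: str = "correlation_heatmap"
) -> None:
    """Population x population correlation matrix figure + CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    corr.to_csv(outdir / f"{name}.csv")
    n = len(corr.population_ids)
    fig, ax = plt.subplots(figsize=(0.3 * n + 3, 0.3 * n + 2.5))
    im = ax.imshow(corr.matrix.to_numpy(), cmap="viridis", vmin=-1, vmax=1)
    ax.set_xticks(range(n))
    ax.set_yticks(range(n))
    ax.set_xticklabels(corr.population_ids, rotation=90, fontsize=6)
    ax.set_yticklabels(corr.population_ids, fontsize=6)
    fig.colorbar(im, ax=ax, label=f"{corr.method} correlation")
    _save(fig, outdir / name)


def timeseries_grid(
    table: PopulationTable,
    metadata: pd.DataFrame,
    outdir,
    name: str = "timeseries_grid",
) -> pd.DataFrame:
    """Mean percent per (group, timepoint) for each population; line per group.

    *metadata* must cover every sample with columns sample_id, group,
    timepoint. Returns (and writes) the table of means.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    required = {"sample_id", "group", "timepoint"}
    if not required <= set(metadata.columns):
        raise ConfigurationError(f"metadata needs columns {sorted(required)}")
    missing = set(table.sample_ids) - set(metadata["sample_id"].astype(str))
    if missing:
        raise ConfigurationError(
            f"metadata missing rows for samples: {sorted(missing)}"
        )
    merged = table.df.merge(metadata, on="sample_id")
    means = (
        merged.groupby(["phenotype", "group", "timepoint"], as_index=False)["percent"]
        .mean()
        .rename(columns={"percent": "mean_percent"})
    )
    if table.population_ids:
        means["population_id"] = means["phenotype"].map(table.population_ids)
        means = means.sort_values(
            ["population_id", "group", "timepoint"]
        ).reset_index(drop=True)
    means.to_csv(outdir / f"{name}.csv", index=False)

    phenos = (
        sorted(table.population_ids, key=table.population_ids.get)
        if table.population_ids
        else sorted(means["phenotype"].unique())
    )
    ncol = min(5, max(1, len(phenos)))
    nrow = math.ceil(len(phenos) / ncol)
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(2.4 * ncol, 2.0 * nrow), squeeze=False, sharex=True
    )
    timepoint_order = sorted(means["timepoint"].unique())
    for k, pheno in enumerate(phenos):
        ax = axes[k // ncol][k % ncol]
        sub = means[means["phenotype"] == pheno]
        for group, g in sub.groupby("group"):
            g = g.set_index("timepoint").reindex(timepoint_order)
            ax.plot(timepoint_order, g["mean_percent"], marker="o", label=group)
        pid = table.population_ids.get(pheno) if table.population_ids else None
        ax.set_title(f"pop {pid}" if pid else pheno, fontsize=7)
        ax.tick_params(labelsize=6)
    for k in range(len(phenos), nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    if phenos:
        axes[0][0].legend(fontsize=6)
    fig.suptitle("Mean population percentage by group and timepoint", fontsize=9)
    _save(fig, outdir / name)
    return means


def association_grid(
    results: Sequence[AssociationResult],
    table: PopulationTable,
    measure: ExternalMeasure,
    outdir,
    name: str = "association_grid",
) -> pd.DataFrame:
    """Percent-vs-outcome scatter per population with fitted line and r².

    Ordering follows population ids, matching the heatmap; the annotation
    values are exactly the association table's values.
    """
    from .stats import associations_frame

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    frame = associations_frame(results)
    frame.to_csv(outdir / f"{name}.csv", index=False)
    grid = table.percent_matrix()
    samples = [s for s in grid.index if str(s) in measure.values]
    y = np.array([measure.values[str(s)] for s in samples], dtype=float)
    ordered = sorted(results, key=lambda r: r.population_id)
    ncol = min(5, max(1, len(ordered)))
    nrow = math.ceil(len(ordered) / ncol) if ordered else 1
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(2.4 * ncol, 2.2 * nrow), squeeze=False
    )
    for k, res in enumerate(ordered):
        ax = axes[k // ncol][k % ncol]
        x = grid.loc[samples, res.phenotype].to_numpy(dtype=float)
        ax.scatter(x, y, s=8)
        if res.defined:
            xs = np.linspace(x.min(), x.max(), 20)
            ax.plot(xs, res.intercept + res.slope * xs, color="k", lw=0.8)
            ax.set_title(
                f"pop {res.population_id}  r²={res.r_squared:.2f}", fontsize=7
            )
        else:
            ax.set_title(f"pop {res.population_id}  (undefined)", fontsize=7)
        ax.tick_params(labelsize=6)
    for k in range(len(ordered), nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    fig.suptitle(f"{measure.name} vs population percentage", fontsize=9)
    _save(fig, outdir / name)
    return frame


def fmo_panels(
    thresholds: ThresholdSet,
    fmo_tables: Mapping[str, EventTable],
    outdir,
    name: str = "fmo_panels",
    max_points: int = 20_000,
) -> list[str]:
    """Marker vs side scatter per FMO, threshold drawn as a vertical line.

    Only markers thresholded by the FMO-quantile route get a panel; this is
    the static stand-in for the interactive review of the learned cutoffs.
    Returns the markers plotted.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    markers = [
        m
        for m, e in thresholds.entries.items()
        if e.method == "fmo_quantile" and m in fmo_tables
    ]
    if not markers:
        return []
    ncol = min(6, len(markers))
    nrow = math.ceil(len(markers) / ncol)
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(2.4 * ncol, 2.2 * nrow), squeeze=False
    )
    for k, marker in enumerate(markers):
        ax = axes[k // ncol][k % ncol]
        table = fmo_tables[marker]
        x = table.marker_values(marker)
        side_channels = table.channel_map.role_detectors("side_scatter")
        yvals = (
            table.channel_values(side_channels[0])
            if side_channels
            else np.arange(x.size, dtype=float)
        )
        stride = max(1, x.size // max_points)  # plot thinning only
        ax.scatter(x[::stride], yvals[::stride], s=1, alpha=0.3)
        ax.axvline(thresholds.threshold(marker), color="k")
        ax.set_title(marker, fontsize=8)
        ax.tick_params(labelsize=6)
    for k in range(len(markers), nrow * ncol):
        axes[k // ncol][k % ncol].axis("off")
    fig.suptitle("FMO 99th-percentile thresholds", fontsize=9)
    _save(fig, outdir / name)
    return markers
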