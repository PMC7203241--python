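"""Fully specified synthetic cytometry experiments with ground truth.

The generator emulates the data structure the pipeline assumes, on the
analysis (transformed) scale: each marker is a two-component Gaussian
(negative/positive) mixture, each cell belongs to one planted phenotype (a
bit pattern over the markers), scatter area/height sit on a line for single
cells, doublets carry roughly twice the area per unit height, debris sits at
low scatter, dead cells are bright on the viability dye, and per-sample
population abundances vary around base weights via a Dirichlet draw. FMO
analogues are full samples with the left-out marker forced to its negative
component. One population's true abundance drives an external outcome
through a planted linear model.

Every draw comes from one seeded generator, so a config + seed pair yields
byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import ConfigurationError
from .fcs_io import ChannelMap, EventTable, write_fcs, write_event_csv

__all__ = [
    "MarkerModel",
    "PlantedPopulation",
    "OutcomeModel",
    "SyntheticConfig",
    "TruthTable",
    "default_config",
    "default_channel_map",
    "generate_experiment",
]


@dataclass(frozen=True)
class MarkerModel:
    """Two-component (negative/positive) Gaussian model for one marker."""

    name: str
    neg_mean: float = 1.0
    neg_sd: float = 0.3
    pos_mean: float = 4.0
    pos_sd: float = 0.3

    def __post_init__(self):
        if self.neg_sd <= 0 or self.pos_sd <= 0:
            raise ConfigurationError(f"marker {self.name}: sds must be positive")


@dataclass(frozen=True)
class PlantedPopulation:
    bits: tuple[int, ...]
    base_weight: float

    @property
    def bitstring(self) -> str:
        return "".join(str(b) for b in self.bits)


@dataclass(frozen=True)
class OutcomeModel:
    """outcome = intercept + slope * (true percent of planted pop) + noise."""

    population_index: int = 0
    slope: float = -0.8
    intercept: float = 5.0
    noise_sd: float = 0.1
    name: str = "log10_cfu"


@dataclass(frozen=True)
class ScatterModel:
    cell_area_mean: float = 50_000.0
    cell_area_sd: float = 5_000.0
    height_ratio: float = 0.9
    height_noise_rel: float = 0.02
    debris_area_mean: float = 8_000.0
    debris_area_sd: float = 2_000.0
    side_mean: float = 30_000.0
    side_sd: float = 8_000.0
    debris_side_mean: float = 5_000.0
    debris_side_sd: float = 1_500.0


@dataclass(frozen=True)
class SyntheticConfig:
    markers: tuple[MarkerModel, ...]
    populations: tuple[PlantedPopulation, ...]
    n_samples: int = 10
    n_events: int = 50_000
    n_fmo_events: int = 20_000
    doublet_frac: float = 0.05
    debris_frac: float = 0.10
    dead_frac: float = 0.10
    dirichlet_concentration: float = 250.0
    outcome: OutcomeModel = OutcomeModel()
    scatter: ScatterModel = ScatterModel()
    viability: MarkerModel = MarkerModel("viability")
    spillover_sd: float = 0.0  # additive cross-channel Gaussian nuisance
    groups: tuple[str, ...] = ("BCG", "control")
    timepoints: tuple[str, ...] = ("D30",)
    seed: int = 0
    write_fcs_files: bool = True  # False writes CSV events instead

    def __post_init__(self):
        fracs = (self.doublet_frac, self.debris_frac, self.dead_frac)
        if any(not 0 <= f < 1 for f in fracs) or sum(fracs) >= 1:
            raise ConfigurationError(
                "artifact fractions must each lie in [0,1) and sum below 1"
            )
        if not self.populations:
            raise ConfigurationError("at least one planted population required")
        n_markers = len(self.markers)
        for pop in self.populations:
            if len(pop.bits) != n_markers:
                raise ConfigurationError(
                    f"population {pop.bitstring}: {len(pop.bits)} bits for "
                    f"{n_markers} markers"
                )
            if any(b not in (0, 1) for b in pop.bits):
                raise ConfigurationError("population bits must be 0/1")
            if pop.base_weight <= 0:
                raise ConfigurationError("base weights must be positive")
        if len({p.bitstring for p in self.populations}) != len(self.populations):
            raise ConfigurationError("planted bit patterns must be distinct")
        if not 0 <= self.outcome.population_index < len(self.populations):
            raise ConfigurationError("outcome population_index out of range")
        if self.n_samples < 1 or self.n_events < 1:
            raise ConfigurationError("n_samples and n_events must be positive")

    @property
    def marker_names(self) -> list[str]:
        return [m.name for m in self.markers]

    @property
    def base_weights(self) -> np.ndarray:
        w = np.array([p.base_weight for p in self.populations], dtype=float)
        return w / w.sum()


# Default study conditions: an 8-marker T-cell-style panel with six planted
# phenotypes. Patterns are pairwise Hamming distance >=2 so a single-marker
# false-positive call can never turn one planted phenotype into another; the
# outcome-planted population (index 0) carries a single negative marker so the
# association check is not dominated by the deterministic ~1%-per-negative-
# marker false-positive rate the 99th-percentile FMO rule carries by design.
_DEFAULT_MARKERS = tuple(
    MarkerModel(name)
    for name in ("CD3", "CD4", "CD8", "CD44", "CD62L", "CD103", "PD1", "IFNg")
)
_DEFAULT_POPULATIONS = (
    PlantedPopulation((1, 1, 0, 1, 1, 1, 1, 1), 0.28),  # activated T helper
    PlantedPopulation((1, 1, 0, 1, 1, 0, 0, 0), 0.16),  # central-memory Th
    PlantedPopulation((1, 0, 1, 1, 0, 0, 1, 1), 0.18),  # effector CTL
    PlantedPopulation((1, 0, 1, 1, 0, 1, 0, 1), 0.14),  # resident CTL
    PlantedPopulation((1, 0, 0, 1, 0, 0, 0, 1), 0.12),  # double-negative T
    PlantedPopulation((0, 0, 0, 0, 0, 0, 0, 0), 0.07),  # non-T / all-negative
)


def default_config(seed: int = 0, **overrides) -> SyntheticConfig:
    """The default synthetic experiment (8 markers, 6 populations, 10x50k)."""
    kwargs = dict(
        markers=_DEFAULT_MARKERS,
        populations=_DEFAULT_POPULATIONS,
        seed=seed,
    )
    kwargs.update(overrides)
    return SyntheticConfig(**kwargs)


def default_channel_map(config: SyntheticConfig) -> ChannelMap:
    entries = [
        ("FSC-A", "FSC-A", "scatter_area"),
        ("FSC-H", "FSC-H", "scatter_height"),
        ("SSC-A", "SSC-A", "side_scatter"),
        ("Zombie-A", "ZombieNIR", "viability"),
    ]
    entries += [(f"{m}-A", m, "marker") for m in config.marker_names]
    return ChannelMap.from_entries(entries)


ARTIFACT_CLASSES = ("none", "doublet", "debris", "dead")


@dataclass
class TruthTable:
    """Ground truth for one generated experiment."""

    config: SyntheticConfig
    event_labels: dict[str, pd.DataFrame]  # sample -> (artifact, phenotype)
    true_percents: pd.DataFrame  # sample_id, phenotype, percent (of clean events)
    true_thresholds: dict[str, float]
    outcome: dict[str, float]
    metadata: pd.DataFrame  # sample_id, group, timepoint
    planted_phenotype: str = ""

    def summary_dict(self) -> dict:
        artifact_counts = {
            sid: labels["artifact"].value_counts().to_dict()
            for sid, labels in sorted(self.event_labels.items())
        }
        return {
            "marker_order": self.config.marker_names,
            "true_percents": [
                {
                    "sample_id": r.sample_id,
                    "phenotype": r.phenotype,
                    "percent": float(r.percent),
                }
                for r in self.true_percents.itertuples(index=False)
            ],
            "true_thresholds": {
                m: float(t) for m, t in sorted(self.true_thresholds.items())
            },
            "outcome": {s: float(v) for s, v in sorted(self.outcome.items())},
            "planted": {
                "phenotype": self.planted_phenotype,
                "slope": self.config.outcome.slope,
                "intercept": self.config.outcome.intercept,
                "noise_sd": self.config.outcome.noise_sd,
            },
            "artifact_counts": artifact_counts,
        }

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")


def _draw_marker_block(
    rng: np.random.Generator,
    config: SyntheticConfig,
    pop_idx: np.ndarray,
    forced_negative: str | None = None,
) -> np.ndarray:
    """Marker values for events with planted population indices *pop_idx*."""
    bits = np.array([p.bits for p in config.populations], dtype=int)
    n = pop_idx.size
    out = np.empty((n, len(config.markers)))
    for j, marker in enumerate(config.markers):
        positive = bits[pop_idx, j].astype(bool)
        if forced_negative == marker.name:
            positive = np.zeros(n, dtype=bool)
        mean = np.where(positive, marker.pos_mean, marker.neg_mean)
        sd = np.where(positive, marker.pos_sd, marker.neg_sd)
        out[:, j] = rng.normal(mean, sd)
    if config.spillover_sd > 0 and out.shape[1] > 1:
        # Small additive bleed from the per-event mean of the other channels.
        bleed = rng.normal(0.0, config.spillover_sd, size=out.shape)
        out = out + bleed * (out.mean(axis=1, keepdims=True) / max(1.0, out.max()))
    return out


def _generate_events(
    rng: np.random.Generator,
    config: SyntheticConfig,
    n_events: int,
    weights: np.ndarray,
    forced_negative: str | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """One acquisition: returns (channel data frame, per-event truth labels)."""
    sc = config.scatter
    via = config.viability
    p_art = [config.doublet_frac, config.debris_frac, config.dead_frac]
    counts = rng.multinomial(n_events, p_art + [1.0 - sum(p_art)])
    n_doublet, n_debris, n_dead, n_good = (int(c) for c in counts)

    blocks, labels = [], []

    def _cells(n: int, artifact: str, doublet: bool = False) -> None:
        if n == 0:
            return
        pop_idx = rng.choice(len(config.populations), size=n, p=weights)
        markers = _draw_marker_block(rng, config, pop_idx, forced_negative)
        if doublet:
            a1 = rng.normal(sc.cell_area_mean, sc.cell_area_sd, n)
            a2 = rng.normal(sc.cell_area_mean, sc.cell_area_sd, n)
            area = a1 + a2
            height = sc.height_ratio * np.maximum(a1, a2)
        else:
            area = rng.normal(sc.cell_area_mean, sc.cell_area_sd, n)
            height = sc.height_ratio * area
        height = height * (1.0 + rng.normal(0.0, sc.height_noise_rel, n))
        side = rng.normal(sc.side_mean, sc.side_sd, n)
        if artifact == "dead":
            viability = rng.normal(via.pos_mean, via.pos_sd, n)
        else:
            viability = rng.normal(via.neg_mean, via.neg_sd, n)
        blocks.append(
            np.column_stack([area, height, side, viability, markers])
        )
        phenos = np.array(
            [config.populations[i].bitstring for i in pop_idx], dtype=object
        )
        labels.append(pd.DataFrame({"artifact": artifact, "phenotype": phenos}))

    _cells(n_good, "none")
    _cells(n_doublet, "doublet", doublet=True)
    _cells(n_dead, "dead")
    if n_debris:
        n = n_debris
        area = np.abs(rng.normal(sc.debris_area_mean, sc.debris_area_sd, n))
        height = sc.height_ratio * area * (1.0 + rng.normal(0.0, sc.height_noise_rel, n))
        side = rng.normal(sc.debris_side_mean, sc.debris_side_sd, n)
        viability = rng.normal(via.neg_mean, via.neg_sd, n)
        # Debris is dim on every marker channel.
        pop_idx = np.zeros(n, dtype=int)
        markers = np.empty((n, len(config.markers)))
        for j, marker in enumerate(config.markers):
            markers[:, j] = rng.normal(marker.neg_mean, marker.neg_sd, n)
        blocks.append(np.column_stack([area, height, side, viability, markers]))
        labels.append(
            pd.DataFrame(
                {"artifact": "debris", "phenotype": np.full(n, "", dtype=object)}
            )
        )

    data = np.vstack(blocks)
    truth = pd.concat(labels, ignore_index=True)
    order = rng.permutation(len(data))  # interleave, as acquisition would
    columns = ["FSC-A", "FSC-H", "SSC-A", "Zombie-A"] + [
        f"{m}-A" for m in config.marker_names
    ]
    frame = pd.DataFrame(data[order], columns=columns)
    return frame, truth.iloc[order].reset_index(drop=True)


def _true_thresholds(config: SyntheticConfig, q: float = 0.99) -> dict[str, float]:
    """The estimand of the FMO rule: the negative component's q-quantile."""
    z = float(norm.ppf(q))
    return {m.name: m.neg_mean + z * m.neg_sd for m in config.markers}


def generate_experiment(config: SyntheticConfig, outdir) -> TruthTable:
    """Write a complete synthetic experiment under *outdir* and return truth.

    Layout: ``samples/*.fcs`` (or ``.csv``), ``fmos/FMO_<marker>.fcs``,
    ``metadata.csv``, ``outcome.csv``, ``truth.json``. Identical config and
    seed produce byte-identical files.
    """
    outdir = Path(outdir)
    (outdir / "samples").mkdir(parents=True, exist_ok=True)
    (outdir / "fmos").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    channel_map = default_channel_map(config)
    base_weights = config.base_weights
    alpha = base_weights * config.dirichlet_concentration
    planted = config.populations[config.outcome.population_index]

    event_labels: dict[str, pd.DataFrame] = {}
    percent_rows = []
    outcome: dict[str, float] = {}
    meta_rows = []
    combos = [
        (g, t) for t in config.timepoints for g in config.groups
    ] or [("all", "all")]

    for i in range(config.n_samples):
        sample_id = f"S{i + 1:02d}"
        weights = rng.dirichlet(alpha)
        frame, truth = _generate_events(rng, config, config.n_events, weights)
        clean = truth[truth["artifact"] == "none"]
        denom = len(clean)
        for pop in config.populations:
            count = int((clean["phenotype"] == pop.bitstring).sum())
            percent_rows.append(
                (sample_id, pop.bitstring, 100.0 * count / denom if denom else 0.0)
            )
        true_pct = next(
            p for s, b, p in percent_rows[-len(config.populations):]
            if b == planted.bitstring
        )
        outcome[sample_id] = (
            config.outcome.intercept
            + config.outcome.slope * true_pct
            + rng.normal(0.0, config.outcome.noise_sd)
        )
        group, timepoint = combos[i % len(combos)]
        meta_rows.append((sample_id, group, timepoint))
        event_labels[sample_id] = truth
        table = EventTable(sample_id, frame, channel_map)
        if config.write_fcs_files:
            write_fcs(outdir / "samples" / f"{sample_id}.fcs", table)
        else:
            write_event_csv(table, outdir / "samples" / f"{sample_id}.csv")

    for marker in config.marker_names:
        frame, _ = _generate_events(
            rng, config, config.n_fmo_events, base_weights, forced_negative=marker
        )
        table = EventTable(f"FMO_{marker}", frame, channel_map)
        if config.write_fcs_files:
            write_fcs(outdir / "fmos" / f"FMO_{marker}.fcs", table)
        else:
            write_event_csv(table, outdir / "fmos" / f"FMO_{marker}.csv")

    metadata = pd.DataFrame(meta_rows, columns=["sample_id", "group", "timepoint"])
    metadata.to_csv(outdir / "metadata.csv", index=False)
    pd.DataFrame(
        {"sample_id": list(outcome), config.outcome.name: list(outcome.values())}
    ).to_csv(outdir / "outcome.csv", index=False)

    truth_table = TruthTable(
        config=config,
        event_labels=event_labels,
        true_percents=pd.DataFrame(
            percent_rows, columns=["sample_id", "phenotype", "percent"]
        ),
        true_thresholds=_true_thresholds(config),
        outcome=outcome,
        metadata=metadata,
        planted_phenotype=planted.bitstring,
    )
    truth_table.write_json(outdir / "truth.json")
    return truth_table


@dataclass
class CheckEntry:
    name: str
    value: float
    tolerance: str
    passed: bool


@dataclass
class EndToEndReport:
    """Truth-vs-pipeline comparison for one generated experiment."""

    entries: list[CheckEntry]
    threshold_errors: dict[str, float]
    recovered_slope: float
    slope_ci: tuple[float, float]
    max_percent_error: float
    n_planted_recovered: int
    n_spurious: int
    good_recall: float
    artifact_removal: dict[str, float]

    @property
    def passed(self) -> bool:
        return all(e.passed for e in self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"check": e.name, "value": e.value, "tolerance": e.tolerance,
                 "passed": e.passed}
                for e in self.entries
            ]
        )


def end_to_end_check(
    config: SyntheticConfig,
    outdir,
    min_percent: float = 0.5,
    percent_tolerance_pp: float = 1.0,
    threshold_tolerance: float = 0.2,
) -> EndToEndReport:
    """Generate an experiment, run the whole pipeline on it, score vs truth.

    Checks: every planted population recovered above the abundance filter; no
    spurious population above it; per-sample per-population percent error
    within ``percent_tolerance_pp``; learned thresholds near the negative
    components' true 99th percentiles; planted outcome slope inside the
    fitted 95% CI; gate recovery of truth-labelled clean events >=95% and
    removal of each artifact class >=90%.
    """
    from . import gating, phenotyping, thresholds as thr
    from .fcs_io import read_fcs
    from .stats import ExternalMeasure, associate

    outdir = Path(outdir)
    truth = generate_experiment(config, outdir)
    channel_map = default_channel_map(config)
    gate_config = gating.GateConfig()
    markers = config.marker_names

    suffix = "fcs" if config.write_fcs_files else "csv"
    read = read_fcs if config.write_fcs_files else _read_csv_events
    binary_by_sample: dict[str, np.ndarray] = {}
    good_kept = good_total = 0
    removed = {c: 0 for c in ("doublet", "debris", "dead")}
    totals = {c: 0 for c in ("doublet", "debris", "dead")}
    cleaned_tables: dict[str, EventTable] = {}

    for sample_id, labels in truth.event_labels.items():
        table = read(outdir / "samples" / f"{sample_id}.{suffix}", channel_map)
        cleaned, audit = gating.clean(table, gate_config)
        kept = gating.composite_kept_mask(audit, table.n_events)
        art = labels["artifact"].to_numpy()
        good = art == "none"
        good_total += int(good.sum())
        good_kept += int((good & kept).sum())
        for cls in removed:
            is_cls = art == cls
            totals[cls] += int(is_cls.sum())
            removed[cls] += int((is_cls & ~kept).sum())
        cleaned_tables[sample_id] = cleaned

    fmo_tables = {
        m: read(outdir / "fmos" / f"FMO_{m}.{suffix}", channel_map)
        for m in markers
    }
    threshold_set = thr.build_threshold_set(
        markers, fmo_tables=fmo_tables, gate_config=gate_config
    )
    threshold_errors = {
        m: abs(threshold_set.threshold(m) - truth.true_thresholds[m])
        for m in markers
    }

    for sample_id, cleaned in cleaned_tables.items():
        binary_by_sample[sample_id] = phenotyping.binarize(cleaned, threshold_set)
    populations = phenotyping.enumerate_populations(binary_by_sample, markers)
    filtered = phenotyping.filter_populations(populations, min_percent=min_percent)

    planted_set = {p.bitstring for p in config.populations}
    recovered = planted_set & set(filtered.phenotypes)
    spurious = set(filtered.phenotypes) - planted_set

    est = populations.df.set_index(["sample_id", "phenotype"])["percent"]
    errors = [
        abs(est.get((r.sample_id, r.phenotype), 0.0) - r.percent)
        for r in truth.true_percents.itertuples(index=False)
    ]
    max_percent_error = float(max(errors))

    measure = ExternalMeasure(values=truth.outcome, name=config.outcome.name)
    results = associate(filtered, measure)
    planted_result = next(
        r for r in results if r.phenotype == truth.planted_phenotype
    )
    ci = planted_result.confint(0.95)
    slope_true = config.outcome.slope

    good_recall = good_kept / good_total if good_total else 1.0
    artifact_removal = {
        cls: (removed[cls] / totals[cls] if totals[cls] else 1.0) for cls in removed
    }
    entries = [
        CheckEntry(
            "planted_populations_recovered", len(recovered),
            f"== {len(planted_set)}", len(recovered) == len(planted_set),
        ),
        CheckEntry(
            "spurious_populations_above_filter", len(spurious), "== 0",
            len(spurious) == 0,
        ),
        CheckEntry(
            "max_abs_percent_error_pp", max_percent_error,
            f"<= {percent_tolerance_pp}", max_percent_error <= percent_tolerance_pp,
        ),
        CheckEntry(
            "max_abs_threshold_error", max(threshold_errors.values()),
            f"<= {threshold_tolerance}",
            max(threshold_errors.values()) <= threshold_tolerance,
        ),
        CheckEntry(
            "planted_slope_in_ci",
            float(ci[0] <= slope_true <= ci[1]),
            f"{slope_true} in fitted 95% CI", ci[0] <= slope_true <= ci[1],
        ),
        CheckEntry("good_event_recall", good_recall, ">= 0.95", good_recall >= 0.95),
    ]
    for cls, rate in artifact_removal.items():
        entries.append(
            CheckEntry(f"{cls}_removal_rate", rate, ">= 0.90", rate >= 0.90)
        )
    return EndToEndReport(
        entries=entries,
        threshold_errors=threshold_errors,
        recovered_slope=planted_result.slope,
        slope_ci=ci,
        max_percent_error=max_percent_error,
        n_planted_recovered=len(recovered),
        n_spurious=len(spurious),
        good_recall=good_recall,
        artifact_removal=artifact_removal,
    )


def _read_csv_events(path, channel_map):
    from .fcs_io import read_event_csv

    return read_event_csv(path, channel_map)
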