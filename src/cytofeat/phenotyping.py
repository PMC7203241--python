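"""Marker binarization, phenotype enumeration, filtering and lineage labels.

A cell's phenotype is its vector of positive/negative calls across the panel
markers, in a fixed marker order shared by the whole experiment. Positivity
is a strict comparison against the learned threshold: a value exactly at the
threshold is negative, because the FMO quantile is defined as the upper
envelope of true negatives (configurable to ``>=``).

Enumeration keeps every phenotype that at least one cell in at least one
sample expresses, on a complete sample x phenotype grid (zero counts filled
in) so that downstream correlation and regression see aligned vectors.
Percentages are always of the *cleaned* per-sample event count, never of a
filtered subset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .fcs_io import EventTable
from .thresholds import ThresholdSet

__all__ = [
    "PhenotypeKey",
    "PopulationTable",
    "LineageRule",
    "LineageRuleset",
    "binarize",
    "enumerate_populations",
    "filter_populations",
    "classify",
]

LABEL_FIELDS = ("lineage", "subset", "resident")


@dataclass(frozen=True)
class PhenotypeKey:
    """One phenotype: the ordered marker list and its 0/1 calls."""

    marker_order: tuple[str, ...]
    bits: tuple[int, ...]

    def __post_init__(self):
        if len(self.bits) != len(self.marker_order):
            raise ConfigurationError("bits and marker_order lengths differ")
        if any(b not in (0, 1) for b in self.bits):
            raise ConfigurationError("bits must be 0 or 1")

    @property
    def bitstring(self) -> str:
        return "".join(str(b) for b in self.bits)

    def render(self) -> str:
        """Human-readable form, e.g. ``CD3+CD4+CD8-``."""
        return "".join(
            f"{m}{'+' if b else '-'}" for m, b in zip(self.marker_order, self.bits)
        )

    @classmethod
    def from_bitstring(
        cls, bitstring: str, marker_order: Sequence[str]
    ) -> "PhenotypeKey":
        return cls(tuple(marker_order), tuple(int(c) for c in bitstring))


@dataclass(frozen=True)
class LineageRule:
    label_field: str  # lineage | subset | resident
    constraints: tuple[tuple[str, int], ...]  # marker -> required bit
    label: str

    def __post_init__(self):
        if self.label_field not in LABEL_FIELDS:
            raise ConfigurationError(
                f"label_field must be one of {LABEL_FIELDS}, got {self.label_field!r}"
            )

    def matches(self, key: PhenotypeKey) -> bool:
        index = {m: i for i, m in enumerate(key.marker_order)}
        for marker, bit in self.constraints:
            if marker not in index:
                raise ConfigurationError(
                    f"rule {self.label!r} references undeclared marker {marker!r}"
                )
            if key.bits[index[marker]] != bit:
                return False
        return True


@dataclass(frozen=True)
class LineageRuleset:
    """Ordered first-match-wins rules per label field, with a default."""

    rules: tuple[LineageRule, ...]
    default_label: str = "unknown"

    @classmethod
    def from_config(
        cls, rules: Sequence[Mapping], default_label: str = "unknown"
    ) -> "LineageRuleset":
        parsed = tuple(
            LineageRule(
                label_field=r["field"],
                constraints=tuple((m, int(b)) for m, b in r["constraints"].items()),
                label=r["label"],
            )
            for r in rules
        )
        return cls(parsed, default_label)

    def labels_for(self, key: PhenotypeKey) -> dict[str, str]:
        labels = {f: self.default_label for f in LABEL_FIELDS}
        remaining = set(LABEL_FIELDS)
        for rule in self.rules:
            if rule.label_field in remaining and rule.matches(key):
                labels[rule.label_field] = rule.label
                remaining.discard(rule.label_field)
        return labels

    @property
    def lineage_order(self) -> list[str]:
        """Lineage labels in rule order (used for population numbering)."""
        seen: list[str] = []
        for rule in self.rules:
            if rule.label_field == "lineage" and rule.label not in seen:
                seen.append(rule.label)
        return seen


@dataclass
class PopulationTable:
    """Per-sample counts and percentages for every observed phenotype.

    ``df`` is tidy: one row per (sample_id, phenotype bitstring) with count
    and percent columns, plus label and population_id columns once classify /
    filter have run. ``denominators`` maps each sample to its cleaned event
    count — the percentage denominator throughout.
    """

    df: pd.DataFrame
    marker_order: tuple[str, ...]
    denominators: dict[str, int]
    population_ids: dict[str, int] = field(default_factory=dict)

    @property
    def phenotypes(self) -> list[str]:
        return sorted(self.df["phenotype"].unique())

    @property
    def sample_ids(self) -> list[str]:
        return sorted(self.df["sample_id"].unique())

    def key(self, bitstring: str) -> PhenotypeKey:
        return PhenotypeKey.from_bitstring(bitstring, self.marker_order)

    def percent_matrix(self) -> pd.DataFrame:
        """samples x phenotypes percent grid (zero-filled by construction)."""
        return self.df.pivot(index="sample_id", columns="phenotype", values="percent")

    def to_frame(self) -> pd.DataFrame:
        out = self.df.copy()
        out["phenotype_label"] = [
            self.key(p).render() for p in out["phenotype"]
        ]
        out["denominator"] = out["sample_id"].map(self.denominators)
        if self.population_ids:
            out["population_id"] = out["phenotype"].map(self.population_ids)
            out = out.sort_values(["population_id", "sample_id"], kind="stable")
        cols = [
            c
            for c in (
                "sample_id", "population_id", "phenotype_label", "phenotype",
                "count", "percent", "denominator", "lineage", "subset", "resident",
            )
            if c in out.columns
        ]
        return out[cols].reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, marker_order: Sequence[str]) -> "PopulationTable":
        """Rebuild a table written by :meth:`to_csv` (bitstrings kept as text)."""
        marker_order = tuple(marker_order)
        frame = pd.read_csv(
            path, comment="#", dtype={"phenotype": str},
            float_precision="round_trip",
        )
        frame["phenotype"] = frame["phenotype"].str.zfill(len(marker_order))
        frame["sample_id"] = frame["sample_id"].astype(str)
        denominators = (
            frame.drop_duplicates("sample_id")
            .set_index("sample_id")["denominator"]
            .astype(int)
            .to_dict()
        )
        ids = {}
        if "population_id" in frame.columns and frame["population_id"].notna().all():
            ids = (
                frame.drop_duplicates("phenotype")
                .set_index("phenotype")["population_id"]
                .astype(int)
                .to_dict()
            )
        keep = [
            c
            for c in ("sample_id", "phenotype", "count", "percent",
                      "lineage", "subset", "resident")
            if c in frame.columns
        ]
        return cls(
            df=frame[keep].copy(),
            marker_order=marker_order,
            denominators=denominators,
            population_ids=ids,
        )


def binarize(table: EventTable, thresholds: ThresholdSet) -> np.ndarray:
    """Events x markers 0/1 matrix; 1 iff value is strictly above threshold."""
    markers = table.channel_map.markers
    thresholds.require_complete(markers)
    out = np.empty((table.n_events, len(markers)), dtype=np.uint8)
    for j, marker in enumerate(markers):
        out[:, j] = table.marker_values(marker) > thresholds.threshold(marker)
    return out


def binarize_ge(table: EventTable, thresholds: ThresholdSet) -> np.ndarray:
    """Variant with inclusive comparison (value >= threshold is positive)."""
    markers = table.channel_map.markers
    thresholds.require_complete(markers)
    out = np.empty((table.n_events, len(markers)), dtype=np.uint8)
    for j, marker in enumerate(markers):
        out[:, j] = table.marker_values(marker) >= thresholds.threshold(marker)
    return out


def _codes(binary: np.ndarray) -> np.ndarray:
    """Pack each 0/1 row into one integer code (marker 0 = most significant)."""
    n_markers = binary.shape[1]
    if n_markers > 62:
        raise ConfigurationError("more than 62 markers is not supported")
    weights = (1 << np.arange(n_markers - 1, -1, -1)).astype(np.int64)
    return binary.astype(np.int64) @ weights


def _code_to_bitstring(code: int, n_markers: int) -> str:
    return format(code, f"0{n_markers}b")


def enumerate_populations(
    binary_by_sample: Mapping[str, np.ndarray],
    marker_order: Sequence[str],
) -> PopulationTable:
    """Count every observed phenotype per sample, on a complete grid.

    A phenotype is included iff at least one cell in at least one sample has
    exactly that bit pattern; samples where it is absent get explicit zero
    rows. Percent uses each sample's own cleaned event count.
    """
    marker_order = tuple(marker_order)
    n_markers = len(marker_order)
    counts: dict[str, dict[int, int]] = {}
    denominators: dict[str, int] = {}
    for sample_id, binary in binary_by_sample.items():
        binary = np.asarray(binary)
        if binary.ndim != 2 or binary.shape[1] != n_markers:
            raise ConfigurationError(
                f"sample {sample_id!r}: binary matrix has "
                f"{binary.shape[1] if binary.ndim == 2 else '?'} columns, "
                f"marker order declares {n_markers}"
            )
        codes, n = np.unique(_codes(binary), return_counts=True)
        counts[sample_id] = dict(zip(codes.tolist(), n.tolist()))
        denominators[sample_id] = int(binary.shape[0])

    all_codes = sorted({c for per in counts.values() for c in per})
    rows = []
    for sample_id in counts:
        denom = denominators[sample_id]
        for code in all_codes:
            count = counts[sample_id].get(code, 0)
            rows.append(
                (
                    sample_id,
                    _code_to_bitstring(code, n_markers),
                    count,
                    100.0 * count / denom if denom else 0.0,
                )
            )
    df = pd.DataFrame(rows, columns=["sample_id", "phenotype", "count", "percent"])
    return PopulationTable(df=df, marker_order=marker_order, denominators=denominators)


def filter_populations(
    table: PopulationTable,
    min_percent: float = 0.5,
    min_count: int | None = None,
    marker_constraints: Mapping[str, int] | None = None,
    lineage_order: Sequence[str] | None = None,
) -> PopulationTable:
    """Keep phenotypes passing the marker constraints and the abundance rule.

    A phenotype survives iff it satisfies every marker constraint AND its
    percent strictly exceeds ``min_percent`` in at least one sample (or, in
    rare-population mode, its count reaches ``min_count`` in at least one
    sample). All samples' rows for surviving phenotypes are retained, and
    population ids are reassigned densely (see :func:`assign_population_ids`).
    """
    marker_constraints = dict(marker_constraints or {})
    index = {m: i for i, m in enumerate(table.marker_order)}
    for marker in marker_constraints:
        if marker not in index:
            raise ConfigurationError(
                f"constraint references undeclared marker {marker!r}"
            )

    def _passes(bitstring: str) -> bool:
        return all(
            int(bitstring[index[m]]) == int(b) for m, b in marker_constraints.items()
        )

    df = table.df
    stats = df.groupby("phenotype").agg(
        max_percent=("percent", "max"), max_count=("count", "max")
    )
    abundant = stats["max_percent"] > min_percent
    if min_count is not None:
        abundant = abundant | (stats["max_count"] >= min_count)
    keep = {p for p in stats.index[abundant] if _passes(p)}
    out = replace(
        table,
        df=df[df["phenotype"].isin(keep)].reset_index(drop=True),
        population_ids={},
    )
    return assign_population_ids(out, lineage_order)


def classify(table: PopulationTable, rules: LineageRuleset) -> PopulationTable:
    """Attach lineage/subset/resident labels to every phenotype.

    First matching rule per label field wins; phenotypes matching no rule get
    the ruleset's default label.
    """
    labels = {
        p: rules.labels_for(table.key(p)) for p in table.df["phenotype"].unique()
    }
    df = table.df.copy()
    for fieldname in LABEL_FIELDS:
        df[fieldname] = df["phenotype"].map(lambda p: labels[p][fieldname])
    return replace(table, df=df)


def assign_population_ids(
    table: PopulationTable, lineage_order: Sequence[str] | None = None
) -> PopulationTable:
    """Dense integer ids: by lineage (config order), then mean percent desc.

    Ties break on the bitstring so numbering is fully deterministic. Ids are
    stable for a given table, not across different filters.
    """
    df = table.df
    mean_percent = df.groupby("phenotype")["percent"].mean()
    if "lineage" in df.columns and lineage_order:
        rank = {label: i for i, label in enumerate(lineage_order)}
        lineage = df.drop_duplicates("phenotype").set_index("phenotype")["lineage"]
        sort_key = sorted(
            mean_percent.index,
            key=lambda p: (
                rank.get(lineage[p], len(rank)),
                -mean_percent[p],
                p,
            ),
        )
    else:
        sort_key = sorted(mean_percent.index, key=lambda p: (-mean_percent[p], p))
    ids = {p: i + 1 for i, p in enumerate(sort_key)}
    return replace(table, population_ids=ids)
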