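"""Per-marker positivity thresholds from FMO controls or density valleys.

An FMO (fluorescence-minus-one) control is stained with every marker except
one, so every event is truly negative on that marker; its high quantile
(default the 99th percentile, leaving 1% headroom for stray debris noise)
defines the ceiling of the negative population. When no FMO exists and the
marker separates cleanly into negative and positive modes, the threshold is
the minimum-density valley of the sample distribution itself. Manual
overrides always win.

Quantiles use the linear-interpolation convention between order statistics
(numpy's default): for sorted values x_(1..n), the q-quantile sits at
position 1 + q(n-1).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import gating
from .errors import ConfigurationError, NoValleyError
from .fcs_io import EventTable

__all__ = [
    "ThresholdEntry",
    "ThresholdSet",
    "fmo_threshold",
    "sample_threshold",
    "build_threshold_set",
]

DEFAULT_QUANTILE = 0.99
MIN_FMO_EVENTS = 100


@dataclass(frozen=True)
class ThresholdEntry:
    marker: str
    threshold: float
    method: str  # fmo_quantile | density_valley | manual
    quantile: float | None = None  # recorded for fmo_quantile only
    source_sample: str | None = None
    n_events_used: int | None = None
    warnings: tuple[str, ...] = ()


@dataclass
class ThresholdSet:
    """One positivity cutoff per marker, with method provenance."""

    entries: dict[str, ThresholdEntry]

    def __getitem__(self, marker: str) -> ThresholdEntry:
        return self.entries[marker]

    def __contains__(self, marker: str) -> bool:
        return marker in self.entries

    def threshold(self, marker: str) -> float:
        return self.entries[marker].threshold

    def require_complete(self, markers: Sequence[str]) -> None:
        missing = [m for m in markers if m not in self.entries]
        if missing:
            raise ConfigurationError(f"markers without thresholds: {missing}")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "marker": e.marker,
                "threshold": e.threshold,
                "method": e.method,
                "quantile": e.quantile,
                "source_sample": e.source_sample,
                "n_events_used": e.n_events_used,
                "warnings": ";".join(e.warnings),
            }
            for e in self.entries.values()
        ]
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ThresholdSet":
        entries = {}
        for row in frame.itertuples(index=False):
            quantile = getattr(row, "quantile", None)
            if quantile is not None and pd.isna(quantile):
                quantile = None
            source = getattr(row, "source_sample", None)
            if isinstance(source, float) and pd.isna(source):
                source = None
            warn = getattr(row, "warnings", "") or ""
            if isinstance(warn, float):
                warn = ""
            n_used = getattr(row, "n_events_used", None)
            if n_used is not None and pd.isna(n_used):
                n_used = None
            entries[row.marker] = ThresholdEntry(
                marker=row.marker,
                threshold=float(row.threshold),
                method=row.method,
                quantile=None if quantile is None else float(quantile),
                source_sample=source,
                n_events_used=None if n_used is None else int(n_used),
                warnings=tuple(w for w in warn.split(";") if w),
            )
        return cls(entries)

    @classmethod
    def from_csv(cls, path) -> "ThresholdSet":
        return cls.from_frame(pd.read_csv(path, comment="#", float_precision="round_trip"))


def fmo_threshold(
    fmo_table: EventTable,
    marker: str,
    q: float = DEFAULT_QUANTILE,
    clean_first: bool = True,
    gate_config: gating.GateConfig = gating.GateConfig(),
) -> ThresholdEntry:
    """Positivity cutoff from the FMO lacking *marker*: its q-quantile.

    The FMO is cleaned with the same gate chain as samples before the
    quantile is taken (cleaning is part of the control's definition, not an
    optimisation), unless ``clean_first`` is disabled.
    """
    if not 0 < q <= 1:
        raise ConfigurationError(f"quantile must be in (0, 1], got {q}")
    fmo_table.channel_map.detector_for(marker)  # raises if undeclared
    table = fmo_table
    if clean_first:
        table, _ = gating.clean(fmo_table, gate_config)
    values = table.marker_values(marker)
    warnings = ()
    if values.size < MIN_FMO_EVENTS:
        warnings = (
            f"only {values.size} events after cleaning (<{MIN_FMO_EVENTS})",
        )
    return ThresholdEntry(
        marker=marker,
        threshold=float(np.quantile(values, q)),  # linear interpolation
        method="fmo_quantile",
        quantile=q,
        source_sample=fmo_table.sample_id,
        n_events_used=int(values.size),
        warnings=warnings,
    )


def sample_threshold(
    table: EventTable,
    marker: str,
    gate_config: gating.GateConfig = gating.GateConfig(),
) -> ThresholdEntry:
    """Positivity cutoff from the sample itself: the density valley.

    Valid when the marker distribution is bimodal with good separation
    between negative and positive modes; otherwise raises
    :class:`NoValleyError` naming the marker.
    """
    values = table.marker_values(marker)
    try:
        valley = gating.density_valley(
            values,
            grid_points=gate_config.grid_points,
            bandwidth_multiplier=gate_config.bandwidth_multiplier,
        )
    except NoValleyError as exc:
        raise NoValleyError(
            f"marker {marker!r}: {exc}", mode_location=exc.mode_location
        ) from exc
    return ThresholdEntry(
        marker=marker,
        threshold=valley.threshold,
        method="density_valley",
        source_sample=table.sample_id,
        n_events_used=int(values.size),
    )


def build_threshold_set(
    markers: Sequence[str],
    fmo_tables: Mapping[str, EventTable] | None = None,
    sample_tables: Sequence[EventTable] | None = None,
    overrides: Mapping[str, float] | None = None,
    q: float = DEFAULT_QUANTILE,
    clean_first: bool = True,
    gate_config: gating.GateConfig = gating.GateConfig(),
) -> ThresholdSet:
    """Resolve one threshold per marker.

    Precedence per marker: manual override > FMO quantile > density valley on
    the samples (cleaned events pooled across samples). A marker no route can
    resolve is a configuration error listing the routes tried.
    """
    fmo_tables = fmo_tables or {}
    overrides = overrides or {}
    sample_tables = list(sample_tables or [])
    unknown = [m for m in overrides if m not in markers]
    if unknown:
        raise ConfigurationError(f"overrides for undeclared markers: {unknown}")

    pooled: EventTable | None = None
    entries: dict[str, ThresholdEntry] = {}
    for marker in markers:
        if marker in overrides:
            entries[marker] = ThresholdEntry(
                marker=marker, threshold=float(overrides[marker]), method="manual"
            )
            continue
        if marker in fmo_tables:
            entries[marker] = fmo_threshold(
                fmo_tables[marker], marker, q=q,
                clean_first=clean_first, gate_config=gate_config,
            )
            continue
        tried = ["manual: no override", "fmo_quantile: no FMO file"]
        if not sample_tables:
            raise ConfigurationError(
                f"cannot resolve threshold for {marker!r}; tried "
                + "; ".join(tried + ["density_valley: no sample tables"])
            )
        if pooled is None:
            pooled = _pool_cleaned(sample_tables, clean_first, gate_config)
        try:
            entry = sample_threshold(pooled, marker, gate_config)
        except NoValleyError as exc:
            raise ConfigurationError(
                f"cannot resolve threshold for {marker!r}; tried "
                + "; ".join(tried + [f"density_valley: {exc}"])
            ) from exc
        entries[marker] = entry
    return ThresholdSet(entries)


def _pool_cleaned(
    sample_tables: Sequence[EventTable],
    clean_first: bool,
    gate_config: gating.GateConfig,
) -> EventTable:
    cleaned = []
    for t in sample_tables:
        ct = gating.clean(t, gate_config)[0] if clean_first else t
        cleaned.append(ct.data)
    pooled = pd.concat(cleaned, ignore_index=True)
    first = sample_tables[0]
    return EventTable(
        sample_id="pooled",
        data=pooled,
        channel_map=first.channel_map,
        transform_applied=first.transform_applied,
    )
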