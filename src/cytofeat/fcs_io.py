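"""Reading FCS event data into tidy per-event tables, and value transforms.

The central container is :class:`EventTable`: a pandas DataFrame of per-event
channel values (rows = events in acquisition order, columns = detectors)
plus the panel's :class:`ChannelMap` and a transform provenance tag. Input
files are assumed compensated/unmixed upstream; no spillover correction is
applied here.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from ._fcs_format import FcsFormatError, read_fcs_file, write_fcs_file
from .errors import ConfigurationError

Role = Literal[
    "scatter_area", "scatter_height", "side_scatter", "viability", "marker", "ignore"
]

ROLES: tuple[str, ...] = (
    "scatter_area",
    "scatter_height",
    "side_scatter",
    "viability",
    "marker",
    "ignore",
)


@dataclass(frozen=True)
class ChannelEntry:
    detector: str
    marker: str
    role: Role


@dataclass(frozen=True)
class ChannelMap:
    """Panel definition: which detector carries which marker, and its role."""

    entries: tuple[ChannelEntry, ...]

    def __post_init__(self):
        detectors = [e.detector for e in self.entries]
        if len(set(detectors)) != len(detectors):
            raise ConfigurationError("detector names must be unique")
        for e in self.entries:
            if e.role not in ROLES:
                raise ConfigurationError(
                    f"unknown channel role {e.role!r} for detector {e.detector!r}"
                )
        if len(self.role_detectors("viability")) > 1:
            raise ConfigurationError("at most one viability channel is allowed")
        if not self.markers:
            raise ConfigurationError("panel declares no marker channels")

    @classmethod
    def from_entries(
        cls, entries: Iterable[tuple[str, str, str]]
    ) -> "ChannelMap":
        return cls(tuple(ChannelEntry(d, m, r) for d, m, r in entries))

    def role_detectors(self, role: str) -> list[str]:
        return [e.detector for e in self.entries if e.role == role]

    @property
    def detectors(self) -> list[str]:
        return [e.detector for e in self.entries]

    @property
    def markers(self) -> list[str]:
        """Marker names in panel order; this order keys every phenotype."""
        return [e.marker for e in self.entries if e.role == "marker"]

    def detector_for(self, marker: str) -> str:
        for e in self.entries:
            if e.role == "marker" and e.marker == marker:
                return e.detector
        raise ConfigurationError(
            f"marker {marker!r} is not declared; markers: {self.markers}"
        )

    def _single(self, role: str, required_by: str) -> str:
        found = self.role_detectors(role)
        if len(found) != 1:
            raise ConfigurationError(
                f"{required_by} requires exactly one {role} channel, "
                f"found {len(found)}"
            )
        return found[0]

    def scatter_area(self, required_by: str = "gating") -> str:
        return self._single("scatter_area", required_by)

    def scatter_height(self, required_by: str = "gating") -> str:
        return self._single("scatter_height", required_by)

    def viability(self, required_by: str = "gating") -> str:
        return self._single("viability", required_by)


@dataclass
class EventTable:
    """Per-event channel measurements for one sample."""

    sample_id: str
    data: pd.DataFrame  # columns = detector names, rows = events
    channel_map: ChannelMap
    transform_applied: str = "identity"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [d for d in self.channel_map.detectors if d not in self.data.columns]
        if missing:
            raise ConfigurationError(
                f"sample {self.sample_id!r} lacks declared detectors {missing}; "
                f"available: {list(self.data.columns)}"
            )
        if self.data.isna().any().any():
            raise ConfigurationError(
                f"sample {self.sample_id!r} contains missing values after read"
            )

    @property
    def n_events(self) -> int:
        return len(self.data)

    def marker_values(self, marker: str) -> np.ndarray:
        return self.data[self.channel_map.detector_for(marker)].to_numpy()

    def channel_values(self, detector: str) -> np.ndarray:
        return self.data[detector].to_numpy()

    def subset(self, mask: np.ndarray) -> "EventTable":
        return replace(self, data=self.data.loc[np.asarray(mask, bool)].reset_index(drop=True))


@dataclass(frozen=True)
class TransformSpec:
    """Per-channel value transform; arcsinh(x / cofactor) or identity.

    The arcsinh cofactor sets the linear-to-log crossover of the transform:
    values well below it stay near-linear, values above compress
    logarithmically. 150 is the conventional default for ordinary
    (non-mass) cytometry fluorescence.
    """

    kind: Literal["identity", "arcsinh"] = "identity"
    cofactor: float = 150.0
    channels: tuple[str, ...] | None = None  # None = all marker + viability

    def __post_init__(self):
        if self.kind not in ("identity", "arcsinh"):
            raise ConfigurationError(f"unknown transform kind {self.kind!r}")
        if self.kind == "arcsinh" and not self.cofactor > 0:
            raise ConfigurationError("arcsinh cofactor must be positive")


def read_fcs(path, channel_map: ChannelMap, sample_id: str | None = None) -> EventTable:
    """Read an FCS 3.0/3.1 file into an :class:`EventTable`.

    Values are the stored channel values (assumed compensated). Events keep
    acquisition order. Instrument metadata ($CYT, $TOT, ...) is retained in
    ``EventTable.metadata`` for provenance.
    """
    path = Path(path)
    try:
        text, names, events = read_fcs_file(path)
    except (OSError, FcsFormatError) as exc:
        raise IOError(f"cannot read FCS file {path}: {exc}") from exc
    missing = [d for d in channel_map.detectors if d not in names]
    if missing:
        raise ConfigurationError(
            f"{path.name}: declared detectors {missing} not in file; "
            f"available channels: {names}"
        )
    frame = pd.DataFrame(events, columns=names)[channel_map.detectors]
    meta = {k: v for k, v in text.items() if k in ("$TOT", "$PAR", "$CYT", "$DATATYPE")}
    meta["source_file"] = str(path)
    return EventTable(
        sample_id=sample_id or path.stem,
        data=frame,
        channel_map=channel_map,
        metadata=meta,
    )


def write_fcs(path, table: EventTable) -> None:
    """Write an EventTable as FCS3.1 float32 (fixture/synthetic use)."""
    write_fcs_file(path, list(table.data.columns), table.data.to_numpy())


def apply_transform(table: EventTable, spec: TransformSpec) -> EventTable:
    """Apply a value transform to selected channels; pure function."""
    if spec.kind == "identity":
        return replace(table, transform_applied=table.transform_applied)
    channels = spec.channels
    if channels is None:
        cm = table.channel_map
        channels = tuple(
            e.detector for e in cm.entries if e.role in ("marker", "viability")
        )
    unknown = [c for c in channels if c not in table.data.columns]
    if unknown:
        raise ConfigurationError(f"transform channels not in table: {unknown}")
    data = table.data.copy()
    for c in channels:
        data[c] = np.arcsinh(data[c].to_numpy() / spec.cofactor)
    tag = f"arcsinh(cofactor={spec.cofactor:g})"
    if table.transform_applied not in ("identity", ""):
        tag = table.transform_applied + ";" + tag
    return replace(table, data=data, transform_applied=tag)


def write_event_csv(table: EventTable, path) -> None:
    """Write the event matrix as CSV (header = detector names, full precision)."""
    table.data.to_csv(path, index=False)


def read_event_csv(path, channel_map: ChannelMap, sample_id: str | None = None) -> EventTable:
    """Read back a CSV written by :func:`write_event_csv`."""
    frame = pd.read_csv(path, comment="#", float_precision="round_trip")
    return EventTable(
        sample_id=sample_id or Path(path).stem,
        data=frame,
        channel_map=channel_map,
        metadata={"source_file": str(path)},
    )
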