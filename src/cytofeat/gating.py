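"""Reproducible cleaning gates: singlets, debris removal, live-cell selection.

The three gates mirror the standard manual cleaning sequence. Doublets are
removed by their disproportionate pulse area versus height: singlets fall on
a line through the origin in (area, height), aggregates fall below it. Debris
is removed as the low-scatter mode of the forward-scatter-area density. Dead
cells are removed as the bright mode of the viability-dye channel. The two
density gates share one primitive, :func:`density_valley`: a Gaussian KDE on
a fixed grid whose threshold is the density minimum between the two highest
modes — a deterministic re-statement of the classic minimum-density gate.

Every gate is a pure function of its inputs and records the fitted
parameters, so a gate can be replayed exactly from its audit record.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats as sps
from scipy.signal import argrelmax

from .errors import ConfigurationError, GateError, NoValleyError
from .fcs_io import EventTable

__all__ = [
    "GateResult",
    "DensityValley",
    "GateConfig",
    "singlet_gate",
    "density_valley",
    "debris_gate",
    "live_gate",
    "clean",
    "composite_kept_mask",
]


@dataclass
class GateResult:
    """Outcome of one gate: the kept mask plus replayable fit parameters."""

    kept_mask: np.ndarray
    gate_name: str
    parameters: dict
    n_in: int
    n_kept: int

    @classmethod
    def from_mask(cls, mask: np.ndarray, name: str, parameters: dict) -> "GateResult":
        mask = np.asarray(mask, dtype=bool)
        return cls(
            kept_mask=mask,
            gate_name=name,
            parameters=parameters,
            n_in=mask.size,
            n_kept=int(mask.sum()),
        )


@dataclass
class DensityValley:
    """A fitted minimum-density threshold between the two dominant modes."""

    threshold: float
    grid: np.ndarray
    density: np.ndarray
    mode_locations: np.ndarray
    bandwidth: float


@dataclass(frozen=True)
class GateConfig:
    """Cleaning-chain configuration with the pipeline defaults.

    ``band_factor`` is the singlet gate's half-width in robust standard
    deviations (1.4826 x MAD of the residuals). ``fallback_quantile`` lets a
    density gate degrade to a plain quantile cut when the channel is
    unimodal; by default that is a hard error.
    """

    singlet_enabled: bool = True
    band_factor: float = 2.5
    fit_intercept: bool = False
    debris_enabled: bool = True
    debris_fallback_quantile: float | None = None
    live_enabled: bool = True
    live_fallback_quantile: float | None = None
    bandwidth_multiplier: float = 1.0
    grid_points: int = 512


def _theil_sen_origin(x: np.ndarray, y: np.ndarray) -> float:
    """Exact Theil-Sen slope for a line constrained through the origin.

    With zero intercept the pairwise-median estimator reduces to the median
    of per-point ratios y_i / x_i, which is O(n log n).
    """
    ok = x != 0
    if not ok.any():
        raise GateError("singlet gate: all scatter-area values are zero")
    return float(np.median(y[ok] / x[ok]))


def _theil_sen_subsampled(x: np.ndarray, y: np.ndarray, max_points: int = 2000):
    """scipy Theil-Sen on a deterministic even-stride subsample."""
    if x.size > max_points:
        idx = np.linspace(0, x.size - 1, max_points).astype(np.intp)
        x, y = x[idx], y[idx]
    slope, intercept, _, _ = sps.theilslopes(y, x)
    return float(slope), float(intercept)


def singlet_gate(
    table: EventTable,
    band_factor: float = 2.5,
    fit_intercept: bool = False,
) -> GateResult:
    """Keep events near the robust height-on-area line.

    Fits a robust (Theil-Sen) line of scatter height on scatter area and
    keeps events whose residual magnitude is at most
    ``band_factor * 1.4826 * MAD(residuals)``. Doublets carry roughly twice
    the area per unit height and land far below the band.
    """
    if not band_factor > 0:
        raise ConfigurationError("band_factor must be positive")
    cm = table.channel_map
    area = table.channel_values(cm.scatter_area("singlet gate"))
    height = table.channel_values(cm.scatter_height("singlet gate"))
    if table.n_events < 10:
        raise GateError(
            f"singlet gate needs >=10 events, got {table.n_events}"
        )
    if np.ptp(area) == 0:
        raise GateError("singlet gate: scatter area has zero variance")
    if fit_intercept:
        slope, intercept = _theil_sen_subsampled(area, height)
    else:
        slope, intercept = _theil_sen_origin(area, height), 0.0
    residuals = height - (slope * area + intercept)
    mad = float(np.median(np.abs(residuals - np.median(residuals))))
    band = band_factor * 1.4826 * mad
    if band == 0:  # perfectly collinear input: every residual is zero
        mask = residuals == 0
    else:
        mask = np.abs(residuals) <= band
    return GateResult.from_mask(
        mask,
        "singlet",
        {
            "slope": slope,
            "intercept": intercept,
            "band": float(band),
            "band_factor": float(band_factor),
            "mad": mad,
        },
    )


def density_valley(
    values: Sequence[float],
    bandwidth_rule: str = "silverman",
    grid_points: int = 512,
    search_range: tuple[float, float] | None = None,
    bandwidth_multiplier: float = 1.0,
) -> DensityValley:
    """Find the minimum-density threshold between the two dominant modes.

    A Gaussian KDE (Silverman's rule by default, scaled by
    ``bandwidth_multiplier``) is evaluated on an evenly spaced grid spanning
    the data range (or ``search_range``). The two highest local maxima are
    the modes; the threshold is the grid point of minimum density strictly
    between them, leftmost point winning ties.
    """
    x = np.asarray(values, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 50:
        raise GateError(f"density_valley needs >=50 finite values, got {x.size}")
    if grid_points < 128:
        raise ConfigurationError("grid_points must be >=128")
    if np.ptp(x) == 0:
        raise NoValleyError(
            "all values identical; density is degenerate", mode_location=float(x[0])
        )
    try:
        kde = sps.gaussian_kde(x, bw_method=bandwidth_rule)
    except np.linalg.LinAlgError as exc:
        raise NoValleyError(f"degenerate density: {exc}", float(np.median(x))) from exc
    kde.set_bandwidth(kde.factor * bandwidth_multiplier)
    bandwidth = float(kde.factor * x.std(ddof=1))
    lo, hi = (float(x.min()), float(x.max())) if search_range is None else map(
        float, search_range
    )
    grid = np.linspace(lo, hi, grid_points)
    density = kde(grid)

    (peaks,) = argrelmax(density)
    # Grid endpoints can carry a mode whose maximum lies at the boundary.
    if density[0] > density[1]:
        peaks = np.concatenate(([0], peaks))
    if density[-1] > density[-2]:
        peaks = np.concatenate((peaks, [grid_points - 1]))
    if peaks.size < 2:
        mode = float(grid[int(np.argmax(density))])
        raise NoValleyError(
            f"no valley found: density is unimodal (mode at {mode:.6g})",
            mode_location=mode,
        )
    top2 = peaks[np.argsort(density[peaks])][-2:]
    left, right = int(top2.min()), int(top2.max())
    if right - left < 2:
        mode = float(grid[int(np.argmax(density))])
        raise NoValleyError(
            "no valley found: dominant modes are adjacent on the grid",
            mode_location=mode,
        )
    interior = slice(left + 1, right)
    valley_idx = left + 1 + int(np.argmin(density[interior]))  # argmin: leftmost tie
    return DensityValley(
        threshold=float(grid[valley_idx]),
        grid=grid,
        density=density,
        mode_locations=np.array([grid[left], grid[right]]),
        bandwidth=bandwidth,
    )


def _valley_threshold_or_fallback(
    values: np.ndarray,
    config: GateConfig,
    fallback_quantile: float | None,
    gate_name: str,
) -> tuple[float, str]:
    try:
        valley = density_valley(
            values,
            grid_points=config.grid_points,
            bandwidth_multiplier=config.bandwidth_multiplier,
        )
        return valley.threshold, "density_valley"
    except NoValleyError:
        if fallback_quantile is None:
            raise
        return float(np.quantile(values, fallback_quantile)), "quantile_fallback"


def debris_gate(table: EventTable, config: GateConfig = GateConfig()) -> GateResult:
    """Remove low-scatter debris: keep events above the scatter-area valley."""
    area = table.channel_values(table.channel_map.scatter_area("debris gate"))
    threshold, method = _valley_threshold_or_fallback(
        area, config, config.debris_fallback_quantile, "debris"
    )
    mask = area > threshold
    return GateResult.from_mask(
        mask, "debris", {"threshold": threshold, "method": method, "keep": "high"}
    )


def live_gate(table: EventTable, config: GateConfig = GateConfig()) -> GateResult:
    """Keep viability-dye-negative (live) events below the dye valley."""
    via = table.channel_values(table.channel_map.viability("live gate"))
    threshold, method = _valley_threshold_or_fallback(
        via, config, config.live_fallback_quantile, "live"
    )
    mask = via < threshold
    return GateResult.from_mask(
        mask, "live", {"threshold": threshold, "method": method, "keep": "low"}
    )


def clean(
    table: EventTable, config: GateConfig = GateConfig()
) -> tuple[EventTable, list[GateResult]]:
    """Apply singlet -> debris -> live gates, each on the previous survivors.

    Returns the cleaned table and the full audit trail. Gate order is fixed;
    individual gates can be disabled in the config. Any gate error aborts and
    propagates with the audit trail attached to the exception.
    """
    audit: list[GateResult] = []
    current = table
    stages = (
        ("singlet", config.singlet_enabled,
         lambda t: singlet_gate(t, config.band_factor, config.fit_intercept)),
        ("debris", config.debris_enabled, lambda t: debris_gate(t, config)),
        ("live", config.live_enabled, lambda t: live_gate(t, config)),
    )
    for name, enabled, fit in stages:
        if not enabled:
            continue
        try:
            result = fit(current)
        except GateError as exc:
            exc.audit = audit  # type: ignore[attr-defined]
            raise
        audit.append(result)
        current = current.subset(result.kept_mask)
    return current, audit


def composite_kept_mask(audit: list[GateResult], n_in: int) -> np.ndarray:
    """Mask over the *original* events kept by a staged gate chain.

    Each audit entry's mask is relative to the previous stage's survivors;
    this folds them back onto original event indices.
    """
    kept = np.ones(n_in, dtype=bool)
    for result in audit:
        idx = np.flatnonzero(kept)
        if idx.size != result.kept_mask.size:
            raise ValueError(
                f"gate {result.gate_name!r} saw {result.kept_mask.size} events, "
                f"expected {idx.size} survivors"
            )
        kept[idx[~result.kept_mask]] = False
    return kept
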