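"""Stage orchestration shared by the CLI: each stage reads files, computes,
and writes its outputs (CSV/JSON) so stages can be swapped or re-run alone.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import gating, phenotyping, report as report_mod, stats as stats_mod
from . import thresholds as thresholds_mod
from .config import RunConfig, write_table
from .errors import ConfigurationError
from .fcs_io import (
    ChannelMap,
    EventTable,
    apply_transform,
    read_event_csv,
    read_fcs,
    write_event_csv,
)

log = logging.getLogger("cytofeat")


def _read_events(path: Path, channel_map: ChannelMap) -> EventTable:
    if path.suffix.lower() == ".fcs":
        return read_fcs(path, channel_map)
    return read_event_csv(path, channel_map)


def _event_files(directory: Path) -> list[Path]:
    files = sorted(
        p
        for p in directory.iterdir()
        if p.suffix.lower() in (".fcs", ".csv") and p.is_file()
    )
    if not files:
        raise ConfigurationError(f"no .fcs/.csv event files under {directory}")
    return files


def load_samples(cfg: RunConfig, base: Path) -> dict[str, EventTable]:
    """Read and transform every sample file under paths.samples."""
    channel_map = cfg.channel_map()
    spec = cfg.transform_spec()
    tables = {}
    for path in _event_files(base / cfg.paths.samples):
        table = apply_transform(_read_events(path, channel_map), spec)
        tables[table.sample_id] = table
    return tables


def load_fmos(cfg: RunConfig, base: Path) -> dict[str, EventTable]:
    """FMO tables keyed by marker, from the explicit config map or, absent
    one, every ``FMO_<marker>`` file in paths.fmos."""
    if cfg.paths.fmos is None:
        return {}
    channel_map = cfg.channel_map()
    spec = cfg.transform_spec()
    fmo_dir = base / cfg.paths.fmos
    mapping = dict(cfg.thresholds.fmo)
    if not mapping:
        for path in _event_files(fmo_dir):
            stem = path.stem
            if stem.startswith("FMO_") and stem[4:] in channel_map.markers:
                mapping[stem[4:]] = path.name
    out = {}
    for marker, filename in mapping.items():
        if marker not in channel_map.markers:
            raise ConfigurationError(f"FMO declared for undeclared marker {marker!r}")
        out[marker] = apply_transform(
            _read_events(fmo_dir / filename, channel_map), spec
        )
    return out


def stage_clean(cfg: RunConfig, base: Path, outdir: Path) -> dict[str, EventTable]:
    tables = load_samples(cfg, base)
    gate_config = cfg.gate_config()
    cleaned_dir = outdir / "cleaned"
    cleaned_dir.mkdir(parents=True, exist_ok=True)
    audit_rows = []
    cleaned = {}
    for sample_id, table in tables.items():
        ct, audit = gating.clean(table, gate_config)
        cleaned[sample_id] = ct
        for g in audit:
            audit_rows.append(
                {
                    "sample_id": sample_id,
                    "gate": g.gate_name,
                    "n_in": g.n_in,
                    "n_kept": g.n_kept,
                    "parameters": json.dumps(g.parameters, sort_keys=True),
                }
            )
            log.info(
                "%s: %s gate kept %d/%d", sample_id, g.gate_name, g.n_kept, g.n_in
            )
        write_event_csv(ct, cleaned_dir / f"{sample_id}.csv")
    chash = cfg.config_hash()
    write_table(pd.DataFrame(audit_rows), outdir / "gate_audit.csv", chash)
    summary = pd.DataFrame(
        {
            "sample_id": list(cleaned),
            "n_raw": [tables[s].n_events for s in cleaned],
            "n_cleaned": [cleaned[s].n_events for s in cleaned],
        }
    )
    write_table(summary, outdir / "sample_summary.csv", chash)
    return cleaned


def load_cleaned(cfg: RunConfig, outdir: Path) -> dict[str, EventTable]:
    channel_map = cfg.channel_map()
    cleaned_dir = outdir / "cleaned"
    if not cleaned_dir.is_dir():
        raise ConfigurationError(
            f"no cleaned events under {cleaned_dir}; run the clean stage first"
        )
    return {
        p.stem: read_event_csv(p, channel_map) for p in _event_files(cleaned_dir)
    }


def stage_thresholds(cfg: RunConfig, base: Path, outdir: Path) -> thresholds_mod.ThresholdSet:
    channel_map = cfg.channel_map()
    fmo_tables = load_fmos(cfg, base)
    markers = channel_map.markers
    needs_samples = any(
        m not in fmo_tables and m not in cfg.thresholds.overrides for m in markers
    )
    sample_tables = list(load_samples(cfg, base).values()) if needs_samples else None
    tset = thresholds_mod.build_threshold_set(
        markers,
        fmo_tables=fmo_tables,
        sample_tables=sample_tables,
        overrides=cfg.thresholds.overrides,
        q=cfg.thresholds.quantile,
        clean_first=cfg.thresholds.clean_fmos,
        gate_config=cfg.gate_config(),
    )
    outdir.mkdir(parents=True, exist_ok=True)
    write_table(tset.to_frame(), outdir / "thresholds.csv", cfg.config_hash())
    for marker in markers:
        e = tset[marker]
        log.info("threshold %s = %.4g (%s)", marker, e.threshold, e.method)
    return tset


def stage_engineer(
    cfg: RunConfig,
    cleaned: dict[str, EventTable],
    tset: thresholds_mod.ThresholdSet,
    outdir: Path,
) -> phenotyping.PopulationTable:
    markers = cfg.channel_map().markers
    tset.require_complete(markers)
    binary = {s: phenotyping.binarize(t, tset) for s, t in cleaned.items()}
    table = phenotyping.enumerate_populations(binary, markers)
    write_table(table.to_frame(), outdir / "populations_all.csv", cfg.config_hash())
    log.info(
        "engineered %d phenotypes across %d samples",
        len(table.phenotypes), len(cleaned),
    )
    return table


def stage_filter(
    cfg: RunConfig, table: phenotyping.PopulationTable, outdir: Path
) -> phenotyping.PopulationTable:
    ruleset = cfg.ruleset()
    classified = phenotyping.classify(table, ruleset)
    filtered = phenotyping.filter_populations(
        classified,
        min_percent=cfg.filter.min_percent,
        min_count=cfg.filter.min_count,
        marker_constraints=cfg.filter.constraints,
        lineage_order=ruleset.lineage_order,
    )
    write_table(filtered.to_frame(), outdir / "populations.csv", cfg.config_hash())
    log.info("filter kept %d phenotypes", len(filtered.phenotypes))
    return filtered


def stage_stats(
    cfg: RunConfig,
    filtered: phenotyping.PopulationTable,
    base: Path,
    outdir: Path,
) -> list[stats_mod.AssociationResult]:
    chash = cfg.config_hash()
    corr = stats_mod.population_correlation(filtered, cfg.stats.correlation_method)
    with open(outdir / "correlation.csv", "w") as fh:
        fh.write(f"# config_hash={chash}\n# method={corr.method}\n")
        corr.matrix.to_csv(fh)
    results: list[stats_mod.AssociationResult] = []
    if cfg.paths.outcome:
        measure = stats_mod.ExternalMeasure.from_csv(base / cfg.paths.outcome)
        results = stats_mod.associate(filtered, measure)
        if cfg.stats.enable_fdr:
            results = stats_mod.attach_adjusted(results, cfg.stats.fdr_method)
        write_table(
            stats_mod.associations_frame(results), outdir / "associations.csv", chash
        )
        if cfg.paths.metadata:
            meta = pd.read_csv(base / cfg.paths.metadata, comment="#")
            meta["sample_id"] = meta["sample_id"].astype(str)
            groups = dict(zip(meta["sample_id"], meta["group"]))
            timepoints = dict(zip(meta["sample_id"], meta["timepoint"]))
            try:
                ttests = stats_mod.group_compare(
                    measure, groups, timepoints,
                    variant=cfg.stats.ttest_variant, alpha=cfg.stats.alpha,
                )
            except ConfigurationError as exc:
                log.warning("group comparison skipped: %s", exc)
            else:
                write_table(ttests, outdir / "group_ttests.csv", chash)
    return results


def stage_report(
    cfg: RunConfig,
    filtered: phenotyping.PopulationTable,
    results: list[stats_mod.AssociationResult],
    base: Path,
    outdir: Path,
    tset: thresholds_mod.ThresholdSet | None = None,
) -> None:
    report_dir = outdir / "report"
    report_dir.mkdir(parents=True, exist_ok=True)
    report_mod.phenotype_heatmap(filtered, report_dir)
    corr = stats_mod.population_correlation(filtered, cfg.stats.correlation_method)
    report_mod.correlation_heatmap(corr, report_dir)
    if cfg.paths.metadata:
        meta = pd.read_csv(base / cfg.paths.metadata, comment="#")
        meta["sample_id"] = meta["sample_id"].astype(str)
        report_mod.timeseries_grid(filtered, meta, report_dir)
    if results and cfg.paths.outcome:
        measure = stats_mod.ExternalMeasure.from_csv(base / cfg.paths.outcome)
        report_mod.association_grid(results, filtered, measure, report_dir)
    if tset is not None and cfg.paths.fmos:
        fmo_tables = load_fmos(cfg, base)
        report_mod.fmo_panels(tset, fmo_tables, report_dir)


def stage_validate(
    cfg: RunConfig, filtered: phenotyping.PopulationTable, base: Path, outdir: Path
) -> stats_mod.ValidationResult:
    if not cfg.paths.manual:
        raise ConfigurationError("paths.manual not set; nothing to validate against")
    manual = pd.read_csv(
        base / cfg.paths.manual, comment="#", dtype={"phenotype": str},
        float_precision="round_trip",
    )
    manual["phenotype"] = manual["phenotype"].str.zfill(len(filtered.marker_order))
    manual["sample_id"] = manual["sample_id"].astype(str)
    result = stats_mod.validate_against_manual(filtered, manual)
    frame = pd.DataFrame(
        [
            {
                "rho": result.rho,
                "rho_p": result.rho_p,
                "mean_abs_diff_percent": result.mean_abs_diff_percent,
                "n_pairs": result.n_pairs,
                "n_unmatched": len(result.unmatched),
                "unmatched": ";".join(result.unmatched),
            }
        ]
    )
    write_table(frame, outdir / "validation_report.csv", cfg.config_hash())
    return result


def run_all(cfg: RunConfig, base: Path, outdir: Path) -> dict:
    """Chain clean -> thresholds -> engineer -> filter -> stats -> report.

    Re-running on identical inputs and config reproduces identical tables.
    """
    outdir.mkdir(parents=True, exist_ok=True)
    cfg.dump_yaml(outdir / "run_config.yaml")
    cleaned = stage_clean(cfg, base, outdir)
    tset = stage_thresholds(cfg, base, outdir)
    table = stage_engineer(cfg, cleaned, tset, outdir)
    filtered = stage_filter(cfg, table, outdir)
    results = stage_stats(cfg, filtered, base, outdir)
    stage_report(cfg, filtered, results, base, outdir, tset)
    if cfg.paths.manual:
        stage_validate(cfg, filtered, base, outdir)
    return {
        "cleaned": cleaned,
        "thresholds": tset,
        "populations": table,
        "filtered": filtered,
        "associations": results,
    }
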