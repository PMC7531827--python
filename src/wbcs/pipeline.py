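"""End-to-end pipeline: classify 1–3 period grids, tabulate, compare, map.

Produces, under an output directory: per-period classified grids (CSV
and GeoJSON), one area table per bioclimatic unit, per-unit change and
stability outputs when two or more periods are given, the trend and
diversity summaries, optional PNG maps, and a run manifest recording
the ruleset version and input checksums.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import change as chg
from .classifier import apply_catalog, build_isobioclimate_catalog, classify_grid
from .grid import ClimateGrid, read_climate_grid, write_classified_grid
from .ruleset import ClassificationRuleset, default_ruleset, load_ruleset

log = logging.getLogger("wbcs")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    input_paths: list[str] = field(default_factory=list)
    period_labels: list[str] = field(default_factory=list)
    ruleset_path: str | None = None
    output_dir: str = "wbcs_out"
    dialect: str = "canonical"
    map_format: str = "geojson"       # "geojson", "png" or "geojson+png"
    rounding_decimals: int = 2
    log_level: str = "INFO"

    def __post_init__(self):
        if not self.period_labels:
            self.period_labels = [f"period_{i + 1}" for i in range(len(self.input_paths))]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _png_map(grid: ClimateGrid, labels: pd.DataFrame, column: str, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import colormaps

    classes = sorted(labels[column].unique())
    cmap = colormaps["tab20"]
    color_of = {c: cmap(i % 20) for i, c in enumerate(classes)}
    fig, ax = plt.subplots(figsize=(9, 4.5))
    for c in classes:
        sel = (labels[column] == c).to_numpy()
        ax.scatter(grid.lon[sel], grid.lat[sel], s=4, color=color_of[c], label=c)
    ax.set_xlabel("lon")
    ax.set_ylabel("lat")
    ax.set_title(f"{column} — {grid.period_label}")
    ax.legend(fontsize=5, ncol=2, markerscale=2, loc="center left", bbox_to_anchor=(1, 0.5))
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_pipeline(
    config: PipelineConfig,
    grids: list[ClimateGrid] | None = None,
    ruleset: ClassificationRuleset | None = None,
) -> dict:
    """Run classification and comparison; returns the in-memory bundle.

    ``grids`` may be passed directly (e.g. from the synthetic generator);
    otherwise they are read from ``config.input_paths``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    rs = ruleset or (load_ruleset(config.ruleset_path) if config.ruleset_path else default_ruleset())
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    checksums = {}
    if grids is None:
        if not config.input_paths:
            raise ValueError("no input paths and no grids given")
        grids = []
        for p, lab in zip(config.input_paths, config.period_labels):
            log.info("reading %s", p)
            grids.append(read_climate_grid(p, dialect=config.dialect, period_label=lab))
            checksums[str(p)] = _checksum(Path(p))
    labels_by_period = []
    for g, lab in zip(grids, config.period_labels):
        log.info("classifying %s (%d cells)", lab, len(g))
        labels_by_period.append(classify_grid(g, rs))

    catalog = build_isobioclimate_catalog(labels_by_period, rs)
    labels_by_period = [apply_catalog(l, catalog) for l in labels_by_period]

    bundle: dict = {
        "labels": labels_by_period,
        "catalog": catalog,
        "area_tables": {},
        "stability": {},
        "change_masks": {},
    }
    want_png = "png" in config.map_format
    want_geojson = "geojson" in config.map_format

    for g, lab, labels in zip(grids, config.period_labels, labels_by_period):
        write_classified_grid(g, labels, out / f"classified_{lab}.csv", "csv")
        if want_geojson:
            write_classified_grid(g, labels, out / f"classified_{lab}.geojson", "geojson")
        if want_png:
            _png_map(g, labels, "isobioclimate", out / f"map_isobioclimate_{lab}.png")

    for unit in chg.UNITS:
        tbl = chg.area_table(
            labels_by_period, unit, config.period_labels, config.rounding_decimals
        )
        tbl.to_csv(out / f"area_{unit}.csv")
        bundle["area_tables"][unit] = tbl

    if len(grids) >= 2:
        stab_rows = []
        for unit in chg.UNITS:
            stable, changed = chg.stability_fraction(labels_by_period, unit)
            stab_rows.append({"unit": unit, "stable_pct": round(stable, 1),
                              "change_pct": round(changed, 1)})
            mask = chg.change_mask(labels_by_period[0], labels_by_period[-1], unit)
            mask.to_csv(out / f"change_{unit}.csv", index=False)
            bundle["change_masks"][unit] = mask
            if want_geojson:
                write_classified_grid(grids[0], mask, out / f"change_{unit}.geojson", "geojson")
        stability = pd.DataFrame(stab_rows).set_index("unit")
        stability.to_csv(out / "stability.csv")
        bundle["stability"] = stability

        diversity = chg.diversity_summary(labels_by_period)
        diversity.to_csv(out / "diversity.csv")
        bundle["diversity"] = diversity

        groups = chg.standard_groupings(rs)
        trends = pd.concat(
            [
                chg.trend_summary(bundle["area_tables"]["thermotype"],
                                  {k: groups[k] for k in
                                   ("warm_thermotypes", "cold_thermotypes", "mountain_thermotypes")}),
                chg.trend_summary(bundle["area_tables"]["ombrotype"],
                                  {k: groups[k] for k in ("arid_ombrotypes", "mountain_ombrotypes")}),
                chg.trend_summary(bundle["area_tables"]["bioclimate"],
                                  {"continental_bioclimates": groups["continental_bioclimates"]}),
            ]
        )
        trends.to_csv(out / "trends.csv")
        bundle["trends"] = trends

    manifest = {
        "ruleset_version": rs.version,
        "n_periods": len(grids),
        "period_labels": list(config.period_labels),
        "n_cells": [len(g) for g in grids],
        "input_checksums": checksums,
        "n_isobioclimates": len(catalog),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["manifest"] = manifest
    pd.Series(catalog, name="key").rename_axis("isobioclimate").to_csv(out / "catalog.csv")
    return bundle
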