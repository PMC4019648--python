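"""Pipeline orchestration: the five-step range-finding protocol.

1. frame a biological question as a gene set (GMT input);
2. sample a wide dose x time grid without replication (expression +
   annotation input, or the synthetic generator);
3. estimate DEGs per design-space cell;
4. restrict the design space: drop non-specific cells and background
   drift genes;
5. locate the per-set sweet spots by competitive enrichment and screen
   the members by dose-response correlation.

Every stage reads and writes plain files under the output directory, so
partial pipelines are resumable and the subcommand composition
(filter -> degmap -> enrich -> correlate -> report) produces outputs
identical to :func:`run_pipeline`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import design_space as ds
from . import dose_response as dr
from . import preprocess as pp
from . import sweetspot as sw
from .core import (
    DesignGrid,
    GeneSetCollection,
    InputError,
    intersect_with_data,
    read_design_grid,
    read_gmt,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All pipeline knobs; every threshold is echoed into summary.json."""

    expression: str
    annotation: str
    outdir: str
    gene_sets: str | None = None
    deg_cutoff: float = ds.DEFAULT_DEG_CUTOFF
    background_cutoff: float = ds.DEFAULT_DEG_CUTOFF
    restriction_threshold: float = ds.DEFAULT_RESTRICTION_THRESHOLD
    restriction_baseline: str = pp.GLOBAL_T0
    correlation_threshold: float = dr.DEFAULT_CORRELATION_THRESHOLD
    min_points: int = dr.DEFAULT_MIN_POINTS
    per_subject_baseline: bool = True
    enrichment: sw.EnrichmentConfig = field(default_factory=sw.EnrichmentConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        enr = raw.pop("enrichment", {})
        if isinstance(enr, dict):
            enr = sw.EnrichmentConfig(**enr)
        return cls(enrichment=enr, **raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    # -- derived paths ----------------------------------------------------

    @property
    def out(self) -> Path:
        return Path(self.outdir)

    @property
    def corrected_expression_path(self) -> Path:
        return self.out / "corrected_expression.tsv"

    @property
    def background_path(self) -> Path:
        return self.out / "background_filter.tsv"

    @property
    def restriction_path(self) -> Path:
        return self.out / "restriction.tsv"

    @property
    def enrichment_path(self) -> Path:
        return self.out / "enrichment.tsv"


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _record_stage(config: RunConfig, name: str, result: dict) -> dict:
    """Persist a stage result so `report` sees it regardless of how stages ran."""
    path = config.out / "stages.json"
    stages = {}
    if path.exists():
        with open(path) as fh:
            stages = json.load(fh)
    stages[name] = _jsonable(result)
    with open(path, "w") as fh:
        json.dump(stages, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return result


# -- shared loading helpers ------------------------------------------------


def _load_grid(config: RunConfig, corrected: bool) -> DesignGrid:
    expr = config.corrected_expression_path if corrected else config.expression
    return read_design_grid(expr, config.annotation)


def _load_kept_genes(config: RunConfig) -> list[str]:
    df = pd.read_csv(config.background_path, sep="\t")
    return df.loc[~df["removed"], "gene_id"].astype(str).tolist()


def _load_restriction(config: RunConfig) -> ds.RestrictionMask:
    df = pd.read_csv(config.restriction_path, sep="\t")
    cells = {(float(r.dose), float(r.time)): r.call for r in df.itertuples()}
    return ds.RestrictionMask(cells=cells, threshold=float("nan"))


# -- stages ----------------------------------------------------------------


def stage_filter(config: RunConfig) -> dict:
    """Subject-effect correction + background (drift) gene filter."""
    config.out.mkdir(parents=True, exist_ok=True)
    grid = _load_grid(config, corrected=False)
    n_subjects = len(grid.subjects)
    if n_subjects >= 2:
        grid = pp.correct_subject_effects(grid)
        logger.info("corrected additive offsets for %d subjects", n_subjects)
    grid.values.to_csv(config.corrected_expression_path, sep="\t", index_label="gene_id")
    untreated = pp.compute_ratio_grid(
        grid, pp.UNTREATED_VS_T0, per_subject=config.per_subject_baseline
    )
    result = ds.filter_background_genes(untreated, cutoff=config.background_cutoff)
    out = pd.DataFrame(
        {
            "gene_id": grid.genes,
            "removed": [g in result.removed_genes for g in grid.genes],
        }
    )
    out.to_csv(config.background_path, sep="\t", index=False)
    return _record_stage(config, "filter", {
        "n_genes": grid.n_genes,
        "n_subjects": n_subjects,
        "background_removed": result.n_removed,
        "background_kept": len(result.kept_genes),
        "background_criterion": result.criterion,
    })


def stage_degmap(config: RunConfig) -> dict:
    """DEG maps (vs t=0 and time-matched) and the non-specific restriction mask."""
    grid = _load_grid(config, corrected=True)
    kept = _load_kept_genes(config)
    maps = {}
    t0 = pp.compute_ratio_grid(grid, pp.GLOBAL_T0, per_subject=config.per_subject_baseline)
    maps["degmap_t0"] = ds.count_degs(t0, cutoff=config.deg_cutoff)
    filtered = grid.subset_genes(kept)
    t0f = pp.compute_ratio_grid(filtered, pp.GLOBAL_T0, per_subject=config.per_subject_baseline)
    maps["degmap_t0_filtered"] = ds.count_degs(t0f, cutoff=config.deg_cutoff)
    tm = pp.compute_ratio_grid(filtered, pp.TIME_MATCHED_DOSE0, per_subject=config.per_subject_baseline)
    maps["degmap_time_matched"] = ds.count_degs(tm, cutoff=config.deg_cutoff)
    for name, degmap in maps.items():
        degmap.to_tidy().to_csv(config.out / f"{name}.tsv", sep="\t", index=False)
        degmap.to_matrix().to_csv(config.out / f"{name}_matrix.tsv", sep="\t")
    restrict_on = (
        maps["degmap_t0"] if config.restriction_baseline == pp.GLOBAL_T0
        else maps["degmap_time_matched"]
    )
    mask = ds.restrict_design_space(restrict_on, threshold=config.restriction_threshold)
    mask.to_tidy().to_csv(config.restriction_path, sep="\t", index=False)
    return _record_stage(config, "degmap", {
        "max_deg_t0": max(maps["degmap_t0"].cells.values()),
        "max_deg_time_matched": max(maps["degmap_time_matched"].cells.values()),
        "restriction_threshold_resolved": mask.threshold,
        "usable_cells": len(mask.usable_cells()),
        "total_cells": len(mask.cells),
        "usable_fraction": mask.usable_fraction,
    })


def _filtered_time_matched(config: RunConfig) -> pp.RatioGrid:
    grid = _load_grid(config, corrected=True)
    filtered = grid.subset_genes(_load_kept_genes(config))
    return pp.compute_ratio_grid(
        filtered, pp.TIME_MATCHED_DOSE0, per_subject=config.per_subject_baseline
    )


def _intersected_sets(config: RunConfig, genes: list[str]) -> tuple[GeneSetCollection, list[str]]:
    sets = read_gmt(config.gene_sets)
    grid_like = type("G", (), {"genes": genes})  # intersect against the filtered gene list
    kept, skipped = [], []
    for s in sets:
        try:
            kept.append(intersect_with_data(s, grid_like))
        except InputError as exc:
            logger.error("%s", exc)
            skipped.append(s.name)
    return GeneSetCollection(kept), skipped


def stage_enrich(config: RunConfig) -> dict:
    """Competitive enrichment over the usable cells, per gene set."""
    if not config.gene_sets:
        logger.warning("no gene sets configured: skipping enrichment")
        return _record_stage(config, "enrich", {"skipped": "no gene sets"})
    ratios = _filtered_time_matched(config)
    mask = _load_restriction(config)
    sets, skipped = _intersected_sets(config, ratios.genes)
    diagrams = sw.enrich_design_space(ratios, mask, sets, config.enrichment)
    if diagrams:
        tidy = pd.concat([d.to_tidy() for d in diagrams], ignore_index=True)
    else:
        tidy = pd.DataFrame(
            columns=["set", "dose", "time", "p_raw", "p_adj", "color_value", "sweet"]
        )
    tidy.to_csv(config.enrichment_path, sep="\t", index=False)
    return _record_stage(config, "enrich", {
        "n_sets_tested": len(diagrams),
        "sets_skipped": skipped,
        "per_set": {
            d.set_name: {
                "pmin": d.pmin,
                "argmin_cell": list(d.argmin_cell()),
                "sweet_cells": [list(c) for c in d.sweet_cells()],
            }
            for d in diagrams
        },
    })


def _diagrams_from_tidy(path: Path) -> dict[str, sw.EnrichmentDiagram]:
    tidy = pd.read_csv(path, sep="\t")
    out = {}
    for name, g in tidy.groupby("set", sort=True):
        cells = [(float(r.dose), float(r.time)) for r in g.itertuples()]
        out[name] = sw.EnrichmentDiagram(
            set_name=name,
            p_raw=dict(zip(cells, g["p_raw"])),
            p_adj=dict(zip(cells, g["p_adj"])),
            pmax=float("nan"),
            color_value=dict(zip(cells, g["color_value"])),
            sweet_mask=dict(zip(cells, g["sweet"].astype(bool))),
        )
    return out


def stage_correlate(config: RunConfig) -> dict:
    """Per-set, per-gene dose-response correlation tables."""
    if not config.gene_sets:
        logger.warning("no gene sets configured: skipping correlation screen")
        return _record_stage(config, "correlate", {"skipped": "no gene sets"})
    ratios = _filtered_time_matched(config)
    sets, _ = _intersected_sets(config, ratios.genes)
    diagrams = (
        _diagrams_from_tidy(config.enrichment_path)
        if config.enrichment_path.exists()
        else {}
    )
    corr_dir = config.out / "correlations"
    corr_dir.mkdir(parents=True, exist_ok=True)
    rows_per_set = {}
    for s in sets:
        try:
            table = dr.dose_response_correlations(
                ratios,
                s,
                min_points=config.min_points,
                threshold=config.correlation_threshold,
            )
        except ValueError as exc:
            logger.error("correlation screen for %s failed: %s", s.name, exc)
            continue
        table = dr.assemble_table(table, diagrams.get(s.name))
        dr.write_correlation_table(table, corr_dir / f"{s.name}.tsv")
        # full matrix in tidy form alongside the display table
        tidy = table.corr.reset_index().melt(
            id_vars="gene", var_name="time", value_name="r"
        )
        tidy.to_csv(corr_dir / f"{s.name}_full.tsv", sep="\t", index=False)
        rows_per_set[s.name] = int(len(table.row_order))
    return _record_stage(config, "correlate", {"table_rows": rows_per_set})


def stage_report(config: RunConfig, stage_results: dict | None = None) -> dict:
    """Machine-readable summary.json + human-readable report.txt."""
    if stage_results is None:
        path = config.out / "stages.json"
        stage_results = json.loads(path.read_text()) if path.exists() else {}
    summary = {
        "config": _jsonable(config.to_dict()),
        "stages": _jsonable(stage_results or {}),
    }
    with open(config.out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    lines = ["range-finding pipeline report", "=" * 29, ""]
    stages = summary["stages"]
    if "filter" in stages:
        f = stages["filter"]
        lines.append(
            f"background filter: removed {f['background_removed']} of "
            f"{f['n_genes']} genes ({f['background_criterion']})"
        )
    if "degmap" in stages:
        d = stages["degmap"]
        lines.append(
            f"design space: {d['usable_cells']}/{d['total_cells']} cells usable "
            f"(threshold {d['restriction_threshold_resolved']:g} DEGs; "
            f"max vs t0 {d['max_deg_t0']})"
        )
    if "enrich" in stages and "per_set" in stages["enrich"]:
        for name, info in sorted(stages["enrich"]["per_set"].items()):
            cells = ", ".join(
                f"({d:g} J/m^2, {t/60:g} h)" for d, t in info["sweet_cells"]
            ) or "none"
            lines.append(
                f"set {name}: lowest adjusted p = {info['pmin']:.3g}; sweet spot(s): {cells}"
            )
    if "correlate" in stages and "table_rows" in stages["correlate"]:
        for name, n in sorted(stages["correlate"]["table_rows"].items()):
            lines.append(f"set {name}: {n} genes with |r| > "
                         f"{config.correlation_threshold:g} at some time")
    (config.out / "report.txt").write_text("\n".join(lines) + "\n")
    return summary


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (bool, int, str)) or obj is None:
        return obj
    if isinstance(obj, float):
        return obj
    if hasattr(obj, "item"):
        return obj.item()
    return str(obj)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full protocol; returns the summary dict written to disk."""
    results: dict = {}
    for name, stage in (
        ("filter", stage_filter),
        ("degmap", stage_degmap),
        ("enrich", stage_enrich),
        ("correlate", stage_correlate),
    ):
        try:
            results[name] = stage(config)
        except (InputError, FileNotFoundError):
            raise
        except Exception as exc:
            raise StageError(f"stage {name} failed: {exc}") from exc
    return stage_report(config, results)
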