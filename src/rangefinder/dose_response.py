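"""Per-time-point Pearson dose-response screening of gene-set members.

When a gene set lights up in several design-space regions, the per-gene
dose-response relation disambiguates: per recovery time, each set gene's
log2 ratios are correlated with the dose values across the available
doses.  |r| > 0.8 marks a strong exposure-expression relation; genes with
no relevant correlation at any time are dropped from the presentation
table, and time columns containing a sweet spot at any dose are flagged —
this reproduces the look of the protocol's per-set gene tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .core import GeneSet
from .preprocess import RatioGrid, TIME_MATCHED_DOSE0
from .sweetspot import EnrichmentDiagram

logger = logging.getLogger(__name__)

DEFAULT_CORRELATION_THRESHOLD = 0.8
DEFAULT_MIN_POINTS = 4


@dataclass
class CorrelationTable:
    """Gene x time Pearson dose-response correlations for one gene set.

    ``corr`` holds r per gene per time (NaN where fewer than ``min_points``
    doses were available or the ratios were constant); ``relevant`` marks
    |r| strictly above the threshold; ``sweet_times`` are the times whose
    diagram column contains a sweet spot at any dose.
    """

    set_name: str
    corr: pd.DataFrame  # genes x times, values r or NaN
    threshold: float = DEFAULT_CORRELATION_THRESHOLD
    sweet_times: frozenset[float] = field(default_factory=frozenset)
    row_order: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = self.corr.to_numpy(dtype=float)
        finite = vals[np.isfinite(vals)]
        if finite.size and (finite.min() < -1 - 1e-9 or finite.max() > 1 + 1e-9):
            raise ValueError("Pearson r outside [-1, 1]")
        if not self.row_order:
            self.row_order = list(self.corr.index)

    @property
    def relevant(self) -> pd.DataFrame:
        with np.errstate(invalid="ignore"):
            return self.corr.abs() > self.threshold

    @property
    def times(self) -> list[float]:
        return list(self.corr.columns)

    def to_display(self) -> pd.DataFrame:
        """Table-style view: relevant r values only, times in hours, ordered rows."""
        disp = self.corr.loc[self.row_order].where(self.relevant.loc[self.row_order])
        disp = disp.round(2)
        disp.columns = [_format_hours(t, t in self.sweet_times) for t in disp.columns]
        disp.index.name = "gene"
        return disp


def _format_hours(minutes: float, sweet: bool) -> str:
    hours = minutes / 60.0
    label = f"{hours:.4g} h" if hours >= 1 else f"{minutes:g} min"
    return label + " *" if sweet else label


def _rowwise_pearson(x: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Pearson r between a dose vector ``x`` and each row of ``Y``."""
    xc = x - x.mean()
    Yc = Y - Y.mean(axis=1, keepdims=True)
    denom = np.sqrt((xc**2).sum()) * np.sqrt((Yc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Yc @ xc) / denom
    r[~np.isfinite(r)] = np.nan
    return np.clip(r, -1.0, 1.0)


def dose_response_correlations(
    ratios: RatioGrid,
    gene_set: GeneSet,
    min_points: int = DEFAULT_MIN_POINTS,
    include_zero_dose: bool = True,
    threshold: float = DEFAULT_CORRELATION_THRESHOLD,
) -> CorrelationTable:
    """Correlate dose with log2 ratio per set gene per recovery time.

    Doses are used on their natural scale.  Dose 0 participates as an
    anchor with log2 ratio identically 0 (ratios are defined against the
    dose-0 sample itself); disable with ``include_zero_dose=False``.
    Times with fewer than ``min_points`` doses (anchor included) are left
    absent.  Genes absent from the (filtered) ratio grid are omitted.
    """
    if ratios.baseline_kind != TIME_MATCHED_DOSE0:
        raise ValueError("dose-response screening requires time_matched_dose0 ratios")
    if min_points < 3:
        raise ValueError("min_points must be >= 3")
    genes = [g for g in ratios.genes if g in gene_set.genes]
    if not genes:
        raise ValueError(f"gene set {gene_set.name!r} has no genes in the ratio grid")
    sub = ratios.subset_genes(genes)
    frame = sub.to_frame()
    times = sorted({t for _, t in sub.cells})
    corr = pd.DataFrame(np.nan, index=genes, columns=times, dtype=float)
    for t in times:
        doses = sorted({d for d, tt in sub.cells if tt == t})
        Y = np.column_stack([frame[(d, t)].to_numpy() for d in doses])
        x = np.array(doses, dtype=float)
        if include_zero_dose:
            x = np.concatenate([[0.0], x])
            Y = np.column_stack([np.zeros(len(genes)), Y])
        if x.size < min_points:
            continue
        corr[t] = _rowwise_pearson(x, Y)
    corr.columns.name = "time"
    corr.index.name = "gene"
    return CorrelationTable(set_name=gene_set.name, corr=corr, threshold=threshold)


def assemble_table(
    table: CorrelationTable, diagram: EnrichmentDiagram | None
) -> CorrelationTable:
    """Drop irrelevant genes, flag sweet-spot time columns, order rows.

    Genes with no |r| above the threshold at any time are removed.  Rows
    are ordered by earliest relevant time, then by descending |r| at that
    time (a presentation convention, not semantics).
    """
    if diagram is not None and diagram.set_name != table.set_name:
        raise ValueError(
            f"diagram is for set {diagram.set_name!r}, table for {table.set_name!r}"
        )
    rel = table.relevant
    keep = rel.any(axis=1)
    corr = table.corr.loc[keep[keep].index]
    rel = rel.loc[corr.index]
    sweet_times: frozenset[float] = frozenset()
    if diagram is not None:
        sweet_times = frozenset(t for (_, t) in diagram.sweet_cells())
    times = list(corr.columns)

    def sort_key(gene: str) -> tuple:
        row = rel.loc[gene]
        first = next(t for t in times if row[t])
        return (times.index(first), -abs(corr.loc[gene, first]), gene)

    order = sorted(corr.index, key=sort_key)
    return replace(
        table,
        corr=corr.loc[order],
        sweet_times=sweet_times,
        row_order=order,
    )


def write_correlation_table(table: CorrelationTable, path: str | Path) -> None:
    """Write the display table (relevant cells only, hours, '*' on sweet columns)."""
    disp = table.to_display()
    with open(path, "w") as fh:
        fh.write(f"# gene set: {table.set_name}\n")
        fh.write(
            f"# relevance: |Pearson r| > {table.threshold}; "
            "'*' marks time columns containing a sweet spot at any dose\n"
        )
        disp.to_csv(fh, sep="\t", na_rep="")
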