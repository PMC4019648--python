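"""DEG counting, non-specific-response restriction, and drift-gene removal.

Without replication there is no per-gene test; a gene is called
differentially expressed (DEG) in a cell when its |log2 ratio| exceeds a
fixed cutoff (default 1, i.e. two-fold).  Cells where a large fraction of
the transcriptome moves (default 2,000 genes, ~10% of a mouse array) are
flagged as non-specific stress responses and excluded from the search for
pathway-specific signal.  Genes that drift in untreated (dose-0) samples —
growth, circadian and other baseline processes — are removed altogether so
treatment responses are not confounded.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .preprocess import Cell, RatioGrid, UNTREATED_VS_T0

logger = logging.getLogger(__name__)

USABLE = "usable"
NONSPECIFIC = "nonspecific"

DEFAULT_DEG_CUTOFF = 1.0
DEFAULT_RESTRICTION_THRESHOLD = 2000.0


@dataclass
class DegMap:
    """Per design-space cell, the number of genes with |log2 FC| > cutoff."""

    cells: dict[Cell, int]
    cutoff: float
    baseline_kind: str
    n_genes: int

    def to_matrix(self) -> pd.DataFrame:
        """Doses x times matrix (NaN for missing cells)."""
        doses = sorted({d for d, _ in self.cells})
        times = sorted({t for _, t in self.cells})
        mat = pd.DataFrame(np.nan, index=doses, columns=times)
        for (d, t), n in self.cells.items():
            mat.loc[d, t] = n
        mat.index.name = "dose"
        mat.columns.name = "time"
        return mat

    def to_tidy(self) -> pd.DataFrame:
        rows = [
            {"dose": d, "time": t, "deg_count": n}
            for (d, t), n in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows, columns=["dose", "time", "deg_count"])


@dataclass
class RestrictionMask:
    """usable / nonspecific call per cell; nonspecific iff count >= threshold."""

    cells: dict[Cell, str]
    threshold: float

    def usable_cells(self) -> list[Cell]:
        return sorted(c for c, v in self.cells.items() if v == USABLE)

    def is_usable(self, cell: Cell) -> bool:
        return self.cells.get(cell) == USABLE

    @property
    def usable_fraction(self) -> float:
        if not self.cells:
            return float("nan")
        return len(self.usable_cells()) / len(self.cells)

    def to_tidy(self) -> pd.DataFrame:
        rows = [
            {"dose": d, "time": t, "call": v}
            for (d, t), v in sorted(self.cells.items())
        ]
        return pd.DataFrame(rows, columns=["dose", "time", "call"])


@dataclass
class BackgroundFilterResult:
    """Outcome of the baseline-drift gene filter.

    A gene is removed when its |log2 ratio| exceeds the cutoff in at least
    one untreated (dose 0, time > 0) cell versus t=0.
    """

    removed_genes: set[str]
    kept_genes: list[str]
    cutoff: float
    criterion: str = field(default="")

    def __post_init__(self) -> None:
        if not self.criterion:
            self.criterion = (
                f"|log2 FC| > {self.cutoff} in any untreated (dose=0, time>0) "
                "cell vs t=0"
            )
        overlap = self.removed_genes & set(self.kept_genes)
        if overlap:
            raise ValueError(f"genes both removed and kept: {sorted(overlap)[:5]}")

    @property
    def n_removed(self) -> int:
        return len(self.removed_genes)


def count_degs(ratios: RatioGrid, cutoff: float = DEFAULT_DEG_CUTOFF) -> DegMap:
    """Count genes with |log2 ratio| strictly greater than ``cutoff`` per cell."""
    if cutoff <= 0:
        raise ValueError("DEG cutoff must be positive")
    cells = {
        cell: int(np.sum(np.abs(vec) > cutoff)) for cell, vec in ratios.cells.items()
    }
    return DegMap(
        cells=cells,
        cutoff=cutoff,
        baseline_kind=ratios.baseline_kind,
        n_genes=len(ratios.genes),
    )


def restrict_design_space(
    degmap: DegMap, threshold: float = DEFAULT_RESTRICTION_THRESHOLD
) -> RestrictionMask:
    """Flag non-specific cells: DEG count >= threshold.

    A ``threshold`` < 1 is read as a fraction of the gene total and
    resolved against the DEG map's gene count (0.10 of 24,302 genes gives
    2,430).
    """
    if threshold <= 0:
        raise ValueError("restriction threshold must be positive")
    resolved = threshold
    if threshold < 1:
        resolved = int(threshold * degmap.n_genes)
    cells = {
        cell: (NONSPECIFIC if n >= resolved else USABLE)
        for cell, n in degmap.cells.items()
    }
    mask = RestrictionMask(cells=cells, threshold=float(resolved))
    logger.info(
        "design-space restriction: %d/%d cells usable (threshold %s DEGs)",
        len(mask.usable_cells()), len(cells), resolved,
    )
    return mask


def filter_background_genes(
    ratios_untreated: RatioGrid, cutoff: float = DEFAULT_DEG_CUTOFF
) -> BackgroundFilterResult:
    """Identify genes drifting in untreated samples (growth/circadian background).

    ``ratios_untreated`` must be an ``untreated_vs_t0`` ratio grid; a gene
    is removed iff |log2 ratio| > cutoff in at least one untreated cell.
    """
    if ratios_untreated.baseline_kind != UNTREATED_VS_T0:
        raise ValueError(
            "background filter requires an untreated_vs_t0 ratio grid, got "
            f"{ratios_untreated.baseline_kind!r}"
        )
    if not ratios_untreated.cells:
        raise ValueError("no untreated cells: background filter undefined")
    mat = ratios_untreated.to_frame().to_numpy()
    hit = np.any(np.abs(mat) > cutoff, axis=1)
    genes = ratios_untreated.genes
    removed = {g for g, h in zip(genes, hit) if h}
    kept = [g for g, h in zip(genes, hit) if not h]
    logger.info(
        "background filter: removed %d of %d genes (%s)",
        len(removed), len(genes), f"cutoff {cutoff}",
    )
    return BackgroundFilterResult(removed_genes=removed, kept_genes=kept, cutoff=cutoff)
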