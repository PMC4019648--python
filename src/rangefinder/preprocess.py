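"""Subject-effect correction, baseline ratio grids, and RNA-yield QC.

Ratio grids are the workhorse of the protocol: every design-space cell is
reduced to a per-gene log2 fold change against a declared baseline.  Three
baselines are supported:

``global_t0``
    the pre-exposure / time-zero control (per subject when subjects exist,
    pooled otherwise) — used for the DEG restriction map;
``time_matched_dose0``
    the dose-0 sample at the same recovery time — used for enrichment and
    dose-response screening so that fold changes reflect dose response
    rather than time drift;
``untreated_vs_t0``
    dose-0 samples over time against t=0 — the input of the background
    (drift) gene filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

from .core import DesignGrid, SampleAnnotation

logger = logging.getLogger(__name__)

GLOBAL_T0 = "global_t0"
TIME_MATCHED_DOSE0 = "time_matched_dose0"
UNTREATED_VS_T0 = "untreated_vs_t0"
BASELINE_KINDS = (GLOBAL_T0, TIME_MATCHED_DOSE0, UNTREATED_VS_T0)

Cell = tuple[float, float]


@dataclass
class RatioGrid:
    """Per design-space cell, a per-gene log2 fold-change vector.

    A cell exists only if both its sample(s) and its baseline sample(s)
    exist and are ok; cells without a baseline are omitted with a warning.
    """

    genes: list[str]
    baseline_kind: str
    cells: dict[Cell, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.baseline_kind not in BASELINE_KINDS:
            raise ValueError(f"unknown baseline kind {self.baseline_kind!r}")
        for cell, vec in self.cells.items():
            if len(vec) != len(self.genes):
                raise ValueError(f"ratio vector length mismatch at cell {cell}")
            if not np.all(np.isfinite(vec)):
                raise ValueError(f"non-finite ratios at cell {cell}")

    @property
    def cell_keys(self) -> list[Cell]:
        return sorted(self.cells)

    @property
    def doses(self) -> list[float]:
        return sorted({d for d, _ in self.cells})

    @property
    def times(self) -> list[float]:
        return sorted({t for _, t in self.cells})

    def to_frame(self) -> pd.DataFrame:
        """Genes x cells DataFrame with a (dose, time) column MultiIndex."""
        cols = pd.MultiIndex.from_tuples(self.cell_keys, names=["dose", "time"])
        data = np.column_stack([self.cells[c] for c in self.cell_keys]) if self.cells else np.empty((len(self.genes), 0))
        return pd.DataFrame(data, index=self.genes, columns=cols)

    def subset_genes(self, genes: Iterable[str]) -> "RatioGrid":
        keep = set(genes)
        idx = [i for i, g in enumerate(self.genes) if g in keep]
        return RatioGrid(
            genes=[self.genes[i] for i in idx],
            baseline_kind=self.baseline_kind,
            cells={c: v[idx] for c, v in self.cells.items()},
        )


# -- subject-effect correction -------------------------------------------


def correct_subject_effects(grid: DesignGrid) -> DesignGrid:
    """Remove additive per-subject offsets from a multi-subject grid.

    Per gene, an intercept + subject-offset model (offsets constrained to
    sum to zero across subjects) is fitted by least squares over the ok
    samples; returned values are observed minus fitted offset, re-centred
    so the per-gene grand mean is preserved.  With a single-replicate
    design there is no information to estimate variance components, so this
    fixed-effect point correction stands in for a mixed model; in the
    balanced case the two coincide.

    With zero or one subject the grid is returned unchanged (no offsets
    are estimable; they are defined as zero).
    """
    subjects = grid.subjects
    if len(subjects) < 2:
        return grid
    ok = grid.ok_samples
    by_subject: dict[str, list[str]] = {}
    for s in ok:
        if s.subject_id:
            by_subject.setdefault(s.subject_id, []).append(s.sample_id)
    for subj, ids in by_subject.items():
        if len(ids) < 2:
            logger.warning(
                "subject %s has a single sample: its offset is confounded "
                "with that sample's condition", subj,
            )
    values = grid.values.copy()
    ok_ids = [s.sample_id for s in ok]
    X = values[ok_ids].to_numpy()
    # subject means per gene
    n_total = 0
    weighted = np.zeros(X.shape[0])
    offsets: dict[str, np.ndarray] = {}
    means = {subj: values[ids].to_numpy().mean(axis=1) for subj, ids in by_subject.items()}
    centre = np.mean(list(means.values()), axis=0)  # mean of subject means
    for subj, m in means.items():
        offsets[subj] = m - centre
        n_s = len(by_subject[subj])
        weighted += n_s * offsets[subj]
        n_total += n_s
    # re-centre so the per-gene grand mean over ok samples is unchanged
    recentre = weighted / n_total
    for s in ok:
        if s.subject_id in offsets:
            values[s.sample_id] = (
                values[s.sample_id].to_numpy() - offsets[s.subject_id] + recentre
            )
    return grid.with_values(values)


# -- ratio grids ----------------------------------------------------------


def _t0_baseline(
    grid: DesignGrid, per_subject: bool
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Per-subject (when available) and pooled t=0 baselines."""
    t0 = [s for s in grid.ok_samples if s.dose == 0 and s.time == 0]
    if not t0:
        raise ValueError("no ok sample with dose=0 and time=0: t0 baseline undefined")
    pooled = grid.ok_values[[s.sample_id for s in t0]].to_numpy().mean(axis=1)
    per: dict[str, np.ndarray] = {}
    if per_subject:
        by_subject: dict[str, list[str]] = {}
        for s in t0:
            if s.subject_id:
                by_subject.setdefault(s.subject_id, []).append(s.sample_id)
        for subj, ids in by_subject.items():
            per[subj] = grid.ok_values[ids].to_numpy().mean(axis=1)
    return per, pooled


def _baseline_for(sample: SampleAnnotation, per: dict[str, np.ndarray], pooled: np.ndarray) -> np.ndarray:
    if sample.subject_id and sample.subject_id in per:
        return per[sample.subject_id]
    return pooled


def compute_ratio_grid(
    grid: DesignGrid,
    baseline_kind: str,
    per_subject: bool = True,
) -> RatioGrid:
    """Reduce a design grid to per-cell log2 ratios against a baseline.

    When several samples qualify for a baseline (or occupy a cell), their
    per-gene mean log2 value is used (geometric mean on the raw scale).
    ``per_subject`` selects each subject's own pre-exposure t=0 sample as
    its baseline where one exists; otherwise the pooled t=0 mean is used.
    """
    if baseline_kind not in BASELINE_KINDS:
        raise ValueError(f"unknown baseline kind {baseline_kind!r}")
    ok = grid.ok_samples
    values = grid.ok_values
    cells: dict[Cell, list[np.ndarray]] = {}

    if baseline_kind in (GLOBAL_T0, UNTREATED_VS_T0):
        per, pooled = _t0_baseline(grid, per_subject)
        for s in ok:
            if s.dose == 0 and s.time == 0:
                continue
            if baseline_kind == UNTREATED_VS_T0 and s.dose != 0:
                continue
            ratio = values[s.sample_id].to_numpy() - _baseline_for(s, per, pooled)
            cells.setdefault(s.cell, []).append(ratio)
    else:  # TIME_MATCHED_DOSE0
        dose0_at: dict[float, list[str]] = {}
        for s in ok:
            if s.dose == 0 and s.time > 0:
                dose0_at.setdefault(s.time, []).append(s.sample_id)
        for s in ok:
            if s.dose == 0:
                continue
            base_ids = dose0_at.get(s.time)
            if not base_ids:
                logger.warning(
                    "cell (dose=%s, time=%s) has no dose-0 sample at its time; omitted",
                    s.dose, s.time,
                )
                continue
            base = values[base_ids].to_numpy().mean(axis=1)
            cells.setdefault(s.cell, []).append(values[s.sample_id].to_numpy() - base)

    merged = {c: np.mean(vs, axis=0) if len(vs) > 1 else vs[0] for c, vs in cells.items()}
    return RatioGrid(genes=grid.genes, baseline_kind=baseline_kind, cells=merged)


# -- RNA-yield QC ---------------------------------------------------------


def read_yield_table(path) -> pd.DataFrame:
    """TSV with columns sample_id, dose, time_min, total_rna_ng, arna_ug."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    required = {"sample_id", "dose", "time_min", "total_rna_ng", "arna_ug"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"yield table lacks column(s) {sorted(missing)}")
    return df


def summarize_yields(yields: pd.DataFrame, fold_threshold: float = 2.0) -> pd.DataFrame:
    """Relative RNA yields against the t=0 sample plus an rRNA/mRNA drift flag.

    ``total_rna_ng`` is total RNA per sample; ``arna_ug`` is the
    post-amplification aRNA yield from equal RNA input, used as an mRNA
    proxy.  Both are expressed relative to the t=0 reference.  A sample is
    flagged when its total-RNA and mRNA-proxy trajectories diverge by more
    than ``fold_threshold``-fold, signalling a changed rRNA/mRNA ratio that
    would hamper downstream analysis.
    """
    t0 = yields[(yields["time_min"] == 0) & (yields["dose"] == 0)]
    if t0.empty:
        t0 = yields[yields["time_min"] == 0]
    if t0.empty:
        raise ValueError("yield table has no t=0 reference row")
    ref = t0.iloc[0]
    out = yields.copy()
    out["relative_total_rna"] = out["total_rna_ng"] / float(ref["total_rna_ng"])
    out["relative_mrna"] = out["arna_ug"] / float(ref["arna_ug"])
    ratio = out["relative_total_rna"] / out["relative_mrna"]
    out["ratio_shift"] = ratio
    out["ratio_flag"] = (ratio > fold_threshold) | (ratio < 1.0 / fold_threshold)
    return out
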