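"""Core containers for design-space expression grids and curated gene sets.

A range-finding experiment samples a dose x recovery-time design space at
high density without replication: every (dose, time) cell holds at most one
sample per subject.  The containers here keep the expression matrix and the
per-sample design coordinates together, flag failed samples so they never
reach a computation, and carry curated gene sets (GMT) through the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: gene sets smaller than this after intersection with the data are unstable:
#: removal of single genes by filtering steps can flip the enrichment result.
SMALL_SET_THRESHOLD = 20

STATUS_OK = "ok"
STATUS_FAILED = "failed"


class InputError(ValueError):
    """Raised when an input file violates the format contract."""


@dataclass(frozen=True)
class SampleAnnotation:
    """Design-space coordinates of one sample.

    ``dose`` is in experiment dose units (e.g. J/m^2), ``time`` in minutes
    since exposure.  ``status`` is ``"ok"`` or ``"failed"``; failed samples
    carry no expression values and are excluded from every computation.
    """

    sample_id: str
    dose: float
    time: float
    subject_id: str | None = None
    status: str = STATUS_OK

    @property
    def is_ok(self) -> bool:
        return self.status == STATUS_OK

    @property
    def cell(self) -> tuple[float, float]:
        return (self.dose, self.time)


class DesignGrid:
    """Genes x samples log2 expression with design-space annotations.

    ``values`` is a DataFrame indexed by gene id with one column per sample,
    in the same order as ``samples``.  The dose/time grid need not be a
    complete rectangle; missing cells are tolerated downstream.
    """

    def __init__(self, values: pd.DataFrame, samples: Sequence[SampleAnnotation]):
        sample_ids = [s.sample_id for s in samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise InputError("duplicate sample_id in annotation")
        if list(values.columns) != sample_ids:
            if set(values.columns) != set(sample_ids):
                missing = set(values.columns) ^ set(sample_ids)
                raise InputError(
                    f"expression columns and annotation rows do not match: {sorted(missing)}"
                )
            values = values[sample_ids]
        if values.index.has_duplicates:
            dups = values.index[values.index.duplicated()].unique().tolist()
            raise InputError(f"duplicate gene id(s): {dups[:5]}")
        for s in samples:
            if s.is_ok:
                col = values[s.sample_id]
                if not np.all(np.isfinite(col.to_numpy(dtype=float))):
                    raise InputError(
                        f"non-finite expression for ok sample {s.sample_id!r}"
                    )
        self.values = values.astype(float)
        self.samples = list(samples)

    # -- basic views ------------------------------------------------------

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def ok_samples(self) -> list[SampleAnnotation]:
        return [s for s in self.samples if s.is_ok]

    @property
    def ok_values(self) -> pd.DataFrame:
        """Expression restricted to ok samples; the only matrix downstream code sees."""
        return self.values[[s.sample_id for s in self.ok_samples]]

    @property
    def doses(self) -> list[float]:
        return sorted({s.dose for s in self.ok_samples})

    @property
    def times(self) -> list[float]:
        return sorted({s.time for s in self.ok_samples})

    @property
    def subjects(self) -> list[str]:
        return sorted({s.subject_id for s in self.ok_samples if s.subject_id})

    def annotation(self, sample_id: str) -> SampleAnnotation:
        for s in self.samples:
            if s.sample_id == sample_id:
                return s
        raise KeyError(sample_id)

    def samples_at(self, dose: float, time: float) -> list[SampleAnnotation]:
        return [s for s in self.ok_samples if s.dose == dose and s.time == time]

    def subset_genes(self, genes: Iterable[str]) -> "DesignGrid":
        keep = [g for g in self.genes if g in set(genes)]
        return DesignGrid(self.values.loc[keep], self.samples)

    def with_values(self, values: pd.DataFrame) -> "DesignGrid":
        return DesignGrid(values, self.samples)


@dataclass
class GeneSet:
    """A named set of gene identifiers with free-text provenance.

    ``small`` is set when the size after intersection with the data drops
    below :data:`SMALL_SET_THRESHOLD`; such sets are unstable under the
    filtering steps and results should be read with caution.
    """

    name: str
    genes: frozenset[str]
    source: str = ""
    small: bool = False
    original_size: int | None = None

    def __post_init__(self) -> None:
        self.genes = frozenset(self.genes)
        if not self.genes:
            raise InputError(f"gene set {self.name!r} is empty")
        if self.original_size is None:
            self.original_size = len(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise InputError(f"duplicate gene set name(s): {dup}")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


# -- readers / writers ----------------------------------------------------


def _parse_annotation_row(row: pd.Series) -> SampleAnnotation:
    subject = row.get("subject_id")
    if subject is None or (isinstance(subject, float) and np.isnan(subject)) or subject == "":
        subject = None
    else:
        subject = str(subject)
    status = str(row.get("status", STATUS_OK)).strip().lower()
    if status not in (STATUS_OK, STATUS_FAILED):
        raise InputError(f"unknown sample status {status!r} for {row['sample_id']!r}")
    return SampleAnnotation(
        sample_id=str(row["sample_id"]),
        dose=float(row["dose"]),
        time=float(row["time_min"]),
        subject_id=subject,
        status=status,
    )


def read_design_grid(expr_path: str | Path, annot_path: str | Path) -> DesignGrid:
    """Read an expression TSV (gene rows, sample columns, log2 scale) and a
    sample annotation TSV (columns sample_id, dose, time_min, optional
    subject_id, status) into a :class:`DesignGrid`.

    Sample columns are matched to annotation rows by sample_id; any
    unmatched entry on either side is fatal.
    """
    expr = pd.read_csv(expr_path, sep="\t", index_col=0, float_precision="round_trip")
    expr.index = expr.index.astype(str)
    expr.columns = expr.columns.astype(str)
    annot = pd.read_csv(annot_path, sep="\t", dtype={"sample_id": str})
    for col in ("sample_id", "dose", "time_min"):
        if col not in annot.columns:
            raise InputError(f"annotation file lacks required column {col!r}")
    samples = [_parse_annotation_row(row) for _, row in annot.iterrows()]
    try:
        return DesignGrid(expr, samples)
    except InputError:
        raise
    except (ValueError, TypeError) as exc:  # non-numeric expression etc.
        raise InputError(str(exc)) from exc


def write_design_grid(grid: DesignGrid, expr_path: str | Path, annot_path: str | Path) -> None:
    """Write a grid back to the TSV pair; round-trips values bit-exactly."""
    grid.values.to_csv(expr_path, sep="\t", index_label="gene_id")
    rows = [
        {
            "sample_id": s.sample_id,
            "dose": s.dose,
            "time_min": s.time,
            "subject_id": "" if s.subject_id is None else s.subject_id,
            "status": s.status,
        }
        for s in grid.samples
    ]
    pd.DataFrame(rows).to_csv(annot_path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file (name TAB description TAB gene ids...) preserving
    file order; duplicate genes within a set are counted once."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise InputError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name, source = parts[0], parts[1]
            genes = frozenset(g for g in parts[2:] if g)
            if not genes:
                raise InputError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets.append(GeneSet(name=name, genes=genes, source=source))
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.source or "na", *sorted(s.genes)]) + "\n")


def intersect_with_data(gene_set: GeneSet, grid: DesignGrid) -> GeneSet:
    """Restrict a gene set to the genes present in the (filtered) data.

    Sets that fall below :data:`SMALL_SET_THRESHOLD` genes are flagged as
    small/unstable; an empty intersection is an error naming the set.
    """
    present = gene_set.genes & set(grid.genes)
    if not present:
        raise InputError(
            f"gene set {gene_set.name!r} has no genes in the data"
        )
    small = len(present) < SMALL_SET_THRESHOLD
    if small:
        logger.warning(
            "gene set %s has only %d genes after intersection (<%d): unstable",
            gene_set.name, len(present), SMALL_SET_THRESHOLD,
        )
    return replace(
        gene_set,
        genes=frozenset(present),
        small=small,
        original_size=gene_set.original_size,
    )
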