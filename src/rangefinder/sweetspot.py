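"""Competitive gene-set enrichment over the design space and sweet-spot calls.

Each usable design-space cell is tested for whether the genes of a curated
set sit higher in the cell's per-gene fold-change ranking than the genes
outside the set (a competitive test with genes as the unit of
randomization; it assumes set genes are no more correlated on average than
random genes, an assumption that cannot be checked without replicates and
whose violation makes p-values optimistic — acceptable for screening).

Two variants are provided:

``rank``
    a one-sided Wilcoxon mean-rank test (midranks on ties).  For small
    instances the p-value is the exact fraction of equal-size gene subsets
    whose mean rank reaches the observed one; otherwise a normal
    approximation with finite-population and tie correction is used.
``permutation``
    a seeded Monte-Carlo gene-permutation test on the mean statistic with
    the add-one estimator, ``p = (1 + #{subset mean >= observed}) / (1 + B)``.

Adjusted p-values (Benjamini-Hochberg across the cells of a diagram) are
rendered with an adaptive color key anchored at the diagram's lowest
adjusted p-value (pmin): color runs from pmin (red) to pmin + pmax (grey).
If pmin exceeds 0.3 a fallback scale from 0.3 (red) to 0.5 (grey) is used
and no sweet spots are declared — the red anchor is unoccupied.  Sweet
spots are the cells in the red band of the active scale.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import GeneSet, GeneSetCollection
from .design_space import RestrictionMask
from .preprocess import Cell, RatioGrid

logger = logging.getLogger(__name__)

ALTERNATIVES = ("mixed", "up", "down")
METHODS = ("rank", "permutation")

#: per-experiment presets for the color-scale span parameter pmax
PMAX_INVITRO = 0.2
PMAX_INVIVO = 0.01


@dataclass
class EnrichmentConfig:
    """Knobs of the enrichment screen.

    ``alternative`` selects the gene statistic: ``mixed`` ranks |log2 FC|
    (change in either direction), ``up``/``down`` rank signed FCs.
    ``pmax`` is the color-scale span; 0.2 (conservative) suits sparse
    in-vitro-like signal, 0.01 dense in-vivo-like signal.  The red band is
    the lowest ``red_band_fraction`` of the active scale.
    """

    alternative: str = "mixed"
    method: str = "rank"
    n_permutations: int = 9999
    seed: int = 0
    pmax: float = PMAX_INVITRO
    red_band_fraction: float = 0.25
    fallback_floor: float = 0.3
    fallback_ceiling: float = 0.5
    max_exact: int = 20000  # exact subset enumeration budget for the rank method
    bh_family: str = "per_set"  # or "global": BH across sets x cells jointly

    def __post_init__(self) -> None:
        if self.alternative not in ALTERNATIVES:
            raise ValueError(f"alternative must be one of {ALTERNATIVES}")
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        if self.method == "permutation" and self.n_permutations < 99:
            raise ValueError("n_permutations must be >= 99")
        if not 0 < self.red_band_fraction < 1:
            raise ValueError("red_band_fraction must be in (0, 1)")


@dataclass
class EnrichmentDiagram:
    """Dose x time grid of enrichment p-values for one gene set."""

    set_name: str
    p_raw: dict[Cell, float]
    p_adj: dict[Cell, float]
    pmax: float
    color_value: dict[Cell, float] = field(default_factory=dict)
    sweet_mask: dict[Cell, bool] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    @property
    def pmin(self) -> float:
        return min(self.p_adj.values())

    def sweet_cells(self) -> list[Cell]:
        return sorted(c for c, flag in self.sweet_mask.items() if flag)

    def argmin_cell(self) -> Cell:
        return min(sorted(self.p_adj), key=lambda c: self.p_adj[c])

    def to_tidy(self) -> pd.DataFrame:
        rows = [
            {
                "set": self.set_name,
                "dose": d,
                "time": t,
                "p_raw": self.p_raw[(d, t)],
                "p_adj": self.p_adj[(d, t)],
                "color_value": self.color_value.get((d, t), float("nan")),
                "sweet": bool(self.sweet_mask.get((d, t), False)),
            }
            for (d, t) in sorted(self.p_adj)
        ]
        return pd.DataFrame(
            rows, columns=["set", "dose", "time", "p_raw", "p_adj", "color_value", "sweet"]
        )


# -- the gene-set test ----------------------------------------------------


def _transform(stat: np.ndarray, alternative: str) -> np.ndarray:
    if alternative == "mixed":
        return np.abs(stat)
    if alternative == "down":
        return -stat
    return stat


def _rank_p(stat: np.ndarray, member: np.ndarray, max_exact: int) -> float:
    """One-sided mean-rank p-value: P(random same-size subset mean rank >= observed)."""
    ranks = stats.rankdata(stat)  # midranks on ties
    n = stat.size
    k = int(member.sum())
    obs = float(ranks[member].sum())
    n_subsets = math.comb(n, k)
    if n_subsets <= max_exact:
        # midranks are half-integers: sums are exact in binary floating point
        count = sum(1 for c in itertools.combinations(ranks, k) if sum(c) >= obs)
        return count / n_subsets
    mu = k * (n + 1) / 2.0
    pop_var = float(np.var(ranks))  # population variance of midranks (tie-corrected)
    var = k * pop_var * (n - k) / (n - 1)
    if var <= 0:
        return 1.0
    z = (obs - mu) / math.sqrt(var)
    return float(stats.norm.sf(z))


def _permutation_p(
    stat: np.ndarray, member: np.ndarray, n_permutations: int, rng: np.random.Generator
) -> float:
    n = stat.size
    k = int(member.sum())
    obs = float(stat[member].mean())
    hits = 0
    for _ in range(n_permutations):
        idx = rng.choice(n, size=k, replace=False)
        if float(stat[idx].mean()) >= obs - 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_permutations)


def gene_set_test(
    cell_stats: pd.Series | np.ndarray,
    gene_set: GeneSet | frozenset | set,
    config: EnrichmentConfig | None = None,
    rng: np.random.Generator | None = None,
) -> float:
    """Competitive enrichment p-value of a gene set in one cell's statistics.

    ``cell_stats`` is the per-gene log2 ratio vector of a cell, indexed by
    gene id (a plain array needs a set given as a boolean membership mask).
    Returns the one-sided p-value that set genes carry larger (transformed)
    statistics than non-set genes.
    """
    config = config or EnrichmentConfig()
    if isinstance(cell_stats, pd.Series):
        members = gene_set.genes if isinstance(gene_set, GeneSet) else frozenset(gene_set)
        member = cell_stats.index.isin(members)
        stat = cell_stats.to_numpy(dtype=float)
    else:
        stat = np.asarray(cell_stats, dtype=float)
        member = np.asarray(gene_set, dtype=bool)
    k = int(member.sum())
    n = stat.size
    if k < 2:
        raise ValueError("gene set has fewer than 2 genes in the data")
    if k >= n:
        raise ValueError("gene set covers the whole statistic vector")
    stat = _transform(stat, config.alternative)
    if np.ptp(stat) == 0:
        logger.warning("constant statistic vector: enrichment undefined, p = 1")
        return 1.0
    if config.method == "rank":
        return _rank_p(stat, member, config.max_exact)
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return _permutation_p(stat, member, config.n_permutations, rng)


# -- multiple-testing correction ------------------------------------------


def benjamini_hochberg(pvec) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvec, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# -- design-space screening ------------------------------------------------


def enrich_design_space(
    ratios: RatioGrid,
    mask: RestrictionMask | None,
    sets: GeneSetCollection,
    config: EnrichmentConfig | None = None,
) -> list[EnrichmentDiagram]:
    """Run the enrichment screen for every gene set over the usable cells.

    ``ratios`` should be a time-matched-dose0 ratio grid with the
    background filter already applied.  BH adjustment spans the cells of
    each set's diagram (or all sets jointly with ``bh_family="global"``).
    Per-set errors (e.g. a set absent from the data) are logged and the
    remaining sets are processed.
    """
    config = config or EnrichmentConfig()
    cells = ratios.cell_keys
    if mask is not None:
        cells = [c for c in cells if mask.is_usable(c)]
    if not cells:
        raise ValueError("no usable cells to test")
    gene_index = pd.Index(ratios.genes)
    frame = ratios.to_frame()
    rng = np.random.default_rng(config.seed)

    diagrams: list[EnrichmentDiagram] = []
    raws: list[tuple[str, dict[Cell, float]]] = []
    for gene_set in sets:
        member = gene_index.isin(gene_set.genes)
        try:
            if member.sum() < 2:
                raise ValueError(
                    f"gene set {gene_set.name!r} has fewer than 2 genes in the data"
                )
            p_raw = {
                cell: gene_set_test(
                    frame[cell].to_numpy(), member, config, rng=rng
                )
                for cell in cells
            }
        except ValueError as exc:
            logger.error("skipping gene set %s: %s", gene_set.name, exc)
            continue
        raws.append((gene_set.name, p_raw))

    if config.bh_family == "global":
        flat = [(name, cell) for name, p_raw in raws for cell in sorted(p_raw)]
        adj = benjamini_hochberg([dict(raws)[name][cell] for name, cell in flat])
        adj_lookup = {key: a for key, a in zip(flat, adj)}
        for name, p_raw in raws:
            p_adj = {cell: float(adj_lookup[(name, cell)]) for cell in p_raw}
            diagrams.append(_make_diagram(name, p_raw, p_adj, config))
    else:
        for name, p_raw in raws:
            order = sorted(p_raw)
            adj = benjamini_hochberg([p_raw[c] for c in order])
            p_adj = {c: float(a) for c, a in zip(order, adj)}
            diagrams.append(_make_diagram(name, p_raw, p_adj, config))
    return diagrams


def _make_diagram(
    name: str, p_raw: dict[Cell, float], p_adj: dict[Cell, float], config: EnrichmentConfig
) -> EnrichmentDiagram:
    diagram = EnrichmentDiagram(
        set_name=name,
        p_raw=p_raw,
        p_adj=p_adj,
        pmax=config.pmax,
        metadata={
            "method": config.method,
            "alternative": config.alternative,
            "pmax": config.pmax,
            "red_band_fraction": config.red_band_fraction,
            "bh_family": config.bh_family,
        },
    )
    return classify_sweet_spots(diagram, config)


def classify_sweet_spots(
    diagram: EnrichmentDiagram, config: EnrichmentConfig | None = None
) -> EnrichmentDiagram:
    """Apply the adaptive color key and mark the red band as sweet spots.

    With pmin the lowest adjusted p in the diagram: if pmin <= 0.3 the
    color scale runs from pmin (red, 0) to pmin + pmax (grey, 1) and cells
    with color <= red_band_fraction are sweet; if pmin > 0.3 a fallback
    scale from 0.3 to 0.5 is drawn and no cell is sweet (nothing reaches
    the red anchor).
    """
    config = config or EnrichmentConfig(pmax=diagram.pmax)
    pmin = diagram.pmin
    color: dict[Cell, float] = {}
    sweet: dict[Cell, bool] = {}
    if pmin > config.fallback_floor:
        span = config.fallback_ceiling - config.fallback_floor
        for cell, p in diagram.p_adj.items():
            color[cell] = float(np.clip((p - config.fallback_floor) / span, 0.0, 1.0))
            sweet[cell] = False
    else:
        pmax = diagram.pmax if diagram.pmax > 0 else config.pmax
        for cell, p in diagram.p_adj.items():
            color[cell] = float(np.clip((p - pmin) / pmax, 0.0, 1.0))
            sweet[cell] = color[cell] <= config.red_band_fraction
    return replace(diagram, color_value=color, sweet_mask=sweet)


def random_set_diagnostic(
    ratios: RatioGrid,
    mask: RestrictionMask | None,
    size: int,
    n_sets: int,
    seed: int,
    config: EnrichmentConfig | None = None,
) -> dict:
    """Run randomly composed gene sets through the screen as a chance check.

    Random sets should not produce coherent sweet-spot patterns; the
    summary reports the distribution of per-diagram pmin and the fraction
    of diagrams declaring any sweet spot.  Deterministic for a fixed seed.
    """
    if size < 2:
        raise ValueError("random set size must be >= 2")
    n = len(ratios.genes)
    if size >= n:
        raise ValueError("random set size must be smaller than the gene total")
    if size > n - 10:
        logger.warning("random set size %d close to gene total %d: degenerate", size, n)
    config = config or EnrichmentConfig()
    rng = np.random.default_rng(seed)
    genes = np.asarray(ratios.genes)
    sets = GeneSetCollection(
        [
            GeneSet(
                name=f"random_{i:04d}",
                genes=frozenset(rng.choice(genes, size=size, replace=False)),
                source="random diagnostic",
            )
            for i in range(n_sets)
        ]
    )
    diagrams = enrich_design_space(ratios, mask, sets, config)
    pmins = sorted(d.pmin for d in diagrams)
    with_sweet = sum(1 for d in diagrams if d.sweet_cells())
    return {
        "size": size,
        "n_sets": n_sets,
        "seed": seed,
        "pmin_min": pmins[0],
        "pmin_median": float(np.median(pmins)),
        "pmin_max": pmins[-1],
        "fraction_with_sweet_spot": with_sweet / n_sets,
        "per_set_pmin": pmins,
    }
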