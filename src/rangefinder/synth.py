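"""Synthetic range-finding experiments with known ground truth.

The generator emulates the two study layouts the protocol was developed
on:

``invitro_single``
    a dose x recovery-time grid with one sample per cell plus a single
    t=0 control (synchronized cell cultures exposed to a UV pulse);
``invivo_paired``
    two subjects per dose sampled alternately over the recovery times,
    each with its own pre-exposure baseline (skin biopsies from paired
    mice), plus additive per-subject offsets.

Planted structure covers every downstream stage: gene modules activated
at chosen cells with a chosen dose-response shape (the enrichment and
correlation screens should find them), background drift genes moving in
all samples over time regardless of dose (the background filter should
remove them), global-stress cells where a stated fraction of the whole
transcriptome moves (the DEG restriction should exclude them), and
Gaussian noise on the log2 scale — the faithful desk-scale stand-in for
log-ratio microarray intensities, which carry no count structure.

The truth record emitted next to the grid suffices to compute every
downstream expectation (DEG counts at sigma=0, the filtered gene list,
the sweet-spot cells) without re-simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import DesignGrid, GeneSet, GeneSetCollection, SampleAnnotation, STATUS_FAILED

DOSE_SHAPES = ("linear", "saturating", "threshold")
TIME_SHAPES = ("step", "linear", "sine")
LAYOUTS = ("invitro_single", "invivo_paired")

#: the two case-study layouts: dose units J/m^2, times in minutes
INVITRO_DOSES = (0.0, 0.25, 0.75, 2.25, 6.7, 20.0)
INVITRO_TIMES = (10.0, 30.0, 60.0, 180.0, 360.0, 720.0, 1440.0, 2880.0)
INVIVO_DOSES = (0.0, 90.0, 180.0, 360.0, 450.0, 720.0)
INVIVO_TIMES = (60.0, 180.0, 360.0, 540.0, 720.0, 1440.0, 2880.0)

Cell = tuple[float, float]

#: gene total of the mouse array the case-study layouts emulate
ARRAY_N_GENES = 24302


def _scaled_drift(count_at_full: int, n_genes: int) -> int:
    """Scale a drift-gene count stated for the full array to a smaller grid."""
    return int(round(count_at_full * min(1.0, n_genes / ARRAY_N_GENES)))


@dataclass
class PlantedModule:
    """A gene module activated at specific design-space cells.

    The added effect at an active cell is ``amplitude * f(dose)`` with
    ``f`` normalized to 1 at the strongest active dose: ``linear`` is
    proportional response, ``saturating`` is ``d/(d+K)`` with K the median
    active dose, ``threshold`` is an on/off indicator — spanning the
    qualitative dose-response forms the correlation screen must detect
    and miss.
    """

    name: str
    size: int
    active_cells: frozenset[Cell]
    amplitude: float
    dose_shape: str = "linear"
    genes: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        self.active_cells = frozenset((float(d), float(t)) for d, t in self.active_cells)
        if self.dose_shape not in DOSE_SHAPES:
            raise ValueError(f"dose_shape must be one of {DOSE_SHAPES}")
        if self.size < 1:
            raise ValueError("module size must be >= 1")

    def dose_factor(self, dose: float) -> float:
        active = sorted({d for d, _ in self.active_cells if d > 0})
        if not active:
            return 1.0
        dmax = active[-1]
        if self.dose_shape == "linear":
            return dose / dmax
        if self.dose_shape == "saturating":
            k = float(np.median(active))
            return (dose / (dose + k)) / (dmax / (dmax + k)) if dose > 0 else 0.0
        return 1.0 if dose >= active[0] else 0.0


@dataclass
class DriftSpec:
    """Background genes changing over time in all samples, dose included."""

    count: int
    amplitude: float
    time_shape: str = "step"

    def __post_init__(self) -> None:
        if self.time_shape not in TIME_SHAPES:
            raise ValueError(f"time_shape must be one of {TIME_SHAPES}")

    def time_factor(self, time: float, tmax: float) -> float:
        if time <= 0:
            return 0.0
        if self.time_shape == "step":
            return 1.0
        if self.time_shape == "linear":
            return time / tmax
        return float(np.sin(np.pi * time / tmax))


@dataclass
class SyntheticSpec:
    """Full recipe for one synthetic range-finding experiment."""

    doses: tuple[float, ...]
    times: tuple[float, ...]  # recovery times (minutes, > 0)
    n_genes: int
    noise_sd: float = 0.25
    layout: str = "invitro_single"
    planted_modules: tuple[PlantedModule, ...] = ()
    drift: DriftSpec | None = None
    subject_offsets_sd: float = 0.3
    global_stress_cells: frozenset[Cell] = frozenset()
    stress_fraction: float = 0.15
    stress_amplitude: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.doses = tuple(float(d) for d in self.doses)
        self.times = tuple(float(t) for t in self.times)
        self.global_stress_cells = frozenset(
            (float(d), float(t)) for d, t in self.global_stress_cells
        )
        if self.layout not in LAYOUTS:
            raise ValueError(f"layout must be one of {LAYOUTS}")
        if any(t <= 0 for t in self.times):
            raise ValueError("recovery times must be positive (t=0 is the baseline)")
        if 0.0 not in self.doses:
            raise ValueError("the dose grid must include dose 0 (untreated)")
        grid_cells = {(d, t) for d in self.doses for t in self.times}
        for m in self.planted_modules:
            if not m.active_cells <= grid_cells:
                raise ValueError(f"module {m.name!r} has active cells outside the grid")
        if not self.global_stress_cells <= grid_cells:
            raise ValueError("global stress cells outside the grid")
        total_planted = sum(m.size for m in self.planted_modules)
        drift_count = self.drift.count if self.drift else 0
        if total_planted + drift_count > self.n_genes:
            raise ValueError("planted module + drift genes exceed the gene total")
        if not 0 <= self.stress_fraction < 1:
            raise ValueError("stress_fraction must be in [0, 1)")


# -- presets ---------------------------------------------------------------


def invitro_like(n_genes: int = 24302, noise_sd: float = 0.25, seed: int = 0, **overrides) -> SyntheticSpec:
    """In-vitro-style preset: 6 UV-C doses x 8 recovery times, one t=0 control.

    One 45-gene module peaks at (2.25 J/m^2, 6 h); ~1,850 drift genes
    emulate the synchronization collapse of growing cultures; late times
    and the highest dose carry transcriptome-wide stress.
    """
    defaults = dict(
        doses=INVITRO_DOSES,
        times=INVITRO_TIMES,
        n_genes=n_genes,
        noise_sd=noise_sd,
        layout="invitro_single",
        planted_modules=(
            PlantedModule(
                name="repair_like",
                size=45,
                active_cells=frozenset({(2.25, 360.0)}),
                amplitude=1.5,
                dose_shape="linear",
            ),
        ),
        drift=DriftSpec(count=_scaled_drift(1854, n_genes), amplitude=2.0, time_shape="step"),
        global_stress_cells=frozenset(
            {(d, t) for d in INVITRO_DOSES if d > 0 for t in (720.0, 1440.0, 2880.0)}
            | {(20.0, 180.0), (20.0, 360.0)}
        ),
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticSpec(**defaults)


def invivo_like(n_genes: int = 24302, noise_sd: float = 0.25, seed: int = 0, **overrides) -> SyntheticSpec:
    """In-vivo-style preset: 6 UV-B doses x 7 times, two subjects per dose.

    A 50-gene stress-response module rises with dose at mid times
    (saturating), a 45-gene repair-like module at late times; ~1,800
    drift genes ramp over time (circadian/housing background); additive
    per-subject offsets; no cell reaches the non-specific threshold.
    """
    defaults = dict(
        doses=INVIVO_DOSES,
        times=INVIVO_TIMES,
        n_genes=n_genes,
        noise_sd=noise_sd,
        layout="invivo_paired",
        planted_modules=(
            PlantedModule(
                name="stress_response_like",
                size=50,
                active_cells=frozenset(
                    (d, t) for d in (180.0, 360.0, 450.0, 720.0) for t in (360.0, 540.0, 720.0)
                ),
                amplitude=1.2,
                dose_shape="saturating",
            ),
            PlantedModule(
                name="repair_like",
                size=45,
                active_cells=frozenset(
                    (d, t) for d in (180.0, 360.0, 450.0, 720.0) for t in (720.0, 1440.0, 2880.0)
                ),
                amplitude=1.0,
                dose_shape="linear",
            ),
        ),
        drift=DriftSpec(count=_scaled_drift(1814, n_genes), amplitude=2.0, time_shape="linear"),
        subject_offsets_sd=0.3,
        seed=seed,
    )
    defaults.update(overrides)
    return SyntheticSpec(**defaults)


# -- generation ------------------------------------------------------------


def _layout_samples(spec: SyntheticSpec) -> list[SampleAnnotation]:
    samples: list[SampleAnnotation] = []
    if spec.layout == "invitro_single":
        samples.append(SampleAnnotation("ctrl_t0", 0.0, 0.0))
        for di, d in enumerate(spec.doses):
            for ti, t in enumerate(spec.times):
                samples.append(SampleAnnotation(f"s_d{di}_t{ti}", d, t))
    else:
        for di, d in enumerate(spec.doses):
            pair = (f"m{di:02d}a", f"m{di:02d}b")
            for subj in pair:
                samples.append(SampleAnnotation(f"{subj}_base", 0.0, 0.0, subject_id=subj))
            for ti, t in enumerate(sorted(spec.times)):
                subj = pair[ti % 2]  # alternate time coverage between the pair
                samples.append(SampleAnnotation(f"{subj}_t{ti}", d, t, subject_id=subj))
    return samples


def _cell_key(cell: Cell) -> str:
    return f"{cell[0]:g}|{cell[1]:g}"


def generate(spec: SyntheticSpec) -> tuple[DesignGrid, dict]:
    """Simulate a design grid from a :class:`SyntheticSpec`; returns (grid, truth record)."""
    rng = np.random.default_rng(spec.seed)
    genes = [f"g{i:05d}" for i in range(spec.n_genes)]
    samples = _layout_samples(spec)
    tmax = max(spec.times)

    # disjoint gene assignment: modules first, then drift, from one permutation
    pool = rng.permutation(spec.n_genes)
    cursor = 0
    modules: list[PlantedModule] = []
    module_idx: dict[str, np.ndarray] = {}
    for m in spec.planted_modules:
        if m.genes:
            idx = np.array([genes.index(g) for g in m.genes])
        else:
            idx = np.sort(pool[cursor : cursor + m.size])
            cursor += m.size
        module_idx[m.name] = idx
        modules.append(replace(m, genes=tuple(genes[i] for i in idx)))
    drift_idx = np.sort(pool[cursor : cursor + (spec.drift.count if spec.drift else 0)])
    drift_sign = rng.choice([-1.0, 1.0], size=drift_idx.size)

    baseline = rng.normal(8.0, 2.0, size=spec.n_genes)
    subjects = sorted({s.subject_id for s in samples if s.subject_id})
    offsets = {
        subj: float(rng.normal(0.0, spec.subject_offsets_sd)) for subj in subjects
    }

    stress_genes: dict[str, np.ndarray] = {}
    stress_sign: dict[str, np.ndarray] = {}
    n_stress = int(spec.stress_fraction * spec.n_genes)
    for cell in sorted(spec.global_stress_cells):
        key = _cell_key(cell)
        stress_genes[key] = np.sort(rng.choice(spec.n_genes, size=n_stress, replace=False))
        stress_sign[key] = rng.choice([-1.0, 1.0], size=n_stress)

    values = np.empty((spec.n_genes, len(samples)))
    for j, s in enumerate(samples):
        col = baseline.copy()
        if s.subject_id:
            col += offsets[s.subject_id]
        if spec.drift and s.time > 0:
            col[drift_idx] += (
                drift_sign * spec.drift.amplitude * spec.drift.time_factor(s.time, tmax)
            )
        for m in modules:
            if s.cell in m.active_cells:
                col[module_idx[m.name]] += m.amplitude * m.dose_factor(s.dose)
        key = _cell_key(s.cell)
        if key in stress_genes:
            col[stress_genes[key]] += stress_sign[key] * spec.stress_amplitude
        if spec.noise_sd > 0:
            col += rng.normal(0.0, spec.noise_sd, size=spec.n_genes)
        values[:, j] = col

    frame = pd.DataFrame(values, index=genes, columns=[s.sample_id for s in samples])
    grid = DesignGrid(frame, samples)

    truth = {
        "layout": spec.layout,
        "seed": spec.seed,
        "n_genes": spec.n_genes,
        "noise_sd": spec.noise_sd,
        "doses": list(spec.doses),
        "times": list(spec.times),
        "modules": [
            {
                "name": m.name,
                "genes": list(m.genes),
                "cells": sorted([d, t] for d, t in m.active_cells),
                "amplitude": m.amplitude,
                "dose_shape": m.dose_shape,
            }
            for m in modules
        ],
        "drift_genes": [genes[i] for i in drift_idx],
        "drift": (
            {
                "count": spec.drift.count,
                "amplitude": spec.drift.amplitude,
                "time_shape": spec.drift.time_shape,
            }
            if spec.drift
            else None
        ),
        "stress_cells": sorted([d, t] for d, t in spec.global_stress_cells),
        "stress_fraction": spec.stress_fraction,
        "stress_amplitude": spec.stress_amplitude,
        "stress_genes": {
            key: [genes[i] for i in idx] for key, idx in sorted(stress_genes.items())
        },
        "subject_offsets": offsets,
    }
    return grid, truth


def truth_gene_sets(truth: dict) -> GeneSetCollection:
    """Planted modules as a gene-set collection for the enrichment screen."""
    return GeneSetCollection(
        [
            GeneSet(
                name=m["name"],
                genes=frozenset(m["genes"]),
                source="synthetic planted module",
            )
            for m in truth["modules"]
        ]
    )


def failure_mask(grid: DesignGrid, n_failed: int, seed: int) -> DesignGrid:
    """Mark ``n_failed`` random non-baseline samples as failed.

    Baselines (time 0) are never failed — without them no ratio grid can
    be formed.  Failed samples get NaN values and are excluded everywhere.
    """
    eligible = [s for s in grid.ok_samples if s.time > 0]
    if n_failed > len(eligible):
        raise ValueError(f"cannot fail {n_failed} of {len(eligible)} eligible samples")
    if n_failed == 0:
        return grid
    rng = np.random.default_rng(seed)
    chosen = set(
        rng.choice([s.sample_id for s in eligible], size=n_failed, replace=False)
    )
    samples = [
        replace(s, status=STATUS_FAILED) if s.sample_id in chosen else s
        for s in grid.samples
    ]
    values = grid.values.copy()
    for sid in chosen:
        values[sid] = np.nan
    return DesignGrid(values, samples)
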