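import numpy as np
import pandas as pd
import pytest

from rangefinder.core import DesignGrid, SampleAnnotation


@pytest.fixture
def tiny_grid() -> DesignGrid:
    """4 genes x 6 samples over a 2-dose x 2-time grid plus a t=0 control;
    one failed sample."""
    samples = [
        SampleAnnotation("c0", 0.0, 0.0),
        SampleAnnotation("u1", 0.0, 60.0),
        SampleAnnotation("u2", 0.0, 120.0),
        SampleAnnotation("a1", 5.0, 60.0),
        SampleAnnotation("a2", 5.0, 120.0),
        SampleAnnotation("bad", 5.0, 120.0, status="failed"),
    ]
    rng = np.random.default_rng(7)
    values = pd.DataFrame(
        rng.normal(8, 1, size=(4, 6)),
        index=["g1", "g2", "g3", "g4"],
        columns=[s.sample_id for s in samples],
    )
    values["bad"] = np.nan
    return DesignGrid(values, samples)


@pytest.fixture
def paired_grid() -> DesignGrid:
    """Two subjects with shared conditions and a pure additive offset.

    Truth (offset-free) expression depends only on (dose, time); subject A
    carries -0.5, subject B +0.5 (sum-to-zero), zero noise.
    """
    conditions = [(0.0, 0.0), (0.0, 60.0), (2.0, 60.0), (2.0, 120.0)]
    rng = np.random.default_rng(11)
    truth = {c: rng.normal(8, 1, size=3) for c in conditions}
    samples, cols = [], {}
    for offset, subj in ((-0.5, "A"), (0.5, "B")):
        for i, c in enumerate(conditions):
            sid = f"{subj}{i}"
            samples.append(SampleAnnotation(sid, c[0], c[1], subject_id=subj))
            cols[sid] = truth[c] + offset
    values = pd.DataFrame(cols, index=["g1", "g2", "g3"])
    grid = DesignGrid(values, samples)
    grid.truth = truth  # offset-free reference for assertions
    return grid
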