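import numpy as np
import pandas as pd
import pytest

from screfine import CountMatrix


def make_matrix(counts, conditions=("A", "B"), n_rep=None, meta=None):
    """Build a CountMatrix from a 2-D array, splitting runs evenly."""
    counts = np.asarray(counts, dtype=float)
    n_runs = counts.shape[1]
    if n_rep is None:
        n_rep = n_runs // 2
    runs = [f"{conditions[0]}_{i+1}" for i in range(n_rep)] + [
        f"{conditions[1]}_{i+1}" for i in range(n_runs - n_rep)
    ]
    design = pd.Series(
        [conditions[0]] * n_rep + [conditions[1]] * (n_runs - n_rep),
        index=runs,
        name="condition",
    )
    if meta is not None:
        ids = meta.index
    else:
        ids = pd.Index(
            [f"P{i:03d}" for i in range(counts.shape[0])], name="protein_id"
        )
    frame = pd.DataFrame(counts, index=ids, columns=runs)
    return CountMatrix(frame, design, meta)


@pytest.fixture
def toy_matrix():
    """4 proteins x (3+3) runs with varied abundance and spread."""
    counts = np.array(
        [
            [10, 12, 11, 25, 22, 28],
            [3, 1, 2, 2, 3, 1],
            [100, 110, 90, 95, 105, 100],
            [5, 8, 6, 14, 18, 15],
        ],
        dtype=float,
    )
    return make_matrix(counts)


@pytest.fixture
def powerlaw_matrix():
    """Counts whose per-protein sample SD lies exactly on ln s = 0.5 ln m.

    Triplicates (m − d, m, m + d) have mean m and sample SD exactly d, so
    setting d = m^0.5 puts every protein exactly on the law k = 0.5, c = 0.
    """
    rng = np.random.default_rng(42)
    m = np.sort(rng.uniform(10.0, 400.0, size=50))
    d = np.sqrt(m)
    counts = np.column_stack([m - d, m, m + d, m - d, m, m + d])
    return make_matrix(counts)
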