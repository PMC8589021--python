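from __future__ import annotations

import numpy as np
import pytest

from ssrkit import genotype_io as gio
from ssrkit.synthetic_data import SimulationConfig, simulate


@pytest.fixture
def rng():
    return np.random.default_rng(20210)


@pytest.fixture
def small_panel():
    return gio.MarkerPanel.from_column_labels(
        ["M1_100", "M1_102", "M1_104", "M2_200", "M2_202"]
    )


@pytest.fixture
def small_matrix(small_panel):
    scores = np.array(
        [
            [1, 0, 1, 1, 0],
            [1, 1, 0, 0, 1],
            [0, 1, 1, 9, 9],
        ],
        dtype=np.int8,
    )
    return gio.AlleleMatrix(small_panel, ("s1", "s2", "s3"), scores)


def random_matrix(rng, n_samples=8, panel=None, missing_rate=0.15):
    """A random 0/1/9 matrix with block-level missingness."""
    if panel is None:
        panel = gio.MarkerPanel.from_column_labels(
            ["A_1", "A_2", "A_3", "B_1", "B_2", "C_1", "C_2", "C_3", "C_4"]
        )
    scores = rng.integers(0, 2, size=(n_samples, panel.n_columns)).astype(np.int8)
    # every sample presents at least one allele per marker to keep stats sane
    for sl in panel.marker_slices().values():
        none = scores[:, sl].sum(axis=1) == 0
        scores[none, sl.start] = 1
    for j, sl in enumerate(panel.marker_slices().values()):
        miss = rng.random(n_samples) < missing_rate
        scores[np.ix_(miss, range(sl.start, sl.stop))] = 9
    ids = tuple(f"acc{i:03d}" for i in range(n_samples))
    return gio.AlleleMatrix(panel, ids, scores)


@pytest.fixture
def structured_sim():
    """A mid-size structured collection shared by several test modules."""
    config = SimulationConfig(
        n_markers=12, alleles_per_marker=10, K=3, n_individuals=120,
        divergence=0.8, admixture_alpha=0.2, seed=77,
    )
    return simulate(config)
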