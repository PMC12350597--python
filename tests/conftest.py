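"""Shared fixtures.

The cohort-level fixtures are session-scoped: phantom generation plus HF-map
feature extraction for a 20-patient cohort takes a few seconds and is reused
by the end-to-end, degradation and index-comparison tests.
"""
from __future__ import annotations

import numpy as np
import pytest

from hfmap import CohortSpec, PhantomSpec, cohort_features, generate_cohort


@pytest.fixture
def annulus() -> np.ndarray:
    """5x5 foreground ring of width 1 around a 3x3 background interior."""
    a = np.zeros((5, 5), dtype=bool)
    a[1:4, 1:4] = True
    a[2, 2] = False
    return a


@pytest.fixture
def double_annulus() -> np.ndarray:
    """Two disjoint annuli on one canvas: (b0, b1) = (2, 2)."""
    a = np.zeros((5, 11), dtype=bool)
    for c0 in (1, 7):
        a[1:4, c0 : c0 + 3] = True
        a[2, c0 + 1] = False
    return a


@pytest.fixture
def checkerboard() -> np.ndarray:
    """4x4 checkerboard, foreground where (row + col) is even."""
    return np.indices((4, 4)).sum(axis=0) % 2 == 0


def random_rasters(n: int, shape=(16, 16), fills=(0.3, 0.5, 0.7), seed: int = 20240601):
    """Deterministic stream of random binary rasters cycling over fill levels."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        out.append(rng.random(shape) < fills[i % len(fills)])
    return out


@pytest.fixture(scope="session")
def default_cohort():
    """The study cohort: 10 fibrosis + 10 normal patients, 2 slices each, seed 0."""
    manifest, samples = generate_cohort(CohortSpec(base_seed=0))
    return manifest, samples


@pytest.fixture(scope="session")
def default_features(default_cohort):
    """Slice features of the default cohort through the full pipeline
    (segmentation -> HF map), with both b0 and b1 columns."""
    _, samples = default_cohort
    return cohort_features(samples, both_indices=True)


@pytest.fixture(scope="session")
def delta_features(default_features):
    """Feature tables for the overlap_delta separability sweep {0, -100, -200}."""
    tables = {0.0: default_features}
    for delta in (-100.0, -200.0):
        _, samples = generate_cohort(
            CohortSpec(template=PhantomSpec(overlap_delta=delta), base_seed=0)
        )
        tables[delta] = cohort_features(samples)
    return tables
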