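"""Shared fixtures: one reference simulation reused across test modules."""

from __future__ import annotations

import numpy as np
import pytest

from tfdep.io import GenomicInterval, PeakSet
from tfdep.simulate import SimulationConfig, simulate_all


@pytest.fixture(scope="session")
def default_config() -> SimulationConfig:
    return SimulationConfig(seed=7)


@pytest.fixture(scope="session")
def bundle(default_config):
    """The full default synthetic study (counts, peaks, TMT, truth)."""
    return simulate_all(default_config)


def random_peakset(
    rng: np.random.Generator,
    n: int,
    n_chroms: int = 2,
    coord_max: int = 1000,
    max_len: int = 60,
) -> PeakSet:
    """Small random interval set for fuzzing overlap logic."""
    ivs = []
    for i in range(n):
        chrom = f"chrS{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, coord_max))
        length = int(rng.integers(1, max_len))
        ivs.append(GenomicInterval(chrom, start, start + length, f"p{i}"))
    return PeakSet(ivs)


def brute_force_overlaps(query: PeakSet, subject: PeakSet) -> set[int]:
    """O(n*m) oracle: indices of query intervals overlapping any subject."""
    hits = set()
    for qi, q in enumerate(query):
        for s in subject:
            if q.chrom == s.chrom and max(q.start, s.start) < min(q.end, s.end):
                hits.add(qi)
                break
    return hits
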