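"""Shared fixtures: small synthetic subjects, random trees, toy cohorts."""

from __future__ import annotations

import numpy as np
import pytest

from dcctree.core_io import Cohort, PhenotypeRecord
from dcctree.mst import SpanningTree
from dcctree.synthetic import GarchGenParams, simulate_garch_series


def random_tree(n: int, rng: np.random.Generator) -> SpanningTree:
    """Uniform random labeled tree via a Pruefer sequence."""
    if n == 2:
        return SpanningTree(n=2, edges=frozenset({(0, 1)}))
    prufer = rng.integers(0, n, size=n - 2)
    return tree_from_prufer(list(prufer), n)


def tree_from_prufer(prufer: list[int], n: int) -> SpanningTree:
    degree = [1] * n
    for v in prufer:
        degree[v] += 1
    edges = []
    for v in prufer:
        for leaf in range(n):
            if degree[leaf] == 1:
                edges.append((min(leaf, v), max(leaf, v)))
                degree[leaf] -= 1
                degree[v] -= 1
                break
    last = [v for v in range(n) if degree[v] == 1]
    edges.append((min(last), max(last)))
    return SpanningTree(n=n, edges=frozenset(edges))


def star_tree(n: int, hub: int = 0) -> SpanningTree:
    return SpanningTree(n=n, edges=frozenset(
        (min(hub, i), max(hub, i)) for i in range(n) if i != hub))


def path_tree(n: int) -> SpanningTree:
    return SpanningTree(n=n, edges=frozenset((i, i + 1) for i in range(n - 1)))


def make_record(sid: str, group: str = "TD", **kw) -> PhenotypeRecord:
    defaults = dict(age=15.0, sex="M", iq=105.0, site="S1",
                    func_mean_fd=0.1, func_perc_fd=5.0)
    defaults.update(kw)
    return PhenotypeRecord(subject_id=sid, group=group, **defaults)


@pytest.fixture(scope="session")
def warm_kernels():
    """Trigger numba compilation once so timings elsewhere are honest."""
    simulate_garch_series(GarchGenParams(), 60, seed=0)
    return True


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def toy_cohort() -> Cohort:
    """Two sites x two groups, 16 subjects, all passing default filters."""
    records = []
    gen = np.random.default_rng(99)
    i = 0
    for site in ("S1", "S2"):
        for group in ("ASD", "TD"):
            for _ in range(4):
                i += 1
                records.append(make_record(
                    f"s{i:02d}", group=group, site=site,
                    age=float(gen.uniform(10, 20)),
                    iq=float(gen.uniform(90, 125)),
                    func_mean_fd=float(gen.uniform(0.03, 0.18)),
                    func_perc_fd=float(gen.uniform(1, 15)),
                    ados_total=10.0 + i if group == "ASD" else None,
                ))
    return Cohort(records=records)
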