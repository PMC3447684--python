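"""Shared fixtures: small hand-built snapshots/series and random generators."""

from __future__ import annotations

import random

import pytest

from tvnet.io import AnnotationMap, NetworkSeries, NetworkSnapshot


def snap(time_label, edges, directed=False, nodes=()):
    """Shorthand snapshot builder used throughout the suite."""
    return NetworkSnapshot.from_edges(time_label, directed, edges, nodes=nodes)


def series_of(*snapshots, directed=False):
    return NetworkSeries.from_snapshots(snapshots, directed=directed)


def random_snapshot(rng: random.Random, n_nodes: int, n_edges: int,
                    directed: bool = False, time_label: str = "1") -> NetworkSnapshot:
    """Uniform random simple graph with weights in (0, 1]."""
    nodes = [f"n{i:02d}" for i in range(n_nodes)]
    pairs = [(u, v) for i, u in enumerate(nodes) for v in nodes[i + 1:]]
    if directed:
        pairs = pairs + [(v, u) for u, v in pairs]
    chosen = rng.sample(pairs, min(n_edges, len(pairs)))
    edges = [(u, v, 1.0 - rng.random() * 0.999) for u, v in chosen]
    return NetworkSnapshot.from_edges(time_label, directed, edges, nodes=nodes)


def modular_series(rng: random.Random, n_modules=3, module_size=6,
                   cross_edges=0, n_timepoints=1):
    """Dense planted modules plus a few cross edges; returns (series, modules)."""
    modules = [
        [f"m{m}g{i}" for i in range(module_size)] for m in range(n_modules)
    ]
    snaps = []
    for t in range(n_timepoints):
        edges = []
        for mod in modules:
            for i, u in enumerate(mod):
                for v in mod[i + 1:]:
                    if rng.random() < 0.8:
                        edges.append((u, v, 0.5 + 0.5 * rng.random()))
        for _ in range(cross_edges):
            a, b = rng.sample(range(n_modules), 2)
            u, v = rng.choice(modules[a]), rng.choice(modules[b])
            edges.append((u, v, 0.5 + 0.5 * rng.random()))
        all_nodes = [g for mod in modules for g in mod]
        snaps.append(NetworkSnapshot.from_edges(str(t + 1), False, edges, nodes=all_nodes))
    return NetworkSeries.from_snapshots(snaps, directed=False), modules


@pytest.fixture
def rng():
    return random.Random(20240901)


@pytest.fixture
def toy_series():
    """3 timepoints, 4 genes; edge a-b persists, b-c blinks."""
    return series_of(
        snap("1", [("a", "b", 0.5), ("b", "c", 0.2)], nodes=["a", "b", "c", "d"]),
        snap("2", [("a", "b", 0.9)], nodes=["a", "b", "c", "d"]),
        snap("3", [("a", "b", 0.4), ("b", "c", 0.7)], nodes=["a", "b", "c", "d"]),
    )


@pytest.fixture
def toy_annotations():
    return AnnotationMap({"a": {"X"}, "b": {"X"}, "c": {"Y"}, "d": {"Y"}})


def contiguous_in(order, members) -> bool:
    """True when `members` occupy consecutive positions of `order`."""
    idx = sorted(list(order).index(g) for g in members)
    return idx[-1] - idx[0] == len(idx) - 1
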