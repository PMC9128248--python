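"""PMI correlation network construction by iterative conditioned edge
elimination, plus the threshold scan that selects a stable ("optimal")
network.

The procedure starts from a fully connected network over the input genes and
removes edges whose PMI falls below a preset threshold.  At conditioning
order k >= 1, each surviving edge (X, Y) is re-tested against k-subsets of
the common network neighbours of X and Y; the edge keeps the *maximum* PMI
over those conditioning sets and is removed if even that maximum is below
the threshold.  Scanning a grid of thresholds from low to high and watching
when consecutive edge sets stabilise selects the final network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from pminet.pmi import pmi

logger = logging.getLogger(__name__)

__all__ = ["Network", "ThresholdScanResult", "build_pmi_network", "optimal_network_scan", "jaccard"]


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Unordered gene pair in sorted order."""
    if a == b:
        raise ValueError(f"self-pair {a!r}")
    return (a, b) if a < b else (b, a)


@dataclass
class Network:
    """Undirected weighted network over an ordered gene universe.

    ``edges`` maps canonical (sorted) gene pairs to a strength — a PMI value
    in nats, or |PCC| for the comparable correlation networks.  ``meta``
    records how the network was built (method tag, threshold, conditioning
    order reached).
    """

    genes: tuple
    edges: dict
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        gene_set = set(self.genes)
        for (a, b) in self.edges:
            if a == b:
                raise ValueError(f"self-edge {a!r}")
            if (a, b) != canonical_pair(a, b):
                raise ValueError(f"non-canonical pair ({a!r}, {b!r})")
            if a not in gene_set or b not in gene_set:
                raise ValueError(f"edge endpoint outside gene universe: ({a!r}, {b!r})")

    @property
    def edge_set(self) -> frozenset:
        return frozenset(self.edges)

    def neighbors(self, gene: str) -> set:
        return {b if a == gene else a for (a, b) in self.edges if gene in (a, b)}

    def __len__(self):
        return len(self.edges)


@dataclass
class ThresholdScanResult:
    """Networks built along an ascending threshold grid.

    ``stability[i]`` is the Jaccard similarity of the edge sets at
    thresholds i and i+1; ``chosen_index`` marks the first threshold whose
    trailing similarity reaches the stability tolerance.
    """

    thresholds: list
    networks: list
    stability: list
    chosen_index: int

    @property
    def chosen(self) -> Network:
        return self.networks[self.chosen_index]


def jaccard(edges_a, edges_b) -> float:
    """Jaccard similarity of two edge sets; two empty sets count as 1."""
    a, b = set(edges_a), set(edges_b)
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)


def _validate_expr(expr: pd.DataFrame, n_bins: int) -> np.ndarray:
    data = expr.to_numpy(dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("expression matrix contains non-finite values")
    if expr.shape[0] < 3:
        raise ValueError("need at least 3 genes")
    min_samples = max(10, n_bins ** 2)
    if expr.shape[1] < min_samples:
        raise ValueError(f"need at least {min_samples} samples for n_bins={n_bins}")
    if expr.index.has_duplicates:
        raise ValueError("duplicate gene identifiers")
    return data


def build_pmi_network(expr: pd.DataFrame, threshold: float, max_order: int = 1,
                      n_bins: int = 3, scheme: str = "equal_frequency",
                      n_bins_z: int = 5, shuffle_correction: int = 10,
                      _cache: dict | None = None) -> Network:
    """Build the PMI network for a genes-by-samples expression matrix.

    Order-0 removes every pair whose unconditioned PMI is below ``threshold``.
    At order k >= 1 the conditioning candidates for an edge are the k-subsets
    of the common neighbours of its endpoints in the current network; the
    edge's retained strength is the maximum PMI over candidates.  Passes are
    synchronous (neighbour sets frozen at the start of each order) so the
    result does not depend on edge enumeration order.

    PMI values are estimated with the seeded shuffle bias correction and a
    finer conditioning grid by default (``shuffle_correction=10``,
    ``n_bins_z=5``), so conditionally independent pairs score near zero on
    the same threshold scale at which direct edges score high; set
    ``shuffle_correction=0`` for the raw plug-in.  The build is fully
    deterministic either way.  ``_cache`` memoises PMI evaluations keyed by
    (pair, conditioning set) and may be shared across threshold-scan calls
    on the same matrix.
    """
    data = _validate_expr(expr, n_bins)
    genes = list(expr.index)
    cache = _cache if _cache is not None else {}

    def cached_pmi(i: int, j: int, cond: tuple) -> float:
        key = (i, j, cond)
        if key not in cache:
            z = data[list(cond)] if cond else None
            cache[key] = pmi(data[i], data[j], z, n_bins=n_bins, scheme=scheme,
                             n_bins_z=n_bins_z, shuffle_correction=shuffle_correction)
        return cache[key]

    # order 0: fully connected start, unconditioned PMI filter
    edges: dict = {}
    for i, j in combinations(range(len(genes)), 2):
        v = cached_pmi(i, j, ())
        if v >= threshold:
            edges[(i, j)] = v

    order_reached = 0
    for order in range(1, max_order + 1):
        adj: dict = {}
        for (i, j) in edges:
            adj.setdefault(i, set()).add(j)
            adj.setdefault(j, set()).add(i)
        removed = False
        new_edges: dict = {}
        for (i, j), strength in edges.items():
            common = sorted(adj[i] & adj[j])
            cands = list(combinations(common, order))
            if not cands:
                new_edges[(i, j)] = strength
                continue
            best = max(cached_pmi(i, j, c) for c in cands)
            if best >= threshold:
                new_edges[(i, j)] = best
            else:
                removed = True
        edges = new_edges
        order_reached = order
        if not removed:
            break

    named = {canonical_pair(genes[i], genes[j]): v for (i, j), v in edges.items()}
    meta = {"method": "PMI", "threshold": threshold, "order": order_reached,
            "n_bins": n_bins, "scheme": scheme}
    return Network(genes=tuple(genes), edges=named, meta=meta)


def optimal_network_scan(expr: pd.DataFrame, threshold_grid, stability_tol: float = 0.95,
                         max_order: int = 1, n_bins: int = 3,
                         scheme: str = "equal_frequency", n_bins_z: int = 5,
                         shuffle_correction: int = 10) -> ThresholdScanResult:
    """Scan thresholds from low to high until consecutive networks stabilise.

    The chosen network is the first whose edge-set Jaccard similarity with
    the next threshold's network reaches ``stability_tol``; if the scan never
    stabilises the last network is chosen and a warning logged.
    """
    grid = [float(t) for t in threshold_grid]
    if not grid:
        raise ValueError("threshold grid must be nonempty")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("threshold grid must be strictly ascending")
    cache: dict = {}
    nets = [build_pmi_network(expr, t, max_order=max_order, n_bins=n_bins,
                              scheme=scheme, n_bins_z=n_bins_z,
                              shuffle_correction=shuffle_correction,
                              _cache=cache) for t in grid]
    stability = [jaccard(a.edge_set, b.edge_set) for a, b in zip(nets, nets[1:])]
    chosen = None
    for i, s in enumerate(stability):
        if s >= stability_tol:
            chosen = i
            break
    if chosen is None:
        chosen = len(nets) - 1
        if len(nets) > 1:
            logger.warning("threshold scan did not stabilise (max Jaccard %.3f); "
                           "choosing the last network", max(stability, default=float("nan")))
    return ThresholdScanResult(thresholds=grid, networks=nets,
                               stability=stability, chosen_index=chosen)
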