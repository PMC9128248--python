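"""Recall of omics-defined gene-pair relationships by network edges.

A network *recalls* a relationship record when the record's gene pair is
also a network edge.  Whether a network recalls more records than chance is
measured with a permutation Z-score: draw the same number of gene pairs
uniformly (without replacement) from all pairs of the gene universe, count
recalls, repeat, and standardise the observed count against that null.  For
weighted relationships (CoTR regulator counts, CoCNV/CoDM sample weights)
the count is replaced by the weight sum, giving one Z-score per weight
variant.  Weight distributions of two recalled sets (e.g. PMI recalls vs
PCC recalls) are compared with a two-sided rank-sum test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import stats

from pminet.network import Network, canonical_pair
from pminet.relations import RelationshipTable

logger = logging.getLogger(__name__)

__all__ = ["RecallResult", "recall_edges", "recall_zscore", "compare_weights"]


@dataclass
class RecallResult:
    """Observed recall of one relationship kind by one network, with the
    permutation null summary and a Z-score per weight variant."""

    network_tag: str
    kind: str
    recalled: frozenset
    recall_count: int
    zscores: dict = field(default_factory=dict)
    null_mean: dict = field(default_factory=dict)
    null_sd: dict = field(default_factory=dict)
    n_perm: int = 0
    seed: int | None = None


def recall_edges(net: Network, rel: RelationshipTable) -> frozenset:
    """Gene pairs that are both network edges and relationship records."""
    return frozenset(net.edge_set & rel.pairs)


def _weight_columns(rel: RelationshipTable) -> list:
    cols = set()
    for weights in rel.records.values():
        cols.update(weights)
    return sorted(cols)


def recall_zscore(net: Network, rel: RelationshipTable, universe=None,
                  n_perm: int = 100, seed: int | None = None) -> RecallResult:
    """Permutation Z-score of the relationship recall of a network.

    The null draws ``|edges|`` pairs without replacement from all pairs of
    ``universe`` (default: the network's gene set), ``n_perm`` times.  For
    each weight column of the relationship a weighted variant replaces the
    recall count with the recalled weight sum.  A degenerate null (sd = 0)
    yields a NaN sentinel with a warning.
    """
    if len(net.edges) == 0:
        raise ValueError("network has no edges")
    genes = sorted(set(universe) if universe is not None else set(net.genes))
    if not set(g for pair in net.edges for g in pair) <= set(genes):
        raise ValueError("universe does not cover the network's edge genes")
    all_pairs = [canonical_pair(a, b) for a, b in combinations(genes, 2)]
    k = len(net.edges)
    if k > len(all_pairs):
        raise ValueError("more edges than pairs in the universe")

    recalled = recall_edges(net, rel)
    variants = ["count"] + _weight_columns(rel)

    def stat(pairs) -> dict:
        hits = [p for p in pairs if p in rel.records]
        out = {"count": float(len(hits))}
        for col in variants[1:]:
            out[col] = float(sum(rel.records[p].get(col, 0.0) for p in hits))
        return out

    observed = stat(net.edges)
    rng = np.random.default_rng(seed)
    null = {v: np.empty(n_perm) for v in variants}
    for t in range(n_perm):
        idx = rng.choice(len(all_pairs), size=k, replace=False)
        s = stat([all_pairs[i] for i in idx])
        for v in variants:
            null[v][t] = s[v]

    zscores, means, sds = {}, {}, {}
    for v in variants:
        mu = float(null[v].mean())
        sd = float(null[v].std(ddof=1)) if n_perm > 1 else 0.0
        means[v], sds[v] = mu, sd
        if sd == 0:
            logger.warning("degenerate null (sd=0) for variant %r of %s", v, rel.kind)
            zscores[v] = float("nan")
        else:
            zscores[v] = (observed[v] - mu) / sd
    return RecallResult(
        network_tag=str(net.meta.get("method", "network")), kind=rel.kind,
        recalled=recalled, recall_count=len(recalled), zscores=zscores,
        null_mean=means, null_sd=sds, n_perm=n_perm, seed=seed)


def compare_weights(recall_a, recall_b, rel: RelationshipTable,
                    column: str | None = None, method: str = "mannwhitney") -> dict:
    """Compare the relationship weights of two recalled pair sets.

    Two-sided Mann–Whitney U by default (distribution-free); Welch's t is
    available with ``method="welch"``.  Pairs absent from the relationship
    are ignored.  Returns statistic, p-value and the two medians.
    """
    wa = [rel.weight(p, column) for p in sorted(recall_a) if p in rel.records]
    wb = [rel.weight(p, column) for p in sorted(recall_b) if p in rel.records]
    if not wa or not wb:
        raise ValueError("both recalled sets must contain relationship records")
    if method == "mannwhitney":
        res = stats.mannwhitneyu(wa, wb, alternative="two-sided")
    elif method == "welch":
        res = stats.ttest_ind(wa, wb, equal_var=False)
    else:
        raise ValueError(f"unknown method {method!r}")
    return {
        "method": method,
        "statistic": float(res.statistic),
        "pvalue": float(res.pvalue),
        "median_a": float(np.median(wa)),
        "median_b": float(np.median(wb)),
        "n_a": len(wa),
        "n_b": len(wb),
    }
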