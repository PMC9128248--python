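"""Comparable Pearson-correlation (PCC) networks for a given PMI network.

Three constructions make a PCC network comparable to a PMI network built on
the same genes:

* type 1 — take gene pairs by descending |PCC| until the edge count matches
  the PMI network (compares sparsity at equal size);
* type 2 — take pairs by descending |PCC| until every PMI-network gene is
  covered (compares sparsity at equal node coverage);
* type 3 — per PMI edge (G1, G2), any third gene G3 whose |PCC| with *both*
  endpoints exceeds |PCC(G1, G2)| contributes the edges (G3, G1) and
  (G3, G2).  Edges of the type-3 network absent from the PMI network are the
  "PCC-only" edges: pairs that plain correlation ranks above a retained
  direct edge but that PMI elimination discarded as indirect.

Ties in |PCC| are broken lexicographically on the sorted gene-pair name so
repeated runs are identical.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from pminet.network import Network, canonical_pair

logger = logging.getLogger(__name__)

__all__ = ["pcc_matrix", "pcc_type1", "pcc_type2", "pcc_type3", "pcc_only_edges"]


def pcc_matrix(expr: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson correlations of the rows (genes) of ``expr``.

    Zero-variance genes yield NaN correlations and a logged warning; they are
    excluded from every comparable-network construction downstream.
    """
    if expr.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    data = expr.to_numpy(dtype=float)
    if not np.all(np.isfinite(data)):
        raise ValueError("expression matrix contains non-finite values")
    zero_var = expr.index[data.std(axis=1) == 0]
    if len(zero_var):
        logger.warning("zero-variance genes with undefined correlations: %s",
                       ", ".join(map(str, zero_var)))
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(data)
    return pd.DataFrame(corr, index=expr.index, columns=expr.index)


def _ranked_pairs(corr: pd.DataFrame, genes):
    """Gene pairs within ``genes`` sorted by descending |PCC|, ties broken by
    the sorted pair name; NaN-correlation (zero-variance) pairs dropped."""
    genes = sorted(genes)
    out = []
    for i, a in enumerate(genes):
        for b in genes[i + 1:]:
            r = corr.at[a, b]
            if np.isnan(r):
                continue
            out.append((abs(float(r)), (a, b)))
    out.sort(key=lambda t: (-t[0], t[1]))
    return out


def pcc_type1(expr: pd.DataFrame, pmi_net: Network) -> Network:
    """Top-|E_PMI| pairs within the PMI gene set by descending |PCC|."""
    corr = pcc_matrix(expr)
    ranked = _ranked_pairs(corr, pmi_net.genes)
    chosen = ranked[:len(pmi_net.edges)]
    edges = {pair: strength for strength, pair in chosen}
    return Network(genes=pmi_net.genes, edges=edges,
                   meta={"method": "PCC1", "reference_edges": len(pmi_net.edges)})


def pcc_type2(expr: pd.DataFrame, pmi_net: Network) -> Network:
    """Shortest descending-|PCC| prefix of pairs covering all PMI-network
    genes that carry at least one edge."""
    corr = pcc_matrix(expr)
    ranked = _ranked_pairs(corr, pmi_net.genes)
    target = set()
    for (a, b) in pmi_net.edges:
        target.add(a)
        target.add(b)
    edges: dict = {}
    covered: set = set()
    for strength, pair in ranked:
        if covered >= target:
            break
        edges[pair] = strength
        covered.update(pair)
    if not covered >= target:
        logger.warning("type-2 construction could not cover all PMI genes")
    return Network(genes=pmi_net.genes, edges=edges, meta={"method": "PCC2"})


def pcc_type3(expr: pd.DataFrame, pmi_net: Network) -> Network:
    """Per-edge dominance construction.

    For each PMI edge (G1, G2), every gene G3 from the PMI gene set with
    |PCC(G3, G1)| > |PCC(G1, G2)| and |PCC(G3, G2)| > |PCC(G1, G2)|
    contributes edges (G3, G1) and (G3, G2).  The returned network is the
    union of contributed edges and the PMI edges themselves.
    """
    corr = pcc_matrix(expr)
    data = expr.loc[list(pmi_net.genes)].to_numpy(dtype=float)
    valid = {g for g, s in zip(pmi_net.genes, data.std(axis=1)) if s > 0}
    edges: dict = {}
    for (g1, g2) in pmi_net.edges:
        ref = abs(float(corr.at[g1, g2]))
        for g3 in pmi_net.genes:
            if g3 in (g1, g2) or g3 not in valid:
                continue
            r1 = abs(float(corr.at[g3, g1]))
            r2 = abs(float(corr.at[g3, g2]))
            if r1 > ref and r2 > ref:
                edges[canonical_pair(g3, g1)] = r1
                edges[canonical_pair(g3, g2)] = r2
    for (a, b) in pmi_net.edges:
        edges.setdefault((a, b), abs(float(corr.at[a, b])))
    return Network(genes=pmi_net.genes, edges=edges, meta={"method": "PCC3"})


def pcc_only_edges(type3_net: Network, pmi_net: Network) -> frozenset:
    """Edges of the type-3 PCC network absent from the PMI network."""
    return frozenset(type3_net.edge_set - pmi_net.edge_set)
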