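"""Omics-defined gene-pair relationships.

Network edges are biologically meaningful when the same gene pair also
appears in an independent omics layer.  Five relationship families are
supported:

* **TR / CoTR** — a transcription-regulation edge list gives direct
  regulator→target pairs (TR) and, per gene pair, the number of common upper
  regulators (CoTR), with transcription factors and microRNAs counted
  separately.
* **PPI** — curated protein–protein interaction pairs.
* **SCGD** — same-chromosome gene distance: |TSS1 − TSS2| between the
  transcription start sites of two genes on one chromosome (coordinates are
  0-based half-open; TSS is the interval start on the + strand and the end
  on the − strand).
* **CoCNV** — joint copy-number status of a pair in a sample from
  GISTIC-style calls in {−2..+2}: GG (both gained), LL (both lost), GL/LG
  (mixed, oriented by the canonical sorted gene order), or NC when either
  gene is unmutated.  Pair weights: sample count, sample fraction, and a
  level-product-weighted count using |cnv1·cnv2|.
* **CoDM** — joint methylation profile: per gene and sample, the counts of
  low- and high-methylation CpG islands (beta below/above configurable
  thresholds); per pair, the four cross products LL, HH, LH, HL.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from pminet.network import canonical_pair

logger = logging.getLogger(__name__)

__all__ = [
    "RelationshipTable",
    "cotr_from_tr", "tr_pairs", "ppi_table", "scgd",
    "cocnv_status", "cocnv_status_table", "cocnv_table",
    "dm_gene_counts", "codm_profile", "codm_profile_table", "codm_table",
]

COCNV_KINDS = ("GG", "LL", "GL", "LG")
CODM_VALUES = ("LL", "HH", "LH", "HL")


@dataclass
class RelationshipTable:
    """Weighted unordered gene-pair records of one relationship kind.

    ``records`` maps canonical pairs to a dict of named nonnegative weight
    columns; ``primary_weight`` names the column used by weighted recall
    statistics.
    """

    kind: str
    records: dict = field(default_factory=dict)
    primary_weight: str = "weight"

    def __post_init__(self):
        for (a, b), weights in self.records.items():
            if a == b:
                raise ValueError(f"self-pair {a!r} in {self.kind}")
            if (a, b) != canonical_pair(a, b):
                raise ValueError(f"non-canonical pair ({a!r}, {b!r})")
            for name, w in weights.items():
                if w < 0:
                    raise ValueError(f"negative weight {name}={w} for ({a}, {b})")

    @property
    def pairs(self) -> frozenset:
        return frozenset(self.records)

    def weight(self, pair, column: str | None = None) -> float:
        return self.records[pair][column or self.primary_weight]

    def __len__(self):
        return len(self.records)


def tr_pairs(tr_edges: pd.DataFrame) -> RelationshipTable:
    """Direct regulator→target records as unordered pairs (weight 1 each)."""
    records = {}
    for _, row in tr_edges.iterrows():
        reg, tgt = str(row["regulator"]), str(row["target"])
        if reg == tgt:
            continue
        records[canonical_pair(reg, tgt)] = {"weight": 1.0}
    return RelationshipTable(kind="TR", records=records)


def cotr_from_tr(tr_edges: pd.DataFrame, regulator_class: str) -> RelationshipTable:
    """Common-upper-regulator (CoTR) pairs for one regulator class.

    ``tr_edges`` needs columns ``regulator``, ``class`` and ``target``; the
    weight of a pair is the number of regulators of ``regulator_class``
    ("TF" or "miRNA") targeting both genes.  TF and miRNA tables are never
    mixed.  Pairs sharing no regulator are omitted.
    """
    if regulator_class not in ("TF", "miRNA"):
        raise ValueError("regulator_class must be 'TF' or 'miRNA'")
    sub = tr_edges[tr_edges["class"] == regulator_class]
    targets_of = sub.groupby("regulator")["target"].apply(lambda s: set(map(str, s)))
    counts: dict = {}
    for _, tset in targets_of.items():
        for a, b in combinations(sorted(tset), 2):
            pair = canonical_pair(a, b)
            counts[pair] = counts.get(pair, 0) + 1
    kind = "TFCoTR" if regulator_class == "TF" else "miRCoTR"
    records = {p: {"weight": float(c)} for p, c in counts.items()}
    return RelationshipTable(kind=kind, records=records)


def ppi_table(ppi_edges: pd.DataFrame) -> RelationshipTable:
    """Protein–protein interaction pairs from a two-column edge list."""
    a_col, b_col = ppi_edges.columns[:2]
    records = {}
    for _, row in ppi_edges.iterrows():
        a, b = str(row[a_col]), str(row[b_col])
        if a == b:
            continue
        records[canonical_pair(a, b)] = {"weight": 1.0}
    return RelationshipTable(kind="PPI", records=records)


def scgd(coords: pd.DataFrame) -> RelationshipTable:
    """Same-chromosome gene distance between transcription start sites.

    ``coords`` needs columns ``gene``, ``chrom``, ``start``, ``end``,
    ``strand`` in BED dialect (0-based half-open).  Pairs on different
    chromosomes are absent.
    """
    tss = {}
    chrom = {}
    for _, row in coords.iterrows():
        strand = str(row["strand"])
        if strand == "+":
            t = int(row["start"])
        elif strand == "-":
            t = int(row["end"])
        else:
            raise ValueError(f"unknown strand {strand!r} for gene {row['gene']!r}")
        g = str(row["gene"])
        tss[g] = t
        chrom[g] = str(row["chrom"])
    records = {}
    for a, b in combinations(sorted(tss), 2):
        if chrom[a] != chrom[b]:
            continue
        records[canonical_pair(a, b)] = {"weight": float(abs(tss[a] - tss[b]))}
    return RelationshipTable(kind="SCGD", records=records)


def cocnv_status(cnv1: int, cnv2: int) -> tuple:
    """Joint copy-number status of an (ordered) gene pair in one sample.

    Returns ``(status, level_product)`` where status is GG/LL/GL/LG/NC and
    the level product is |cnv1·cnv2| (0 for NC).  NC whenever either gene is
    unmutated (call 0).
    """
    c1, c2 = int(cnv1), int(cnv2)
    for c in (c1, c2):
        if not -2 <= c <= 2:
            raise ValueError(f"CNV call {c} outside {{-2..2}}")
    if c1 == 0 or c2 == 0:
        return "NC", 0
    if c1 > 0:
        status = "GG" if c2 > 0 else "GL"
    else:
        status = "LG" if c2 > 0 else "LL"
    return status, abs(c1 * c2)


def cocnv_status_table(cnv: pd.DataFrame, pair_list) -> dict:
    """Per-pair, per-sample CoCNV statuses.

    ``cnv`` is a genes-by-samples integer matrix.  Statuses of each pair are
    computed in its canonical (sorted) gene order, so GL means the
    alphabetically first gene gained.  Returns pair -> DataFrame with
    columns ``status`` and ``level_product`` indexed by sample.
    """
    out = {}
    for pair in pair_list:
        a, b = canonical_pair(*pair)
        rows = []
        for s in cnv.columns:
            status, prod = cocnv_status(cnv.at[a, s], cnv.at[b, s])
            rows.append((status, prod))
        out[(a, b)] = pd.DataFrame(rows, index=cnv.columns,
                                   columns=["status", "level_product"])
    return out


def cocnv_table(cnv: pd.DataFrame, pair_list) -> dict:
    """CoCNV relationship tables, one per status type GG/LL/GL/LG.

    Per pair and type, weights are the raw sample count, the fraction of
    samples (count / n_samples), and the level-product-weighted count
    (sum of |cnv1·cnv2| over samples with that status).  Pairs never showing
    a status are absent from that table.
    """
    n_samples = cnv.shape[1]
    statuses = cocnv_status_table(cnv, pair_list)
    tables = {k: {} for k in COCNV_KINDS}
    for pair, df in statuses.items():
        for kind in COCNV_KINDS:
            mask = df["status"] == kind
            count = int(mask.sum())
            if count == 0:
                continue
            tables[kind][pair] = {
                "weight": float(count),
                "fraction": count / n_samples,
                "level_weighted": float(df.loc[mask, "level_product"].sum()),
            }
    return {k: RelationshipTable(kind=f"CoCNV-{k}", records=recs)
            for k, recs in tables.items()}


def dm_gene_counts(beta: pd.DataFrame, cpg_to_gene: pd.DataFrame,
                   low_thr: float = 0.3, high_thr: float = 0.7) -> tuple:
    """Per-gene, per-sample counts of low/high-methylation CpG islands.

    ``beta`` is CpG-island-by-sample with values in [0, 1]; ``cpg_to_gene``
    maps island identifiers to genes (columns ``cpg``, ``gene``).  An island
    is L if beta < ``low_thr`` and H if beta > ``high_thr``; intermediate
    islands count in neither.  Genes with no mapped island are absent (with
    a warning).  Returns ``(L_counts, H_counts)`` genes-by-samples frames.
    """
    if not (0 <= low_thr < high_thr <= 1):
        raise ValueError("need 0 <= low_thr < high_thr <= 1")
    vals = beta.to_numpy(dtype=float)
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("beta values outside [0, 1]")
    mapping = cpg_to_gene.astype(str)
    mapped = mapping[mapping["cpg"].isin(beta.index)]
    dropped = set(mapping["gene"]) - set(mapped["gene"])
    if dropped:
        logger.warning("genes with no mapped CpG island: %s", ", ".join(sorted(dropped)))
    low = (beta < low_thr).astype(int)
    high = (beta > high_thr).astype(int)
    groups = mapped.groupby("gene")["cpg"].apply(list)
    l_rows, h_rows = {}, {}
    for gene, islands in groups.items():
        l_rows[gene] = low.loc[islands].sum(axis=0)
        h_rows[gene] = high.loc[islands].sum(axis=0)
    l_df = pd.DataFrame(l_rows).T.reindex(columns=beta.columns)
    h_df = pd.DataFrame(h_rows).T.reindex(columns=beta.columns)
    return l_df, h_df


def codm_profile(counts1, counts2) -> tuple:
    """Cross products of two genes' (L, H) island counts: (LL, HH, LH, HL)."""
    l1, h1 = counts1
    l2, h2 = counts2
    return (l1 * l2, h1 * h2, l1 * h2, h1 * l2)


def codm_profile_table(l_counts: pd.DataFrame, h_counts: pd.DataFrame, pair_list) -> dict:
    """Per-pair, per-sample CoDM profiles.

    Returns pair -> DataFrame indexed by sample with columns LL, HH, LH, HL
    (cross products taken in the pair's canonical gene order).
    """
    out = {}
    for pair in pair_list:
        a, b = canonical_pair(*pair)
        ll, hh, lh, hl = codm_profile(
            (l_counts.loc[a].to_numpy(), h_counts.loc[a].to_numpy()),
            (l_counts.loc[b].to_numpy(), h_counts.loc[b].to_numpy()),
        )
        out[(a, b)] = pd.DataFrame(
            {"LL": ll, "HH": hh, "LH": lh, "HL": hl}, index=l_counts.columns)
    return out


def codm_table(l_counts: pd.DataFrame, h_counts: pd.DataFrame, pair_list) -> dict:
    """CoDM relationship tables, one per value LL/HH/LH/HL.

    Per pair and value, weights are the count of samples with a positive
    value, the fraction of samples, and the summed value over samples.
    Pairs whose value is 0 in every sample are absent from that table.
    """
    profiles = codm_profile_table(l_counts, h_counts, pair_list)
    n_samples = l_counts.shape[1]
    tables = {v: {} for v in CODM_VALUES}
    for pair, df in profiles.items():
        for v in CODM_VALUES:
            col = df[v]
            count = int((col > 0).sum())
            if count == 0:
                continue
            tables[v][pair] = {
                "weight": float(count),
                "fraction": count / n_samples,
                "value_sum": float(col.sum()),
            }
    return {v: RelationshipTable(kind=f"CoDM-{v}", records=recs)
            for v, recs in tables.items()}
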