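"""Readers and writers for the pipeline's tabular formats.

TSV with a header row is the lingua franca throughout; gene coordinates are
BED-dialect (0-based half-open); networks export as edge-list TSV and SIF
("geneA pp geneB") for Cytoscape.  Gene pairs are always emitted in
canonical (sorted) order.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from pminet.change import ChangeNetwork, pattern_str
from pminet.network import Network

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_expression", "write_expression", "read_cnv", "read_beta",
    "read_cpg_map", "read_coords", "read_clinical", "read_pairs", "read_tr",
    "write_edges_tsv", "read_edges_tsv", "write_sif",
    "write_change_network", "write_relationships", "write_recall_report",
]


@dataclass
class RunConfig:
    """Parameters of one pipeline run; round-trips through JSON."""

    n_bins: int = 3
    scheme: str = "equal_frequency"
    threshold_grid: list = field(default_factory=lambda: [0.02, 0.04, 0.06, 0.08, 0.1, 0.15, 0.2, 0.25, 0.3])
    stability_tol: float = 0.95
    max_order: int = 1
    beta_low: float = 0.3
    beta_high: float = 0.7
    nmad_thr: float = 0.25
    min_group_n: int = 20
    alpha: float = 0.05
    n_perm: int = 100
    seed: int = 0

    def __post_init__(self):
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")
        if not (0 <= self.beta_low < self.beta_high <= 1):
            raise ValueError("beta thresholds must satisfy 0 <= low < high <= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if list(self.threshold_grid) != sorted(self.threshold_grid):
            raise ValueError("threshold grid must be ascending")

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        return cls(**json.loads(Path(path).read_text()))


def _read_matrix(path, dtype=float) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique()
        raise ValueError(f"duplicate row identifiers: {list(dups)}")
    if df.columns.has_duplicates:
        raise ValueError("duplicate column identifiers")
    try:
        df = df.astype(dtype)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cells in {path}: {exc}") from exc
    if df.isna().any().any():
        raise ValueError(f"missing values in {path}")
    logger.info("read %s: %d rows x %d columns", path, *df.shape)
    return df


def read_expression(path) -> pd.DataFrame:
    """Genes-by-samples expression matrix from TSV."""
    return _read_matrix(path, float)


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene")


def read_cnv(path) -> pd.DataFrame:
    """Gene-level integer CNV calls in {-2..2} from TSV."""
    df = _read_matrix(path, int)
    if not df.isin([-2, -1, 0, 1, 2]).all().all():
        raise ValueError("CNV calls outside {-2..2}")
    return df


def read_beta(path) -> pd.DataFrame:
    """CpG-island-by-sample methylation beta matrix from TSV."""
    df = _read_matrix(path, float)
    vals = df.to_numpy()
    if np.any((vals < 0) | (vals > 1)):
        raise ValueError("beta values outside [0, 1]")
    return df


def read_cpg_map(path) -> pd.DataFrame:
    """Two-column CpG-island-to-gene mapping (columns cpg, gene)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"cpg", "gene"} <= set(df.columns):
        raise ValueError("CpG map needs columns 'cpg' and 'gene'")
    return df


def read_coords(path) -> pd.DataFrame:
    """BED-like gene coordinate table (chrom, start, end, gene, strand)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "gene": str, "strand": str})
    needed = {"chrom", "start", "end", "gene", "strand"}
    if not needed <= set(df.columns):
        raise ValueError(f"coordinate table needs columns {sorted(needed)}")
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]]["gene"].tolist()
        raise ValueError(f"malformed intervals (start >= end) for genes {bad}")
    if df["gene"].duplicated().any():
        raise ValueError("duplicate gene entries in coordinates")
    return df


def read_clinical(path) -> pd.DataFrame:
    """Clinical table indexed by sample with time, event and covariates."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not {"time", "event"} <= set(df.columns):
        raise ValueError("clinical table needs 'time' and 'event' columns")
    if df.index.has_duplicates:
        raise ValueError("duplicate sample identifiers")
    if (df["time"] < 0).any() or not df["event"].isin([0, 1]).all():
        raise ValueError("invalid time/event values")
    return df


def read_pairs(path) -> list:
    """Two-column TSV of gene pairs, canonicalized."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    a_col, b_col = df.columns[:2]
    return [tuple(sorted((str(r[a_col]), str(r[b_col])))) for _, r in df.iterrows()]


def read_tr(path) -> pd.DataFrame:
    """Transcription-regulation edge list (regulator, class, target)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"regulator", "class", "target"} <= set(df.columns):
        raise ValueError("TR table needs columns regulator, class, target")
    return df


def write_edges_tsv(net: Network, path) -> None:
    """Edge list TSV: geneA, geneB, strength, method, threshold."""
    rows = [{"geneA": a, "geneB": b, "strength": s,
             "method": net.meta.get("method", ""),
             "threshold": net.meta.get("threshold", "")}
            for (a, b), s in sorted(net.edges.items())]
    pd.DataFrame(rows, columns=["geneA", "geneB", "strength", "method", "threshold"]) \
        .to_csv(path, sep="\t", index=False)


def read_edges_tsv(path) -> Network:
    df = pd.read_csv(path, sep="\t", dtype={"geneA": str, "geneB": str})
    edges = {tuple(sorted((r["geneA"], r["geneB"]))): float(r["strength"])
             for _, r in df.iterrows()}
    genes = tuple(sorted({g for pair in edges for g in pair}))
    meta = {}
    if len(df) and "method" in df.columns:
        meta["method"] = df["method"].iloc[0]
    return Network(genes=genes, edges=edges, meta=meta)


def write_sif(net: Network, path) -> None:
    """Cytoscape SIF: one "geneA pp geneB" line per edge."""
    lines = [f"{a} pp {b}" for (a, b) in sorted(net.edges)]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


_PATTERN_COLORS = {
    (1, 1, 1, 1): "black", (0, 1, 1, 1): "black",
    (1, 0, 0, 0): "blue", (0, 1, 0, 0): "green",
    (0, 0, 1, 0): "yellow", (0, 0, 0, 1): "red",
}


def write_change_network(cn: ChangeNetwork, prefix) -> None:
    """Write edge patterns (TSV), node mean stages (TSV) and a colored SIF."""
    from pminet.change import mean_stage_value

    prefix = Path(prefix)
    rows = [{"geneA": a, "geneB": b, "pattern": pattern_str(bits)}
            for (a, b), bits in sorted(cn.edges.items())]
    pd.DataFrame(rows, columns=["geneA", "geneB", "pattern"]) \
        .to_csv(prefix.with_suffix(".edges.tsv"), sep="\t", index=False)
    genes = sorted({g for pair in cn.edges for g in pair})
    node_rows = [{"gene": g, "mean_stage": mean_stage_value(cn, g)} for g in genes]
    pd.DataFrame(node_rows, columns=["gene", "mean_stage"]) \
        .to_csv(prefix.with_suffix(".nodes.tsv"), sep="\t", index=False)
    sif_lines = []
    for (a, b), bits in sorted(cn.edges.items()):
        color = _PATTERN_COLORS.get(tuple(bits), "grey")
        sif_lines.append(f"{a} pp {b}\t{color}")
    prefix.with_suffix(".sif").write_text("\n".join(sif_lines) + ("\n" if sif_lines else ""))


def write_relationships(tables, path) -> None:
    """Unified relationship TSV (geneA, geneB, kind, weight columns)."""
    rows = []
    for table in tables:
        for (a, b), weights in sorted(table.records.items()):
            row = {"geneA": a, "geneB": b, "kind": table.kind}
            row.update(weights)
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_recall_report(results, path) -> None:
    """Per-network recall summary TSV (kind, recall count, Z variants)."""
    rows = []
    for res in results:
        row = {"network": res.network_tag, "kind": res.kind,
               "recall_count": res.recall_count, "n_perm": res.n_perm}
        for variant, z in res.zscores.items():
            row[f"Z_{variant}"] = z
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
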