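"""Synthetic multi-omics data with known ground truth.

Every pipeline input can be generated here so each stage is testable
without cohort downloads: expression matrices sampled from a known directed
linear-Gaussian cascade (so direct and indirect correlations are planted by
construction), staged variants of the same graph, GISTIC-style copy-number
matrices with controllable pair co-gain/co-loss rates, CpG-island beta
matrices with per-gene low/mid/high mixture weights, and exponential
survival times whose hazard depends on planted pair statuses.

The linear-Gaussian structural model is deliberate: path correlations have
closed forms (the product of edge correlations along a chain), which gives
independent oracles for the network-recovery tests.  A quadratic link
option exists to exercise detection of non-monotonic dependence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from pminet.network import canonical_pair

__all__ = [
    "GroundTruth", "random_dag",
    "simulate_expression", "simulate_staged", "simulate_cnv",
    "simulate_dm", "simulate_survival",
]


@dataclass
class GroundTruth:
    """What was planted: the generative graph and per-omics pair effects."""

    true_direct_edges: frozenset
    graph: list = field(default_factory=list)     # (parent, child, coefficient)
    noise_sd: float = 0.5
    planted_relationships: dict = field(default_factory=dict)
    planted_survival_effects: dict = field(default_factory=dict)

    def __post_init__(self):
        for mult in self.planted_survival_effects.values():
            if isinstance(mult, dict):
                if any(m <= 0 for m in mult.values()):
                    raise ValueError("hazard multipliers must be > 0")
            elif mult <= 0:
                raise ValueError("hazard multipliers must be > 0")


def random_dag(n_genes: int, n_edges: int, seed=None, coefficient: float = 1.0):
    """Random DAG over ``n_genes`` gene names with ``n_edges`` directed edges.

    Genes are ordered g00, g01, ...; edges point from lower to higher index
    in a random permutation, guaranteeing acyclicity.
    """
    rng = np.random.default_rng(seed)
    genes = [f"g{i:02d}" for i in range(n_genes)]
    order = rng.permutation(n_genes)
    candidates = [(int(order[i]), int(order[j]))
                  for i in range(n_genes) for j in range(i + 1, n_genes)]
    if n_edges > len(candidates):
        raise ValueError("too many edges for the gene count")
    chosen = rng.choice(len(candidates), size=n_edges, replace=False)
    edges = [(genes[candidates[k][0]], genes[candidates[k][1]], coefficient)
             for k in sorted(chosen)]
    return genes, edges


def _topological(genes, edges):
    parents: dict = {g: [] for g in genes}
    for p, c, w in edges:
        parents[c].append((p, w))
    done, order = set(), []
    while len(order) < len(genes):
        progressed = False
        for g in genes:
            if g in done:
                continue
            if all(p in done for p, _ in parents[g]):
                order.append(g)
                done.add(g)
                progressed = True
        if not progressed:
            raise ValueError("graph contains a cycle")
    return order, parents


def simulate_expression(genes, edges, n_samples: int, noise_sd: float = 0.5,
                        seed=None, link: str = "linear"):
    """Sample an expression matrix from a directed cascade.

    Each root gene is N(0, 1); each child is the coefficient-weighted sum of
    its parents (or of their squares for ``link="quadratic"``) plus
    N(0, noise_sd²) noise, sampled in topological order.  Returns the
    genes-by-samples DataFrame and the :class:`GroundTruth` holding the true
    direct edge set.
    """
    rng = np.random.default_rng(seed)
    order, parents = _topological(genes, edges)
    data = {}
    for g in order:
        if not parents[g]:
            data[g] = rng.normal(0.0, 1.0, n_samples)
        else:
            acc = rng.normal(0.0, noise_sd, n_samples)
            for p, w in parents[g]:
                contrib = data[p] ** 2 if link == "quadratic" else data[p]
                acc = acc + w * contrib
            data[g] = acc
    expr = pd.DataFrame({g: data[g] for g in genes}).T
    expr.columns = [f"s{i:03d}" for i in range(n_samples)]
    truth = GroundTruth(
        true_direct_edges=frozenset(canonical_pair(p, c) for p, c, _ in edges),
        graph=list(edges), noise_sd=noise_sd)
    return expr, truth


def simulate_staged(genes, edges, stage_edge_masks, n_per_stage: int,
                    noise_sd: float = 0.5, seed=None):
    """Four stage-wise expression matrices from one base graph.

    ``stage_edge_masks`` is a sequence of four boolean masks over ``edges``;
    stage i is generated from the base graph restricted to mask i, with a
    per-stage seed derived deterministically from ``seed``.
    """
    masks = list(stage_edge_masks)
    if len(masks) != 4:
        raise ValueError("need exactly 4 stage masks")
    rng = np.random.default_rng(seed)
    stage_seeds = rng.integers(0, 2**31 - 1, size=4)
    out = []
    for mask, s in zip(masks, stage_seeds):
        active = [e for e, keep in zip(edges, mask) if keep]
        expr, truth = simulate_expression(genes, active, n_per_stage,
                                          noise_sd=noise_sd, seed=int(s))
        out.append((expr, truth))
    return out


def simulate_cnv(genes, n_samples: int, pair_comutation_spec: dict | None = None,
                 background_rate: float = 0.05, seed=None):
    """GISTIC-style CNV call matrix with planted pair co-mutation.

    ``pair_comutation_spec`` maps gene pairs to ``{status: rate}`` dicts
    (statuses GG/LL/GL/LG); in each sample the pair takes one planted status
    with the stated probability (levels drawn from {1, 2} with sign by
    status) and is otherwise left to independent background mutations, each
    gene mutated with ``background_rate`` to a uniform call in
    {-2, -1, +1, +2}.  Returns the genes-by-samples integer DataFrame and
    ground truth.
    """
    rng = np.random.default_rng(seed)
    genes = list(genes)
    samples = [f"s{i:03d}" for i in range(n_samples)]
    gi = {g: k for k, g in enumerate(genes)}
    mat = np.zeros((len(genes), n_samples), dtype=int)
    background = rng.random((len(genes), n_samples)) < background_rate
    calls = rng.choice([-2, -1, 1, 2], size=(len(genes), n_samples))
    mat[background] = calls[background]

    spec = pair_comutation_spec or {}
    signs = {"GG": (1, 1), "LL": (-1, -1), "GL": (1, -1), "LG": (-1, 1)}
    for pair, rates in spec.items():
        a, b = canonical_pair(*pair)
        total = sum(rates.values())
        if total > 1:
            raise ValueError(f"co-mutation rates for {pair} exceed 1")
        u = rng.random(n_samples)
        lo = 0.0
        for status, rate in rates.items():
            sa, sb = signs[status]
            hit = (u >= lo) & (u < lo + rate)
            lvls_a = rng.choice([1, 2], size=n_samples)
            lvls_b = rng.choice([1, 2], size=n_samples)
            mat[gi[a], hit] = sa * lvls_a[hit]
            mat[gi[b], hit] = sb * lvls_b[hit]
            lo += rate
    cnv = pd.DataFrame(mat, index=genes, columns=samples)
    truth = GroundTruth(true_direct_edges=frozenset(),
                        planted_relationships={"CoCNV": dict(spec)})
    return cnv, truth


def simulate_dm(genes, islands_per_gene: int, n_samples: int,
                gene_mixture: dict | None = None, seed=None):
    """Beta-value matrix over CpG islands plus the island-to-gene mapping.

    Each island's beta is drawn per sample from one of three uniform
    components — low [0, 0.25], mid [0.35, 0.65], high [0.75, 1] — with
    per-gene mixture weights (``gene_mixture``: gene -> (w_low, w_mid,
    w_high); default uniform thirds).
    """
    rng = np.random.default_rng(seed)
    samples = [f"s{i:03d}" for i in range(n_samples)]
    rows, mapping = [], []
    bounds = [(0.0, 0.25), (0.35, 0.65), (0.75, 1.0)]
    for g in genes:
        w = np.asarray((gene_mixture or {}).get(g, (1 / 3, 1 / 3, 1 / 3)), dtype=float)
        w = w / w.sum()
        for k in range(islands_per_gene):
            island = f"cg_{g}_{k}"
            comp = rng.choice(3, size=n_samples, p=w)
            lo = np.array([bounds[c][0] for c in comp])
            hi = np.array([bounds[c][1] for c in comp])
            rows.append(pd.Series(rng.uniform(lo, hi), index=samples, name=island))
            mapping.append({"cpg": island, "gene": g})
    beta = pd.DataFrame(rows)
    return beta, pd.DataFrame(mapping)


def simulate_survival(statuses: pd.DataFrame | None = None,
                      effect_spec: dict | None = None,
                      baseline_hazard: float = 0.01,
                      censor_rate: float = 0.2, seed=None,
                      hazard_multipliers: pd.Series | None = None,
                      covariates: pd.DataFrame | None = None) -> pd.DataFrame:
    """Exponential survival times with planted status-dependent hazards.

    Per-sample hazard = ``baseline_hazard`` × the product of the multipliers
    for the sample's statuses (``statuses``: samples-by-columns of status
    strings; ``effect_spec``: column -> {status: multiplier}); alternatively
    pass precomputed ``hazard_multipliers`` directly.  Each sample is
    independently censored with probability ``censor_rate`` at a uniform
    fraction of its event time.  Optional ``covariates`` columns are joined
    onto the output clinical table (time, event, ...).
    """
    rng = np.random.default_rng(seed)
    if hazard_multipliers is None:
        if statuses is None:
            raise ValueError("need statuses+effect_spec or hazard_multipliers")
        hazard_multipliers = pd.Series(1.0, index=statuses.index)
        for col, effects in (effect_spec or {}).items():
            hazard_multipliers *= statuses[col].map(lambda s: effects.get(s, 1.0))
    hz = baseline_hazard * hazard_multipliers.astype(float)
    if (hz <= 0).any():
        raise ValueError("nonpositive hazards")
    times = rng.exponential(1.0 / hz.to_numpy())
    censored = rng.random(len(hz)) < censor_rate
    obs = np.where(censored, times * rng.random(len(hz)), times)
    clinical = pd.DataFrame({"time": obs, "event": (~censored).astype(int)},
                            index=hz.index)
    if covariates is not None:
        clinical = clinical.join(covariates)
    return clinical
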