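"""Correlation change networks across a four-stage disease progression.

Single-stage networks (normal plus three cancer stages, stage numbers 1–4)
are combined into one union network.  Each edge carries a 4-bit *existence
pattern* — e.g. ``0-1-1-1`` for an edge present in all three cancer stages
but not in normal tissue.  Each node carries a *mean stage value*: the
average of the stage numbers over all of its (edge, stage) incidences, which
places a gene early or late along the progression.  Edges whose stage bits
do not form one contiguous run (e.g. ``1-0-1-0``) are treated as unstable
and can be filtered out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from pminet.network import Network

__all__ = ["ChangeNetwork", "combine_stages", "filter_inconsecutive",
           "mean_stage_value", "pattern_str"]

N_STAGES = 4
STAGE_LABELS = ("normal", "s1", "s2", "s3")


def pattern_str(bits) -> str:
    """Render a 4-bit existence pattern as ``a-b-c-d``."""
    return "-".join(str(int(b)) for b in bits)


@dataclass
class ChangeNetwork:
    """Union network over 4 stages with per-edge existence patterns."""

    stages: tuple = STAGE_LABELS
    edges: dict = field(default_factory=dict)   # pair -> tuple of 4 ints
    genes: tuple = ()

    def __post_init__(self):
        for pair, bits in self.edges.items():
            if len(bits) != N_STAGES or not any(bits):
                raise ValueError(f"invalid existence pattern for {pair}: {bits}")


def combine_stages(stage_nets) -> ChangeNetwork:
    """Combine exactly 4 single-stage networks into a change network.

    Pattern bit i of an edge is set iff the edge exists in the stage-(i+1)
    network.  All stage networks must share one gene universe.
    """
    nets = list(stage_nets)
    if len(nets) != N_STAGES:
        raise ValueError(f"expected {N_STAGES} stage networks, got {len(nets)}")
    universe = nets[0].genes
    for net in nets[1:]:
        if net.genes != universe:
            raise ValueError("stage networks have mismatched gene universes")
    all_pairs = set()
    for net in nets:
        all_pairs.update(net.edge_set)
    edges = {}
    for pair in sorted(all_pairs):
        edges[pair] = tuple(int(pair in net.edges) for net in nets)
    return ChangeNetwork(edges=edges, genes=universe)


def filter_inconsecutive(cn: ChangeNetwork) -> ChangeNetwork:
    """Drop edges whose set stage bits do not form one contiguous run."""
    def consecutive(bits) -> bool:
        on = [i for i, b in enumerate(bits) if b]
        return on == list(range(on[0], on[-1] + 1))
    kept = {pair: bits for pair, bits in cn.edges.items() if consecutive(bits)}
    return ChangeNetwork(stages=cn.stages, edges=kept, genes=cn.genes)


def mean_stage_value(cn: ChangeNetwork, gene: str) -> float:
    """Average stage number over every (edge, stage) incidence of ``gene``.

    An edge present in stages 1 and 2 contributes the numbers 1 and 2; a
    gene with no edges has no defined mean stage value.
    """
    stage_numbers = []
    for (a, b), bits in cn.edges.items():
        if gene in (a, b):
            stage_numbers.extend(i + 1 for i, bit in enumerate(bits) if bit)
    if not stage_numbers:
        raise ValueError(f"gene {gene!r} has no edges in the change network")
    return sum(stage_numbers) / len(stage_numbers)
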