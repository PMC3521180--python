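"""Tissue-specific networks by expression filtering, and their analytics.

A tissue network (TTN, or eTTN when derived from the expanded reference
network) is the induced subnetwork on the genes expressed in that tissue: an
edge survives only if both the regulator and the target are expressed.
Analytics cover tissue breadth (in how many tissue networks a TF is active),
the degree/count inflation caused by paralogous expansion, and the TF versus
nonTF in-degree contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple

import networkx as nx

from .network_build import RegulatoryNetwork

__all__ = [
    "DEFAULT_TISSUES",
    "ExpressionTable",
    "filter_tissue",
    "tissue_breadth",
    "breadth_split",
    "ExpansionRatios",
    "expansion_ratios",
    "tf_vs_nontf_indegree",
]

#: the eight tissues of the reference expression panel
DEFAULT_TISSUES = (
    "brain", "heart", "kidney", "liver", "ovary", "prostate", "spleen",
    "testis",
)


@dataclass
class ExpressionTable:
    """Binary presence/absence of genes per tissue."""

    tissues: tuple[str, ...]
    expressed: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self):
        if len(set(self.tissues)) != len(self.tissues):
            raise ValueError("tissue labels must be unique")
        for t in self.tissues:
            self.expressed.setdefault(t, set())
        unknown = set(self.expressed) - set(self.tissues)
        if unknown:
            raise ValueError(f"expression sets for unknown tissues {unknown}")

    def genes(self) -> set[str]:
        out: set[str] = set()
        for s in self.expressed.values():
            out |= s
        return out

    def tissues_of(self, gene: str) -> set[str]:
        return {t for t, s in self.expressed.items() if gene in s}


def filter_tissue(
    network: RegulatoryNetwork, expressed: set[str]
) -> RegulatoryNetwork:
    """Induced subnetwork on the expressed genes.

    An edge is kept iff both endpoints are expressed; unexpressed nodes are
    dropped entirely.  Monotone in the expressed set and idempotent.
    """
    sub = network.graph.subgraph(
        n for n in network.graph if n in expressed
    ).copy()
    return RegulatoryNetwork(nx.DiGraph(sub))


def tissue_breadth(
    networks: Mapping[str, RegulatoryNetwork],
    *,
    presence: str = "active",
) -> dict[str, int]:
    """Number of tissue networks in which each TF appears.

    By default a TF counts in a tissue only when *active* there (out-degree
    > 0); ``presence="node"`` counts mere node membership.  TFs appearing in
    no tissue network are absent from the result.
    """
    if not networks:
        raise ValueError("at least one tissue network is required")
    if presence not in ("active", "node"):
        raise ValueError(f"presence must be 'active' or 'node', got {presence!r}")
    counts: dict[str, int] = {}
    for net in networks.values():
        tfs = net.active_tfs if presence == "active" else net.tf_nodes
        for tf in tfs:
            counts[tf] = counts.get(tf, 0) + 1
    return counts


def breadth_split(
    breadth: Mapping[str, int], original_tfs: set[str]
) -> tuple[dict[str, int], dict[str, int]]:
    """Split a breadth table into original-network TFs and expansion-added
    TFs (the blue/yellow contrast of the tissue-distribution analysis)."""
    original = {t: b for t, b in breadth.items() if t in original_tfs}
    added = {t: b for t, b in breadth.items() if t not in original_tfs}
    return original, added


class ExpansionRatios(NamedTuple):
    """eTTN-over-TTN ratios; NaN where the TTN-side quantity is zero."""

    tf_out_ratio: float
    tf_in_ratio: float
    nontf_in_ratio: float
    tf_count_ratio: float
    edge_count_ratio: float


def _mean(values: list[int]) -> float:
    return sum(values) / len(values) if values else math.nan


def _mean_degrees(net: RegulatoryNetwork) -> tuple[float, float, float]:
    g = net.graph
    tfs = sorted(net.tf_nodes)
    nontfs = sorted(net.nontf_nodes)
    return (
        _mean([g.out_degree(n) for n in tfs]),
        _mean([g.in_degree(n) for n in tfs]),
        _mean([g.in_degree(n) for n in nontfs]),
    )


def expansion_ratios(
    ttn: RegulatoryNetwork, ettn: RegulatoryNetwork
) -> ExpansionRatios:
    """How much expansion inflates one tissue network.

    Ratios of the mean TF out-degree, mean TF in-degree and mean nonTF
    in-degree, plus TF-count and edge-count ratios, expanded over
    non-expanded."""
    t_out, t_in, n_in = _mean_degrees(ttn)
    e_out, e_in, en_in = _mean_degrees(ettn)

    def ratio(num: float, denom: float) -> float:
        if math.isnan(denom) or math.isnan(num):
            return math.nan
        if denom == 0:
            # unchanged degenerate quantity (0 -> 0) is a unit ratio;
            # growth out of nothing is undefined
            return 1.0 if num == 0 else math.nan
        return num / denom

    return ExpansionRatios(
        tf_out_ratio=ratio(e_out, t_out),
        tf_in_ratio=ratio(e_in, t_in),
        nontf_in_ratio=ratio(en_in, n_in),
        tf_count_ratio=ratio(len(ettn.tf_nodes), len(ttn.tf_nodes)),
        edge_count_ratio=ratio(ettn.n_edges(), ttn.n_edges()),
    )


def tf_vs_nontf_indegree(
    network: RegulatoryNetwork,
) -> tuple[float, float, float]:
    """Mean in-degree of TF nodes, of nonTF nodes, and their ratio
    (TF over nonTF); NaN components where a class is empty."""
    g = network.graph
    tf_in = _mean([g.in_degree(n) for n in network.tf_nodes])
    nontf_in = _mean([g.in_degree(n) for n in network.nontf_nodes])
    if math.isnan(tf_in) or math.isnan(nontf_in) or nontf_in == 0:
        return tf_in, nontf_in, math.nan
    return tf_in, nontf_in, tf_in / nontf_in
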