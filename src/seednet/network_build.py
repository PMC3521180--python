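"""TF-target network construction and paralogous expansion.

Matrix hits in promoters are translated into directed TF-gene -> target-gene
edges, giving the reference transcriptional network (RTN).  Because only a
subset of TFs has a characterised binding matrix, the network is then
expanded: within each bottommost clade of a DNA-binding-domain classification
(family or subfamily), the union of the matrix-bearing members' direct target
sets is copied to every other clade member, on the rationale that nearly
identical DNA-binding domains imply nearly identical binding specificity.
The expanded network is the eRTN; copied edges carry ``expanded`` provenance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable

import networkx as nx

from .conservation import ConservedSite

__all__ = [
    "TF",
    "NONTF",
    "DIRECT",
    "EXPANDED",
    "TFClassification",
    "RegulatoryNetwork",
    "matrix_to_tf_genes",
    "build_rtn",
    "expand_paralogous",
    "cross_validate_expansion",
]

TF = "TF"
NONTF = "nonTF"
DIRECT = "direct"
EXPANDED = "expanded"


@dataclass
class TFClassification:
    """Hierarchical TF classification by DNA-binding domain.

    ``clades`` maps a bottommost clade identifier (its level path, e.g.
    ``"1.2.3.4"``) to the gene symbols of its members; every TF gene belongs
    to exactly one bottommost clade.  ``matrix_assoc`` records which matrices
    (if any) are associated with each gene.
    """

    clades: dict[str, tuple[str, ...]]
    matrix_assoc: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for clade, genes in self.clades.items():
            if not genes:
                raise ValueError(f"clade {clade!r} is empty")
            for g in genes:
                if g in seen:
                    raise ValueError(
                        f"gene {g!r} appears in clades {seen[g]!r} and {clade!r}"
                    )
                seen[g] = clade
        self._clade_of = seen

    def clade_of(self, gene: str) -> str | None:
        return self._clade_of.get(gene)

    def matrices_of(self, gene: str) -> frozenset[str]:
        return self.matrix_assoc.get(gene, frozenset())


class RegulatoryNetwork:
    """Directed TF -> target network over gene symbols.

    Thin wrapper around a :class:`networkx.DiGraph`.  Nodes carry a ``kind``
    attribute (``TF`` or ``nonTF``); edges are deduplicated at the gene level
    and carry ``provenance`` (``direct`` or ``expanded``), the supporting
    matrix ids, and ``n_sites``, the number of binding sites behind the edge.
    """

    def __init__(self, graph: nx.DiGraph | None = None):
        self.graph = graph if graph is not None else nx.DiGraph()

    # -- construction -----------------------------------------------------
    def add_node(self, gene: str, kind: str) -> None:
        if kind not in (TF, NONTF):
            raise ValueError(f"node kind must be TF or nonTF, got {kind!r}")
        prev = self.graph.nodes[gene]["kind"] if gene in self.graph else None
        # TF label wins: a gene ever seen as a regulator stays a TF
        self.graph.add_node(gene, kind=TF if TF in (prev, kind) else NONTF)

    def add_edge(
        self,
        tf: str,
        target: str,
        *,
        provenance: str,
        matrices: Iterable[str] = (),
        n_sites: int = 1,
    ) -> None:
        self.add_node(tf, TF)
        if target not in self.graph:
            self.add_node(target, NONTF)
        if self.graph.has_edge(tf, target):
            data = self.graph.edges[tf, target]
            data["matrices"] = data["matrices"] | frozenset(matrices)
            data["n_sites"] += n_sites
            if provenance == DIRECT:
                data["provenance"] = DIRECT  # never downgraded
        else:
            self.graph.add_edge(
                tf,
                target,
                provenance=provenance,
                matrices=frozenset(matrices),
                n_sites=n_sites,
            )

    # -- queries -----------------------------------------------------------
    def nodes_of_kind(self, kind: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if d["kind"] == kind}

    @property
    def tf_nodes(self) -> set[str]:
        return self.nodes_of_kind(TF)

    @property
    def nontf_nodes(self) -> set[str]:
        return self.nodes_of_kind(NONTF)

    @property
    def active_tfs(self) -> set[str]:
        """TFs with out-degree > 0."""
        return {n for n in self.tf_nodes if self.graph.out_degree(n) > 0}

    def edges(self, provenance: str | None = None) -> set[tuple[str, str]]:
        if provenance is None:
            return set(self.graph.edges())
        return {
            (u, v)
            for u, v, p in self.graph.edges(data="provenance")
            if p == provenance
        }

    def targets_of(self, tf: str, provenance: str | None = None) -> set[str]:
        if tf not in self.graph:
            return set()
        out = set()
        for _, v, p in self.graph.out_edges(tf, data="provenance"):
            if provenance is None or p == provenance:
                out.add(v)
        return out

    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def copy(self) -> "RegulatoryNetwork":
        return RegulatoryNetwork(self.graph.copy())

    def __eq__(self, other) -> bool:
        if not isinstance(other, RegulatoryNetwork):
            return NotImplemented
        return (
            dict(self.graph.nodes(data=True)) == dict(other.graph.nodes(data=True))
            and {(u, v): d for u, v, d in self.graph.edges(data=True)}
            == {(u, v): d for u, v, d in other.graph.edges(data=True)}
        )


def matrix_to_tf_genes(matrix_id: str, library) -> set[str]:
    """Human gene symbols a matrix stands for (may be empty for matrices
    built from non-human factors only)."""
    try:
        matrix = library[matrix_id]
    except KeyError:
        raise KeyError(f"unknown matrix {matrix_id!r}") from None
    return set(matrix.tf_genes)


def build_rtn(
    sites: Iterable[ConservedSite],
    annotation,
    library,
) -> RegulatoryNetwork:
    """Build the reference network from a site profile.

    Every conserved site of matrix m in a promoter of gene g contributes the
    edge tf -> g for each TF gene of m, with ``direct`` provenance.  Multiple
    promoters of one gene and multiple sites collapse onto one edge whose
    ``n_sites`` counts the support.
    """
    net = RegulatoryNetwork()
    for site in sites:
        gene = annotation.gene_of(site.promoter_id)
        tfs = matrix_to_tf_genes(site.matrix_id, library)
        for tf in sorted(tfs):
            net.add_edge(
                tf,
                gene,
                provenance=DIRECT,
                matrices=[site.matrix_id],
                n_sites=1,
            )
        if gene not in net.graph:
            net.add_node(gene, annotation.kind_of(gene))
    # label target genes that the annotation knows to be TFs
    for gene in list(net.graph.nodes):
        if annotation.kind_of(gene) == TF:
            net.add_node(gene, TF)
    return net


def expand_paralogous(
    network: RegulatoryNetwork, classification: TFClassification
) -> RegulatoryNetwork:
    """Copy direct target sets across bottommost clades (eRTN).

    For every clade, the union of the direct target sets of its
    matrix-bearing members is granted to every member; newly created edges
    carry ``expanded`` provenance, existing direct edges are untouched.
    The operation is idempotent and never removes edges.
    """
    out = network.copy()
    unclassified = [
        tf
        for tf in sorted(network.active_tfs)
        if network.targets_of(tf, DIRECT)
        and classification.clade_of(tf) is None
    ]
    if unclassified:
        warnings.warn(
            f"TFs absent from the classification pass through unexpanded: "
            f"{unclassified}",
            stacklevel=2,
        )
    for clade in sorted(classification.clades):
        members = classification.clades[clade]
        bearing = [m for m in members if classification.matrices_of(m)]
        union: set[str] = set()
        matrices: set[str] = set()
        for m in bearing:
            union |= network.targets_of(m, DIRECT)
            for _, _, d in network.graph.out_edges(m, data=True):
                matrices |= d["matrices"]
        if not union:
            continue
        for member in members:
            for target in sorted(union):
                if not out.graph.has_edge(member, target):
                    out.add_edge(
                        member,
                        target,
                        provenance=EXPANDED,
                        matrices=matrices,
                        n_sites=0,
                    )
    return out


def cross_validate_expansion(
    network: RegulatoryNetwork, classification: TFClassification
) -> dict[str, float]:
    """Per-clade agreement of independently characterised members.

    For every clade with at least two matrix-bearing members, the mean
    pairwise Jaccard index of those members' direct target sets: 1.0 means
    the members are interchangeable, 0.0 that expansion would conflate
    factors with disjoint targets.
    """
    report: dict[str, float] = {}
    for clade, members in classification.clades.items():
        bearing = [m for m in members if classification.matrices_of(m)]
        if len(bearing) < 2:
            continue
        jaccards = []
        for a, b in combinations(bearing, 2):
            ta = network.targets_of(a, DIRECT)
            tb = network.targets_of(b, DIRECT)
            denom = len(ta | tb)
            jaccards.append(len(ta & tb) / denom if denom else 1.0)
        report[clade] = sum(jaccards) / len(jaccards)
    return report
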