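"""Degree-distribution characterisation of regulatory networks.

Out-degrees span several orders of magnitude while each degree class is
sparsely populated, so distributions are summarised by the inverse cumulative
distribution F(d) = fraction of nodes with degree >= d.  An exponentially
decaying degree distribution appears as a straight line in a semi-log plot;
the slope and Pearson correlation of that line quantify how well the network
follows an exponential law.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .network_build import RegulatoryNetwork

__all__ = [
    "DegreeDistribution",
    "ExponentialFit",
    "degree_sequences",
    "inverse_cumulative",
    "semilog_fit",
    "network_shares",
]


def degree_sequences(network: RegulatoryNetwork) -> dict[str, list[int]]:
    """Per-class degree lists.

    ``tf_out``: out-degrees of TF nodes; ``all_in``: in-degrees of every
    node; ``tf_in`` / ``nontf_in``: the same split by node class.
    """
    g = network.graph
    tfs = sorted(network.tf_nodes)
    nontfs = sorted(network.nontf_nodes)
    return {
        "tf_out": [g.out_degree(n) for n in tfs],
        "tf_in": [g.in_degree(n) for n in tfs],
        "nontf_in": [g.in_degree(n) for n in nontfs],
        "all_in": [g.in_degree(n) for n in sorted(g.nodes)],
    }


@dataclass
class DegreeDistribution:
    """Inverse cumulative degree distribution.

    ``degrees`` holds the observed degree values d >= 1 in increasing order
    and ``cumfreq`` the matching F(d).  ``n`` is the denominator: by default
    all nodes, including zero-degree ones, so that F(1) is the fraction of
    nodes with any degree at all.
    """

    degrees: np.ndarray
    cumfreq: np.ndarray
    n: int
    label: str = ""


def inverse_cumulative(
    degrees: list[int] | np.ndarray,
    *,
    positive_only_denominator: bool = False,
    as_counts: bool = False,
    label: str = "",
) -> DegreeDistribution:
    """F(d) = |{i : degree_i >= d}| / n over the observed degrees d >= 1.

    ``positive_only_denominator`` drops zero-degree nodes from n;
    ``as_counts`` reports absolute counts instead of fractions.
    """
    arr = np.asarray(degrees, dtype=int)
    if arr.size == 0:
        raise ValueError("empty degree sequence")
    if np.any(arr < 0):
        raise ValueError("degrees must be non-negative")
    n = int((arr > 0).sum()) if positive_only_denominator else arr.size
    support = np.unique(arr[arr >= 1])
    counts = np.array([(arr >= d).sum() for d in support], dtype=float)
    if not as_counts:
        if n == 0:
            raise ValueError("no positive degrees to normalise by")
        counts = counts / n
    return DegreeDistribution(support, counts, n=n, label=label)


@dataclass
class ExponentialFit:
    """Least-squares line through (d, ln F(d)).

    ``slope`` is the decay rate (negative for decaying distributions) and
    ``r`` the Pearson correlation of the semi-log points; ``r`` is NaN for a
    degenerate (constant) distribution.
    """

    slope: float
    intercept: float
    r: float


def semilog_fit(dist: DegreeDistribution) -> ExponentialFit:
    """Fit ln F(d) = slope * d + intercept by unweighted least squares over
    all points with F(d) > 0."""
    mask = dist.cumfreq > 0
    d = dist.degrees[mask].astype(float)
    logf = np.log(dist.cumfreq[mask])
    if d.size < 3:
        raise ValueError(f"need >= 3 positive points to fit, got {d.size}")
    if np.allclose(logf, logf[0]):
        return ExponentialFit(slope=0.0, intercept=float(logf[0]), r=math.nan)
    res = stats.linregress(d, logf)
    return ExponentialFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
    )


def plot_distributions(
    dists: list[DegreeDistribution], path: str, *, title: str = ""
) -> None:
    """Linear and semi-logarithmic panels of inverse cumulative degree
    distributions, one curve per distribution label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax_lin, ax_log) = plt.subplots(1, 2, figsize=(9, 4))
    for dist in dists:
        for ax in (ax_lin, ax_log):
            ax.plot(dist.degrees, dist.cumfreq, marker=".",
                    label=dist.label or None)
    ax_log.set_yscale("log")
    for ax in (ax_lin, ax_log):
        ax.set_xlabel("degree d")
        ax.set_ylabel("F(d)")
        if any(d.label for d in dists):
            ax.legend(fontsize="small")
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def network_shares(
    tissue_network: RegulatoryNetwork, reference: RegulatoryNetwork
) -> tuple[float, float, float]:
    """Fractions of the reference network retained by a tissue network:
    (TF-node share, nonTF-node share, edge share)."""
    ref_tf = reference.tf_nodes
    ref_nontf = reference.nontf_nodes
    ref_edges = reference.edges()
    if not ref_tf or not ref_nontf or not ref_edges:
        raise ValueError("reference network must have TFs, nonTFs and edges")
    return (
        len(tissue_network.tf_nodes & ref_tf) / len(ref_tf),
        len(tissue_network.nontf_nodes & ref_nontf) / len(ref_nontf),
        len(tissue_network.edges() & ref_edges) / len(ref_edges),
    )
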