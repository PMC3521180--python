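"""Top-percentile selection of conserved sites, per matrix.

Conserved sites are ranked within each matrix by their Match similarity
score; the p% profile keeps the ceil(p/100 * n) best-scoring sites of every
matrix, so profiles are nested across percentiles and every matrix stays
represented even at p = 1 on small site counts.
"""

from __future__ import annotations

import math
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable

from .conservation import ConservedSite

__all__ = ["Profile", "select_profile", "DEFAULT_PERCENTILES"]

#: the 20 quality levels used for validation curves
DEFAULT_PERCENTILES = (1, 2, 3, 5, 10, 15, 20, 25, 30, 35, 40, 45, 50, 55,
                       60, 65, 70, 75, 80, 100)


def _rank_key(site: ConservedSite):
    # highest score first; deterministic tie-break by site coordinates
    hs = site.human_site
    return (-site.score, hs.promoter_id, hs.start, hs.strand)


@dataclass
class Profile:
    """The per-matrix top-p% slice of a conserved-site collection."""

    percentile: int
    selected: dict[str, list[ConservedSite]] = field(default_factory=dict)

    @property
    def sites(self) -> list[ConservedSite]:
        """All selected sites, flattened in matrix order."""
        return [s for sites in self.selected.values() for s in sites]

    def __len__(self) -> int:
        return sum(len(v) for v in self.selected.values())


def select_profile(
    conserved: Iterable[ConservedSite],
    percentile: int,
    *,
    keep_ties: bool = False,
) -> Profile:
    """Select the top-``percentile`` percent of sites of each matrix.

    Per matrix with n sites, ceil(percentile/100 * n) sites are kept, the
    score-maximal ones.  Ties at the cut boundary are broken by
    (promoter_id, start, strand) so output is deterministic; with
    ``keep_ties`` every site tied with the last selected score is admitted
    instead.
    """
    if not 1 <= percentile <= 100:
        raise ValueError(f"percentile must be in 1..100, got {percentile}")
    by_matrix: dict[str, list[ConservedSite]] = defaultdict(list)
    for site in conserved:
        by_matrix[site.matrix_id].append(site)
    selected: dict[str, list[ConservedSite]] = {}
    for matrix_id in sorted(by_matrix):
        sites = sorted(by_matrix[matrix_id], key=_rank_key)
        k = math.ceil(percentile / 100.0 * len(sites))
        if keep_ties and k < len(sites):
            cut = sites[k - 1].score
            while k < len(sites) and sites[k].score == cut:
                k += 1
        selected[matrix_id] = sites[:k]
    return Profile(percentile=percentile, selected=selected)
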