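"""Phylogenetic-footprint filtering of predicted binding sites.

Promoters are scanned as gap-stripped per-species sequences; this module maps
hits back into alignment-column space and applies the four-species
conservation rule: a human site is kept when mouse, dog and cow each carry a
same-matrix, same-strand hit whose alignment interval shares the human site's
start or end column, and that shared boundary column is a non-gap symbol in
all four aligned rows.  A relaxed mode drops the cross-species prediction
requirement and keeps any human site whose start or end column is non-gap in
all four rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import defaultdict
from typing import Mapping, Sequence

import numpy as np

from .pwm_scan import PredictedSite

__all__ = [
    "SPECIES",
    "GAP",
    "OrthologAlignment",
    "ConservedSite",
    "coordinate_map",
    "site_to_columns",
    "conserved_sites",
]

#: canonical species order of every promoter alignment block
SPECIES = ("human", "mouse", "dog", "cow")
GAP = "-"


def coordinate_map(aligned_row: str) -> np.ndarray:
    """Columns of the non-gap characters of an aligned row.

    ``map[k]`` is the alignment column holding the k-th character of the
    gap-stripped sequence; the map is strictly increasing.
    """
    if not aligned_row:
        raise ValueError("empty aligned row")
    cols = np.nonzero(np.frombuffer(aligned_row.encode("ascii"), dtype=np.uint8) != ord(GAP))[0]
    if len(cols) == 0:
        raise ValueError("aligned row contains only gaps")
    return cols


def site_to_columns(site: PredictedSite, coordmap: np.ndarray) -> tuple[int, int]:
    """Alignment columns of a site's first and last base."""
    last = site.start + site.length - 1
    if site.start < 0 or last >= len(coordmap):
        raise ValueError(
            f"site [{site.start}, {site.end}) out of range for a "
            f"{len(coordmap)}-base sequence"
        )
    return int(coordmap[site.start]), int(coordmap[last])


@dataclass
class OrthologAlignment:
    """A four-species promoter alignment block.

    Rows are aligned strings over {A, C, G, T, N, -} of equal width, in the
    canonical order human, mouse, dog, cow.
    """

    promoter_id: str
    rows: dict[str, str]

    coord_maps: dict[str, np.ndarray] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if tuple(self.rows) != SPECIES:
            missing = set(SPECIES) - set(self.rows)
            if missing:
                raise ValueError(
                    f"{self.promoter_id}: missing species {sorted(missing)}"
                )
            # normalise ordering
            self.rows = {sp: self.rows[sp] for sp in SPECIES}
        widths = {len(r) for r in self.rows.values()}
        if len(widths) != 1:
            raise ValueError(
                f"{self.promoter_id}: aligned rows have unequal lengths {sorted(widths)}"
            )
        self.coord_maps = {}
        for sp, row in self.rows.items():
            try:
                self.coord_maps[sp] = coordinate_map(row)
            except ValueError as exc:
                raise ValueError(f"{self.promoter_id}/{sp}: {exc}") from None

    @property
    def width(self) -> int:
        return len(self.rows["human"])

    def stripped(self, species: str) -> str:
        """Gap-stripped sequence of one species."""
        return self.rows[species].replace(GAP, "")

    def column_gapless(self, col: int) -> bool:
        """True when no row carries a gap at this column."""
        return all(row[col] != GAP for row in self.rows.values())


@dataclass(frozen=True)
class ConservedSite:
    """A human site that passed the conservation filter, with its
    cross-species supporting hits and alignment-column footprint."""

    human_site: PredictedSite
    support: Mapping[str, PredictedSite]
    start_col: int
    end_col: int
    boundary_conserved: bool

    @property
    def matrix_id(self) -> str:
        return self.human_site.matrix_id

    @property
    def promoter_id(self) -> str:
        return self.human_site.promoter_id

    @property
    def score(self) -> float:
        return self.human_site.score


def conserved_sites(
    alignment: OrthologAlignment,
    per_species_sites: Mapping[str, Sequence[PredictedSite]],
    *,
    relaxed_boundary: bool = False,
) -> list[ConservedSite]:
    """Apply the four-species conservation filter to one promoter.

    ``per_species_sites`` maps each species to the hits found in its
    gap-stripped promoter sequence.  Output is a pure filter of the human
    hits: scores and coordinates are unchanged, order follows the human scan
    order.  In relaxed mode only the non-gap-boundary condition is applied
    and no ortholog support is recorded.
    """
    for sp, sites in per_species_sites.items():
        for s in sites:
            if s.promoter_id and s.promoter_id != alignment.promoter_id:
                raise ValueError(
                    f"site for promoter {s.promoter_id!r} given with "
                    f"alignment {alignment.promoter_id!r}"
                )
    human_sites = per_species_sites.get("human", ())

    # index ortholog hits by (matrix, strand, boundary column)
    by_start: dict[str, dict[tuple[str, str, int], list[PredictedSite]]] = {}
    by_end: dict[str, dict[tuple[str, str, int], list[PredictedSite]]] = {}
    if not relaxed_boundary:
        for sp in SPECIES[1:]:
            cmap = alignment.coord_maps[sp]
            by_start[sp] = defaultdict(list)
            by_end[sp] = defaultdict(list)
            for s in per_species_sites.get(sp, ()):
                sc, ec = site_to_columns(s, cmap)
                by_start[sp][(s.matrix_id, s.strand, sc)].append(s)
                by_end[sp][(s.matrix_id, s.strand, ec)].append(s)

    human_map = alignment.coord_maps["human"]
    out: list[ConservedSite] = []
    for hs in human_sites:
        sc, ec = site_to_columns(hs, human_map)
        start_ok = alignment.column_gapless(sc)
        end_ok = alignment.column_gapless(ec)
        if relaxed_boundary:
            if start_ok or end_ok:
                out.append(
                    ConservedSite(hs, {}, sc, ec, boundary_conserved=True)
                )
            continue
        support: dict[str, PredictedSite] = {}
        for boundary_ok, index, col in (
            (start_ok, by_start, sc),
            (end_ok, by_end, ec),
        ):
            if not boundary_ok:
                continue
            candidate: dict[str, PredictedSite] = {}
            for sp in SPECIES[1:]:
                hits = index[sp].get((hs.matrix_id, hs.strand, col))
                if not hits:
                    break
                candidate[sp] = min(hits, key=lambda s: (s.start, s.strand))
            else:
                support = candidate
                break
        if support:
            out.append(
                ConservedSite(hs, support, sc, ec, boundary_conserved=True)
            )
    return out
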