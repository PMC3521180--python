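"""Validation of predicted sites against ChIP-derived region sets.

Each promoter contributes exactly one outcome so that the four confusion
categories partition the promoter universe:

* TP -- the promoter has a predicted site lying inside a ChIP region;
* FP -- it has predicted sites but none inside a ChIP region;
* FN -- it has no predicted site, but a ChIP region overlaps the promoter
  by at least 500 nt;
* TN -- neither a prediction nor such a ChIP overlap.

From these, PPV = TP/(TP+FP), specificity = TN/(TN+FP) and
TPR = TP/(TP+FN).  A site-level counting mode (each site a TP or FP,
promoters only supplying FN/TN) is available for comparison, as is an
overlap- rather than containment-based notion of "found in a ChIP region".
Sweeping the percentile profile from 1% to 100% yields the validation curve;
because profiles are nested, TPR is non-decreasing and specificity
non-increasing along the sweep.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

from .conservation import ConservedSite
from .profile_ranking import DEFAULT_PERCENTILES, select_profile
from .pwm_scan import PredictedSite

__all__ = [
    "MIN_FN_OVERLAP",
    "ChipRegion",
    "ChipRegionSet",
    "ConfusionCounts",
    "Metrics",
    "confusion",
    "metrics",
    "validation_curve",
    "venn_triple",
]

#: minimum ChIP-fragment/promoter overlap (nt) for a missed region to count
#: as a false negative
MIN_FN_OVERLAP = 500


@dataclass(frozen=True)
class ChipRegion:
    """A genomic interval from a ChIP experiment (0-based half-open)."""

    chrom: str
    start: int
    end: int
    name: str = ""

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(
                f"region {self.chrom}:{self.start}-{self.end}: end <= start"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, start: int, end: int) -> bool:
        return chrom == self.chrom and self.start <= start and end <= self.end

    def overlap(self, chrom: str, start: int, end: int) -> int:
        if chrom != self.chrom:
            return 0
        return max(0, min(self.end, end) - max(self.start, start))


@dataclass
class ChipRegionSet:
    """A named collection of ChIP regions (one experiment / cell line)."""

    regions: list[ChipRegion]
    name: str = ""

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self):
        return iter(self.regions)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


class Metrics(NamedTuple):
    """PPV, specificity and TPR; NaN where the denominator is zero."""

    ppv: float
    spc: float
    tpr: float


def metrics(counts: ConfusionCounts) -> Metrics:
    def ratio(num: int, denom: int) -> float:
        return num / denom if denom > 0 else math.nan

    return Metrics(
        ppv=ratio(counts.tp, counts.tp + counts.fp),
        spc=ratio(counts.tn, counts.tn + counts.fp),
        tpr=ratio(counts.tp, counts.tp + counts.fn),
    )


def _site_genomic_interval(
    site: PredictedSite, interval
) -> tuple[str, int, int]:
    """Genomic coordinates of a site given its promoter's interval.

    The promoter sequence is given 5'->3'; on a minus-strand promoter the
    sequence start maps to the genomic end.
    """
    chrom, pstart, pend, strand = interval
    if strand == "-":
        gstart = pend - site.end
    else:
        gstart = pstart + site.start
    return chrom, gstart, gstart + site.length


def _as_predicted(site) -> PredictedSite:
    return site.human_site if isinstance(site, ConservedSite) else site


def confusion(
    predicted_sites: Iterable[PredictedSite | ConservedSite],
    chip_regions: ChipRegionSet,
    promoters,
    *,
    mode: str = "promoter",
    containment: bool = True,
) -> ConfusionCounts:
    """Confusion counts of a site set against one ChIP region set.

    ``promoters`` is an annotation-like object exposing ``promoter_ids`` and
    ``interval_of(promoter_id) -> (chrom, start, end, strand)``.  In the
    default promoter mode TP+FP+FN+TN equals the number of promoters.  In
    site mode, TP/FP count sites instead while FN/TN still count promoters.
    With ``containment`` a site must lie fully inside a ChIP region to be
    "found" (sites are tens of nt, fragments hundreds); otherwise any overlap
    counts.
    """
    if mode not in ("promoter", "site"):
        raise ValueError(f"mode must be 'promoter' or 'site', got {mode!r}")
    sites_by_promoter: dict[str, list[PredictedSite]] = {}
    for s in predicted_sites:
        ps = _as_predicted(s)
        sites_by_promoter.setdefault(ps.promoter_id, []).append(ps)

    tp = fp = fn = tn = 0
    for pid in promoters.promoter_ids:
        interval = promoters.interval_of(pid)
        if interval is None:
            raise ValueError(f"promoter {pid!r} has no genomic interval")
        chrom, pstart, pend, _ = interval
        psites = sites_by_promoter.get(pid, [])
        if psites:
            n_found = 0
            for s in psites:
                schrom, sstart, send = _site_genomic_interval(s, interval)
                if containment:
                    found = any(
                        r.contains(schrom, sstart, send) for r in chip_regions
                    )
                else:
                    found = any(
                        r.overlap(schrom, sstart, send) > 0
                        for r in chip_regions
                    )
                n_found += found
            if mode == "site":
                tp += n_found
                fp += len(psites) - n_found
            elif n_found:
                tp += 1
            else:
                fp += 1
        else:
            chip_hit = any(
                r.overlap(chrom, pstart, pend) >= MIN_FN_OVERLAP
                for r in chip_regions
            )
            if chip_hit:
                fn += 1
            else:
                tn += 1
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


@dataclass
class ValidationCurve:
    """Confusion counts and metrics per percentile profile."""

    percentiles: tuple[int, ...]
    counts: dict[int, ConfusionCounts]
    metrics: dict[int, Metrics]


def validation_curve(
    conserved: Sequence[ConservedSite],
    chip_regions: ChipRegionSet,
    promoters,
    *,
    percentiles: Sequence[int] = DEFAULT_PERCENTILES,
    matrix_ids: set[str] | None = None,
    mode: str = "promoter",
    containment: bool = True,
) -> ValidationCurve:
    """PPV/SPC/TPR across percentile profiles for one TF.

    ``matrix_ids``, if given, restricts the evaluation to the matrices of the
    TF under study before profiles are cut.
    """
    if not set(percentiles) <= set(range(1, 101)):
        raise ValueError("percentiles must lie in 1..100")
    if matrix_ids is not None:
        conserved = [s for s in conserved if s.matrix_id in matrix_ids]
    counts: dict[int, ConfusionCounts] = {}
    mets: dict[int, Metrics] = {}
    for p in percentiles:
        profile = select_profile(conserved, p)
        counts[p] = confusion(
            profile.sites,
            chip_regions,
            promoters,
            mode=mode,
            containment=containment,
        )
        mets[p] = metrics(counts[p])
    return ValidationCurve(tuple(percentiles), counts, mets)


def venn_triple(
    pred: set[str], chip_a: set[str], chip_b: set[str]
) -> dict[str, int]:
    """Counts of the seven regions of a three-set Venn diagram.

    Used to compare predicted target genes with the targets implied by two
    independent ChIP experiments for the same TF.
    """
    return {
        "pred_only": len(pred - chip_a - chip_b),
        "chip_a_only": len(chip_a - pred - chip_b),
        "chip_b_only": len(chip_b - pred - chip_a),
        "pred_and_chip_a": len((pred & chip_a) - chip_b),
        "pred_and_chip_b": len((pred & chip_b) - chip_a),
        "chip_a_and_chip_b": len((chip_a & chip_b) - pred),
        "all_three": len(pred & chip_a & chip_b),
    }
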