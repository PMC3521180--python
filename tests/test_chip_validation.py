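"""Confusion counting, validation curves and Venn overlaps."""

import math

import pytest

from oracles import brute_confusion
from seednet.chip_validation import (
    ChipRegion,
    ChipRegionSet,
    ConfusionCounts,
    confusion,
    metrics,
    validation_curve,
    venn_triple,
)
from seednet.formats_io import AnnotationTable, PromoterRecord
from seednet.conservation import ConservedSite
from seednet.pwm_scan import PredictedSite


def annotation(n=1, length=1000, spacing=2000, strand="+"):
    promoters = {
        f"P{i}": PromoterRecord(
            f"P{i}", f"G{i}", f"NM_{i}", "chrT", strand,
            i * spacing, i * spacing + length,
        )
        for i in range(n)
    }
    return AnnotationTable(promoters)


def psite(pid, start, length=10, mid="M$X", score=0.9, strand="+"):
    return PredictedSite(mid, pid, "human", start, strand, score, length)


def regions(*triples):
    return ChipRegionSet([ChipRegion("chrT", s, e, "r") for s, e in triples])


class TestConfusion:
    def test_site_inside_region_is_tp(self):
        counts = confusion(
            [psite("P0", 100)], regions((50, 200)), annotation()
        )
        assert counts == ConfusionCounts(tp=1, fp=0, fn=0, tn=0)

    def test_site_outside_region_is_fp(self):
        counts = confusion(
            [psite("P0", 500)], regions((50, 200)), annotation()
        )
        assert counts == ConfusionCounts(tp=0, fp=1, fn=0, tn=0)

    def test_overlap_499_below_fn_rule_is_tn(self):
        # region overlaps the promoter by exactly 499 nt: not an FN
        counts = confusion([], regions((-101, 499)), annotation())
        assert counts == ConfusionCounts(tn=1)

    def test_overlap_500_is_fn(self):
        counts = confusion([], regions((-100, 500)), annotation())
        assert counts == ConfusionCounts(fn=1)

    def test_partial_site_overlap_needs_containment(self):
        # site [95,105) sticks out of region [100,200)
        counts = confusion(
            [psite("P0", 95)], regions((100, 200)), annotation()
        )
        assert counts.fp == 1
        loose = confusion(
            [psite("P0", 95)], regions((100, 200)), annotation(),
            containment=False,
        )
        assert loose.tp == 1

    def test_minus_strand_promoter_coordinates(self):
        ann = annotation(strand="-")
        # site offset 0 on a minus promoter [0,1000) maps to [990,1000)
        counts = confusion([psite("P0", 0)], regions((985, 1000)), ann)
        assert counts.tp == 1

    def test_site_mode_counts_sites(self):
        counts = confusion(
            [psite("P0", 100), psite("P0", 500)],
            regions((50, 200)), annotation(), mode="site",
        )
        assert (counts.tp, counts.fp) == (1, 1)

    def test_partition_property(self, rng):
        """TP+FP+FN+TN equals the number of promoters, always."""
        for _ in range(20):
            ann = annotation(n=10)
            sites = [
                psite(f"P{int(rng.integers(10))}", int(rng.integers(990)))
                for _ in range(int(rng.integers(0, 15)))
            ]
            regs = []
            for _ in range(int(rng.integers(0, 8))):
                s = int(rng.integers(-500, 20000))
                regs.append((s, s + 600))
            counts = confusion(sites, regions(*regs), ann)
            assert counts.total == 10

    def test_matches_brute_force_classifier(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 8))
            ann = annotation(n=n)
            sites = [
                psite(f"P{int(rng.integers(n))}", int(rng.integers(990)))
                for _ in range(int(rng.integers(0, 12)))
            ]
            regs = []
            for _ in range(int(rng.integers(0, 6))):
                s = int(rng.integers(-700, n * 2000))
                regs.append((s, s + int(rng.integers(100, 900))))
            chip = regions(*regs)
            counts = confusion(sites, chip, ann)
            assert (counts.tp, counts.fp, counts.fn, counts.tn) == \
                brute_confusion(sites, chip, ann)


class TestMetrics:
    @pytest.mark.parametrize(
        "counts, field, expected",
        [
            (ConfusionCounts(tp=3, fp=1), "ppv", 0.75),
            (ConfusionCounts(tn=9, fp=1), "spc", 0.9),
            (ConfusionCounts(tp=2, fn=6), "tpr", 0.25),
        ],
    )
    def test_ratios(self, counts, field, expected):
        assert getattr(metrics(counts), field) == pytest.approx(expected)

    def test_zero_denominator_flags_nan(self):
        m = metrics(ConfusionCounts(tn=5))
        assert math.isnan(m.ppv) and math.isnan(m.tpr)
        assert m.spc == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1)


def _conserved(pid, start, score, mid="M$X", length=10):
    hs = PredictedSite(mid, pid, "human", start, "+", score, length)
    return ConservedSite(hs, {}, start, start + length - 1, True)


class TestValidationCurve:
    def make_sites(self, rng, n_promoters=20, per=4):
        sites = []
        for i in range(n_promoters):
            for _ in range(per):
                sites.append(
                    _conserved(f"P{i}", int(rng.integers(0, 990)),
                               float(rng.random()))
                )
        return sites

    def test_tpr_monotone_spc_antitone(self, rng):
        ann = annotation(n=20)
        sites = self.make_sites(rng)
        regs = []
        for i in range(0, 20, 2):
            s = i * 2000 + int(rng.integers(0, 400))
            regs.append((s, s + 600))
        curve = validation_curve(
            sites, regions(*regs), ann, percentiles=(1, 5, 10, 25, 50, 100)
        )
        tprs = [curve.metrics[p].tpr for p in curve.percentiles]
        spcs = [curve.metrics[p].spc for p in curve.percentiles]
        tprs = [t for t in tprs if not math.isnan(t)]
        spcs = [s for s in spcs if not math.isnan(s)]
        assert tprs == sorted(tprs)
        assert spcs == sorted(spcs, reverse=True)

    def test_empty_chip_set_yields_no_tp_no_fn(self, rng):
        ann = annotation(n=10)
        sites = self.make_sites(rng, n_promoters=10)
        curve = validation_curve(
            sites, ChipRegionSet([]), ann, percentiles=(1, 50, 100)
        )
        for p in curve.percentiles:
            assert curve.counts[p].tp == 0
            assert curve.counts[p].fn == 0
        # specificity falls as more promoters acquire (false) predictions
        spcs = [curve.metrics[p].spc for p in curve.percentiles]
        assert spcs == sorted(spcs, reverse=True)

    def test_curve_equals_per_percentile_recomputation(self, rng):
        from seednet.profile_ranking import select_profile

        ann = annotation(n=15)
        sites = self.make_sites(rng, n_promoters=15)
        regs = [(i * 2000 + 100, i * 2000 + 700) for i in range(0, 15, 3)]
        chip = regions(*regs)
        curve = validation_curve(
            sites, chip, ann, percentiles=(2, 20, 80)
        )
        for p in curve.percentiles:
            manual = confusion(select_profile(sites, p).sites, chip, ann)
            assert curve.counts[p] == manual

    def test_bad_percentiles_rejected(self, rng):
        with pytest.raises(ValueError):
            validation_curve([], ChipRegionSet([]), annotation(),
                             percentiles=(0, 5))


class TestVennTriple:
    def test_identical_sets(self):
        s = {"a", "b", "c"}
        counts = venn_triple(s, set(s), set(s))
        assert counts["all_three"] == 3
        assert sum(v for k, v in counts.items() if k != "all_three") == 0

    def test_pairwise_disjoint(self):
        counts = venn_triple({"a"}, {"b"}, {"c"})
        assert counts == {
            "pred_only": 1, "chip_a_only": 1, "chip_b_only": 1,
            "pred_and_chip_a": 0, "pred_and_chip_b": 0,
            "chip_a_and_chip_b": 0, "all_three": 0,
        }

    def test_regions_partition_the_union(self, rng):
        """Inclusion-exclusion: the 7 regions sum to |union|."""
        universe = [f"g{i}" for i in range(50)]
        for _ in range(50):
            a, b, c = (
                {g for g in universe if rng.random() < 0.4}
                for _ in range(3)
            )
            counts = venn_triple(a, b, c)
            assert sum(counts.values()) == len(a | b | c)
            assert counts["all_three"] == len(a & b & c)
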