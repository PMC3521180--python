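"""Independent brute-force reference implementations used to check the
library.  Everything here is written as plainly as possible -- explicit
loops, no shared code with the package internals beyond the public data
types -- so agreement is meaningful."""

import math

from seednet.conservation import GAP, SPECIES
from seednet.pwm_scan import PredictedSite


def brute_score(freq_rows, window):
    """MSS by direct evaluation of the definition."""

    def info(row):
        return sum(f * math.log(4.0 * f) for f in row if f > 0)

    cur = lo = hi = 0.0
    for row, base in zip(freq_rows, window):
        i = info(row)
        contribs = [i * f for f in row]
        if base == "N":
            cur += min(contribs)
        else:
            cur += contribs["ACGT".index(base)]
        lo += min(contribs)
        hi += max(contribs)
    if hi == lo:
        return 1.0
    return (cur - lo) / (hi - lo)


def brute_revcomp(seq):
    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}
    return "".join(comp[b] for b in reversed(seq))


def brute_scan(matrix, seq, threshold, promoter_id="", species="human"):
    """Naive double loop over positions and strands."""
    L = len(matrix)
    hits = []
    for pos in range(len(seq) - L + 1):
        window = seq[pos : pos + L]
        for strand, w in (("+", window), ("-", brute_revcomp(window))):
            s = brute_score(matrix.freq, w)
            if s >= threshold:
                hits.append(
                    PredictedSite(matrix.id, promoter_id, species, pos,
                                  strand, s, L)
                )
    hits.sort(key=lambda s: (s.start, s.strand))
    return hits


def brute_columns(aligned_row, start, length):
    """Alignment columns of positions start and start+length-1 by walking
    the row character by character."""
    k = -1
    first = last = None
    for col, ch in enumerate(aligned_row):
        if ch != GAP:
            k += 1
            if k == start:
                first = col
            if k == start + length - 1:
                last = col
                break
    return first, last


def brute_conserved(alignment, per_species_sites):
    """Direct restatement of the conservation rule."""
    result = []
    for hs in per_species_sites.get("human", []):
        sc, ec = brute_columns(alignment.rows["human"], hs.start, hs.length)
        ok = False
        for col, end_kind in ((sc, "start"), (ec, "end")):
            if any(alignment.rows[sp][col] == GAP for sp in SPECIES):
                continue
            supported = True
            for sp in SPECIES[1:]:
                found = False
                for s in per_species_sites.get(sp, []):
                    if s.matrix_id != hs.matrix_id or s.strand != hs.strand:
                        continue
                    osc, oec = brute_columns(
                        alignment.rows[sp], s.start, s.length
                    )
                    if (end_kind == "start" and osc == sc) or (
                        end_kind == "end" and oec == ec
                    ):
                        found = True
                        break
                if not found:
                    supported = False
                    break
            if supported:
                ok = True
                break
        if ok:
            result.append(hs)
    return result


def brute_profile(conserved, percentile):
    """Sort-and-slice per matrix."""
    out = []
    matrices = {s.matrix_id for s in conserved}
    for mid in matrices:
        sites = [s for s in conserved if s.matrix_id == mid]
        sites.sort(
            key=lambda c: (
                -c.score,
                c.human_site.promoter_id,
                c.human_site.start,
                c.human_site.strand,
            )
        )
        k = math.ceil(percentile / 100.0 * len(sites))
        out.extend(sites[:k])
    return out


def brute_confusion(sites, chip_regions, promoters):
    """Exhaustive per-promoter classifier (containment semantics)."""
    tp = fp = fn = tn = 0
    for pid in promoters.promoter_ids:
        chrom, pstart, pend, strand = promoters.interval_of(pid)
        psites = [s for s in sites if s.promoter_id == pid]
        if psites:
            found = False
            for s in psites:
                ps = s.human_site if hasattr(s, "human_site") else s
                if strand == "-":
                    g0 = pend - (ps.start + ps.length)
                else:
                    g0 = pstart + ps.start
                for r in chip_regions:
                    if (r.chrom == chrom and r.start <= g0
                            and g0 + ps.length <= r.end):
                        found = True
            if found:
                tp += 1
            else:
                fp += 1
        else:
            hit = False
            for r in chip_regions:
                if r.chrom != chrom:
                    continue
                if min(r.end, pend) - max(r.start, pstart) >= 500:
                    hit = True
            if hit:
                fn += 1
            else:
                tn += 1
    return tp, fp, fn, tn


def brute_inverse_cumulative(degrees):
    """(d, count of degrees >= d, n) for every observed positive degree."""
    n = len(degrees)
    support = sorted({d for d in degrees if d >= 1})
    return [(d, sum(1 for x in degrees if x >= d), n) for d in support]
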