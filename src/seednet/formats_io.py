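"""Readers and writers for every external representation of the pipeline.

Conventions: all genomic and promoter coordinates are 0-based half-open
internally, matching BED natively; any 1-based input would be converted at
this boundary.  Sequences are over {A, C, G, T, N}, alignments additionally
use '-' as the only gap symbol.  Readers validate strictly and raise rather
than silently repairing malformed input; ``write`` then ``read`` restores
the in-memory model (frequencies to within 1e-12).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from Bio import SeqIO

from .chip_validation import ChipRegion, ChipRegionSet
from .conservation import SPECIES, ConservedSite, OrthologAlignment
from .network_build import (
    DIRECT,
    EXPANDED,
    NONTF,
    TF,
    RegulatoryNetwork,
    TFClassification,
)
from .pwm_scan import PredictedSite, WeightMatrix
from .tissue_networks import ExpressionTable

__all__ = [
    "ParseError",
    "MatrixLibrary",
    "AnnotationTable",
    "read_matrix_library",
    "write_matrix_library",
    "read_alignments",
    "write_alignments",
    "read_bed",
    "write_bed",
    "write_sites_bed",
    "read_sites_tsv",
    "write_sites_tsv",
    "read_conserved_tsv",
    "write_conserved_tsv",
    "read_annotation",
    "write_annotation",
    "read_expression",
    "write_expression",
    "read_network",
    "write_edges_tsv",
    "read_classification",
    "write_classification",
]


class ParseError(ValueError):
    """Malformed input file; the message names the offending line."""


# ---------------------------------------------------------------------------
# matrix library (TRANSFAC-like flat file)
# ---------------------------------------------------------------------------

@dataclass
class MatrixLibrary:
    """Ordered collection of weight matrices keyed by identifier."""

    entries: dict[str, WeightMatrix] = field(default_factory=dict)

    def __post_init__(self):
        if not self.entries:
            raise ValueError("matrix library must not be empty")

    def __getitem__(self, matrix_id: str) -> WeightMatrix:
        return self.entries[matrix_id]

    def __iter__(self):
        return iter(self.entries.values())

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, matrix_id: str) -> bool:
        return matrix_id in self.entries

    @property
    def ids(self) -> list[str]:
        return list(self.entries)

    def tf_genes(self) -> set[str]:
        out: set[str] = set()
        for m in self:
            out |= set(m.tf_genes)
        return out


def read_matrix_library(path: str | Path) -> MatrixLibrary:
    """Parse a TRANSFAC-style flat file of weight matrices.

    Records are ``ID`` / ``BF`` (gene symbols, ';'-separated) / ``P0`` header
    / numbered count rows in A C G T order / optional ``TH`` minFN threshold,
    terminated by ``//``.  Counts (or frequencies) are normalised to
    per-position frequencies; a row summing to zero is an error.
    """
    entries: dict[str, WeightMatrix] = {}
    cur_id: str | None = None
    genes: tuple[str, ...] = ()
    rows: list[list[float]] = []
    threshold = 0.0
    in_matrix = False

    def finish(lineno: int) -> None:
        nonlocal cur_id, genes, rows, threshold, in_matrix
        if cur_id is None:
            return
        if not rows:
            raise ParseError(f"line {lineno}: matrix {cur_id!r} has no rows")
        freq = np.asarray(rows, dtype=float)
        sums = freq.sum(axis=1)
        if np.any(sums == 0):
            bad = int(np.argmin(sums)) + 1
            raise ParseError(
                f"matrix {cur_id!r}: position {bad:02d} has all-zero counts"
            )
        freq = freq / sums[:, None]
        entries[cur_id] = WeightMatrix(cur_id, freq, genes, threshold)
        cur_id, genes, rows, threshold, in_matrix = None, (), [], 0.0, False

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("VV", "XX")):
                continue
            tag, _, rest = line.partition(" ")
            rest = rest.strip()
            if tag == "ID":
                if cur_id is not None:
                    raise ParseError(
                        f"line {lineno}: new ID before '//' terminator"
                    )
                if not rest:
                    raise ParseError(f"line {lineno}: empty matrix ID")
                if rest in entries:
                    raise ParseError(f"line {lineno}: duplicate ID {rest!r}")
                cur_id = rest
            elif tag == "BF":
                genes = tuple(
                    g.strip() for g in rest.split(";") if g.strip()
                )
            elif tag == "P0":
                in_matrix = True
            elif tag == "TH":
                try:
                    threshold = float(rest)
                except ValueError:
                    raise ParseError(
                        f"line {lineno}: bad threshold {rest!r}"
                    ) from None
            elif tag == "//":
                finish(lineno)
            elif tag.isdigit():
                if cur_id is None or not in_matrix:
                    raise ParseError(
                        f"line {lineno}: count row outside a matrix record"
                    )
                fields = rest.split()
                if len(fields) < 4:
                    raise ParseError(
                        f"line {lineno}: expected 4 counts, got {len(fields)}"
                    )
                try:
                    rows.append([float(x) for x in fields[:4]])
                except ValueError:
                    raise ParseError(
                        f"line {lineno}: non-numeric count in {rest!r}"
                    ) from None
            else:
                raise ParseError(f"line {lineno}: unknown record tag {tag!r}")
    if cur_id is not None:
        raise ParseError(f"matrix {cur_id!r} not terminated by '//'")
    return MatrixLibrary(entries)


def write_matrix_library(library: MatrixLibrary, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("VV  seednet matrix library\nXX\n")
        for m in library:
            fh.write(f"ID {m.id}\n")
            if m.tf_genes:
                fh.write(f"BF {'; '.join(m.tf_genes)}\n")
            fh.write("P0      A      C      G      T\n")
            for i, row in enumerate(m.freq, start=1):
                vals = "  ".join(f"{x:.17g}" for x in row)
                fh.write(f"{i:02d} {vals}\n")
            fh.write(f"TH {m.min_fn:.17g}\n//\n")


# ---------------------------------------------------------------------------
# four-species promoter alignments (aligned FASTA)
# ---------------------------------------------------------------------------

_ALN_ALPHABET = set("ACGTN-")


def read_alignments(path: str | Path) -> dict[str, OrthologAlignment]:
    """Aligned FASTA with headers ``>promoter_id|species``; every promoter
    block must contain exactly the four species human, mouse, dog, cow with
    equal row lengths."""
    blocks: dict[str, dict[str, str]] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if "|" not in rec.id:
            raise ParseError(
                f"header {rec.id!r}: expected 'promoter_id|species'"
            )
        pid, _, species = rec.id.partition("|")
        if species not in SPECIES:
            raise ParseError(f"header {rec.id!r}: unknown species {species!r}")
        seq = str(rec.seq).upper()
        bad = set(seq) - _ALN_ALPHABET
        if bad:
            raise ParseError(
                f"{rec.id}: invalid characters {sorted(bad)} in alignment row"
            )
        block = blocks.setdefault(pid, {})
        if species in block:
            raise ParseError(f"{rec.id}: duplicate species row")
        block[species] = seq
    out: dict[str, OrthologAlignment] = {}
    for pid, rows in blocks.items():
        if set(rows) != set(SPECIES):
            missing = sorted(set(SPECIES) - set(rows))
            raise ParseError(f"promoter {pid!r}: missing species {missing}")
        out[pid] = OrthologAlignment(pid, {sp: rows[sp] for sp in SPECIES})
    return out


def write_alignments(
    alignments: Mapping[str, OrthologAlignment], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for pid, aln in alignments.items():
            for sp in SPECIES:
                fh.write(f">{pid}|{sp}\n{aln.rows[sp]}\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# BED intervals
# ---------------------------------------------------------------------------

def read_bed(path: str | Path, name: str = "") -> ChipRegionSet:
    """BED4 (chrom, start, end[, name]); 0-based half-open; empty file gives
    an empty region set."""
    regions: list[ChipRegion] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                raise ParseError(f"line {lineno}: expected >= 3 BED fields")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(
                    f"line {lineno}: non-integer BED coordinates"
                ) from None
            if end <= start:
                raise ParseError(
                    f"line {lineno}: end {end} <= start {start}"
                )
            label = fields[3] if len(fields) > 3 else ""
            regions.append(ChipRegion(chrom, start, end, label))
    return ChipRegionSet(regions, name=name or Path(path).stem)


def write_bed(regions: ChipRegionSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for r in regions:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.name}\n")


def write_sites_bed(
    sites: Iterable[PredictedSite | ConservedSite],
    path: str | Path,
    annotation: "AnnotationTable | None" = None,
) -> None:
    """Sites as BED4.  With an annotation the intervals are genomic;
    otherwise the promoter id serves as the 'chromosome' and coordinates are
    promoter offsets."""
    with open(path, "w") as fh:
        for s in sites:
            ps = s.human_site if isinstance(s, ConservedSite) else s
            if annotation is None:
                fh.write(
                    f"{ps.promoter_id}\t{ps.start}\t{ps.end}\t{ps.matrix_id}\n"
                )
            else:
                chrom, pstart, pend, strand = annotation.interval_of(
                    ps.promoter_id
                )
                if strand == "-":
                    gstart = pend - ps.end
                else:
                    gstart = pstart + ps.start
                fh.write(
                    f"{chrom}\t{gstart}\t{gstart + ps.length}\t{ps.matrix_id}\n"
                )


# ---------------------------------------------------------------------------
# site tables (TSV)
# ---------------------------------------------------------------------------

_SITE_COLUMNS = (
    "promoter_id", "matrix_id", "species", "start", "strand", "score",
    "length",
)


def write_sites_tsv(
    sites: Iterable[PredictedSite], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_SITE_COLUMNS) + "\n")
        for s in sites:
            fh.write(
                f"{s.promoter_id}\t{s.matrix_id}\t{s.species}\t{s.start}\t"
                f"{s.strand}\t{s.score:.17g}\t{s.length}\n"
            )


def read_sites_tsv(path: str | Path) -> list[PredictedSite]:
    sites: list[PredictedSite] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _SITE_COLUMNS:
            raise ParseError(f"unexpected site-table header {header}")
        for lineno, line in enumerate(fh, start=2):
            f = line.rstrip("\n").split("\t")
            if len(f) != len(_SITE_COLUMNS):
                raise ParseError(f"line {lineno}: wrong field count")
            sites.append(
                PredictedSite(
                    promoter_id=f[0],
                    matrix_id=f[1],
                    species=f[2],
                    start=int(f[3]),
                    strand=f[4],
                    score=float(f[5]),
                    length=int(f[6]),
                )
            )
    return sites


_CONS_COLUMNS = _SITE_COLUMNS + ("start_col", "end_col", "support")


def write_conserved_tsv(
    sites: Iterable[ConservedSite], path: str | Path
) -> None:
    """Conserved sites with their column footprint; cross-species support is
    encoded compactly as ``species:start`` pairs."""
    with open(path, "w") as fh:
        fh.write("\t".join(_CONS_COLUMNS) + "\n")
        for c in sites:
            s = c.human_site
            supp = ";".join(
                f"{sp}:{c.support[sp].start}" for sp in SPECIES[1:]
                if sp in c.support
            )
            fh.write(
                f"{s.promoter_id}\t{s.matrix_id}\t{s.species}\t{s.start}\t"
                f"{s.strand}\t{s.score:.17g}\t{s.length}\t"
                f"{c.start_col}\t{c.end_col}\t{supp}\n"
            )


def read_conserved_tsv(path: str | Path) -> list[ConservedSite]:
    out: list[ConservedSite] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _CONS_COLUMNS:
            raise ParseError(f"unexpected conserved-table header {header}")
        for lineno, line in enumerate(fh, start=2):
            f = line.rstrip("\n").split("\t")
            if len(f) != len(_CONS_COLUMNS):
                raise ParseError(f"line {lineno}: wrong field count")
            human = PredictedSite(
                promoter_id=f[0], matrix_id=f[1], species=f[2],
                start=int(f[3]), strand=f[4], score=float(f[5]),
                length=int(f[6]),
            )
            support: dict[str, PredictedSite] = {}
            if f[9]:
                for part in f[9].split(";"):
                    sp, _, start = part.partition(":")
                    support[sp] = PredictedSite(
                        promoter_id=f[0], matrix_id=f[1], species=sp,
                        start=int(start), strand=f[4], score=math.nan,
                        length=int(f[6]),
                    )
            out.append(
                ConservedSite(
                    human, support, int(f[7]), int(f[8]),
                    boundary_conserved=True,
                )
            )
    return out


# ---------------------------------------------------------------------------
# promoter annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PromoterRecord:
    promoter_id: str
    gene_symbol: str
    transcript_id: str
    chrom: str
    strand: str
    start: int
    end: int


@dataclass
class AnnotationTable:
    """Promoter-to-gene mapping with genomic intervals and node classes.

    Promoter ids are unique; a gene may own several promoters.  ``gene_class``
    labels genes TF or nonTF; genes absent from it default to nonTF.
    """

    promoters: dict[str, PromoterRecord]
    gene_class: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for g, k in self.gene_class.items():
            if k not in (TF, NONTF):
                raise ValueError(f"gene {g!r}: class must be TF or nonTF")

    @property
    def promoter_ids(self) -> list[str]:
        return list(self.promoters)

    def gene_of(self, promoter_id: str) -> str:
        try:
            return self.promoters[promoter_id].gene_symbol
        except KeyError:
            raise KeyError(f"unknown promoter {promoter_id!r}") from None

    def kind_of(self, gene: str) -> str:
        return self.gene_class.get(gene, NONTF)

    def interval_of(self, promoter_id: str) -> tuple[str, int, int, str]:
        rec = self.promoters[promoter_id]
        return rec.chrom, rec.start, rec.end, rec.strand

    def genes(self) -> set[str]:
        return {r.gene_symbol for r in self.promoters.values()}


_ANN_COLUMNS = (
    "promoter_id", "gene_symbol", "transcript_id", "chrom", "strand",
    "start", "end", "gene_class",
)


def read_annotation(path: str | Path) -> AnnotationTable:
    promoters: dict[str, PromoterRecord] = {}
    gene_class: dict[str, str] = {}
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _ANN_COLUMNS:
            raise ParseError(f"unexpected annotation header {header}")
        for lineno, line in enumerate(fh, start=2):
            f = line.rstrip("\n").split("\t")
            if len(f) != len(_ANN_COLUMNS):
                raise ParseError(f"line {lineno}: wrong field count")
            pid = f[0]
            if pid in promoters:
                raise ParseError(f"line {lineno}: duplicate promoter {pid!r}")
            start, end = int(f[5]), int(f[6])
            if end <= start:
                raise ParseError(f"line {lineno}: end <= start")
            if f[4] not in "+-":
                raise ParseError(f"line {lineno}: bad strand {f[4]!r}")
            promoters[pid] = PromoterRecord(pid, f[1], f[2], f[3], f[4],
                                            start, end)
            if f[7] not in (TF, NONTF):
                raise ParseError(f"line {lineno}: bad gene class {f[7]!r}")
            prev = gene_class.get(f[1])
            if prev is not None and prev != f[7]:
                raise ParseError(
                    f"line {lineno}: gene {f[1]!r} labeled both {prev} and {f[7]}"
                )
            gene_class[f[1]] = f[7]
    return AnnotationTable(promoters, gene_class)


def write_annotation(annotation: AnnotationTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_ANN_COLUMNS) + "\n")
        for rec in annotation.promoters.values():
            fh.write(
                f"{rec.promoter_id}\t{rec.gene_symbol}\t{rec.transcript_id}\t"
                f"{rec.chrom}\t{rec.strand}\t{rec.start}\t{rec.end}\t"
                f"{annotation.kind_of(rec.gene_symbol)}\n"
            )


# ---------------------------------------------------------------------------
# expression tables
# ---------------------------------------------------------------------------

def read_expression(path: str | Path) -> ExpressionTable:
    """Gene x tissue 0/1 table, genes as rows."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty and df.columns.empty:
        raise ParseError("expression table has no tissue columns")
    if not df.isin([0, 1]).all().all():
        raise ParseError("expression table must contain only 0/1 values")
    tissues = tuple(df.columns)
    expressed = {
        t: set(df.index[df[t] == 1].astype(str)) for t in tissues
    }
    return ExpressionTable(tissues, expressed)


def write_expression(table: ExpressionTable, path: str | Path) -> None:
    genes = sorted(table.genes())
    df = pd.DataFrame(
        {
            t: [int(g in table.expressed[t]) for g in genes]
            for t in table.tissues
        },
        index=pd.Index(genes, name="gene"),
    )
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# networks (edge TSV) and TF classification (JSON)
# ---------------------------------------------------------------------------

_EDGE_COLUMNS = ("tf", "target", "provenance", "matrices", "n_sites")


def write_edges_tsv(network: RegulatoryNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_EDGE_COLUMNS) + "\n")
        for u, v, d in sorted(network.graph.edges(data=True)):
            mats = ",".join(sorted(d["matrices"]))
            fh.write(
                f"{u}\t{v}\t{d['provenance']}\t{mats}\t{d['n_sites']}\n"
            )
        # isolated nodes kept via a node section
        for n in sorted(network.graph.nodes):
            if network.graph.degree(n) == 0:
                kind = network.graph.nodes[n]["kind"]
                fh.write(f"#node\t{n}\t{kind}\n")
        for n in sorted(network.tf_nodes):
            fh.write(f"#tf\t{n}\n")


def read_network(path: str | Path) -> RegulatoryNetwork:
    net = RegulatoryNetwork()
    tf_labels: list[str] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _EDGE_COLUMNS:
            raise ParseError(f"unexpected edge-table header {header}")
        for lineno, line in enumerate(fh, start=2):
            f = line.rstrip("\n").split("\t")
            if f[0] == "#node":
                net.add_node(f[1], f[2])
                continue
            if f[0] == "#tf":
                tf_labels.append(f[1])
                continue
            if len(f) != len(_EDGE_COLUMNS):
                raise ParseError(f"line {lineno}: wrong field count")
            if f[2] not in (DIRECT, EXPANDED):
                raise ParseError(f"line {lineno}: bad provenance {f[2]!r}")
            mats = [m for m in f[3].split(",") if m]
            net.add_edge(
                f[0], f[1], provenance=f[2], matrices=mats,
                n_sites=int(f[4]),
            )
    for n in tf_labels:
        net.add_node(n, TF)
    return net


def read_classification(path: str | Path) -> TFClassification:
    """JSON: ``{"clades": {clade_id: [genes...]}, "matrix_assoc":
    {gene: [matrix ids...]}}``."""
    with open(path) as fh:
        data = json.load(fh)
    try:
        clades = {
            cid: tuple(genes) for cid, genes in data["clades"].items()
        }
    except (KeyError, TypeError) as exc:
        raise ParseError(f"malformed classification file: {exc}") from None
    assoc = {
        g: frozenset(ms) for g, ms in data.get("matrix_assoc", {}).items()
    }
    return TFClassification(clades, assoc)


def write_classification(
    classification: TFClassification, path: str | Path
) -> None:
    data = {
        "clades": {c: list(g) for c, g in classification.clades.items()},
        "matrix_assoc": {
            g: sorted(ms) for g, ms in classification.matrix_assoc.items()
        },
    }
    with open(path, "w") as fh:
        json.dump(data, fh, indent=1, sort_keys=True)
        fh.write("\n")
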