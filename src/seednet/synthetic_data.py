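"""Synthetic inputs with known ground truth for the whole pipeline.

The generator emulates the statistical structure of the real inputs the
analysis was designed for: 1-kb promoters aligned across four species with
planted high-scoring binding sites that are either faithfully conserved or
deliberately broken in one ortholog; a toy weight-matrix library built from
sampled training sites with minFN thresholds derived the same way the
scanner uses them; ChIP-like region sets thinned to a controlled sensitivity
with uniform noise fragments; and a DNA-binding-domain classification whose
matrix-bearing members are broadly expressed while the matrix-less paralogs
are tissue-restricted.

Every quantity a downstream module is later scored on is recorded as ground
truth at generation time, and everything is reproducible from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chip_validation import ChipRegion, ChipRegionSet
from .conservation import SPECIES, OrthologAlignment
from .formats_io import (
    AnnotationTable,
    MatrixLibrary,
    PromoterRecord,
    write_alignments,
    write_annotation,
    write_bed,
    write_classification,
    write_expression,
    write_matrix_library,
)
from .network_build import NONTF, TF, TFClassification
from .pwm_scan import (
    ALPHABET,
    WeightMatrix,
    derive_min_fn_threshold,
    score_window,
)
from .tissue_networks import DEFAULT_TISSUES, ExpressionTable

__all__ = [
    "SyntheticConfig",
    "PlantedSite",
    "SyntheticDataset",
    "gen_matrix_library",
    "gen_promoter_set",
    "gen_chip_regions",
    "gen_classification_and_expression",
    "generate_dataset",
    "write_dataset",
]


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the generator; probabilities all lie in [0, 1].

    Defaults mirror the modelled study setting at desk scale: 1-kb
    promoters in four species, a handful of matrices standing in for a
    vertebrate matrix library, two planted sites per promoter, and an
    eight-tissue expression panel.
    """

    seed: int = 0
    n_promoters: int = 60
    promoter_length: int = 1000
    n_matrices: int = 8
    matrix_length_range: tuple[int, int] = (8, 12)
    n_training_sites: int = 10
    sites_per_promoter: int = 2
    #: probability a planted site is replicated intact in all three orthologs
    conservation_prob: float = 0.7
    #: per-position probability of a gap column outside planted sites
    gap_rate: float = 0.05
    #: per-position ortholog substitution rate outside planted sites
    ortholog_divergence: float = 0.25
    #: background nucleotide composition (A, C, G, T); promoters run GC-rich
    background: tuple[float, float, float, float] = (0.23, 0.27, 0.27, 0.23)
    chip_sensitivity: float = 0.7
    #: expected uniform noise fragments per promoter
    chip_noise_rate: float = 0.5
    chip_fragment_length: int = 600
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    #: per-tissue expression probability of matrix-bearing (broad) TFs
    broad_expression_prob: float = 0.9
    #: number of tissues a restricted (expansion-added) TF is expressed in
    restricted_tissue_count: tuple[int, int] = (1, 2)
    #: per-tissue expression probability of nonTF target genes
    target_expression_prob: float = 0.6
    clade_size_range: tuple[int, int] = (2, 4)
    #: probability two matrix-bearing TFs share one clade
    paired_clade_prob: float = 0.25
    #: fraction of promoters owned by TF genes (autoregulation / TF in-degree)
    tf_promoter_fraction: float = 0.15
    #: fraction of nonTF genes owning two promoters
    shared_gene_fraction: float = 0.1
    promoter_spacing: int = 2500

    def validate(self) -> None:
        probs = (
            self.conservation_prob, self.gap_rate, self.ortholog_divergence,
            self.chip_sensitivity, self.broad_expression_prob,
            self.target_expression_prob, self.paired_clade_prob,
            self.tf_promoter_fraction, self.shared_gene_fraction,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background composition must sum to 1")


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted human site."""

    promoter_id: str
    matrix_id: str
    start: int
    strand: str
    score: float
    conserved: bool
    #: the ortholog in which a non-conserved site was destroyed ("" if intact)
    broken_species: str


@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    library: MatrixLibrary
    alignments: dict[str, OrthologAlignment]
    annotation: AnnotationTable
    truth: list[PlantedSite]
    chip_sets: list[ChipRegionSet]
    classification: TFClassification
    expression: ExpressionTable
    consensus: dict[str, str] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int,
                composition) -> str:
    return "".join(
        rng.choice(list(ALPHABET), size=length, p=list(composition))
    )


def _sample_site(rng: np.random.Generator, matrix: WeightMatrix,
                 min_score: float, max_tries: int = 100) -> str:
    """A site sequence drawn from the matrix distribution, rejected until it
    reaches ``min_score`` (falling back to the consensus)."""
    for _ in range(max_tries):
        seq = "".join(
            ALPHABET[rng.choice(4, p=row)] for row in matrix.freq
        )
        if score_window(matrix, seq) >= min_score:
            return seq
    return matrix.consensus


def _sample_nonsite(rng: np.random.Generator, matrix: WeightMatrix,
                    composition, max_tries: int = 500) -> str:
    """A background-composition window guaranteed to score below the matrix
    minFN threshold on the forward strand."""
    for _ in range(max_tries):
        seq = _random_seq(rng, len(matrix), composition)
        if score_window(matrix, seq) < matrix.min_fn:
            return seq
    raise RuntimeError(
        f"could not sample a sub-threshold window for {matrix.id}; "
        "the matrix threshold is too permissive"
    )


def gen_matrix_library(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[MatrixLibrary, dict[str, str]]:
    """Toy matrix library plus per-matrix consensus strings.

    Each matrix is estimated from ``n_training_sites`` sequences sampled
    from a sharp underlying preference; its minFN threshold is the lowest
    training-site score, exactly how the scanner later interprets it.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    entries: dict[str, WeightMatrix] = {}
    consensus: dict[str, str] = {}
    lo, hi = config.matrix_length_range
    for i in range(config.n_matrices):
        L = int(rng.integers(lo, hi + 1))
        gene = f"TF{i + 1:02d}"
        mid = f"M$TOY_{gene}_01"
        ideal = rng.integers(0, 4, size=L)
        sharp = rng.uniform(0.75, 0.95, size=L)
        pref = np.full((L, 4), 0.0)
        for pos in range(L):
            pref[pos] = (1.0 - sharp[pos]) / 3.0
            pref[pos, ideal[pos]] = sharp[pos]
        # empirical counts from training sites, as a curated library would be
        training = [
            "".join(ALPHABET[rng.choice(4, p=row)] for row in pref)
            for _ in range(config.n_training_sites)
        ]
        counts = np.zeros((L, 4))
        for site in training:
            for pos, base in enumerate(site):
                counts[pos, ALPHABET.index(base)] += 1
        freq = counts / counts.sum(axis=1, keepdims=True)
        matrix = WeightMatrix(mid, freq, (gene,), 0.0)
        matrix = WeightMatrix(
            mid, freq, (gene,),
            min_fn=derive_min_fn_threshold(matrix, training),
        )
        entries[mid] = matrix
        consensus[mid] = matrix.consensus
    return MatrixLibrary(entries), consensus


def _make_annotation(
    config: SyntheticConfig, library: MatrixLibrary,
    rng: np.random.Generator,
) -> AnnotationTable:
    tf_genes = sorted(library.tf_genes())
    n_tf_prom = max(1, int(round(config.tf_promoter_fraction
                                 * config.n_promoters)))
    promoters: dict[str, PromoterRecord] = {}
    gene_class: dict[str, str] = {g: TF for g in tf_genes}
    n_nontf = config.n_promoters - n_tf_prom
    nontf_genes: list[str] = []
    gi = 0
    while len(nontf_genes) < n_nontf:
        gi += 1
        gene = f"G{gi:04d}"
        nontf_genes.append(gene)
        # some genes own two promoters
        if (len(nontf_genes) < n_nontf
                and rng.random() < config.shared_gene_fraction):
            nontf_genes.append(gene)
    for i in range(config.n_promoters):
        pid = f"PROM_{i + 1:04d}"
        if i < n_tf_prom:
            gene = tf_genes[i % len(tf_genes)]
        else:
            gene = nontf_genes[i - n_tf_prom]
        gene_class.setdefault(gene, NONTF)
        start = i * config.promoter_spacing
        promoters[pid] = PromoterRecord(
            pid, gene, f"NM_{i + 1:06d}", "chrS", "+",
            start, start + config.promoter_length,
        )
    return AnnotationTable(promoters, gene_class)


def gen_promoter_set(
    config: SyntheticConfig,
    library: MatrixLibrary,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, OrthologAlignment], AnnotationTable, list[PlantedSite]]:
    """Four-species promoter alignments with planted sites.

    Human promoters are background sequence with ``sites_per_promoter``
    planted sites sampled above their matrix's minFN threshold.  With
    probability ``conservation_prob`` a planted site is copied intact into
    all three ortholog rows; otherwise it is overwritten in one randomly
    chosen ortholog by a verified sub-threshold window, breaking the
    four-species support.  Ortholog background diverges at the configured
    substitution rate; gap columns are inserted only outside planted-site
    footprints (with a one-column margin), so a planted conserved site always
    starts and ends on all-species non-gap columns.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    annotation = _make_annotation(config, library, rng)
    matrices = list(library)
    alignments: dict[str, OrthologAlignment] = {}
    truth: list[PlantedSite] = []
    bases = np.array(list(ALPHABET))
    comp = np.array(config.background)

    for pid in annotation.promoter_ids:
        L = config.promoter_length
        human = list(_random_seq(rng, L, comp))
        # choose non-overlapping planted intervals (1-base margin for gaps)
        planted: list[tuple[int, WeightMatrix, bool, str]] = []
        occupied: list[tuple[int, int]] = []
        for _ in range(config.sites_per_promoter):
            matrix = matrices[int(rng.integers(len(matrices)))]
            for _ in range(200):
                start = int(rng.integers(0, L - len(matrix) + 1))
                span = (start - 1, start + len(matrix) + 1)
                if all(span[1] <= s or span[0] >= e for s, e in occupied):
                    occupied.append(span)
                    break
            else:
                continue
            conserved = bool(rng.random() < config.conservation_prob)
            broken = (
                "" if conserved
                else str(rng.choice(list(SPECIES[1:])))
            )
            planted.append((start, matrix, conserved, broken))
        planted.sort(key=lambda t: t[0])

        site_cols: set[int] = set()
        rows = {sp: None for sp in SPECIES}
        # plant into human
        for start, matrix, _, _ in planted:
            site = _sample_site(rng, matrix, matrix.min_fn)
            human[start : start + len(matrix)] = list(site)
            site_cols.update(range(start - 1, start + len(matrix) + 1))
        human_s = "".join(human)

        # orthologs: diverged copies, sites intact or broken
        ortho: dict[str, list[str]] = {}
        for sp in SPECIES[1:]:
            seq = list(human_s)
            mutate = rng.random(L) < config.ortholog_divergence
            for pos in np.nonzero(mutate)[0]:
                if int(pos) in site_cols:
                    continue
                seq[pos] = str(rng.choice(bases))
            ortho[sp] = seq
        for start, matrix, conserved, broken in planted:
            if not conserved:
                bad = _sample_nonsite(rng, matrix, comp)
                ortho[broken][start : start + len(matrix)] = list(bad)
            truth.append(
                PlantedSite(
                    promoter_id=pid,
                    matrix_id=matrix.id,
                    start=start,
                    strand="+",
                    score=score_window(
                        matrix, human_s[start : start + len(matrix)]
                    ),
                    conserved=conserved,
                    broken_species=broken,
                )
            )

        # assemble alignment columns with gaps outside planted footprints
        cols = {sp: [] for sp in SPECIES}
        for pos in range(L):
            gap_ok = pos not in site_cols
            # insertion column: human gap, some orthologs carry a base
            if gap_ok and rng.random() < config.gap_rate / 2.0:
                cols["human"].append("-")
                for sp in SPECIES[1:]:
                    cols[sp].append(
                        str(rng.choice(bases)) if rng.random() < 0.5 else "-"
                    )
            cols["human"].append(human_s[pos])
            for sp in SPECIES[1:]:
                if gap_ok and rng.random() < config.gap_rate:
                    cols[sp].append("-")  # deletion in this ortholog
                else:
                    cols[sp].append(ortho[sp][pos])
        alignments[pid] = OrthologAlignment(
            pid, {sp: "".join(cols[sp]) for sp in SPECIES}
        )
    return alignments, annotation, truth


def gen_chip_regions(
    truth: list[PlantedSite],
    annotation: AnnotationTable,
    *,
    sensitivity: float,
    noise_rate: float,
    fragment_length: int = 600,
    site_lengths: dict[str, int] | None = None,
    rng: np.random.Generator | None = None,
    name: str = "chip",
) -> ChipRegionSet:
    """ChIP-like fragments over the planted sites.

    Every planted human site is covered by a centred fragment with
    probability ``sensitivity``; uniform noise fragments are added per
    promoter at rate ``noise_rate``.  Drawing two sets with independent RNG
    streams emulates two cell lines whose peak lists overlap only partially.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    regions: list[ChipRegion] = []
    for ps in truth:
        if rng.random() >= sensitivity:
            continue
        chrom, pstart, _, _ = annotation.interval_of(ps.promoter_id)
        length = (site_lengths or {}).get(ps.matrix_id, 10)
        g0 = pstart + ps.start
        frag_start = g0 - (fragment_length - length) // 2
        regions.append(
            ChipRegion(chrom, frag_start, frag_start + fragment_length,
                       f"{name}_{ps.promoter_id}")
        )
    if noise_rate > 0:
        for pid in annotation.promoter_ids:
            chrom, pstart, pend, _ = annotation.interval_of(pid)
            for _ in range(rng.poisson(noise_rate)):
                s = int(rng.integers(pstart - fragment_length // 2,
                                     pend - fragment_length // 2))
                regions.append(
                    ChipRegion(chrom, s, s + fragment_length,
                               f"{name}_noise_{pid}")
                )
    regions.sort(key=lambda r: (r.chrom, r.start, r.end))
    return ChipRegionSet(regions, name=name)


def gen_classification_and_expression(
    config: SyntheticConfig,
    library: MatrixLibrary,
    annotation: AnnotationTable,
    rng: np.random.Generator | None = None,
) -> tuple[TFClassification, ExpressionTable]:
    """DNA-binding-domain clades plus the tissue expression panel.

    Matrix-bearing TFs seed the clades (occasionally two per clade, giving
    expansion something to cross-validate); the remaining members are
    matrix-less paralogs.  Matrix-bearing TFs draw broad expression,
    matrix-less paralogs tissue-restricted expression, and nonTF targets an
    intermediate breadth -- the mixture behind the tissue-breadth contrast
    between original and expansion-added TFs.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    bearing = sorted(library.tf_genes())
    assoc: dict[str, frozenset[str]] = {
        g: frozenset(m.id for m in library if g in m.tf_genes)
        for g in bearing
    }
    clades: dict[str, tuple[str, ...]] = {}
    added: list[str] = []
    lo, hi = config.clade_size_range
    queue = list(bearing)
    ci = 0
    pi = 0
    while queue:
        ci += 1
        members = [queue.pop(0)]
        if queue and rng.random() < config.paired_clade_prob:
            members.append(queue.pop(0))
        size = max(len(members), int(rng.integers(lo, hi + 1)))
        while len(members) < size:
            pi += 1
            para = f"PTF{pi:02d}"
            members.append(para)
            added.append(para)
        clades[f"1.1.{ci}"] = tuple(members)
    classification = TFClassification(clades, assoc)

    tissues = config.tissues
    expressed: dict[str, set[str]] = {t: set() for t in tissues}
    for g in bearing:
        chosen = [t for t in tissues
                  if rng.random() < config.broad_expression_prob]
        if not chosen:
            chosen = [str(rng.choice(list(tissues)))]
        for t in chosen:
            expressed[t].add(g)
    rlo, rhi = config.restricted_tissue_count
    for g in added:
        k = int(rng.integers(rlo, rhi + 1))
        for t in rng.choice(list(tissues), size=k, replace=False):
            expressed[str(t)].add(g)
    for g in sorted(annotation.genes()):
        if g in bearing:
            continue
        for t in tissues:
            if rng.random() < config.target_expression_prob:
                expressed[t].add(g)
    return classification, ExpressionTable(tissues, expressed)


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """All pipeline inputs from one seed, with two independent ChIP sets."""
    config.validate()
    root = np.random.default_rng(config.seed)
    seeds = root.integers(0, 2**31 - 1, size=5)
    library, consensus = gen_matrix_library(
        config, np.random.default_rng(seeds[0])
    )
    alignments, annotation, truth = gen_promoter_set(
        config, library, np.random.default_rng(seeds[1])
    )
    site_lengths = {m.id: len(m) for m in library}
    chip_sets = [
        gen_chip_regions(
            truth, annotation,
            sensitivity=config.chip_sensitivity,
            noise_rate=config.chip_noise_rate,
            fragment_length=config.chip_fragment_length,
            site_lengths=site_lengths,
            rng=np.random.default_rng(seeds[2 + k]),
            name=f"cell_line_{'AB'[k]}",
        )
        for k in range(2)
    ]
    classification, expression = gen_classification_and_expression(
        config, library, annotation, np.random.default_rng(seeds[4])
    )
    return SyntheticDataset(
        config=config,
        library=library,
        alignments=alignments,
        annotation=annotation,
        truth=truth,
        chip_sets=chip_sets,
        classification=classification,
        expression=expression,
        consensus=consensus,
    )


def write_dataset(dataset: SyntheticDataset, outdir: str | Path) -> None:
    """Write every input in its standard on-disk format plus the ground
    truth under ``truth/``."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix_library(dataset.library, out / "matrices.txt")
    write_alignments(dataset.alignments, out / "alignments.fasta")
    write_annotation(dataset.annotation, out / "annotation.tsv")
    for chip in dataset.chip_sets:
        write_bed(chip, out / f"{chip.name}.bed")
    write_classification(dataset.classification, out / "tfclass.json")
    write_expression(dataset.expression, out / "expression.tsv")
    tdir = out / "truth"
    tdir.mkdir(exist_ok=True)
    with open(tdir / "planted_sites.tsv", "w") as fh:
        fh.write("promoter_id\tmatrix_id\tstart\tstrand\tscore\t"
                 "conserved\tbroken_species\n")
        for ps in dataset.truth:
            fh.write(
                f"{ps.promoter_id}\t{ps.matrix_id}\t{ps.start}\t{ps.strand}"
                f"\t{ps.score:.17g}\t{int(ps.conserved)}\t"
                f"{ps.broken_species}\n"
            )
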