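"""End-to-end orchestration: simulate -> scan -> conserve -> rank -> build
-> expand -> validate -> tissue -> stats.

Each stage reads and writes plain text artifacts (TSV/BED/FASTA/JSON), so a
run is resumable and every intermediate is independently inspectable.  A run
manifest records the configuration, seed and per-stage counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import degree_stats, reporting
from .chip_validation import validation_curve
from .conservation import SPECIES, ConservedSite, OrthologAlignment, conserved_sites
from .formats_io import (
    MatrixLibrary,
    write_conserved_tsv,
    write_edges_tsv,
    write_sites_tsv,
)
from .network_build import (
    RegulatoryNetwork,
    build_rtn,
    expand_paralogous,
)
from .profile_ranking import DEFAULT_PERCENTILES, select_profile
from .pwm_scan import PredictedSite, scan_sequence
from .synthetic_data import SyntheticConfig, generate_dataset, write_dataset
from .tissue_networks import filter_tissue

log = logging.getLogger("seednet")

__all__ = [
    "RunConfig",
    "scan_alignments",
    "conserve_alignments",
    "run_pipeline",
]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    outdir: str = "seednet_run"
    seed: int = 0
    #: percentile of the profile used to build the networks
    profile_percentile: int = 1
    percentiles: tuple[int, ...] = DEFAULT_PERCENTILES
    relaxed_boundary: bool = False
    keep_ties: bool = False
    validation_mode: str = "promoter"
    containment: bool = True
    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        syn = SyntheticConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in (data.pop("synthetic", {}) or {}).items()
        })
        for key in ("percentiles",):
            if key in data:
                data[key] = tuple(data[key])
        return cls(synthetic=syn, **data)


def scan_alignments(
    library: MatrixLibrary,
    alignments: Mapping[str, OrthologAlignment],
) -> dict[str, dict[str, list[PredictedSite]]]:
    """Scan every species' gap-stripped promoter sequence with every matrix
    at its minFN threshold."""
    out: dict[str, dict[str, list[PredictedSite]]] = {}
    for pid, aln in alignments.items():
        per_species: dict[str, list[PredictedSite]] = {}
        for sp in SPECIES:
            seq = aln.stripped(sp)
            sites: list[PredictedSite] = []
            for matrix in library:
                sites.extend(
                    scan_sequence(
                        matrix, seq, promoter_id=pid, species=sp
                    )
                )
            sites.sort(key=lambda s: (s.start, s.strand, s.matrix_id))
            per_species[sp] = sites
        out[pid] = per_species
    return out


def conserve_alignments(
    alignments: Mapping[str, OrthologAlignment],
    scanned: Mapping[str, Mapping[str, Sequence[PredictedSite]]],
    *,
    relaxed_boundary: bool = False,
) -> list[ConservedSite]:
    out: list[ConservedSite] = []
    for pid, aln in alignments.items():
        out.extend(
            conserved_sites(
                aln, scanned[pid], relaxed_boundary=relaxed_boundary
            )
        )
    return out


def _config_hash(config: RunConfig) -> str:
    # the output location is not part of the scientific configuration
    blob = json.dumps(
        {k: v for k, v in asdict(config).items() if k != "outdir"},
        sort_keys=True, default=str,
    )
    return hashlib.sha256(blob.encode()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages on a synthetic dataset and return the manifest."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": {},
    }
    stages = manifest["stages"]

    # 1. simulate
    syn = SyntheticConfig(**{**asdict(config.synthetic),
                             "seed": config.seed})
    dataset = generate_dataset(syn)
    write_dataset(dataset, out / "inputs")
    stages["simulate"] = {
        "promoters": len(dataset.alignments),
        "matrices": len(dataset.library),
        "planted_sites": len(dataset.truth),
    }
    log.info("simulate: %s", stages["simulate"])

    # 2. scan
    scanned = scan_alignments(dataset.library, dataset.alignments)
    human_sites = [s for per in scanned.values() for s in per["human"]]
    write_sites_tsv(human_sites, out / "sites_human.tsv")
    stages["scan"] = {"human_sites": len(human_sites)}
    log.info("scan: %s", stages["scan"])

    # 3. conserve
    conserved = conserve_alignments(
        dataset.alignments, scanned,
        relaxed_boundary=config.relaxed_boundary,
    )
    write_conserved_tsv(conserved, out / "conserved.tsv")
    stages["conserve"] = {"conserved_sites": len(conserved)}
    log.info("conserve: %s", stages["conserve"])

    # 4. rank
    profile = select_profile(
        conserved, config.profile_percentile, keep_ties=config.keep_ties
    )
    write_conserved_tsv(profile.sites, out / f"profile_{profile.percentile}.tsv")
    stages["rank"] = {
        "percentile": profile.percentile,
        "selected_sites": len(profile),
    }
    log.info("rank: %s", stages["rank"])

    # 5. build
    rtn = build_rtn(profile.sites, dataset.annotation, dataset.library)
    write_edges_tsv(rtn, out / "rtn.tsv")
    stages["build"] = {
        "tf_nodes": len(rtn.tf_nodes),
        "nontf_nodes": len(rtn.nontf_nodes),
        "edges": rtn.n_edges(),
    }
    log.info("build: %s", stages["build"])

    # 6. expand
    ertn = expand_paralogous(rtn, dataset.classification)
    write_edges_tsv(ertn, out / "ertn.tsv")
    stages["expand"] = {
        "tf_nodes": len(ertn.tf_nodes),
        "edges": ertn.n_edges(),
        "tf_percent_increase": reporting.percent_increase(
            len(rtn.tf_nodes), len(ertn.tf_nodes)
        ) if rtn.tf_nodes else math.nan,
        "edge_percent_increase": reporting.percent_increase(
            rtn.n_edges(), ertn.n_edges()
        ) if rtn.n_edges() else math.nan,
    }
    log.info("expand: %s", stages["expand"])

    # 7. validate (first ChIP set, all matrices pooled)
    curve = validation_curve(
        conserved, dataset.chip_sets[0], dataset.annotation,
        percentiles=config.percentiles,
        mode=config.validation_mode,
        containment=config.containment,
    )
    with open(out / "validation_curve.tsv", "w") as fh:
        fh.write("percentile\ttp\tfp\tfn\ttn\tppv\tspc\ttpr\n")
        for p in curve.percentiles:
            c, m = curve.counts[p], curve.metrics[p]
            fh.write(
                f"{p}\t{c.tp}\t{c.fp}\t{c.fn}\t{c.tn}\t"
                f"{m.ppv:.6g}\t{m.spc:.6g}\t{m.tpr:.6g}\n"
            )
    stages["validate"] = {
        "percentiles": list(curve.percentiles),
        "top_metrics": curve.metrics[curve.percentiles[0]]._asdict(),
    }
    log.info("validate: %s", stages["validate"])

    # 8. tissue
    ttns: dict[str, RegulatoryNetwork] = {}
    ettns: dict[str, RegulatoryNetwork] = {}
    for tissue in dataset.expression.tissues:
        expressed = dataset.expression.expressed[tissue]
        ttns[tissue] = filter_tissue(rtn, expressed)
        ettns[tissue] = filter_tissue(ertn, expressed)
        write_edges_tsv(ttns[tissue], out / f"ttn_{tissue}.tsv")
        write_edges_tsv(ettns[tissue], out / f"ettn_{tissue}.tsv")
    stages["tissue"] = {
        t: {"ttn_edges": ttns[t].n_edges(), "ettn_edges": ettns[t].n_edges()}
        for t in dataset.expression.tissues
    }
    log.info("tissue: %s", stages["tissue"])

    # 9. stats
    fits = {}
    with open(out / "degree_fits.tsv", "w") as fh:
        fh.write("network\tclass\tslope\tintercept\tr\n")
        for name, net in (("rtn", rtn), ("ertn", ertn)):
            seqs = degree_stats.degree_sequences(net)
            for cls in ("all_in", "tf_out"):
                degrees = seqs[cls]
                if not degrees or sum(d > 0 for d in degrees) == 0:
                    continue
                dist = degree_stats.inverse_cumulative(degrees, label=cls)
                try:
                    fit = degree_stats.semilog_fit(dist)
                except ValueError:
                    continue
                fits[f"{name}.{cls}"] = fit.r
                fh.write(
                    f"{name}\t{cls}\t{fit.slope:.6g}\t{fit.intercept:.6g}"
                    f"\t{fit.r:.6g}\n"
                )
    stages["stats"] = {"fits_r": fits}
    log.info("stats: %s", stages["stats"])

    manifest["completed_stages"] = list(stages)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
        fh.write("\n")
    return manifest
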