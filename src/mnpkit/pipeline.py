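"""End-to-end orchestration: simulate -> filter -> screen -> genotype ->
compare -> cluster, file-mediated so stages can be re-run independently.

Every stage reads its inputs from the run directory and writes its outputs
there; a manifest JSON records parameters and SHA-256 digests of every
output, so a fixed seed yields digest-identical runs.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from .config import RunConfig, config_to_dict
from .errors import DataError
from .filtering import filter_variants
from .genotyping import genotype_cohort, read_fingerprints, \
    write_fingerprints
from .io import read_fasta, read_fastq, sha256_of_file
from .metrics import (allele_stats, build_allele_registry,
                      comparisons_to_frame, molecular_id, pairwise_compare,
                      panel_stats_to_frame, write_tsv)
from .population import (distance_matrix_from_comparisons, pcoa, to_newick,
                         upgma)
from .screening import read_panel, screen_panel, write_panel
from .simulate import simulate_run
from .variants import read_vcf, write_vcf

logger = logging.getLogger(__name__)

STAGES = ("simulate", "filter", "screen", "genotype", "compare", "cluster")


def _require_input(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DataError(f"stage {stage!r}: required input missing: {path}")
    return path


def run_pipeline(config: RunConfig, only: tuple[str, ...] | None = None
                 ) -> dict:
    """Execute the pipeline stages in order and write a run manifest.

    ``only`` restricts execution to a subset of stages (in pipeline
    order); inputs of the first requested stage must already exist in the
    run directory. Returns the manifest dict.
    """
    config.validate()
    requested = STAGES if only is None else tuple(only)
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise DataError(f"unknown pipeline stages: {sorted(unknown)}")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.simulation.rng_seed = config.seed

    manifest = {
        "mnpkit_version": __version__,
        "seed": config.seed,
        "parameters": config_to_dict(config),
        "stages": [],
    }

    paths = {
        "reference": out / "reference.fasta",
        "vcf": out / "population.vcf",
        "reads": out / "reads.fastq",
        "truth": out / "truth.json",
        "filtered_vcf": out / "filtered.vcf",
        "filter_tally": out / "filter_tally.tsv",
        "panel": out / "panel.tsv",
        "fingerprints": out / "fingerprints.tsv",
        "sample_summary": out / "sample_summary.tsv",
        "comparisons": out / "comparisons.tsv",
        "panel_stats": out / "panel_stats.tsv",
        "molecular_ids": out / "molecular_ids.tsv",
        "tree": out / "tree.nwk",
        "ordination": out / "ordination.tsv",
    }

    def record_stage(name: str, outputs: list[str], **info) -> None:
        manifest["stages"].append({
            "stage": name,
            "outputs": {key: {"path": str(paths[key]),
                              "sha256": sha256_of_file(paths[key])}
                        for key in outputs},
            **info,
        })

    for stage in STAGES:
        if stage not in requested:
            continue
        if stage == "simulate":
            info = simulate_run(config.simulation, out, config.screening)
            record_stage("simulate", ["reference", "vcf", "reads", "truth"],
                         n_reads=info["n_reads"], n_snps=info["n_snps"],
                         n_planted_loci=info["n_planted_loci"])
        elif stage == "filter":
            gm = read_vcf(_require_input(paths["vcf"], stage))
            retained, tally = filter_variants(gm, config.filtering)
            write_vcf(retained, paths["filtered_vcf"])
            with open(paths["filter_tally"], "w") as handle:
                handle.write("rule\trejected\n")
                for rule in ("contig_length", "maf", "call_rate", "hwe",
                             "cnv"):
                    handle.write(f"{rule}\t{tally.get(rule, 0)}\n")
            record_stage("filter", ["filtered_vcf", "filter_tally"],
                         n_retained=retained.n_variants,
                         n_input=gm.n_variants)
        elif stage == "screen":
            gm = read_vcf(_require_input(paths["filtered_vcf"], stage))
            reference = read_fasta(_require_input(paths["reference"], stage))
            panel = screen_panel(gm, config.screening, reference)
            if not panel.loci:
                raise DataError("screening produced an empty panel")
            write_panel(panel, paths["panel"])
            record_stage("screen", ["panel"], panel_size=len(panel),
                         panel_id=panel.panel_id)
        elif stage == "genotype":
            panel = read_panel(_require_input(paths["panel"], stage))
            reads = read_fastq(_require_input(paths["reads"], stage))
            fingerprints, summary = genotype_cohort(
                reads, panel, config.genotyping, mode="flank")
            if not fingerprints:
                raise DataError("no reads could be grouped by accession")
            write_fingerprints(fingerprints, paths["fingerprints"])
            write_tsv(summary, paths["sample_summary"])
            record_stage("genotype", ["fingerprints", "sample_summary"],
                         n_accessions=len(fingerprints),
                         mean_detection_rate=float(
                             summary["detection_rate"].mean()))
        elif stage == "compare":
            fingerprints = read_fingerprints(
                _require_input(paths["fingerprints"], stage))
            results = pairwise_compare(fingerprints)
            write_tsv(comparisons_to_frame(results), paths["comparisons"])
            stats = allele_stats(fingerprints)
            write_tsv(panel_stats_to_frame(stats), paths["panel_stats"])
            registry = build_allele_registry(fingerprints)
            ids = [molecular_id(fingerprints[acc], registry)
                   for acc in sorted(fingerprints)]
            write_tsv(_ids_frame(ids), paths["molecular_ids"])
            record_stage("compare", ["comparisons", "panel_stats",
                                     "molecular_ids"],
                         n_pairs=len(results),
                         mean_pic=stats.mean_pic,
                         mean_alleles=stats.mean_alleles)
        elif stage == "cluster":
            fingerprints = read_fingerprints(
                _require_input(paths["fingerprints"], stage))
            results = pairwise_compare(fingerprints)
            dm = distance_matrix_from_comparisons(results)
            tree = upgma(dm)
            Path(paths["tree"]).write_text(to_newick(tree) + "\n")
            coords, explained = pcoa(dm, n_axes=min(2, len(dm.labels) - 1))
            with open(paths["ordination"], "w") as handle:
                handle.write("# explained fractions: "
                             + ",".join(f"{e:.6f}" for e in explained)
                             + "\n")
                coords.to_csv(handle, sep="\t",
                              index_label="accession_id")
            record_stage("cluster", ["tree", "ordination"],
                         n_accessions=len(dm.labels))
        logger.info("stage %s complete", stage)

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return manifest


def _ids_frame(ids):
    return pd.DataFrame([{
        "accession_id": m.accession_id,
        "molecular_id": m.digest,
        "canonical": m.canonical,
    } for m in ids])
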