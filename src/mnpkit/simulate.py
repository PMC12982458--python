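"""Synthetic cohort generator: reference contigs, population SNPs with
planted MNP loci, amplicon reads, and the truth set they derive from.

The generator emulates the data a marker-design study works from without
requiring the deposited sequencing archive: a fragmented contig assembly,
a screening cohort genotyped at biallelic SNPs (with population
substructure induced by founder haplotypes shared within clusters),
high-linkage SNP clusters planted inside 300-bp windows so that true MNP
loci exist to be rediscovered, and per-locus amplicon reads with
substitution errors and Bernoulli locus dropout.

No ploidy model is assumed downstream: an accession carries 1..k allele
sequences per locus (k = ``alleles_per_accession``, drawn with
replacement from its cluster's founder pool, so identical draws collapse
to a single allele).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Optional

import numpy as np

from .config import ScreeningConfig, SimulationConfig
from .errors import GenerationError
from .io import write_fasta, write_fastq
from .screening import (CandidateLocus, MNPPanel, amplicon_bounds,
                        discriminative_power, haplotype_of)
from .variants import GenotypeMatrix
from . import variants as vt

logger = logging.getLogger(__name__)

BASES = np.array(list("ACGT"))
READ_NAME_DELIMITER = "|"

# Layout constants for planted loci (bp). The exclusion margin keeps
# background SNPs far enough from a planted window that no sliding window
# can chain a planted locus with background variation; the edge margin
# leaves room for primer-landing flanks at contig ends.
_EXCLUSION_BP = 650
_EDGE_BP = 60
_JITTER_BP = 40


@dataclass
class PlantedLocus:
    """One simulated MNP locus with its founder allele sequences."""

    locus_id: str
    contig: str
    window_start: int
    window_end: int
    snp_positions: tuple[int, ...]       # absolute, 0-based
    ref_bases: tuple[str, ...]
    alt_bases: tuple[str, ...]
    amplicon_start: int
    amplicon_end: int
    ref_amplicon: str
    founder_haplotypes: list[str]        # amplicon sequence per founder
    dp: float = 0.0
    genotype_labels: dict[str, str] = field(default_factory=dict)


@dataclass
class TruthSet:
    """Ground truth paired with the generated cohort."""

    loci: list[PlantedLocus]
    # accession -> locus_id -> sorted tuple of distinct allele sequences
    fingerprints: dict[str, dict[str, tuple[str, ...]]]
    # accession -> locus_id -> the k drawn allele sequences (with repeats)
    accession_haplotypes: dict[str, dict[str, tuple[str, ...]]]
    dropout_events: set[tuple[str, str]] = field(default_factory=set)
    accessions: list[str] = field(default_factory=list)
    clusters: dict[str, int] = field(default_factory=dict)

    def locus_ids(self) -> list[str]:
        return [loc.locus_id for loc in self.loci]


def accession_names(config: SimulationConfig) -> list[str]:
    width = max(2, len(str(config.n_accessions)))
    return [f"ACC{i + 1:0{width}d}" for i in range(config.n_accessions)]


def generate_reference(config: SimulationConfig) -> dict[str, str]:
    """Random contigs over {A,C,G,T}; deterministic for a fixed seed."""
    config.validate()
    rng = np.random.default_rng([1, config.rng_seed])
    width = max(4, len(str(config.n_contigs)))
    out = {}
    for i in range(config.n_contigs):
        seq = rng.choice(BASES, size=config.contig_length_bp)
        out[f"CTG{i + 1:0{width}d}"] = "".join(seq.tolist())
    return out


def _plant_layout(config: SimulationConfig, window_bp: int = 300
                  ) -> list[tuple[int, int]]:
    """(contig_index, slot_index) per planted locus; round-robin over
    contigs, raising when loci cannot be placed without overlap."""
    slot_len = window_bp + _EXCLUSION_BP
    slots_per_contig = config.contig_length_bp // slot_len
    capacity = config.n_contigs * slots_per_contig
    if config.planted_locus_count > capacity:
        raise GenerationError(
            f"cannot place {config.planted_locus_count} planted loci without "
            f"overlap: capacity is {capacity} "
            f"({slots_per_contig} per {config.contig_length_bp}-bp contig)")
    layout = []
    for i in range(config.planted_locus_count):
        layout.append((i % config.n_contigs, i // config.n_contigs))
    return layout


def generate_population_variants(
    reference: dict[str, str], config: SimulationConfig,
    screening_config: ScreeningConfig | None = None,
) -> tuple[GenotypeMatrix, TruthSet]:
    """Plant high-linkage MNP loci and scatter background SNPs; derive
    per-accession genotypes, allele sequences and dropout events.

    Planted-locus amplicon bounds follow the same arithmetic the screening
    stage uses, so an error-free round trip recovers them exactly.
    """
    config.validate()
    scfg = (screening_config or ScreeningConfig()).validate()
    rng = np.random.default_rng([2, config.rng_seed])
    contig_names = sorted(reference)
    if len(contig_names) != config.n_contigs:
        raise GenerationError("reference does not match config.n_contigs")
    accs = accession_names(config)
    clusters = {acc: i % config.cluster_count for i, acc in enumerate(accs)}
    nf = config.n_founder_haplotypes
    k = config.alleles_per_accession
    w = scfg.window_bp

    # global per-cluster founder sampling weights (population substructure)
    weights = rng.dirichlet(np.full(nf, config.cluster_founder_alpha),
                            size=config.cluster_count)

    layout = _plant_layout(config, w)
    slot_len = w + _EXCLUSION_BP

    loci: list[PlantedLocus] = []
    fingerprints: dict[str, dict[str, tuple[str, ...]]] = \
        {acc: {} for acc in accs}
    acc_haps: dict[str, dict[str, tuple[str, ...]]] = \
        {acc: {} for acc in accs}
    exclusion: dict[str, list[tuple[int, int]]] = \
        {c: [] for c in contig_names}

    rows_contig, rows_pos, rows_ref, rows_alt, rows_gt = [], [], [], [], []

    for idx, (ci, slot) in enumerate(layout):
        contig = contig_names[ci]
        ref_seq = reference[contig]
        jitter = int(rng.integers(0, _JITTER_BP + 1))
        wstart = slot * slot_len + _EDGE_BP + jitter
        wend = wstart + w
        m = int(rng.integers(config.planted_snps_min,
                             config.planted_snps_max + 1))
        span = int(rng.integers(config.planted_span_min,
                                config.planted_span_max + 1))
        offset = (w - span) // 2
        first = wstart + offset
        last = first + span - 1
        interior = rng.choice(np.arange(first + 1, last), size=m - 2,
                              replace=False)
        positions = tuple(sorted([first, last] + interior.tolist()))
        refs = tuple(ref_seq[p] for p in positions)
        alts = tuple(
            str(rng.choice([b for b in "ACGT" if b != r])) for r in refs)
        # founder allele matrix: 0 = ref, 1 = alt at each planted SNP
        fmat = np.zeros((nf, m), dtype=np.int8)
        for j in range(m):
            lo = max(1, round(0.25 * nf))
            hi = max(lo, int(0.75 * nf))
            n_alt = int(rng.integers(lo, hi + 1))
            carriers = rng.choice(nf, size=n_alt, replace=False)
            fmat[carriers, j] = 1

        bounds = amplicon_bounds(positions[0], positions[-1],
                                 len(ref_seq), scfg)
        if bounds is None:   # cannot happen with the span defaults
            raise GenerationError(
                f"planted locus at {contig}:{wstart} violates the amplicon "
                "length constraint; adjust planted_span_min/max")
        amp_start, amp_end = bounds
        ref_amplicon = ref_seq[amp_start:amp_end]
        founder_seqs = []
        for f in range(nf):
            seq = list(ref_amplicon)
            for j, p in enumerate(positions):
                if fmat[f, j]:
                    seq[p - amp_start] = alts[j]
            founder_seqs.append("".join(seq))

        locus_id = f"L{idx + 1:04d}"
        locus = PlantedLocus(
            locus_id=locus_id, contig=contig, window_start=wstart,
            window_end=wend, snp_positions=positions, ref_bases=refs,
            alt_bases=alts, amplicon_start=amp_start, amplicon_end=amp_end,
            ref_amplicon=ref_amplicon, founder_haplotypes=founder_seqs)

        # per-accession haplotype draws and genotype codes
        gt_block = np.zeros((m, len(accs)), dtype=np.int8)
        labels = []
        for a, acc in enumerate(accs):
            draws = rng.choice(nf, size=k, p=weights[clusters[acc]])
            seqs = tuple(founder_seqs[h] for h in draws)
            acc_haps[acc][locus_id] = seqs
            fingerprints[acc][locus_id] = tuple(sorted(set(seqs)))
            codes = fmat[draws, :].sum(axis=0)
            if k == 1:   # single allele sequence: hom-coded genotype
                codes = codes * 2
            elif k > 2:  # collapse multi-draw dosage to diploid-like codes
                codes = np.where(codes == 0, 0, np.where(codes == k, 2, 1))
            gt_block[:, a] = codes
            labels.append(haplotype_of(codes.tolist(), refs, alts))
        locus.genotype_labels = dict(zip(accs, labels))
        locus.dp = (discriminative_power(labels)
                    if len(set(labels)) > 1 else 0.0)
        loci.append(locus)
        exclusion[contig].append((max(0, wstart - _EXCLUSION_BP),
                                  min(len(ref_seq), wend + _EXCLUSION_BP)))
        for j, p in enumerate(positions):
            rows_contig.append(contig)
            rows_pos.append(p)
            rows_ref.append(refs[j])
            rows_alt.append(alts[j])
            rows_gt.append(gt_block[j])

    # background SNPs outside the planted exclusion zones
    for contig in contig_names:
        ref_seq = reference[contig]
        allowed = np.ones(len(ref_seq), dtype=bool)
        allowed[:_EDGE_BP] = False
        allowed[-_EDGE_BP:] = False
        for lo, hi in exclusion[contig]:
            allowed[lo:hi] = False
        candidates = np.flatnonzero(allowed)
        if candidates.size == 0:
            continue
        count = rng.binomial(candidates.size, config.snp_rate)
        if count == 0:
            continue
        pos = np.sort(rng.choice(candidates, size=count, replace=False))
        for p in pos.tolist():
            ref_base = ref_seq[p]
            alt_base = str(rng.choice([b for b in "ACGT" if b != ref_base]))
            q = float(rng.uniform(0.1, 0.4))
            codes = rng.binomial(2, q, size=len(accs)).astype(np.int8)
            rows_contig.append(contig)
            rows_pos.append(p)
            rows_ref.append(ref_base)
            rows_alt.append(alt_base)
            rows_gt.append(codes)

    gt = np.array(rows_gt, dtype=np.int8).reshape(len(rows_gt), len(accs))
    # screening-stage missing calls
    if config.missing_call_rate > 0 and gt.size:
        mask = rng.random(gt.shape) < config.missing_call_rate
        gt = np.where(mask, np.int8(vt.MISSING), gt)
    depths = rng.poisson(30, size=gt.shape).astype(np.int64) + 1

    gm = GenotypeMatrix(
        contigs=np.array(rows_contig, dtype=object),
        positions=np.array(rows_pos, dtype=np.int64),
        ref=np.array(rows_ref, dtype=object),
        alt=np.array(rows_alt, dtype=object),
        genotypes=gt,
        samples=accs,
        contig_lengths={c: len(reference[c]) for c in contig_names},
        depths=depths,
    ).sort()

    # locus x sample Bernoulli dropout (independent), with per-accession
    # overrides emulating low-panel-compatibility samples
    dropout: set[tuple[str, str]] = set()
    for acc in accs:
        rate = config.dropout_overrides.get(acc, config.dropout_rate)
        if rate <= 0:
            continue
        hits = rng.random(len(loci)) < rate
        for loc, hit in zip(loci, hits.tolist()):
            if hit:
                dropout.add((acc, loc.locus_id))

    truth = TruthSet(loci=loci, fingerprints=fingerprints,
                     accession_haplotypes=acc_haps, dropout_events=dropout,
                     accessions=accs, clusters=clusters)
    logger.info("simulated %d planted loci, %d SNPs, %d accessions, "
                "%d dropout events", len(loci), gm.n_variants, len(accs),
                len(dropout))
    return gm, truth


def generate_amplicon_reads(truth: TruthSet, config: SimulationConfig
                            ) -> Iterator[tuple[str, str]]:
    """Yield (read_name, sequence) per accession x locus.

    Read names carry accession and locus identity as
    ``accession|locus|index``. Depth is Poisson (or negative binomial when
    ``depth_dispersion`` is set); each read is one of the accession's true
    allele sequences with independent per-base substitution errors.
    """
    config.validate()
    rng = np.random.default_rng([3, config.rng_seed])
    mean = config.read_depth_mean
    for acc in truth.accessions:
        for locus in truth.loci:
            if (acc, locus.locus_id) in truth.dropout_events:
                continue
            if config.depth_dispersion is None:
                depth = int(rng.poisson(mean))
            else:
                k = config.depth_dispersion
                depth = int(rng.negative_binomial(k, k / (k + mean)))
            haps = truth.accession_haplotypes[acc][locus.locus_id]
            for i in range(depth):
                seq = haps[int(rng.integers(len(haps)))]
                if config.seq_error_rate > 0:
                    arr = np.frombuffer(seq.encode(), dtype="S1")
                    errs = np.flatnonzero(
                        rng.random(len(seq)) < config.seq_error_rate)
                    if errs.size:
                        arr = arr.copy()
                        for p in errs.tolist():
                            base = arr[p].decode()
                            arr[p] = rng.choice(
                                [b for b in "ACGT" if b != base]).encode()
                        seq = arr.tobytes().decode()
                yield (f"{acc}{READ_NAME_DELIMITER}{locus.locus_id}"
                       f"{READ_NAME_DELIMITER}{i + 1}", seq)


def panel_from_truth(truth: TruthSet) -> MNPPanel:
    """The planted loci expressed as an MNP panel (oracle panel)."""
    loci = []
    for loc in truth.loci:
        loci.append(CandidateLocus(
            contig=loc.contig, window_start=loc.window_start,
            window_end=loc.window_end, snp_positions=loc.snp_positions,
            dp=loc.dp, amplicon_start=loc.amplicon_start,
            amplicon_end=loc.amplicon_end,
            haplotype_table=dict(loc.genotype_labels),
            ref_seq=loc.ref_amplicon, locus_id=loc.locus_id))
    return MNPPanel(loci=loci)


def write_truth(truth: TruthSet, path: str | Path) -> None:
    data = {
        "accessions": truth.accessions,
        "clusters": truth.clusters,
        "loci": [{
            "locus_id": loc.locus_id, "contig": loc.contig,
            "window_start": loc.window_start, "window_end": loc.window_end,
            "snp_positions": list(loc.snp_positions),
            "ref_bases": list(loc.ref_bases),
            "alt_bases": list(loc.alt_bases),
            "amplicon_start": loc.amplicon_start,
            "amplicon_end": loc.amplicon_end,
            "ref_amplicon": loc.ref_amplicon,
            "founder_haplotypes": loc.founder_haplotypes,
            "dp": loc.dp,
            "genotype_labels": loc.genotype_labels,
        } for loc in truth.loci],
        "fingerprints": {acc: {lid: list(seqs) for lid, seqs in by_loc.items()}
                         for acc, by_loc in truth.fingerprints.items()},
        "accession_haplotypes": {
            acc: {lid: list(seqs) for lid, seqs in by_loc.items()}
            for acc, by_loc in truth.accession_haplotypes.items()},
        "dropout_events": sorted(map(list, truth.dropout_events)),
    }
    Path(path).write_text(json.dumps(data))


def read_truth(path: str | Path) -> TruthSet:
    data = json.loads(Path(path).read_text())
    loci = [PlantedLocus(
        locus_id=d["locus_id"], contig=d["contig"],
        window_start=d["window_start"], window_end=d["window_end"],
        snp_positions=tuple(d["snp_positions"]),
        ref_bases=tuple(d["ref_bases"]), alt_bases=tuple(d["alt_bases"]),
        amplicon_start=d["amplicon_start"], amplicon_end=d["amplicon_end"],
        ref_amplicon=d["ref_amplicon"],
        founder_haplotypes=d["founder_haplotypes"], dp=d["dp"],
        genotype_labels=d["genotype_labels"]) for d in data["loci"]]
    return TruthSet(
        loci=loci,
        fingerprints={acc: {lid: tuple(s) for lid, s in by_loc.items()}
                      for acc, by_loc in data["fingerprints"].items()},
        accession_haplotypes={
            acc: {lid: tuple(s) for lid, s in by_loc.items()}
            for acc, by_loc in data["accession_haplotypes"].items()},
        dropout_events={(a, l) for a, l in data["dropout_events"]},
        accessions=data["accessions"],
        clusters={k: int(v) for k, v in data["clusters"].items()})


def simulate_run(config: SimulationConfig, out_dir: str | Path,
                 screening_config: ScreeningConfig | None = None) -> dict:
    """Generate and write the full fixture set; returns output paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reference = generate_reference(config)
    gm, truth = generate_population_variants(reference, config,
                                             screening_config)
    paths = {
        "reference": out / "reference.fasta",
        "vcf": out / "population.vcf",
        "reads": out / "reads.fastq",
        "truth": out / "truth.json",
    }
    write_fasta(reference, paths["reference"])
    vt.write_vcf(gm, paths["vcf"])
    n_reads = write_fastq(generate_amplicon_reads(truth, config),
                          paths["reads"])
    write_truth(truth, paths["truth"])
    logger.info("simulate: wrote %d reads to %s", n_reads, paths["reads"])
    return {name: str(p) for name, p in paths.items()} | {
        "n_reads": n_reads, "n_snps": gm.n_variants,
        "n_planted_loci": len(truth.loci)}
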