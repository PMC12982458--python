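"""Configuration dataclasses for every pipeline stage.

Defaults encode the marker-system design rules: SNP retention thresholds
(MAF >= 0.05, call rate >= 80%, HWE p >= 0.01), a 300-bp sliding window with
1-bp step, "more than three" SNPs and discriminative power >= 0.2 per window,
amplicon lengths restricted to 200-300 bp, and a target core panel of 505
loci screened from a 30-accession cohort.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .errors import ConfigError


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


def _check_prob(value: float, name: str) -> None:
    _require(0.0 <= value <= 1.0, f"{name} must lie in [0, 1], got {value}")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic cohort generator.

    The generator emulates the study conditions of the marker system:
    a fragmented contig-level reference, a 30-accession screening cohort
    with mild population substructure, ~500 planted high-polymorphism MNP
    windows, multiplex amplicon reads with substitution errors, and
    per-sample locus dropout mimicking low-compatibility accessions.
    """

    n_contigs: int = 520
    contig_length_bp: int = 4000
    n_accessions: int = 30
    n_founder_haplotypes: int = 12
    snp_rate: float = 5e-4            # background (non-planted) SNPs per bp
    cluster_count: int = 3
    planted_locus_count: int = 505
    read_depth_mean: int = 50
    seq_error_rate: float = 0.001
    dropout_rate: float = 0.01
    rng_seed: int = 0
    # ploidy is deliberately not assumed: each accession carries 1..k allele
    # sequences per locus; k = alleles_per_accession (haplotype draws).
    alleles_per_accession: int = 2
    planted_snps_min: int = 6
    planted_snps_max: int = 10
    planted_span_min: int = 170       # first..last planted SNP distance (bp)
    planted_span_max: int = 230
    missing_call_rate: float = 0.02   # screening-stage missing genotypes
    cluster_founder_alpha: float = 2.0  # Dirichlet concentration per cluster
    depth_dispersion: Optional[float] = None  # neg-binomial k; None = Poisson
    dropout_overrides: dict = field(default_factory=dict)

    def validate(self) -> "SimulationConfig":
        for name in ("n_contigs", "contig_length_bp", "n_accessions",
                     "n_founder_haplotypes", "cluster_count",
                     "planted_locus_count", "read_depth_mean",
                     "alleles_per_accession", "planted_snps_min"):
            _require(getattr(self, name) >= 1, f"{name} must be >= 1")
        _require(self.contig_length_bp >= 301,
                 "contig_length_bp must be >= 301 to host one 300-bp window")
        for name in ("snp_rate", "seq_error_rate", "dropout_rate",
                     "missing_call_rate"):
            _check_prob(getattr(self, name), name)
        for acc, rate in self.dropout_overrides.items():
            _check_prob(rate, f"dropout_overrides[{acc}]")
        _require(self.planted_snps_max >= self.planted_snps_min,
                 "planted_snps_max must be >= planted_snps_min")
        _require(self.planted_span_max >= self.planted_span_min >= 2,
                 "planted span bounds must satisfy 2 <= min <= max")
        _require(self.planted_snps_min >= 4,
                 "planted loci must carry at least 4 SNPs "
                 "(window admission needs more than three)")
        _require(self.cluster_count <= self.n_founder_haplotypes,
                 "cluster_count cannot exceed n_founder_haplotypes")
        if self.depth_dispersion is not None:
            _require(self.depth_dispersion > 0, "depth_dispersion must be > 0")
        return self


@dataclass
class FilterConfig:
    """SNP retention thresholds applied before marker screening."""

    maf_min: float = 0.05
    call_rate_min: float = 0.80
    hwe_p_min: float = 0.01
    cnv_depth_ratio_max: float = 2.0
    cnv_sample_fraction_max: float = 0.10
    min_contig_length_bp: int = 251   # retain contigs longer than 250 bp

    def validate(self) -> "FilterConfig":
        _check_prob(self.maf_min, "maf_min")
        _require(self.maf_min <= 0.5, "maf_min cannot exceed 0.5")
        _check_prob(self.call_rate_min, "call_rate_min")
        _check_prob(self.hwe_p_min, "hwe_p_min")
        _check_prob(self.cnv_sample_fraction_max, "cnv_sample_fraction_max")
        _require(self.cnv_depth_ratio_max > 0, "cnv_depth_ratio_max must be > 0")
        _require(self.min_contig_length_bp >= 1,
                 "min_contig_length_bp must be >= 1")
        return self


@dataclass
class ScreeningConfig:
    """Sliding-window MNP locus discovery and panel assembly parameters."""

    window_bp: int = 300
    step_bp: int = 1
    min_snps_exclusive: int = 3       # admission requires MORE THAN this many
    dp_min: float = 0.2
    amplicon_min_bp: int = 200
    amplicon_max_bp: int = 300
    flank_clear_bp: int = 20          # SNP-free flank for primer landing
    min_spacing_bp: int = 10_000      # start-to-start, same contig
    target_panel_size: int = 505

    def validate(self) -> "ScreeningConfig":
        _require(self.step_bp >= 1, "step_bp must be >= 1")
        _require(self.window_bp >= 1, "window_bp must be >= 1")
        _require(self.amplicon_min_bp <= self.amplicon_max_bp <= self.window_bp,
                 "need amplicon_min_bp <= amplicon_max_bp <= window_bp")
        _check_prob(self.dp_min, "dp_min")
        _require(self.min_snps_exclusive >= 0,
                 "min_snps_exclusive must be >= 0")
        _require(self.flank_clear_bp >= 0, "flank_clear_bp must be >= 0")
        _require(self.min_spacing_bp >= 0, "min_spacing_bp must be >= 0")
        _require(self.target_panel_size >= 1, "target_panel_size must be >= 1")
        return self


@dataclass
class GenotypingConfig:
    """Allele calling thresholds for amplicon read groups."""

    min_locus_depth: int = 20
    min_allele_fraction: float = 0.2
    max_alleles_per_locus: int = 2
    # at 200-300 bp amplicons a per-base error of a few per mille puts one
    # or two substitutions on a large share of reads, so the collapse
    # radius must cover two mismatches and the abundance skew must let a
    # modest true-allele centroid absorb its error cloud; only sequences
    # below error_collapse_fraction are ever folded, so a real minor
    # allele (>= min_allele_fraction) can never be absorbed
    error_collapse_max_mismatch: int = 2
    error_collapse_fraction: float = 0.05
    error_collapse_ratio: float = 5.0   # target/rare abundance skew

    def validate(self) -> "GenotypingConfig":
        _require(self.min_locus_depth >= 1, "min_locus_depth must be >= 1")
        _require(0.0 < self.min_allele_fraction <= 0.5,
                 "min_allele_fraction must lie in (0, 0.5]")
        _require(self.max_alleles_per_locus >= 1,
                 "max_alleles_per_locus must be >= 1")
        _require(self.error_collapse_max_mismatch >= 0,
                 "error_collapse_max_mismatch must be >= 0")
        _check_prob(self.error_collapse_fraction, "error_collapse_fraction")
        _require(self.error_collapse_ratio >= 1.0,
                 "error_collapse_ratio must be >= 1")
        return self


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (simulate -> ... -> ordinate)."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    filtering: FilterConfig = field(default_factory=FilterConfig)
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    genotyping: GenotypingConfig = field(default_factory=GenotypingConfig)
    seed: int = 0
    out_dir: str = "mnpkit_run"
    log_level: str = "INFO"

    def validate(self) -> "RunConfig":
        self.simulation.validate()
        self.filtering.validate()
        self.screening.validate()
        self.genotyping.validate()
        return self


_SECTIONS = {
    "simulation": SimulationConfig,
    "filtering": FilterConfig,
    "screening": ScreeningConfig,
    "genotyping": GenotypingConfig,
}


def _from_mapping(cls, mapping: dict):
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - known
    if unknown:
        raise ConfigError(
            f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return cls(**mapping)


def run_config_from_dict(data: dict) -> RunConfig:
    """Build a validated :class:`RunConfig` from a plain (JSON) mapping."""
    kwargs = {}
    for key, value in data.items():
        if key in _SECTIONS:
            kwargs[key] = _from_mapping(_SECTIONS[key], value)
        elif key in ("seed", "out_dir", "log_level"):
            kwargs[key] = value
        else:
            raise ConfigError(f"unknown run-config section: {key!r}")
    return RunConfig(**kwargs).validate()


def load_run_config(path: str | Path) -> RunConfig:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    try:
        data = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ConfigError(f"config file is not valid JSON: {exc}") from exc
    return run_config_from_dict(data)


def config_to_dict(cfg) -> dict:
    """Serialize any stage config (or RunConfig) to plain JSON-able data."""
    return dataclasses.asdict(cfg)
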