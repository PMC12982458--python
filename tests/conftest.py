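import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True)
settings.load_profile("ci")

from mnpkit.config import ScreeningConfig, SimulationConfig
from mnpkit.genotyping import (STATUS_CALLED, STATUS_LOW_DEPTH, AlleleCall,
                               Fingerprint)
from mnpkit.simulate import (generate_amplicon_reads, generate_reference,
                             generate_population_variants)
from mnpkit.variants import GenotypeMatrix


def make_matrix(contig_snps, samples, contig_lengths, depths=None):
    """Build a GenotypeMatrix from {contig: [(pos, ref, alt, codes)]}."""
    contigs, positions, refs, alts, rows = [], [], [], [], []
    for contig in sorted(contig_snps):
        for pos, ref, alt, codes in sorted(contig_snps[contig]):
            contigs.append(contig)
            positions.append(pos)
            refs.append(ref)
            alts.append(alt)
            rows.append(codes)
    return GenotypeMatrix(
        contigs=np.array(contigs, dtype=object),
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(refs, dtype=object),
        alt=np.array(alts, dtype=object),
        genotypes=np.array(rows, dtype=np.int8).reshape(len(rows),
                                                        len(samples)),
        samples=list(samples),
        contig_lengths=dict(contig_lengths),
        depths=None if depths is None else np.asarray(depths,
                                                      dtype=np.int64),
    )


def make_fingerprint(accession, calls):
    """calls: {locus_id: allele tuple or None (no-call)}."""
    fp = Fingerprint(accession_id=accession)
    for locus, alleles in calls.items():
        if alleles is None:
            fp.calls[locus] = AlleleCall(locus_id=locus,
                                         status=STATUS_LOW_DEPTH)
        else:
            alleles = tuple(sorted(alleles))
            fp.calls[locus] = AlleleCall(
                locus_id=locus, alleles=alleles, depth=100,
                allele_fractions={a: 1 / len(alleles) for a in alleles},
                status=STATUS_CALLED)
    return fp


@pytest.fixture(scope="session")
def small_cohort():
    """A 10-accession, 12-locus error-free cohort shared across tests."""
    cfg = SimulationConfig(n_contigs=12, contig_length_bp=5000,
                           n_accessions=10, planted_locus_count=12,
                           n_founder_haplotypes=8, snp_rate=3e-4,
                           seq_error_rate=0.0, dropout_rate=0.0,
                           read_depth_mean=100, rng_seed=5)
    reference = generate_reference(cfg)
    gm, truth = generate_population_variants(reference, cfg)
    reads = list(generate_amplicon_reads(truth, cfg))
    return {"config": cfg, "reference": reference, "gm": gm,
            "truth": truth, "reads": reads}


@pytest.fixture(scope="session")
def screening_defaults():
    return ScreeningConfig()
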