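"""SNP retention rules applied before marker screening.

A variant survives when its minor allele frequency, genotype call rate and
Hardy-Weinberg exact-test p-value all clear their thresholds, it carries no
copy-number-variation depth signal, and its contig is long enough to host
an amplicon. Genotypes are conventional diploid-coded calls at this stage;
missing calls are excluded (not imputed) from MAF and HWE counts.
"""

from __future__ import annotations

import logging
from collections import Counter
from functools import lru_cache
from math import comb
from typing import Optional, Sequence

import numpy as np

from .config import FilterConfig
from .errors import DataError
from .variants import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING

logger = logging.getLogger(__name__)


def compute_call_rate(genotypes: Sequence[int] | np.ndarray) -> float:
    """(non-missing calls) / (cohort size)."""
    arr = np.asarray(genotypes)
    if arr.size == 0:
        raise DataError("call rate is undefined for an empty cohort")
    return float(np.count_nonzero(arr != MISSING) / arr.size)


def compute_maf(genotypes: Sequence[int] | np.ndarray) -> float:
    """Minor allele frequency over non-missing diploid calls.

    Each call contributes two allele observations; returns min(p, 1-p)
    where p is the alt-allele frequency.
    """
    arr = np.asarray(genotypes)
    called = arr[arr != MISSING]
    if called.size == 0:
        raise DataError("MAF is undefined when every call is missing")
    alt_copies = int(np.sum(called))   # codes 0/1/2 equal alt dosage
    p = alt_copies / (2 * called.size)
    return float(min(p, 1.0 - p))


def hwe_exact_test(n_homref: int, n_het: int, n_homalt: int) -> float:
    """Exact conditional Hardy-Weinberg test on diploid genotype counts.

    Conditions on the allele totals: the probability of observing ``h``
    heterozygotes among ``n`` individuals given ``na`` minor-allele copies
    is proportional to ``C(n, h) * C(n - h, (na - h) / 2) * 2**h`` over the
    support ``h in {na mod 2, na mod 2 + 2, ...}``. The p-value sums the
    probabilities of all heterozygote counts no more likely than the
    observed one (two-sided, standard rather than mid-p).

    Exact integer arithmetic throughout; monomorphic tables return 1.0.
    """
    for name, v in (("n_homref", n_homref), ("n_het", n_het),
                    ("n_homalt", n_homalt)):
        if v < 0:
            raise DataError(f"{name} must be non-negative")
    n = n_homref + n_het + n_homalt
    if n < 1:
        raise DataError("HWE test needs at least one genotype")
    na = min(2 * n_homref + n_het, 2 * n_homalt + n_het)
    if na == 0:
        return 1.0

    def weight(h: int) -> int:
        rare_hom = (na - h) // 2
        return comb(n, h) * comb(n - h, rare_hom) * (2 ** h)

    support = range(na % 2, na + 1, 2)
    weights = {h: weight(h) for h in support if (na - h) // 2 + h <= n}
    w_obs = weights[n_het]
    total = sum(weights.values())
    numer = sum(w for w in weights.values() if w <= w_obs)
    return numer / total


_hwe_cached = lru_cache(maxsize=None)(hwe_exact_test)


def cnv_flag(depths: Optional[np.ndarray],
             cohort_median_locus_depth: Optional[float],
             sample_median_depths: Optional[np.ndarray],
             config: FilterConfig) -> bool:
    """Heuristic copy-number-variation signal for one locus.

    True when the locus mean depth exceeds ``cnv_depth_ratio_max`` times the
    cohort median locus depth, or when more than ``cnv_sample_fraction_max``
    of samples exceed that ratio against their own median depth. With no
    depth information the flag is False (logged once per call site).
    """
    if depths is None or cohort_median_locus_depth is None:
        logger.warning("per-sample depths unavailable; CNV filter disabled")
        return False
    mean_depth = float(np.mean(depths))
    if mean_depth > config.cnv_depth_ratio_max * cohort_median_locus_depth:
        return True
    if sample_median_depths is not None:
        high = depths > config.cnv_depth_ratio_max * sample_median_depths
        if np.mean(high) > config.cnv_sample_fraction_max:
            return True
    return False


def filter_variants(gm: GenotypeMatrix, config: FilterConfig | None = None
                    ) -> tuple[GenotypeMatrix, Counter]:
    """Apply all retention rules; returns (retained matrix, rejection tally).

    The tally attributes each rejected record to its FIRST failing rule in
    the fixed order contig_length -> maf -> call_rate -> hwe -> cnv. A
    record with no callable genotype is attributed to call_rate (its MAF is
    undefined).
    """
    config = (config or FilterConfig()).validate()
    if not gm.is_sorted():
        raise DataError("records must be sorted by (contig, position)")
    tally: Counter = Counter()
    keep = np.zeros(gm.n_variants, dtype=bool)

    have_depth = gm.depths is not None
    if have_depth:
        locus_means = gm.depths.mean(axis=1)
        cohort_median = float(np.median(locus_means))
        sample_medians = np.median(gm.depths, axis=0)
    else:
        cohort_median = sample_medians = None
        if gm.n_variants:
            logger.warning("no depth matrix; CNV filter disabled for all "
                           "records")

    for i in range(gm.n_variants):
        contig = str(gm.contigs[i])
        length = gm.contig_lengths.get(contig)
        if length is not None and length <= config.min_contig_length_bp - 1:
            tally["contig_length"] += 1
            continue
        row = gm.genotypes[i]
        called = row[row != MISSING]
        if called.size == 0:
            tally["call_rate"] += 1
            continue
        if compute_maf(row) < config.maf_min:
            tally["maf"] += 1
            continue
        if compute_call_rate(row) < config.call_rate_min:
            tally["call_rate"] += 1
            continue
        counts = (int(np.count_nonzero(called == HOM_REF)),
                  int(np.count_nonzero(called == HET)),
                  int(np.count_nonzero(called == HOM_ALT)))
        if _hwe_cached(*counts) < config.hwe_p_min:
            tally["hwe"] += 1
            continue
        if have_depth and cnv_flag(gm.depths[i], cohort_median,
                                   sample_medians, config):
            tally["cnv"] += 1
            continue
        keep[i] = True

    retained = gm.subset(keep)
    logger.info("filtering: %d/%d SNPs retained (%s)",
                retained.n_variants, gm.n_variants, dict(tally) or "none "
                "rejected")
    return retained, tally
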