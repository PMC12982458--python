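"""Identification statistics over MNP fingerprints.

Genetic similarity (GS) between two accessions is the number of loci at
which both are called with identical allele-sequence sets, divided by the
core panel size (default) or by the number of loci called in both
(``shared_called`` mode). Reproducibility compares two independent runs of
the same accessions; genotyping accuracy follows
``accuracy = 1 - (1 - reproducibility) / 2`` (a discordant pair of runs
contains exactly one wrong call). Marker informativeness uses the
polymorphism information content (PIC) of Botstein et al.:
``PIC = 1 - sum(p_i^2) - sum_{i<j} 2 p_i^2 p_j^2``.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from math import comb
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .genotyping import Fingerprint

logger = logging.getLogger(__name__)


@dataclass
class ComparisonResult:
    accession_a: str
    accession_b: str
    n_compared: int
    n_identical: int
    n_differential: int
    gs: float
    differentiation_ratio: float


@dataclass
class PanelStats:
    locus_ids: list[str]
    allele_counts: list[int]
    pic_values: list[float]
    detection_rates: list[float]
    mean_alleles: float
    sd_alleles: float
    mean_pic: float
    sd_pic: float
    n_loci_over_10_alleles: int


def _panel_of(fp: Fingerprint) -> tuple[str, ...]:
    return tuple(fp.calls.keys())


def genetic_similarity(fp_a: Fingerprint, fp_b: Fingerprint,
                       denominator_mode: str = "panel") -> ComparisonResult:
    """GS and differential-locus statistics for one accession pair."""
    if denominator_mode not in ("panel", "shared_called"):
        raise DataError(f"unknown denominator mode {denominator_mode!r}")
    panel_a, panel_b = _panel_of(fp_a), _panel_of(fp_b)
    if set(panel_a) != set(panel_b):
        raise DataError("fingerprints cover different panels")
    n_compared = n_identical = 0
    for locus in panel_a:
        call_a, call_b = fp_a.calls[locus], fp_b.calls[locus]
        if not (call_a.called and call_b.called):
            continue
        n_compared += 1
        if call_a.allele_set() == call_b.allele_set():
            n_identical += 1
    n_diff = n_compared - n_identical
    denom = len(panel_a) if denominator_mode == "panel" else n_compared
    gs = n_identical / denom if denom else 0.0
    ratio = n_diff / n_compared if n_compared else 0.0
    return ComparisonResult(fp_a.accession_id, fp_b.accession_id,
                            n_compared, n_identical, n_diff, gs, ratio)


def pairwise_compare(fingerprints: dict[str, Fingerprint],
                     denominator_mode: str = "panel"
                     ) -> list[ComparisonResult]:
    """All C(n, 2) comparisons in sorted accession-pair order."""
    accs = sorted(fingerprints)
    if len(accs) < 2:
        raise DataError("pairwise comparison needs at least two accessions")
    if len(accs) != len(fingerprints):
        raise DataError("duplicate accession ids")
    results = []
    for i, a in enumerate(accs):
        for b in accs[i + 1:]:
            results.append(genetic_similarity(fingerprints[a],
                                              fingerprints[b],
                                              denominator_mode))
    assert len(results) == comb(len(accs), 2)
    return results


def reproducibility(run1: dict[str, Fingerprint],
                    run2: dict[str, Fingerprint]
                    ) -> tuple[int, int, float]:
    """Compare two independent runs of the same accessions and panel.

    Returns (n_compared, n_reproducible, fraction) over accession x locus
    cells called in both runs; identical allele sets are reproducible.
    """
    if set(run1) != set(run2):
        raise DataError("the two runs cover different accession sets")
    n_compared = n_repro = 0
    for acc in sorted(run1):
        fp1, fp2 = run1[acc], run2[acc]
        if set(_panel_of(fp1)) != set(_panel_of(fp2)):
            raise DataError(f"panels differ between runs for {acc}")
        for locus in fp1.calls:
            c1, c2 = fp1.calls[locus], fp2.calls[locus]
            if c1.called and c2.called:
                n_compared += 1
                if c1.allele_set() == c2.allele_set():
                    n_repro += 1
    if n_compared == 0:
        raise DataError("no locus was called in both runs; "
                        "reproducibility is undefined")
    return n_compared, n_repro, n_repro / n_compared


def accuracy_from_reproducibility(r: float) -> float:
    """``1 - (1 - r) / 2``: of a discordant run pair, one run is wrong."""
    if not 0.0 <= r <= 1.0:
        raise DataError(f"reproducibility must lie in [0, 1], got {r}")
    return 1.0 - (1.0 - r) / 2.0


def pic(frequencies: Sequence[float]) -> float:
    """Polymorphism information content from allele frequencies."""
    freqs = np.asarray(frequencies, dtype=float)
    if freqs.size == 0:
        raise DataError("PIC needs at least one allele frequency")
    if abs(freqs.sum() - 1.0) > 1e-9:
        raise DataError("allele frequencies must sum to 1")
    s2 = float(np.sum(freqs ** 2))
    s4 = float(np.sum(freqs ** 4))
    return 1.0 - s2 - (s2 * s2 - s4)


def locus_allele_frequencies(fingerprints: dict[str, Fingerprint],
                             locus_id: str) -> dict[str, float]:
    """Allele frequencies at one locus: each accession's called allele set
    contributes one observation per member allele (ploidy-agnostic)."""
    counts: dict[str, int] = {}
    for fp in fingerprints.values():
        call = fp.calls.get(locus_id)
        if call is not None and call.called:
            for allele in call.allele_set():
                counts[allele] = counts.get(allele, 0) + 1
    total = sum(counts.values())
    return {a: c / total for a, c in counts.items()} if total else {}


def allele_stats(fingerprints: dict[str, Fingerprint]) -> PanelStats:
    """Per-locus allele counts, PIC and cohort detection rates."""
    if not fingerprints:
        raise DataError("allele_stats needs at least one fingerprint")
    any_fp = next(iter(fingerprints.values()))
    locus_ids = list(any_fp.calls.keys())
    n_acc = len(fingerprints)
    allele_counts, pics, det_rates = [], [], []
    for locus in locus_ids:
        freqs = locus_allele_frequencies(fingerprints, locus)
        called = sum(1 for fp in fingerprints.values()
                     if fp.calls[locus].called)
        allele_counts.append(len(freqs))
        pics.append(pic(list(freqs.values())) if freqs else 0.0)
        det_rates.append(called / n_acc)
    counts_arr = np.asarray(allele_counts, dtype=float)
    pic_arr = np.asarray(pics, dtype=float)

    def _sd(arr: np.ndarray) -> float:
        return float(np.std(arr, ddof=1)) if arr.size > 1 else 0.0

    return PanelStats(
        locus_ids=locus_ids, allele_counts=allele_counts, pic_values=pics,
        detection_rates=det_rates,
        mean_alleles=float(counts_arr.mean()), sd_alleles=_sd(counts_arr),
        mean_pic=float(pic_arr.mean()), sd_pic=_sd(pic_arr),
        n_loci_over_10_alleles=int(np.sum(counts_arr > 10)))


@dataclass
class MolecularID:
    accession_id: str
    canonical: str
    digest: str


def build_allele_registry(fingerprints: dict[str, Fingerprint]
                          ) -> dict[str, dict[str, int]]:
    """locus -> allele sequence -> integer index (lexicographic order)."""
    any_fp = next(iter(fingerprints.values()))
    registry: dict[str, dict[str, int]] = {}
    for locus in any_fp.calls:
        alleles = set()
        for fp in fingerprints.values():
            call = fp.calls.get(locus)
            if call is not None and call.called:
                alleles.update(call.alleles)
        registry[locus] = {seq: i for i, seq in enumerate(sorted(alleles))}
    return registry


def molecular_id(fingerprint: Fingerprint,
                 registry: dict[str, dict[str, int]]) -> MolecularID:
    """Canonical molecular ID code of one accession.

    The canonical string lists, locus by locus in panel order, the sorted
    allele indices (``.`` for a no-call); the digest is a fixed-length
    hexadecimal SHA-256 prefix of it. The canonical string is the
    normative identifier; the digest is a convenience handle.
    """
    parts = []
    for locus, call in fingerprint.calls.items():
        locus_registry = registry.setdefault(locus, {})
        if not call.called:
            parts.append(".")
            continue
        indices = []
        for allele in call.alleles:
            if allele not in locus_registry:
                locus_registry[allele] = (max(locus_registry.values(),
                                              default=-1) + 1)
                logger.warning("allele at %s absent from registry; extended "
                               "deterministically", locus)
            indices.append(locus_registry[allele])
        parts.append(",".join(map(str, sorted(indices))))
    canonical = ";".join(parts)
    digest = hashlib.sha256(canonical.encode()).hexdigest()[:16]
    return MolecularID(fingerprint.accession_id, canonical, digest)


def comparisons_to_frame(results: Sequence[ComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "accession_a": r.accession_a, "accession_b": r.accession_b,
        "n_compared": r.n_compared, "n_identical": r.n_identical,
        "n_differential": r.n_differential, "gs": r.gs,
        "differentiation_ratio": r.differentiation_ratio,
    } for r in results])


def panel_stats_to_frame(stats: PanelStats) -> pd.DataFrame:
    return pd.DataFrame({
        "locus_id": stats.locus_ids,
        "allele_count": stats.allele_counts,
        "pic": stats.pic_values,
        "detection_rate": stats.detection_rates,
    })


def write_tsv(frame: pd.DataFrame, path: str | Path) -> None:
    frame.to_csv(path, sep="\t", index=False)
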