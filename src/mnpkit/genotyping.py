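"""Amplicon read groups -> MNP genotype calls (allele-sequence sets).

Allele identity is the full amplicon sequence: two accessions share a
genotype at a locus only when their amplicon sequence sets are identical.
Reads reach their locus either through an identity tag embedded in the
read name (``accession|locus|index``, the simulator contract) or through
exact, orientation-aware matching of the locus's primer-landing flanks.
No alignment or mapping is performed.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

from .config import GenotypingConfig
from .errors import DataError
from .screening import MNPPanel
from .simulate import READ_NAME_DELIMITER

logger = logging.getLogger(__name__)

STATUS_CALLED = "called"
STATUS_LOW_DEPTH = "no_call_low_depth"
STATUS_UNASSIGNED = "no_call_unassigned"

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class AlleleCall:
    locus_id: str
    alleles: tuple[str, ...] = ()
    depth: int = 0
    allele_fractions: dict[str, float] = field(default_factory=dict)
    status: str = STATUS_LOW_DEPTH

    @property
    def called(self) -> bool:
        return self.status == STATUS_CALLED

    def allele_set(self) -> frozenset[str]:
        return frozenset(self.alleles)


@dataclass
class Fingerprint:
    """Full-panel genotype of one accession (no-calls explicit)."""

    accession_id: str
    calls: dict[str, AlleleCall] = field(default_factory=dict)

    def n_detected(self) -> int:
        return sum(c.called for c in self.calls.values())


def assign_reads_to_loci(reads: Iterable[tuple[str, str]], panel: MNPPanel,
                         mode: str = "tagged",
                         flank_bp: int = 20
                         ) -> tuple[dict[str, list[str]], int]:
    """Group read sequences by locus; returns (groups, n_unassigned).

    ``tagged`` mode parses the locus id from the read name (second field,
    ``|``-delimited). ``flank`` mode requires both terminal ``flank_bp``
    bases of a locus's reference amplicon to match exactly; the reverse
    complement is attempted before giving up.
    """
    if mode not in ("tagged", "flank"):
        raise DataError(f"unknown assignment mode {mode!r}")
    groups: dict[str, list[str]] = {lid: [] for lid in panel.locus_ids()}
    unassigned = 0
    if mode == "tagged":
        for name, seq in reads:
            parts = name.split(READ_NAME_DELIMITER)
            locus = parts[1] if len(parts) >= 2 else None
            if locus in groups:
                groups[locus].append(seq)
            else:
                unassigned += 1
                logger.debug("read %s: unknown locus tag", name)
    else:
        flanks = {}
        for loc in panel.loci:
            if not loc.ref_seq:
                raise DataError(
                    f"flank assignment needs reference amplicon sequences "
                    f"(missing for {loc.locus_id})")
            flanks[(loc.ref_seq[:flank_bp], loc.ref_seq[-flank_bp:])] = \
                loc.locus_id
        for _, seq in reads:
            locus = flanks.get((seq[:flank_bp], seq[-flank_bp:]))
            if locus is None:
                rc = reverse_complement(seq)
                locus = flanks.get((rc[:flank_bp], rc[-flank_bp:]))
                seq = rc if locus is not None else seq
            if locus is None:
                unassigned += 1
            else:
                groups[locus].append(seq)
    return groups, unassigned


def collapse_errors(sequences: Iterable[str],
                    config: GenotypingConfig | None = None) -> Counter:
    """Tally exact sequences, folding likely sequencing errors.

    A sequence whose count fraction is below ``error_collapse_fraction``
    and which lies within ``error_collapse_max_mismatch`` substitutions of
    a sequence at least ``error_collapse_ratio`` times more abundant is
    folded into that sequence. Rare sequences are processed in descending
    count (ties lexicographic) against current counts, and passes repeat
    until a fixpoint: an absorbing sequence grows as errors fold into it,
    which can qualify further fragments on the next pass. Deterministic.
    """
    config = (config or GenotypingConfig()).validate()
    counts = Counter(sequences)
    total = sum(counts.values())
    if total == 0:
        return counts
    changed = True
    while changed:
        changed = False
        rare = sorted((s for s, c in counts.items()
                       if c / total < config.error_collapse_fraction),
                      key=lambda s: (-counts[s], s))
        for seq in rare:
            count = counts[seq]
            best = None
            for target in sorted(counts, key=lambda s: (-counts[s], s)):
                if target == seq or counts[target] < \
                        config.error_collapse_ratio * count:
                    continue
                if _within_mismatch(seq, target,
                                    config.error_collapse_max_mismatch):
                    best = target
                    break
            if best is not None:
                counts[best] += count
                del counts[seq]
                changed = True
    return counts


def _within_mismatch(a: str, b: str, max_mismatch: int) -> bool:
    if len(a) != len(b):
        return False
    mismatches = 0
    for x, y in zip(a, b):
        if x != y:
            mismatches += 1
            if mismatches > max_mismatch:
                return False
    return True


def call_genotype(counts: Counter, locus_id: str,
                  config: GenotypingConfig | None = None) -> AlleleCall:
    """Allele set from collapsed sequence counts.

    Depth below ``min_locus_depth`` is a no-call. Alleles are the
    sequences with read fraction >= ``min_allele_fraction``, capped at
    ``max_alleles_per_locus`` by descending count (ties lexicographic);
    exceeding the cap is logged, not fatal, because ploidy is not assumed.
    """
    config = (config or GenotypingConfig()).validate()
    depth = sum(counts.values())
    if depth < config.min_locus_depth:
        return AlleleCall(locus_id=locus_id, depth=depth,
                          status=STATUS_LOW_DEPTH)
    passing = [(s, c) for s, c in counts.items()
               if c / depth >= config.min_allele_fraction]
    passing.sort(key=lambda item: (-item[1], item[0]))
    if not passing:
        return AlleleCall(locus_id=locus_id, depth=depth,
                          status=STATUS_UNASSIGNED)
    if len(passing) > config.max_alleles_per_locus:
        logger.warning("locus %s: %d alleles exceed cap %d; keeping the "
                       "most abundant", locus_id, len(passing),
                       config.max_alleles_per_locus)
        passing = passing[:config.max_alleles_per_locus]
    alleles = tuple(sorted(s for s, _ in passing))
    fractions = {s: c / depth for s, c in passing}
    return AlleleCall(locus_id=locus_id, alleles=alleles, depth=depth,
                      allele_fractions=fractions, status=STATUS_CALLED)


def genotype_accession(accession_id: str, reads: Iterable[tuple[str, str]],
                       panel: MNPPanel,
                       config: GenotypingConfig | None = None,
                       mode: str = "tagged") -> tuple[Fingerprint, int]:
    """Genotype one accession; returns (fingerprint, n_unassigned_reads)."""
    config = (config or GenotypingConfig()).validate()
    groups, unassigned = assign_reads_to_loci(reads, panel, mode=mode)
    calls = {}
    for locus_id in panel.locus_ids():
        collapsed = collapse_errors(groups[locus_id], config)
        calls[locus_id] = call_genotype(collapsed, locus_id, config)
    return Fingerprint(accession_id=accession_id, calls=calls), unassigned


def genotype_cohort(reads: Iterable[tuple[str, str]], panel: MNPPanel,
                    config: GenotypingConfig | None = None,
                    mode: str = "tagged"
                    ) -> tuple[dict[str, Fingerprint], pd.DataFrame]:
    """Genotype every accession found in a tagged read stream.

    Returns fingerprints keyed by accession and a per-sample summary table
    (total reads, detected loci, detection rate, mean locus coverage over
    detected loci).
    """
    config = (config or GenotypingConfig()).validate()
    per_acc: dict[str, list[tuple[str, str]]] = {}
    for name, seq in reads:
        acc = name.split(READ_NAME_DELIMITER)[0]
        per_acc.setdefault(acc, []).append((name, seq))
    fingerprints = {}
    rows = []
    for acc in sorted(per_acc):
        fp, unassigned = genotype_accession(acc, per_acc[acc], panel,
                                            config, mode=mode)
        fingerprints[acc] = fp
        detected = [c for c in fp.calls.values() if c.called]
        rows.append({
            "accession_id": acc,
            "total_reads": len(per_acc[acc]),
            "unassigned_reads": unassigned,
            "detected_loci": len(detected),
            "detection_rate": detection_rate(fp, len(panel)),
            "mean_locus_coverage": (sum(c.depth for c in detected)
                                    / len(detected) if detected else 0.0),
        })
    summary = pd.DataFrame(rows)
    return fingerprints, summary


def detection_rate(fingerprint: Fingerprint, panel_size: int) -> float:
    """(number of detected loci) / (total target loci)."""
    if panel_size < 1:
        raise DataError("panel_size must be >= 1")
    return fingerprint.n_detected() / panel_size


_FP_COLUMNS = ["accession_id", "locus_id", "status", "depth", "alleles",
               "fractions"]


def write_fingerprints(fingerprints: dict[str, Fingerprint],
                       path: str | Path) -> None:
    rows = []
    for acc in sorted(fingerprints):
        fp = fingerprints[acc]
        for locus_id, call in fp.calls.items():
            rows.append({
                "accession_id": acc,
                "locus_id": locus_id,
                "status": call.status,
                "depth": call.depth,
                "alleles": ";".join(call.alleles),
                "fractions": ";".join(
                    f"{call.allele_fractions[a]:.4f}" for a in call.alleles),
            })
    pd.DataFrame(rows, columns=_FP_COLUMNS).to_csv(path, sep="\t",
                                                   index=False)


def read_fingerprints(path: str | Path) -> dict[str, Fingerprint]:
    path = Path(path)
    if not path.exists():
        raise DataError(f"fingerprint file not found: {path}")
    frame = pd.read_csv(path, sep="\t", keep_default_na=False, dtype=str)
    out: dict[str, Fingerprint] = {}
    for _, row in frame.iterrows():
        fp = out.setdefault(row["accession_id"],
                            Fingerprint(accession_id=row["accession_id"]))
        alleles = tuple(a for a in row["alleles"].split(";") if a)
        fracs = [float(x) for x in row["fractions"].split(";") if x]
        fp.calls[row["locus_id"]] = AlleleCall(
            locus_id=row["locus_id"], alleles=alleles,
            depth=int(row["depth"]),
            allele_fractions=dict(zip(alleles, fracs)),
            status=row["status"])
    return out
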