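"""Sliding-window discovery of MNP marker loci.

An MNP (multiple nucleotide polymorphism) marker is a short amplicon whose
several tightly linked SNPs form one multi-allelic haplotype marker.
Discovery scans every window position (300 bp, 1-bp step by default) over the
filtered SNP set; a window is admitted when it holds more than
``min_snps_exclusive`` SNPs and its haplotype discriminative power (DP) —
the fraction of accession pairs whose window genotypes differ — reaches
``dp_min``. Overlapping admitted windows are merged into runs, one
representative locus per run, amplicons are constrained to 200-300 bp with
SNP-free primer-landing flanks, and a genome-spaced panel is assembled
greedily by DP.

Coordinates are 0-based half-open throughout this module.
"""

from __future__ import annotations

import hashlib
import logging
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import ScreeningConfig
from .errors import DataError
from .variants import GenotypeMatrix, HET, HOM_ALT, HOM_REF, MISSING

logger = logging.getLogger(__name__)

# IUPAC ambiguity code for an unphased heterozygous base pair
IUPAC_HET = {frozenset("AC"): "M", frozenset("AG"): "R", frozenset("AT"): "W",
             frozenset("CG"): "S", frozenset("CT"): "Y", frozenset("GT"): "K"}


def haplotype_of(codes: Sequence[int], refs: Sequence[str],
                 alts: Sequence[str]) -> Optional[str]:
    """Window genotype label for one sample: per-SNP symbols concatenated.

    Hom-ref -> ref base, hom-alt -> alt base, het -> IUPAC ambiguity code.
    Returns ``None`` when any constituent call is missing.
    """
    if len(codes) == 0:
        raise DataError("haplotype_of needs at least one SNP position")
    out = []
    for code, ref, alt in zip(codes, refs, alts):
        if code == MISSING:
            return None
        if code == HOM_REF:
            out.append(ref)
        elif code == HOM_ALT:
            out.append(alt)
        elif code == HET:
            out.append(IUPAC_HET[frozenset((ref, alt))])
        else:
            raise DataError(f"unknown genotype code {code}")
    return "".join(out)


def discriminative_power(labels: Sequence) -> float:
    """Fraction of unordered sample pairs with different genotype labels.

    Missing labels (``None``) are excluded from both numerator and
    denominator. Closed form: 1 - sum C(n_i, 2) / C(n, 2) over label
    multiplicities n_i.
    """
    present = [lab for lab in labels if lab is not None]
    n = len(present)
    if n < 2:
        raise DataError("discriminative power needs >= 2 non-missing labels")
    counts: dict = {}
    for lab in present:
        counts[lab] = counts.get(lab, 0) + 1
    same = sum(c * (c - 1) // 2 for c in counts.values())
    total = n * (n - 1) // 2
    return 1.0 - same / total


@dataclass(frozen=True)
class QualifyingWindowRun:
    """A maximal run of window starts sharing one SNP subset that qualify.

    ``start_lo``..``start_hi`` (inclusive) are the qualifying window start
    positions; with a 1-bp step each start in the range is an admitted
    window.
    """

    contig: str
    start_lo: int
    start_hi: int
    snp_indices: tuple[int, ...]   # row indices into the GenotypeMatrix
    dp: float

    @property
    def n_snps(self) -> int:
        return len(self.snp_indices)


@dataclass
class CandidateLocus:
    contig: str
    window_start: int
    window_end: int
    snp_positions: tuple[int, ...]
    dp: float
    amplicon_start: int
    amplicon_end: int
    haplotype_table: dict[str, Optional[str]] = field(default_factory=dict)
    ref_seq: Optional[str] = None
    locus_id: str = ""

    @property
    def n_snps(self) -> int:
        return len(self.snp_positions)

    @property
    def amplicon_length(self) -> int:
        return self.amplicon_end - self.amplicon_start


@dataclass
class MNPPanel:
    loci: list[CandidateLocus]
    panel_id: str = ""

    def __post_init__(self) -> None:
        if not self.panel_id:
            self.panel_id = panel_digest(self.loci)

    def __len__(self) -> int:
        return len(self.loci)

    def locus_ids(self) -> list[str]:
        return [loc.locus_id for loc in self.loci]

    def by_id(self) -> dict[str, CandidateLocus]:
        return {loc.locus_id: loc for loc in self.loci}


def panel_digest(loci: Sequence[CandidateLocus]) -> str:
    text = ";".join(f"{l.contig}:{l.amplicon_start}-{l.amplicon_end}:"
                    f"{','.join(map(str, l.snp_positions))}" for l in loci)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def _window_dp(gm: GenotypeMatrix, snp_idx: Sequence[int]) -> Optional[float]:
    """DP over window haplotype labels; None when < 2 samples are callable."""
    sub = gm.genotypes[list(snp_idx), :]
    # label per sample: tuple of codes; missing if any constituent missing
    labels = []
    missing_any = (sub == MISSING).any(axis=0)
    for j in range(gm.n_samples):
        labels.append(None if missing_any[j] else tuple(sub[:, j].tolist()))
    present = sum(lab is not None for lab in labels)
    if present < 2:
        return None
    return discriminative_power(labels)


def scan_windows(gm: GenotypeMatrix, config: ScreeningConfig | None = None
                 ) -> list[QualifyingWindowRun]:
    """Emit every qualifying window of the genome-wide sliding scan.

    Equivalent to evaluating each window start independently (the brute
    force definition) but implemented as a sweep over the O(n_snps) start
    intervals within which the covered SNP subset is constant.
    """
    config = (config or ScreeningConfig()).validate()
    if not gm.is_sorted():
        raise DataError("GenotypeMatrix must be sorted by (contig, position)")
    w, step = config.window_bp, config.step_bp
    runs: list[QualifyingWindowRun] = []
    contigs = np.asarray(gm.contigs)
    for contig in sorted(set(contigs.tolist())):
        length = gm.contig_lengths.get(contig)
        if length is None:
            raise DataError(f"no length known for contig {contig!r}")
        if length < w:
            logger.warning("contig %s (%d bp) shorter than window (%d bp); "
                           "skipped", contig, length, w)
            continue
        rows = np.flatnonzero(contigs == contig)
        pos = gm.positions[rows]
        plist = pos.tolist()
        last_start = length - w
        # breakpoints where the window SNP subset changes
        events = {0}
        for p in pos.tolist():
            events.add(p - w + 1)   # SNP enters at this start
            events.add(p + 1)       # SNP has exited at this start
        bounds = sorted(e for e in events if 0 <= e <= last_start)
        bounds.append(last_start + 1)
        for lo, hi_excl in zip(bounds, bounds[1:]):
            hi = hi_excl - 1
            # align to the step grid
            first = lo if lo % step == 0 else lo + (step - lo % step)
            if first > hi:
                continue
            last = hi - (hi - first) % step
            i = bisect_left(plist, lo)
            j = bisect_right(plist, lo + w - 1)
            if j - i <= config.min_snps_exclusive:
                continue
            snp_idx = tuple(int(r) for r in rows[i:j])
            dp = _window_dp(gm, snp_idx)
            if dp is None or dp < config.dp_min:
                continue
            runs.append(QualifyingWindowRun(contig, first, last, snp_idx, dp))
    return runs


def iter_window_starts(runs: Sequence[QualifyingWindowRun],
                       step_bp: int = 1):
    """Expand runs into individual (contig, start, snp_indices, dp)."""
    for run in runs:
        for start in range(run.start_lo, run.start_hi + 1, step_bp):
            yield run.contig, start, run.snp_indices, run.dp


def amplicon_bounds(snp_lo: int, snp_hi: int, contig_length: int,
                    config: ScreeningConfig) -> Optional[tuple[int, int]]:
    """Amplicon span for SNPs in [snp_lo, snp_hi]: tightest SNP span plus
    ``flank_clear_bp`` on each side, widened symmetrically to the minimum
    amplicon length and clamped to the contig. Returns None when the
    length constraint cannot be met.
    """
    start = snp_lo - config.flank_clear_bp
    end = snp_hi + 1 + config.flank_clear_bp
    if end - start < config.amplicon_min_bp:
        deficit = config.amplicon_min_bp - (end - start)
        start -= deficit // 2
        end += deficit - deficit // 2
    if start < 0:
        end += -start
        start = 0
    if end > contig_length:
        start -= end - contig_length
        end = contig_length
    if start < 0:
        return None
    if not (config.amplicon_min_bp <= end - start <= config.amplicon_max_bp):
        return None
    return start, end


def merge_to_candidates(runs: Sequence[QualifyingWindowRun],
                        gm: GenotypeMatrix,
                        config: ScreeningConfig | None = None,
                        reference: dict[str, str] | None = None
                        ) -> list[CandidateLocus]:
    """Merge overlapping qualifying windows into candidate loci.

    Windows whose spans overlap form a run-chain; within each chain the
    single window maximizing (DP, SNP count, leftmost start) represents the
    locus. The amplicon must keep its flanks free of ANY filtered SNP;
    candidates violating the amplicon rules are dropped with a log entry.
    """
    config = (config or ScreeningConfig()).validate()
    w = config.window_bp
    by_contig: dict[str, list[QualifyingWindowRun]] = {}
    for run in runs:
        by_contig.setdefault(run.contig, []).append(run)
    contig_pos = {c: sorted(gm.positions[np.asarray(gm.contigs) == c].tolist())
                  for c in by_contig}
    candidates: list[CandidateLocus] = []
    for contig in sorted(by_contig):
        chain: list[QualifyingWindowRun] = []
        chains: list[list[QualifyingWindowRun]] = []
        for run in sorted(by_contig[contig], key=lambda r: r.start_lo):
            if chain and run.start_lo - chain[-1].start_hi >= w:
                chains.append(chain)
                chain = []
            chain.append(run)
        if chain:
            chains.append(chain)
        for chain in chains:
            # The representative window should capture the full local SNP
            # cluster, so rank by SNP count before DP: within one run DP
            # differences are mostly missing-call noise, and a subset
            # window would leave the remaining SNPs in the primer flanks.
            # When the best window's amplicon is infeasible (length or
            # occupied flank) fall back to the next-ranked window.
            ranked = sorted(chain,
                            key=lambda r: (-r.n_snps, -r.dp, r.start_lo))
            for run in ranked:
                cand = _build_candidate(run, gm, contig_pos[contig], config,
                                        reference)
                if cand is not None:
                    candidates.append(cand)
                    break
            else:
                logger.info("qualifying run at %s:%d dropped entirely: no "
                            "window yields a feasible amplicon", contig,
                            chain[0].start_lo)
    candidates.sort(key=lambda c: (c.contig, c.amplicon_start))
    for cand in candidates:
        cand.locus_id = f"MNP_{cand.contig}_{cand.amplicon_start}"
    return candidates


def _build_candidate(run: QualifyingWindowRun, gm: GenotypeMatrix,
                     all_positions: list[int], config: ScreeningConfig,
                     reference: dict[str, str] | None
                     ) -> Optional[CandidateLocus]:
    snp_pos = [int(gm.positions[i]) for i in run.snp_indices]
    length = gm.contig_lengths[run.contig]
    bounds = amplicon_bounds(snp_pos[0], snp_pos[-1], length, config)
    if bounds is None:
        logger.info("candidate at %s:%d dropped: amplicon length constraint "
                    "unsatisfiable", run.contig, run.start_lo)
        return None
    amp_start, amp_end = bounds
    # flanks (amplicon minus SNP span) must be SNP-free for primer landing
    lo = bisect_left(all_positions, amp_start)
    hi = bisect_right(all_positions, amp_end - 1)
    inside = all_positions[lo:hi]
    if any(p < snp_pos[0] or p > snp_pos[-1] for p in inside):
        logger.info("candidate at %s:%d dropped: foreign SNP in primer "
                    "flank", run.contig, run.start_lo)
        return None
    refs = [str(gm.ref[i]) for i in run.snp_indices]
    alts = [str(gm.alt[i]) for i in run.snp_indices]
    table = {}
    for j, sample in enumerate(gm.samples):
        codes = [int(gm.genotypes[i, j]) for i in run.snp_indices]
        table[sample] = haplotype_of(codes, refs, alts)
    ref_seq = None
    if reference is not None:
        ref_seq = reference[run.contig][amp_start:amp_end]
    return CandidateLocus(
        contig=run.contig, window_start=run.start_lo,
        window_end=run.start_lo + config.window_bp,
        snp_positions=tuple(snp_pos), dp=run.dp,
        amplicon_start=amp_start, amplicon_end=amp_end,
        haplotype_table=table, ref_seq=ref_seq)


def space_panel(candidates: Sequence[CandidateLocus],
                config: ScreeningConfig | None = None) -> MNPPanel:
    """Greedy genome-spaced panel selection.

    Candidates are taken in descending (DP, SNP count), leftmost-first,
    contig-lexicographic order; a candidate within ``min_spacing_bp``
    (start-to-start) of an already selected locus on the same contig is
    skipped. Selection stops at ``target_panel_size``.
    """
    config = (config or ScreeningConfig()).validate()
    ranked = sorted(candidates,
                    key=lambda c: (-c.dp, -c.n_snps, c.amplicon_start,
                                   c.contig))
    chosen: list[CandidateLocus] = []
    starts: dict[str, list[int]] = {}
    for cand in ranked:
        if len(chosen) >= config.target_panel_size:
            break
        taken = starts.setdefault(cand.contig, [])
        if any(abs(cand.amplicon_start - s) < config.min_spacing_bp
               for s in taken):
            continue
        chosen.append(cand)
        taken.append(cand.amplicon_start)
    chosen.sort(key=lambda c: (c.contig, c.amplicon_start))
    return MNPPanel(loci=chosen)


def screen_panel(gm: GenotypeMatrix, config: ScreeningConfig | None = None,
                 reference: dict[str, str] | None = None) -> MNPPanel:
    """Full screen: sliding windows -> candidates -> spaced panel."""
    config = (config or ScreeningConfig()).validate()
    runs = scan_windows(gm, config)
    candidates = merge_to_candidates(runs, gm, config, reference)
    logger.info("screening: %d qualifying runs, %d candidate loci",
                len(runs), len(candidates))
    panel = space_panel(candidates, config)
    logger.info("screening: %d loci selected into the panel", len(panel))
    return panel


_PANEL_COLUMNS = ["contig", "amplicon_start", "amplicon_end", "locus_id",
                  "dp", "n_snps", "snp_positions", "ref_seq"]


def write_panel(panel: MNPPanel, path: str | Path) -> None:
    """Panel as BED-like TSV; coordinates 0-based half-open."""
    rows = []
    for loc in panel.loci:
        rows.append({
            "contig": loc.contig,
            "amplicon_start": loc.amplicon_start,
            "amplicon_end": loc.amplicon_end,
            "locus_id": loc.locus_id,
            "dp": round(loc.dp, 6),
            "n_snps": loc.n_snps,
            "snp_positions": ",".join(map(str, loc.snp_positions)),
            "ref_seq": loc.ref_seq or "",
        })
    frame = pd.DataFrame(rows, columns=_PANEL_COLUMNS)
    with open(path, "w") as handle:
        handle.write(f"# mnpkit panel {panel.panel_id}; "
                     "coordinates 0-based half-open\n")
        frame.to_csv(handle, sep="\t", index=False)


def read_panel(path: str | Path) -> MNPPanel:
    path = Path(path)
    if not path.exists():
        raise DataError(f"panel file not found: {path}")
    frame = pd.read_csv(path, sep="\t", comment="#",
                        keep_default_na=False, dtype=str)
    loci = []
    for _, row in frame.iterrows():
        snps = tuple(int(x) for x in row["snp_positions"].split(",") if x)
        start, end = int(row["amplicon_start"]), int(row["amplicon_end"])
        loci.append(CandidateLocus(
            contig=row["contig"], window_start=start, window_end=end,
            snp_positions=snps, dp=float(row["dp"]),
            amplicon_start=start, amplicon_end=end,
            ref_seq=row["ref_seq"] or None, locus_id=row["locus_id"]))
    return MNPPanel(loci=loci)
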