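"""Sliding-window MNP screening: DP, window scan vs brute force, merging,
panel spacing."""

import itertools
from bisect import bisect_left, bisect_right
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mnpkit.config import ScreeningConfig
from mnpkit.errors import DataError
from mnpkit.filtering import filter_variants
from mnpkit.screening import (CandidateLocus, discriminative_power,
                              haplotype_of, iter_window_starts,
                              merge_to_candidates, scan_windows,
                              space_panel, screen_panel)
from mnpkit.simulate import (generate_population_variants,
                             generate_reference)
from mnpkit.config import SimulationConfig
from tests.conftest import make_matrix


def brute_force_windows(gm, config):
    """Evaluate every window start independently (the oracle)."""
    out = {}
    contigs = np.asarray(gm.contigs)
    for contig in sorted(set(contigs.tolist())):
        length = gm.contig_lengths[contig]
        if length < config.window_bp:
            continue
        rows = np.flatnonzero(contigs == contig)
        pos = gm.positions[rows].tolist()
        for start in range(0, length - config.window_bp + 1,
                           config.step_bp):
            i = bisect_left(pos, start)
            j = bisect_right(pos, start + config.window_bp - 1)
            if j - i <= config.min_snps_exclusive:
                continue
            idx = [int(r) for r in rows[i:j]]
            labels = []
            for s in range(gm.n_samples):
                codes = [int(gm.genotypes[r, s]) for r in idx]
                labels.append(None if -1 in codes else tuple(codes))
            present = [l for l in labels if l is not None]
            if len(present) < 2:
                continue
            pairs = list(itertools.combinations(present, 2))
            dp = sum(a != b for a, b in pairs) / len(pairs)
            if dp >= config.dp_min:
                out[(contig, start)] = (tuple(idx), dp)
    return out


class TestHaplotypeOf:
    def test_all_hom_ref(self):
        assert haplotype_of([0, 0, 0, 0], "ACGT", "GTAC") == "ACGT"

    def test_missing_constituent_is_missing(self):
        assert haplotype_of([0, -1, 0, 0], "ACGT", "GTAC") is None

    def test_het_uses_iupac_code(self):
        # A/G het -> R; the others hom-ref
        assert haplotype_of([1, 0, 0, 0], "ACGT", "GTAC") == "RCGT"

    def test_hom_alt_uses_alt_base(self):
        assert haplotype_of([2, 0], "AC", "GT") == "GC"


class TestDiscriminativePower:
    def test_all_identical_is_zero(self):
        assert discriminative_power(["g"] * 30) == 0.0

    def test_all_distinct_is_one(self):
        assert discriminative_power([f"g{i}" for i in range(30)]) == 1.0

    def test_two_by_two(self):
        assert discriminative_power(["g1", "g1", "g2", "g2"]) == \
            pytest.approx(4 / 6)

    def test_missing_excluded(self):
        assert discriminative_power(["a", "a", None, "b"]) == \
            pytest.approx(2 / 3)

    def test_fewer_than_two_labels_rejected(self):
        with pytest.raises(DataError):
            discriminative_power(["a", None])

    @given(st.lists(st.integers(0, 3), min_size=2, max_size=40))
    @settings(max_examples=200, deadline=None)
    def test_closed_form_equals_pair_enumeration(self, labels):
        pairs = list(itertools.combinations(labels, 2))
        oracle = sum(a != b for a, b in pairs) / len(pairs)
        assert discriminative_power(labels) == pytest.approx(oracle,
                                                             abs=1e-12)


def _four_snp_contig():
    """4 SNPs at 100/150/200/250 with fully distinct sample haplotypes."""
    samples = [f"S{i}" for i in range(6)]
    codes = [[0, 0, 1, 1, 2, 2], [0, 1, 0, 2, 1, 2],
             [0, 2, 2, 0, 1, 1], [0, 1, 2, 1, 0, 2]]
    snps = {"C1": [(100, "A", "G", codes[0]), (150, "C", "T", codes[1]),
                   (200, "G", "A", codes[2]), (250, "T", "C", codes[3])]}
    return make_matrix(snps, samples, {"C1": 2000})


class TestScanWindows:
    def test_windows_covering_all_four_snps(self):
        gm = _four_snp_contig()
        cfg = ScreeningConfig()
        runs = scan_windows(gm, cfg)
        starts = sorted(s for _, s, _, _ in iter_window_starts(runs))
        # only windows covering all 4 SNPs qualify (> 3 SNPs needed):
        # start <= 100 and start + 300 > 250
        assert starts == list(range(0, 101))

    def test_exactly_three_snps_not_emitted(self):
        gm = _four_snp_contig()
        gm = gm.subset(np.array([True, True, True, False]))
        assert scan_windows(gm, ScreeningConfig()) == []

    def test_no_snps_no_windows(self):
        gm = make_matrix({}, ["S1", "S2"], {"C1": 1000})
        assert scan_windows(gm, ScreeningConfig()) == []

    def test_short_contig_skipped(self):
        samples = [f"S{i}" for i in range(4)]
        gm = make_matrix(
            {"TINY": [(10, "A", "G", [0, 1, 2, 1])]}, samples,
            {"TINY": 120})
        assert scan_windows(gm, ScreeningConfig()) == []

    def test_equals_brute_force_oracle_on_simulated_contigs(self):
        cfg = SimulationConfig(n_contigs=4, contig_length_bp=6000,
                               n_accessions=12, planted_locus_count=8,
                               n_founder_haplotypes=6, snp_rate=1e-3,
                               rng_seed=17)
        ref = generate_reference(cfg)
        gm, _ = generate_population_variants(ref, cfg)
        scfg = ScreeningConfig()
        runs = scan_windows(gm, scfg)
        swept = {(c, s): (idx, dp)
                 for c, s, idx, dp in iter_window_starts(runs)}
        oracle = brute_force_windows(gm, scfg)
        assert swept.keys() == oracle.keys()
        for key, (idx, dp) in swept.items():
            assert idx == oracle[key][0]
            assert dp == pytest.approx(oracle[key][1], abs=1e-12)

    def test_equals_brute_force_with_coarser_step(self):
        gm = _four_snp_contig()
        cfg = ScreeningConfig(step_bp=7)
        swept = {(c, s) for c, s, _, _ in
                 iter_window_starts(scan_windows(gm, cfg), cfg.step_bp)}
        assert swept == set(brute_force_windows(gm, cfg))


class TestMergeToCandidates:
    def test_isolated_run_yields_one_candidate(self):
        gm = _four_snp_contig()
        cands = merge_to_candidates(scan_windows(gm), gm)
        assert len(cands) == 1
        cand = cands[0]
        assert cand.snp_positions == (100, 150, 200, 250)
        # SNP span 100..250 plus 20-bp flanks is 191 bp; widened
        # symmetrically to the 200-bp amplicon minimum
        assert (cand.amplicon_start, cand.amplicon_end) == (76, 276)
        assert 200 <= cand.amplicon_length <= 300

    def test_two_separated_runs_yield_two_candidates(self):
        samples = [f"S{i}" for i in range(6)]
        codes = [[0, 0, 1, 1, 2, 2], [0, 1, 0, 2, 1, 2],
                 [0, 2, 2, 0, 1, 1], [0, 1, 2, 1, 0, 2]]
        snps = {"C1": [(p, "A", "G", codes[k % 4])
                       for k, p in enumerate(
                           [100, 150, 200, 250, 1400, 1450, 1500, 1550])]}
        gm = make_matrix(snps, samples, {"C1": 3000})
        cands = merge_to_candidates(scan_windows(gm), gm)
        assert len(cands) == 2
        assert [c.snp_positions[0] for c in cands] == [100, 1400]

    def test_wide_span_with_flanks_dropped(self, caplog):
        samples = [f"S{i}" for i in range(6)]
        codes = [[0, 0, 1, 1, 2, 2], [0, 1, 0, 2, 1, 2],
                 [0, 2, 2, 0, 1, 1], [0, 1, 2, 1, 0, 2]]
        # SNP span 290 bp -> amplicon would be 330 bp > 300
        snps = {"C1": [(100, "A", "G", codes[0]), (200, "C", "T", codes[1]),
                       (300, "G", "A", codes[2]),
                       (389, "T", "C", codes[3])]}
        gm = make_matrix(snps, samples, {"C1": 2000})
        with caplog.at_level("INFO"):
            cands = merge_to_candidates(scan_windows(gm), gm)
        assert cands == []
        assert "amplicon" in caplog.text

    def test_haplotype_table_strings(self):
        gm = _four_snp_contig()
        cand = merge_to_candidates(scan_windows(gm), gm)[0]
        assert cand.haplotype_table["S0"] == "ACGT"   # all hom-ref
        assert len(set(cand.haplotype_table.values())) == 6


def _candidate(contig, start, dp, n_snps=5):
    positions = tuple(range(start + 30, start + 30 + n_snps))
    return CandidateLocus(contig=contig, window_start=start,
                          window_end=start + 300,
                          snp_positions=positions, dp=dp,
                          amplicon_start=start + 10,
                          amplicon_end=start + 240,
                          locus_id=f"{contig}_{start}")


class TestSpacePanel:
    def test_nearby_pair_keeps_higher_dp(self):
        a = _candidate("C1", 0, dp=0.9)
        b = _candidate("C1", 5000, dp=0.95)
        panel = space_panel([a, b], ScreeningConfig(min_spacing_bp=10_000))
        assert panel.locus_ids() == [b.locus_id]

    def test_distinct_contigs_all_selected(self):
        cands = [_candidate(f"C{i}", 0, dp=0.5 + i / 100)
                 for i in range(5)]
        panel = space_panel(cands, ScreeningConfig(target_panel_size=10))
        assert len(panel) == 5

    def test_target_size_and_spacing_respected(self):
        rng = np.random.default_rng(4)
        cands = [_candidate(f"C{i % 40}", 12_000 * (i // 40),
                            dp=float(rng.uniform(0.2, 1.0)))
                 for i in range(400)]
        cfg = ScreeningConfig(target_panel_size=150)
        panel = space_panel(cands, cfg)
        assert len(panel) == 150
        per_contig = {}
        for loc in panel.loci:
            per_contig.setdefault(loc.contig, []).append(
                loc.amplicon_start)
        for starts in per_contig.values():
            starts.sort()
            assert all(b - a >= cfg.min_spacing_bp
                       for a, b in zip(starts, starts[1:]))


class TestPanelInvariants:
    def test_every_panel_locus_satisfies_admission_rules(self):
        cfg = SimulationConfig(n_contigs=30, contig_length_bp=6000,
                               n_accessions=20, planted_locus_count=30,
                               n_founder_haplotypes=8, snp_rate=5e-4,
                               rng_seed=23)
        ref = generate_reference(cfg)
        gm, _ = generate_population_variants(ref, cfg)
        retained, _ = filter_variants(gm)
        scfg = ScreeningConfig(target_panel_size=40)
        panel = screen_panel(retained, scfg, ref)
        assert len(panel) > 0
        for loc in panel.loci:
            assert loc.n_snps > 3
            assert loc.dp >= 0.2
            assert 200 <= loc.amplicon_length <= 300
            labels = list(loc.haplotype_table.values())
            assert discriminative_power(labels) == pytest.approx(loc.dp)
            assert all(loc.amplicon_start <= p < loc.amplicon_end
                       for p in loc.snp_positions)
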