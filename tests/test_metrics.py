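"""Identification statistics: GS, reproducibility/accuracy, PIC,
allele stats, molecular IDs."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mnpkit.errors import DataError
from mnpkit.metrics import (accuracy_from_reproducibility, allele_stats,
                            build_allele_registry, genetic_similarity,
                            locus_allele_frequencies, molecular_id,
                            pairwise_compare, pic, reproducibility)
from tests.conftest import make_fingerprint


def _pair(calls_a, calls_b):
    return (make_fingerprint("A", calls_a), make_fingerprint("B", calls_b))


class TestGeneticSimilarity:
    def test_identical_fingerprints(self):
        calls = {f"L{i}": (f"seq{i}",) for i in range(505)}
        a, b = _pair(calls, dict(calls))
        res = genetic_similarity(a, b)
        assert res.gs == 1.0
        assert res.n_differential == 0
        assert res.differentiation_ratio == 0.0

    def test_fully_different(self):
        a, b = _pair({f"L{i}": ("x",) for i in range(10)},
                     {f"L{i}": ("y",) for i in range(10)})
        res = genetic_similarity(a, b)
        assert res.gs == 0.0
        assert res.differentiation_ratio == 1.0

    def test_panel_denominator(self):
        calls_a = {f"L{i}": ("same",) if i < 324 else ("a",)
                   for i in range(505)}
        calls_b = {f"L{i}": ("same",) if i < 324 else ("b",)
                   for i in range(505)}
        a, b = _pair(calls_a, calls_b)
        res = genetic_similarity(a, b, "panel")
        assert res.n_identical == 324
        assert res.gs == pytest.approx(324 / 505)

    def test_shared_called_denominator_ignores_nocalls(self):
        calls_a = {"L1": ("x",), "L2": ("y",), "L3": None}
        calls_b = {"L1": ("x",), "L2": ("z",), "L3": ("w",)}
        a, b = _pair(calls_a, calls_b)
        res = genetic_similarity(a, b, "shared_called")
        assert res.n_compared == 2
        assert res.gs == pytest.approx(0.5)
        panel_res = genetic_similarity(a, b, "panel")
        assert panel_res.gs == pytest.approx(1 / 3)

    def test_symmetry(self):
        a, b = _pair({"L1": ("x", "y"), "L2": ("z",)},
                     {"L1": ("y", "x"), "L2": ("w",)})
        assert genetic_similarity(a, b).gs == genetic_similarity(b, a).gs
        # allele sets are order-insensitive
        assert genetic_similarity(a, b).n_identical == 1

    def test_mismatched_panels_rejected(self):
        a, b = _pair({"L1": ("x",)}, {"L2": ("x",)})
        with pytest.raises(DataError):
            genetic_similarity(a, b)


class TestPairwiseCompare:
    @pytest.mark.parametrize("n,expected", [(80, 3160), (2, 1), (30, 435)])
    def test_pair_counts(self, n, expected):
        fps = {f"A{i:03d}": make_fingerprint(f"A{i:03d}", {"L1": (str(i),)})
               for i in range(n)}
        assert len(pairwise_compare(fps)) == expected

    def test_deterministic_sorted_order(self):
        fps = {acc: make_fingerprint(acc, {"L1": ("x",)})
               for acc in ["C", "A", "B"]}
        results = pairwise_compare(fps)
        assert [(r.accession_a, r.accession_b) for r in results] == \
            [("A", "B"), ("A", "C"), ("B", "C")]


class TestReproducibility:
    def test_identical_runs(self):
        run = {"A": make_fingerprint("A", {"L1": ("x",), "L2": ("y",)})}
        n, r, frac = reproducibility(run, run)
        assert (n, r, frac) == (2, 2, 1.0)

    def test_paper_scale_counts(self):
        """14,425 compared cells with 33 discordant -> 0.99771..."""
        loci = {f"L{i}": ("x",) for i in range(14425)}
        run1 = {"A": make_fingerprint("A", loci)}
        loci2 = dict(loci)
        for i in range(33):
            loci2[f"L{i}"] = ("y",)
        run2 = {"A": make_fingerprint("A", loci2)}
        n, r, frac = reproducibility(run1, run2)
        assert (n, r) == (14425, 14392)
        assert frac == pytest.approx(14392 / 14425)
        assert frac == pytest.approx(0.99771, abs=5e-6)

    def test_no_shared_called_cells_rejected(self):
        run1 = {"A": make_fingerprint("A", {"L1": None})}
        run2 = {"A": make_fingerprint("A", {"L1": ("x",)})}
        with pytest.raises(DataError):
            reproducibility(run1, run2)

    def test_accession_mismatch_rejected(self):
        run1 = {"A": make_fingerprint("A", {"L1": ("x",)})}
        run2 = {"B": make_fingerprint("B", {"L1": ("x",)})}
        with pytest.raises(DataError):
            reproducibility(run1, run2)


class TestAccuracy:
    @pytest.mark.parametrize("r,expected", [(0.9980, 0.9990),
                                            (0.9978, 0.9989),
                                            (1.0, 1.0), (0.0, 0.5)])
    def test_values(self, r, expected):
        assert accuracy_from_reproducibility(r) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            accuracy_from_reproducibility(1.2)

    @given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
    @settings(max_examples=50, deadline=None)
    def test_affine_and_monotone(self, r1, r2):
        a1 = accuracy_from_reproducibility(r1)
        a2 = accuracy_from_reproducibility(r2)
        if r1 <= r2:
            assert a1 <= a2
        assert a1 == pytest.approx(0.5 + r1 / 2)


class TestPic:
    def test_monomorphic_zero(self):
        assert pic([1.0]) == 0.0

    def test_two_equal_alleles(self):
        assert pic([0.5, 0.5]) == pytest.approx(0.375)

    def test_many_equal_alleles_approach_one(self):
        assert pic([1 / 50] * 50) > 0.95

    def test_empty_rejected(self):
        with pytest.raises(DataError):
            pic([])

    def test_not_normalized_rejected(self):
        with pytest.raises(DataError):
            pic([0.5, 0.4])

    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=12))
    @settings(max_examples=200, deadline=None)
    def test_bounded_by_expected_heterozygosity(self, raw):
        freqs = np.asarray(raw) / np.sum(raw)
        h_exp = 1.0 - float(np.sum(freqs ** 2))
        value = pic(freqs)
        assert value <= h_exp + 1e-12
        assert 0.0 <= value < 1.0


class TestAlleleStats:
    def test_single_accession_single_alleles(self):
        fps = {"A": make_fingerprint("A", {"L1": ("x",), "L2": ("y",)})}
        stats = allele_stats(fps)
        assert stats.allele_counts == [1, 1]
        assert stats.mean_alleles == 1.0
        assert stats.sd_alleles == 0.0
        assert stats.pic_values == [0.0, 0.0]

    def test_disjoint_alleles_counted(self):
        fps = {"A": make_fingerprint("A", {"L1": ("x",)}),
               "B": make_fingerprint("B", {"L1": ("y",)})}
        stats = allele_stats(fps)
        assert stats.allele_counts == [2]
        assert stats.detection_rates == [1.0]

    def test_matches_truth_inventory(self, small_cohort):
        truth = small_cohort["truth"]
        fps = {acc: make_fingerprint(
                   acc, {loc.locus_id: truth.fingerprints[acc][loc.locus_id]
                         for loc in truth.loci})
               for acc in truth.accessions}
        stats = allele_stats(fps)
        for loc, count in zip(truth.loci, stats.allele_counts):
            inventory = set()
            for acc in truth.accessions:
                inventory.update(truth.fingerprints[acc][loc.locus_id])
            assert count == len(inventory)

    def test_frequencies_count_set_membership_once(self):
        fps = {"A": make_fingerprint("A", {"L1": ("x", "y")}),
               "B": make_fingerprint("B", {"L1": ("x",)})}
        freqs = locus_allele_frequencies(fps, "L1")
        assert freqs == {"x": 2 / 3, "y": 1 / 3}


class TestMolecularId:
    def _fps(self):
        return {"A": make_fingerprint("A", {"L1": ("x",), "L2": ("p", "q")}),
                "B": make_fingerprint("B", {"L1": ("y",), "L2": ("p",)}),
                "C": make_fingerprint("C", {"L1": ("x",), "L2": None})}

    def test_identical_fingerprints_same_id(self):
        fps = self._fps()
        registry = build_allele_registry(fps)
        twin = make_fingerprint("Z", {"L1": ("x",), "L2": ("p", "q")})
        assert molecular_id(fps["A"], registry).canonical == \
            molecular_id(twin, registry).canonical

    def test_one_locus_difference_changes_id(self):
        fps = self._fps()
        registry = build_allele_registry(fps)
        ids = {acc: molecular_id(fps[acc], registry).canonical
               for acc in fps}
        assert len(set(ids.values())) == 3
        assert ids["C"].endswith(";.")   # no-call encoded as '.'

    def test_rerun_is_byte_identical(self):
        fps = self._fps()
        r1 = build_allele_registry(fps)
        r2 = build_allele_registry(fps)
        m1 = molecular_id(fps["A"], r1)
        m2 = molecular_id(fps["A"], r2)
        assert (m1.canonical, m1.digest) == (m2.canonical, m2.digest)

    def test_unknown_allele_extends_registry(self, caplog):
        fps = self._fps()
        registry = build_allele_registry(fps)
        novel = make_fingerprint("N", {"L1": ("zz",), "L2": ("p",)})
        with caplog.at_level("WARNING"):
            mid = molecular_id(novel, registry)
        assert "absent from registry" in caplog.text
        assert registry["L1"]["zz"] == 2   # appended after x, y

    def test_all_ids_distinct_on_simulated_cohort(self, small_cohort):
        truth = small_cohort["truth"]
        fps = {acc: make_fingerprint(
                   acc, {loc.locus_id: truth.fingerprints[acc][loc.locus_id]
                         for loc in truth.loci})
               for acc in truth.accessions}
        # precondition: every pair differs somewhere
        distinct_inputs = len({tuple(sorted(
            (l, fp.calls[l].alleles) for l in fp.calls))
            for fp in fps.values()})
        registry = build_allele_registry(fps)
        digests = {molecular_id(fp, registry).digest
                   for fp in fps.values()}
        assert len(digests) == distinct_inputs == len(fps)
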