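"""Unit, property and oracle tests for flip-over detection."""

import itertools
from collections import Counter

import numpy as np
import pytest

from gcflip.flipover_detector import (
    ChangeClass,
    classify_change,
    detect_in_individual,
    distinct_acceptor_count,
    hamming,
    occurrence_bounds,
    scan_population,
)
from gcflip.haplotype_catalog import extract_haplotypes, rank_haplotypes

from conftest import catalog_from_matrix, make_population

COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


class TestHamming:
    @pytest.mark.parametrize(
        "a,b,expected",
        [("0000", "0000", 0), ("0000", "0100", 1), ("01" * 25, "10" * 25, 50)],
    )
    def test_examples(self, a, b, expected):
        assert hamming(a, b) == expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            hamming("00", "000")


def _expected_class(x, y):
    """Independent restatement: weak = {A,T}, strong = {G,C}."""
    weak = "AT"
    if x in weak and y not in weak:
        return ChangeClass.AT_TO_GC
    if x not in weak and y in weak:
        return ChangeClass.GC_TO_AT
    return ChangeClass.NO_BASE_CHANGE


ORDERED_PAIRS = [(x, y) for x in "ACGT" for y in "ACGT" if x != y]


class TestClassifyChange:
    @pytest.mark.parametrize("common,rare", ORDERED_PAIRS)
    def test_all_twelve_ordered_pairs(self, common, rare):
        assert classify_change(common, rare) is _expected_class(common, rare)

    @pytest.mark.parametrize("common,rare", ORDERED_PAIRS)
    def test_direction_antisymmetry(self, common, rare):
        forward = classify_change(common, rare)
        backward = classify_change(rare, common)
        if forward is ChangeClass.AT_TO_GC:
            assert backward is ChangeClass.GC_TO_AT
        elif forward is ChangeClass.GC_TO_AT:
            assert backward is ChangeClass.AT_TO_GC
        else:
            assert backward is ChangeClass.NO_BASE_CHANGE

    @pytest.mark.parametrize("common,rare", ORDERED_PAIRS)
    def test_complement_invariance(self, common, rare):
        assert classify_change(common, rare) is classify_change(
            COMPLEMENT[common], COMPLEMENT[rare]
        )

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            classify_change("N", "A")
        with pytest.raises(ValueError):
            classify_change("A", "A")


def _pair_matrix(common_hap, rare_hap, n_common, n_rare_extra, k):
    """Allele matrix: individual 0 carries (common, rare); fillers are
    homozygous common; optional extra rare carriers are (common, rare)."""
    n = 1 + n_rare_extra + n_common
    matrix = np.zeros((k, n, 2), dtype=int)
    for vi in range(k):
        matrix[vi, 0, 0] = int(common_hap[vi])
        matrix[vi, 0, 1] = int(rare_hap[vi])
        for j in range(1, 1 + n_rare_extra):
            matrix[vi, j, 0] = int(common_hap[vi])
            matrix[vi, j, 1] = int(rare_hap[vi])
        for j in range(1 + n_rare_extra, n):
            matrix[vi, j, :] = int(common_hap[vi])
    return matrix


class TestDetectInIndividual:
    def test_event_emitted_for_common_rare_hamming1(self):
        k = 6
        matrix = _pair_matrix("000000", "010000", n_common=5, n_rare_extra=0, k=k)
        ref_alt = [("A", "G")] * k
        segment, samples = make_population(matrix, ref_alt=ref_alt)
        haps = extract_haplotypes(segment, samples)
        cat = rank_haplotypes(segment, haps, samples, common_min=5, rare_max=2)
        event, reason = detect_in_individual(haps[0], haps[1], cat, "I000")
        assert reason == "ok"
        assert event.acceptor_index == 1
        assert event.common_allele == "A" and event.rare_allele == "G"
        assert event.change_class is ChangeClass.AT_TO_GC
        assert event.acceptor_occurrence == 1
        assert event.common_occurrence == 11

    def test_identical_haplotypes_rejected(self):
        matrix = np.zeros((4, 6, 2), dtype=int)
        _, _, haps, cat = catalog_from_matrix(matrix)
        event, reason = detect_in_individual(haps[0], haps[1], cat)
        assert event is None and reason == "identical"

    def test_distance_two_rejected(self):
        matrix = _pair_matrix("0000", "0110", n_common=5, n_rare_extra=0, k=4)
        _, _, haps, cat = catalog_from_matrix(matrix, common_min=5, rare_max=2)
        event, reason = detect_in_individual(haps[0], haps[1], cat)
        assert event is None and reason == "distance"

    def test_indel_acceptor_rejected(self):
        k = 4
        matrix = _pair_matrix("0000", "0100", n_common=5, n_rare_extra=0, k=k)
        ref_alt = [("A", "G"), ("AT", "A"), ("A", "G"), ("A", "G")]
        segment, samples = make_population(matrix, ref_alt=ref_alt)
        haps = extract_haplotypes(segment, samples)
        cat = rank_haplotypes(segment, haps, samples, common_min=5, rare_max=2)
        event, reason = detect_in_individual(haps[0], haps[1], cat)
        assert event is None and reason == "acceptor_not_snp"

    def test_intermediate_partner_rejected(self):
        # the "rare" haplotype occurs 4 times: above rare_max=2
        matrix = _pair_matrix("0000", "0100", n_common=8, n_rare_extra=3, k=4)
        _, _, haps, cat = catalog_from_matrix(matrix, common_min=5, rare_max=2)
        event, reason = detect_in_individual(haps[0], haps[1], cat)
        assert event is None and reason == "occurrence"

    def test_emitted_event_implies_single_heterozygous_site(self, planted_dataset):
        from gcflip.pipeline import RunConfig, build_catalogs

        reader, catalogs, _ = build_catalogs(
            RunConfig(vcf=planted_dataset.vcf_path, local_gc=False)
        )
        events = scan_population(catalogs, reader.samples, "1-5")
        assert events
        by_seg = {c.segment.index: c for c in catalogs}
        for e in events:
            cat = by_seg[e.segment_index]
            by_indiv = cat.haplotypes_by_individual()
            a, b = by_indiv[e.individual_id]
            het_sites = [i for i, (x, y) in enumerate(zip(a, b)) if x != y]
            assert het_sites == [e.acceptor_index]


def _oracle_scan(matrix, segment, samples, common_min, rare_max, lo, hi):
    """Exhaustive pair enumeration, independent of the detector code path."""
    k, n, _ = matrix.shape
    strings = {
        (i, p): "".join(str(matrix[v, i, p]) for v in range(k))
        for i in range(n)
        for p in (0, 1)
    }
    counts = Counter(strings.values())
    found = []
    for i in range(n):
        a, b = strings[(i, 0)], strings[(i, 1)]
        diff = [v for v in range(k) if a[v] != b[v]]
        if len(diff) != 1:
            continue
        for common, rare in ((a, b), (b, a)):
            if counts[common] >= common_min and lo <= counts[rare] <= hi:
                variant = segment.variants[diff[0]]
                if variant.is_snp:
                    found.append(
                        (samples.sample_ids[i], diff[0], counts[common], counts[rare])
                    )
                break
    return sorted(found)


class TestScanPopulation:
    def test_matches_bruteforce_oracle_on_random_instances(self):
        """Exhaustive enumeration reproduces the event multiset on 50
        random small populations (k <= 8, N <= 16)."""
        rng = np.random.default_rng(2024)
        common_min, rare_max = 5, 2
        for trial in range(50):
            k = int(rng.integers(2, 9))
            n = int(rng.integers(4, 17))
            # skew toward shared haplotypes so common/rare structure arises
            base = rng.integers(0, 2, size=k)
            matrix = np.tile(base[:, None, None], (1, n, 2))
            n_mut = int(rng.integers(0, 3 * n))
            for _ in range(n_mut):
                matrix[
                    rng.integers(0, k), rng.integers(0, n), rng.integers(0, 2)
                ] ^= 1
            ref_alt = []
            for _ in range(k):
                if rng.random() < 0.15:
                    ref_alt.append(("AT", "A"))
                else:
                    pair = rng.choice(list("ACGT"), size=2, replace=False)
                    ref_alt.append((str(pair[0]), str(pair[1])))
            segment, samples = make_population(matrix, ref_alt=ref_alt)
            haps = extract_haplotypes(segment, samples)
            cat = rank_haplotypes(
                segment, haps, samples, common_min=common_min, rare_max=rare_max
            )
            events = scan_population([cat], samples, category="1-2")
            got = sorted(
                (e.individual_id, e.acceptor_index, e.common_occurrence,
                 e.acceptor_occurrence)
                for e in events
            )
            expected = _oracle_scan(
                matrix, segment, samples, common_min, rare_max, 1, 2
            )
            assert got == expected, f"trial {trial}"

    def test_no_events_when_all_common(self):
        matrix = np.zeros((4, 10, 2), dtype=int)
        segment, samples, haps, cat = catalog_from_matrix(matrix, rare_max=5)
        assert scan_population([cat], samples) == []

    def test_category_bounds(self):
        assert occurrence_bounds("1") == (1, 1)
        assert occurrence_bounds("1-5") == (1, 5)
        with pytest.raises(ValueError):
            occurrence_bounds("3-7")

    def test_category_upper_bound_enforced(self):
        matrix = np.zeros((4, 10, 2), dtype=int)
        segment, samples, haps, cat = catalog_from_matrix(matrix, rare_max=2)
        with pytest.raises(ValueError):
            scan_population([cat], samples, category="1-5")

    def test_sample_relabeling_preserves_event_count(self):
        matrix = _pair_matrix("00000", "01000", n_common=6, n_rare_extra=1, k=5)
        segment, samples, haps, cat = catalog_from_matrix(
            matrix, common_min=5, rare_max=2
        )
        events = scan_population([cat], samples, category="2")
        n, perm_rng = matrix.shape[1], np.random.default_rng(3)
        perm = perm_rng.permutation(n)
        segment2, samples2, _, cat2 = catalog_from_matrix(
            matrix[:, perm, :], common_min=5, rare_max=2
        )
        events2 = scan_population([cat2], samples2, category="2")
        assert len(events) == len(events2) == 2
        assert {e.acceptor_occurrence for e in events} == {2}

    def test_distinct_acceptor_counting(self):
        matrix = _pair_matrix("00000", "01000", n_common=6, n_rare_extra=1, k=5)
        _, samples, _, cat = catalog_from_matrix(matrix, common_min=5, rare_max=2)
        events = scan_population([cat], samples, category="1-2")
        assert len(events) == 2  # per-carrier counting
        assert distinct_acceptor_count(events) == 1
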