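import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import brute_force_anchor
from peplib import (ErrorModel, LibraryModel, ReadRecord, extract_region,
                    find_anchor, generate_reads, generate_truth,
                    reverse_complement)

DNA = st.text(alphabet="ACGT", min_size=1, max_size=50)


def _random_dna(rng, length):
    return "".join(rng.choice(list("ACGT"), size=length))


class TestFindAnchor:
    def test_exact_occurrence(self):
        seq = "GG" + "ACGTACGTAC" + "TTTT"
        match = find_anchor(seq, "ACGTACGTAC", 0.1)
        assert (match.start, match.end, match.distance) == (2, 12, 0)

    def test_threshold_arithmetic(self):
        anchor = "ACGTACGTAC"  # length 10
        seq = "GG" + "ACGTACGTAA" + "TT"  # one substitution
        hit = find_anchor(seq, anchor, 0.1)  # floor(0.1 * 10) = 1 edit allowed
        assert hit is not None and hit.distance == 1
        assert find_anchor(seq, anchor, 0.05) is None  # floor = 0 edits

    def test_absence_is_none_not_error(self):
        assert find_anchor("AAAA", "CCCCCCCC", 0.1) is None

    def test_empty_anchor_rejected(self):
        with pytest.raises(ValueError):
            find_anchor("ACGT", "", 0.1)

    def test_agrees_with_brute_force_on_random_cases(self):
        rng = np.random.default_rng(20240917)
        for case in range(1500):
            n = int(rng.integers(10, 51))
            m = int(rng.integers(4, 21))
            seq = _random_dna(rng, n)
            anchor = _random_dna(rng, m)
            if case % 2 == 0 and n > m:
                # plant a corrupted copy so the accept branch is exercised
                start = int(rng.integers(0, n - m))
                corrupted = list(anchor)
                for _ in range(int(rng.integers(0, 3))):
                    pos = int(rng.integers(0, m))
                    corrupted[pos] = rng.choice(list("ACGT"))
                seq = seq[:start] + "".join(corrupted) + seq[start + m:]
            rate = float(rng.choice([0.05, 0.1, 0.2, 0.3]))
            mine = find_anchor(seq, anchor, rate)
            ref = brute_force_anchor(seq, anchor, rate)
            if ref is None:
                assert mine is None, (seq, anchor, rate)
            else:
                assert mine is not None, (seq, anchor, rate)
                assert (mine.start, mine.end, mine.distance) == ref


def _designed_read(template, insert):
    return (template.upstream_anchor + template.left_flank + insert
            + template.right_flank + template.downstream_anchor)


class TestExtractRegion:
    def test_designed_read_passes(self, template, config):
        rng = np.random.default_rng(7)
        insert = _random_dna(rng, 54)
        read = ReadRecord("r", _designed_read(template, insert))
        region = extract_region(read, template, config)
        assert region.passed and region.fail_reason is None
        assert len(region.region) == 60
        assert region.region == (template.left_flank + insert
                                 + template.right_flank)
        assert region.orientation == "forward"

    def test_reverse_complement_strand_symmetry(self, template, config):
        rng = np.random.default_rng(8)
        insert = _random_dna(rng, 54)
        fwd = ReadRecord("f", _designed_read(template, insert))
        rev = ReadRecord("r", reverse_complement(fwd.sequence))
        a = extract_region(fwd, template, config)
        b = extract_region(rev, template, config)
        assert b.region == a.region and b.passed == a.passed
        assert b.orientation == "reverse_complement"

    def test_length_not_multiple_of_three(self, template, config):
        rng = np.random.default_rng(9)
        read = ReadRecord("r", _designed_read(template, _random_dna(rng, 53)))
        region = extract_region(read, template, config)
        assert not region.passed
        assert region.fail_reason == "length_not_multiple_of_3"
        assert len(region.region) == 59

    def test_flank_mismatch(self, template, config):
        rng = np.random.default_rng(10)
        insert = _random_dna(rng, 54)
        bad_flank = "G" + template.left_flank[1:]
        read = ReadRecord("r", template.upstream_anchor + bad_flank + insert
                          + template.right_flank + template.downstream_anchor)
        region = extract_region(read, template, config)
        assert not region.passed and region.fail_reason == "flank_mismatch"

    def test_ambiguous_base_fails(self, template, config):
        insert = "N" * 54
        read = ReadRecord("r", _designed_read(template, insert))
        region = extract_region(read, template, config)
        assert region.fail_reason == "ambiguous_base"

    def test_missing_anchors(self, template, config):
        region = extract_region(ReadRecord("r", "ACGT" * 20), template, config)
        assert not region.passed
        assert region.fail_reason == "no_upstream_anchor"
        up_only = ReadRecord("r", template.upstream_anchor + "ACGT" * 10)
        region = extract_region(up_only, template, config)
        assert region.fail_reason == "no_downstream_anchor"

    @settings(derandomize=True, max_examples=30)
    @given(st.integers(0, 2 ** 31 - 1))
    def test_extraction_involutive_under_rc(self, template, config, seed):
        rng = np.random.default_rng(seed)
        insert = _random_dna(rng, int(rng.integers(1, 60)))
        read = ReadRecord("r", _designed_read(template, insert))
        a = extract_region(read, template, config)
        b = extract_region(
            ReadRecord("r", reverse_complement(read.sequence)),
            template, config)
        assert (a.region, a.passed, a.fail_reason) == \
            (b.region, b.passed, b.fail_reason)


class TestErrorFreePassRates:
    def test_in_frame_inserts_all_pass_and_broken_frames_all_fail(
            self, template, config, clean_error_model):
        in_frame = LibraryModel(n_true_variants=30, colony_count=30)
        truth = generate_truth(in_frame, template, seed=3)
        reads = generate_reads(truth, template, clean_error_model,
                               n_reads=300, seed=4)
        outcomes = [extract_region(r, template, config) for r in reads]
        assert all(o.passed for o in outcomes)

        bad = ReadRecord("bad", _designed_read(
            template, _random_dna(np.random.default_rng(0), 52)))
        assert not extract_region(bad, template, config).passed
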