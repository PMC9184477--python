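import itertools

import numpy as np
import pytest

from terralabel.validation import (ABSENT, INVALID, AgreementReport,
                                   ConfusionMatrix, ValidationError,
                                   VotingScheme, agreement_report,
                                   compare_external, confusion, consensus_grid,
                                   merge_classes_grid, merge_classes_matrix,
                                   vote_pixel)
from terralabel.io_core import RasterGrid


def vote_oracle(labels, scheme):
    """Independent rule-table evaluation of the four voting schemes."""
    present = [v for v in labels if v is not None]
    n = len(present)
    counts = {}
    for v in present:
        counts[v] = counts.get(v, 0) + 1
    best = max(counts.values()) if counts else 0
    agreed = [v for v, c in counts.items() if c == best and c >= 2]
    if scheme is VotingScheme.three_expert_strict:
        return present[0] if n == 3 and len(counts) == 1 else INVALID
    if scheme is VotingScheme.expert_consensus:
        return present[0] if n >= 1 and len(counts) == 1 else INVALID
    if scheme is VotingScheme.expert_majority:
        if best >= 2:
            return agreed[0]
        return present[0] if n == 1 else INVALID
    if scheme is VotingScheme.expert_simple_majority:
        return agreed[0] if n >= 2 and best >= 2 else INVALID
    raise AssertionError


class TestVotePixel:
    @pytest.mark.parametrize("scheme", list(VotingScheme))
    def test_matches_exhaustive_enumeration(self, scheme):
        # all 4^3 = 64 presence/label patterns over {A, B, C, absent}
        domain = [0, 1, 2, None]
        for combo in itertools.product(domain, repeat=3):
            got = vote_pixel(combo, scheme)
            assert got == vote_oracle(combo, scheme), (combo, scheme)

    def test_unanimous_agreement_valid_everywhere(self):
        for scheme in VotingScheme:
            assert vote_pixel((4, 4, 4), scheme) == 4

    def test_single_opinion_cases(self):
        combo = (4, None, None)
        assert vote_pixel(combo, VotingScheme.expert_consensus) == 4
        assert vote_pixel(combo, VotingScheme.expert_majority) == 4
        assert vote_pixel(combo, VotingScheme.three_expert_strict) == INVALID
        assert vote_pixel(combo, VotingScheme.expert_simple_majority) == INVALID

    def test_two_against_one(self):
        combo = (4, 4, 7)
        assert vote_pixel(combo, VotingScheme.three_expert_strict) == INVALID
        assert vote_pixel(combo, VotingScheme.expert_consensus) == INVALID
        assert vote_pixel(combo, VotingScheme.expert_majority) == 4
        assert vote_pixel(combo, VotingScheme.expert_simple_majority) == 4


class TestConsensusGrid:
    def test_identical_rasters_reproduce_labels(self):
        rng = np.random.default_rng(0)
        r = rng.integers(0, 10, size=(12, 12)).astype(np.int16)
        out = consensus_grid([r, r, r], VotingScheme.three_expert_strict)
        np.testing.assert_array_equal(out, r)

    def test_all_unlabeled_all_invalid(self):
        r = np.full((6, 6), ABSENT, dtype=np.int16)
        out = consensus_grid([r, r, r], VotingScheme.expert_majority)
        assert np.all(out == INVALID)

    def test_nesting_with_label_consistency(self):
        # strict-valid set <= consensus-valid <= majority-valid, labels equal
        rng = np.random.default_rng(1)
        for _ in range(10):
            rasters = [np.where(rng.random((20, 20)) < 0.25, ABSENT,
                                rng.integers(0, 4, (20, 20))).astype(np.int16)
                       for _ in range(3)]
            strict = consensus_grid(rasters, VotingScheme.three_expert_strict)
            cons = consensus_grid(rasters, VotingScheme.expert_consensus)
            major = consensus_grid(rasters, VotingScheme.expert_majority)
            assert np.all((strict == INVALID) | (strict == cons))
            assert np.all((cons == INVALID) | (cons == major))

    def test_requires_three_aligned_rasters(self):
        r = np.zeros((4, 4), dtype=np.int16)
        with pytest.raises(ValidationError):
            consensus_grid([r, r], VotingScheme.expert_majority)
        with pytest.raises(ValidationError):
            consensus_grid([r, r, np.zeros((5, 5), np.int16)],
                           VotingScheme.expert_majority)


class TestConfusion:
    def test_identity_when_candidate_equals_reference(self):
        rng = np.random.default_rng(2)
        r = rng.integers(0, 10, size=(10, 10)).astype(np.int16)
        cm = confusion(r, r)
        rep = agreement_report(cm)
        assert rep.overall == 1.0
        assert np.all(cm.counts == np.diag(np.diag(cm.counts)))

    def test_hand_tallied_toy_matrix(self):
        ref = np.array([[0, 0, 0], [1, 1, 1], [2, 2, 2]], dtype=np.int16)
        cand = ref.copy()
        cand[0, 0] = 1  # one disagreement among 9 pixels
        cm = confusion(ref, cand, n_classes=3)
        rep = agreement_report(cm)
        assert rep.overall == pytest.approx(8 / 9)
        expect = np.array([[2, 0, 0], [1, 3, 0], [0, 0, 3]])
        np.testing.assert_array_equal(cm.counts, expect)
        assert rep.precision[1] == pytest.approx(3 / 4)
        assert rep.recall[0] == pytest.approx(2 / 3)

    def test_margins_conserve_totals(self):
        rng = np.random.default_rng(3)
        ref = rng.integers(-1, 10, size=(20, 20)).astype(np.int16)
        cand = rng.integers(-2, 10, size=(20, 20)).astype(np.int16)
        cm = confusion(ref, cand)
        n = ((ref >= 0) & (cand >= 0)).sum()
        assert cm.n_valid == n
        assert cm.counts.sum(axis=0).sum() == n
        assert cm.counts.sum(axis=1).sum() == n

    def test_zero_valid_pixels_flagged(self):
        ref = np.full((4, 4), -1, dtype=np.int16)
        with pytest.warns(UserWarning, match="zero"):
            cm = confusion(ref, ref)
        assert cm.n_valid == 0
        assert np.isnan(agreement_report(cm).overall)

    def test_overall_invariant_under_simultaneous_permutation(self):
        rng = np.random.default_rng(4)
        ref = rng.integers(0, 10, size=(15, 15)).astype(np.int16)
        cand = rng.integers(0, 10, size=(15, 15)).astype(np.int16)
        base = agreement_report(confusion(ref, cand)).overall
        perm = rng.permutation(10)
        rep = agreement_report(confusion(perm[ref], perm[cand]))
        assert rep.overall == pytest.approx(base)


class TestMergeClasses:
    def test_identity_mapping_unchanged(self):
        rng = np.random.default_rng(5)
        r = rng.integers(0, 5, size=(8, 8)).astype(np.int16)
        np.testing.assert_array_equal(merge_classes_grid(r, {c: c for c in range(5)}), r)

    def test_merging_mutually_confused_classes_raises_agreement(self):
        # grass (2) and shrub (5) only confused with each other
        counts = np.zeros((10, 10), dtype=np.int64)
        np.fill_diagonal(counts, 50)
        counts[2, 5] = 30
        counts[5, 2] = 20
        cm = ConfusionMatrix(counts)
        before = agreement_report(cm).overall
        mapping = {c: c for c in range(10)}
        mapping[5] = 2
        merged = merge_classes_matrix(cm, mapping)
        after = agreement_report(merged).overall
        assert after > before
        assert merged.n_valid == cm.n_valid

    def test_matrix_total_preserved_under_any_merge(self):
        rng = np.random.default_rng(6)
        cm = ConfusionMatrix(rng.integers(0, 40, size=(10, 10)))
        mapping = {c: rng.integers(0, 4) for c in range(10)}
        assert merge_classes_matrix(cm, mapping).n_valid == cm.n_valid

    def test_partial_mapping_rejected(self):
        r = np.array([[0, 1], [2, 3]], dtype=np.int16)
        with pytest.raises(ValidationError, match="3"):
            merge_classes_grid(r, {0: 0, 1: 1, 2: 2})


class TestCompareExternal:
    def test_same_resolution_identity(self):
        rng = np.random.default_rng(7)
        r = RasterGrid(rng.integers(0, 9, size=(12, 12)).astype(np.int16), 10.0)
        rep = compare_external(r, r, {c: c for c in range(9)})
        assert rep.overall == 1.0

    def test_30m_external_replicates_3x3_blocks(self):
        rng = np.random.default_rng(8)
        ext = RasterGrid(rng.integers(0, 9, size=(4, 4)).astype(np.int16), 30.0)
        from terralabel.io_core import resample_nearest
        up = resample_nearest(ext, 10.0)
        assert np.array_equal(up.values, np.kron(ext.values, np.ones((3, 3), int)))

    def test_block_coarsened_reference_agreement_matches_oracle(self):
        rng = np.random.default_rng(9)
        ref_vals = rng.integers(0, 3, size=(12, 12)).astype(np.int16)
        ref = RasterGrid(ref_vals, 10.0)
        # external = per-block majority of the reference at 30 m
        blocks = ref_vals.reshape(4, 3, 4, 3).transpose(0, 2, 1, 3).reshape(4, 4, 9)
        maj = np.array([[np.bincount(blocks[i, j], minlength=3).argmax()
                         for j in range(4)] for i in range(4)]).astype(np.int16)
        rep = compare_external(ref, RasterGrid(maj, 30.0), {c: c for c in range(3)})
        expect = np.mean(np.kron(maj, np.ones((3, 3), int)) == ref_vals)
        assert rep.overall == pytest.approx(expect)

    def test_missing_crosswalk_entry_named(self):
        r = RasterGrid(np.zeros((6, 6), dtype=np.int16), 10.0)
        ext = RasterGrid(np.full((2, 2), 4, dtype=np.int16), 30.0)
        with pytest.raises(ValidationError, match="4"):
            compare_external(r, ext, {0: 0})
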