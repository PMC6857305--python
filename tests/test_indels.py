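"""Deletion context classification, ID-83 channels and size distributions."""

import numpy as np
import pytest

from hrsig import (IndelSimSpec, classify_deletion, classify_indel_id83,
                   deletion_size_ecdf, id83_spectrum, max_microhomology,
                   simulate_genome_with_indels, tandem_copies)
from hrsig.indels import ID83_CHANNELS
from hrsig.records import MutationKind, MutationRecord


# ---------------------------------------------------------------------------
# independent brute-force string oracles
# ---------------------------------------------------------------------------

def oracle_mh(deleted: str, left: str, right: str) -> int:
    best = 0
    for k in range(1, len(deleted)):
        if deleted[:k] == right[:k] or deleted[-k:] == left[-k:]:
            best = k
    return best


def oracle_copies(deleted: str, left: str, right: str) -> int:
    L = len(deleted)
    copies = 1
    k = 1
    while len(left) >= k * L and left[-k * L:][:L] == deleted:
        copies += 1
        k += 1
    k = 1
    while len(right) >= k * L and right[(k - 1) * L: k * L] == deleted:
        copies += 1
        k += 1
    return copies


class TestMicrohomology:
    def test_prefix_match_on_right_flank(self):
        assert max_microhomology("TAGC", "GGGGG", "TAGTT") == 3

    def test_no_match(self):
        assert max_microhomology("A", "GGGGG", "CCCCC") == 0

    def test_capped_at_length_minus_one(self):
        # left flank ends with the full deleted sequence: cap applies
        assert max_microhomology("AT", "CCCAT", "GGGGG") == 1

    def test_empty_deletion_raises(self):
        with pytest.raises(ValueError):
            max_microhomology("", "AAA", "AAA")


class TestTandemCopies:
    def test_adjacent_copies_both_sides(self):
        # reference ...CA[CA]CA...: deleted copy plus one on each side
        assert tandem_copies("CA", "GGCA", "CAGG") == 3

    def test_unique_context(self):
        assert tandem_copies("T", "GGGA", "GCCC") == 1

    def test_single_right_copy(self):
        assert tandem_copies("AGG", "TTTTTT", "AGGTTT") == 2

    def test_empty_deletion_raises(self):
        with pytest.raises(ValueError):
            tandem_copies("", "AAA", "AAA")


class TestOracleEquivalence:
    def test_random_deletions_agree_with_string_oracle(self):
        """10^4 random deletions over random genomes match the brute force."""
        rng = np.random.default_rng(123)
        n_checked = 0
        while n_checked < 10_000:
            L = int(rng.integers(1, 12))
            flank = 6 * L + 10
            seq = "".join(rng.choice(list("ACGT"), size=2 * flank + L))
            left, deleted, right = seq[:flank], seq[flank: flank + L], seq[flank + L:]
            assert tandem_copies(deleted, left, right) == oracle_copies(
                deleted, left, right
            )
            if L > 1:
                assert max_microhomology(deleted, left, right) == min(
                    oracle_mh(deleted, left, right), L - 1
                )
            n_checked += 1


class TestClassifyDeletion:
    def test_one_bp_deletion_in_homopolymer_is_repeat(self):
        genome = {"c": "GGTAAAGTC"}
        rec = MutationRecord("s", "c", 3, "TA", "T", MutationKind.DEL)
        call = classify_deletion(rec, genome)
        assert call.context_class == "repeat"
        assert call.tandem_copies == 3

    def test_breakpoint_homology_without_tandem_copy(self):
        # deleted TAGC followed by TAGT...: 3 bp of homology, no full copy
        genome = {"c": "GGGGG" + "TAGC" + "TAGTTCCC"}
        rec = MutationRecord("s", "c", 5, "GTAGC", "G", MutationKind.DEL)
        call = classify_deletion(rec, genome)
        assert call.context_class == "microhomology"
        assert call.mh_length == 3

    def test_unique_context_is_none(self):
        genome = {"c": "GGTCC" + "TACG" + "CATTA"}
        rec = MutationRecord("s", "c", 5, "CTACG", "C", MutationKind.DEL)
        call = classify_deletion(rec, genome)
        assert call.context_class == "none"
        assert call.mh_length == 0 and call.tandem_copies == 1

    def test_repeat_takes_precedence_over_microhomology(self):
        # two tandem copies: full-length breakpoint match counts as repeat
        genome = {"c": "GGGGG" + "TACG" + "TACG" + "CCAAT"}
        rec = MutationRecord("s", "c", 5, "GTACG", "G", MutationKind.DEL)
        call = classify_deletion(rec, genome)
        assert call.context_class == "repeat"
        assert call.tandem_copies == 2

    def test_right_shifted_representation_gives_identical_call(self):
        genome = {"c": "GGCACACATT"}
        leftmost = MutationRecord("s", "c", 2, "GCA", "G", MutationKind.DEL)
        shifted = MutationRecord("s", "c", 4, "ACA", "A", MutationKind.DEL)
        a = classify_deletion(leftmost, genome)
        b = classify_deletion(shifted, genome)
        assert a == b

    def test_snv_rejected(self):
        with pytest.raises(ValueError):
            classify_deletion(
                MutationRecord("s", "c", 2, "A", "T", MutationKind.SNV),
                {"c": "AAA"},
            )


class TestID83:
    @pytest.mark.parametrize(
        "genome,rec,expected",
        [
            # 1-bp T deletion inside a TTTT homopolymer
            ({"c": "GGCTTTTAGG"}, ("c", 3, "CT", "C"), "1:Del:T:4"),
            # 1-bp A deletion (counts as T on the pyrimidine strand), unique
            ({"c": "GGCAGTC"}, ("c", 3, "CA", "C"), "1:Del:T:1"),
            # 4-bp deletion with 2-bp microhomology, no tandem copy
            ({"c": "GGGGG" + "ACGT" + "ACTTTTT"}, ("c", 5, "GACGT", "G"),
             "4:Del:M:2"),
            # 3-bp deletion with one adjacent copy: repeat channel
            ({"c": "GGGGG" + "ACG" + "ACG" + "TTTTT"}, ("c", 5, "GACG", "G"),
             "3:Del:R:1"),
            # long deletion, no context
            ({"c": "GGGGG" + "ACGTAC" + "GGCCAAT"}, ("c", 5, "GACGTAC", "G"),
             "5+:Del:R:0"),
        ],
    )
    def test_deletion_channels(self, genome, rec, expected):
        record = MutationRecord("s", rec[0], rec[1], rec[2], rec[3],
                                MutationKind.DEL)
        idx = classify_indel_id83(record, genome)
        assert ID83_CHANNELS[idx] == expected

    @pytest.mark.parametrize(
        "genome,rec,expected",
        [
            # 1-bp C insertion next to no C
            ({"c": "GGATAGG"}, ("c", 3, "A", "AC"), "1:Ins:C:0"),
            # 1-bp G insertion extending a GG run (pyrimidine strand: C)
            ({"c": "TTAGGATT"}, ("c", 3, "A", "AG"), "1:Ins:C:2"),
            # 2-bp insertion duplicating an existing unit
            ({"c": "TTTACGTT"}, ("c", 3, "T", "TAC"), "2:Ins:R:1"),
        ],
    )
    def test_insertion_channels(self, genome, rec, expected):
        record = MutationRecord("s", rec[0], rec[1], rec[2], rec[3],
                                MutationKind.INS)
        idx = classify_indel_id83(record, genome)
        assert ID83_CHANNELS[idx] == expected

    def test_snv_rejected(self):
        with pytest.raises(ValueError):
            classify_indel_id83(
                MutationRecord("s", "c", 2, "A", "T", MutationKind.SNV),
                {"c": "AAA"},
            )

    def test_channel_conservation(self, tiny_genome):
        """The ID-83 vector sums to the number of classified indels."""
        rng = np.random.default_rng(9)
        seq = tiny_genome["chr1"]
        records = []
        for _ in range(40):
            pos = int(rng.integers(30, len(seq) - 40))
            if rng.random() < 0.5:
                L = int(rng.integers(1, 6))
                records.append(MutationRecord(
                    "s", "chr1", pos, seq[pos - 1: pos + L], seq[pos - 1],
                    MutationKind.DEL))
            else:
                ins = "".join(rng.choice(list("ACGT"), size=int(rng.integers(1, 4))))
                records.append(MutationRecord(
                    "s", "chr1", pos, seq[pos - 1], seq[pos - 1] + ins,
                    MutationKind.INS))
        spectrum = id83_spectrum(records, tiny_genome)
        assert spectrum.sum() == len(records)
        assert len(spectrum) == 83


class TestPlantedClasses:
    def test_planted_contexts_recovered_exactly(self):
        spec = IndelSimSpec(genome_length=80_000, n_events=75,
                            class_mix=(0.34, 0.33, 0.33), seed=21)
        genome, truth = simulate_genome_with_indels(spec)
        assert len(truth) == 75
        seen = {"repeat": 0, "microhomology": 0, "none": 0}
        for planted in truth:
            call = classify_deletion(planted.record, genome)
            assert call.context_class == planted.truth_class
            if call.context_class == "microhomology":
                assert call.mh_length == planted.truth_mh >= 1
            if call.context_class == "repeat":
                assert call.tandem_copies == planted.truth_copies >= 2
            seen[call.context_class] += 1
        assert all(v > 0 for v in seen.values())


class TestDeletionSizeEcdf:
    def test_degenerate_lengths(self):
        ecdf, median = deletion_size_ecdf([1, 1, 1])
        assert median == 1 and ecdf[1] == 1.0

    def test_ecdf_midpoint(self):
        ecdf, median = deletion_size_ecdf([1, 2, 4, 8])
        assert ecdf[2] == pytest.approx(0.5)
        assert median == 2  # lower-midpoint convention

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            deletion_size_ecdf([])
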