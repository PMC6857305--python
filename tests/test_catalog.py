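"""Catalog ingestion, triplet classification and rate summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hrsig import (build_spectrum, load_catalog, open_genome,
                   summarize_rates, triplet_class, tune_control_threshold)
from hrsig.rates import ScoredCall
from hrsig.records import (CatalogParseError, MutationKind, MutationRecord,
                           left_align, normalize)
from hrsig.spectrum import CHANNELS_96, revcomp


class TestLoadCatalog:
    def test_tsv_single_snv(self, tmp_path):
        path = tmp_path / "cat.tsv"
        path.write_text("sample\tchrom\tpos\tref\talt\ns1\tchr1\t100\tC\tT\n")
        (record,) = load_catalog(path)
        assert record == MutationRecord("s1", "chr1", 100, "C", "T",
                                        MutationKind.SNV)

    def test_vcf_anchored_deletion(self, tmp_path):
        path = tmp_path / "c.vcf"
        path.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="g">\n'
            "##contig=<ID=chr1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\n"
            "chr1\t100\t.\tCAG\tC\t.\t.\t.\tGT\t0/1\n"
        )
        (record,) = load_catalog(path)
        assert record.kind is MutationKind.DEL
        assert record.indel_seq == "AG"
        assert record.pos == 100 and record.alt == "C"

    def test_non_acgt_alt_is_parse_error(self, tmp_path):
        path = tmp_path / "cat.tsv"
        path.write_text("sample\tchrom\tpos\tref\talt\ns1\tchr1\t100\tC\tN\n")
        with pytest.raises(CatalogParseError, match="line 2"):
            load_catalog(path)

    def test_missing_sample_column(self, tmp_path):
        path = tmp_path / "cat.tsv"
        path.write_text("chrom\tpos\tref\talt\nchr1\t100\tC\tT\n")
        with pytest.raises(CatalogParseError, match="sample"):
            load_catalog(path)

    def test_normalize_trims_to_minimal_representation(self):
        # VCF-style padded alleles reduce to the same anchored deletion
        a = normalize("s", "chr1", 99, "TCAG", "TC")
        b = normalize("s", "chr1", 100, "CAG", "C")
        assert (a.pos, a.ref, a.alt) == (b.pos, b.ref, b.alt) == (100, "CAG", "C")


class TestTripletClass:
    def _record(self, pos, ref, alt):
        return MutationRecord("s", "chr1", pos, ref, alt, MutationKind.SNV)

    def test_pyrimidine_reference_direct(self):
        genome = {"chr1": "AACAA"}
        idx = triplet_class(genome, self._record(3, "C", "T"))
        assert CHANNELS_96[idx] == "A[C>T]A"

    def test_purine_is_reverse_complemented(self):
        # context TGC with G>A: revcomp(TGC) = GCA, so G>A reads C>T in G[.]A
        genome = {"chr1": "ATGCA"}
        idx = triplet_class(genome, self._record(3, "G", "A"))
        assert CHANNELS_96[idx] == "G[C>T]A"

    def test_reference_mismatch_raises(self):
        genome = {"chr1": "AACAA"}
        with pytest.raises(ValueError, match="chr1:3"):
            triplet_class(genome, self._record(3, "T", "G"))


class TestBuildSpectrum:
    def test_empty_catalog_gives_zero_spectrum(self, tiny_genome):
        spectrum = build_spectrum([], tiny_genome)
        assert spectrum.sum() == 0 and len(spectrum) == 96

    def test_identical_records_stack_in_one_channel(self):
        genome = {"chr1": "AACAA"}
        recs = [MutationRecord("s", "chr1", 3, "C", "T", MutationKind.SNV)] * 10
        spectrum = build_spectrum(recs, genome)
        assert spectrum["A[C>T]A"] == 10
        assert spectrum.sum() == 10

    def test_spectrum_matches_per_record_tally(self, tiny_genome):
        rng = np.random.default_rng(7)
        recs = []
        seq = tiny_genome["chr1"]
        for pos in rng.choice(np.arange(2, len(seq)), size=25, replace=False):
            ref = seq[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            recs.append(
                MutationRecord("s", "chr1", int(pos), ref, alt, MutationKind.SNV)
            )
        spectrum = build_spectrum(recs, tiny_genome)
        # independent per-record tally
        expected = np.zeros(96)
        for r in recs:
            expected[triplet_class(tiny_genome, r)] += 1
        assert (spectrum.to_numpy() == expected).all()
        assert spectrum.sum() == len(recs)

    def test_strand_symmetry(self, tiny_genome):
        """A catalog and its full reverse-complement mirror give one spectrum."""
        seq = tiny_genome["chr1"]
        mirror = {"chr1": revcomp(seq)}
        rng = np.random.default_rng(3)
        recs, mirrored = [], []
        for pos in rng.choice(np.arange(2, len(seq)), size=20, replace=False):
            pos = int(pos)
            ref = seq[pos - 1]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            recs.append(MutationRecord("s", "chr1", pos, ref, alt,
                                       MutationKind.SNV))
            mpos = len(seq) - pos + 1
            mirrored.append(
                MutationRecord("s", "chr1", mpos, revcomp(ref), revcomp(alt),
                               MutationKind.SNV)
            )
        direct = build_spectrum(recs, tiny_genome)
        flipped = build_spectrum(mirrored, mirror)
        assert (direct == flipped).all()

    def test_genome_file_equivalent_to_mapping(self, tiny_genome, tiny_fasta):
        fasta = open_genome(tiny_fasta)
        rec = MutationRecord("s", "chr1", 10, tiny_genome["chr1"][9],
                             "A" if tiny_genome["chr1"][9] != "A" else "C",
                             MutationKind.SNV)
        assert triplet_class(fasta, rec) == triplet_class(tiny_genome, rec)


class TestLeftAlign:
    def test_deletion_in_repeat_shifts_left(self):
        genome = {"chr1": "TTGCACACAGG"}
        # delete "CA" at the right edge of the CACACA run: shifts to the start
        rec = MutationRecord("s", "chr1", 7, "ACA", "A", MutationKind.DEL)
        shifted = left_align(rec, genome)
        assert shifted.pos == 3
        assert shifted.ref == "GCA" and shifted.alt == "G"

    def test_insertion_shifts_left(self):
        genome = {"chr1": "TTGAAAACGG"}
        rec = MutationRecord("s", "chr1", 7, "A", "AA", MutationKind.INS)
        shifted = left_align(rec, genome)
        assert shifted.pos == 3
        assert shifted.indel_seq == "A"

    def test_snv_unchanged(self):
        genome = {"chr1": "AACAA"}
        rec = MutationRecord("s", "chr1", 3, "C", "T", MutationKind.SNV)
        assert left_align(rec, genome) == rec


class TestTuneControlThreshold:
    def test_controls_within_limits_need_no_filtering(self):
        calls = [ScoredCall("anc", "SNV", s) for s in (1, 2, 3)]
        snv_thr, indel_thr = tune_control_threshold(calls, {"anc"})
        assert snv_thr == 0.0 and indel_thr == 0.0

    def test_threshold_removes_lowest_scores(self):
        # 7 control SNVs scored 1..7 with a cap of 5: drop the two lowest
        calls = [ScoredCall("anc", "SNV", s) for s in range(1, 8)]
        snv_thr, _ = tune_control_threshold(calls, {"anc"}, max_snv=5)
        assert snv_thr == 2.0
        assert sum(c.score > snv_thr for c in calls) == 5

    def test_worst_control_binds(self):
        calls = [ScoredCall("a", "SNV", s) for s in (5, 6, 7)]
        calls += [ScoredCall("b", "SNV", s) for s in range(1, 8)]
        snv_thr, _ = tune_control_threshold(calls, {"a", "b"}, max_snv=5)
        # control b needs its two lowest scores removed; a is already fine
        assert snv_thr == 2.0

    def test_unattainable_returns_inf(self):
        calls = [ScoredCall("anc", "indel", 5.0) for _ in range(4)]
        with pytest.warns(UserWarning, match="unattainable"):
            _, indel_thr = tune_control_threshold(calls, {"anc"}, max_indel=1)
        assert indel_thr == np.inf

    @pytest.mark.parametrize("cap_pair", [(1, 3), (3, 5), (5, 7)])
    def test_monotone_in_cap(self, cap_pair):
        lo, hi = cap_pair
        rng = np.random.default_rng(0)
        calls = [ScoredCall("anc", "SNV", float(s)) for s in rng.integers(0, 20, 15)]
        thr_lo, _ = tune_control_threshold(calls, {"anc"}, max_snv=lo)
        thr_hi, _ = tune_control_threshold(calls, {"anc"}, max_snv=hi)
        assert thr_hi <= thr_lo


class TestSummarizeRates:
    @staticmethod
    def _frame(wt, mut, name="MUT"):
        rows = [{"genotype": "WT", "sample": f"w{i}", "snv": c}
                for i, c in enumerate(wt)]
        rows += [{"genotype": name, "sample": f"m{i}", "snv": c}
                 for i, c in enumerate(mut)]
        return pd.DataFrame(rows)

    def test_equal_counts_give_unit_fold_and_p_one(self):
        table = self._frame([40, 50, 60], [40, 50, 60])
        summary = summarize_rates(table, "WT", n_comparisons=1)
        assert summary.loc["MUT", "fold_vs_wt"] == 1.0
        assert summary.loc["MUT", "chi2"] == pytest.approx(0.0, abs=1e-12)
        assert summary.loc["MUT", "p_adjusted"] == 1.0

    def test_fold_change_is_ratio_of_means(self):
        table = self._frame([40, 50, 60], [70, 80, 75])
        summary = summarize_rates(table, "WT", n_comparisons=1)
        assert summary.loc["MUT", "fold_vs_wt"] == pytest.approx(1.5)

    def test_chi2_matches_independent_computation(self):
        table = self._frame([50, 50, 50], [75, 75, 75])
        n_comparisons = 4
        summary = summarize_rates(table, "WT", n_comparisons=n_comparisons)
        # independent 1-df chi-square on summed counts 150 vs 225,
        # expected an even split for equal clone numbers
        observed = np.array([225.0, 150.0])
        expected = np.array([187.5, 187.5])
        chi2 = float(((observed - expected) ** 2 / expected).sum())
        p = float(stats.chi2.sf(chi2, df=1))
        assert summary.loc["MUT", "chi2"] == pytest.approx(chi2)
        assert summary.loc["MUT", "p_adjusted"] == pytest.approx(
            min(1.0, p * n_comparisons)
        )

    def test_zero_wt_mean_warns_and_gives_nan_fold(self):
        table = self._frame([0, 0], [5, 5])
        with pytest.warns(UserWarning, match="wild-type mean"):
            summary = summarize_rates(table, "WT", n_comparisons=1)
        assert np.isnan(summary.loc["MUT", "fold_vs_wt"])
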