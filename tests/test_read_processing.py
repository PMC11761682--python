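"""Trim / merge / flank / translate behavior against small oracles."""

import itertools

import numpy as np
import pytest

from conftest import write_fastq_file
from vnarmine.config import DEFAULT_FLANK5, PipelineConfig
from vnarmine.reads import (Amplicon, FlankNotFound, MergeFailure, ReadPair,
                            TranslationReject, extract_insert, locate_flanks,
                            merge_pair, process_library, quality_trim, revcomp,
                            translate_insert)


def _pair(fwd, rev, q="I"):
    return ReadPair("p", fwd, rev, q * len(fwd), q * len(rev))


# -- independent brute-force overlap enumerator (same documented rule) -------

def oracle_merge(fwd, rev, min_overlap, max_frac):
    rc = revcomp(rev)
    candidates = []
    for L in range(min_overlap, min(len(fwd), len(rc)) + 1):
        a, b = fwd[len(fwd) - L:], rc[:L]
        mism = sum(1 for x, y in zip(a, b) if x != y)
        if mism * 100 <= max_frac * 100 * L:
            candidates.append((mism / L, L, mism))
    if not candidates:
        return None
    frac, L, mism = min(candidates)
    return fwd[: len(fwd) - L] + fwd[len(fwd) - L:] + rc[L:] if mism == 0 else None


class TestQualityTrim:
    def test_high_quality_read_unchanged(self):
        pair = _pair("ACGTACGT", "ACGTACGT")
        assert quality_trim(pair, 20) == pair

    def test_trailing_low_quality_removed(self):
        qual = "I" * 5 + "#" * 3  # '#' is Phred 2
        pair = ReadPair("p", "ACGTACGT", "ACGTACGT", qual, qual)
        trimmed = quality_trim(pair, 20)
        assert trimmed.fwd_seq == "ACGTA" and trimmed.rev_seq == "ACGTA"
        assert len(trimmed.fwd_qual) == len(trimmed.fwd_seq)

    def test_exact_adapter_suffix_removed(self):
        adapter = "AGATCGGAAGAG"
        pair = _pair("ACGTACGT" + adapter, "TTTTTTTT")
        trimmed = quality_trim(pair, 0, adapter=adapter)
        assert trimmed.fwd_seq == "ACGTACGT"

    def test_never_lengthens(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 40))
            seq = "".join(rng.choice(list("ACGT"), n))
            qual = "".join(chr(int(q) + 33) for q in rng.integers(2, 41, n))
            pair = ReadPair("p", seq, seq, qual, qual)
            out = quality_trim(pair, 20)
            assert len(out.fwd_seq) <= n and len(out.rev_seq) <= n


class TestMergePair:
    def test_constructed_exact_overlap(self):
        # rev mate reverse-complements to CCGGGTTT; 4-nt overlap on CCGG
        pair = _pair("AAACCCGG", "AAACCCGG")
        result = merge_pair(pair, 4, 0.25)
        assert isinstance(result, Amplicon)
        assert result.seq == "AAACCCGGGTTT"
        assert result.overlap_len == 4 and result.overlap_mismatches == 0

    def test_disjoint_halves_fail(self):
        template = "ACGTACGTAAGGTTCCAACC"
        pair = _pair(template[:8], revcomp(template[-8:]))
        assert isinstance(merge_pair(pair, 5, 0.0), MergeFailure)

    def test_overlap_disagreement_resolved_by_quality(self):
        template = "ACGTAAGGTCCT"  # aperiodic
        fwd = template[:8]
        # reverse mate carries one low-quality error inside the 4-nt overlap
        rc_err = "AAAGTCCT"  # template[4:12] with G->A at overlap position 2
        pair = ReadPair("p", fwd, revcomp(rc_err), "I" * 8, "#" * 8)
        result = merge_pair(pair, 4, 0.5)
        assert isinstance(result, Amplicon)
        assert result.overlap_mismatches == 1
        assert result.seq == template  # high-quality forward base wins

    @pytest.mark.parametrize("length", [8, 9, 10, 11, 12])
    def test_exhaustive_binary_templates_reconstructed(self, length):
        """Error-free reads sized so the true overlap is the minimum qualifying
        one reconstruct every 2-letter template of this length exactly."""
        min_overlap = 4
        a = (length + min_overlap + 1) // 2
        b = length + min_overlap - a
        for template in map("".join, itertools.product("AC", repeat=length)):
            pair = _pair(template[:a], revcomp(template[-b:]))
            result = merge_pair(pair, min_overlap, 0.0)
            assert isinstance(result, Amplicon)
            assert result.seq == template
            assert result.seq == oracle_merge(pair.fwd_seq, pair.rev_seq,
                                              min_overlap, 0.0)


class TestLocateFlanks:
    FLANK3 = "GGTGGAGGCGGTTCAGGCGGA"

    def test_printed_flank_bounds_insert(self):
        seq = "NNN" + DEFAULT_FLANK5 + "ATGGCC" + self.FLANK3
        res = locate_flanks(seq, DEFAULT_FLANK5, self.FLANK3, 0)
        start, end = res
        assert seq[start:end] == "ATGGCC"

    def test_missing_flank5_reports_which(self):
        res = locate_flanks("ACGT" * 30, DEFAULT_FLANK5, self.FLANK3, 0)
        assert isinstance(res, FlankNotFound) and res.reason == "flank5"

    def test_orientation_normalized(self):
        seq = "AATT" + DEFAULT_FLANK5 + "ATGGCCTTG" + self.FLANK3 + "CCGG"
        fwd_insert = extract_insert(seq, DEFAULT_FLANK5, self.FLANK3, 0)
        rc_insert = extract_insert(revcomp(seq), DEFAULT_FLANK5, self.FLANK3, 0)
        assert fwd_insert == rc_insert == "ATGGCCTTG"

    def test_empty_flank3_extends_to_end(self):
        seq = DEFAULT_FLANK5 + "ATGGCC"
        assert extract_insert(seq, DEFAULT_FLANK5, "", 0) == "ATGGCC"

    def test_mismatch_allowance(self):
        mutated = "T" + DEFAULT_FLANK5[1:]
        seq = mutated + "ATG" + self.FLANK3
        assert isinstance(locate_flanks(seq, DEFAULT_FLANK5, self.FLANK3, 0),
                          FlankNotFound)
        assert extract_insert(seq, DEFAULT_FLANK5, self.FLANK3, 1) == "ATG"


class TestTranslateInsert:
    def test_standard_code(self):
        result = translate_insert("ATGGCC")
        assert result.protein == "MA"
        assert result.nt_insert == "ATGGCC"

    @pytest.mark.parametrize("nt,reason", [
        ("ATGTAAGCC", "internal_stop"),
        ("ATGGC", "frame"),
        ("ATGNCC", "ambiguous"),
    ])
    def test_reject_reasons(self, nt, reason):
        result = translate_insert(nt)
        assert isinstance(result, TranslationReject) and result.reason == reason

    def test_trailing_stop_stripped(self):
        result = translate_insert("ATGGCCTAA")
        assert result.protein == "MA" and result.nt_insert == "ATGGCC"

    def test_length_bounds(self):
        assert translate_insert("ATGGCC", min_protein_len_aa=3).reason == "length"

    def test_no_star_or_x_in_output(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 20)) * 3
            nt = "".join(rng.choice(list("ACGT"), n))
            result = translate_insert(nt)
            if not isinstance(result, TranslationReject):
                assert "*" not in result.protein and "X" not in result.protein


class TestProcessLibrary:
    @staticmethod
    def _reads_for_inserts(inserts, cfg):
        fwd, rev = [], []
        for i, nt in enumerate(inserts):
            amplicon = cfg.flank5 + nt + cfg.flank3
            fwd.append((f"m{i}/1", amplicon[:90], "I" * min(90, len(amplicon))))
            rc = revcomp(amplicon)[:90]
            rev.append((f"m{i}/2", rc, "I" * len(rc)))
        return fwd, rev

    def test_error_free_inserts_all_survive(self, tmp_path):
        cfg = PipelineConfig(min_protein_len_aa=1, max_protein_len_aa=50,
                             min_overlap_nt=10)
        inserts = [("ATGGCCAAA" * 3) for _ in range(20)]
        fwd, rev = self._reads_for_inserts(inserts, cfg)
        f1 = write_fastq_file(tmp_path / "r1.fastq", fwd)
        f2 = write_fastq_file(tmp_path / "r2.fastq", rev)
        proteins, qc = process_library(f1, f2, cfg)
        assert len(proteins) == 20
        assert len(set(qc.as_dict().values())) == 1  # all counters equal

    def test_internal_stop_counted(self, tmp_path):
        cfg = PipelineConfig(min_protein_len_aa=1, max_protein_len_aa=50,
                             min_overlap_nt=10)
        good = "ATGGCCAAA" * 3
        stopped = "ATGTAAAAA" * 3
        fwd, rev = self._reads_for_inserts([good] * 10 + [stopped] * 4, cfg)
        f1 = write_fastq_file(tmp_path / "r1.fastq", fwd)
        f2 = write_fastq_file(tmp_path / "r2.fastq", rev)
        proteins, qc = process_library(f1, f2, cfg)
        assert qc.n_in_frame == 14 and qc.n_no_stop == 10
        assert len(proteins) == 10

    def test_qc_monotone_on_random_input(self, tmp_path, rng):
        cfg = PipelineConfig(min_overlap_nt=10)
        records_f, records_r = [], []
        for i in range(60):
            n = int(rng.integers(30, 120))
            seq = "".join(rng.choice(list("ACGT"), n))
            qual = "".join(chr(int(q) + 33) for q in rng.integers(2, 41, n))
            records_f.append((f"r{i}/1", seq, qual))
            seq2 = "".join(rng.choice(list("ACGT"), n))
            records_r.append((f"r{i}/2", seq2, qual))
        f1 = write_fastq_file(tmp_path / "r1.fastq", records_f)
        f2 = write_fastq_file(tmp_path / "r2.fastq", records_r)
        _, qc = process_library(f1, f2, cfg)
        counters = list(qc.as_dict().values())
        assert counters == sorted(counters, reverse=True)
        assert qc.n_pairs_in == 60
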