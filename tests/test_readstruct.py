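"""Read structure: orientation, anchor search, UMI extraction, whitelists, tagging."""

from pathlib import Path

import numpy as np
import pytest
from hypothesis import given, strategies as st

from trimercount.codec import encode_homotrimer
from trimercount.readstruct import (
    ExtractionConfig,
    extract_umi,
    find_anchor,
    orient_read,
    revcomp,
    tag_reads_with_genes,
    whitelist_barcodes,
)
from trimercount.sim import SimConfig, run_simulation

ANCHOR = "GTACTCTGCGTTGATACCACTGCTT"

dna = st.text(alphabet="ACGT", min_size=1, max_size=80)


def test_revcomp_basics():
    assert revcomp("AAGC") == "GCTT"
    assert revcomp("ACGTN") == "NACGT"


@given(dna)
def test_revcomp_involution(seq):
    assert revcomp(revcomp(seq)) == seq


def test_polyT_read_is_flipped():
    seq = "T" * 9 + "GACGACGAC"
    flipped, was = orient_read(seq)
    assert was is True
    assert flipped == revcomp(seq)


def test_polyA_read_unchanged():
    seq = "GACGACGAC" + "A" * 9
    out, was = orient_read(seq)
    assert was is False and out == seq


def test_unorientable_read_signalled():
    out, was = orient_read("ACGTACGTACGT")
    assert was is None and out == "ACGTACGTACGT"


def test_orientation_is_idempotent():
    seq = "T" * 9 + "GACGACGAC"
    once, f1 = orient_read(seq)
    twice, f2 = orient_read(once)
    assert f1 is True and f2 is False and twice == once


class TestFindAnchor:
    def test_exact_match_at_offset(self):
        seq = "GGGGGGG" + ANCHOR + "CCCC"
        assert find_anchor(seq, ANCHOR, 0) == 7

    def test_mismatch_tolerance_boundary(self):
        mutated = "T" + ANCHOR[1] + "C" + ANCHOR[3:]  # two substitutions
        seq = "AAAA" + mutated + "GGGG"
        assert find_anchor(seq, mutated, 0) == 4
        assert find_anchor(seq, ANCHOR, 2) == 4
        assert find_anchor(seq, ANCHOR, 1) is None

    def test_leftmost_window_wins(self):
        seq = ANCHOR + ANCHOR
        assert find_anchor(seq, ANCHOR, 2) == 0

    def test_agrees_with_bruteforce_on_random_sequences(self, rng):
        anchor = "GTACTCTGCGTT"
        for _ in range(100):
            seq = "".join("ACGT"[i] for i in rng.integers(0, 4, size=60))
            got = find_anchor(seq, anchor, 2)
            brute = next(
                (
                    i
                    for i in range(len(seq) - len(anchor) + 1)
                    if sum(a != b for a, b in zip(anchor, seq[i : i + len(anchor)])) <= 2
                ),
                None,
            )
            assert got == brute


class TestExtractUmi:
    def _config(self, **kw):
        defaults = dict(anchor=ANCHOR, umi_length=30, umi_side="upstream")
        defaults.update(kw)
        return ExtractionConfig(**defaults)

    def test_umi_recovered_upstream_of_anchor(self):
        umi = encode_homotrimer("GACTGCTACT")
        read = "CGCGCG" + umi + ANCHOR + "A" * 12 + "GATTACA"
        rec = extract_umi("r1", read, self._config())
        assert rec.ok and rec.umi == umi and rec.flipped is False

    def test_reverse_complemented_read_recovered(self):
        umi = encode_homotrimer("GACTGCTACT")
        read = revcomp("CGCGCG" + umi + ANCHOR + "A" * 12 + "GATTACA")
        rec = extract_umi("r1", read, self._config())
        assert rec.ok and rec.umi == umi and rec.flipped is True

    def test_read_name_tagging_convention(self):
        umi = encode_homotrimer("GACTGCTACT")
        read = umi + ANCHOR + "A" * 12
        rec = extract_umi("r1", read, self._config())
        assert rec.tagged_id == f"r1_{umi}"

    def test_barcode_then_umi_layout(self):
        barcode, umi = "C" * 16, encode_homotrimer("GACTGCTACT")
        read = "GG" + barcode + umi + ANCHOR + "A" * 12
        rec = extract_umi("r1", read, self._config(barcode_length=16))
        assert rec.ok and rec.barcode == barcode and rec.umi == umi
        assert rec.tagged_id == f"r1_{barcode}_{umi}"

    def test_short_segment_rejected(self):
        read = "ACGT" + ANCHOR + "A" * 12
        rec = extract_umi("r1", read, self._config(umi_length=10, min_segment_length=48))
        assert not rec.ok and rec.reject_reason in ("segment_truncated", "segment_too_short")

    def test_missing_anchor_rejected(self):
        rec = extract_umi("r1", "ACGT" * 20 + "A" * 9, self._config())
        assert rec.reject_reason == "anchor_not_found"

    def test_unoriented_rejected(self):
        rec = extract_umi("r1", "ACGT" * 10, self._config())
        assert rec.reject_reason == "unoriented"

    def test_simulated_zero_error_reads_fully_recovered(self):
        cfg = SimConfig(perm_num=1, seed=9, pcr_err=0.0, seq_err=0.0, seq_depth=100)
        rep = run_simulation(cfg).replicates[0]
        # simulator reads are synthesized forward; a UMI can itself contain a
        # poly-T run (consecutive T blocks), so orientation is switched off
        config = self._config(umi_length=36, require_orientation=False)
        n_ok = 0
        for read, tid in zip(rep.reads, rep.read_truth):
            synthetic = read + ANCHOR + "A" * 12
            rec = extract_umi("r", synthetic, config)
            assert rec.ok and rec.umi == rep.true_seqs[tid]
            n_ok += 1
        assert n_ok == 100


class TestWhitelist:
    def test_top_n_by_frequency(self):
        bcs = ["AAAA"] * 100 + ["CCCC"] * 90 + ["GGGG"]
        wl, _ = whitelist_barcodes(bcs, expected_cells=2)
        assert wl == ["AAAA", "CCCC"]

    def test_one_mismatch_assigned(self):
        bcs = ["AAAA"] * 50 + ["CCCC"] * 40 + ["AAAT"]
        _, assignment = whitelist_barcodes(bcs, expected_cells=2)
        assert assignment["AAAT"] == "AAAA"

    def test_equidistant_barcode_unassigned(self):
        bcs = ["AAAA"] * 50 + ["AATT"] * 40 + ["AAAT"]
        _, assignment = whitelist_barcodes(bcs, expected_cells=2)
        assert assignment["AAAT"] is None

    def test_beyond_mismatch_budget_unassigned(self):
        bcs = ["AAAA"] * 50 + ["CCCG"]
        _, assignment = whitelist_barcodes(bcs, expected_cells=1)
        assert assignment["CCCG"] is None

    def test_frequency_tie_at_cutoff_keeps_all(self):
        bcs = ["AAAA"] * 10 + ["CCCC"] * 5 + ["GGGG"] * 5
        wl, _ = whitelist_barcodes(bcs, expected_cells=2)
        assert set(wl) == {"AAAA", "CCCC", "GGGG"}


class TestGeneTagging:
    def _write_sam(self, path: Path, rows):
        import pysam

        header = {"HD": {"VN": "1.6"}, "SQ": [{"LN": 1000, "SN": "chr1"}]}
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for name, gene, mapped in rows:
                a = pysam.AlignedSegment()
                a.query_name = name
                a.query_sequence = "ACGT" * 5
                a.flag = 4 if not mapped else 0
                a.reference_id = -1 if not mapped else 0
                a.reference_start = -1 if not mapped else 100
                a.mapping_quality = 0 if not mapped else 60
                a.cigarstring = None if not mapped else "20M"
                if gene:
                    a.set_tag("XT", gene)
                out.write(a)

    def test_sam_records_joined_with_umi_from_name(self, tmp_path):
        sam = tmp_path / "reads.sam"
        self._write_sam(
            sam,
            [("r1_AAACCC", "geneA", True), ("r2", "geneA", True),
             ("r3_TTTGGG", None, True), ("r4_AAACCC", "geneB", False)],
        )
        out = list(tag_reads_with_genes(sam))
        assert out == [("r1", "geneA", "AAACCC")]

    def test_tsv_fallback_roundtrips_with_sam(self, tmp_path):
        sam = tmp_path / "reads.sam"
        rows = [(f"r{i}_AAACCC", "geneA", True) for i in range(3)]
        self._write_sam(sam, rows)
        from_sam = list(tag_reads_with_genes(sam))
        tsv = tmp_path / "reads.tsv"
        tsv.write_text("".join(f"{r}\t{g}\t{u}\n" for r, g, u in from_sam))
        assert list(tag_reads_with_genes(tsv)) == from_sam

    def test_malformed_tsv_rows_skipped(self, tmp_path):
        tsv = tmp_path / "bad.tsv"
        tsv.write_text("r1\tgeneA\tAAACCC\nbroken_row\n\nr2\tgeneB\tTTTGGG\n")
        out = list(tag_reads_with_genes(tsv))
        assert out == [("r1", "geneA", "AAACCC"), ("r2", "geneB", "TTTGGG")]
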