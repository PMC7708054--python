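"""Motif parsing, log-odds scoring, exact thresholds and scanning."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from minsyn.motifs import (
    BackgroundModel,
    Motif,
    MotifParseError,
    log_odds,
    parse_meme_motifs,
    reverse_complement,
    scan_sequence,
    threshold_for_pvalue,
    write_meme_motifs,
)
from _oracles import GRID, oracle_scan, oracle_threshold

IDENTITY_DOC = """MEME version 4

ALPHABET= ACGT

MOTIF TEST1
letter-probability matrix: alength= 4 w= 3
1 0 0 0
0 1 0 0
0 0 1 0
"""


class TestParseMeme:
    def test_identity_motif(self):
        motifs = parse_meme_motifs(IDENTITY_DOC)
        assert len(motifs) == 1
        assert motifs[0].width == 3
        assert motifs[0].consensus == "ACG"
        # pseudocount renormalization keeps rows stochastic
        assert np.allclose(motifs[0].ppm.sum(axis=1), 1.0)

    def test_empty_document(self):
        assert parse_meme_motifs("MEME version 4\n\nALPHABET= ACGT\n") == []

    def test_two_blocks(self):
        doc = IDENTITY_DOC + "\nMOTIF TEST2\nletter-probability matrix: alength= 4 w= 1\n0 0 0 1\n"
        motifs = parse_meme_motifs(doc)
        assert [m.id for m in motifs] == ["TEST1", "TEST2"]
        assert motifs[1].consensus == "T"

    def test_bad_column_sum_names_motif_and_line(self):
        doc = IDENTITY_DOC.replace("0 1 0 0", "0 0.5 0 0")
        with pytest.raises(MotifParseError, match="TEST1.*line 8"):
            parse_meme_motifs(doc)

    def test_non_dna_alphabet_rejected(self):
        with pytest.raises(MotifParseError, match="non-DNA"):
            parse_meme_motifs("ALPHABET= ACDEFGHIKLMNPQRSTVWY\nMOTIF X\n")

    def test_round_trip(self, tmp_path, soft_motifs):
        path = tmp_path / "motifs.meme"
        write_meme_motifs(soft_motifs, path)
        back = parse_meme_motifs(path.read_text(), pseudocount=0.0)
        assert [m.id for m in back] == [m.id for m in soft_motifs]
        for a, b in zip(soft_motifs, back):
            assert np.allclose(a.ppm, b.ppm, atol=5e-6)


class TestLogOdds:
    def test_uniform_column_is_zero(self, bg):
        motif = Motif("flat", np.full((2, 4), 0.25))
        assert np.allclose(log_odds(motif, bg), 0.0)

    def test_half_half_column_with_pseudocount(self, bg):
        motif = Motif.from_raw_ppm("hh", np.array([[0.5, 0.5, 0.0, 0.0]]), pseudocount=1e-3)
        lo = log_odds(motif, bg)
        expected_major = np.log2(((0.5 + 1e-3) / 1.004) / 0.25)  # ~1 bit
        assert lo[0, 0] == pytest.approx(expected_major)
        assert lo[0, 1] == pytest.approx(expected_major)
        assert abs(expected_major - 1.0) < 0.01

    def test_doubling_background_drops_score_one_bit(self):
        motif = Motif.from_raw_ppm("m", np.array([[0.7, 0.1, 0.1, 0.1]]))
        lo_uniform = log_odds(motif, BackgroundModel.uniform())
        lo_biased = log_odds(motif, BackgroundModel(0.5, 1 / 6, 1 / 6, 1 / 6))
        assert lo_biased[0, 0] == pytest.approx(lo_uniform[0, 0] - 1.0)


class TestThreshold:
    @pytest.mark.parametrize("p", [1e-2, 1e-3, 1e-4])
    def test_matches_exhaustive_enumeration(self, soft_motifs, bg, p):
        for motif in soft_motifs:
            t = threshold_for_pvalue(motif, bg, p)
            assert round(t * GRID) == oracle_threshold(motif, bg, p), motif.id

    def test_width_one_quarter_pvalue_selects_best_base(self, bg):
        motif = Motif.from_raw_ppm("w1", np.array([[0.7, 0.15, 0.1, 0.05]]))
        t = threshold_for_pvalue(motif, bg, 0.25)
        q = np.rint(log_odds(motif, bg) * GRID).astype(int)[0]
        # only the single best base (background probability exactly 1/4) passes
        passing = [base for base, s in zip("ACGT", q) if s >= round(t * GRID)]
        assert passing == [("ACGT")[int(np.argmax(q))]]
        assert scan_sequence("C", [motif], bg, 0.25) == []
        assert len(scan_sequence("A", [motif], bg, 0.25)) == 1

    def test_pvalue_one_admits_every_word(self, soft_motifs, bg):
        for motif in soft_motifs:
            t = threshold_for_pvalue(motif, bg, 1.0)
            q = np.rint(log_odds(motif, bg) * GRID).astype(int)
            assert round(t * GRID) == q.min(axis=1).sum()

    def test_unattainable_pvalue_yields_no_hits(self, bg):
        motif = Motif.from_raw_ppm("tiny", np.array([[0.9, 0.05, 0.03, 0.02]] * 2))
        # best 2-mer has p-value 1/16 under uniform background
        t = threshold_for_pvalue(motif, bg, 1e-3)
        q = np.rint(log_odds(motif, bg) * GRID).astype(int)
        assert round(t * GRID) == q.max(axis=1).sum() + 1
        assert scan_sequence(motif.consensus, [motif], bg, 1e-3) == []


class TestScan:
    def test_consensus_single_forward_hit(self, bundle, bg):
        motif = bundle.motifs[0]  # sharp, width >= 8
        hits = scan_sequence(motif.consensus, [motif], bg, 1e-4, sequence_id="s")
        assert len(hits) == 1
        (h,) = hits
        assert (h.start, h.end, h.strand) == (0, motif.width, "+")
        q = np.rint(log_odds(motif, bg) * GRID).astype(int)
        assert round(h.score * GRID) == q.max(axis=1).sum()
        assert 0 < h.p_value <= 1e-4

    def test_reverse_complement_hit_on_minus_strand(self, bundle, bg):
        motif = bundle.motifs[0]
        hits = scan_sequence(reverse_complement(motif.consensus), [motif], bg, 1e-4)
        assert len(hits) == 1
        assert hits[0].strand == "-"
        assert (hits[0].start, hits[0].end) == (0, motif.width)

    def test_matches_brute_force_on_random_sequence(self, soft_motifs, bg):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), 200))
        p = 1e-2
        hits = scan_sequence(seq, soft_motifs, bg, p)
        for motif in soft_motifs:
            got = sorted(
                (h.start, h.end, h.strand, round(h.score * GRID))
                for h in hits
                if h.motif_id == motif.id
            )
            assert got == oracle_scan(seq, motif, bg, p), motif.id

    def test_windows_with_n_are_skipped(self, bundle, bg):
        motif = bundle.motifs[0]
        seq = motif.consensus[:-1] + "N" + motif.consensus
        hits = scan_sequence(seq, [motif], bg, 1e-4)
        assert [(h.start, h.strand) for h in hits] == [(motif.width, "+")]

    def test_sequence_shorter_than_motif(self, bundle, bg):
        assert scan_sequence("ACG", [bundle.motifs[0]], bg, 1e-4) == []

    def test_hit_set_shrinks_with_p(self, soft_motifs, bg):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), 300))
        loose = scan_sequence(seq, soft_motifs, bg, 1e-2)
        strict = scan_sequence(seq, soft_motifs, bg, 1e-3)
        key = lambda h: (h.motif_id, h.start, h.strand)
        assert {key(h) for h in strict} <= {key(h) for h in loose}
        for motif in soft_motifs:
            assert threshold_for_pvalue(motif, bg, 1e-3) >= threshold_for_pvalue(
                motif, bg, 1e-2
            )

    def test_determinism(self, soft_motifs, bg):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), 150))
        assert scan_sequence(seq, soft_motifs, bg, 1e-2) == scan_sequence(
            seq, soft_motifs, bg, 1e-2
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=10, max_size=80))
    def test_strand_symmetry(self, seq):
        """Hits on a sequence and its reverse complement are mirror images."""
        bg = BackgroundModel.uniform()
        motif = Motif.from_raw_ppm(
            "m", np.array([[0.85, 0.05, 0.05, 0.05], [0.05, 0.05, 0.05, 0.85], [0.05, 0.85, 0.05, 0.05]])
        )
        fwd = scan_sequence(seq, [motif], bg, 1e-1)
        rev = scan_sequence(reverse_complement(seq), [motif], bg, 1e-1)
        flip = {"+": "-", "-": "+"}
        mirrored = sorted(
            (len(seq) - h.end, len(seq) - h.start, flip[h.strand], round(h.score * GRID))
            for h in rev
        )
        assert mirrored == sorted(
            (h.start, h.end, h.strand, round(h.score * GRID)) for h in fwd
        )
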