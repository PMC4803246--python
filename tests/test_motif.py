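"""Unit and property tests for PWM construction and scanning."""

import io
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from vdrescan.errors import DegenerateMatrixError, FormatError, WindowLengthError
from vdrescan.motif import (
    CountMatrix,
    anti_consensus,
    build_pwm,
    consensus,
    read_jaspar,
    relative_score,
    reverse_complement,
    scan,
    score_window,
    write_hits_tsv,
)
from vdrescan.simulate import plant_motif, simulate_background

from conftest import brute_force_scan


class TestReadJaspar:
    def test_bracketed_format(self, dr3_text):
        cm = read_jaspar(dr3_text)
        assert cm.motif_id == "SYN_DR3"
        assert cm.length == 15
        assert cm.counts.sum(axis=0).tolist() == [100.0] * 15

    def test_matches_biopython_parser(self, dr3_text):
        """Independent cross-check against Bio.motifs' JASPAR reader."""
        from Bio import motifs

        ref = motifs.read(io.StringIO(dr3_text), "jaspar")
        cm = read_jaspar(dr3_text)
        for i, base in enumerate("ACGT"):
            assert cm.counts[i].tolist() == list(ref.counts[base])

    def test_bare_four_row_matrix(self):
        cm = read_jaspar("1 2\n3 4\n5 6\n7 8\n")
        assert cm.length == 2
        assert cm.counts[3, 1] == 8

    def test_row_order_normalised(self):
        shuffled = ">X\nT [ 1 ]\nG [ 2 ]\nC [ 3 ]\nA [ 4 ]\n"
        cm = read_jaspar(shuffled)
        assert cm.counts[:, 0].tolist() == [4.0, 3.0, 2.0, 1.0]

    def test_single_column_g_only(self):
        cm = read_jaspar("A [0]\nC [0]\nG [1]\nT [0]")
        assert cm.length == 1
        assert cm.counts[2, 0] == 1

    @pytest.mark.parametrize(
        "text, fragment",
        [
            (">X\nA [1]\nC [1]\nG [1]\n", "T"),  # missing base row
            (">X\nA [1 2]\nC [1]\nG [1]\nT [1]\n", "ragged"),
            (">X\nA [-1]\nC [1]\nG [1]\nT [1]\n", "A"),  # negative count
            ("", "empty"),
        ],
    )
    def test_format_errors_name_the_problem(self, text, fragment):
        with pytest.raises(FormatError, match=fragment):
            read_jaspar(text)


class TestBuildPwm:
    def test_uniform_column_is_uninformative(self):
        cm = CountMatrix("u", np.full((4, 1), 25.0))
        pwm = build_pwm(cm)
        assert np.allclose(pwm.weights, 0.0)

    def test_single_base_column_weight(self):
        # counts (100,0,0,0), uniform background, pseudocount 0.8:
        # weight(A) = log2((100 + 0.2) / (100.8 * 0.25))
        cm = CountMatrix("a", np.array([[100.0], [0.0], [0.0], [0.0]]))
        pwm = build_pwm(cm, pseudocount=0.8)
        assert pwm.weights[0, 0] == pytest.approx(math.log2(100.2 / (100.8 * 0.25)))
        assert pwm.weights[0, 0] == pytest.approx(1.992, abs=1e-3)

    def test_zero_pseudocount_zero_column_errors(self):
        cm = CountMatrix("z", np.array([[1.0, 0.0]] + [[0.0, 0.0]] * 3))
        with pytest.raises(DegenerateMatrixError):
            build_pwm(cm, pseudocount=0.0)

    def test_score_range_matches_columnwise_extrema(self, dr3_pwm):
        assert dr3_pwm.max_score == pytest.approx(
            dr3_pwm.weights.max(axis=0).sum()
        )
        assert dr3_pwm.min_score == pytest.approx(
            dr3_pwm.weights.min(axis=0).sum()
        )
        assert dr3_pwm.max_score >= dr3_pwm.min_score


class TestScoring:
    def test_consensus_hits_max_score(self, dr3_pwm):
        assert score_window(dr3_pwm, consensus(dr3_pwm)) == pytest.approx(
            dr3_pwm.max_score
        )

    def test_anti_consensus_hits_min_score(self, dr3_pwm):
        assert score_window(dr3_pwm, anti_consensus(dr3_pwm)) == pytest.approx(
            dr3_pwm.min_score
        )

    def test_two_column_hand_sum(self, toy_pwm):
        expected = toy_pwm.weights[0, 0] + toy_pwm.weights[3, 1] + toy_pwm.weights[2, 2]
        assert score_window(toy_pwm, "ATG") == pytest.approx(expected)

    def test_wrong_length_and_bad_base(self, toy_pwm):
        with pytest.raises(WindowLengthError):
            score_window(toy_pwm, "AT")
        with pytest.raises(WindowLengthError):
            score_window(toy_pwm, "ANG")

    def test_relative_score_endpoints_and_midpoint(self, dr3_pwm):
        assert relative_score(dr3_pwm, dr3_pwm.max_score) == pytest.approx(100.0)
        assert relative_score(dr3_pwm, dr3_pwm.min_score) == pytest.approx(0.0)
        mid = (dr3_pwm.max_score + dr3_pwm.min_score) / 2
        assert relative_score(dr3_pwm, mid) == pytest.approx(50.0)

    def test_degenerate_matrix_relative_score(self):
        pwm = build_pwm(CountMatrix("u", np.full((4, 2), 10.0)))
        with pytest.raises(DegenerateMatrixError):
            relative_score(pwm, 0.0)


class TestConsensus:
    def test_tie_breaks_alphabetically(self):
        pwm = build_pwm(CountMatrix("t", np.full((4, 3), 7.0)))
        assert consensus(pwm) == "AAA"

    def test_single_column_argmax(self):
        pwm = build_pwm(CountMatrix("g", np.array([[0.0], [0.0], [9.0], [1.0]])))
        assert consensus(pwm) == "G"


class TestScan:
    def test_planted_consensus_found_once(self, dr3_pwm):
        seq = simulate_background(400, 0.4, seed=5)
        seq, rec = plant_motif(seq, dr3_pwm, 137, 1, target_relative=100.0)
        hits = scan(dr3_pwm, seq, threshold=99.0)
        assert len(hits) == 1
        assert (hits[0].start, hits[0].strand) == (137, 1)
        assert hits[0].relative_score >= 99.0
        assert hits[0].site == consensus(dr3_pwm)

    def test_short_sequence_returns_empty(self, dr3_pwm):
        assert scan(dr3_pwm, "ACGT", threshold=0.0) == []

    def test_matches_brute_force_oracle(self, dr3_pwm):
        seq = simulate_background(300, 0.5, seed=11)
        hits = {(h.start, h.strand): h.raw_score for h in scan(dr3_pwm, seq, 0.0)}
        oracle = brute_force_scan(dr3_pwm, seq)
        assert len(hits) == len(oracle)
        for start, strand, raw in oracle:
            assert hits[(start, strand)] == pytest.approx(raw, abs=1e-9)

    def test_threshold_only_filters(self, dr3_pwm):
        seq = simulate_background(800, 0.4, seed=3)
        lo = {(h.start, h.strand): h for h in scan(dr3_pwm, seq, 40.0)}
        hi = scan(dr3_pwm, seq, 65.0)
        assert all((h.start, h.strand) in lo for h in hi)
        for h in hi:
            match = lo[(h.start, h.strand)]
            assert match.raw_score == h.raw_score
            assert match.site == h.site

    def test_minus_strand_site_is_reverse_complement(self, dr3_pwm):
        seq = simulate_background(200, 0.4, seed=9)
        site = consensus(dr3_pwm)
        seq = seq[:50] + reverse_complement(site) + seq[50 + len(site):]
        hits = [h for h in scan(dr3_pwm, seq, 99.0) if h.strand == -1]
        assert len(hits) == 1
        assert hits[0].site == site

    def test_windows_with_n_are_skipped(self, dr3_pwm):
        seq = "N" * 20 + consensus(dr3_pwm) + "N" * 20
        hits = scan(dr3_pwm, seq, 99.0)
        assert [(h.start, h.strand) for h in hits] == [(20, 1)]

    @given(st.integers(0, 10_000))
    def test_reverse_complement_symmetry(self, dr3_pwm, seed):
        """Scanning the reverse complement flips strands and mirrors
        starts but preserves the multiset of scores."""
        seq = simulate_background(120, 0.45, seed=seed)
        n, L = len(seq), dr3_pwm.length
        fwd = scan(dr3_pwm, seq, 60.0)
        rev = scan(dr3_pwm, reverse_complement(seq), 60.0)
        mapped = sorted(
            (n - L - h.start, -h.strand, round(h.raw_score, 9)) for h in rev
        )
        assert mapped == sorted(
            (h.start, h.strand, round(h.raw_score, 9)) for h in fwd
        )

    def test_palindromic_pwm_scores_strands_equally(self):
        counts = np.array(
            [
                [10, 2, 5, 5, 2, 10],
                [3, 20, 5, 5, 20, 3],
                [3, 20, 5, 5, 20, 3],
                [10, 2, 5, 5, 2, 10],
            ],
            dtype=float,
        )
        pwm = build_pwm(CountMatrix("pal", counts))
        assert np.allclose(pwm.weights, pwm.weights[::-1, ::-1])
        seq = simulate_background(150, 0.5, seed=21)
        by_pos = {}
        for h in scan(pwm, seq, 0.0):
            by_pos.setdefault(h.start, {})[h.strand] = h.raw_score
        for strands in by_pos.values():
            assert strands[1] == pytest.approx(strands[-1], abs=1e-9)


def test_hits_tsv_round_coordinates(tmp_path, dr3_pwm):
    seq = simulate_background(120, 0.4, seed=2)
    seq, _ = plant_motif(seq, dr3_pwm, 30, -1, 100.0)
    out = tmp_path / "hits.tsv"
    write_hits_tsv(scan(dr3_pwm, seq, 99.0), out)
    header, row = out.read_text().splitlines()
    fields = row.split("\t")
    assert header.split("\t")[0] == "sequence_id"
    assert fields[1] == "31" and fields[2] == "45"  # 1-based inclusive
    assert fields[3] == "-"
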