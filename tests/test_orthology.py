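"""AWSI scoring, anchor-space alignment and subfamily assignment."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from selannot.fixtures import make_family_dataset, with_gap_columns
from selannot.orthology import (
    AnchorAlignment,
    AnchorRow,
    align_to_anchor,
    awsi,
    build_anchor,
    column_weights,
    read_anchor,
    score_subfamilies,
    write_anchor,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


def awsi_oracle(x, y, w):
    """Naive per-column summation, independent of the vectorized path."""
    num = den = 0.0
    for a, b, wc in zip(x, y, w):
        if a != "-" and b != "-":
            den += wc
            if a == b:
                num += wc
    return None if den <= 0 else num / den


def random_aligned_pair(rng, length=None, gap_frac=None):
    length = length or rng.randint(10, 200)
    gap_frac = gap_frac if gap_frac is not None else rng.uniform(0, 0.3)
    def seq():
        return "".join(
            "-" if rng.random() < gap_frac else rng.choice(AA) for _ in range(length)
        )
    w = [rng.random() for _ in range(length)]
    return seq(), seq(), w


def anchor_of(seqs, subfams=None):
    subfams = subfams or ["S1"] * len(seqs)
    return AnchorAlignment(
        [AnchorRow(f"r{i}", sf, "all", s) for i, (s, sf) in enumerate(zip(seqs, subfams))]
    )


class TestColumnWeights:
    def test_conserved_occupied_column_weighs_one(self):
        w = column_weights(anchor_of(["AA", "AA", "AA", "AA"]))
        assert w.tolist() == [1.0, 1.0]

    def test_all_gap_column_weighs_zero(self):
        w = column_weights(anchor_of(["A-", "A-", "C-"]))
        assert w[1] == 0.0

    def test_gap_rows_dilute_conservation(self):
        # 4-row column {A, A, V, -}: max non-gap count 2 over 4 rows
        w = column_weights(anchor_of(["AK", "AK", "VK", "-K"]))
        assert w[0] == pytest.approx(0.5)


class TestAwsi:
    def test_identity_without_gaps_is_one(self):
        assert awsi("ACDE", "ACDE", [1, 1, 1, 1]) == 1.0

    def test_total_mismatch_is_zero(self):
        assert awsi("ACDE", "DEAC", [1, 0.5, 1, 0.2]) == 0.0

    def test_undefined_when_no_shared_columns(self):
        assert awsi("A-C-", "-A-C", [1, 1, 1, 1]) is None

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            awsi("AC", "A", [1, 1])

    def test_matches_bruteforce_oracle_on_random_pairs(self, rng):
        for _ in range(1000):
            x, y, w = random_aligned_pair(rng)
            got, want = awsi(x, y, w), awsi_oracle(x, y, w)
            if want is None:
                assert got is None
            else:
                assert got == pytest.approx(want, abs=1e-12)
                assert got == pytest.approx(awsi(y, x, w), abs=0)  # symmetry
                self_score = awsi(x, x, w)
                assert self_score is None or self_score == 1.0

    @settings(derandomize=True, max_examples=200)
    @given(st.data())
    def test_bounds_symmetry_and_self_identity_hold_generally(self, data):
        length = data.draw(st.integers(1, 60))
        cell = st.sampled_from(AA + "-")
        x = "".join(data.draw(st.lists(cell, min_size=length, max_size=length)))
        y = "".join(data.draw(st.lists(cell, min_size=length, max_size=length)))
        w = data.draw(st.lists(st.floats(0, 1), min_size=length, max_size=length))
        got = awsi(x, y, w)
        if got is not None:
            assert 0.0 <= got <= 1.0
            assert got == awsi(y, x, w)
            sx = awsi(x, x, w)
            assert sx is None or sx == 1.0

    def test_invariant_under_uniform_weight_rescaling(self, rng):
        x, y, w = random_aligned_pair(rng, length=60, gap_frac=0.1)
        base = awsi(x, y, w)
        scaled = awsi(x, y, [5.0 * wc for wc in w])
        assert scaled == pytest.approx(base, abs=1e-12)


class TestAlignToAnchor:
    def test_self_alignment_recovers_ungapped_row(self, rng):
        seqs = ["".join(rng.choice(AA) for _ in range(80)) for _ in range(4)]
        anchor = anchor_of(seqs)
        assert align_to_anchor(seqs[0], anchor) == seqs[0]

    def test_degapped_row_recovers_gap_pattern(self):
        ds = make_family_dataset(3, 12, 0.08, 0.4, 90, seed=5)
        gapped = with_gap_columns(ds.anchor, 8, seed=6)
        row = gapped.rows[2]
        assert align_to_anchor(row.seq.replace("-", ""), gapped) == row.seq

    def test_insertion_keeps_column_count(self, rng):
        seqs = ["".join(rng.choice(AA) for _ in range(60)) for _ in range(2)]
        anchor = anchor_of(seqs)
        candidate = seqs[0][:30] + "WWWWW" + seqs[0][30:]
        out = align_to_anchor(candidate, anchor)
        assert len(out) == anchor.columns

    def test_empty_candidate_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            align_to_anchor("", anchor_of(["ACDE"]))


class TestScoreSubfamilies:
    def test_identical_to_representative_scores_one(self):
        ds = make_family_dataset(3, 6, 0.05, 0.4, 60, seed=9)
        rep = ds.anchor.rows[0]
        res = score_subfamilies(rep.seq, ds.anchor, candidate_id="x")
        assert res.assigned == rep.subfamily
        assert res.scores[rep.subfamily] == pytest.approx(1.0, abs=0.05)

    def test_accuracy_on_divergent_subfamilies(self):
        ds = make_family_dataset(4, 60, 0.10, 0.35, 120, seed=1)
        hits = sum(
            score_subfamilies(seq, ds.anchor).assigned == subfam
            for _, seq, subfam in ds.candidates
        )
        assert hits / len(ds.candidates) >= 0.95

    def test_single_subfamily_margin_is_zero(self):
        ds = make_family_dataset(1, 4, 0.0, 0.3, 50, seed=2)
        res = score_subfamilies(ds.candidates[0][1], ds.anchor)
        assert res.assigned == "SF1"
        assert res.margin == 0.0


class TestBuildAnchor:
    def _rows(self, rng, n, subfam="S1", lineage="all", length=50):
        return [
            AnchorRow(f"{subfam}_{i}", subfam, lineage,
                      "".join(rng.choice(AA) for _ in range(length)))
            for i in range(n)
        ]

    def test_small_group_returned_unchanged(self, rng):
        rows = self._rows(rng, 5)
        anchor = build_anchor(rows, k=12)
        assert anchor.rows == rows

    def test_identical_pair_never_both_chosen(self, rng):
        a = "".join(rng.choice(AA) for _ in range(50))
        b = "".join(rng.choice(AA) for _ in range(50))
        rows = [AnchorRow("dup1", "S1", "all", a),
                AnchorRow("dup2", "S1", "all", a),
                AnchorRow("other", "S1", "all", b)]
        anchor = build_anchor(rows, k=2)
        ids = {r.sequence_id for r in anchor.rows}
        assert not {"dup1", "dup2"} <= ids
        assert "other" in ids

    def test_default_k_is_twelve(self, rng):
        rows = self._rows(rng, 30)
        anchor = build_anchor(rows)
        assert len(anchor.rows) == 12

    def test_unlabeled_row_rejected(self, rng):
        rows = [AnchorRow("r0", "", "all", "ACDE")]
        with pytest.raises(ValueError, match="subfamily"):
            build_anchor(rows)

    def test_groups_reduced_per_subfamily_and_lineage(self, rng):
        rows = (self._rows(rng, 20, "S1", "fish") + self._rows(rng, 20, "S1", "birds")
                + self._rows(rng, 3, "S2", "fish"))
        anchor = build_anchor(rows, k=4)
        got = {}
        for r in anchor.rows:
            got[(r.subfamily, r.lineage)] = got.get((r.subfamily, r.lineage), 0) + 1
        assert got == {("S1", "fish"): 4, ("S1", "birds"): 4, ("S2", "fish"): 3}


class TestAnchorIO:
    def test_fasta_round_trip(self, tmp_path):
        ds = make_family_dataset(2, 4, 0.05, 0.4, 40, seed=3)
        path = tmp_path / "anchor.fa"
        write_anchor(ds.anchor, path)
        back = read_anchor(str(path))
        assert back.rows == ds.anchor.rows

    def test_missing_subfamily_label_rejected(self, tmp_path):
        path = tmp_path / "bad.fa"
        path.write_text(">r1 lineage=all\nACDE\n")
        with pytest.raises(ValueError, match="subfamily"):
            read_anchor(str(path))
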