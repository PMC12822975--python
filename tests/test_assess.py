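"""Overlap matching and the annotation-status classification."""

import dataclasses
import random

import pytest

from selannot.assess import (
    GeneStatus,
    TranscriptStatus,
    aggregate_gene_status,
    assess,
    classify_pair,
    match_overlaps,
    summarize,
)
from selannot.fixtures import ASSESSMENT_LABELS, make_assessment_case
from selannot.model import AnnotatedTranscript, GenomicInterval, SecPrediction

from conftest import interval


def transcript(blocks, strand="+", tid="t", stop_included=None, phases=None,
               chrom="chr1"):
    return AnnotatedTranscript(tid, "g", chrom, strand,
                               list(blocks), phases=phases or [],
                               stop_included=stop_included)


def relocate(rec, chrom, new_id=None):
    """Copy a prediction/transcript onto another chromosome (blocks included)."""
    blocks = [GenomicInterval(chrom, b.start, b.end, b.strand) for b in rec.cds_blocks]
    if isinstance(rec, SecPrediction):
        return dataclasses.replace(rec, chrom=chrom, cds_blocks=blocks,
                                   prediction_id=new_id or rec.prediction_id)
    return dataclasses.replace(rec, chrom=chrom, cds_blocks=blocks,
                               transcript_id=new_id or rec.transcript_id)


class TestMatchOverlaps:
    def test_overlapping_same_strand_pair(self, simple_prediction):
        t = transcript([interval(150, 220)])
        assert len(match_overlaps([simple_prediction], [t])) == 1

    def test_opposite_strand_never_pairs(self, simple_prediction):
        t = transcript([interval(150, 220, "-")], strand="-")
        assert match_overlaps([simple_prediction], [t]) == []

    def test_matches_quadratic_oracle_on_random_fixtures(self):
        preds, ts = [], []
        for i in range(100):
            case = make_assessment_case(ASSESSMENT_LABELS[i % 8], 900 + i)
            pred = dataclasses.replace(case.prediction,
                                       prediction_id=f"p{i}")
            preds.append(pred)
            t = case.annotation[0]
            t.transcript_id = f"t{i}"
            ts.append(t)
        got = {(p.prediction_id, t.transcript_id)
               for p, t in match_overlaps(preds, ts)}
        want = set()
        for p in preds:
            for t in ts:
                if any(bp.overlaps(bt) for bp in p.cds_blocks for bt in t.cds_blocks):
                    want.add((p.prediction_id, t.transcript_id))
        assert got == want


class TestClassifyPair:
    def test_identical_structure_is_well_annotated(self, simple_prediction):
        t = transcript([interval(101, 160)])
        assert classify_pair(simple_prediction, t) is TranscriptStatus.WELL_ANNOTATED

    def test_cds_ending_one_base_before_sec_is_stop_codon(self, simple_prediction):
        # stop-excluded dialect: CDS covers codon 1 only, Sec is the next codon
        t = transcript([interval(101, 103)], stop_included=False)
        assert classify_pair(simple_prediction, t) is TranscriptStatus.STOP_CODON

    def test_final_codon_on_sec_positions_is_stop_codon(self, simple_prediction):
        t = transcript([interval(101, 106)], stop_included=True)
        assert classify_pair(simple_prediction, t) is TranscriptStatus.STOP_CODON

    def test_missing_sec_exon_with_flanks_is_skipped(self):
        pred = SecPrediction(
            "p", "GPX", "chr1", "+",
            [interval(101, 130), interval(200, 229), interval(300, 329)],
            sec_protein_index=13,  # codon tc 36..38, inside the middle exon
        )
        t = transcript([interval(101, 130), interval(300, 329)])
        assert classify_pair(pred, t) is TranscriptStatus.SKIPPED

    def test_one_base_shift_is_out_of_frame(self, simple_prediction):
        t = transcript([interval(102, 161)])
        assert classify_pair(simple_prediction, t) is TranscriptStatus.OUT_OF_FRAME

    def test_non_overlapping_pair_is_contract_violation(self, simple_prediction):
        t = transcript([interval(500, 560)])
        with pytest.raises(ValueError, match="overlap"):
            classify_pair(simple_prediction, t)

    @pytest.mark.parametrize("label", ASSESSMENT_LABELS)
    def test_fixture_round_trip_per_label(self, label):
        """The generator's intended label is recovered for every seed."""
        for seed in range(50):
            case = make_assessment_case(label, seed)
            records = assess([case.prediction], case.annotation)
            if label == "ABSENT":
                assert records[0].gene_status is GeneStatus.ABSENT
            else:
                assert records[0].transcript_status is TranscriptStatus[label], (
                    f"{label} seed {seed}: got {records[0].transcript_status}"
                )


class TestAggregation:
    def test_no_overlap_is_absent(self):
        assert aggregate_gene_status([]) is GeneStatus.ABSENT

    def test_one_well_annotated_pair_wins(self):
        got = aggregate_gene_status(
            [TranscriptStatus.STOP_CODON, TranscriptStatus.WELL_ANNOTATED]
        )
        assert got is GeneStatus.WELL_ANNOTATED

    def test_only_flawed_pairs_is_misannotation(self):
        got = aggregate_gene_status([TranscriptStatus.UPSTREAM, TranscriptStatus.SKIPPED])
        assert got is GeneStatus.MISANNOTATION


class TestAssessProperties:
    def _batch(self, n=60):
        preds, ts, labels = [], [], []
        for i in range(n):
            label = ASSESSMENT_LABELS[i % 8]
            case = make_assessment_case(label, 3000 + i)
            preds.append(relocate(case.prediction, f"c{i}", f"p{i}"))
            for t in case.annotation:
                # preserve the ABSENT cases' different-chromosome property
                chrom = f"c{i}" if t.chrom == case.prediction.chrom else f"alt{i}"
                ts.append(relocate(t, chrom, f"t{i}"))
            labels.append(label)
        return preds, ts, labels

    def test_every_prediction_gets_exactly_one_gene_status(self):
        preds, ts, _ = self._batch()
        records = assess(preds, ts)
        per_pred = {}
        for r in records:
            per_pred.setdefault(r.prediction_id, set()).add(r.gene_status)
        assert set(per_pred) == {p.prediction_id for p in preds}
        assert all(len(v) == 1 for v in per_pred.values())

    def test_input_order_does_not_change_results(self):
        preds, ts, _ = self._batch(24)
        records = assess(preds, ts)
        rng = random.Random(1)
        preds2, ts2 = preds[:], ts[:]
        rng.shuffle(preds2)
        rng.shuffle(ts2)
        records2 = assess(preds2, ts2)
        key = lambda r: (r.prediction_id, r.transcript_id or "")
        assert sorted(records, key=key) == sorted(records2, key=key)

    def test_reversing_all_strands_makes_everything_absent(self):
        preds, ts, _ = self._batch(24)
        flipped = []
        for t in ts:
            other = "-" if t.strand == "+" else "+"
            blocks = [GenomicInterval(b.chrom, b.start, b.end, other)
                      for b in t.cds_blocks][::-1]
            flipped.append(transcript(blocks, strand=other, tid=t.transcript_id,
                                      chrom=t.chrom))
        records = assess(preds, flipped)
        assert all(r.gene_status is GeneStatus.ABSENT for r in records)


class TestSummarize:
    def test_counts_match_generator_label_tally(self):
        preds, ts, labels = [], [], []
        for i in range(200):
            label = ASSESSMENT_LABELS[i % 8]
            case = make_assessment_case(label, 7000 + i)
            pred = relocate(case.prediction, f"c{i}", f"p{i}")
            pred = dataclasses.replace(pred, family="GPX")
            preds.append(pred)
            for t in case.annotation:
                chrom = f"c{i}" if t.chrom == case.prediction.chrom else f"alt{i}"
                ts.append(relocate(t, chrom, f"t{i}"))
            labels.append(label)
        records = assess(preds, ts)
        table = summarize(records, level="transcript")
        want = {}
        for label in labels:
            name = ("Absent" if label == "ABSENT" else TranscriptStatus[label].value)
            want[name] = want.get(name, 0) + 1
        got = dict(zip(table["status"], table["count"]))
        assert got == want
        assert table["count"].sum() == len(records)
        assert table.groupby("family")["percent"].sum().round(6).eq(100.0).all()

    def test_gene_level_counts_sum_to_prediction_count(self):
        case = make_assessment_case("WELL_ANNOTATED", 1)
        records = assess([case.prediction], case.annotation)
        table = summarize(records, level="gene")
        assert table["count"].sum() == 1

    def test_unknown_level_rejected(self):
        with pytest.raises(ValueError, match="level"):
            summarize([], level="exon")
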