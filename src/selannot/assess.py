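"""Annotation assessment: match selenoprotein gene predictions to database
transcripts by genomic overlap and classify each pair.

A prediction and a transcript are compared only when they share the
chromosome and strand and their CDS blocks intersect in at least one
base.  Each overlapping pair receives exactly one transcript-level
status; per prediction these are aggregated to a gene-level status
(well annotated / misannotation / absent).

Status semantics, relative to the prediction's (first) Sec-UGA codon:

* ``WELL_ANNOTATED`` — the three Sec positions are coding in the
  transcript, in the same frame as the prediction, and the codon is not
  the transcript's terminal stop.
* ``STOP_CODON`` — the transcript's translation terminates exactly at
  the Sec UGA.  Both stop-codon dialects are recognized: a CDS whose
  final codon occupies the Sec positions (stop included in CDS) and a
  CDS ending at the base immediately 5' of the codon (stop excluded).
* ``UPSTREAM`` / ``DOWNSTREAM`` — in-frame coding overlap only 5' /
  only 3' of the Sec codon.
* ``SKIPPED`` — in-frame coding overlap on both sides, but the codon
  itself is not (fully) coding.
* ``OUT_OF_FRAME`` — no position of the CDS intersection is in the same
  frame in both models.
* ``SPLICED`` — the transcript places an intron boundary strictly
  inside the Sec codon where the prediction has none.

When several conditions co-occur, structural incompatibilities win:
OUT_OF_FRAME, then SPLICED, then WELL_ANNOTATED, then STOP_CODON, then
SKIPPED, then UPSTREAM/DOWNSTREAM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .model import (
    AnnotatedTranscript,
    GeneStatus,
    SecPrediction,
    TranscriptStatus,
    frame_at,
)

__all__ = [
    "TranscriptStatus",
    "GeneStatus",
    "AssessmentRecord",
    "match_overlaps",
    "classify_pair",
    "aggregate_gene_status",
    "assess",
    "summarize",
]


@dataclass
class AssessmentRecord:
    """One classified (prediction, transcript) pair, or an absent prediction."""

    prediction_id: str
    family: str
    transcript_id: str | None
    transcript_status: TranscriptStatus | None
    gene_status: GeneStatus


def match_overlaps(
    predictions: Sequence[SecPrediction],
    transcripts: Sequence[AnnotatedTranscript],
) -> list[tuple[SecPrediction, AnnotatedTranscript]]:
    """All (prediction, transcript) pairs whose CDS overlap on the same strand.

    Pairs are returned in prediction order; a pair appears once however
    many blocks intersect.  Opposite-strand or different-chromosome
    pairs are never returned.
    """
    trees: dict[tuple[str, str], IntervalTree] = {}
    for ti, t in enumerate(transcripts):
        tree = trees.setdefault((t.chrom, t.strand), IntervalTree())
        for b in t.cds_blocks:
            tree.addi(b.start, b.end + 1, ti)  # half-open internally
    pairs: list[tuple[SecPrediction, AnnotatedTranscript]] = []
    for pred in predictions:
        tree = trees.get((pred.chrom, pred.strand))
        if tree is None:
            continue
        hits: set[int] = set()
        for b in pred.cds_blocks:
            hits.update(iv.data for iv in tree.overlap(b.start, b.end + 1))
        for ti in sorted(hits):
            pairs.append((pred, transcripts[ti]))
    return pairs


def _is_five_prime(p: int, codon: Sequence[int], strand: str) -> bool:
    return p < min(codon) if strand == "+" else p > max(codon)


def _is_three_prime(p: int, codon: Sequence[int], strand: str) -> bool:
    return p > max(codon) if strand == "+" else p < min(codon)


def classify_pair(pred: SecPrediction, t: AnnotatedTranscript) -> TranscriptStatus:
    """Classify one overlapping same-strand pair into a transcript status."""
    shared = pred.position_set() & t.position_set()
    if not shared:
        raise ValueError("classify_pair requires an overlapping pair")

    in_frame = {p for p in shared if frame_at(pred, p) == frame_at(t, p)}
    if not in_frame:
        return TranscriptStatus.OUT_OF_FRAME

    codon = pred.sec_codon
    lo, hi = min(codon), max(codon)
    # an intron between c and c+1 falls strictly inside the codon span
    t_cuts = {c for c in t.intron_cuts() if lo <= c < hi}
    if t_cuts - pred.intron_cuts():
        return TranscriptStatus.SPLICED

    codon_coding = all(t.contains(p) for p in codon)
    codon_in_frame = codon_coding and all(
        frame_at(t, p) == frame_at(pred, p) for p in codon
    )
    t_path = t.genomic_positions()
    terminal_codon = t_path[-3:]
    # a final CDS codon on the Sec positions is a stop unless the dialect
    # explicitly excludes stops from the CDS
    is_terminal_stop = (
        codon_coding
        and list(terminal_codon) == list(codon)
        and t.stop_included is not False
    )
    if codon_in_frame and not is_terminal_stop:
        return TranscriptStatus.WELL_ANNOTATED

    if is_terminal_stop:
        return TranscriptStatus.STOP_CODON
    # stop-excluded dialect: CDS ends at the base immediately 5' of the codon
    t_end = t_path[-1]
    if pred.contains(t_end):
        pred_idx = pred.transcript_index(t_end)
        codon_start_idx = pred.transcript_index(codon[0])
        if (
            pred_idx == codon_start_idx - 1
            and frame_at(pred, t_end) == 2
            and frame_at(t, t_end) == 2
        ):
            return TranscriptStatus.STOP_CODON

    has_5p = any(_is_five_prime(p, codon, pred.strand) for p in in_frame)
    has_3p = any(_is_three_prime(p, codon, pred.strand) for p in in_frame)
    if has_5p and has_3p:
        return TranscriptStatus.SKIPPED
    if has_5p:
        return TranscriptStatus.UPSTREAM
    if has_3p:
        return TranscriptStatus.DOWNSTREAM
    # the in-frame overlap consists solely of codon positions: decide by
    # which end of the codon the transcript reaches
    if t.contains(codon[0]):
        return TranscriptStatus.UPSTREAM
    return TranscriptStatus.DOWNSTREAM


def aggregate_gene_status(statuses: Iterable[TranscriptStatus]) -> GeneStatus:
    """Gene-level status from all transcript statuses of one prediction.

    Absent when no transcript overlaps; well annotated as soon as one
    pair is; otherwise every overlapping annotation is flawed and the
    gene counts as a misannotation.
    """
    statuses = list(statuses)
    if not statuses:
        return GeneStatus.ABSENT
    if TranscriptStatus.WELL_ANNOTATED in statuses:
        return GeneStatus.WELL_ANNOTATED
    return GeneStatus.MISANNOTATION


def assess(
    predictions: Sequence[SecPrediction],
    transcripts: Sequence[AnnotatedTranscript],
) -> list[AssessmentRecord]:
    """Full assessment: overlap matching, pair classification, aggregation.

    Returns one record per overlapping pair, plus one record with
    ``transcript_id=None`` for every prediction without any overlap.
    """
    pairs = match_overlaps(predictions, transcripts)
    by_pred: dict[str, list[tuple[AnnotatedTranscript, TranscriptStatus]]] = {
        p.prediction_id: [] for p in predictions
    }
    for pred, t in pairs:
        by_pred[pred.prediction_id].append((t, classify_pair(pred, t)))
    records: list[AssessmentRecord] = []
    for pred in predictions:
        classified = by_pred[pred.prediction_id]
        gene_status = aggregate_gene_status(s for _, s in classified)
        if not classified:
            records.append(
                AssessmentRecord(pred.prediction_id, pred.family, None, None, gene_status)
            )
        else:
            for t, s in classified:
                records.append(
                    AssessmentRecord(pred.prediction_id, pred.family, t.transcript_id, s, gene_status)
                )
    return records


def summarize(records: Sequence[AssessmentRecord], level: str = "gene") -> pd.DataFrame:
    """Counts and percentages per (family, status) at gene or transcript level.

    At gene level each prediction contributes once via its gene status.
    At transcript level each overlapping pair contributes via its
    transcript status, and predictions without overlap count as Absent.
    """
    if level not in ("gene", "transcript"):
        raise ValueError(f"level must be 'gene' or 'transcript', got {level!r}")
    rows = []
    if level == "gene":
        seen: set[str] = set()
        for r in records:
            if r.prediction_id in seen:
                continue
            seen.add(r.prediction_id)
            rows.append((r.family, r.gene_status.value))
    else:
        for r in records:
            status = r.transcript_status.value if r.transcript_status else GeneStatus.ABSENT.value
            rows.append((r.family, status))
    df = pd.DataFrame(rows, columns=["family", "status"])
    out = df.groupby(["family", "status"], as_index=False).size().rename(columns={"size": "count"})
    totals = out.groupby("family")["count"].transform("sum")
    out["percent"] = 100.0 * out["count"] / totals
    return out.sort_values(["family", "status"], ignore_index=True)
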