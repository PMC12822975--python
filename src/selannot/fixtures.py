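"""Seeded synthetic-data generation with known ground truth.

Every input the other modules consume — prediction and database
GTF/GFFs, anchor alignments, candidate proteins, expectation tables —
can be generated here with its correct answer known *by construction*,
so the generator doubles as the oracle in tests.  This is not a
biological simulator: gene geometry is arbitrary-but-plausible
(exons 30-300 bp, introns 50-500 bp) and protein families evolve by
site substitutions only, so that the true alignment of a family is the
identity mapping.  Realism is deliberately traded for exactly knowable
truth.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from .lineage import ExpectationTable, LineageReport, ScoredPrediction
from .model import (
    AnnotatedTranscript,
    GenomicInterval,
    SecPrediction,
    write_gtf,
)
from .orthology import AnchorAlignment, AnchorRow, write_anchor

__all__ = [
    "ASSESSMENT_LABELS",
    "AssessmentCase",
    "FamilyDataset",
    "make_assessment_case",
    "make_family_dataset",
    "make_lineage_scenario",
    "with_gap_columns",
    "write_assessment_files",
    "write_orthology_files",
    "write_lineage_files",
]

ASSESSMENT_LABELS = (
    "WELL_ANNOTATED",
    "STOP_CODON",
    "UPSTREAM",
    "DOWNSTREAM",
    "SKIPPED",
    "OUT_OF_FRAME",
    "SPLICED",
    "ABSENT",
)

_AA = "ACDEFGHIKLMNPQRSTVWY"

EXON_LENGTH_RANGE = (30, 300)
INTRON_LENGTH_RANGE = (50, 500)


@dataclass
class AssessmentCase:
    """One prediction plus a database annotation engineered to yield a
    specific annotation status."""

    intended_label: str
    prediction: SecPrediction
    annotation: list[AnnotatedTranscript]
    seed: int


@dataclass
class FamilyDataset:
    """A synthetic multimember family: anchor plus labelled candidates."""

    anchor: AnchorAlignment
    candidates: list[tuple[str, str, str]]  # (id, sequence, true subfamily)
    params: dict = field(default_factory=dict)
    seed: int = 0


# ---------------------------------------------------------------------------
# assessment cases


def _blocks_from_positions(
    chrom: str, strand: str, positions: list[int]
) -> list[GenomicInterval]:
    """Rebuild CDS blocks from coding positions in translation order."""
    step = 1 if strand == "+" else -1
    runs: list[list[int]] = [[positions[0]]]
    for p in positions[1:]:
        if p == runs[-1][-1] + step:
            runs[-1].append(p)
        else:
            runs.append([p])
    return [
        GenomicInterval(chrom, min(r[0], r[-1]), max(r[0], r[-1]), strand)
        for r in runs
    ]


def _random_prediction(
    rng: random.Random,
    label: str,
    chrom: str = "chr1",
) -> SecPrediction:
    strand = rng.choice("+-")
    n_exons = rng.randint(1, 5)
    # lens are exon lengths in *translation* order
    lens = [rng.randint(*EXON_LENGTH_RANGE) for _ in range(n_exons)]
    total = sum(lens)
    lens[-1] += (3 - total % 3) % 3
    total = sum(lens)
    n_codons = total // 3

    # Sec residue placement: leave room for the transforms each label applies
    lo_i, hi_i = 3, n_codons - 3
    if label == "SPLICED":
        # codon wholly inside one exon, with >=1 exon base on each side
        choices = []
        for exon in range(n_exons):
            offset = sum(lens[:exon])
            first = max(offset // 3 + 2, lo_i)
            last = min((offset + lens[exon]) // 3 - 3, hi_i)
            for i in range(first, last + 1):
                tc = 3 * i
                if offset < tc and tc + 3 < offset + lens[exon]:
                    choices.append(i)
        sec_index = rng.choice(choices) + 1
    else:
        sec_index = rng.randint(lo_i, hi_i) + 1

    start = rng.randint(1_000, 100_000)
    blocks = []
    pos = start
    genomic_lens = lens if strand == "+" else lens[::-1]
    for ln in genomic_lens:
        blocks.append((pos, pos + ln - 1))
        pos += ln + rng.randint(*INTRON_LENGTH_RANGE)
    if strand == "-":
        blocks = blocks[::-1]
    cds = [GenomicInterval(chrom, s, e, strand) for s, e in blocks]
    protein = [rng.choice(_AA) for _ in range(n_codons)]
    protein[sec_index - 1] = "U"
    return SecPrediction(
        prediction_id=f"pred_{label.lower()}",
        family=rng.choice(["GPX", "TXNRD", "DIO", "SELENOW"]),
        chrom=chrom,
        strand=strand,
        cds_blocks=cds,
        sec_protein_index=sec_index,
        protein_seq="".join(protein),
    )


def _transcript_from_positions(
    pred: SecPrediction,
    positions: list[int],
    label: str,
    stop_included: bool | None = None,
    first_phase: int = 0,
    chrom: str | None = None,
) -> AnnotatedTranscript:
    blocks = _blocks_from_positions(chrom or pred.chrom, pred.strand, positions)
    t = AnnotatedTranscript(
        transcript_id=f"t_{label.lower()}",
        gene_id=f"g_{label.lower()}",
        chrom=chrom or pred.chrom,
        strand=pred.strand,
        cds_blocks=blocks,
        stop_included=stop_included,
    )
    if first_phase:
        # recompute per-block phases against the shifted codon register
        consumed = 0
        phases = []
        for b in t.cds_blocks:
            phases.append((first_phase - consumed) % 3)
            consumed += len(b)
        t.phases = phases
    return t


def _verify_case(case: AssessmentCase) -> None:
    """Independent by-construction checks, deliberately not using assess()."""
    pred = case.prediction
    codon = set(pred.sec_codon)
    label = case.intended_label
    if label == "ABSENT":
        for t in case.annotation:
            assert t.chrom != pred.chrom, "ABSENT case must not share a chromosome"
        return
    (t,) = case.annotation
    t_pos = t.position_set()
    if label == "WELL_ANNOTATED":
        assert codon <= t_pos
        assert set(pred.position_set()) <= t_pos
    elif label == "STOP_CODON":
        path = t.genomic_positions()
        if t.stop_included:
            assert path[-3:] == pred.sec_codon
        else:
            assert pred.transcript_index(path[-1]) == pred.transcript_index(pred.sec_codon[0]) - 1
    elif label == "UPSTREAM":
        assert not (codon & t_pos)
        assert all(pred.transcript_index(p) < pred.transcript_index(pred.sec_codon[0])
                   for p in t_pos)
    elif label == "DOWNSTREAM":
        assert not (codon & t_pos)
        assert all(pred.transcript_index(p) > pred.transcript_index(pred.sec_codon[2])
                   for p in t_pos)
    elif label == "SKIPPED":
        assert not (codon & t_pos)
        idx = sorted(pred.transcript_index(p) for p in t_pos)
        assert idx[0] < pred.transcript_index(pred.sec_codon[0])
        assert idx[-1] > pred.transcript_index(pred.sec_codon[2])
    elif label == "OUT_OF_FRAME":
        shared = pred.position_set() & t_pos
        assert shared
        for p in shared:
            assert pred.transcript_index(p) % 3 != t.transcript_index(p) % 3
    elif label == "SPLICED":
        lo, hi = min(codon), max(codon)
        cuts = {c for c in t.intron_cuts() if lo <= c < hi}
        assert cuts and not (cuts & pred.intron_cuts())


def make_assessment_case(target: str, seed: int) -> AssessmentCase:
    """Build a (prediction, annotation) pair whose correct status is ``target``.

    Deterministic per seed: the same (target, seed) always yields
    byte-identical structures.
    """
    if target not in ASSESSMENT_LABELS:
        raise ValueError(f"unknown status label {target!r}; expected one of {ASSESSMENT_LABELS}")
    rng = random.Random(f"{target}:{seed}")
    pred = _random_prediction(rng, target)
    P = pred.genomic_positions()
    s0 = pred.transcript_index(pred.sec_codon[0])
    s2 = s0 + 2
    L = len(P)

    if target == "WELL_ANNOTATED":
        ext5 = 3 * rng.randint(0, 5)
        ext3 = rng.randint(6, 60)
        first, last = P[0], P[-1]
        step = 1 if pred.strand == "+" else -1
        head = [first - step * k for k in range(ext5, 0, -1)]
        tail = [last + step * k for k in range(1, ext3 + 1)]
        positions = [p for p in head if p >= 1] + P + [p for p in tail if p >= 1]
        t = _transcript_from_positions(pred, positions, target)
    elif target == "STOP_CODON":
        if rng.random() < 0.5:
            t = _transcript_from_positions(pred, P[: s2 + 1], target, stop_included=True)
        else:
            t = _transcript_from_positions(pred, P[:s0], target, stop_included=False)
    elif target == "UPSTREAM":
        end = rng.randint(2, s0 - 2)
        t = _transcript_from_positions(pred, P[: end + 1], target)
    elif target == "DOWNSTREAM":
        b = s2 + 1 + rng.randint(1, min(6, L - s0 - 6))
        t = _transcript_from_positions(pred, P[b:], target, first_phase=(-b) % 3)
    elif target == "SKIPPED":
        a = 3 * rng.randint(0, 1)
        c = 3 * rng.randint(0, 1)
        cut_from, cut_to = s0 - a, s2 + c
        positions = P[:cut_from] + P[cut_to + 1:]
        t = _transcript_from_positions(pred, positions, target)
    elif target == "OUT_OF_FRAME":
        shift = rng.choice([1, 2])
        positions = [p + shift for p in P]
        t = _transcript_from_positions(pred, positions, target)
    elif target == "SPLICED":
        c = s0 + rng.randint(0, 1)            # cut between codon bases c and c+1
        cut_g = max(P[c], P[c + 1]) - 1       # genomic coordinate of the cut
        shift = rng.randint(50, 200)
        positions = [p if p <= cut_g else p + shift for p in P]
        t = _transcript_from_positions(pred, positions, target)
    else:  # ABSENT
        t = _transcript_from_positions(pred, P, target, chrom="chr2")

    case = AssessmentCase(target, pred, [t], seed)
    _verify_case(case)
    return case


# ---------------------------------------------------------------------------
# protein families


def _mutate(rng: random.Random, seq: str, p: float) -> str:
    out = []
    for ch in seq:
        if rng.random() < p:
            out.append(rng.choice([a for a in _AA if a != ch]))
        else:
            out.append(ch)
    return "".join(out)


def make_family_dataset(
    n_subfamilies: int = 4,
    n_candidates: int = 200,
    p_within: float = 0.10,
    p_between: float = 0.35,
    length: int = 120,
    seed: int = 0,
    n_representatives: int = 4,
) -> FamilyDataset:
    """Simulate a multimember protein family with known subfamily labels.

    An ancestor sequence spawns one founder per subfamily by per-site
    substitution with probability ``p_between``; anchor representatives
    and candidates derive from their founder with per-site probability
    ``p_within``.  Substitution-only evolution means the true alignment
    is columnwise identity, so candidate labels are exact ground truth.
    """
    if not (0 <= p_within < p_between <= 1):
        raise ValueError("require 0 <= p_within < p_between <= 1")
    if n_subfamilies < 1 or length < 1:
        raise ValueError("n_subfamilies and length must be positive")
    rng = random.Random(seed)
    ancestor = "".join(rng.choice(_AA) for _ in range(length))
    names = [f"SF{i + 1}" for i in range(n_subfamilies)]
    founders = {name: _mutate(rng, ancestor, p_between) for name in names}
    rows = [
        AnchorRow(f"{name}_rep{r + 1}", name, "all",
                  _mutate(rng, founders[name], p_within))
        for name in names
        for r in range(n_representatives)
    ]
    candidates = []
    for i in range(n_candidates):
        name = names[i % n_subfamilies]
        candidates.append((f"cand{i:04d}", _mutate(rng, founders[name], p_within), name))
    params = dict(
        n_subfamilies=n_subfamilies, n_candidates=n_candidates,
        p_within=p_within, p_between=p_between, length=length,
        n_representatives=n_representatives,
    )
    return FamilyDataset(AnchorAlignment(rows), candidates, params, seed)


def with_gap_columns(anchor: AnchorAlignment, n_columns: int, seed: int = 0) -> AnchorAlignment:
    """Insert ``n_columns`` all-gap columns at random places (aligner stress)."""
    rng = random.Random(seed)
    cols = sorted(rng.randint(0, anchor.columns) for _ in range(n_columns))
    rows = []
    for r in anchor.rows:
        seq = list(r.seq)
        for off, c in enumerate(cols):
            seq.insert(c + off, "-")
        rows.append(AnchorRow(r.sequence_id, r.subfamily, r.lineage, "".join(seq)))
    return AnchorAlignment(rows)


# ---------------------------------------------------------------------------
# lineage scenarios


def make_lineage_scenario(
    expected_counts: dict[str, int],
    predicted_counts: dict[str, int],
    seed: int = 0,
    lineage: str = "testlineage",
) -> tuple[ExpectationTable, list[ScoredPrediction], LineageReport]:
    """A toy expectation table, scored predictions, and their correct report.

    The expected report is computed here by the direct sort-and-slice
    rule (rank by score, keep the top N expected), independently of the
    lineage module.
    """
    if any(n < 0 for n in expected_counts.values()) or any(
        n < 0 for n in predicted_counts.values()
    ):
        raise ValueError("counts must be non-negative")
    rng = random.Random(seed)
    table = ExpectationTable({(lineage, s): n for s, n in expected_counts.items()})
    preds: list[ScoredPrediction] = []
    for subfam in sorted(predicted_counts):
        for j in range(predicted_counts[subfam]):
            preds.append(
                ScoredPrediction(f"{subfam}_p{j}", subfam, round(rng.uniform(0.3, 1.0), 6))
            )
    rng.shuffle(preds)

    expected = LineageReport()
    for subfam in sorted(set(predicted_counts) | set(expected_counts)):
        ranked = sorted(
            (p for p in preds if p.subfamily == subfam),
            key=lambda p: (-p.score, p.prediction_id),
        )
        n_exp = expected_counts.get(subfam)
        if n_exp is None:
            expected.kept.extend(p.prediction_id for p in ranked)
            expected.unexpected.extend(p.prediction_id for p in ranked)
            continue
        expected.kept.extend(p.prediction_id for p in ranked[:n_exp])
        expected.filtered_out.extend(p.prediction_id for p in ranked[n_exp:])
        if n_exp > len(ranked):
            expected.missing[subfam] = n_exp - len(ranked)
    return table, preds, expected


# ---------------------------------------------------------------------------
# file emission (the CLI fixture writer)


def write_assessment_files(case: AssessmentCase, outdir) -> dict[str, Path]:
    """Write prediction GTF, annotation GTF and protein FASTA for one case."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "prediction": outdir / "prediction.gtf",
        "annotation": outdir / "annotation.gtf",
        "proteins": outdir / "proteins.fa",
    }
    paths["prediction"].write_text(write_gtf([case.prediction]))
    paths["annotation"].write_text(write_gtf(case.annotation))
    pred = case.prediction
    paths["proteins"].write_text(f">{pred.prediction_id}\n{pred.protein_seq}\n")
    return paths


def write_orthology_files(dataset: FamilyDataset, outdir) -> dict[str, Path]:
    """Write anchor FASTA, candidate FASTA and a truth table for one family."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "anchor": outdir / "family.anchor.fa",
        "candidates": outdir / "candidates.fa",
        "truth": outdir / "truth.tsv",
    }
    write_anchor(dataset.anchor, paths["anchor"])
    with open(paths["candidates"], "w") as fh:
        for cid, seq, _ in dataset.candidates:
            fh.write(f">{cid}\n{seq}\n")
    with open(paths["truth"], "w") as fh:
        fh.write("candidate_id\ttrue_subfamily\n")
        for cid, _, subfam in dataset.candidates:
            fh.write(f"{cid}\t{subfam}\n")
    return paths


def write_lineage_files(
    table: ExpectationTable,
    predictions: list[ScoredPrediction],
    outdir,
    family: str = "FAM",
) -> dict[str, Path]:
    """Write an orthology result TSV and expectation CSV for one scenario."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "orthology": outdir / "orthology.tsv",
        "expectations": outdir / "expectation_table.csv",
    }
    with open(paths["orthology"], "w") as fh:
        fh.write("candidate_id\tfamily\tassigned_subfamily\tscore\tmargin\tall_scores\n")
        for p in predictions:
            fh.write(f"{p.prediction_id}\t{family}\t{p.subfamily}\t{p.score:.6f}\t0.0\t"
                     f"{p.subfamily}={p.score:.6f}\n")
    with open(paths["expectations"], "w") as fh:
        fh.write("lineage,subfamily,expected_count\n")
        for lin in sorted(table.lineages):
            for subfam in table.subfamilies(lin):
                fh.write(f"{lin},{subfam},{table.expected(lin, subfam)}\n")
    return paths
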