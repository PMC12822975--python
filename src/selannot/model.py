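"""Gene-structure data model and GTF/GFF3 I/O.

Coordinates are 1-based and inclusive throughout (the GTF convention);
GFF3 input uses the same convention so no conversion is needed.  CDS
blocks are stored in *translation order*: ascending genomic coordinate
on the ``+`` strand, descending on ``-``.  All "5' of" / "3' of"
language in this package refers to translation order, i.e. position
along the mRNA, not along the genome.
"""

from __future__ import annotations

import enum
import io
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from gffutils.feature import feature_from_line

__all__ = [
    "GenomicInterval",
    "AnnotatedTranscript",
    "SecPrediction",
    "TranscriptStatus",
    "GeneStatus",
    "ParseError",
    "parse_gtf",
    "parse_predictions",
    "write_gtf",
    "frame_at",
    "sec_codon_span",
]


class TranscriptStatus(enum.Enum):
    """Annotation status of one (prediction, transcript) overlapping pair."""

    WELL_ANNOTATED = "Well annotated"
    STOP_CODON = "Stop codon"
    UPSTREAM = "Upstream"
    DOWNSTREAM = "Downstream"
    SKIPPED = "Skipped"
    OUT_OF_FRAME = "Out of frame"
    SPLICED = "Spliced"


class GeneStatus(enum.Enum):
    """Aggregated annotation status of one prediction against a database."""

    WELL_ANNOTATED = "Well annotated"
    MISANNOTATION = "Misannotation"
    ABSENT = "Absent"


class ParseError(ValueError):
    """Raised for malformed GTF/GFF3 input; carries the offending line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A closed genomic interval on one strand.

    ``start`` and ``end`` are 1-based inclusive with ``end >= start``.
    """

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"end ({self.end}) < start ({self.start})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.strand == other.strand
            and self.start <= other.end
            and other.start <= self.end
        )


def _check_blocks(chrom: str, strand: str, blocks: Sequence[GenomicInterval]) -> None:
    if not blocks:
        raise ValueError("at least one CDS block is required")
    for b in blocks:
        if b.chrom != chrom or b.strand != strand:
            raise ValueError("all CDS blocks must share chrom and strand")
    ordered = sorted(blocks, key=lambda b: b.start)
    for a, b in zip(ordered, ordered[1:]):
        if b.start <= a.end:
            raise ValueError("CDS blocks overlap")
    expected = ordered if strand == "+" else ordered[::-1]
    if list(blocks) != expected:
        raise ValueError("CDS blocks are not in translation order")


class _CodingModel:
    """Shared coordinate arithmetic over ordered CDS blocks."""

    chrom: str
    strand: str
    cds_blocks: Sequence[GenomicInterval]

    @property
    def coding_length(self) -> int:
        return sum(len(b) for b in self.cds_blocks)

    def genomic_positions(self) -> list[int]:
        """All coding genomic positions in translation order."""
        out: list[int] = []
        for b in self.cds_blocks:
            rng = range(b.start, b.end + 1)
            out.extend(rng if self.strand == "+" else reversed(rng))
        return out

    def position_set(self) -> set[int]:
        s: set[int] = set()
        for b in self.cds_blocks:
            s.update(range(b.start, b.end + 1))
        return s

    def contains(self, p: int) -> bool:
        return any(b.start <= p <= b.end for b in self.cds_blocks)

    def transcript_index(self, p: int) -> int:
        """0-based index of genomic position ``p`` along the spliced CDS."""
        offset = 0
        for b in self.cds_blocks:
            if b.start <= p <= b.end:
                return offset + (p - b.start if self.strand == "+" else b.end - p)
            offset += len(b)
        raise ValueError(f"position {p} is not coding in this model")

    def genomic_position(self, idx: int) -> int:
        """Inverse of :meth:`transcript_index`."""
        if idx < 0 or idx >= self.coding_length:
            raise ValueError(f"transcript index {idx} outside coding region")
        offset = 0
        for b in self.cds_blocks:
            if idx < offset + len(b):
                k = idx - offset
                return b.start + k if self.strand == "+" else b.end - k
            offset += len(b)
        raise AssertionError("unreachable")

    def intron_cuts(self) -> set[int]:
        """Genomic positions ``c`` such that an intron lies between ``c`` and ``c+1``."""
        ordered = sorted(self.cds_blocks, key=lambda b: b.start)
        return {a.end for a in ordered[:-1]}

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(
            self.chrom,
            min(b.start for b in self.cds_blocks),
            max(b.end for b in self.cds_blocks),
            self.strand,
        )


@dataclass
class AnnotatedTranscript(_CodingModel):
    """A database transcript: ordered CDS blocks with phases.

    ``stop_included`` records the stop-codon dialect of the source file:
    ``True`` when the terminal stop codon lies inside the CDS (some
    GenBank submissions), ``False`` when it is excluded (Ensembl), and
    ``None`` when the file gives no ``stop_codon`` feature to decide.
    """

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    cds_blocks: list[GenomicInterval]
    phases: list[int] = field(default_factory=list)
    stop_included: bool | None = None

    def __post_init__(self) -> None:
        _check_blocks(self.chrom, self.strand, self.cds_blocks)
        if self.coding_length < 3:
            raise ValueError("total coding length must be >= 3")
        if not self.phases:
            self.phases = _default_phases(self.cds_blocks, first_phase=0)
        if len(self.phases) != len(self.cds_blocks):
            raise ValueError("one phase per CDS block is required")
        if any(ph not in (0, 1, 2) for ph in self.phases):
            raise ValueError("phases must be in {0,1,2}")


@dataclass
class SecPrediction(_CodingModel):
    """A predicted selenoprotein gene model with a known Sec-UGA codon.

    ``sec_codon`` holds the three genomic positions of the *first* Sec
    codon in translation order; multi-Sec proteins (SELENOP, SELENOL)
    are represented by their first Sec only.  ``sec_protein_index`` is
    the 1-based residue index of that Sec in ``protein_seq``.
    """

    prediction_id: str
    family: str
    chrom: str
    strand: str
    cds_blocks: list[GenomicInterval]
    sec_protein_index: int
    sec_codon: list[int] = field(default_factory=list)
    protein_seq: str | None = None
    subfamily: str | None = None

    def __post_init__(self) -> None:
        _check_blocks(self.chrom, self.strand, self.cds_blocks)
        if self.coding_length < 3:
            raise ValueError("total coding length must be >= 3")
        if not self.sec_codon:
            self.sec_codon = sec_codon_span(self)
        if len(self.sec_codon) != 3:
            raise ValueError("sec_codon must hold exactly 3 genomic positions")
        idxs = [self.transcript_index(p) for p in self.sec_codon]
        if idxs != [idxs[0], idxs[0] + 1, idxs[0] + 2]:
            raise ValueError("sec_codon positions are not consecutive in transcript coordinates")
        if self.protein_seq is not None:
            i = self.sec_protein_index
            if not (1 <= i <= len(self.protein_seq)) or self.protein_seq[i - 1] != "U":
                raise ValueError("protein_seq must carry 'U' at sec_protein_index")


def _default_phases(blocks: Sequence[GenomicInterval], first_phase: int = 0) -> list[int]:
    phases = []
    consumed = 0
    for b in blocks:
        phases.append((first_phase + (3 - consumed % 3)) % 3 if consumed else first_phase)
        consumed += len(b)
    return phases


def frame_at(model: _CodingModel, p: int) -> int:
    """Codon frame {0,1,2} of genomic position ``p`` within ``model``.

    Frame 0 marks the first base of a codon along the spliced CDS; for
    annotated transcripts the first block's phase offsets the register
    (a phase of 1 means the first complete codon starts at the second
    coding base).  Predictions always start in phase 0.
    """
    idx = model.transcript_index(p)  # raises if p is not coding
    phase = model.phases[0] if isinstance(model, AnnotatedTranscript) else 0
    return (idx - phase) % 3


def sec_codon_span(pred: SecPrediction) -> list[int]:
    """The three genomic positions of the prediction's first Sec codon.

    Positions are in translation order; when the codon straddles an
    intron the list is non-contiguous in genomic space.
    """
    start = 3 * (pred.sec_protein_index - 1)
    if start + 3 > pred.coding_length:
        raise ValueError(
            f"Sec residue index {pred.sec_protein_index} lies beyond the coding region"
        )
    return [pred.genomic_position(start + k) for k in range(3)]


# ---------------------------------------------------------------------------
# GTF / GFF3 reading


def _iter_features(stream, dialect: str):
    if dialect not in ("gtf", "gff3"):
        raise ValueError(f"dialect must be 'gtf' or 'gff3', got {dialect!r}")
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) != 9:
            raise ParseError(f"expected 9 tab-separated columns, found {len(fields)}", lineno)
        try:
            start, end = int(fields[3]), int(fields[4])
        except ValueError:
            raise ParseError(f"non-numeric coordinates {fields[3]!r}/{fields[4]!r}", lineno)
        if end < start:
            raise ParseError(f"end ({end}) < start ({start})", lineno)
        if fields[6] not in ("+", "-"):
            raise ParseError(f"strand must be '+' or '-', got {fields[6]!r}", lineno)
        try:
            feat = feature_from_line(line, dialect=None)
        except Exception as exc:  # noqa: BLE001 - re-raise with location
            raise ParseError(f"unparseable attributes: {exc}", lineno)
        yield lineno, feat


def _group_key(feat, dialect: str, lineno: int) -> str:
    keys = ("transcript_id",) if dialect == "gtf" else ("Parent", "transcript_id")
    for key in keys:
        if key in feat.attributes:
            return feat.attributes[key][0]
    raise ParseError(
        f"{feat.featuretype} feature lacks a transcript grouping attribute "
        f"({' or '.join(keys)})",
        lineno,
    )


def _assemble_blocks(chrom: str, strand: str, raw: list[tuple[int, int, str]]):
    raw = sorted(raw, key=lambda r: r[0], reverse=(strand == "-"))
    blocks = [GenomicInterval(chrom, s, e, strand) for s, e, _ in raw]
    phases = []
    for _, _, frame in raw:
        phases.append(int(frame) if frame in ("0", "1", "2") else None)
    if any(ph is None for ph in phases):
        phases = _default_phases(blocks, first_phase=phases[0] or 0)
    return blocks, phases


def parse_gtf(stream, dialect: str = "gtf") -> list[AnnotatedTranscript]:
    """Parse CDS features from a GTF/GFF3 document into transcripts.

    ``stream`` may be a text file object or a string.  One transcript is
    built per grouping identifier (``transcript_id`` for GTF, ``Parent``
    for GFF3) that carries at least one CDS feature.  ``stop_codon``
    features, when present, decide the ``stop_included`` dialect flag.
    """
    cds: dict[str, dict] = {}
    stops: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    for lineno, feat in _iter_features(stream, dialect):
        ftype = feat.featuretype
        if ftype not in ("CDS", "stop_codon"):
            continue
        tid = _group_key(feat, dialect, lineno)
        if ftype == "stop_codon":
            stops.setdefault(tid, []).append((feat.start, feat.end))
            continue
        rec = cds.setdefault(tid, {"chrom": feat.chrom, "strand": feat.strand, "blocks": [],
                                   "gene_id": None})
        if tid not in order:
            order.append(tid)
        if rec["chrom"] != feat.chrom or rec["strand"] != feat.strand:
            raise ParseError(f"transcript {tid!r} mixes chromosomes or strands", lineno)
        rec["blocks"].append((feat.start, feat.end, feat.frame))
        if rec["gene_id"] is None:
            for key in ("gene_id", "geneID", "gene"):
                if key in feat.attributes:
                    rec["gene_id"] = feat.attributes[key][0]
                    break

    out = []
    for tid in order:
        rec = cds[tid]
        blocks, phases = _assemble_blocks(rec["chrom"], rec["strand"], rec["blocks"])
        stop_included: bool | None = None
        if tid in stops:
            coding = set()
            for b in blocks:
                coding.update(range(b.start, b.end + 1))
            stop_pos = {p for s, e in stops[tid] for p in range(s, e + 1)}
            stop_included = stop_pos <= coding
        out.append(
            AnnotatedTranscript(
                transcript_id=tid,
                gene_id=rec["gene_id"] or tid,
                chrom=rec["chrom"],
                strand=rec["strand"],
                cds_blocks=blocks,
                phases=phases,
                stop_included=stop_included,
            )
        )
    return out


def parse_predictions(
    stream,
    dialect: str = "gtf",
    proteins: Mapping[str, str] | None = None,
) -> list[SecPrediction]:
    """Parse a prediction GTF/GFF3 into :class:`SecPrediction` records.

    Prediction files carry two extra attributes on their CDS features:
    ``family`` (profile name) and either ``sec_codon`` (comma-separated
    genomic positions of the Sec codon) or ``sec_pos`` (1-based Sec
    residue index, from which the codon span is recomputed).  Protein
    sequences, if available, are supplied via ``proteins`` keyed by
    prediction id.
    """
    recs: dict[str, dict] = {}
    order: list[str] = []
    for lineno, feat in _iter_features(stream, dialect):
        if feat.featuretype != "CDS":
            continue
        pid = _group_key(feat, dialect, lineno)
        rec = recs.setdefault(
            pid, {"chrom": feat.chrom, "strand": feat.strand, "blocks": [],
                  "family": None, "sec_codon": None, "sec_pos": None}
        )
        if pid not in order:
            order.append(pid)
        rec["blocks"].append((feat.start, feat.end, feat.frame))
        attrs = feat.attributes
        if rec["family"] is None and "family" in attrs:
            rec["family"] = attrs["family"][0]
        if rec["sec_codon"] is None and "sec_codon" in attrs:
            rec["sec_codon"] = [int(x) for x in attrs["sec_codon"]]
        if rec["sec_pos"] is None and "sec_pos" in attrs:
            rec["sec_pos"] = int(attrs["sec_pos"][0])

    out = []
    for pid in order:
        rec = recs[pid]
        blocks, _ = _assemble_blocks(rec["chrom"], rec["strand"], rec["blocks"])
        if rec["sec_pos"] is None and rec["sec_codon"] is None:
            raise ParseError(f"prediction {pid!r} lacks sec_codon and sec_pos attributes")
        sec_codon = rec["sec_codon"] or []
        protein = proteins.get(pid) if proteins else None
        pred = SecPrediction(
            prediction_id=pid,
            family=rec["family"] or "unknown",
            chrom=rec["chrom"],
            strand=rec["strand"],
            cds_blocks=blocks,
            sec_protein_index=rec["sec_pos"] or 0,
            sec_codon=sec_codon,
            protein_seq=protein,
        )
        if rec["sec_pos"] is None:
            # derive the residue index from the codon span
            pred.sec_protein_index = pred.transcript_index(sec_codon[0]) // 3 + 1
        out.append(pred)
    return out


# ---------------------------------------------------------------------------
# GTF / GFF3 writing


def _fmt_attrs(pairs: list[tuple[str, str]], dialect: str) -> str:
    if dialect == "gtf":
        return " ".join(f'{k} "{v}";' for k, v in pairs)
    return ";".join(f"{k}={v}" for k, v in pairs)


def _stop_codon_intervals(model: _CodingModel, stop_included: bool) -> list[tuple[int, int]]:
    """Genomic interval(s) of the terminal stop codon implied by the dialect."""
    if stop_included:
        positions = sorted(model.genomic_positions()[-3:])
    else:
        sp = model.span
        if model.strand == "+":
            positions = [sp.end + 1, sp.end + 2, sp.end + 3]
        else:
            positions = [sp.start - 3, sp.start - 2, sp.start - 1]
    runs: list[list[int]] = [[positions[0]]]
    for p in positions[1:]:
        if p == runs[-1][-1] + 1:
            runs[-1].append(p)
        else:
            runs.append([p])
    return [(r[0], r[-1]) for r in runs]


def write_gtf(records: Iterable[AnnotatedTranscript | SecPrediction],
              dialect: str = "gtf", source: str = "selannot") -> str:
    """Serialize transcripts or predictions back to GTF/GFF3 text.

    CDS features are emitted in ascending genomic order (translation
    order is recoverable from the strand).  ``parse_gtf(write_gtf(x))``
    reconstructs ``x`` exactly, up to attribute ordering.
    """
    if dialect not in ("gtf", "gff3"):
        raise ValueError(f"dialect must be 'gtf' or 'gff3', got {dialect!r}")
    lines = ["##gff-version 3"] if dialect == "gff3" else []
    for rec in records:
        if isinstance(rec, SecPrediction):
            rid, gid = rec.prediction_id, rec.prediction_id
            extra = [("family", rec.family),
                     ("sec_codon", ",".join(str(p) for p in rec.sec_codon)),
                     ("sec_pos", str(rec.sec_protein_index))]
            phases = _default_phases(rec.cds_blocks, first_phase=0)
            stop_included = None
        else:
            rid, gid = rec.transcript_id, rec.gene_id
            extra = []
            phases = rec.phases
            stop_included = rec.stop_included
        if dialect == "gtf":
            base = [("gene_id", gid), ("transcript_id", rid)]
        else:
            base = [("Parent", rid), ("gene_id", gid)]
        by_start = sorted(zip(rec.cds_blocks, phases), key=lambda bp: bp[0].start)
        for b, ph in by_start:
            cols = [rec.chrom, source, "CDS", str(b.start), str(b.end), ".",
                    rec.strand, str(ph), _fmt_attrs(base + extra, dialect)]
            lines.append("\t".join(cols))
        if stop_included is not None:
            for s, e in _stop_codon_intervals(rec, stop_included):
                cols = [rec.chrom, source, "stop_codon", str(s), str(e), ".",
                        rec.strand, "0", _fmt_attrs(base, dialect)]
                lines.append("\t".join(cols))
    return "\n".join(lines) + ("\n" if lines else "")
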