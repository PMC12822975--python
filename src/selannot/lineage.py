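"""Lineage-expectation filtering of predicted selenoproteomes.

Vertebrate lineages carry characteristic selenoprotein repertoires: a
curated expectation table states how many genes of each subfamily a
genome of a given lineage should contain.  Given subfamily-assigned and
similarity-scored predictions, the filter keeps, per subfamily, only
the N top-scoring candidates where N is the expected count; the rest —
typically retrotransposed pseudogenes picked up by homology search —
are filtered out.  Subfamilies with fewer predictions than expected are
reported as missing.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

__all__ = [
    "ExpectationTable",
    "ScoredPrediction",
    "LineageReport",
    "load_expectation_table",
    "load_species_lineage_map",
    "resolve_lineage",
    "apply_lineage_filter",
]


@dataclass(frozen=True)
class ScoredPrediction:
    """A prediction after orthology assignment: id, subfamily, AWSI score."""

    prediction_id: str
    subfamily: str
    score: float


class ExpectationTable:
    """Expected gene counts per (lineage, subfamily)."""

    def __init__(self, counts: Mapping[tuple[str, str], int]):
        for (lin, sub), n in counts.items():
            if n < 0:
                raise ValueError(f"negative expected count for ({lin}, {sub})")
        self._counts = dict(counts)
        self.lineages = {lin for lin, _ in counts}

    def expected(self, lineage: str, subfamily: str) -> int | None:
        """Expected count, or ``None`` when the subfamily is not listed."""
        return self._counts.get((lineage, subfamily))

    def subfamilies(self, lineage: str) -> list[str]:
        return sorted(sub for lin, sub in self._counts if lin == lineage)

    def __contains__(self, lineage: str) -> bool:
        return lineage in self.lineages

    def __len__(self) -> int:
        return len(self._counts)


@dataclass
class LineageReport:
    """Outcome of lineage filtering: a partition of the input predictions.

    ``kept`` and ``filtered_out`` are disjoint and jointly cover the
    input.  ``unexpected`` flags kept predictions whose subfamily is not
    listed for the lineage; ``missing`` maps each under-predicted
    subfamily to its deficit; ``boundary_ties`` flags subfamilies where
    the keep/cut boundary fell inside a score tie (broken by id).
    """

    kept: list[str] = field(default_factory=list)
    filtered_out: list[str] = field(default_factory=list)
    unexpected: list[str] = field(default_factory=list)
    missing: dict[str, int] = field(default_factory=dict)
    boundary_ties: list[str] = field(default_factory=list)


def load_expectation_table(source) -> ExpectationTable:
    """Read an expectation table from CSV.

    Requires columns ``lineage``, ``subfamily`` and ``expected_count``;
    counts must be non-negative integers and (lineage, subfamily) keys
    unique.
    """
    if isinstance(source, str) and "\n" not in source:
        fh: io.TextIOBase = open(source, newline="")
    elif isinstance(source, str):
        fh = io.StringIO(source)
    else:
        fh = source
    try:
        reader = csv.DictReader(fh)
        required = {"lineage", "subfamily", "expected_count"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            missing = sorted(required - set(reader.fieldnames or []))
            raise ValueError(f"expectation table lacks column(s): {', '.join(missing)}")
        counts: dict[tuple[str, str], int] = {}
        for row in reader:
            key = (row["lineage"].strip(), row["subfamily"].strip())
            raw = row["expected_count"].strip()
            try:
                n = int(raw)
            except ValueError:
                raise ValueError(f"non-integer expected count {raw!r} for {key}")
            if n < 0:
                raise ValueError(f"negative expected count {n} for {key}")
            if key in counts:
                raise ValueError(f"duplicate expectation row for {key}")
            counts[key] = n
        return ExpectationTable(counts)
    finally:
        if fh is not source:
            fh.close()


def load_species_lineage_map(source=None) -> dict[str, str]:
    """Species-to-lineage mapping from a two-column TSV.

    With no argument the small editable table shipped with the package
    is used; it covers common vertebrate model species and is meant to
    be extended by the user (or bypassed with an explicit lineage).
    """
    if source is None:
        text = (resources.files("selannot") / "data" / "species_lineage.tsv").read_text()
    elif isinstance(source, str) and "\n" not in source:
        text = open(source).read()
    elif isinstance(source, str):
        text = source
    else:
        text = source.read()
    mapping: dict[str, str] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"species-lineage rows need 2 tab-separated fields: {line!r}")
        mapping[parts[0]] = parts[1]
    return mapping


def resolve_lineage(
    species: str,
    mapping: Mapping[str, str],
    override: str | None = None,
) -> str:
    """Lineage label for a species: an explicit override wins, else the map."""
    if override is not None:
        return override
    if species in mapping:
        return mapping[species]
    raise KeyError(
        f"species {species!r} is not in the lineage mapping; "
        "pass an explicit lineage (e.g. --lineage placentals)"
    )


def apply_lineage_filter(
    assigned: Sequence[ScoredPrediction],
    lineage: str,
    table: ExpectationTable,
) -> LineageReport:
    """Keep, per subfamily, the N top-scoring predictions (N = expected count).

    Predictions are ranked by score descending, ties broken by
    prediction id; the remainder is filtered out and any deficit
    reported as missing.  Subfamilies predicted but not listed for the
    lineage are kept whole and flagged as unexpected — the expectation
    table cannot anticipate lineage-specific duplications, so
    surfacing beats deleting.  Subfamilies expected but never predicted
    appear in ``missing`` with their full expected count.
    """
    if lineage not in table:
        raise KeyError(f"lineage {lineage!r} is absent from the expectation table")
    report = LineageReport()
    by_subfam: dict[str, list[ScoredPrediction]] = {}
    for p in assigned:
        by_subfam.setdefault(p.subfamily, []).append(p)

    for subfam in sorted(set(by_subfam) | set(table.subfamilies(lineage))):
        preds = sorted(
            by_subfam.get(subfam, ()), key=lambda p: (-p.score, p.prediction_id)
        )
        expected = table.expected(lineage, subfam)
        if expected is None:
            report.kept.extend(p.prediction_id for p in preds)
            report.unexpected.extend(p.prediction_id for p in preds)
            continue
        n_keep = min(expected, len(preds))
        report.kept.extend(p.prediction_id for p in preds[:n_keep])
        report.filtered_out.extend(p.prediction_id for p in preds[n_keep:])
        if expected > len(preds):
            report.missing[subfam] = expected - len(preds)
        if 0 < n_keep < len(preds) and preds[n_keep - 1].score == preds[n_keep].score:
            report.boundary_ties.append(subfam)
    return report
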