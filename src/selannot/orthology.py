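"""Subfamily (orthology) assignment of candidate proteins against anchor
alignments, scored by average weighted sequence identity (AWSI).

An *anchor* is a fixed-column reference alignment whose rows are
representative sequences labelled with their subfamily (orthologous
group) and, optionally, the lineage they were sampled from.  A
candidate protein is placed into the anchor's column space, its AWSI
against every anchor row is computed, and the candidate is assigned to
the subfamily with the highest mean AWSI over its representatives.

AWSI between two rows of an alignment is the per-column identity
restricted to columns where neither row has a gap, weighted by column
conservation::

    AWSI(x, y) = sum_c w_c [x_c == y_c] / sum_c w_c   over mutually
                 non-gap columns c

where ``w_c`` is the frequency of the most common non-gap character in
column ``c`` of the anchor, taken over all anchor rows.  Gap rows count
in the denominator of the weight, so poorly occupied columns carry
little weight.
"""

from __future__ import annotations

import io
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices

__all__ = [
    "AnchorRow",
    "AnchorAlignment",
    "SubfamilyScores",
    "column_weights",
    "awsi",
    "align_to_anchor",
    "score_subfamilies",
    "build_anchor",
    "read_anchor",
    "write_anchor",
    "read_fasta",
]

GAP = "-"

# affine gap costs on the BLOSUM62 scale
_GAP_OPEN = 11.0
_GAP_EXTEND = 1.0


@dataclass(frozen=True)
class AnchorRow:
    sequence_id: str
    subfamily: str
    lineage: str
    seq: str


@dataclass
class AnchorAlignment:
    """A fixed-column reference alignment with subfamily-labelled rows."""

    rows: list[AnchorRow]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("an anchor needs at least one row")
        n = len(self.rows[0].seq)
        if any(len(r.seq) != n for r in self.rows):
            raise ValueError("anchor rows differ in length")
        if any(set(r.seq) == {GAP} for r in self.rows):
            raise ValueError("anchor contains an all-gap row")

    @property
    def columns(self) -> int:
        return len(self.rows[0].seq)

    @property
    def subfamilies(self) -> list[str]:
        return sorted({r.subfamily for r in self.rows})

    def rows_for(self, subfamily: str) -> list[AnchorRow]:
        return [r for r in self.rows if r.subfamily == subfamily]


@dataclass
class SubfamilyScores:
    """Per-subfamily AWSI of one candidate, and the resulting assignment.

    ``assigned`` is the argmax subfamily (ties broken lexicographically
    by name) or ``None`` when no anchor row yields a defined AWSI;
    ``margin`` is best minus second-best (0 for a single subfamily).
    """

    candidate_id: str
    scores: dict[str, float] = field(default_factory=dict)
    assigned: str | None = None
    margin: float = 0.0

    @property
    def unassignable(self) -> bool:
        return self.assigned is None


def column_weights(anchor: AnchorAlignment) -> np.ndarray:
    """Per-column conservation weights in [0, 1].

    The weight of a column is the count of its most frequent non-gap
    character divided by the total number of rows, so all-gap columns
    weigh 0 and fully conserved, fully occupied columns weigh 1.
    """
    n_rows = len(anchor.rows)
    mat = np.array([list(r.seq) for r in anchor.rows])
    weights = np.zeros(anchor.columns)
    for c in range(anchor.columns):
        col = mat[:, c]
        residues = col[col != GAP]
        if residues.size:
            _, counts = np.unique(residues, return_counts=True)
            weights[c] = counts.max() / n_rows
    return weights


def awsi(x: str, y: str, w: Sequence[float]) -> float | None:
    """Average weighted sequence identity of two aligned strings.

    Columns where either sequence has a gap are excluded.  Returns
    ``None`` when no mutually non-gap column with positive weight
    exists (undefined identity).
    """
    if not (len(x) == len(y) == len(w)):
        raise ValueError("x, y and w must have equal length")
    xa = np.frombuffer(x.encode("ascii"), dtype="S1")
    ya = np.frombuffer(y.encode("ascii"), dtype="S1")
    wa = np.asarray(w, dtype=float)
    both = (xa != b"-") & (ya != b"-")
    total = wa[both].sum()
    if not both.any() or total <= 0.0:
        return None
    return float(wa[both & (xa == ya)].sum() / total)


# ---------------------------------------------------------------------------
# candidate placement into anchor column space


def _residue_indices(seq: str, alphabet: str) -> np.ndarray:
    lut = np.full(128, alphabet.index("X"), dtype=np.int64)
    for i, ch in enumerate(alphabet):
        lut[ord(ch)] = i
    lut[ord("U")] = alphabet.index("C")  # selenocysteine scores as cysteine
    return lut[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def _profile_scores(anchor: AnchorAlignment) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-column substitution scores and occupancies.

    Returns ``(scores, occupancy, keep)`` where ``scores[c, a]`` is the
    mean BLOSUM62 score of residue ``a`` against the residues observed
    in column ``c`` (non-gap columns only), ``occupancy[c]`` the non-gap
    fraction, and ``keep`` the indices of columns with any residue.
    """
    blosum = substitution_matrices.load("BLOSUM62")
    alphabet = blosum.alphabet
    B = np.array(blosum)
    n_rows = len(anchor.rows)
    occ = np.zeros(anchor.columns)
    scores = np.zeros((anchor.columns, len(alphabet)))
    idx_rows = [_residue_indices(r.seq.replace(GAP, "X"), alphabet) for r in anchor.rows]
    gap_mask = np.array([[ch == GAP for ch in r.seq] for r in anchor.rows])
    for c in range(anchor.columns):
        present = [idx_rows[i][c] for i in range(n_rows) if not gap_mask[i][c]]
        if present:
            occ[c] = len(present) / n_rows
            scores[c] = B[np.array(present)].mean(axis=0)
    keep = np.flatnonzero(occ > 0)
    return scores, occ, keep


def align_to_anchor(candidate: str, anchor: AnchorAlignment) -> str:
    """Place a candidate protein into the anchor's fixed column space.

    Global profile-to-sequence alignment: per-column scores are the
    mean BLOSUM62 score against the column's observed residues, gaps
    are affine with costs scaled by column occupancy, and candidate
    residues that would require new columns (insertions relative to the
    anchor) are dropped.  The returned string has exactly
    ``anchor.columns`` characters; all-gap anchor columns always
    receive a gap.
    """
    if not candidate:
        raise ValueError("candidate sequence is empty")
    blosum = substitution_matrices.load("BLOSUM62")
    alphabet = blosum.alphabet
    scores, occ, keep = _profile_scores(anchor)
    S = scores[keep]                      # (C, A): columns with residues only
    occ = occ[keep]
    C = int(keep.size)
    cand_idx = _residue_indices(candidate, alphabet)
    L = len(candidate)

    go_del = _GAP_OPEN * occ              # skipping a well-occupied column is costly
    ge_del = _GAP_EXTEND * occ
    NEG = -1e18

    # three-state affine DP over (candidate prefix i, column prefix j)
    M = np.full((L + 1, C + 1), NEG)      # candidate[i-1] placed in column j-1
    X = np.full((L + 1, C + 1), NEG)      # column j-1 skipped (gap in candidate)
    Y = np.full((L + 1, C + 1), NEG)      # candidate[i-1] dropped (insertion)
    M[0, 0] = 0.0
    G = np.concatenate([[0.0], np.cumsum(ge_del)])

    def fill_deletions(i: int) -> None:
        # X[i, j] = max(A[j-1] - go_del[j-1], X[i, j-1] - ge_del[j-1]) solved
        # as a prefix max over A[j-1] + G[j-1] - (go_del[j-1] - ge_del[j-1])
        if not C:
            return
        A = np.maximum(M[i], Y[i])
        run = np.maximum.accumulate(A[:-1] + G[:-1] - (go_del - ge_del))
        X[i, 1:] = run - G[1:]

    fill_deletions(0)
    for i in range(1, L + 1):
        sub = S[:, cand_idx[i - 1]]       # score of candidate residue vs each column
        prev_best = np.maximum(np.maximum(M[i - 1], X[i - 1]), Y[i - 1])
        M[i, 1:] = prev_best[:-1] + sub
        Y[i] = np.maximum(
            np.maximum(M[i - 1], X[i - 1]) - _GAP_OPEN, Y[i - 1] - _GAP_EXTEND
        )
        fill_deletions(i)

    # traceback; state validity is enforced so boundary cells never pick an
    # unreachable predecessor
    def pick(i: int, j: int) -> str:
        cand = []
        if i >= 1 and j >= 1 or (i == 0 and j == 0):
            cand.append((M[i, j], 0, "M"))
        if j >= 1:
            cand.append((X[i, j], 1, "X"))
        if i >= 1:
            cand.append((Y[i, j], 2, "Y"))
        return max(cand, key=lambda t: (t[0], -t[1]))[2]

    aligned = [GAP] * C
    i, j = L, C
    state = pick(i, j)
    while i > 0 or j > 0:
        if state == "M":
            aligned[j - 1] = candidate[i - 1]
            i, j = i - 1, j - 1
            state = pick(i, j)
        elif state == "X":
            opened = max(M[i, j - 1], Y[i, j - 1]) - go_del[j - 1]
            extended = X[i, j - 1] - ge_del[j - 1] if j >= 2 else NEG
            j -= 1
            if extended > opened:
                state = "X"
            else:
                cand = []
                if (i >= 1 and j >= 1) or (i == 0 and j == 0):
                    cand.append((M[i, j], 0, "M"))
                if i >= 1:
                    cand.append((Y[i, j], 1, "Y"))
                state = max(cand, key=lambda t: (t[0], -t[1]))[2] if cand else "X"
        else:  # Y: candidate residue dropped
            opened = max(M[i - 1, j], X[i - 1, j]) - _GAP_OPEN
            extended = Y[i - 1, j] - _GAP_EXTEND if i >= 2 else NEG
            i -= 1
            if extended > opened:
                state = "Y"
            else:
                cand = []
                if (i >= 1 and j >= 1) or (i == 0 and j == 0):
                    cand.append((M[i, j], 0, "M"))
                if j >= 1:
                    cand.append((X[i, j], 1, "X"))
                state = max(cand, key=lambda t: (t[0], -t[1]))[2] if cand else "Y"

    # expand back into the full column space (all-gap columns stay gaps)
    full = [GAP] * anchor.columns
    for k, col in enumerate(keep):
        full[col] = aligned[k]
    return "".join(full)


def _mafft_align_to_anchor(candidate: str, anchor: AnchorAlignment,
                           candidate_id: str = "candidate") -> str:
    """Optional external backend: ``mafft --add --keeplength``.

    Produces the same contract as the built-in aligner (fixed anchor
    columns, insertions dropped).  Requires ``mafft`` on PATH.
    """
    with tempfile.TemporaryDirectory() as tmp:
        ref = Path(tmp) / "anchor.fa"
        new = Path(tmp) / "candidate.fa"
        ref.write_text("".join(f">{r.sequence_id}\n{r.seq}\n" for r in anchor.rows))
        new.write_text(f">{candidate_id}\n{candidate}\n")
        res = subprocess.run(
            ["mafft", "--add", str(new), "--keeplength", "--anysymbol", str(ref)],
            capture_output=True, text=True, check=True,
        )
        recs = list(SeqIO.parse(io.StringIO(res.stdout), "fasta"))
        return str(recs[-1].seq).upper()


_ALIGNERS = {"builtin": align_to_anchor,
             "mafft": _mafft_align_to_anchor}


def score_subfamilies(
    candidate: str,
    anchor: AnchorAlignment,
    candidate_id: str = "candidate",
    aligner: str = "builtin",
) -> SubfamilyScores:
    """Align a candidate to the anchor and score it against each subfamily.

    The subfamily score is the arithmetic mean AWSI over that
    subfamily's representative rows (rows with undefined AWSI are
    skipped).  A candidate with no defined AWSI against any row is
    returned as unassignable rather than raising.
    """
    aligned = _ALIGNERS[aligner](candidate, anchor)
    w = column_weights(anchor)
    scores: dict[str, float] = {}
    for subfam in anchor.subfamilies:
        vals = [awsi(aligned, r.seq, w) for r in anchor.rows_for(subfam)]
        vals = [v for v in vals if v is not None]
        if vals:
            scores[subfam] = float(np.mean(vals))
    result = SubfamilyScores(candidate_id=candidate_id, scores=scores)
    if scores:
        ranked = sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))
        result.assigned = ranked[0][0]
        result.margin = ranked[0][1] - ranked[1][1] if len(ranked) > 1 else 0.0
    return result


# ---------------------------------------------------------------------------
# anchor construction


def _plain_identity(x: str, y: str) -> float:
    both = [(a, b) for a, b in zip(x, y) if a != GAP and b != GAP]
    if not both:
        return 0.0
    return sum(a == b for a, b in both) / len(both)


def build_anchor(rows: Iterable[AnchorRow], k: int = 12) -> AnchorAlignment:
    """Reduce a labelled alignment to at most ``k`` representatives per
    (subfamily, lineage) group, preserving sequence diversity.

    Selection is greedy maximal-diversity: the two most dissimilar rows
    seed the set, then the row minimizing its maximum identity to the
    chosen set is added until ``k`` rows are picked.  Groups of size
    ``<= k`` are kept whole.  The default of 12 representatives
    balances assignment accuracy against anchor size.
    """
    rows = list(rows)
    if k < 1:
        raise ValueError("k must be >= 1")
    for r in rows:
        if not r.subfamily:
            raise ValueError(f"row {r.sequence_id!r} has no subfamily label")
    groups: dict[tuple[str, str], list[int]] = {}
    for pos, r in enumerate(rows):
        groups.setdefault((r.subfamily, r.lineage), []).append(pos)
    selected: set[int] = set()
    for key, members in groups.items():
        if len(members) <= k:
            selected.update(members)
            continue
        members = sorted(members, key=lambda m: (rows[m].sequence_id, m))
        n = len(members)
        ident = [[_plain_identity(rows[a].seq, rows[b].seq) for b in members]
                 for a in members]
        best_pair = min(
            ((ident[i][j], i, j) for i in range(n) for j in range(i + 1, n)),
            key=lambda t: t[0],
        )
        chosen = [best_pair[1], best_pair[2]]
        while len(chosen) < k:
            rest = [i for i in range(n) if i not in chosen]
            nxt = min(rest, key=lambda i: (max(ident[i][j] for j in chosen),
                                           rows[members[i]].sequence_id))
            chosen.append(nxt)
        selected.update(members[i] for i in chosen)
    return AnchorAlignment([r for pos, r in enumerate(rows) if pos in selected])


# ---------------------------------------------------------------------------
# FASTA I/O


def read_anchor(source) -> AnchorAlignment:
    """Read an anchor from aligned FASTA.

    Headers carry labels as ``>id subfamily=<name> lineage=<name>``;
    a missing lineage defaults to ``"all"``.
    """
    rows = []
    for rec in SeqIO.parse(source, "fasta"):
        tokens = dict(
            tok.split("=", 1) for tok in rec.description.split()[1:] if "=" in tok
        )
        if "subfamily" not in tokens:
            raise ValueError(f"anchor row {rec.id!r} lacks a subfamily= label")
        rows.append(
            AnchorRow(rec.id, tokens["subfamily"], tokens.get("lineage", "all"),
                      str(rec.seq).upper())
        )
    return AnchorAlignment(rows)


def write_anchor(anchor: AnchorAlignment, path) -> None:
    with open(path, "w") as fh:
        for r in anchor.rows:
            fh.write(f">{r.sequence_id} subfamily={r.subfamily} lineage={r.lineage}\n")
            fh.write(r.seq + "\n")


def read_fasta(source) -> dict[str, str]:
    """Plain FASTA to an ordered ``{id: sequence}`` mapping."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(source, "fasta")}
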