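# Methods

## Coordinate model

All coordinates are 1-based inclusive (the GTF convention; GFF3 uses
the same base so both dialects parse losslessly). CDS blocks are stored
in *translation order* — ascending genomic coordinate on `+`, descending
on `-` — and every "5' of / 3' of" statement in this package is made
along the mRNA, not the genome, because the annotation-status classes
are defined relative to translation.

The frame of a genomic position is `(i - phase₀) mod 3`, where `i` is
the position's 0-based index along the spliced CDS and `phase₀` is the
first block's phase (predictions are always phase 0). Two gene models
"share frame" at a position when these values agree; this positional
definition lets exon structures differ while the region around the Sec
codon still matches.

Stop-codon dialects: Ensembl-style files exclude the terminal stop from
the CDS and mark it with a `stop_codon` feature; some GenBank
submissions include it. On parsing, `stop_included` is derived from
`stop_codon` features when present (inside the CDS → included) and left
unknown otherwise. On writing, a known dialect is materialized as a
`stop_codon` feature at the implied coordinates, which makes
parse∘write the identity.

Prediction files carry the Sec codon explicitly as a `sec_codon`
attribute (comma-separated genomic positions) plus `sec_pos` (1-based
residue index); either suffices, the other is recomputed. Only the
first Sec codon of multi-Sec genes is carried, matching the assessment
rule below.

## Annotation status classification

A prediction and a database transcript are compared iff they share
chromosome and strand and their CDS blocks overlap by ≥ 1 base
(interval-tree matching; gene-level records in the database are
ignored — transcripts are classified and then aggregated per
prediction). Each pair receives exactly one status, checked in this
order:

1. **Out of frame** — no position of the CDS intersection agrees in
   frame. One agreeing base suffices to escape this class.
2. **Spliced** — the transcript has an intron boundary strictly inside
   the Sec codon's genomic span at a point where the prediction has
   none. This precedes the well-annotated check deliberately: a
   transcript that splices within the codon is treated as a
   misannotation even if the codon's bases are all coding.
3. **Well annotated** — all three Sec positions coding, in matching
   frame, and the codon is not the transcript's terminal stop.
4. **Stop codon** — translation ends exactly at the Sec UGA, in either
   dialect: the final CDS codon occupies the Sec positions
   (stop-included), or the CDS ends at the base immediately 5' of the
   codon with the codon as the next in-frame triplet (stop-excluded).
   When the dialect is unknown, a final codon sitting exactly on the
   Sec positions counts as a stop: a CDS "ending precisely at the Sec
   UGA" is overwhelmingly a truncation, not a deliberate Sec
   annotation. Only an explicit stop-excluded dialect rescues such a
   transcript into class 3.
5. **Skipped** — in-frame coding positions exist both 5' and 3' of the
   codon, but the codon itself is not fully coding.
6. **Upstream / Downstream** — in-frame coding overlap only 5' / only
   3' of the codon. If the only in-frame overlap lies *inside* the
   codon (a partial-codon edge case), the side the transcript reaches
   decides.

Structural incompatibilities are checked before positional ones so that
co-occurring conditions resolve deterministically. Gene-level
aggregation: absent with zero overlapping transcripts, well annotated
as soon as one pair is, misannotation otherwise. All transcripts of all
overlapping genes contribute; the database's gene grouping is not
consulted.

## AWSI and subfamily assignment

Column weights are `w_c = max count of a non-gap character in column c
/ number of rows`; the denominator counts gap rows too, so sparsely
occupied columns carry proportionally little weight (the alternative —
normalizing by non-gap rows only — would let a column occupied by a
single sequence weigh 1.0). All-gap columns weigh 0. AWSI between two
aligned rows sums weights over mutually non-gap columns; with no such
column (or zero total weight) the identity is undefined and reported as
`None` rather than 0, and a candidate undefined against every row is
returned as "unassignable" rather than raising.

Candidates are placed into the anchor's fixed column space by a global
profile-to-sequence alignment: per-column match scores are the mean
BLOSUM62 score of the candidate residue against the column's observed
residues; gaps are affine (open 11, extend 1 on the BLOSUM62 scale)
with deletion costs scaled by column occupancy, so skipping a
poorly-occupied column is cheap; selenocysteine scores as cysteine
(BLOSUM62 has no U row). Candidate residues that would require new
columns are dropped without penalty — the anchor's column space is
fixed, and unscored insertions cannot inflate or deflate identity over
the compared columns. All-gap anchor columns are excluded from the DP
and always receive a gap. An external profile-add aligner (mafft
`--add --keeplength`) can be selected as an alternative backend with
the identical output contract.

The subfamily score is the arithmetic mean AWSI over the subfamily's
representatives — robust to unequal representative counts — and the
assignment is the argmax, ties broken lexicographically by subfamily
name, with the best-minus-second-best margin exposed so callers can see
ambiguity.

Anchor reduction keeps at most k representatives per (subfamily,
lineage) group (default 12, the size at which assignment accuracy
saturates against anchor cost): the two most dissimilar rows seed the
selection, then the row minimizing its maximum identity to the chosen
set is added greedily. Plain (unweighted) identity over mutually
non-gap columns drives the selection; ties fall back to sequence id for
determinism.

## Lineage filtering

The expectation table maps (lineage, subfamily) to a non-negative
expected gene count; a species resolves to a lineage through an
explicit override or a small editable species→lineage TSV shipped with
the package (automatic taxonomy resolution is deliberately out of
scope — no network, no downloads). Per subfamily, predictions are
ranked by their assigned-subfamily AWSI, the top `min(expected,
predicted)` are kept, the rest filtered out, and `max(0, expected −
predicted)` is reported as the missing deficit. Score ties at the
keep/cut boundary break by prediction id and are flagged. Subfamilies
predicted but absent from the lineage's table are kept and flagged
"unexpected" rather than dropped: the table cannot anticipate
lineage-specific duplications, and surfacing beats silently deleting.
The filter conserves its input (kept ⊎ filtered out), is idempotent,
and keeping never shrinks when an expected count rises.

Known limitation: ranking by sequence similarity can prefer a recent
retrotransposed pseudogene over the functional copy when the two are
nearly identical; exon–intron structure is not consulted.

## Synthetic data

`selannot.fixtures` inverts each definition to manufacture inputs whose
correct answer is known by construction, and every generated case is
re-verified by independent assertions inside the generator (position
arithmetic, not the classifier under test).

Gene geometry: 1–5 exons of 30–300 bp (coding length padded to a
multiple of 3), introns of 50–500 bp, both strands, Sec at an internal
codon with margins wide enough for every transformation. These ranges
are arbitrary fixed defaults in a realistic order of magnitude, not
fitted to any genome. Per target label the annotation is derived from
the prediction by: 3'/in-frame-5' extension (well annotated),
truncation at or immediately before the codon in either stop dialect
(stop codon), earlier truncation (upstream), start beyond the codon
with a compensating phase (downstream), removal of a codon-aligned
window covering the Sec codon (skipped), a 1–2 bp coordinate shift
(out of frame), an intron inserted inside the codon by shifting the
genomically-later half (spliced), or relocation to another chromosome
(absent).

Protein families evolve by per-site substitution only (ancestor →
subfamily founders at probability `p_between` per site → members at
`p_within`), so the true alignment is columnwise identity and candidate
labels are exact. Gap handling in the aligner is exercised separately
by inserting all-gap columns into finished anchors. No codon model, no
indels, no selection: passing these tests demonstrates correctness of
the algorithms under exactly known truth, not robustness to the
alignment ambiguity of deeply diverged real families.

Default family-simulation conditions (4 subfamilies, 200 candidates,
`p_within = 0.10`, `p_between = 0.35`, length 120) put within-subfamily
divergence well below between-subfamily divergence, the regime the
anchor method targets; at `p_within = 0` assignment must be exact.

All generators are seeded and byte-reproducible: the same (target,
seed) yields identical files.

## Numerical choices

AWSI is computed in double precision with a single vectorized pass and
agrees with a naive per-column summation to ≤ 1e-12. Alignment DP
tie-breaks prefer residue placement over gaps, and gap opening over
extension only when strictly better, giving a deterministic traceback.
Sort orders everywhere use (score descending, id ascending) so outputs
are independent of input order. Degenerate inputs have defined
behaviour: empty candidate → error; unalignable candidate →
unassignable result; empty expectation table → every lookup absent;
empty prediction set → empty reports.
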