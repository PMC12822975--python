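# selannot

Quality control for selenoprotein gene annotations.

Selenoproteins incorporate selenocysteine (Sec, U) at an in-frame UGA
codon — the triplet that normally terminates translation. Annotation
pipelines without a dedicated selenoprotein routine therefore tend to
truncate these genes at the Sec UGA, skip the Sec-containing exon, or
shift frame around it. `selannot` provides three utilities to detect,
resolve and filter such cases:

* **assess** — match Sec-aware gene predictions (GTF/GFF with known Sec
  codon coordinates) to database CDS annotations by genomic overlap on
  the same strand, and classify each (prediction, transcript) pair:
  *Well annotated* (the Sec UGA is coding, in frame), *Stop codon* (the
  CDS ends precisely at the Sec UGA), *Upstream* / *Downstream* (coding
  overlap only 5' / 3' of it), *Skipped* (coding on both sides but the
  codon excluded), *Out of frame*, *Spliced* (a splice site inside the
  codon), or *Absent* (no overlap at all). Per prediction these
  aggregate to gene level: well annotated if any transcript is,
  misannotation otherwise, absent without overlap. Multi-Sec proteins
  (SELENOP, SELENOL) are assessed at their first Sec residue.
* **orthology** — assign candidate proteins to subfamilies (paralogs
  such as GPX1…GPX8 within the GPX family) by aligning them into a
  fixed-column *anchor* alignment of labelled representatives and
  scoring the average weighted sequence identity

      AWSI(x, y) = Σ_c w_c·[x_c = y_c] / Σ_c w_c

  over mutually non-gap columns, where `w_c` is the frequency of the
  most common non-gap character in anchor column `c`. The candidate is
  assigned to the subfamily with the highest mean AWSI over its
  representatives. Anchors can be built from larger labelled alignments
  by greedy maximal-diversity reduction (default 12 representatives per
  subfamily per lineage).
* **lineage** — filter an assigned selenoproteome against the expected
  gene content of the species' lineage: per subfamily with expected
  count N, only the N top-scoring predictions are kept; extras
  (typically retrotransposed pseudogenes) are filtered out and deficits
  reported as missing.

A fourth module, `selannot.fixtures`, generates every input with known
ground truth, so the whole toolkit is testable without downloading a
single genome.

## Worked example

```python
>>> from selannot.fixtures import make_assessment_case
>>> from selannot.assess import assess
>>> case = make_assessment_case("SKIPPED", seed=3)
>>> r = assess([case.prediction], case.annotation)[0]
>>> r.transcript_status.value, r.gene_status.value
('Skipped', 'Misannotation')
```

The annotation covers the prediction's CDS in matching frame both 5'
and 3' of the Sec UGA, but splices out the codon itself — the most
common misannotation mode after Sec-as-stop truncation. Longer
narrative walkthroughs live in `examples/`; for instance
`python examples/assign_subfamilies.py` prints

```
anchor: 16 representatives, 120 columns, subfamilies ['SF1', 'SF2', 'SF3', 'SF4']
cand0000: assigned SF1 (true SF1), margin 0.331
  per-subfamily AWSI: SF1=0.866, SF2=0.512, SF3=0.535, SF4=0.482
assignment accuracy: 60/60 = 100.0%
```

i.e. the candidate matches its own subfamily's representatives at ~87%
of conservation-weighted columns, well clear of the runner-up, and all
60 simulated candidates are assigned to their true subfamily.

The same steps are available as shell commands:

```bash
selannot fixtures  --what assess --target SKIPPED --seed 3 --out fx/
selannot assess    --prediction fx/prediction.gtf --annotation fx/annotation.gtf \
                   --out records.tsv --summary summary.tsv --level transcript
selannot orthology --fasta candidates.fa --anchor family.anchor.fa --out orthology.tsv
selannot lineage   --orthology orthology.tsv --expectations expectation_table.csv \
                   --species "Mus musculus" --out lineage.tsv
```

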