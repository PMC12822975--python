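"""Classify how a database annotates a selenoprotein gene.

Builds a synthetic Sec-containing gene prediction together with a
database transcript engineered to skip the Sec-UGA exon, then runs the
assessment. The transcript status names the misannotation mode; the
gene status aggregates all overlapping transcripts of the prediction.
"""

from selannot.assess import assess, summarize
from selannot.fixtures import make_assessment_case

case = make_assessment_case("SKIPPED", seed=3)
pred = case.prediction
print(f"prediction {pred.prediction_id} ({pred.family}), strand {pred.strand}, "
      f"{len(pred.cds_blocks)} CDS blocks")
print(f"Sec residue #{pred.sec_protein_index}, codon at genomic positions "
      f"{pred.sec_codon}")

records = assess([pred], case.annotation)
for r in records:
    print(f"vs {r.transcript_id}: transcript status = {r.transcript_status.value}, "
          f"gene status = {r.gene_status.value}")

print("\nper-family summary (transcript level):")
print(summarize(records, level="transcript").to_string(index=False))
print("\n'Skipped' means the annotated CDS covers regions both 5' and 3' of the")
print("Sec UGA in matching frame, but the codon itself is not coding - the")
print("annotation spliced out the Sec-containing exon.")
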