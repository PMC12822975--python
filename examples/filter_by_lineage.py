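"""Filter a predicted selenoproteome against its lineage's expectations.

Mouse carries two GPX4-like loci but placental genomes are expected to
hold a single functional GPX4, so homology search typically reports one
extra (a retrotransposed pseudogene). The lineage filter keeps the
top-scoring prediction per subfamily up to the expected count.
"""

from selannot.lineage import (
    ExpectationTable,
    ScoredPrediction,
    apply_lineage_filter,
    load_species_lineage_map,
    resolve_lineage,
)

lineage = resolve_lineage("Mus musculus", load_species_lineage_map())
print(f"Mus musculus -> lineage {lineage!r}")

table = ExpectationTable({
    ("placentals", "GPX4"): 1,
    ("placentals", "GPX1"): 1,
    ("placentals", "DIO2"): 1,
})
predictions = [
    ScoredPrediction("gpx4_chr10", "GPX4", 0.981),
    ScoredPrediction("gpx4_chr7_retro", "GPX4", 0.914),
    ScoredPrediction("gpx1_chr9", "GPX1", 0.965),
]
report = apply_lineage_filter(predictions, lineage, table)
print(f"kept:         {report.kept}")
print(f"filtered out: {report.filtered_out}")
print(f"missing:      {report.missing}")
print("\nThe lower-scoring GPX4 copy is filtered as an unexpected extra; DIO2")
print("is expected but unpredicted, so it is reported missing (deficit 1).")
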