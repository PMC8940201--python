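"""Score a taxonomic classification against ground truth with negative
controls.

Builds a planted scenario of 200 reads (40 of them negative controls from
shuffled sequences, which should stay unclassified) in which the
classifier gets most reads right, misses some, and wrongly classifies a few
controls — then prints the per-rank confusion counts, MCC and species
recovery.
"""

from annotran.evaluation import (
    GroundTruthEntry,
    TaxAssignment,
    evaluate_taxonomic,
    format_report,
)

lineage = lambda sp: {"superkingdom": "Bacteria", "genus": sp + "_genus",
                      "species": sp}

truth, preds = [], []
for i in range(160):  # real reads from 8 species
    sp = f"Species_{i % 8}"
    truth.append(GroundTruthEntry(f"r{i}", False, lineage(sp)))
    if i % 10 == 0:  # 16 reads left unclassified -> FN
        preds.append(TaxAssignment(f"r{i}", False))
    elif i % 10 == 1:  # 16 reads misclassified -> FP
        preds.append(TaxAssignment(f"r{i}", True, lineage("Species_wrong")))
    else:  # 128 correct -> TP
        preds.append(TaxAssignment(f"r{i}", True, lineage(sp)))
for i in range(40):  # negative controls: unknown organisms
    truth.append(GroundTruthEntry(f"nc{i}", True))
    if i < 4:  # 4 controls wrongly classified -> FP
        preds.append(TaxAssignment(f"nc{i}", True, lineage("Species_0")))
    else:  # 36 correctly unclassified -> TN
        preds.append(TaxAssignment(f"nc{i}", False))

report = evaluate_taxonomic(preds, truth, ranks=("genus", "species"))
print(format_report(report))
# TP/FP/TN/FN partition all 200 reads; MCC summarises them in [-1, 1] and
# recovery is the share of true species with at least one correct read
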