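"""Benchmark predicted relations against a reference interaction set.

Simplifies KEGG-style interaction subtypes to activate/inhibit, matches
predicted and reference gene pairs after alias normalization, and reports
the directional confusion matrix with precision/recall/F1.
"""

from ickg import (
    AliasTable,
    prf_from_confusion,
    relation_confusion,
    simplify_kegg_interaction,
)
from ickg.types import Direction, RelationTriple

# Reference interactions as (genes, raw subtype); anything that is not an
# activation or inhibition subtype is excluded from the benchmark.
raw_reference = [
    ("TP53", "MDM2", "activation"),
    ("MDM2", "TP53", "inhibition"),
    ("IL15", "JAK1", "activation-indirect effect"),
    ("JAK1", "STAT5", "activation"),
    ("FOXP3", "IL2", "inhibition-repression"),
    ("CD28", "PIK3CA", "binding/association"),
]
reference = []
for src, tgt, subtype in raw_reference:
    simplified = simplify_kegg_interaction(subtype)
    print(f"{subtype:<28} -> {simplified}")
    if simplified != "excluded":
        reference.append((src, tgt, simplified))

# Predictions use alias surface forms ("p53") on purpose.
predicted = [
    RelationTriple("p53", "MDM2", Direction.ACTIVATE, "pm1"),
    RelationTriple("MDM2", "p53", Direction.INHIBIT, "pm2"),
    RelationTriple("IL15", "JAK1", Direction.ACTIVATE, "pm3"),
    RelationTriple("JAK1", "STAT5", Direction.INHIBIT, "pm4"),  # wrong sign
    RelationTriple("GZMB", "PRF1", Direction.ACTIVATE, "pm5"),  # not in reference
]

aliases = AliasTable({"p53": "TP53"})
m = relation_confusion(predicted, reference, aliases)
prf = prf_from_confusion(m)
print(f"confusion cells A={m.a} B={m.b} C={m.c} D={m.d} (overlap E={m.overlap})")
print(f"precision={prf.precision:.3f} recall={prf.recall:.3f} f1={prf.f1:.3f}")
# A/D count sign agreement on pairs present in both sets; pairs absent from
# the reference (GZMB->PRF1) never enter the table.
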