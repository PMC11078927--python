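"""Union of curated edge lists, then expression-based contextualization.

A TF whose mean raw count in a condition falls below 10 cannot regulate
there: its outgoing edges are removed (incoming edges stay).

Run:  python examples/03_contextualize_network.py
"""

import pandas as pd

from mrgrn import CountMatrix, EdgeRecord, build_reference_network, contextualize, expression_status

trrust_like = [
    EdgeRecord("Lef1", "Ccnd1", "activation", frozenset({"trrust"})),
    EdgeRecord("Foxo3", "Bcl2l11", "activation", frozenset({"trrust"})),
]
dorothea_like = [
    EdgeRecord("Lef1", "Ccnd1", "activation", frozenset({"dorothea"}), "A"),
    EdgeRecord("Mybl2", "Ccnb1", "activation", frozenset({"dorothea"}), "B"),
    EdgeRecord("Mybl2", "Lef1", "repression", frozenset({"dorothea"}), "C"),
]
reference = build_reference_network([trrust_like, dorothea_like])
print(f"reference union: {reference.number_of_edges()} edges "
      f"(shared Lef1->Ccnd1 edge merged, sources combined)")

counts = pd.DataFrame(
    {
        "case_1": [120, 4, 80, 95, 60, 100],
        "case_2": [140, 6, 70, 105, 55, 90],
    },
    index=["Lef1", "Foxo3", "Mybl2", "Ccnd1", "Bcl2l11", "Ccnb1"],
)
meta = pd.DataFrame(
    {
        "sample_id": ["case_1", "case_2"],
        "tissue": ["colon"] * 2,
        "condition": ["case"] * 2,
        "batch": ["B1"] * 2,
    }
).set_index("sample_id")
cm = CountMatrix(counts, meta)

status = expression_status(cm, "case", tau=10)
ctx = contextualize(reference, status)
print(f"Foxo3 mean raw count = {status.mean_raw_count['Foxo3']:.0f} < 10 "
      "-> not expressed in this condition")
print("contextualized edges:")
for rec in sorted(ctx.edge_records(), key=lambda r: (r.regulator, r.target)):
    print(f"  {rec.regulator} -> {rec.target}  [{rec.mode}; {'+'.join(sorted(rec.sources))}]")
print("Foxo3's outgoing regulation is gone; everything else survives.")
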