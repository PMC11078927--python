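"""Hypergeometric overrepresentation of a DEG list against gene sets.

Run:  python examples/06_enrichment.py
"""

from mrgrn.enrich import overrepresentation_test, results_to_frame
from mrgrn.io import GeneSetCollection

universe = {f"gene{i:03d}" for i in range(100)}
ordered = sorted(universe)

sets = GeneSetCollection()
sets.add("BP:0001", "leukocyte migration", set(ordered[:15]))
sets.add("BP:0002", "response to cytokine", set(ordered[10:30]))
sets.add("BP:0003", "ribosome biogenesis", set(ordered[60:90]))

degs = set(ordered[:12])  # strongly overlaps the first term

results = overrepresentation_test(degs, sets, universe, min_size=5)
print(results_to_frame(results).round(6).to_string(index=False))
print(
    "\nk of n DEGs fall in a term of size K within the N-gene universe; "
    "p is the exact hypergeometric upper tail, padj its BH adjustment."
)
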