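"""Hypergeometric enrichment of called interactions in external evidence.

Recomputes the enrichment of a 37-interaction call set in pairwise
regulatory evidence over a 316-pair universe from published counts:
26 genetic-buffering pairs with 9 hits among the calls, and 77
any-evidence pairs with 18 hits.
"""

from episens import EvidenceTable, enrichment_test
from episens.interactions import CallRecord, InteractionCallSet

universe, n_calls = 316, 37
counts = {"buffering": (26, 9), "any": (77, 18)}

for category, (k_universe, k_calls) in counts.items():
    evidence_pairs = {frozenset({f"T{i:02d}", f"U{i:02d}"}): {"buffering"} for i in range(k_universe)}
    evidence = EvidenceTable(evidence_pairs, universe_size=universe)
    pairs = list(evidence_pairs)[:k_calls] + [
        frozenset({f"X{i:02d}", f"Y{i:02d}"}) for i in range(n_calls - k_calls)
    ]
    calls = InteractionCallSet(
        method="S",
        calls=[CallRecord(p, -0.3, 0.01, "cross-environment") for p in pairs],
        selection_rule="P < 0.05",
    )
    res = enrichment_test(calls, evidence, "buffering")
    print(
        f"{category:>9}: {res.hits_in_calls}/{res.n_calls} hits vs "
        f"{res.hits_in_universe}/{res.universe} in the universe -> "
        f"R = {res.fold_r:.1f}, P = {res.p_value:.4f}"
    )
print(
    "\nR is the ratio of hit frequencies (calls vs universe); P is the\n"
    "upper-tail hypergeometric probability of at least that many hits by\n"
    "chance. A 3-fold buffering enrichment at P ~ 0.001 says the called\n"
    "interactions are strongly over-represented in independent regulatory\n"
    "evidence."
)
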