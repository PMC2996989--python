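"""Detect directional phenotypic masking within declared complexes.

When X acts upstream of Y, the double mutant resembles the X single
(masking).  On the "complex" preset, two of three planted complexes give
the double an extra environment-independent growth defect: they still
mask in sensitivity space (the defect cancels from the rate ratio) but
not in fitness space.
"""

import numpy as np

from episens import analyze_library
from episens.masking import ComplexDefinition, detect_masking, recovery_curve
from episens.simulate import E1, E2, generate_library, scenario_spec

table, truth = generate_library(scenario_spec("complex", seed=3))
scores = analyze_library(table, e1=E1, e2=E2, n_trials=10_000, seed=3)

complexes = [
    ComplexDefinition("rad6_like", {"G01", "G02", "G03"}),
    ComplexDefinition("shu_like", {"G04", "G05", "G06", "G07"}),
    ComplexDefinition("hrr_like", {"G08", "G09", "G10"}),
]

records = detect_masking(complexes, scores, family="S", delta_thr=0.1, alpha=0.05)
n_mask = sum(r.is_masking for r in records)
print(f"sensitivity family: {n_mask}/{len(records)} directed within-complex pairs mask at delta < 0.1")

grid = np.linspace(0.0, 0.3, 7)
curve_s = recovery_curve(complexes, scores, "S", delta_grid=grid)
curve_f = recovery_curve(complexes, scores, "F", delta_grid=grid, phenotypes=table, environment=E2)
print("\n delta_thr   TPR(S)   TPR(F)")
for (_, rs), (_, rf) in zip(curve_s.iterrows(), curve_f.iterrows()):
    print(f"   {rs.delta_thr:5.2f}    {rs.tpr:5.2f}    {rf.tpr:5.2f}")
print(
    "\nThe sensitivity family recovers all planted maskings by delta 0.10;\n"
    "the fitness family tops out at the one purely co-equivalent complex\n"
    "(12 of 24 directions) because the extra double-mutant defect breaks\n"
    "fitness-space equivalence."
)
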