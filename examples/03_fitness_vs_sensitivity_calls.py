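"""The fitness-vs-sensitivity dichotomy on designed contrasts.

Two libraries: one where every pair interacts identically in both
environments ("static") and one where interactions appear only under the
perturbation ("modulated").  Fitness-based calls find both; the
sensitivity-based score responds only to the environment-modulated set.
"""

from episens import analyze_library, call_by_threshold, compare_call_sets
from episens.simulate import E1, E2, generate_library, scenario_spec

for preset in ("static", "modulated"):
    table, truth = generate_library(scenario_spec(preset, seed=2))
    scores = analyze_library(table, e1=E1, e2=E2, n_trials=10_000, seed=2)
    calls_f = call_by_threshold(scores, alpha=0.01, family="F", env_order=(E1, E2))
    calls_s = call_by_threshold(scores, alpha=0.01, family="S")
    overlap = compare_call_sets(calls_f, calls_s)
    n_pairs = truth.pair_truth["assayed"].sum()
    print(f"{preset}: {n_pairs} pairs, F calls {len(calls_f)}, S calls {len(calls_s)}, shared {len(overlap.shared)}")

print(
    "\n'static' interactions (equal epsilon in both environments) are caught\n"
    "by the F-score but are invisible to the S-score; 'modulated' ones\n"
    "(epsilon only under the perturbation) light up both, with the S-score\n"
    "specifically certifying that the interaction changes between\n"
    "environments."
)
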