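"""Cluster genes by their sensitivity-epistasis profiles.

On the "two_module" preset (alleviating interactions within two planted
modules, aggravating between them) average-linkage clustering on the
correlation distance between S-score profiles separates the modules at
the first split.
"""

from episens import analyze_library, build_profile_matrix, cluster_profiles
from episens.simulate import E1, E2, generate_library, scenario_spec

table, _ = generate_library(scenario_spec("two_module", seed=4))
scores = analyze_library(table, e1=E1, e2=E2, families=("S",), n_trials=1000, seed=4)

matrix = build_profile_matrix(scores, family="S")
dendro = cluster_profiles(matrix, n_bootstrap=100, seed=4)

cut = dendro.cut(2)
for cluster_id in sorted(set(cut.values())):
    members = sorted(g for g, c in cut.items() if c == cluster_id)
    print(f"cluster {cluster_id}: {', '.join(members)}")
print("\nnewick:", dendro.to_newick())
print(
    "\nThe 2-cut recovers the planted modules (G01-G05 vs G06-G10) exactly;\n"
    "node labels in the newick string are plain bootstrap support values\n"
    "from resampling profile columns."
)
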