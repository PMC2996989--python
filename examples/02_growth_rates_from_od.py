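"""Estimate growth rates from OD600 time courses.

Builds noisy exponential OD courses for a wildtype and one mutant,
fits log-linear growth rates inside the exponential window (OD 0.1-0.4,
minutes 60-360), and summarises replicates.
"""

from episens import PhenotypeTable, StrainKey, fit_growth_rate
from episens.growth import fit_od_table
from episens.simulate import E1, generate_od_curves

truth = PhenotypeTable.from_records(
    [
        (StrainKey.wildtype(), E1, 0.0077, 0.0, 8),
        (StrainKey.single("RPN4"), E1, 0.0060, 0.0, 8),
    ]
)
curves = generate_od_curves(truth, od0=0.05, od_noise_cv=0.02, seed=4)
print(f"{len(curves)} replicate OD courses, {curves[0].times.size} readings each")

one = fit_growth_rate(curves[0])
print(f"first wildtype replicate: rate {one.rate:.5f}/min over {one.n_points} points, R^2 {one.r_squared:.4f}")

table, rejected = fit_od_table(curves)
for strain in (StrainKey.wildtype(), StrainKey.single("RPN4")):
    p = table.get(strain, E1)
    print(f"{strain.label():>5}: mean rate {p.mean_rate:.5f}/min (cv {p.cv:.3f}, n={p.n})")
print(
    "\nThe fitted rates recover the generating rates (0.0077 and 0.0060/min)\n"
    "to within the OD noise; replicate cv reflects the 2% multiplicative\n"
    "noise placed on the OD readings."
)
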