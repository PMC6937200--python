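"""Feeding-strategy diagram coordinates (prey-specific abundance vs FO).

A prey group in the upper right (high FO, high Pi) dominates the diet of a
specialised population; upper left means a subset of individuals specialise
on it; the lower band is rare or generalist prey.
"""

import dietstat as ds

dataset = ds.generate(ds.GeneratorConfig(seed=11, years=(2011, 2012), n_stations=2))
matrix = ds.build_diet_matrix(dataset.stomachs, dataset.stations)

for p in sorted(ds.amundsen_plot(matrix), key=lambda p: -p.fo):
    print(f"{p.prey_group:18s} FO {p.fo:5.1f}%  Pi {p.pi:5.1f}%  -> {p.quadrant}")
print("\nPi is the weight share of the group within the stomachs containing it.")
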