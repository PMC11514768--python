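"""Quantify how much shape variation size explains (Procrustes ANOVA).

The generator plants an allometric component worth 12% of the within-species
shape variance; the permutational regression of shape on log centroid size
recovers it, and the fitted shapes at the size extremes drive the deformation
colour-map workflow.
"""

import numpy as np

from patellamorph import gpa, procrustes_anova, allometric_shapes, displacement_field
from patellamorph.landmark_io import read_newick
from patellamorph.synthetic import SyntheticDesign, simulate_sample

design = SyntheticDesign(tree=read_newick("(OneSpecies:1);"), n_per_species=60,
                         bm_rate=0.0, allometry_fraction=0.12,
                         noise_sd=1e-3, size_log_sd=0.1,
                         asymmetry_by_clade={}, seed=4)
sample, _ = simulate_sample(design)
aligned = gpa(sample)

table = procrustes_anova(aligned, np.log(aligned.centroid_sizes),
                         n_permutations=1000, seed=4, term="log CS")
row = table.rows[0]
print(table.to_frame().to_string(index=False))
print(f"\nsize explains R2={row.r2:.2f} of shape variance "
      f"(planted 0.12), F={row.f:.2f}, Z={row.z:.2f}, p={row.p:.4f}")

small, large = allometric_shapes(table)
dist, norm = displacement_field(small, large)
print(f"fitted small->large shapes: max landmark displacement {dist.max():.4f} "
      f"(landmark {int(np.argmax(dist))}); colour-map values in [0,1]")
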