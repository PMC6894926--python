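"""Surface searchlight RSA over a planted representational region.

Plants a known mixture of two model geometries into one region of a toy
cortical mesh (squared-Euclidean distances add over disjoint feature
blocks, so the region's RDM is exactly the weighted mixture), then runs
both the standard (single-model correlation) and the multiple-regression
searchlight analyses.
"""

import numpy as np

from actionrsa import make_ground_truth, make_toy_surface
from actionrsa.models import ModelSet
from actionrsa.patterns import plant_brain_patterns
from actionrsa.searchlight import (Searchlight, build_searchlights,
                                   regression_rsa_map, standard_rsa_map)

models = ModelSet({
    "semantic": make_ground_truth(seed=1).true_rdm.copy(model="semantic"),
    "body": make_ground_truth(seed=2).true_rdm.copy(model="body"),
})
mesh = make_toy_surface(subdivisions=3, n_regions=1, region_size=80, seed=0)
print(f"toy cortex: {mesh.n_vertices} vertices, planted region of "
      f"{len(mesh.region_vertices(1))} vertices")

ds = plant_brain_patterns(mesh, models, {1: {"semantic": 2.0, "body": 3.0}},
                          n_subjects=1, n_runs=4, noise_sd=0.0, seed=0)[0]

region = mesh.region_vertices(1)
roi = Searchlight(int(region[0]), tuple(int(v) for v in region))
betas = regression_rsa_map(ds, models, [roi], mode="raw")
print(f"\nplanted weights (semantic, body) = (2, 3); recovered = "
      f"({betas['semantic'].values[roi.center]:.6f}, "
      f"{betas['body'].values[roi.center]:.6f})")
print("At zero noise the regression RSA recovers the planted mixture "
      "exactly — the additivity oracle for the whole stack.")

searchlights = build_searchlights(mesh, n_features=10)
corr_map = standard_rsa_map(ds, models["semantic"], searchlights)
in_region = np.nanmean(corr_map.values[region])
background = np.delete(corr_map.values, region)
print(f"\nstandard RSA map (semantic model): mean r inside region "
      f"{in_region:.2f}; {np.isnan(background).sum()} of "
      f"{background.size} background vertices undefined (no signal, "
      "flagged NaN at zero noise)")
print("Correlations are defined only where a searchlight touches the "
      "planted geometry; the ring just outside the region sees part of "
      "it, which is why group inference quantifies overlap by Dice.")
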