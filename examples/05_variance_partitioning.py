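"""Partition compositional variation among climate, soils and space.

Simulates a metacommunity with both environmental filtering and dispersal
limitation, then splits the adjusted R^2 of compositional variation
(PCoA axes of taxonomic turnover) into fractions unique to climate, soil
and spatial eigenfunctions, their overlaps, and the residual.
"""
import numpy as np

from betascape import betadiv, ordination, varpart
from betascape.pcnm import pcnm_basis
from betascape.simulate import SimulationParams, generate_dataset

params = SimulationParams(n_plots=35, n_species=150, target_richness=30,
                          filter_strength=1.5, dispersal_scale=60.0)
sd = generate_dataset(params, seed=9)
ds = sd.dataset

dm = betadiv.dissimilarity_matrix(ds.community, "sorensen_turnover")
resp, _ = ordination.pcoa_axes(dm)
env = ds.environment
climate = ordination.pca(env.variables[env.columns_of("climate")]).scores[:, :2]
soil = ordination.pca(env.variables[env.columns_of("soil")]).scores[:, :2]
space = pcnm_basis(ds.coordinates).eigenvectors[:, :6]

vp = varpart.partition_variation(resp[:, :2],
                                 {"climate": climate, "soil": soil,
                                  "space": space},
                                 n_perm=499, rng=3)
print(vp.to_frame().to_string(index=False, float_format=lambda v: f"{v:.3f}"))
print(f"\ntotal explained (adj R2): {vp.total_explained:.3f}; "
      f"residual: {vp.residual:.3f}")
print("Unique 'space' beyond environment indicates dispersal limitation; "
      "environment-space overlap is spatially structured filtering.")
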