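"""beta NRI / beta NTI with the tip-shuffling null.

Builds a filtered metacommunity (species sorted along a conserved climate
niche), computes standardized effect sizes of between-community mean
pairwise (beta NRI, deep nodes) and nearest-taxon (beta NTI, tips)
distances, and prints how many plot pairs fall outside the 95% null
envelope.  Positive SES = phylogenetic evenness, negative = clustering.
"""
import numpy as np

from betascape.nulls import beta_nri, beta_nti
from betascape.simulate import SimulationParams, generate_dataset

params = SimulationParams(n_plots=15, n_species=120, target_richness=25,
                          filter_strength=2.0, dispersal_scale=np.inf)
sd = generate_dataset(params, seed=21)
ds = sd.dataset

for name, fn in (("beta NRI", beta_nri), ("beta NTI", beta_nti)):
    mat = fn(ds.community, ds.phylogeny, n_iter=199, rng=0)
    ses = mat.condensed()
    ses = ses[np.isfinite(ses)]
    outside = np.mean(np.abs(ses) > 1.96)
    print(f"{name}: mean SES {ses.mean():+.2f}, "
          f"{100 * outside:.0f}% of pairs outside the 95% envelope")
print("\nUnder neutral assembly ~5% of pairs would sit outside the "
      "envelope; filtering on a conserved niche pushes pairs out of it.")
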