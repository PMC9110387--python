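"""Density-weighted geodesic distance and build direction.

Solves the eikonal equation from the substrate of a comb phantom with
the density field as the speed metric, then averages unit gradients
over the comb to infer the build direction. The phantom grows along
(0, 1, 0), which the mean gradient recovers; the dispersion is low
because growth is strongly directional.
"""

import numpy as np

from combscan import geodesics as geo, synthetic_comb as syn

spec = syn.CombPhantomSpec(rows=3, cols=4, spacing_mm=0.3, rng_seed=11)
vol, truth = syn.generate(spec)

field = geo.solve_eikonal(vol, truth.substrate_mask, metric=vol.values, iso_threshold=0.2)
finite = np.isfinite(field.u) & field.domain_mask & ~field.source_mask
print(f"travel cost over {finite.sum()} voxels, max u = {field.u[finite].max():.1f} "
      f"(density-weighted mm), {field.n_unreached} unreached")

report = geo.build_direction(field, truth.segment_labels == 1)
print(f"build direction {np.round(report.mean_gradient, 3)} "
      f"(planted growth axis {np.round(truth.growth_axes[0], 3)})")
print(f"dispersion {report.dispersion:.3f} (0 = perfectly aligned growth)")
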