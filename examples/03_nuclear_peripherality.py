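"""Nuclear radial distribution as a proxy for notochord pressure.

In a pressurised (wild-type-like) notochord the vacuole pushes the
nucleus against the outer cell boundary, so the radial fraction ρ
(distance from the axis / local notochord radius) clusters near 1.
When vacuoles fragment, nuclei sit near the cell centroids instead.
The peripherality test compares ρ against uniform placement over the
cross-sectional disk (null CDF x², E[ρ] = 2/3).
"""

import numpy as np

from notomorph import build_notochord_volume, peripherality_test, radial_positions
from notomorph.config import mutant_config, wildtype_config

for name, cfg in (("wild type", wildtype_config(seed=0)),
                  ("mutant-like", mutant_config(seed=0))):
    sample = build_notochord_volume(cfg)
    records = radial_positions(
        sample.nucleus_labels, sample.notochord_mask, measure_shape=False
    )
    rhos = [r.radial_fraction for r in records]
    d_stat, p = peripherality_test(rhos, n_null=9999, seed=1)
    print(f"{name:12s}: mean ρ = {np.mean(rhos):.3f}, "
          f"D = {d_stat:.3f}, p = {p:.4g}  (n = {len(rhos)})")

# Both phenotypes deviate from uniform (the mutant clusters centrally),
# but only the wild type shows the peripheral clustering (mean ρ ≈ 0.9).
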