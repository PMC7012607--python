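"""Per-centrum circle-fit deformation index on sagittal profiles.

Under each vertebral centrum, circles are fitted to the dorsal and the
ventral indentation of the notochord; D = -min(r)/max(r) is -1 for
symmetric compression and approaches 0 as one side flattens.  The
signed asymmetry A = (r_v - r_d)/(r_v + r_d) flips sign where the
deformation changes orientation.
"""

import math

from notomorph import build_spine_profile, deformation_index
from notomorph.config import CentrumSpec, wildtype_config

cfg = wildtype_config()
cfg.notochord_length = 700.0
cfg.centra = [
    CentrumSpec(50.0, 170.0, dorsal_radius=50.0, ventral_radius=50.0),
    CentrumSpec(220.0, 340.0, dorsal_radius=50.0, ventral_radius=100.0),
    CentrumSpec(390.0, 510.0, dorsal_radius=50.0, ventral_radius=math.inf),
]
profile = build_spine_profile(cfg)

print("centrum  r_dorsal  r_ventral      D        A")
for i in range(len(cfg.centra)):
    d = deformation_index(profile, i)
    print(f"{i:^7d}  {d.r_dorsal:8.1f}  {d.r_ventral:9.1f}  "
          f"{d.deformation_index:7.3f}  {d.signed_asymmetry:7.3f}")

# Row 0: symmetric compression, D = -1.  Row 1: the ventral side is
# compressed half as tightly, D = -0.5.  Row 2: flat ventral side, the
# sentinel D = 0 with |A| = 1.
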