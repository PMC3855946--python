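"""Score tube-likeness with the multiscale Hessian filter.

On a noise-free cylinder the response peaks on the axis at the matched
scale; on the abdominal phantom the near-isointense vessels (5 HU darker
than liver) still separate cleanly from parenchyma.
"""

import numpy as np

import ctus
from ctus.vessel_enhance import VesselnessParams, multiscale_enhance

# --- ideal tube: radius 4 mm, probed at half / matched / double scale -----
tube = ctus.make_cylinder_volume(dims=(64, 64, 64), radius=4.0, axis="z",
                                 inside_val=100.0, outside_val=0.0)
params = VesselnessParams(scales=(2.0, 4.0, 8.0), c=20.0)
nu, argmax_scale = multiscale_enhance(tube, params, return_scales=True)
print(f"cylinder axis vesselness: {nu[31, 31, 31]:.3f} "
      f"(winning scale {argmax_scale[31, 31, 31]:.0f} mm = tube radius)")

# --- clinical-contrast situation: vessels at 55 HU inside liver at 60 HU --
volume, masks = ctus.make_abdominal_phantom(seed=0)
p = VesselnessParams(scales=(2.0, 3.0, 4.0), c=1.0, polarity="dark")
nu = multiscale_enhance(volume, p)
v = nu[masks["vessel"]].mean()
l = nu[masks["liver"]].mean()
print(f"abdominal phantom: mean vesselness {v:.3f} in vessel lumina vs "
      f"{l:.3f} in liver parenchyma ({v / l:.0f}x separation despite "
      f"5 HU contrast under 8 HU noise)")
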