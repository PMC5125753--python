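"""Sizing RNA particles in a synthetic super-resolution image.

Generates a field of ~112 nm Lorentzian spots at 14.6 nm pixels, detects
intensity maxima with a prominence tolerance, fits per-axis Lorentzians
and reports the particle-size distribution of the accepted spots.
"""

import numpy as np

import mrnatrack as mt
from mrnatrack import profiler as prof

params = mt.ImageSimParams(shape=(512, 512), n_spots=80,
                           fwhm_mean=112.0, fwhm_sd=10.0, seed=3)
image, truth = mt.simulate_sted_image(params)

spots = prof.profile_image(image, tolerance=10.0)
accepted = [s for s in spots if s.accepted]
sizes = np.array([s.diameter for s in accepted])

print(f"maxima detected:   {len(spots)}")
print(f"accepted spots:    {len(accepted)} "
      f"(rejections: { {s.rejection_reason for s in spots if not s.accepted} or 'none'})")
print(f"mean size:         {sizes.mean():.1f} ± "
      f"{sizes.std(ddof=1) / np.sqrt(len(sizes)):.1f} nm (mean ± SEM)")
print(f"generator truth:   {truth.fwhm_nm.mean():.1f} nm")

centres = [(s.x0, s.y0) for s in accepted]
nn = prof.nearest_neighbour_stats(centres, image.pixel_size)
print(f"mean nearest-neighbour distance: {nn:.0f} nm")
print()
print("Sizes are the mean of the X- and Y-axis Lorentzian FWHMs; spots with")
print("poor fits (r² < 0.8), elongated shapes (axis ratio > 2), edge contact")
print("or a neighbour inside the profile diameter are excluded.")
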