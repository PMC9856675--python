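"""Turn ERPs into 3-plane bandpower scalp images.

Welch band powers (alpha 9-13, beta 14-30, gamma 31-60 Hz) per electrode
are projected to the plane (azimuthal equidistant), interpolated over the
scalp disk and stacked as RGB planes (R = alpha, G = beta, B = gamma).
"""

import numpy as np

import rtspect as r

montage = r.default_montage()
ts = r.generate_trials(1, 60, seed=3)

erp = ts.data[ts.true_category == "fast"][0]  # one fast trial
bp = r.compute_bandpowers(erp, ts.sfreq)
bp.channel_names = montage.channel_names

ft7 = montage.index("FT7")
oz = montage.index("OZ")
print("band powers (uV^2) at FT7 vs OZ for a fast trial:")
for j, band in enumerate(("alpha", "beta", "gamma")):
    print(f"  {band:5s}: FT7 = {bp.values[ft7, j]:7.2f}, "
          f"OZ = {bp.values[oz, j]:7.2f}")
# Fast trials carry the planted left-frontal alpha spot; posterior alpha
# is the category-independent anchor.

coords = r.project_montage(montage)
img = r.render_topomap(bp, coords, grid=(32, 32))
row, col = img.electrode_pixels[ft7]
print(f"image: {img.pixels.shape}, FT7 pixel ({row}, {col}), "
      f"red plane value {img.pixels[row, col, 0]:.2f} "
      f"(1.0 = per-image alpha maximum)")

# Optional PNG export for visual inspection:
#   import matplotlib.pyplot as plt
#   plt.imsave("topomap.png", img.pixels)
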