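"""50%-isocontour PET VOI and SUV statistics.

Places a synthetic uptake blob in a PET volume, grows the 3D VOI from the
hottest voxel inside a circular seed region at the 50% isocontour and
reports SUVmax / SUVmean — the standard uptake summary for a lesion.
"""

import numpy as np

from radgen import MapVolume, isocontour_voi

x, y, z = np.meshgrid(np.arange(24), np.arange(24), np.arange(12),
                      indexing="ij")
pet = 12.0 * np.exp(-(((x - 12) ** 2 + (y - 10) ** 2) / 10.0
                      + (z - 6) ** 2 / 5.0))
pet += 0.1  # low diffuse background
vol = MapVolume(pet, spacing=(2.0, 2.0, 3.0), kind="PET")

mask, stats = isocontour_voi(vol, seed_center=(12, 10), seed_slice=6,
                             seed_radius=4.0)
print(f"SUVmax  = {stats.suv_max:.2f}")
print(f"SUVmean = {stats.suv_mean:.2f}")
print(f"VOI size = {stats.n_voxels} voxels "
      f"({stats.n_voxels * vol.voxel_volume / 1000:.2f} mL)")
# the VOI is the 26-connected set of voxels >= 50% of the peak that touches
# the peak; SUVmean averages uptake over exactly that volume.
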