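"""OS-EM reconstruction of a uniform cylinder with calibration and SNR.

Simulates a noisy acquisition of a uniformly filled cylinder
(2 MBq/mL), reconstructs it with attenuation-compensated OS-EM
(6 iterations x 6 subsets at this 60-view desk scale), derives the image
calibration factor from the known total activity and reports the
signal-to-noise ratio (VOI mean / voxel SD) in a central cubic VOI.
"""

import numpy as np

from spectsynth import (AcquisitionConfig, ActivityMask, VOISpec,
                        add_poisson_noise, calibrate, cylinder_support,
                        elliptical_orbit, forward_project, get_preset,
                        osem_reconstruct, scale_to_counts, snr,
                        to_concentration)

grid = get_preset("desk")
acq = AcquisitionConfig(n_projections=60, matrix=32)
orbit = elliptical_orbit(60, 8.0, 12.0)
support = cylinder_support(grid)
conc = 2.0  # MBq/mL

phantom = ActivityMask((support * 100).astype(np.int16), grid.voxel_size_mm,
                       "inverted", conc, dataset_id="uniform")
counts = scale_to_counts(forward_project(phantom, orbit, acq, grid), conc,
                         acq, grid)
noisy = add_poisson_noise(counts, "A", seed=11)
recon = osem_reconstruct(noisy, acq, grid, iterations=6, subsets=6)

total_activity = conc * support.sum() * grid.voxel_volume_ml
factor = calibrate(recon, total_activity, acq.time_per_view_s)
conc_map = to_concentration(recon, factor, acq.time_per_view_s)

c = grid.center
voi = VOISpec("cube", (c, c, c), 0.5 * grid.cylinder_diameter_mm)
voi_mask = voi.mask(conc_map.shape, grid.voxel_size_mm)
print(f"total activity: {total_activity:.1f} MBq, "
      f"total counts: {noisy.images.sum():.0f}")
print(f"calibration factor: {factor:.2f} cps/MBq")
print(f"VOI mean concentration: {conc_map[voi_mask].mean():.2f} MBq/mL "
      f"(true {conc:.2f})")
print(f"SNR in VOI: {snr(recon, voi):.1f}")
# The calibration factor recovers the simulated system sensitivity
# (10 cps/MBq) and the VOI concentration the filled value, within the
# reconstruction accuracy at this scale.
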