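"""Train a small u-net to rotate projections by half the angular step.

Twelve simulated datasets are split 10/2 train/val; the network sees 30
noisy projections (every 12 degrees, cyclically padded to 32) and learns
the projections 6 degrees further round.  Prints the loss history and
where the best validation epoch landed.  At this miniature scale the
network only reaches a rough interpolation; the test suite runs the
full desk-scale training.
"""

import numpy as np

from spectsynth import (AcquisitionConfig, UNetConfig, add_poisson_noise,
                        build_activity_mask, build_manifest, cylinder_support,
                        cyclic_expand, elliptical_orbit, forward_project,
                        get_preset, normalize_stack, scale_composition,
                        scale_to_counts, step_schedule, train)

grid = get_preset("desk")
acq = AcquisitionConfig(n_projections=60, matrix=32)
orbit = elliptical_orbit(60, 8.0, 12.0)
support = cylinder_support(grid)

manifest = build_manifest(scale_composition(12), seed=3,
                          split_fractions=(10 / 12, 2 / 12, 0.0))
inputs, targets = [], []
for i, row in enumerate(manifest.itertuples()):
    mask = build_activity_mask(row, grid, support)
    nf = scale_to_counts(forward_project(mask, orbit, acq, grid),
                         mask.max_activity_conc_mbq_ml, acq, grid)
    noisy = add_poisson_noise(nf, "A", seed=i).images
    inp = cyclic_expand(noisy[0::2], 32)     # 0, 12, ..., 348 deg
    tgt = cyclic_expand(noisy[1::2], 32)     # 6, 18, ..., 354 deg
    inp, factor = normalize_stack(inp)
    inputs.append(inp)
    targets.append(tgt / factor)
inputs, targets = np.stack(inputs), np.stack(targets)

cfg = UNetConfig(label="demo", n_input=30, n_output=30, cyclic_target=32,
                 rotation_shift_deg=6.0, n_train=10, n_val=2, epochs=5,
                 lr_schedule=step_schedule(2.8e-3, 5))
model = train(cfg, inputs[:10], targets[:10], inputs[10:], targets[10:],
              seed=0, verbose=True)
print(f"best validation L1 loss {model.best_val_loss:.5f} "
      f"at epoch {model.best_epoch}")
# The loss is the mean absolute error on [0,1]-normalized projections;
# it should fall several-fold within these few epochs.
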