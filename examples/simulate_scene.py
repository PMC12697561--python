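"""Generate a synthetic epithelium scene and inspect its ground truth.

Builds a 12-nucleus columnar-epithelium scene (32-um-deep cells, nuclei
starting near a common apical plane), simulates 5 minutes of mixed
active/diffusive/confined motion, renders the noisy volume, and prints
where the population ends up.  Depths are um below the apical surface.
"""

import numpy as np

from nucdyn import SceneConfig, generate_trajectories, render_volume

config = SceneConfig(n_nuclei=12, n_frames=20, rng_seed=8)
truth = generate_trajectories(config)
volume, labels = render_volume(truth, config)

print(f"scene: {config.n_nuclei} nuclei, {config.n_frames} frames "
      f"every {config.frame_interval:.0f} s, grid {config.grid_shape} voxels "
      f"at {config.voxel_size} um")
print(f"volume intensity range: {volume.data.min():.1f}..{volume.data.max():.1f} "
      "(signal 100 over noisy background)")

depth0 = truth.positions[:, 0, 0]
depth_end = truth.positions[:, -1, 0]
for cls in ("active", "diffusive", "confined"):
    idx = [i for i, c in enumerate(truth.motion_class) if c == cls]
    moved = depth_end[idx] - depth0[idx]
    print(f"{cls:>10}: n={len(idx)}, mean basal displacement over "
          f"{(config.n_frames - 1) * config.frame_interval / 60:.0f} min = "
          f"{np.mean(moved):+.2f} um")
# Active nuclei drive basally (~0.4-0.5 um/min); diffusive ones wander with
# near-zero mean displacement; confined ones stay within ~0.5 um of the start.
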