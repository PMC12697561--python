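import dataclasses

import numpy as np
import pytest

from nucdyn import SceneConfig, generate_trajectories, render_volume


def single_class_config(kind: str, **kw) -> SceneConfig:
    mix = {k: (1.0 if k == kind else 0.0) for k in ("active", "diffusive", "confined")}
    base = dict(
        n_nuclei=1,
        n_frames=60,
        frame_interval=15.0,
        gaussian_sd=0.0,
        motion_mix=mix,
        run_speed=0.5,
        pause_duration_s=0.0,
        diffusion_coeff=0.1,
    )
    base.update(kw)
    return SceneConfig(**base)


def class_trajectories(kind: str, n: int, seed: int, noise_sd: float = 0.05,
                       **kw) -> list[np.ndarray]:
    """n depth trajectories of one motion class with localization noise."""
    rng = np.random.default_rng(seed)
    out = []
    base = single_class_config(kind, **kw)
    for _ in range(n):
        sc = dataclasses.replace(base, rng_seed=int(rng.integers(2**31)))
        z = generate_trajectories(sc).positions[0, :, 0]
        if noise_sd > 0:
            z = z + rng.normal(0.0, noise_sd, size=z.shape)
        out.append(z)
    return out


@pytest.fixture(scope="session")
def dense_scene():
    """40-nucleus SNR-5 scene at 1-um z spacing, with isotropic truth labels.

    The truth labels are rendered directly on the isotropic grid from the
    same trajectories (position generation is voxel-independent), so
    segmentation output can be compared voxel-for-voxel.
    """
    kw = dict(
        n_nuclei=40, n_frames=2, gaussian_sd=20.0, intensity=100.0,
        initial_apical_depth=6.0, depth_spread=14.0, rng_seed=3,
    )
    sc = SceneConfig(grid_shape=(32, 112, 168), voxel_size=(1.0, 0.4, 0.4), **kw)
    truth = generate_trajectories(sc)
    vol, labels_aniso = render_volume(truth, sc)
    sc_iso = SceneConfig(grid_shape=(80, 112, 168), voxel_size=(0.4, 0.4, 0.4), **kw)
    truth_iso = generate_trajectories(sc_iso)
    assert np.allclose(truth.positions, truth_iso.positions)
    _, labels_iso = render_volume(truth_iso, sc_iso)
    return {"config": sc, "truth": truth, "volume": vol,
            "labels_truth_aniso": labels_aniso, "labels_truth_iso": labels_iso}


@pytest.fixture(scope="session")
def tracking_scene():
    """20-frame mixed-motion scene with per-frame displacement <= 1/3 radius."""
    kw = dict(
        n_nuclei=9, n_frames=20, gaussian_sd=15.0,
        initial_apical_depth=6.0, depth_spread=10.0, rng_seed=5,
        motion_mix={"active": 0.5, "diffusive": 0.5, "confined": 0.0},
        run_speed=2.0, pause_duration_s=0.0, diffusion_coeff=0.2,
    )
    sc = SceneConfig(grid_shape=(32, 96, 96), voxel_size=(1.0, 0.4, 0.4), **kw)
    truth = generate_trajectories(sc)
    vol, _ = render_volume(truth, sc)
    sc_iso = SceneConfig(grid_shape=(80, 96, 96), voxel_size=(0.4, 0.4, 0.4), **kw)
    _, labels_iso = render_volume(generate_trajectories(sc_iso), sc_iso)
    return {"config": sc, "truth": truth, "volume": vol, "labels_truth_iso": labels_iso}
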