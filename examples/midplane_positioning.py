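"""Apical-basal nuclear positioning: midplanes and depth categories.

Tracks each nucleus's midplane (midpoint between the half-max flanks of
its cross-sectional-area profile) through a dispersal scene and reports
the fraction of the population in the apical exclusion zone (top 2 um),
the apical 10 um, and deeper basal cytoplasm at the first and last frame.
"""

from nucdyn import (SceneConfig, category_fractions, generate_trajectories,
                    midplane_table, render_volume, segment_series)

scene = SceneConfig(n_nuclei=12, n_frames=20, rng_seed=8,
                    initial_apical_depth=5.0, run_speed=1.2)
volume, _ = render_volume(generate_trajectories(scene), scene)
labels, _, _ = segment_series(volume)

table = midplane_table(labels, apical_reference=0.0)
print(table.head(6).to_string(index=False))

for frame in (0, labels.n_frames - 1):
    grp = table[(table["frame"] == frame) & table["valid"]]
    f = category_fractions(grp["midplane_depth_um"].to_numpy())
    t_min = frame * scene.frame_interval / 60
    print(f"t = {t_min:4.1f} min: exclusion-zone {f['exclusion_zone']:.2f}, "
          f"apical-10-um {f['apical10']:.2f}, basal {f['basal']:.2f} "
          f"(n = {f['n']})")
# As active nuclei disperse basally the apical-10-um fraction falls and the
# basal fraction rises; the two always sum to 1, and the exclusion-zone
# fraction (a subset of apical10) stays near 0 when apical positioning is
# intact.
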