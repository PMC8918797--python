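"""Zone-sorted comparison of site intensities.

Sites are split by an axis-aligned boundary plane into an active and a
repressed zone (modelling the sharp edge of a stripe expression pattern);
the planted active/repressed mean intensity ratio is 1.5.  Groups are
summarised as mean / +-1 s.d. / +-2 s.d. and compared with a two-tailed
pooled-variance Student's t-test; following the usual figure convention,
only pairs with P < 0.05 are listed as significant (the full table is
always computed).
"""

import numpy as np

import nucquant as nq

stack, truth = nq.generate_scene(nq.SceneParams(
    field_shape=(5, 640, 640), voxel_size=(300.0, 85.0, 85.0),
    n_nuclei=40, nucleus_radius=2000.0, spot_fraction=1.0,
    zone_effect=1.5, photon_scale=200.0, seed=4))

labels = nq.segment_nuclei(stack, "nuclei", min_volume=1.0)
sites = nq.detect_sites(stack, "spots", labels, log_sigma=120.0)
boundary = nq.SurfacePlane(axis=1, position=640 * 85.0 / 2.0, inward=1)
nq.classify_sites(sites, boundary)

by_zone = {}
for s in sites:
    by_zone.setdefault(s.zone, []).append(s.peak_intensity)
summaries, significant, comparisons = nq.compare_zones(
    {k: np.asarray(v) for k, v in by_zone.items()})

for s in summaries:
    print(f"{s.label:>10}: n={s.n:<3} mean={s.mean:.2f}  +-1sd=({s.sd_bounds[0]:.2f}, "
          f"{s.sd_bounds[1]:.2f})  +-2sd=({s.sd2_bounds[0]:.2f}, {s.sd2_bounds[1]:.2f})")
for c in comparisons:
    flag = "significant" if c.significant else "not significant"
    print(f"{c.group_a} vs {c.group_b}: t={c.t_statistic:.2f}, df={c.df}, "
          f"p={c.p_value:.2e} ({flag})")
print("planted ratio 1.5: the active-zone mean should exceed the repressed-zone "
      "mean by ~50% and the pair should be significant.")
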