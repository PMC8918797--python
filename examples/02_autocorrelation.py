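"""Radially averaged spatial autocorrelation of the mark channel.

Compares a spatially uniform mark (early-embryo-like) against a textured
mark with a 300 nm correlation kernel (late-embryo-like).  The ACF value at
a shift distance r reports how prevalent structures of size ~r are: the
textured nucleus keeps high correlation out to several hundred nm, the
uniform one decays to the noise floor immediately.
"""

import nucquant as nq


def curve_for(mode: str) -> nq.AcfCurve:
    stack, _ = nq.generate_scene(nq.SceneParams(
        field_shape=(7, 700, 700), voxel_size=(300.0, 85.0, 85.0),
        n_nuclei=20, nucleus_radius=2500.0, mark_mode=mode,
        grf_kernel_sigma=300.0, psf_sigma=(250.0, 80.0, 80.0),
        photon_scale=200.0, seed=21))
    labels = nq.segment_nuclei(stack, "nuclei", min_volume=2.0)
    return nq.acf_curve_for_stack(stack, "mark", labels, max_radius=900.0)


uniform = curve_for("uniform")
textured = curve_for("grf")

print(f"{'shift r (nm)':>12} {'uniform':>9} {'textured':>9}")
for r in (100, 200, 400, 600):
    print(f"{r:>12} {uniform.value_at(r):>9.3f} {textured.value_at(r):>9.3f}")
print(f"(averaged over {uniform.n_regions} and {textured.n_regions} nuclei)")

ell = nq.fit_correlation_length(textured)
print(f"fitted correlation length of the textured mark: {ell:.0f} nm "
      "(planted kernel: 300 nm; the small residual gap comes from PSF blur and "
      "per-nucleus masking)")
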