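# nucquant

Quantification of how heterogeneous the inside of a nucleus looks in
multi-channel fluorescence microscopy, and of the local chromatin environment
around individual transcription sites.

During embryo development, transcription factors and histone modifications go
from roughly uniform nuclear distributions to strongly partitioned ones, and
the chromatin environment around an active gene locus depends on when and
where the cell sits in the expression pattern. `nucquant` implements the
image-quantification side of that kind of study as a tested, reusable
pipeline:

- **Radially averaged spatial autocorrelation (ACF)** of an intensity channel
  inside nuclear masks — the heterogeneity statistic. For an image *I* with
  nucleus mask *m*, mask mean μ and variance σ²,

  C(Δ) = Σₓ δI(x)·δI(x+Δ)·m(x)·m(x+Δ) / (N(Δ)·σ²),  δI = I − μ,

  where N(Δ) counts voxel pairs with both ends in the mask. C(0) = 1, the
  curve is invariant under affine intensity transforms, and C(Δ) radially
  averaged over |Δ| gives correlation vs physical shift distance in nm. The
  FFT implementation is exact (tested against a direct double sum).
- **Transcription-site detection** (Laplacian-of-Gaussian, at most one site
  per nucleus) and **radial intensity profiles** of a mark channel in
  concentric annuli around each site, each profile normalised so that its
  maximum over the entire radial distribution is 1.
- **Zone-sorted group statistics**: sites split into *active*/*repressed*
  zones by a boundary plane; groups summarised as mean ± 1 s.d. / ± 2 s.d.
  and compared with a two-tailed pooled-variance Student's t-test (only
  pairs with P < 0.05 are reported as significant; the full table is kept).
- **Nucleus segmentation** (Otsu + distance-transform watershed) with a
  depth filter that keeps only nuclei within a maximum depth (e.g. 20 µm) of
  a reference surface, preserving optical resolution.
- A **synthetic-scene generator** that renders embryo-like stacks with known
  ground truth — nuclei, a mark channel that is uniform or textured with a
  controllable correlation length ℓ (Gaussian random field, whose ACF is
  exp(−r²/(4ℓ²))), sparse reporter spots with planted mark enrichment or
  depletion, zone-dependent site intensities, Gaussian PSF and
  Poisson+Gaussian noise — so every statistic above can be validated against
  a known answer.

## Worked example

```python
import nucquant as nq

stack, truth = nq.generate_scene(nq.SceneParams(
    field_shape=(7, 700, 700), voxel_size=(300.0, 85.0, 85.0),
    n_nuclei=20, nucleus_radius=2500.0, mark_mode="grf",
    grf_kernel_sigma=300.0, psf_sigma=(250.0, 80.0, 80.0),
    photon_scale=200.0, seed=21))
labels = nq.segment_nuclei(stack, "nuclei", min_volume=2.0)
curve = nq.acf_curve_for_stack(stack, "mark", labels, max_radius=900.0)
print(round(curve.value_at(200.0), 3), nq.fit_correlation_length(curve))
```

Running `examples/02_autocorrelation.py` (this computation for a uniform and
a textured mark side by side) prints:

```
shift r (nm)   uniform  textured
         100     0.267     0.793
         200     0.146     0.715
         400     0.061     0.432
         600     0.042     0.246
(averaged over 20 and 20 nuclei)
fitted correlation length of the textured mark: 273 nm (planted kernel: 300 nm; ...)
```

The textured mark stays correlated out to hundreds of nm while the uniform
mark decays to the noise floor — the ACF separates the two conditions, and
the fitted correlation length recovers the planted kernel width.

The other examples show scene generation and export
(`01_simulate_scene.py`), site detection with max-normalised radial mark
profiles against the planted enrichment (`03_site_profiles.py`), and the
zone-sorted t-test comparison (`04_zone_comparison.py`). Each prints the
numbers it computes and what they mean.

## Command line

A thin CLI wraps the pipeline for shell use; one YAML config drives
everything (see `nucquant.pipeline.DEFAULT_CONFIG` for the schema):

```bash
nucquant run-all -c run.yaml          # segment -> ACF; segment -> sites -> profiles -> stats
nucquant simulate -c run.yaml        # write a synthetic scene (OME-TIFF + CSV + YAML)
nucquant acf / sites / profiles / compare ...
```

Runs are deterministic under a fixed config + seed; every output directory
carries a provenance JSON (config hash, seed, versions, per-stage counts),
and outputs of failed runs are quarantined in a `.partial` directory.

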