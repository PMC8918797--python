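"""Synthetic embryo-like fluorescence scenes with known ground truth.

The generator produces three-channel 3-D stacks mimicking the statistical
structure of fixed-embryo imaging data:

* a **nuclear counterstain** channel (compact non-overlapping nuclei),
* a **mark** channel (a protein or histone-modification stain) whose
  in-nucleus texture is either spatially uniform — the early-embryo,
  "stage-5-like" situation — or heterogeneous with a controllable
  correlation length, emulating the coalescence of factors into distinct
  nuclear regions seen in older embryos, and
* a sparse **spots** channel marking at most one transcription site per
  nucleus, with optional local enrichment (or depletion) of the mark around
  each site and a two-zone spatial split ("active" vs "repressed") with
  different mean site intensities.

All channels pass through an axis-separable Gaussian PSF and a
Poisson-plus-Gaussian detection-noise model.  Every random draw derives from
one root seed, so identical parameters and seed reproduce bit-identical
stacks.

The heterogeneous texture is a Gaussian random field: white noise convolved
with a Gaussian kernel of width ℓ (``grf_kernel_sigma``).  Its radially
averaged autocorrelation is exp(−r²/(4ℓ²)) — a Gaussian of width ℓ√2 — which
gives every downstream correlation estimate a closed-form target.  The field
is generated over the full volume and then masked by the nuclei, so the
correlation structure is stationary inside each mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable

import numpy as np
from scipy import ndimage as ndi

from .stack import ImageStack, write_stack, write_table
from .segment import NucleusLabelMap

CHANNEL_NAMES = ["nuclei", "mark", "spots"]


class SceneParamError(ValueError):
    pass


class PackingError(RuntimeError):
    """Raised when the requested nuclei cannot be placed without overlap."""


@dataclass
class SceneParams:
    """Forward-model parameters of one synthetic scene.

    Lengths are nm; axes are ordered (z, y, x).

    Key parameters
    --------------
    mark_mode
        ``"uniform"``: constant mark level inside nuclei.
        ``"grf"``: Gaussian random field with kernel width ``grf_kernel_sigma``.
        ``"blobs"``: Poisson-distributed Gaussian blobs (density in blobs/µm³).
    enrichment_amplitude
        Multiplicative mark level at a transcription site: the mark is scaled
        by ``1 + (A − 1)·exp(−r²/(2·enrichment_sigma²))`` around each site.
        ``A > 1`` enriches, ``A < 1`` depletes (produces the central-dip
        phenomenology), ``A = 1`` leaves the mark untouched.
    zone_boundary / zone_axis / zone_effect
        A single axis-aligned plane splits sites into an *active* side
        (coordinate ≥ boundary) and a *repressed* side; active sites have
        ``zone_effect`` times the repressed mean spot intensity.
    psf_sigma / photon_scale / read_noise_sd
        Axis-separable Gaussian PSF width (scalar nm or per-axis triple;
        0 disables) and the Poisson + Gaussian noise model (``photon_scale``
        is the expected photon count at unit intensity; 0 disables shot
        noise; ``read_noise_sd`` in intensity units, 0 disables).
    """

    field_shape: tuple[int, int, int] = (9, 512, 512)
    voxel_size: tuple[float, float, float] = (190.0, 42.5, 42.5)
    n_nuclei: int = 20
    nucleus_radius: float = 2500.0
    nucleus_radius_sd: float = 150.0
    min_gap: float = 300.0
    mark_mode: str = "uniform"
    mark_mean: float = 1.0
    grf_kernel_sigma: float = 300.0
    grf_contrast: float = 0.25
    blob_density: float = 0.05
    blob_sigma: float = 250.0
    blob_amplitude: float = 1.0
    spot_fraction: float = 0.0
    spot_sigma: float = 120.0
    spot_intensity_mean: float = 5.0
    site_intensity_cv: float = 0.2
    enrichment_amplitude: float = 1.0
    enrichment_sigma: float = 200.0
    zone_axis: int = 1
    zone_boundary: float | None = None
    zone_effect: float = 1.0
    psf_sigma: float | tuple[float, float, float] = 0.0
    photon_scale: float = 0.0
    read_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.field_shape = tuple(int(s) for s in self.field_shape)
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.field_shape) != 3 or any(s < 1 for s in self.field_shape):
            raise SceneParamError(f"field_shape must be 3 positive ints, got {self.field_shape}")
        if any(v <= 0 for v in self.voxel_size):
            raise SceneParamError("voxel sizes must be positive nm")
        for name in ("nucleus_radius", "grf_kernel_sigma", "blob_sigma",
                     "spot_sigma", "enrichment_sigma"):
            if getattr(self, name) <= 0:
                raise SceneParamError(f"{name} must be > 0")
        if not 0.0 <= self.spot_fraction <= 1.0:
            raise SceneParamError("spot_fraction must lie in [0, 1]")
        if self.mark_mode not in ("uniform", "grf", "blobs"):
            raise SceneParamError(f"unknown mark_mode {self.mark_mode!r}")
        if min(self.mark_mean, self.spot_intensity_mean, self.enrichment_amplitude) < 0:
            raise SceneParamError("intensities and amplitudes must be >= 0")
        if self.zone_axis not in (0, 1, 2):
            raise SceneParamError("zone_axis must be 0 (z), 1 (y) or 2 (x)")

    @property
    def psf_sigma_zyx(self) -> tuple[float, float, float]:
        s = self.psf_sigma
        return tuple(float(v) for v in (s, s, s)) if np.isscalar(s) else tuple(float(v) for v in s)

    @property
    def extent_nm(self) -> np.ndarray:
        return np.asarray(self.field_shape) * np.asarray(self.voxel_size)

    def resolved_zone_boundary(self) -> float:
        if self.zone_boundary is not None:
            return float(self.zone_boundary)
        return float(self.extent_nm[self.zone_axis] / 2.0)


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    nucleus_centers: np.ndarray          # (n, 3) nm
    nucleus_radii: np.ndarray            # (n,) nm
    label_map: NucleusLabelMap
    sites: list[dict] = field(default_factory=list)  # site_id, nucleus_id, z/y/x nm, zone, true_intensity
    true_correlation_length: float | None = None     # nm, grf mode only
    true_profile: Callable[[np.ndarray], np.ndarray] | None = None
    zone_means: dict[str, float] = field(default_factory=dict)

    def site_positions_nm(self) -> np.ndarray:
        return np.array([[s["z_nm"], s["y_nm"], s["x_nm"]] for s in self.sites]).reshape(-1, 3)


def _place_nuclei(params: SceneParams, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample non-overlapping nucleus centres; returns (centres nm, radii nm)."""
    extent = params.extent_nm
    centers: list[np.ndarray] = []
    radii: list[float] = []
    max_tries = 400 * max(params.n_nuclei, 1)
    tries = 0
    while len(centers) < params.n_nuclei:
        if tries >= max_tries:
            raise PackingError(
                f"placed only {len(centers)} of {params.n_nuclei} nuclei in a "
                f"{tuple(np.round(extent / 1000, 1))} µm field without overlap"
            )
        tries += 1
        r = max(float(rng.normal(params.nucleus_radius, params.nucleus_radius_sd)),
                0.3 * params.nucleus_radius)
        lo = np.minimum(r, extent / 2.0)
        hi = np.maximum(extent - lo, lo)
        c = np.array([rng.uniform(l, h) if h > l else extent[i] / 2.0
                      for i, (l, h) in enumerate(zip(lo, hi))])
        ok = all(np.linalg.norm(c - c0) >= r + r0 + params.min_gap
                 for c0, r0 in zip(centers, radii))
        if ok:
            centers.append(c)
            radii.append(r)
    return np.asarray(centers).reshape(-1, 3), np.asarray(radii)


def _paint_labels(params: SceneParams, centers: np.ndarray, radii: np.ndarray) -> np.ndarray:
    """Sphere-in-nm label volume (clipped by the field along thin axes)."""
    labels = np.zeros(params.field_shape, dtype=np.int32)
    vs = np.asarray(params.voxel_size)
    for i, (c, r) in enumerate(zip(centers, radii), start=1):
        lo = np.maximum(0, np.floor((c - r) / vs).astype(int))
        hi = np.minimum(params.field_shape, np.ceil((c + r) / vs).astype(int) + 1)
        grid = np.meshgrid(*(np.arange(l, h) * v - cc for l, h, v, cc in zip(lo, hi, vs, c)),
                           indexing="ij")
        inside = grid[0] ** 2 + grid[1] ** 2 + grid[2] ** 2 <= r**2
        sub = labels[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
        sub[inside] = i
    return labels


def _grf(shape: tuple[int, ...], sigma_vox: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Standardised Gaussian random field: smoothed white noise, mean 0, s.d. 1."""
    noise = rng.standard_normal(shape)
    sig = np.where(np.asarray(shape) > 3, sigma_vox, 0.0)
    # circular smoothing keeps the field stationary up to the border
    # (reflect/constant padding would distort variance in a 5-sigma border strip)
    f = ndi.gaussian_filter(noise, sigma=sig, mode="wrap", truncate=5.0)
    return (f - f.mean()) / f.std()


def _add_gaussian(volume: np.ndarray, center_nm: np.ndarray, sigma_nm: float,
                  amplitude: float, voxel_size: np.ndarray, reach: float = 4.5) -> None:
    """Add amplitude·exp(−d²/2σ²) around ``center_nm`` in place (bounding-box render)."""
    lo = np.maximum(0, np.floor((center_nm - reach * sigma_nm) / voxel_size).astype(int))
    hi = np.minimum(volume.shape, np.ceil((center_nm + reach * sigma_nm) / voxel_size).astype(int) + 1)
    if np.any(lo >= hi):
        return
    grid = np.meshgrid(*(np.arange(l, h) * v - c for l, h, v, c in zip(lo, hi, voxel_size, center_nm)),
                       indexing="ij")
    d2 = grid[0] ** 2 + grid[1] ** 2 + grid[2] ** 2
    volume[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += amplitude * np.exp(-d2 / (2.0 * sigma_nm**2))


def _mark_base(params: SceneParams, rng: np.random.Generator) -> np.ndarray:
    vs = np.asarray(params.voxel_size)
    if params.mark_mode == "uniform":
        return np.full(params.field_shape, params.mark_mean)
    if params.mark_mode == "grf":
        g = _grf(params.field_shape, params.grf_kernel_sigma / vs, rng)
        return np.clip(params.mark_mean * (1.0 + params.grf_contrast * g), 0.0, None)
    # blobs
    vol_um3 = float(np.prod(params.extent_nm)) * 1e-9
    n_blobs = int(rng.poisson(params.blob_density * vol_um3))
    base = np.ones(params.field_shape)
    for _ in range(n_blobs):
        c = rng.uniform(0, params.extent_nm)
        _add_gaussian(base, c, params.blob_sigma, params.blob_amplitude, vs)
    return params.mark_mean * base / base.mean() if base.mean() > 0 else base


def sample_site_intensities(n: int, mean: float, cv: float,
                            rng: np.random.Generator) -> np.ndarray:
    """Site spot intensities: Normal(mean, cv·mean), floored at 5% of the mean.

    This is the generator's site-intensity model, exposed so that group-level
    power/calibration simulations sample intensities exactly as rendered
    scenes do.
    """
    vals = rng.normal(mean, cv * mean, size=n)
    return np.maximum(vals, 0.05 * mean)


def _make_sites(params: SceneParams, centers: np.ndarray, radii: np.ndarray,
                rng: np.random.Generator) -> list[dict]:
    boundary = params.resolved_zone_boundary()
    sites: list[dict] = []
    mean_rep = params.spot_intensity_mean
    mean_act = params.spot_intensity_mean * params.zone_effect
    # clip to the voxel-centre coordinate range so the nearest voxel exists
    hi_nm = (np.asarray(params.field_shape) - 1) * np.asarray(params.voxel_size)
    for nid, (c, r) in enumerate(zip(centers, radii), start=1):
        if rng.random() >= params.spot_fraction:
            continue
        # uniform inside a ball of 0.4 r around the centre, clipped into the field
        while True:
            off = rng.uniform(-0.4 * r, 0.4 * r, size=3)
            if np.linalg.norm(off) <= 0.4 * r:
                break
        pos = np.clip(c + off, 0.0, hi_nm)
        zone = "active" if pos[params.zone_axis] >= boundary else "repressed"
        mean = mean_act if zone == "active" else mean_rep
        intensity = float(sample_site_intensities(1, mean, params.site_intensity_cv, rng)[0])
        sites.append({
            "site_id": len(sites) + 1, "nucleus_id": nid,
            "z_nm": float(pos[0]), "y_nm": float(pos[1]), "x_nm": float(pos[2]),
            "zone": zone, "true_intensity": intensity,
        })
    return sites


def _true_profile(params: SceneParams) -> Callable[[np.ndarray], np.ndarray]:
    a, s = params.enrichment_amplitude, params.enrichment_sigma

    def profile(r: np.ndarray) -> np.ndarray:
        raw = 1.0 + (a - 1.0) * np.exp(-np.asarray(r, dtype=float) ** 2 / (2.0 * s**2))
        return raw / max(a, 1.0)

    return profile


def generate_scene(params: SceneParams, seed: int | None = None) -> tuple[ImageStack, GroundTruth]:
    """Render one synthetic scene; returns the stack and its ground truth.

    ``seed`` overrides ``params.seed``.  One root seed is deterministically
    split into independent streams (placement, texture, sites, noise), so a
    given (params, seed) pair is bit-reproducible.
    """
    root = np.random.SeedSequence(params.seed if seed is None else seed)
    rng_place, rng_mark, rng_sites, rng_noise = (
        np.random.default_rng(s) for s in root.spawn(4)
    )
    vs = np.asarray(params.voxel_size)

    centers, radii = _place_nuclei(params, rng_place)
    labels = _paint_labels(params, centers, radii)
    nuc_mask = labels > 0

    counterstain = nuc_mask.astype(float)

    mark = _mark_base(params, rng_mark)
    sites = _make_sites(params, centers, radii, rng_sites)
    if params.enrichment_amplitude != 1.0:
        enrich = np.zeros(params.field_shape)
        for s in sites:
            _add_gaussian(enrich, np.array([s["z_nm"], s["y_nm"], s["x_nm"]]),
                          params.enrichment_sigma, 1.0, vs)
        mark = mark * (1.0 + (params.enrichment_amplitude - 1.0) * np.clip(enrich, 0.0, 1.0))
    mark = np.where(nuc_mask, mark, 0.0)

    spots = np.zeros(params.field_shape)
    for s in sites:
        _add_gaussian(spots, np.array([s["z_nm"], s["y_nm"], s["x_nm"]]),
                      params.spot_sigma, s["true_intensity"], vs)

    data = np.stack([counterstain, mark, spots])

    psf = np.asarray(params.psf_sigma_zyx)
    if np.any(psf > 0):
        sig = np.where((np.asarray(params.field_shape) > 3) & (psf > 0), psf / vs, 0.0)
        for c in range(data.shape[0]):
            data[c] = ndi.gaussian_filter(data[c], sigma=sig, mode="reflect")

    if params.photon_scale > 0:
        data = rng_noise.poisson(np.clip(data, 0, None) * params.photon_scale) / params.photon_scale
    if params.read_noise_sd > 0:
        data = data + rng_noise.normal(0.0, params.read_noise_sd, size=data.shape)
    data = np.clip(data, 0.0, None)

    stack = ImageStack(data=data, voxel_size=params.voxel_size,
                       channel_names=list(CHANNEL_NAMES))
    truth = GroundTruth(
        nucleus_centers=centers,
        nucleus_radii=radii,
        label_map=NucleusLabelMap(labels=labels, voxel_size=params.voxel_size),
        sites=sites,
        true_correlation_length=params.grf_kernel_sigma if params.mark_mode == "grf" else None,
        true_profile=_true_profile(params),
        zone_means={"repressed": params.spot_intensity_mean,
                    "active": params.spot_intensity_mean * params.zone_effect},
    )
    return stack, truth


def write_scene(stack: ImageStack, truth: GroundTruth, params: SceneParams,
                out_dir: str | Path, name: str = "scene") -> dict[str, Path]:
    """Write a scene to disk: OME-TIFF stack, ground-truth CSV, params YAML."""
    import yaml

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "stack": out / f"{name}.ome.tif",
        "sites": out / f"{name}_sites.csv",
        "params": out / f"{name}_params.yaml",
    }
    write_stack(stack, paths["stack"])
    write_table(truth.sites, paths["sites"],
                columns=["site_id", "nucleus_id", "z_nm", "y_nm", "x_nm", "zone", "true_intensity"])
    cfg = asdict(params)
    with open(paths["params"], "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return paths
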