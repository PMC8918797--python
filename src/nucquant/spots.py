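"""Transcription-site detection and site-centred radial intensity profiles.

Sites are detected in the spot channel with a Laplacian-of-Gaussian filter;
at most one site per nucleus is kept (the strongest response), since the
reporter marks a single locus per nucleus.

For each site the mark channel is averaged in concentric lateral annuli
around the sub-voxel centroid, in the site's z-plane (2-D annuli rather
than spherical shells, matching the ~4–5× z anisotropy of the voxel).  Each
per-site profile is then normalised so that its maximum over the entire
radial distribution equals 1 — note: the *maximum*, not the value at r = 0,
so that profiles with a central dip keep their shape with their peak pinned
at 1.  Aggregation across sites reports the per-bin mean and variance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .stack import ImageStack
from .segment import NucleusLabelMap

log = logging.getLogger(__name__)


class SpotError(ValueError):
    pass


@dataclass
class TranscriptionSite:
    """One detected transcription site."""

    nucleus_id: int
    centroid_nm: tuple[float, float, float]  # (z, y, x), sub-voxel
    peak_intensity: float                    # spot-channel units
    zone: str = "unassigned"                 # {"active", "repressed", "unassigned"}
    site_id: int = 0

    def as_record(self) -> dict:
        z, y, x = self.centroid_nm
        return {"site_id": self.site_id, "nucleus_id": self.nucleus_id,
                "z_nm": z, "y_nm": y, "x_nm": x,
                "peak_intensity": self.peak_intensity, "zone": self.zone}


@dataclass
class SiteProfile:
    """Max-normalised radial profile of one site (max over bins = 1)."""

    site_id: int
    radii: np.ndarray   # nm bin centres
    values: np.ndarray  # normalised intensity


@dataclass
class RadialProfile:
    """Aggregate radial profile: per-bin mean and variance across sites."""

    radii: np.ndarray
    mean: np.ndarray
    variance: np.ndarray       # population variance (figure shading)
    sample_variance: np.ndarray
    n_sites: int

    def sem(self) -> np.ndarray:
        """Per-bin standard error of the mean (uses the sample variance)."""
        return np.sqrt(self.sample_variance / self.n_sites)


def detect_sites(
    stack: ImageStack,
    spot_channel: str,
    labels: NucleusLabelMap,
    log_sigma: float = 120.0,
    threshold: float = 8.0,
) -> list[TranscriptionSite]:
    """Detect at most one transcription site per nucleus.

    Parameters
    ----------
    log_sigma
        Scale of the Laplacian-of-Gaussian filter in nm (the expected spot
        radius).
    threshold
        Detection threshold as a multiple of the robust (MAD-based) standard
        deviation of the in-nucleus background LoG response.  The default is
        deliberately strict: candidate maxima are screened across millions of
        voxels, so the cutoff must sit well above the extreme-value tail of
        the background response, and genuine reporter spots respond tens of
        standard deviations above it.

    Returns
    -------
    list of TranscriptionSite — possibly empty; not every nucleus transcribes.
    """
    if labels.n_labels == 0:
        raise SpotError("empty label map: no nuclei to search for sites")
    vol = np.asarray(stack.channel(spot_channel), dtype=float)
    vs = np.asarray(stack.voxel_size)

    sig = np.where(np.asarray(vol.shape) > 3, log_sigma / vs, 0.0)
    response = -ndi.gaussian_laplace(vol, sigma=np.maximum(sig, 1e-9))
    # noise from the in-nucleus background (spots are sparse, so the median
    # and MAD inside the masks are background-dominated)
    in_mask = response[labels.labels > 0]
    mad = np.median(np.abs(in_mask - np.median(in_mask)))
    noise_sd = 1.4826 * mad
    if noise_sd == 0:
        noise_sd = in_mask.std()
    if noise_sd == 0:
        return []
    cutoff = threshold * noise_sd

    foot = np.ones(np.minimum(vol.shape, 3), dtype=bool)
    is_max = (response == ndi.maximum_filter(response, footprint=foot)) & (response > cutoff)
    is_max &= labels.labels > 0
    if not is_max.any():
        return []

    coords = np.argwhere(is_max)
    resp = response[tuple(coords.T)]
    nuc = labels.labels[tuple(coords.T)]
    sites: list[TranscriptionSite] = []
    for lab in np.unique(nuc):
        sel = nuc == lab
        best = coords[sel][np.argmax(resp[sel])]
        centroid = _refine_centroid(vol, best)
        peak = float(vol[tuple(best)])
        sites.append(TranscriptionSite(
            nucleus_id=int(lab),
            centroid_nm=tuple(centroid * vs),
            peak_intensity=peak,
            site_id=len(sites) + 1,
        ))
    return sites


def _refine_centroid(vol: np.ndarray, peak_idx: np.ndarray) -> np.ndarray:
    """Intensity-weighted centroid in a 3³ neighbourhood; voxel units, sub-voxel."""
    lo = np.maximum(0, peak_idx - 1)
    hi = np.minimum(vol.shape, peak_idx + 2)
    sub = vol[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]]
    w = np.clip(sub, 0, None)
    if w.sum() == 0:
        return peak_idx.astype(float)
    grids = np.meshgrid(*(np.arange(l, h) for l, h in zip(lo, hi)), indexing="ij")
    return np.array([(g * w).sum() / w.sum() for g in grids])


class SiteNearBorderError(SpotError):
    """Site centroid closer than max_radius to the lateral border (excluded)."""


def radial_profile_at_site(
    site: TranscriptionSite,
    stack: ImageStack,
    mark_channel: str = "mark",
    max_radius: float = 800.0,
    bin_width: float | None = None,
) -> SiteProfile:
    """Max-normalised lateral radial profile of the mark around one site.

    Annuli are half-open bins [r, r + w) of width ``bin_width`` (default: the
    lateral pixel size) out to ``max_radius`` nm, in the site's nearest
    z-plane, with voxel membership decided by voxel-centre distance to the
    sub-voxel centroid.  The profile is divided by its maximum, so
    ``max(values) == 1`` exactly.

    Raises
    ------
    SiteNearBorderError
        If the centroid is within ``max_radius`` of the lateral image border;
        partially covered outer annuli would bias the profile, so the site is
        excluded (callers log and count exclusions, never drop them silently).
    """
    vol = np.asarray(stack.channel(mark_channel), dtype=float)
    vz, vy, vx = stack.voxel_size
    if bin_width is None:
        bin_width = float((vy + vx) / 2.0)
    if bin_width <= 0 or max_radius <= bin_width:
        raise SpotError("need 0 < bin_width < max_radius")

    z_nm, y_nm, x_nm = site.centroid_nm
    nz, ny, nx = vol.shape
    if (y_nm < max_radius or x_nm < max_radius
            or y_nm > (ny - 1) * vy - max_radius or x_nm > (nx - 1) * vx - max_radius):
        raise SiteNearBorderError(
            f"site {site.site_id} at (y={y_nm:.0f}, x={x_nm:.0f}) nm is within "
            f"{max_radius:.0f} nm of the lateral border"
        )
    zi = int(np.clip(round(z_nm / vz), 0, nz - 1))
    plane = vol[zi]

    y0 = int(np.floor((y_nm - max_radius) / vy))
    y1 = int(np.ceil((y_nm + max_radius) / vy)) + 1
    x0 = int(np.floor((x_nm - max_radius) / vx))
    x1 = int(np.ceil((x_nm + max_radius) / vx)) + 1
    yy = (np.arange(max(y0, 0), min(y1, ny)) * vy - y_nm)[:, None]
    xx = (np.arange(max(x0, 0), min(x1, nx)) * vx - x_nm)[None, :]
    r = np.hypot(yy, xx)
    sub = plane[max(y0, 0):min(y1, ny), max(x0, 0):min(x1, nx)]

    nb = int(np.ceil(max_radius / bin_width))
    idx = np.floor(r / bin_width).astype(np.int64)   # half-open [r, r+w)
    inside = idx < nb
    sums = np.bincount(idx[inside], weights=sub[inside], minlength=nb)
    cnts = np.bincount(idx[inside], minlength=nb)
    keep = cnts > 0
    values = sums[keep] / cnts[keep]
    radii = (np.nonzero(keep)[0] + 0.5) * bin_width

    peak = values.max()
    if peak <= 0:
        raise SpotError(f"site {site.site_id}: non-positive mark everywhere in the profile")
    return SiteProfile(site_id=site.site_id, radii=radii, values=values / peak)


def profiles_for_sites(
    sites: list[TranscriptionSite],
    stack: ImageStack,
    mark_channel: str = "mark",
    max_radius: float = 800.0,
    bin_width: float | None = None,
) -> tuple[list[SiteProfile], list[dict]]:
    """Per-site profiles for all sites; border-excluded sites are returned
    separately as records with the exclusion reason (and logged)."""
    profiles: list[SiteProfile] = []
    excluded: list[dict] = []
    for s in sites:
        try:
            profiles.append(radial_profile_at_site(s, stack, mark_channel, max_radius, bin_width))
        except SiteNearBorderError as exc:
            log.info("excluding site %d: %s", s.site_id, exc)
            excluded.append({"site_id": s.site_id, "reason": str(exc)})
    return profiles, excluded


def aggregate_profiles(profiles: list[SiteProfile]) -> RadialProfile:
    """Per-bin mean and variance of max-normalised profiles across sites.

    All profiles must share the same binning.  The headline ``variance`` is
    the population variance (n denominator) used for the shaded band in the
    figures; the sample variance (n−1) is carried alongside for standard
    errors.
    """
    if not profiles:
        raise SpotError("no profiles to aggregate")
    radii = profiles[0].radii
    for p in profiles[1:]:
        if len(p.radii) != len(radii) or not np.allclose(p.radii, radii):
            raise SpotError("profiles have inconsistent radial binning")
    mat = np.vstack([p.values for p in profiles])
    n = mat.shape[0]
    mean = mat.mean(axis=0)
    var_pop = mat.var(axis=0)
    var_samp = mat.var(axis=0, ddof=1) if n > 1 else np.zeros_like(mean)
    return RadialProfile(radii=radii, mean=mean, variance=var_pop,
                         sample_variance=var_samp, n_sites=n)


def site_mark_intensity(
    site: TranscriptionSite,
    stack: ImageStack,
    mark_channel: str = "mark",
    aperture_radius: float = 300.0,
) -> float:
    """Mean mark intensity in a lateral disc of ``aperture_radius`` nm around
    the site centroid, in the site's z-plane — the "level at the
    transcription site" used for zone comparisons.

    Raises
    ------
    SiteNearBorderError
        If the aperture is clipped by the lateral border.
    """
    vol = np.asarray(stack.channel(mark_channel), dtype=float)
    vz, vy, vx = stack.voxel_size
    z_nm, y_nm, x_nm = site.centroid_nm
    nz, ny, nx = vol.shape
    if (y_nm < aperture_radius or x_nm < aperture_radius
            or y_nm > (ny - 1) * vy - aperture_radius or x_nm > (nx - 1) * vx - aperture_radius):
        raise SiteNearBorderError(
            f"site {site.site_id}: aperture of {aperture_radius:.0f} nm clipped by the border"
        )
    zi = int(np.clip(round(z_nm / vz), 0, nz - 1))
    y0 = max(int(np.floor((y_nm - aperture_radius) / vy)), 0)
    y1 = min(int(np.ceil((y_nm + aperture_radius) / vy)) + 1, ny)
    x0 = max(int(np.floor((x_nm - aperture_radius) / vx)), 0)
    x1 = min(int(np.ceil((x_nm + aperture_radius) / vx)) + 1, nx)
    yy = (np.arange(y0, y1) * vy - y_nm)[:, None]
    xx = (np.arange(x0, x1) * vx - x_nm)[None, :]
    disc = np.hypot(yy, xx) <= aperture_radius
    if not disc.any():
        raise SpotError("aperture contains no voxel centres; increase aperture_radius")
    return float(vol[zi, y0:y1, x0:x1][disc].mean())
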