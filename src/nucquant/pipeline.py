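"""End-to-end experiment orchestration from a single YAML config.

Two experiment flavours:

* **ACF experiment** — per condition: obtain a stack (from disk or from the
  synthetic generator), segment nuclei, optionally filter by depth from a
  reference surface, and compute the radially averaged spatial ACF of the
  mark channel.  One curve CSV per condition.
* **Profile experiment** — per condition: obtain a stack, segment, detect
  transcription sites, compute max-normalised radial mark profiles and
  per-site mark intensities, classify sites into zones, and run the group
  comparisons.  Site / profile / summary / comparison CSVs per condition.

Runs are deterministic under a fixed (config, seed); every output directory
carries a JSON provenance record (config hash, seed, package versions,
per-stage counts).  Outputs are staged into a ``.partial`` directory and
renamed on success, so a failed run never leaves files that look complete.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import shutil
import time
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import acf as acf_mod
from . import groupstats, spots, synth
from .segment import NucleusLabelMap, SurfacePlane, filter_by_depth, segment_nuclei
from .stack import ImageStack, read_stack

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """An error in a named pipeline stage."""

    def __init__(self, stage: str, condition: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed for condition {condition!r}: {cause}")
        self.stage = stage
        self.condition = condition
        self.__cause__ = cause


DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "output_dir": "nucquant_out",
    "channels": {"nuclei": "nuclei", "mark": "mark", "spots": "spots"},
    "conditions": [],
    "segmentation": {"min_volume": 2.0, "smoothing_sigma": 200.0, "use_truth_labels": False},
    "depth_filter": None,  # {"axis": 1, "position_nm": 0, "inward": 1, "max_depth_um": 20}
    "acf": {"plane_mode": "central", "bin_width": None, "max_radius": 1000.0,
            "min_pair_count": 16, "min_mask_voxels": 64},
    "spots": {"log_sigma": 120.0, "threshold": 8.0},
    "profiles": {"max_radius": 800.0, "bin_width": None},
    "zone_boundary": None,  # {"axis": 1, "position_nm": ..., "active_side": 1}
    # which per-site quantity the zone comparison tests: "peak" = spot-channel
    # site intensity; "mark" = mean mark intensity in an aperture at the site
    "compare_on": "peak",
    "aperture_radius": 300.0,
    "plots": False,
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        out[k] = _merge(base[k], v) if isinstance(v, dict) and isinstance(base.get(k), dict) else v
    return out


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> dict:
    """Load a YAML run config, filling defaults; ``overrides`` win over the file."""
    cfg = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        cfg = _merge(cfg, user)
    if overrides:
        cfg = _merge(cfg, overrides)
    return cfg


def config_hash(cfg: dict) -> str:
    canon = yaml.safe_dump(cfg, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _condition_stack(cond: dict, cfg: dict) -> tuple[ImageStack, synth.GroundTruth | None]:
    """A condition either references an image file or embeds scene parameters."""
    if "input" in cond:
        override = cond.get("voxel_size_nm")
        return read_stack(cond["input"], voxel_size_override=override), None
    if "scene" in cond:
        scene = dict(cond["scene"])
        name_tag = int(hashlib.sha256(str(cond["name"]).encode()).hexdigest()[:6], 16)
        scene.setdefault("seed", int(cfg["seed"]) + name_tag % 100_000)
        params = synth.SceneParams(**scene)
        stack, truth = synth.generate_scene(params)
        return stack, truth
    raise ValueError(f"condition {cond.get('name')!r} needs an 'input' path or a 'scene' block")


def _labels_for(stack: ImageStack, truth: synth.GroundTruth | None, cfg: dict,
                counts: dict) -> NucleusLabelMap:
    seg = cfg["segmentation"]
    if seg.get("use_truth_labels") and truth is not None:
        labels = truth.label_map
    else:
        labels = segment_nuclei(stack, cfg["channels"]["nuclei"],
                                min_volume=seg["min_volume"],
                                smoothing_sigma=seg["smoothing_sigma"])
    counts["nuclei_segmented"] = labels.n_labels
    if cfg.get("depth_filter"):
        df = cfg["depth_filter"]
        surface = SurfacePlane(axis=int(df["axis"]), position=float(df["position_nm"]),
                               inward=int(df.get("inward", 1)))
        labels = filter_by_depth(labels, surface, float(df["max_depth_um"]))
    counts["nuclei_kept"] = labels.n_labels
    return labels


def _provenance(cfg: dict, counts: dict) -> dict:
    import nucquant

    return {"config_hash": config_hash(cfg), "seed": cfg["seed"],
            "nucquant_version": nucquant.__version__,
            "numpy_version": np.__version__, "counts": counts}


class _StagedOutput:
    """Write into <out>/.partial-<name>, atomically rename to <out>/<name> on success."""

    def __init__(self, root: Path, name: str):
        self.final = root / name
        self.dir = root / f".partial-{name}"
        if self.dir.exists():
            shutil.rmtree(self.dir)
        self.dir.mkdir(parents=True)

    def commit(self) -> Path:
        if self.final.exists():
            shutil.rmtree(self.final)
        self.dir.rename(self.final)
        return self.final


def run_acf_experiment(cfg: dict, out_dir: str | Path | None = None) -> dict[str, acf_mod.AcfCurve]:
    """One radially averaged ACF curve per condition; CSVs + provenance JSON."""
    out_root = Path(out_dir if out_dir is not None else cfg["output_dir"])
    staged = _StagedOutput(out_root, "acf")
    curves: dict[str, acf_mod.AcfCurve] = {}
    report: dict[str, dict] = {}
    for cond in cfg["conditions"]:
        name = cond["name"]
        counts: dict[str, Any] = {}
        t0 = time.perf_counter()
        try:
            stack, truth = _condition_stack(cond, cfg)
        except Exception as exc:
            raise PipelineError("load", name, exc) from exc
        try:
            labels = _labels_for(stack, truth, cfg, counts)
        except Exception as exc:
            raise PipelineError("segment", name, exc) from exc
        try:
            a = cfg["acf"]
            curve = acf_mod.acf_curve_for_stack(
                stack, cfg["channels"]["mark"], labels,
                plane_mode=a["plane_mode"], bin_width=a["bin_width"],
                max_radius=a["max_radius"], min_pair_count=a["min_pair_count"],
                min_mask_voxels=a["min_mask_voxels"])
        except Exception as exc:
            raise PipelineError("acf", name, exc) from exc
        curves[name] = curve
        pd.DataFrame({"radius_nm": curve.radii, "acf": curve.values,
                      "pair_count": curve.counts,
                      "n_regions": np.full(len(curve.radii), curve.n_regions)}
                     ).to_csv(staged.dir / f"acf_{name}.csv", index=False)
        counts["elapsed_s"] = round(time.perf_counter() - t0, 3)
        report[name] = counts
        log.info("acf condition %s: %s", name, counts)
    with open(staged.dir / "acf_report.json", "w") as fh:
        json.dump(_provenance(cfg, report), fh, indent=2, sort_keys=True)
    if cfg.get("plots"):
        from .plotting import plot_acf_curves

        plot_acf_curves(curves, staged.dir / "acf.png")
    staged.commit()
    return curves


@dataclasses.dataclass
class ProfileResult:
    sites: list[spots.TranscriptionSite]
    profile: spots.RadialProfile | None
    excluded: list[dict]
    intensities_by_zone: dict[str, np.ndarray]
    mark_intensity: dict[int, float]  # site_id -> aperture mark level
    summaries: list[groupstats.GroupSummary]
    significant: list[groupstats.PairComparison]
    comparisons: list[groupstats.PairComparison]


def run_profile_experiment(cfg: dict, out_dir: str | Path | None = None) -> dict[str, ProfileResult]:
    """Sites, radial profiles and zone comparisons per condition; CSVs + JSON."""
    out_root = Path(out_dir if out_dir is not None else cfg["output_dir"])
    staged = _StagedOutput(out_root, "profiles")
    results: dict[str, ProfileResult] = {}
    report: dict[str, dict] = {}
    for cond in cfg["conditions"]:
        name = cond["name"]
        counts: dict[str, Any] = {}
        t0 = time.perf_counter()
        try:
            stack, truth = _condition_stack(cond, cfg)
            labels = _labels_for(stack, truth, cfg, counts)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("segment", name, exc) from exc

        try:
            sp = cfg["spots"]
            sites = spots.detect_sites(stack, cfg["channels"]["spots"], labels,
                                       log_sigma=sp["log_sigma"], threshold=sp["threshold"])
        except Exception as exc:
            raise PipelineError("detect", name, exc) from exc
        counts["sites_detected"] = len(sites)

        zb = cfg.get("zone_boundary")
        if zb is None and "scene" in cond:
            params_zone = cond["scene"]
            axis = int(params_zone.get("zone_axis", 1))
            pos = params_zone.get("zone_boundary")
            if pos is None:
                shape = params_zone.get("field_shape", synth.SceneParams().field_shape)
                vs = params_zone.get("voxel_size", synth.SceneParams().voxel_size)
                pos = shape[axis] * vs[axis] / 2.0
            zb = {"axis": axis, "position_nm": float(pos), "active_side": 1}
        if zb is not None:
            boundary = SurfacePlane(axis=int(zb["axis"]), position=float(zb["position_nm"]),
                                    inward=int(zb.get("active_side", 1)))
            groupstats.classify_sites(sites, boundary)

        try:
            pr = cfg["profiles"]
            site_profiles, excluded = spots.profiles_for_sites(
                sites, stack, cfg["channels"]["mark"],
                max_radius=pr["max_radius"], bin_width=pr["bin_width"])
            profile = spots.aggregate_profiles(site_profiles) if site_profiles else None
        except Exception as exc:
            raise PipelineError("profiles", name, exc) from exc
        counts["sites_profiled"] = len(site_profiles)
        counts["sites_excluded_border"] = len(excluded)

        compare_on = cfg.get("compare_on", "peak")
        intensities: dict[str, list[float]] = {}
        mark_levels: dict[int, float] = {}
        for s in sites:
            try:
                mark_levels[s.site_id] = spots.site_mark_intensity(
                    s, stack, cfg["channels"]["mark"], aperture_radius=cfg["aperture_radius"])
            except spots.SiteNearBorderError as exc:
                log.info("%s", exc)
                continue
            v = s.peak_intensity if compare_on == "peak" else mark_levels[s.site_id]
            intensities.setdefault(s.zone, []).append(v)
        intensities_arr = {k: np.asarray(v) for k, v in intensities.items()}

        if len(intensities_arr) >= 2:
            try:
                summaries, significant, comparisons = groupstats.compare_zones(intensities_arr)
            except Exception as exc:
                raise PipelineError("compare", name, exc) from exc
        else:
            summaries = [groupstats.summarize_group(k, v) for k, v in intensities_arr.items()]
            significant, comparisons = [], []

        res = ProfileResult(sites, profile, excluded, intensities_arr, mark_levels,
                            summaries, significant, comparisons)
        results[name] = res
        _write_profile_outputs(staged.dir, name, res, cfg)
        counts["elapsed_s"] = round(time.perf_counter() - t0, 3)
        report[name] = counts
        log.info("profile condition %s: %s", name, counts)
    with open(staged.dir / "profiles_report.json", "w") as fh:
        json.dump(_provenance(cfg, report), fh, indent=2, sort_keys=True)
    staged.commit()
    return results


def _write_profile_outputs(out: Path, name: str, res: ProfileResult, cfg: dict) -> None:
    recs = []
    for s in res.sites:
        rec = s.as_record()
        rec["mark_intensity"] = res.mark_intensity.get(s.site_id)
        recs.append(rec)
    pd.DataFrame(recs, columns=["site_id", "nucleus_id", "z_nm", "y_nm", "x_nm",
                                "peak_intensity", "zone", "mark_intensity"]
                 ).to_csv(out / f"sites_{name}.csv", index=False)
    if res.profile is not None:
        p = res.profile
        pd.DataFrame({"radius_nm": p.radii, "mean": p.mean, "variance": p.variance,
                      "sample_variance": p.sample_variance,
                      "n_sites": np.full(len(p.radii), p.n_sites)}
                     ).to_csv(out / f"profile_{name}.csv", index=False)
    pd.DataFrame([s.as_record() for s in res.summaries],
                 columns=["group", "n", "mean", "sd", "sd1_lo", "sd1_hi", "sd2_lo", "sd2_hi"]
                 ).to_csv(out / f"zone_summary_{name}.csv", index=False)
    cols = ["group_a", "group_b", "t", "df", "p_value", "significant"]
    pd.DataFrame([c.as_record() for c in res.comparisons], columns=cols
                 ).to_csv(out / f"comparisons_all_{name}.csv", index=False)
    pd.DataFrame([c.as_record() for c in res.significant], columns=cols
                 ).to_csv(out / f"comparisons_significant_{name}.csv", index=False)
    if cfg.get("plots") and res.summaries:
        from .plotting import plot_group_summaries

        plot_group_summaries(res.summaries, res.intensities_by_zone,
                             out / f"zones_{name}.png")


def run_all(cfg: dict, out_dir: str | Path | None = None) -> dict:
    """Run the ACF and profile experiments from one config."""
    curves = run_acf_experiment(cfg, out_dir)
    profiles = run_profile_experiment(cfg, out_dir)
    return {"acf": curves, "profiles": profiles}
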