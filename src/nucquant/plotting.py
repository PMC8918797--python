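"""Figure-style plots: ACF curves, radial profiles, zone summaries."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .acf import AcfCurve
from .groupstats import GroupSummary
from .spots import RadialProfile


def plot_acf_curves(curves: dict[str, AcfCurve], path: str | Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, c in curves.items():
        ax.plot(c.radii, c.values, label=f"{name} (n={c.n_regions})")
    ax.set_xlabel("shift distance (nm)")
    ax.set_ylabel("autocorrelation")
    ax.axhline(0, color="0.8", lw=0.8)
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_radial_profiles(profiles: dict[str, RadialProfile], path: str | Path) -> None:
    """Mean line with variance shading, one curve per condition."""
    fig, ax = plt.subplots(figsize=(5, 4))
    for name, p in profiles.items():
        ax.plot(p.radii, p.mean, label=f"{name} (n={p.n_sites})")
        ax.fill_between(p.radii, p.mean - p.variance, p.mean + p.variance, alpha=0.3)
    ax.set_xlabel("radius (nm)")
    ax.set_ylabel("normalized intensity")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_group_summaries(summaries: list[GroupSummary],
                         values: dict[str, np.ndarray], path: str | Path) -> None:
    """Mean bar, ±1 s.d. box, ±2 s.d. dotted lines, jittered points."""
    fig, ax = plt.subplots(figsize=(1.2 * len(summaries) + 1.5, 4))
    rng = np.random.default_rng(0)
    for i, s in enumerate(summaries):
        pts = np.asarray(values.get(s.label, []))
        if len(pts):
            ax.scatter(i + rng.uniform(-0.15, 0.15, len(pts)), pts, s=8, color="0.6", zorder=1)
        if s.sd is not None:
            ax.add_patch(plt.Rectangle((i - 0.25, s.mean - s.sd), 0.5, 2 * s.sd,
                                       facecolor="0.85", edgecolor="none", zorder=0))
            for b in s.sd2_bounds:
                ax.hlines(b, i - 0.25, i + 0.25, color="0.3", ls=":", lw=1, zorder=2)
        ax.hlines(s.mean, i - 0.3, i + 0.3, color="crimson", lw=2, zorder=3)
    ax.set_xticks(range(len(summaries)), [s.label for s in summaries])
    ax.set_ylabel("site mark intensity")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
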