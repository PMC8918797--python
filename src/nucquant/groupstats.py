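"""Zone classification and group comparisons of site intensities.

Sites are sorted into an *active* and a *repressed* zone by which side of an
axis-aligned boundary plane they fall on (the boundary models the sharp
ventral edge of a stripe expression pattern).  Group summaries report the
mean and ±1/±2 sample standard deviations; pairs of groups are compared with
the classical two-tailed pooled-variance Student's t-test, and — matching
the reporting convention of the figures this reproduces — only pairs with
P < 0.05 are listed in the headline output, while the full table of all
comparisons is always available.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .segment import SurfacePlane
from .spots import TranscriptionSite

log = logging.getLogger(__name__)

ALPHA = 0.05


class StatsError(ValueError):
    pass


@dataclass
class GroupSummary:
    label: str
    n: int
    mean: float
    sd: float | None  # sample s.d. (n−1); None when n < 2

    @property
    def sd_bounds(self) -> tuple[float, float] | None:
        """(mean − 1 s.d., mean + 1 s.d.)."""
        return None if self.sd is None else (self.mean - self.sd, self.mean + self.sd)

    @property
    def sd2_bounds(self) -> tuple[float, float] | None:
        """(mean − 2 s.d., mean + 2 s.d.)."""
        return None if self.sd is None else (self.mean - 2 * self.sd, self.mean + 2 * self.sd)

    def as_record(self) -> dict:
        rec = {"group": self.label, "n": self.n, "mean": self.mean, "sd": self.sd}
        if self.sd is not None:
            rec.update(sd1_lo=self.mean - self.sd, sd1_hi=self.mean + self.sd,
                       sd2_lo=self.mean - 2 * self.sd, sd2_hi=self.mean + 2 * self.sd)
        return rec


@dataclass
class PairComparison:
    group_a: str
    group_b: str
    t_statistic: float
    p_value: float
    df: int

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA

    def as_record(self) -> dict:
        return {"group_a": self.group_a, "group_b": self.group_b,
                "t": self.t_statistic, "df": self.df,
                "p_value": self.p_value, "significant": self.significant}


def classify_zone(site: TranscriptionSite, boundary: SurfacePlane) -> str:
    """Assign a site to the active or repressed zone.

    The *active* side is the side the plane's ``inward`` direction points to;
    a site exactly on the boundary is assigned *active* (documented
    tie-break).
    """
    coord = site.centroid_nm[boundary.axis]
    return "active" if boundary.inward * (coord - boundary.position) >= 0 else "repressed"


def classify_sites(sites: list[TranscriptionSite], boundary: SurfacePlane) -> list[TranscriptionSite]:
    """Set ``zone`` on every site in place; returns the same list."""
    for s in sites:
        s.zone = classify_zone(s, boundary)
    return sites


def student_t_two_tailed(a, b, welch: bool = False) -> PairComparison:
    """Two-sample two-tailed Student's t-test (pooled variance by default).

    ``welch=True`` switches to the unequal-variance Welch form.  Degenerate
    inputs: two identical constant samples give t = 0, p = 1 by convention;
    constant samples with different means have no defined t and raise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise StatsError("each sample needs n >= 2")
    pooled_num = ((len(a) - 1) * a.var(ddof=1) + (len(b) - 1) * b.var(ddof=1))
    df = len(a) + len(b) - 2
    if pooled_num == 0:
        if a.mean() == b.mean():
            return PairComparison("a", "b", 0.0, 1.0, df)
        raise StatsError("zero pooled variance with unequal means: t undefined")
    res = sps.ttest_ind(a, b, equal_var=not welch)
    df_out = df if not welch else float(res.df)
    return PairComparison("a", "b", float(res.statistic), float(res.pvalue), int(round(df_out)))


def summarize_group(label: str, values) -> GroupSummary:
    values = np.asarray(values, dtype=float)
    sd = float(values.std(ddof=1)) if len(values) >= 2 else None
    return GroupSummary(label=label, n=len(values), mean=float(values.mean()), sd=sd)


def compare_zones(
    intensities_by_group: dict[str, "np.ndarray | list[float]"],
    welch: bool = False,
    bonferroni: bool = False,
) -> tuple[list[GroupSummary], list[PairComparison], list[PairComparison]]:
    """Summaries and all pairwise t-tests over named groups of site intensities.

    Returns ``(summaries, significant, all_comparisons)``: every group is
    summarised, but — following the figures' convention — the ``significant``
    list holds only pairs with p < 0.05 (after optional Bonferroni scaling by
    the number of comparisons; off by default, and the number of comparisons
    is logged either way).  Groups with n < 2 are summarised but excluded
    from testing.
    """
    if len(intensities_by_group) < 2:
        raise StatsError("need at least two groups to compare")
    summaries = [summarize_group(k, v) for k, v in intensities_by_group.items()]
    testable = {k: np.asarray(v, float) for k, v in intensities_by_group.items() if len(v) >= 2}
    for k in intensities_by_group:
        if k not in testable:
            log.warning("group %r has n < 2: summarised but excluded from t-tests", k)

    pairs = list(itertools.combinations(sorted(testable), 2))
    n_comp = len(pairs)
    log.info("%d pairwise comparisons (Bonferroni %s)", n_comp, "on" if bonferroni else "off")
    comparisons: list[PairComparison] = []
    for ga, gb in pairs:
        c = student_t_two_tailed(testable[ga], testable[gb], welch=welch)
        p = min(c.p_value * n_comp, 1.0) if bonferroni else c.p_value
        comparisons.append(PairComparison(ga, gb, c.t_statistic, p, c.df))
    significant = [c for c in comparisons if c.significant]
    return summaries, significant, comparisons


def rejection_rate(
    effect: float,
    n_per_group: int,
    cv: float,
    n_replicates: int,
    seed: int,
    mean: float = 5.0,
) -> float:
    """Fraction of replicates where active vs repressed reaches p < 0.05.

    Site intensities are drawn from the generator's site-intensity model
    (Normal with s.d. = cv·mean, floored): the repressed group at ``mean``,
    the active group at ``effect * mean``.  ``effect=1`` measures the type-I
    error rate; ``effect>1`` measures power.
    """
    from .synth import sample_site_intensities

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        rep = sample_site_intensities(n_per_group, mean, cv, rng)
        act = sample_site_intensities(n_per_group, effect * mean, cv, rng)
        if student_t_two_tailed(act, rep).p_value < ALPHA:
            hits += 1
    return hits / n_replicates
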