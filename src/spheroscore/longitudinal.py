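"""Dose-response time series, z-plane distributions, and spheroid tracking.

Aggregates the per-image and per-spheroid tables produced by the scoring
stage into the views used for longitudinal perturbation studies: raw
(unnormalized) group viability curves over days, mean log10 spheroid area
trends, day-vs-day matched single-spheroid trajectories, and per-focal-
plane viability histograms in 10% bins.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .viability import SENTINEL_NO_SPHEROID, SpheroidRecord, WellSummary

log = logging.getLogger(__name__)

#: default z-plane layout (um): 11 planes, 40 um apart, centred on the
#: 320 um bulk midplane of the gel
DEFAULT_Z_PLANES_UM = tuple(float(z) for z in range(120, 521, 40))

#: default cap for cross-day centroid matching, in microns
DEFAULT_MATCH_DIST_UM = 150.0


@dataclass
class TimeSeriesRecord:
    """One well-image observation within a dose-response run."""

    group: str
    well_id: str
    day: int
    z_um: float | None
    summary: WellSummary

    def __post_init__(self) -> None:
        if self.day < 0:
            raise ValidationError("day must be >= 0")


@dataclass
class SpheroidTrack:
    """A single spheroid (or matched pair) followed across days."""

    track_id: int
    entries: dict[int, tuple[float, float, tuple[float, float]]] = field(
        default_factory=dict)  # day -> (viability_pct, area_um2, centroid)

    def add(self, day: int, viability: float, area: float,
            centroid: tuple[float, float]) -> None:
        if day in self.entries:
            raise ValidationError(f"track {self.track_id} already has day {day}")
        self.entries[day] = (viability, area, centroid)


def aggregate_group_viability(records: list[TimeSeriesRecord]) -> pd.DataFrame:
    """Mean/sd/n of well-average viability per (group, day).

    Viabilities are the raw well averages (no normalization).  Sentinel
    summaries are excluded; a group-day with only sentinel wells is emitted
    with ``n = 0`` and a missing mean.
    """
    if not records:
        raise ValidationError("no records to aggregate")
    rows = [{
        "group": r.group, "day": r.day,
        "avg_viability": (r.summary.avg_viability if r.summary.has_spheroids
                          else np.nan),
    } for r in records]
    df = pd.DataFrame(rows)
    out = (df.groupby(["group", "day"])["avg_viability"]
             .agg(mean="mean", sd="std", n="count")
             .reset_index())
    return out


def mean_log_area(records: list[SpheroidRecord],
                  group_of: dict | None = None) -> pd.DataFrame:
    """Mean log10 spheroid area (um^2) per (group, day) over all spheroids.

    ``group_of`` optionally maps well_id -> group label; otherwise the
    record's own metadata group is used (empty string when absent).
    """
    if not records:
        raise ValidationError("no spheroid records")
    rows = []
    for r in records:
        if r.area_um2 <= 0:
            raise ValidationError("areas must be positive for log transform")
        group = (group_of.get(r.meta.well_id) if group_of else r.meta.group) or ""
        rows.append({"group": group, "day": r.meta.day,
                     "log10_area": math.log10(r.area_um2)})
    df = pd.DataFrame(rows)
    return (df.groupby(["group", "day"])["log10_area"]
              .agg(mean_log10_area="mean", n="count")
              .reset_index())


def match_across_days(records_day_a: list[SpheroidRecord],
                      records_day_b: list[SpheroidRecord],
                      max_centroid_dist_um: float = DEFAULT_MATCH_DIST_UM,
                      microns_per_pixel: float = 2.5) -> list[SpheroidTrack]:
    """Greedy nearest-centroid one-to-one pairing of spheroids across days.

    Both record lists must come from the same well and focal plane.  Pairs
    farther apart than ``max_centroid_dist_um`` are not formed; unmatched
    spheroids are dropped from the output and their count logged.  How a
    study pairs spheroids across imaging days is an analysis choice of this
    module, not a property of the data — treat matched trajectories
    accordingly.
    """
    if records_day_a and records_day_b:
        wa = {(r.meta.well_id, r.meta.z_um) for r in records_day_a}
        wb = {(r.meta.well_id, r.meta.z_um) for r in records_day_b}
        if wa != wb or len(wa) != 1:
            raise ValidationError(
                "cross-day matching requires records from one common well/plane")
    cap_px = max_centroid_dist_um / microns_per_pixel
    dists = [
        (math.hypot(ra.centroid[0] - rb.centroid[0],
                    ra.centroid[1] - rb.centroid[1]), i, j)
        for i, ra in enumerate(records_day_a)
        for j, rb in enumerate(records_day_b)
    ]
    dists.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    tracks: list[SpheroidTrack] = []
    for d, i, j in dists:
        if d > cap_px or i in used_a or j in used_b:
            if d > cap_px:
                break
            continue
        ra, rb = records_day_a[i], records_day_b[j]
        t = SpheroidTrack(track_id=len(tracks))
        t.add(ra.meta.day, ra.viability_pct, ra.area_um2, ra.centroid)
        t.add(rb.meta.day, rb.viability_pct, rb.area_um2, rb.centroid)
        tracks.append(t)
        used_a.add(i)
        used_b.add(j)
    n_dropped = (len(records_day_a) - len(used_a)) + (len(records_day_b) - len(used_b))
    if n_dropped:
        log.info("cross-day matching dropped %d unmatched spheroids", n_dropped)
    return tracks


def plane_viability_histogram(records: list[SpheroidRecord],
                              bin_width: float = 10.0
                              ) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Per-z-plane viability histogram plus per-plane means and totals.

    Bins are ``[0, w), [w, 2w), ..., [100-w, 100]`` with the top bin
    closed.  The per-plane mean is taken over the raw (unbinned) values.
    Returns ``(counts, means, totals)``: counts indexed by z_um with one
    column per bin-left-edge, means and totals indexed by z_um.
    """
    if bin_width <= 0 or 100.0 % bin_width != 0:
        raise ValidationError("bin_width must be positive and divide 100")
    edges = np.arange(0.0, 100.0 + bin_width, bin_width)
    rows = [{"z_um": r.meta.z_um if r.meta.z_um is not None else 0.0,
             "viability": r.viability_pct} for r in records]
    df = pd.DataFrame(rows, columns=["z_um", "viability"])
    counts = {}
    means = {}
    totals = {}
    for z, sub in df.groupby("z_um"):
        h, _ = np.histogram(sub["viability"], bins=edges)  # top bin closed
        counts[z] = h
        means[z] = float(sub["viability"].mean())
        totals[z] = int(len(sub))
    count_df = pd.DataFrame.from_dict(counts, orient="index", columns=edges[:-1])
    count_df.index.name = "z_um"
    return (count_df.sort_index(),
            pd.Series(means, name="mean_viability").sort_index(),
            pd.Series(totals, name="total").sort_index())


def kde_density(points: list[tuple[float, float]]) -> np.ndarray:
    """Gaussian-kernel density (Scott's rule) at each sample point.

    Used to color day-vs-day scatter plots by local point density.  With
    degenerate input (all points identical, or otherwise singular
    covariance) every point gets the same density.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2 or pts.shape[1] != 2:
        raise ValidationError("kde_density requires >= 2 two-dimensional points")
    try:
        kde = sps.gaussian_kde(pts.T, bw_method="scott")
        dens = kde(pts.T)
    except np.linalg.LinAlgError:
        return np.ones(pts.shape[0])
    if not np.all(np.isfinite(dens)):
        return np.ones(pts.shape[0])
    return dens


# ---------------------------------------------------------------------------
# plotting helpers (optional figure output)
# ---------------------------------------------------------------------------

def plot_group_viability(agg: pd.DataFrame, out_path) -> None:
    """Line plot of mean group viability over days with sd error bars."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for group, sub in agg.groupby("group"):
        ax.errorbar(sub["day"], sub["mean"], yerr=sub["sd"].fillna(0),
                    marker="o", capsize=3, label=str(group))
    ax.set_xlabel("day")
    ax.set_ylabel("average viability (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_day_scatter(tracks: list[SpheroidTrack], day_a: int, day_b: int,
                     out_path, metric: str = "viability") -> None:
    """Day-b vs day-a scatter of matched spheroids, colored by KDE density."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    idx = 0 if metric == "viability" else 1
    pts = [(t.entries[day_a][idx], t.entries[day_b][idx]) for t in tracks
           if day_a in t.entries and day_b in t.entries]
    if len(pts) < 2:
        raise ValidationError("need at least two matched tracks to plot")
    dens = kde_density(pts)
    xs, ys = zip(*pts)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    sc = ax.scatter(xs, ys, c=dens, cmap="coolwarm", s=12)
    lo = min(min(xs), min(ys))
    hi = max(max(xs), max(ys))
    ax.plot([lo, hi], [lo, hi], "k-", lw=1)
    ax.set_xlabel(f"day {day_a} {metric}")
    ax.set_ylabel(f"day {day_b} {metric}")
    fig.colorbar(sc, ax=ax, label="density")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_plane_histogram(counts: pd.DataFrame, means: pd.Series, out_path) -> None:
    """2-D histogram of viability bins per z-plane with per-plane mean marks."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    im = ax.imshow(counts.values, aspect="auto", cmap="coolwarm",
                   extent=(0, 100, len(counts.index), 0))
    for k, z in enumerate(counts.index):
        ax.plot([means[z], means[z]], [k, k + 1], "k-", lw=2)
    ax.set_yticks(np.arange(len(counts.index)) + 0.5)
    ax.set_yticklabels([f"{z:.0f}" for z in counts.index])
    ax.set_xlabel("viability (%)")
    ax.set_ylabel("z (um)")
    fig.colorbar(im, ax=ax, label="spheroid count")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
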