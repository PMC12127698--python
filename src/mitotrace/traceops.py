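"""Trace-level statistics for multiscale 3D chromatin traces.

A Trace is an ordered polyline of (genomic coordinate, x, y, z) points for a
single chromatid with a cell-cycle stage label.  The operations here cover
the structural readouts used to characterize mitotic chromosome folding:
distance scaling curves and power-law exponents, close-contact loop calling
with base / nested / Z-loop classification, compaction metrics (radius of
gyration, elongation, contour length), the 20-Mb rolling-mean chromosome
axis with derived length and width, helical-regularity profiles, robust
axial scaling slopes, observed/expected + correlation (compartment)
matrices, and comparison with Hi-C contact-probability P(s) curves.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.spatial import cKDTree

logger = logging.getLogger(__name__)

__all__ = [
    "Trace",
    "ScalingCurve",
    "PowerLawFit",
    "LoopCallParams",
    "LoopCallSet",
    "TraceMetrics",
    "AxisPath",
    "STAGES",
    "rolling_mean_axis",
    "distances_to_polyline",
    "scaling_curve",
    "fit_power_law",
    "call_and_classify_loops",
    "trace_metrics",
    "axis_and_dimensions",
    "axial_scaling_slope",
    "helicity_profile",
    "rolling_outlier_filter",
    "observed_over_expected_and_correlation",
    "compare_with_ps",
    "find_scaling_minimum",
]

STAGES = ("interphase", "prophase", "prometaphase", "metaphase", "anaphase")


@dataclass
class Trace:
    """Ordered (genomic coordinate -> 3D position) polyline for one chromatid.

    Genomic coordinates are 0-based bp and strictly increasing; absent points
    (dropouts) keep their slot with present = False.
    """

    trace_id: str
    cell_id: str
    stage: str
    genomic: np.ndarray
    xyz: np.ndarray
    present: np.ndarray | None = None
    chrom: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.genomic = np.asarray(self.genomic, dtype=np.int64)
        self.xyz = np.asarray(self.xyz, dtype=np.float64)
        if self.present is None:
            self.present = np.ones(self.genomic.size, dtype=bool)
        self.present = np.asarray(self.present, dtype=bool)
        if self.xyz.shape != (self.genomic.size, 3):
            raise ValueError("xyz must be (n_points, 3)")
        if self.present.size != self.genomic.size:
            raise ValueError("present flag length mismatch")
        if np.any(np.diff(self.genomic) <= 0):
            raise ValueError(
                f"trace {self.trace_id!r}: genomic coordinates must be "
                "strictly increasing")

    @property
    def n_present(self) -> int:
        return int(self.present.sum())

    @property
    def completeness(self) -> float:
        return self.n_present / self.genomic.size

    def present_points(self) -> tuple[np.ndarray, np.ndarray]:
        return self.genomic[self.present], self.xyz[self.present]

    def copy(self) -> "Trace":
        return Trace(self.trace_id, self.cell_id, self.stage,
                     self.genomic.copy(), self.xyz.copy(), self.present.copy(),
                     self.chrom, self.condition)


@dataclass
class ScalingCurve:
    """Median pairwise 3D distance vs genomic separation, with SEM and counts."""

    separation: np.ndarray  # bp, sorted ascending
    median_distance: np.ndarray  # nm
    sem: np.ndarray
    count: np.ndarray

    def __post_init__(self) -> None:
        self.separation = np.asarray(self.separation, dtype=np.float64)
        self.median_distance = np.asarray(self.median_distance, dtype=np.float64)
        self.sem = np.asarray(self.sem, dtype=np.float64)
        self.count = np.asarray(self.count, dtype=np.int64)
        if np.any(self.separation <= 0):
            raise ValueError("separations must be positive")
        if np.any(np.diff(self.separation) <= 0):
            raise ValueError("separations must be sorted ascending")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "separation_bp": self.separation,
            "median_distance_nm": self.median_distance,
            "sem_nm": self.sem,
            "n_pairs": self.count,
        })


def _pool_pairs(traces: Iterable[Trace], min_points: int,
                interval: tuple[float, float] | None = None
                ) -> tuple[np.ndarray, np.ndarray]:
    """All within-trace (genomic separation, 3D distance) pairs, pooled."""
    seps, dists = [], []
    for tr in traces:
        g, p = tr.present_points()
        if g.size < min_points:
            continue
        i, j = np.triu_indices(g.size, k=1)
        s = (g[j] - g[i]).astype(np.float64)
        d = np.linalg.norm(p[j] - p[i], axis=1)
        if interval is not None:
            keep = (s >= interval[0]) & (s <= interval[1])
            s, d = s[keep], d[keep]
        seps.append(s)
        dists.append(d)
    if not seps:
        raise ValueError("no traces pass the minimum point cutoff")
    return np.concatenate(seps), np.concatenate(dists)


def scaling_curve(traces: Iterable[Trace], min_points_per_trace: int = 30,
                  bins: str | None = None, bins_per_decade: int = 30,
                  interval: tuple[float, float] | None = None
                  ) -> ScalingCurve:
    """Pooled distance scaling curve.

    With bins=None, one output bin per unique genomic separation (suited to
    single-resolution traces); with bins="log", logarithmic bins (default 30
    per decade) for pooled multiscale data.  ``interval`` restricts pooling
    to a genomic-separation range (bp), which keeps very large ensembles
    tractable when only part of the curve is needed.
    """
    s, d = _pool_pairs(list(traces), min_points_per_trace, interval=interval)
    if bins == "log":
        lo, hi = np.log10(s.min()), np.log10(s.max())
        n_bins = max(int(np.ceil((hi - lo) * bins_per_decade)), 1)
        edges = np.logspace(lo, hi, n_bins + 1)
        edges[0] *= 1 - 1e-12
        edges[-1] *= 1 + 1e-12
        which = np.clip(np.digitize(s, edges) - 1, 0, n_bins - 1)
        centers = np.sqrt(edges[:-1] * edges[1:])
    elif bins is None:
        centers, which = np.unique(s, return_inverse=True)
    else:
        raise ValueError("bins must be None or 'log'")
    df = pd.DataFrame({"bin": which, "d": d})
    grp = df.groupby("bin")["d"]
    med = grp.median()
    sem = grp.std(ddof=1) / np.sqrt(grp.count())
    idx = med.index.to_numpy()
    return ScalingCurve(separation=np.asarray(centers)[idx],
                        median_distance=med.to_numpy(),
                        sem=sem.fillna(0.0).to_numpy(),
                        count=grp.count().to_numpy())


@dataclass(frozen=True)
class PowerLawFit:
    """y = a * x^b with x in bp and y in nm; b is the scaling exponent."""

    prefactor: float
    exponent: float
    interval: tuple[float, float]


def fit_power_law(curve: ScalingCurve,
                  interval: tuple[float, float]) -> PowerLawFit:
    """Nonlinear least squares fit of median distance = a * separation^b
    restricted to a genomic-separation interval (bp)."""
    sel = (curve.separation >= interval[0]) & (curve.separation <= interval[1])
    x = curve.separation[sel]
    y = curve.median_distance[sel]
    if x.size < 3:
        raise ValueError("need at least 3 bins inside the fit interval")
    slope, intercept = np.polyfit(np.log(x), np.log(np.maximum(y, 1e-300)), 1)
    p0 = (float(np.exp(intercept)), float(slope))
    popt, _ = optimize.curve_fit(lambda xx, a, b: a * xx ** b, x, y,
                                 p0=p0, maxfev=20_000)
    return PowerLawFit(prefactor=float(popt[0]), exponent=float(popt[1]),
                       interval=(float(interval[0]), float(interval[1])))


@dataclass(frozen=True)
class LoopCallParams:
    distance_cutoff: float = 100.0  # nm
    min_genomic_span: int = 30_000  # bp
    anchor_tolerance: int = 1  # probe steps when matching shared anchors

    def __post_init__(self) -> None:
        if self.distance_cutoff <= 0 or self.min_genomic_span <= 0:
            raise ValueError("loop-call parameters must be positive")


@dataclass
class LoopCallSet:
    """Close contacts with base / nested / Z-loop labels.

    anchors_index are indices into the trace's present points; anchors_bp the
    corresponding genomic coordinates.
    """

    anchors_index: np.ndarray  # (m, 2), i < j
    anchors_bp: np.ndarray  # (m, 2)
    labels: list[str] = field(default_factory=list)

    def count(self, label: str) -> int:
        return sum(1 for lb in self.labels if lb == label)


def _classify_contacts(contacts: np.ndarray, tol: int) -> list[str]:
    """Classify each contact (index pairs, i<j) as nested / z_loop / base.

    (a, b) is nested if contacts matching (a, c) and (c, b) exist for some
    a < c < b (the merged bases of two loops), matching anchors within tol
    steps; (a, b) and (c, d) with a < c < b < d are Z-loops; nested takes
    precedence over Z.
    """
    m = contacts.shape[0]
    labels = ["base"] * m
    if m == 0:
        return labels
    cset = contacts

    def match(x: int, y: int) -> bool:
        return bool(np.any((np.abs(cset[:, 0] - x) <= tol) &
                           (np.abs(cset[:, 1] - y) <= tol)))

    for k in range(m):
        a, b = contacts[k]
        nested = False
        for c in range(a + 1, b):
            if match(a, c) and match(c, b):
                nested = True
                break
        if nested:
            labels[k] = "nested"
            continue
        interleaved = np.any(
            ((cset[:, 0] > a) & (cset[:, 0] < b) & (cset[:, 1] > b)) |
            ((cset[:, 0] < a) & (cset[:, 1] > a) & (cset[:, 1] < b)))
        if interleaved:
            labels[k] = "z_loop"
    return labels


def call_and_classify_loops(trace: Trace,
                            params: LoopCallParams = LoopCallParams()
                            ) -> LoopCallSet:
    """Close contacts (< cutoff nm, >= min span) classified into base loops,
    nested loops (merged bases) and Z-loops (partially interleaved)."""
    g, p = trace.present_points()
    if g.size < 2:
        raise ValueError("trace must have at least 2 present points")
    i, j = np.triu_indices(g.size, k=1)
    span = g[j] - g[i]
    dist = np.linalg.norm(p[j] - p[i], axis=1)
    keep = (dist < params.distance_cutoff) & (span >= params.min_genomic_span)
    idx = np.stack([i[keep], j[keep]], axis=1).astype(np.int64)
    labels = _classify_contacts(idx, params.anchor_tolerance)
    return LoopCallSet(anchors_index=idx,
                       anchors_bp=np.stack([g[idx[:, 0]], g[idx[:, 1]]], axis=1)
                       if idx.size else np.empty((0, 2), dtype=np.int64),
                       labels=labels)


@dataclass(frozen=True)
class TraceMetrics:
    radius_of_gyration: float  # nm
    elongation: float  # minor/major axis ratio, 0..1
    contour_length: float  # nm
    n_base: int
    n_nested: int
    n_z: int
    completeness: float


def trace_metrics(trace: Trace,
                  loop_params: LoopCallParams = LoopCallParams(),
                  min_completeness: float = 0.8,
                  min_points: int = 80) -> TraceMetrics | None:
    """Compaction and loop metrics for a single trace.

    Traces below the completeness or point-count cutoff are skipped (returns
    None with a logged reason).  Elongation is sqrt(smallest/largest
    eigenvalue) of the coordinate covariance, an ellipsoid-fit proxy.
    """
    if trace.completeness < min_completeness:
        logger.info("trace %s skipped: completeness %.3f < %.3f",
                    trace.trace_id, trace.completeness, min_completeness)
        return None
    if trace.n_present < min_points:
        logger.info("trace %s skipped: %d points < %d",
                    trace.trace_id, trace.n_present, min_points)
        return None
    _, p = trace.present_points()
    centered = p - p.mean(axis=0)
    rg = float(np.sqrt((centered ** 2).sum(axis=1).mean()))
    cov = np.cov(centered.T)
    evals = np.sort(np.linalg.eigvalsh(cov))
    elong = float(np.sqrt(evals[0] / evals[-1])) if evals[-1] > 0 else 0.0
    contour = float(np.linalg.norm(np.diff(p, axis=0), axis=1).sum())
    loops = call_and_classify_loops(trace, loop_params)
    return TraceMetrics(
        radius_of_gyration=rg, elongation=elong, contour_length=contour,
        n_base=loops.count("base"), n_nested=loops.count("nested"),
        n_z=loops.count("z_loop"), completeness=trace.completeness)


def rolling_mean_axis(genomic: np.ndarray, xyz: np.ndarray,
                      window_bp: float) -> np.ndarray:
    """Genomic rolling mean of coordinates: for each point, the mean of all
    points within +/- window/2 bp.  Edge windows are truncated."""
    g = np.asarray(genomic, dtype=np.float64)
    half = window_bp / 2.0
    lo = np.searchsorted(g, g - half, side="left")
    hi = np.searchsorted(g, g + half, side="right")
    csum = np.vstack([np.zeros(3), np.cumsum(xyz, axis=0)])
    sums = csum[hi] - csum[lo]
    counts = (hi - lo).astype(np.float64)[:, None]
    return sums / counts


def distances_to_polyline(points: np.ndarray, axis: np.ndarray) -> np.ndarray:
    """Distance of each point to an axis polyline.

    Projection is onto the nearest segments (found via the nearest vertex);
    the two terminal segments are extrapolated beyond the axis ends, so a
    straight rod has zero radial distance along its whole length.
    """
    p = np.asarray(points, dtype=np.float64)
    ax = np.asarray(axis, dtype=np.float64)
    m = ax.shape[0]
    if m == 1:
        return np.linalg.norm(p - ax[0], axis=1)
    best = np.full(p.shape[0], np.inf)
    a_all = ax[:-1]
    ab_all = np.diff(ax, axis=0)
    denom_all = np.einsum("ij,ij->i", ab_all, ab_all)
    denom_all[denom_all == 0] = 1.0
    chunk = 256
    for s0 in range(0, m - 1, chunk):
        a = a_all[s0:s0 + chunk]
        ab = ab_all[s0:s0 + chunk]
        denom = denom_all[s0:s0 + chunk]
        rel = p[:, None, :] - a[None, :, :]
        t = np.einsum("nsj,sj->ns", rel, ab) / denom
        seg_ids = np.arange(s0, s0 + a.shape[0])
        lo = np.where(seg_ids == 0, -np.inf, 0.0)
        hi = np.where(seg_ids == m - 2, np.inf, 1.0)
        t = np.clip(t, lo, hi)
        proj = rel - t[:, :, None] * ab[None, :, :]
        d2 = np.einsum("nsj,nsj->ns", proj, proj)
        best = np.minimum(best, np.sqrt(d2.min(axis=1)))
    return best


@dataclass
class AxisPath:
    points: np.ndarray  # (n, 3) nm
    window_bp: float
    length: float  # nm, polyline arc length
    width: float  # nm, median point-to-axis distance


def axis_and_dimensions(trace: Trace, window_bp: float = 20e6) -> AxisPath:
    """Chromosome axis from a rolling genomic mean; length is its arc length,
    width the median distance of trace points to the nearest axis point."""
    g, p = trace.present_points()
    if g.size < 2 or g[-1] - g[0] <= window_bp:
        raise ValueError("trace genomic extent must exceed the axis window")
    axis = rolling_mean_axis(g, p, window_bp)
    seglen = np.linalg.norm(np.diff(axis, axis=0), axis=1)
    dists = distances_to_polyline(p, axis)
    return AxisPath(points=axis, window_bp=window_bp,
                    length=float(seglen.sum()),
                    width=float(np.median(dists)))


def axial_scaling_slope(traces: Iterable[Trace],
                        interval: tuple[float, float] = (20e6, 60e6),
                        min_points_per_trace: int = 2,
                        max_direct_pairs: int = 20_000) -> float:
    """Siegel repeated-median slope (nm/bp) of physical vs genomic distance
    over pooled within-trace pairs restricted to the interval.

    For very large pools the pairs are reduced to per-separation medians
    before the repeated-median regression (which is quadratic in n).
    """
    s, d = _pool_pairs(list(traces), min_points_per_trace, interval=interval)
    if s.size == 0:
        raise ValueError("no pairs inside the interval")
    if s.size > max_direct_pairs:
        seps, inv = np.unique(s, return_inverse=True)
        med = pd.Series(d).groupby(inv).median()
        s, d = seps[med.index.to_numpy()], med.to_numpy()
    res = stats.siegelslopes(d, s)
    return float(res.slope)


def _parallel_transport_frames(axis: np.ndarray
                               ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Tangents and a parallel-transported normal frame along a polyline."""
    n = axis.shape[0]
    tang = np.empty_like(axis)
    tang[1:-1] = axis[2:] - axis[:-2]
    tang[0] = axis[1] - axis[0]
    tang[-1] = axis[-1] - axis[-2]
    norms = np.linalg.norm(tang, axis=1, keepdims=True)
    norms[norms == 0] = 1.0
    tang /= norms
    e1 = np.empty_like(axis)
    e2 = np.empty_like(axis)
    # initial normal: any vector perpendicular to the first tangent
    ref = np.array([1.0, 0.0, 0.0])
    if abs(tang[0] @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    v = ref - (ref @ tang[0]) * tang[0]
    e1[0] = v / np.linalg.norm(v)
    e2[0] = np.cross(tang[0], e1[0])
    for i in range(1, n):
        v = e1[i - 1] - (e1[i - 1] @ tang[i]) * tang[i]
        nv = np.linalg.norm(v)
        if nv < 1e-12:  # degenerate: keep previous frame
            v = e1[i - 1]
            nv = np.linalg.norm(v)
        e1[i] = v / nv
        e2[i] = np.cross(tang[i], e1[i])
    return tang, e1, e2


def helicity_profile(trace: Trace, window_bp: float = 20e6,
                     separations: Sequence[float] | None = None
                     ) -> pd.DataFrame:
    """Helical-regularity profile: SD of the radial-angle difference between
    points at given genomic separations, measured against the rolling-mean
    axis with a parallel-transported reference frame.

    Radial angles live on [0, 2pi); the profile is the plain standard
    deviation of their lagged differences.  For a regular helix the angle is
    a sawtooth of the genomic coordinate, so lagged differences take two
    values 2pi apart whose mixture vanishes at integer multiples of the
    pitch (SD ~ 0) and is maximal at half a pitch (SD ~ pi); random-walk
    traces give a flat profile at the uniform-difference value 2pi/sqrt(6).
    """
    g, p = trace.present_points()
    if g.size < 3 or g[-1] - g[0] <= window_bp:
        raise ValueError("trace genomic extent must exceed the axis window")
    # smooth the rolling-mean axis once more before building the frame:
    # residual periodic wobble of the axis would otherwise add spurious
    # torsion to the transported frame and shift the apparent pitch
    axis = rolling_mean_axis(g, rolling_mean_axis(g, p, window_bp), window_bp)
    _, e1, e2 = _parallel_transport_frames(axis)
    radial = p - axis
    angles = np.arctan2(np.einsum("ij,ij->i", radial, e2),
                        np.einsum("ij,ij->i", radial, e1))
    angles = np.mod(angles, 2 * np.pi)
    step = float(np.median(np.diff(g)))
    if separations is None:
        separations = np.arange(step, (g[-1] - g[0]) / 2, step)
    rows = []
    for s in separations:
        k = int(round(s / step))
        if k < 1 or k >= g.size:
            continue
        ii = np.arange(g.size - k)
        jj = ii + k
        ok = np.abs((g[jj] - g[ii]) - s) <= step / 2
        if ok.sum() < 3:
            continue
        delta = angles[jj[ok]] - angles[ii[ok]]
        rows.append((float(s), float(delta.std()), int(ok.sum())))
    return pd.DataFrame(rows, columns=["separation_bp", "angle_sd_rad", "n_pairs"])


def rolling_outlier_filter(trace: Trace, window: int = 11,
                           k: float = 3.0) -> Trace:
    """Remove spurious localizations: points deviating more than k standard
    deviations from the median position of their centered window of present
    points.  The SD is the RMS spread of the window positions about their
    median, so ends of smooth traces (whose windows are truncated and
    asymmetric) are not flagged."""
    out = trace.copy()
    g, p = trace.present_points()
    n = g.size
    if n < window:
        return out
    half = window // 2
    remove = np.zeros(n, dtype=bool)
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        win = p[lo:hi]
        med = np.median(win, axis=0)
        d2 = ((win - med) ** 2).sum(axis=1)
        sd = np.sqrt(d2.mean())
        di = np.linalg.norm(p[i] - med)
        if sd > 0 and di > k * sd:
            remove[i] = True
    present_idx = np.nonzero(trace.present)[0]
    out.present[present_idx[remove]] = False
    return out


def observed_over_expected_and_correlation(matrix: np.ndarray,
                                           stat: str = "median"
                                           ) -> tuple[np.ndarray, np.ndarray]:
    """Distance-normalize a square symmetric matrix by its expected value at
    each diagonal offset (median for distance maps, mean for contact maps)
    and return the Pearson correlation matrix of its rows/columns with
    pairwise-complete handling."""
    m = np.asarray(matrix, dtype=np.float64)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("matrix must be square")
    with np.errstate(invalid="ignore"):
        if not np.allclose(np.nan_to_num(m), np.nan_to_num(m.T),
                           rtol=1e-8, atol=1e-8):
            raise ValueError("matrix must be symmetric")
    n = m.shape[0]
    agg = np.nanmedian if stat == "median" else np.nanmean
    expected = np.full(n, np.nan)
    for off in range(n):
        diag = np.diagonal(m, offset=off)
        if np.any(np.isfinite(diag)):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                expected[off] = agg(diag)
    offsets = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = m / expected[offsets]
    finite = normalized[np.isfinite(normalized)]
    if finite.size and np.allclose(finite, finite[0]):
        warnings.warn("normalized matrix is constant; correlation is degenerate")
    corr = pd.DataFrame(normalized).corr(min_periods=3).to_numpy()
    return normalized, corr


@dataclass
class PsComparison:
    separation: np.ndarray  # bp, common grid
    contact_probability: np.ndarray  # mean balanced frequency
    inverse_distance: np.ndarray  # nm^-1
    median_distance: np.ndarray  # nm
    fit_below: tuple[float, float] | None = None  # slope, intercept of log10 P vs d
    fit_above: tuple[float, float] | None = None


def compare_with_ps(curve: ScalingCurve, contacts: pd.DataFrame,
                    resolution: int = 1_000_000,
                    split_nm: float = 1000.0,
                    fit: bool = True) -> PsComparison:
    """Align a distance scaling curve (inverted to nm^-1) with a Hi-C P(s)
    curve computed from a pre-balanced binned contact table with columns
    (bin1_start, bin2_start, balanced_frequency).

    Optional piecewise log-linear fits of log10 P(s) against median distance,
    split at 1,000 nm.
    """
    cols = list(contacts.columns[:3])
    b1 = contacts[cols[0]].to_numpy(dtype=np.int64)
    b2 = contacts[cols[1]].to_numpy(dtype=np.int64)
    freq = contacts[cols[2]].to_numpy(dtype=np.float64)
    if np.allclose(freq, np.round(freq)) and freq.max() > 1:
        warnings.warn("contact frequencies look like raw counts; "
                      "this comparison expects balanced frequencies")
    sep = np.abs(b2 - b1)
    keep = sep > 0
    grid = (sep[keep] // resolution) * resolution + resolution // 2
    ps = pd.Series(freq[keep]).groupby(grid).mean()

    cgrid = (curve.separation.astype(np.int64) // resolution) * resolution \
        + resolution // 2
    med = pd.Series(curve.median_distance).groupby(cgrid).median()

    common = ps.index.intersection(med.index)
    if len(common) == 0:
        raise ValueError("no common genomic separations between curves")
    p_s = ps.loc[common].to_numpy()
    d = med.loc[common].to_numpy()
    below = above = None
    if fit:
        logp = np.log10(np.maximum(p_s, 1e-300))
        for name, mask in (("below", d < split_nm), ("above", d >= split_nm)):
            if mask.sum() >= 2:
                slope, intercept = np.polyfit(d[mask], logp[mask], 1)
                if name == "below":
                    below = (float(slope), float(intercept))
                else:
                    above = (float(slope), float(intercept))
    return PsComparison(separation=common.to_numpy(dtype=np.float64),
                        contact_probability=p_s,
                        inverse_distance=1.0 / d,
                        median_distance=d,
                        fit_below=below, fit_above=above)


def find_scaling_minimum(curve: ScalingCurve,
                         interval: tuple[float, float],
                         smooth_bins: int | None = None) -> float | None:
    """Genomic separation of the interior local minimum of the scaling curve
    within an interval, after optional log-space moving-average smoothing.

    Scaling curves rise overall, so candidate minima are ranked by their
    prominence in log space (depth below the enclosing local maxima) rather
    than by absolute value; returns None if the curve has no interior local
    minimum in the interval.
    """
    from scipy.signal import find_peaks

    sel = (curve.separation >= interval[0]) & (curve.separation <= interval[1])
    if sel.sum() < 5:
        raise ValueError("need at least 5 bins inside the search interval")
    x = curve.separation[sel]
    y = np.log(curve.median_distance[sel])
    if smooth_bins and smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        pad = smooth_bins // 2
        ypad = np.pad(y, pad, mode="edge")
        y = np.convolve(ypad, kernel, mode="valid")[: x.size]
    dips, props = find_peaks(-y, prominence=0.0)
    if dips.size == 0:
        return None
    best = dips[np.argmax(props["prominences"])]
    return float(x[best])
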