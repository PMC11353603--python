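"""Along-tract profiling with central-segment reduction and pointwise tests.

Each streamline is resampled to 100 equidistant arc-length points (labelled
1..100); a scalar map is sampled at every point and averaged over streamlines
to give the subject's tract profile. The central segment is the mean of
points 40–60 inclusive. Group comparisons run pointwise over points 5–95 at
α = 0.01, reporting contiguous significant runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .io import ScalarMap, StreamlineBundle, sample_scalar

__all__ = [
    "TractProfile",
    "CentralSegmentValue",
    "resample_streamline",
    "orient_bundle",
    "tract_profile",
    "central_segment",
    "mean_group_profile",
    "pointwise_test",
]

N_POINTS = 100
CENTRAL_RANGE = (40, 60)   # 1-based labels, inclusive
TEST_RANGE = (5, 95)       # 1-based labels, inclusive
ALPHA = 0.01


@dataclass
class TractProfile:
    tract: str
    metric: str
    values: np.ndarray        # (n_streamlines, 100), NaN = missing
    mean_profile: np.ndarray  # (100,)
    n_valid: np.ndarray       # (100,) int

    def __post_init__(self) -> None:
        if self.mean_profile.shape != (N_POINTS,):
            raise ValueError(f"mean profile must have {N_POINTS} points")


@dataclass
class CentralSegmentValue:
    tract: str
    metric: str
    subject: str
    value: float


@dataclass
class PointwiseTestResult:
    points: np.ndarray        # tested point labels
    p_values: np.ndarray
    significant_runs: list[tuple[int, int]]  # inclusive label ranges
    alpha: float = ALPHA


def resample_streamline(polyline: np.ndarray, n: int = N_POINTS) -> np.ndarray:
    """Resample a polyline to ``n`` equidistant arc-length points.

    Endpoints are preserved exactly; interior points interpolate linearly
    between vertices at arc-length positions k·L/(n−1).
    """
    poly = np.asarray(polyline, dtype=float).reshape(-1, 3)
    seg = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    L = seg.sum()
    if L <= 0:
        raise ValueError("zero-length polyline")
    s = np.concatenate([[0.0], np.cumsum(seg)])
    targets = np.linspace(0.0, L, n)
    out = np.empty((n, 3))
    for d in range(3):
        out[:, d] = np.interp(targets, s, poly[:, d])
    out[0] = poly[0]
    out[-1] = poly[-1]
    return out


def orient_bundle(bundle: StreamlineBundle, reference_start: np.ndarray) -> StreamlineBundle:
    """Flip streamlines so every one starts near ``reference_start``.

    A streamline is reversed iff its last point is strictly nearer the
    reference than its first point (ties keep the stored order).
    """
    ref = np.asarray(reference_start, dtype=float)
    out = []
    for sl in bundle.streamlines:
        d_first = np.linalg.norm(sl[0] - ref)
        d_last = np.linalg.norm(sl[-1] - ref)
        out.append(sl[::-1].copy() if d_last < d_first else sl)
    oriented = StreamlineBundle.__new__(StreamlineBundle)
    oriented.streamlines = out
    oriented.name = bundle.name
    return oriented


def tract_profile(
    bundle: StreamlineBundle,
    smap: ScalarMap,
    affine: np.ndarray | None = None,
    mask: np.ndarray | None = None,
    n: int = N_POINTS,
) -> TractProfile:
    """Sample a scalar map along every streamline and average per point.

    Missing samples (outside the volume or the mask) are excluded from the
    per-point means; a point where every streamline is missing gets a NaN
    mean and ``n_valid = 0``.
    """
    affine = smap.affine if affine is None else affine
    vals = np.full((len(bundle), n), np.nan)
    import warnings as _warnings

    for i, sl in enumerate(bundle.streamlines):
        pts = resample_streamline(sl, n)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            vals[i] = sample_scalar(smap, affine, pts, mask=mask)
    n_valid = np.sum(~np.isnan(vals), axis=0)
    sums = np.nansum(vals, axis=0)
    mean = np.where(n_valid > 0, sums / np.maximum(n_valid, 1), np.nan)
    return TractProfile(bundle.name, smap.metric_name, vals, mean, n_valid)


def central_segment(
    profile: TractProfile,
    subject: str = "",
    point_range: tuple[int, int] = CENTRAL_RANGE,
) -> CentralSegmentValue:
    """Mean of the mean profile over points 40–60 inclusive (21 points).

    Missing points are excluded; an all-missing central segment raises.
    """
    lo, hi = point_range
    seg = profile.mean_profile[lo - 1 : hi]  # labels 1..100 -> 0-based slice
    if np.all(np.isnan(seg)):
        raise ValueError("central segment entirely missing")
    return CentralSegmentValue(
        profile.tract, profile.metric, subject, float(np.nanmean(seg))
    )


def mean_group_profile(profiles: list[TractProfile]) -> tuple[np.ndarray, np.ndarray]:
    """Per-point mean and standard deviation over subjects' mean profiles."""
    if not profiles:
        raise ValueError("need at least one subject profile")
    mat = np.stack([p.mean_profile for p in profiles])
    with np.errstate(invalid="ignore"):
        return np.nanmean(mat, axis=0), np.nanstd(mat, axis=0, ddof=0)


def pointwise_test(
    group_profiles: dict[str, list[TractProfile]],
    point_range: tuple[int, int] = TEST_RANGE,
    alpha: float = ALPHA,
) -> PointwiseTestResult:
    """Rank-based two-group (Mann–Whitney) or k-group (Kruskal–Wallis) test at
    every tract point in ``point_range``; contiguous p < alpha runs are
    reported as significant segments. All-tied points record p = 1."""
    groups = list(group_profiles)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    mats = {g: np.stack([p.mean_profile for p in group_profiles[g]]) for g in groups}
    for g, m in mats.items():
        if m.shape[0] < 2:
            raise ValueError(f"group {g!r} needs >= 2 subjects")
    lo, hi = point_range
    labels = np.arange(lo, hi + 1)
    pvals = np.ones(len(labels))
    for j, lab in enumerate(labels):
        samples = [mats[g][:, lab - 1] for g in groups]
        samples = [s[~np.isnan(s)] for s in samples]
        if any(len(s) < 2 for s in samples):
            pvals[j] = np.nan
            continue
        pooled = np.concatenate(samples)
        if np.all(pooled == pooled[0]):
            pvals[j] = 1.0
            continue
        if len(groups) == 2:
            _, p = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided")
        else:
            _, p = stats.kruskal(*samples)
        pvals[j] = p

    runs: list[tuple[int, int]] = []
    in_run = False
    start = 0
    for lab, p in zip(labels, pvals):
        sig = np.isfinite(p) and p < alpha
        if sig and not in_run:
            in_run, start = True, lab
        elif not sig and in_run:
            runs.append((start, lab - 1))
            in_run = False
    if in_run:
        runs.append((start, int(labels[-1])))
    return PointwiseTestResult(labels, pvals, runs, alpha)
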