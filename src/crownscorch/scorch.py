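"""Crown scorch height, crown base height, and crown volume scorched.

For a burned tree the vertical greenness structure of its point cloud tells
where live foliage begins: per-point GLI values are aggregated into 10-cm
height slices, the slice medians form a vertical profile, and a cubic
smoothing spline fitted to the profile is scanned from the bottom for its
lowest negative-to-positive transition — the crown scorch height. A
completely negative spline means no live foliage survives and scorch height
equals the maximum point height. Crown base height comes from the point-count
histogram in 25-cm slices (lowest inflection of the smoothed counts), and
crown volume scorched follows the conical-crown formula

    CVS = 100 * CLS * (2*CL - CLS) / CL**2

with CL the total crown length and CLS the crown length scorched.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

from ._spline import smoothing_spline
from .classify import BurnCall, gli
from .cloud import ColoredPointCloud
from .segmentation import CrownSegment

__all__ = [
    "VerticalProfile",
    "ScorchAssessment",
    "vertical_gli_profile",
    "fit_profile_spline",
    "scorch_height_from_spline",
    "crown_base_height",
    "crown_volume_scorched",
    "assess_tree",
]


@dataclass
class VerticalProfile:
    """Per-slice vertical statistic (median GLI or point count)."""

    centers: np.ndarray  # slice center heights, m, strictly increasing
    stat: np.ndarray  # per-slice statistic; NaN where the slice is empty
    n: np.ndarray  # points per slice
    spacing: float

    @property
    def nonempty(self) -> np.ndarray:
        return self.n > 0


@dataclass
class ScorchAssessment:
    """Per-tree severity outputs."""

    tree_id: int
    label: str
    positive_gli_fraction: float
    scorch_height: float  # m above ground
    crown_base_height: float  # m
    total_height: float  # m
    cl: float  # crown length, m
    cls: float  # crown length scorched, m
    cvs: float  # crown volume scorched, percent
    pct_length_scorched: float
    flags: list[str] = field(default_factory=list)


class FittedProfile:
    """Callable profile trend over [lowest, highest] slice center.

    Either a smoothing spline, or (with too few slices) a step interpolant
    through the slice medians flagged low-confidence.
    """

    def __init__(self, fn: Callable, domain: tuple[float, float],
                 low_confidence: bool = False):
        self._fn = fn
        self.domain = domain
        self.low_confidence = low_confidence

    def __call__(self, h):
        return self._fn(h)


def vertical_gli_profile(
    points: ColoredPointCloud, slice: float = 0.10
) -> VerticalProfile:
    """Median point GLI in uniform height slices anchored at the lowest point."""
    if len(points) == 0:
        raise ValueError("cannot profile an empty cloud")
    if slice <= 0:
        raise ValueError("slice thickness must be positive")
    vals = gli(points.r, points.g, points.b)
    z0 = points.z.min()
    idx = np.minimum(
        ((points.z - z0) / slice).astype(int),
        max(int((points.z.max() - z0) / slice), 0),
    )
    n_slices = idx.max() + 1
    stat = np.full(n_slices, np.nan)
    counts = np.bincount(idx, minlength=n_slices)
    for i in np.nonzero(counts)[0]:
        stat[i] = np.median(vals[idx == i])
    centers = z0 + (np.arange(n_slices) + 0.5) * slice
    return VerticalProfile(centers=centers, stat=stat, n=counts, spacing=slice)


def fit_profile_spline(
    profile: VerticalProfile, smoothing: float = 0.65, weight_by_n: bool = True
) -> FittedProfile:
    """Fit a cubic smoothing spline to the non-empty slices of a profile.

    ``smoothing`` is a normalized [0, 1] roughness parameter (0 near-
    interpolating, 1 near-linear). Empty slices are excluded, not imputed.
    By default slices are weighted by their point counts, so a sparse slice
    (a few bole points above a consumed crown, say) cannot swing the trend
    the way a fully populated one can. With fewer than 4 usable slices,
    falls back to a nearest-slice step rule flagged low-confidence.
    """
    mask = profile.nonempty
    x = profile.centers[mask]
    y = profile.stat[mask]
    w = profile.n[mask].astype(float) if weight_by_n else None
    if len(x) < 4:
        if len(x) == 0:
            raise ValueError("profile has no non-empty slices")
        warnings.warn(
            "fewer than 4 non-empty slices; step-rule fallback", stacklevel=2
        )

        def step(h, x=x, y=y):
            h = np.asarray(h, dtype=float)
            j = np.abs(h[..., None] - x).argmin(axis=-1)
            out = y[j]
            return out if out.ndim else float(out)

        return FittedProfile(step, (float(x[0]), float(x[-1])), low_confidence=True)
    spl = smoothing_spline(x, y, spar=smoothing, weights=w)
    return FittedProfile(spl, (float(x[0]), float(x[-1])))


def scorch_height_from_spline(
    spline: FittedProfile,
    max_point_height: float,
    crown_base_height: float,
) -> tuple[float, list[str]]:
    """Scorch height from the sign structure of the fitted profile.

    Mixed-sign spline: the lowest height where the spline turns positive
    (lowest negative-to-positive crossing, bisected to mm). Always negative:
    no surviving foliage, scorch height = maximum point height. Always
    positive: no detectable scorch — returns the crown base height flagged
    inconsistent-with-classification, since this arises only for trees the
    classifier called burned.
    """
    lo, hi = spline.domain
    if not np.isfinite([lo, hi]).all() or hi < lo:
        raise ValueError("spline domain is undefined")
    grid = np.arange(lo, hi + 5e-3, 0.01)
    vals = np.asarray(spline(grid), dtype=float)
    pos = vals > 0
    if not pos.any():
        return float(max_point_height), []
    if pos.all():
        return float(crown_base_height), ["inconsistent-with-classification"]
    first = int(np.argmax(pos))
    if first == 0:
        return float(grid[0]), []
    a, b = grid[first - 1], grid[first]
    for _ in range(8):  # bisect the bracketing cm to ~0.04 mm
        mid = 0.5 * (a + b)
        if spline(mid) > 0:
            b = mid
        else:
            a = mid
    return float(b), []


def crown_base_height(
    points: ColoredPointCloud, bin: float = 0.25
) -> tuple[float, list[str]]:
    """Crown base height from the vertical point-count histogram.

    Counts per 25-cm slice are smoothed with a 3-bin moving average; crown
    base height is the lowest inflection (sign change of the discrete second
    difference). Two guards keep the rule on the histogram feature it is
    meant to find — the sparse-to-dense transition at the base of the live
    crown. First, the inflection search presumes the cloud reaches below the
    crown; when the lowest bins are already densely populated (at least half
    the median bin count) the crown base is simply the lowest point. Second,
    because slice counts are Poisson-noisy, a sign change only counts as an
    inflection when the second difference on both sides exceeds twice the
    local Poisson scale sqrt(count), and only inflections at or below the
    histogram peak qualify; without these the estimator latches onto noise
    wiggles or onto the conical taper at the apex. Degenerate profiles
    (span < 1 m, < 8 points, or no qualifying inflection) fall back to the
    lowest point height with a flag.
    """
    if len(points) == 0:
        raise ValueError("cannot derive crown base height from an empty cloud")
    z0, z1 = points.z.min(), points.z.max()
    if len(points) < 8 or (z1 - z0) < 1.0:
        return float(z0), ["cbh-degenerate-profile"]
    edges = np.arange(z0, z1 + bin, bin)
    counts, _ = np.histogram(points.z, bins=edges)
    if len(counts) < 4:
        return float(z0), ["cbh-degenerate-profile"]
    kernel = np.ones(3)
    smooth = np.convolve(counts, kernel, mode="same") / np.convolve(
        np.ones_like(counts, dtype=float), kernel, mode="same"
    )
    if smooth[0] >= 0.5 * np.median(smooth[smooth > 0]):
        return float(z0), []  # cloud starts inside the crown
    d2 = np.diff(smooth, 2)  # d2[j] is centered on bin j+1
    noise_scale = 2.0 * np.sqrt(np.maximum(smooth[1:-1], 1.0))
    signs = np.where(np.abs(d2) > noise_scale, np.sign(d2), 0.0)
    peak = int(np.argmax(smooth))
    nz = [j for j in np.nonzero(signs)[0] if j + 1 <= peak]
    for a, b in zip(nz[:-1], nz[1:]):
        if signs[a] != signs[b]:
            bin_idx = 0.5 * (a + b) + 1
            return float(z0 + (bin_idx + 0.5) * bin), []
    return float(z0), ["cbh-no-inflection"]


def crown_volume_scorched(cl: float, cls: float) -> float:
    """Percent of conical crown volume scorched from crown lengths (m)."""
    if cl <= 0:
        raise ValueError("crown length must be positive")
    if cls > cl:
        warnings.warn("CLS exceeds CL; clamped", stacklevel=2)
        cls = cl
    if cls < 0:
        raise ValueError("CLS must be non-negative")
    return float(np.clip(100.0 * cls * (2.0 * cl - cls) / cl**2, 0.0, 100.0))


def assess_tree(
    segment: CrownSegment,
    burn_call: BurnCall,
    slice: float = 0.10,
    smoothing: float = 0.65,
    cbh_bin: float = 0.25,
) -> ScorchAssessment:
    """Full severity assessment of one segmented tree.

    Unburned trees get scorch height at the crown base and zero scorched
    length/volume. Burned trees run the profile chain: median-GLI slices →
    smoothing spline → scorch height; count histogram → crown base height;
    conical formula → CVS.
    """
    points = segment.points
    if points is None or len(points) == 0:
        raise ValueError(f"tree {segment.tree_id}: segment carries no points")
    total_height = float(points.z.max())
    cbh, flags = crown_base_height(points, bin=cbh_bin)
    cbh = min(cbh, total_height)
    cl = max(total_height - cbh, 1e-6)

    if burn_call.label == "unburned":
        scorch, cls = cbh, 0.0
    else:
        profile = vertical_gli_profile(points, slice=slice)
        fitted = fit_profile_spline(profile, smoothing=smoothing)
        if fitted.low_confidence:
            flags.append("low-confidence-profile")
        scorch, s_flags = scorch_height_from_spline(fitted, total_height, cbh)
        flags.extend(s_flags)
        cls = float(np.clip(scorch - cbh, 0.0, cl))

    cvs = crown_volume_scorched(cl, cls)
    return ScorchAssessment(
        tree_id=segment.tree_id,
        label=burn_call.label,
        positive_gli_fraction=burn_call.positive_gli_fraction,
        scorch_height=float(scorch),
        crown_base_height=float(cbh),
        total_height=total_height,
        cl=float(cl),
        cls=cls,
        cvs=float(cvs),
        pct_length_scorched=100.0 * cls / cl,
        flags=flags,
    )
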