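"""Aggregate signal profiles around anchor positions.

Mean coverage (or any per-base signal) is averaged across anchors at each
offset in a window, with optional strand-aware mirroring; peaks can be
stratified into enrichment quartiles; profiles can be smoothed with a
Nadaraya-Watson kernel smoother whose bandwidth semantics follow the
classical ``ksmooth`` convention (kernels scaled so their quartiles sit at
+-0.25 * bandwidth), and divided pointwise to form ratio profiles with
optional edge normalization.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .genome import CoverageTrack
from .peaks import Peak

logger = logging.getLogger(__name__)

__all__ = [
    "Profile",
    "aggregate_profile",
    "stratify_by_quartile",
    "smooth_profile",
    "ratio_profile",
]


@dataclass
class Profile:
    offsets: np.ndarray  # bp, [-halfwidth, +halfwidth]
    values: np.ndarray  # mean signal per offset
    n_anchors: int
    se: np.ndarray | None = None

    def __post_init__(self) -> None:
        if len(self.offsets) != len(self.values):
            raise ValueError("offsets/values length mismatch")
        if self.n_anchors < 1:
            raise ValueError("profile needs at least one anchor")


def aggregate_profile(
    track: CoverageTrack,
    anchors: list[tuple[str, int, str]],
    halfwidth: int,
    mirror_minus: bool = True,
    with_se: bool = False,
) -> Profile:
    """Mean of ``track`` at anchor+offset over all anchors, offsets in
    [-halfwidth, +halfwidth].  Minus-strand anchors are mirrored when
    ``mirror_minus`` (so profiles are oriented 5'->3' around motifs);
    anchors whose window leaves the sequence are dropped and logged."""
    width = 2 * halfwidth + 1
    rows = []
    dropped = 0
    for chrom, pos, strand in anchors:
        vals = track.values[chrom]
        lo, hi = pos - halfwidth, pos + halfwidth + 1
        if lo < 0 or hi > len(vals):
            dropped += 1
            continue
        window = vals[lo:hi]
        if mirror_minus and strand == "-":
            window = window[::-1]
        rows.append(window)
    if dropped:
        logger.info("aggregate_profile: dropped %d clipped anchor(s)", dropped)
    if not rows:
        raise ValueError("no anchors with complete windows")
    mat = np.stack(rows)
    se = mat.std(axis=0, ddof=1) / np.sqrt(len(rows)) if (with_se and len(rows) > 1) else None
    return Profile(
        offsets=np.arange(-halfwidth, halfwidth + 1),
        values=mat.mean(axis=0),
        n_anchors=len(rows),
        se=se,
    )


def stratify_by_quartile(peaks: list[Peak], key=lambda pk: pk.enrichment) -> list[list[Peak]]:
    """Split peaks into four groups at the empirical 25/50/75 percentiles of
    ``key``; ties go to the lower quartile."""
    if len(peaks) < 4:
        raise ValueError("need at least 4 peaks to stratify")
    vals = np.array([key(pk) for pk in peaks])
    qs = np.percentile(vals, [25, 50, 75])
    groups: list[list[Peak]] = [[], [], [], []]
    for pk, v in zip(peaks, vals):
        gi = int((v > qs).sum())  # ties (v == boundary) fall to the lower group
        groups[gi].append(pk)
    if len(groups[0]) == len(peaks):
        logger.warning("all peaks tied; quartile 1 holds everything")
    return groups


def _kernel_weights(offsets: np.ndarray, x0: float, bandwidth: float, kernel: str) -> np.ndarray:
    """ksmooth-convention kernels: quartiles at +-0.25 * bandwidth."""
    d = np.abs(offsets - x0)
    if kernel == "box":
        return (d <= 0.5 * bandwidth).astype(float)
    if kernel == "normal":
        sd = 0.25 * bandwidth / 0.6744897501960817  # quartile of N(0,1)
        return np.exp(-0.5 * (d / sd) ** 2)
    raise ValueError(f"unknown kernel {kernel!r}")


def smooth_profile(
    profile: Profile, bandwidth: float, kernel: str = "box"
) -> Profile:
    """Nadaraya-Watson smoothing; edges renormalize over available support.

    A bandwidth at least as wide as the profile span returns the flat
    global mean (with a warning)."""
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    x = profile.offsets.astype(float)
    y = profile.values
    span = x[-1] - x[0]
    if kernel == "box" and bandwidth >= 2 * span:
        logger.warning("bandwidth >= profile span; returning global mean")
        return Profile(profile.offsets, np.full_like(y, y.mean()), profile.n_anchors)
    if kernel == "box":
        # uniform offsets: moving average over +-bandwidth/2, via cumsum
        half = int(np.floor(0.5 * bandwidth))
        cum = np.concatenate(([0.0], np.cumsum(y)))
        idx = np.arange(len(y))
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half + 1, len(y))
        sm = (cum[hi] - cum[lo]) / (hi - lo)
    else:
        sm = np.empty_like(y)
        for i, x0 in enumerate(x):
            w = _kernel_weights(x, x0, bandwidth, kernel)
            sm[i] = np.average(y, weights=w)
    return Profile(profile.offsets, sm, profile.n_anchors)


def ratio_profile(
    numerator: Profile,
    denominator: Profile,
    edge_normalize: bool = False,
    edge_fraction: float = 0.10,
    eps: float = 1e-6,
) -> Profile:
    """Pointwise ratio of two profiles on the same offsets.

    Denominator values below ``eps`` are floored (with a warning).  With
    ``edge_normalize`` the ratio is divided by the mean over the outer
    ``edge_fraction`` of offsets on each side, so it equals 1 at the edges.
    """
    if not np.array_equal(numerator.offsets, denominator.offsets):
        raise ValueError("profiles must share offsets")
    den = denominator.values
    if (den < eps).any():
        logger.warning("ratio_profile: flooring %d denominator value(s)", int((den < eps).sum()))
        den = np.maximum(den, eps)
    ratio = numerator.values / den
    if edge_normalize:
        n_edge = max(1, int(len(ratio) * edge_fraction / 2))
        edge_mean = np.concatenate([ratio[:n_edge], ratio[-n_edge:]]).mean()
        ratio = ratio / edge_mean
    return Profile(numerator.offsets, ratio, numerator.n_anchors)
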