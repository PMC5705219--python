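"""Chance-corrected overlap statistics between genomic feature sets.

When n query points (e.g. peak centers) are compared with t target
intervals of widths w_i on a genome of size g, the expected number of
chance overlaps is

    c = sum_i [ 1 - ((g - w_i) / g)^n ],

each term being the probability that at least one of n uniform points
lands in an interval of width w_i.  Given f observed overlaps, the
systematic (chance-corrected) overlap fraction o/t solves

    (1 - f/t) = (1 - o/t)(1 - c/t)   =>   o/t = 1 - (1 - f/t)/(1 - c/t),

valid only when chance overlaps are fewer than total overlaps.  For
interval-vs-interval comparisons the chance term is estimated empirically
by randomly shifting one interval set (uniformly in +-shift_range per
interval) and counting the overlaps that remain.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .genome import GenomeIndex, IntervalSet

__all__ = [
    "OverlapSummary",
    "expected_chance_overlaps",
    "corrected_overlap_fraction",
    "count_point_overlaps",
    "shift_chance_overlaps",
    "summarize_overlap",
]


@dataclass
class OverlapSummary:
    n: int  # query points
    t: int  # target intervals
    f: float  # observed overlap count
    c: float  # expected chance overlap count
    g: int  # genome size, bp
    corrected: float  # o/t
    valid: bool  # c < f and c < t


def expected_chance_overlaps(
    widths: np.ndarray | list[int], n: int, g: int
) -> float:
    """Closed-form expected chance overlaps c = sum_i 1 - ((g-w_i)/g)^n.

    Evaluated as -expm1(n * log1p(-w_i/g)) for stability at large n.
    """
    w = np.asarray(widths, dtype=np.float64)
    if n < 0:
        raise ValueError("n must be non-negative")
    if np.any(w > g):
        raise ValueError("interval width exceeds genome size")
    if n == 0 or len(w) == 0:
        return 0.0
    # w == g hits log1p(-1); the overlap probability is exactly 1 there
    with np.errstate(divide="ignore"):
        per = -np.expm1(n * np.log1p(-w / g))
    per = np.where(w == g, 1.0, per)
    return float(per.sum())


def corrected_overlap_fraction(f: float, c: float, t: float) -> tuple[float, bool]:
    """Corrected overlap fraction o/t = 1 - (1 - f/t)/(1 - c/t).

    Returns (o/t, valid); the result is flagged unreliable when chance
    overlaps are not fewer than observed overlaps.  c >= t is an error
    (the correction is undefined).
    """
    if t <= 0:
        raise ValueError("t must be positive")
    if c >= t:
        raise ValueError("chance overlaps >= number of targets; correction undefined")
    o_t = 1.0 - (1.0 - f / t) / (1.0 - c / t)
    return float(o_t), bool(c < f)


def count_point_overlaps(points: IntervalSet, targets: IntervalSet) -> int:
    """Number of target intervals containing at least one query point
    (query intervals are reduced to their start positions; use single-base
    intervals for peak centers)."""
    count = 0
    for chrom in np.unique(targets.chroms):
        p = np.sort(points.starts[points.chroms == chrom])
        mask = targets.chroms == chrom
        s, e = targets.starts[mask], targets.ends[mask]
        # a target [s, e) is hit iff some point lies in it
        left = np.searchsorted(p, s, side="left")
        right = np.searchsorted(p, e, side="left")
        count += int((right > left).sum())
    return count


def shift_chance_overlaps(
    set_a: IntervalSet,
    set_b: IntervalSet,
    genome: GenomeIndex,
    shift_range: int = 60_000,
    reps: int = 100,
    seed: int = 0,
    per_set: bool = False,
) -> tuple[float, float]:
    """Chance overlap estimate by random shifting.

    Per repetition, every interval of ``set_b`` is displaced by a uniform
    draw in [-shift_range, shift_range] (one draw per interval by default;
    one shared draw per repetition with ``per_set=True``); shifted intervals
    that leave their sequence are discarded for that repetition; the number
    of ``set_b`` intervals overlapped by >= 1 ``set_a`` interval is counted.
    Returns (mean overlap count, standard error over repetitions).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    counts = np.empty(reps)
    lengths = {name: genome.length_of(name) for name in np.unique(set_b.chroms)}
    for rep in range(reps):
        if per_set:
            delta = np.full(len(set_b), rng.integers(-shift_range, shift_range + 1))
        else:
            delta = rng.integers(-shift_range, shift_range + 1, size=len(set_b))
        s = set_b.starts + delta
        e = set_b.ends + delta
        limits = np.array([lengths[c] for c in set_b.chroms])
        ok = (s >= 0) & (e <= limits)
        counts[rep] = _interval_overlap_count(
            set_a, set_b.chroms[ok], s[ok], e[ok]
        )
    se = float(counts.std(ddof=1) / np.sqrt(reps)) if reps > 1 else 0.0
    return float(counts.mean()), se


def _interval_overlap_count(
    set_a: IntervalSet, chroms: np.ndarray, starts: np.ndarray, ends: np.ndarray
) -> int:
    """Number of (chroms, starts, ends) intervals intersected by >= 1
    interval of set_a."""
    total = 0
    for chrom in np.unique(chroms):
        am = set_a.chroms == chrom
        if not am.any():
            continue
        a_s = set_a.starts[am]
        a_e = set_a.ends[am]
        order = np.argsort(a_s)
        a_s, a_e = a_s[order], a_e[order]
        cummax_e = np.maximum.accumulate(a_e)
        m = chroms == chrom
        s, e = starts[m], ends[m]
        # overlap iff exists a interval with a_s < e and a_e > s
        idx = np.searchsorted(a_s, e, side="left")  # intervals with a_s < e
        has = (idx > 0) & (cummax_e[np.maximum(idx - 1, 0)] > s)
        total += int(has.sum())
    return total


def summarize_overlap(
    points: IntervalSet,
    targets: IntervalSet,
    g: int,
) -> OverlapSummary:
    """End-to-end point-vs-interval summary with the analytic chance term."""
    n = len(points)
    t = len(targets)
    f = count_point_overlaps(points, targets)
    c = expected_chance_overlaps(targets.widths, n, g)
    o_t, valid = corrected_overlap_fraction(f, c, t)
    return OverlapSummary(
        n=n, t=t, f=float(f), c=c, g=g, corrected=o_t, valid=valid and c < t
    )
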