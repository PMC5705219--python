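"""Likelihood-based ChIP-seq peak calling against a local background.

Model: at a base with local background rate ``b`` (expected input-scale
fragments per base, estimated from the total-chromatin control) and
per-sample scale factors ``r_s`` (sample depth / input depth), replicate
counts are

    x_s ~ Poisson(r_s * b * (1 + e)),   e >= 0 shared across replicates.

The enrichment MLE has the closed form

    e_hat = max(0, (x_1 + x_2) / ((r_1 + r_2) * b) - 1),

i.e. estimated signal divided by background, minus 1, floored at 0.  The
one-sided test of e > 0 uses the likelihood-ratio statistic with the
boundary mixture (1/2)delta_0 + (1/2)chi2_1, so p = (1/2) P(chi2_1 >= LRT)
when the statistic is positive and 1 otherwise.  95% confidence intervals
for e are profile-likelihood intervals at a drop of 3.84, truncated at 0.

Peaks are maximal runs of bases with p below the calling threshold
(default 1e-6), merged across gaps of up to 250 bp; the peak center is the
base with the smallest p-value (leftmost on ties) and the reported
enrichment, CI and counts are taken at the center.  Fixed intervals can be
force-called: the same test applied to window-summed counts, flagged
undefined when the window holds too few input reads.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import chi2

from .genome import CoverageTrack, FragmentSet, IntervalSet

logger = logging.getLogger(__name__)

__all__ = [
    "BackgroundEstimate",
    "Peak",
    "ForceCallResult",
    "estimate_background",
    "base_test",
    "poisson_lrt",
    "profile_ci",
    "call_peaks",
    "force_call",
    "pseudo_replicates",
    "filter_peaks_for_motifs",
    "peaks_to_frame",
    "write_peaks",
]

CHI2_95 = 3.841458820694124  # chi2_1 95% quantile; profile-CI drop


@dataclass
class BackgroundEstimate:
    """Windowed per-base background rate plus per-sample scale factors."""

    rates: dict[str, np.ndarray]  # per-sequence b arrays
    window: int
    scale_factors: tuple[float, ...]  # r_s = sample total / input total


def estimate_background(
    input_track: CoverageTrack,
    window: int = 10_000,
    sample_totals: tuple[float, ...] = (),
) -> BackgroundEstimate:
    """Background rate b at base i = mean input coverage in the ``window``-bp
    window centered on i (truncated at sequence edges).

    A plain window mean absorbs regional coverage multipliers (aneuploidy)
    at scales above the window.  All-zero stretches are floored at the
    pseudocount 0.5 / window so the likelihood is defined everywhere.
    """
    if window < 1_000:
        raise ValueError("background window must be >= 1,000 bp")
    floor = 0.5 / window
    rates = {}
    for name, vals in input_track.values.items():
        n = len(vals)
        half = window // 2
        cum = np.concatenate(([0.0], np.cumsum(vals)))
        idx = np.arange(n)
        lo = np.maximum(idx - half, 0)
        hi = np.minimum(idx + half + 1, n)
        b = (cum[hi] - cum[lo]) / (hi - lo)
        if not vals.any():
            logger.warning("all-zero input coverage on %s; flooring background", name)
        b = np.maximum(b, floor)
        rates[name] = b
    input_total = max(input_track.total_fragments, 1)
    scales = tuple(t / input_total for t in sample_totals)
    return BackgroundEstimate(rates=rates, window=window, scale_factors=scales)


def poisson_lrt(
    counts: np.ndarray, scaled_background: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized shared-enrichment Poisson LRT.

    ``counts``: total observed count X (summed over replicates);
    ``scaled_background``: R*b = sum over replicates of r_s * b.
    Returns (e_hat, LRT statistic, one-sided boundary p-value).
    """
    X = np.asarray(counts, dtype=np.float64)
    Rb = np.asarray(scaled_background, dtype=np.float64)
    if np.any(Rb <= 0):
        raise ValueError("background must be positive; floor it first")
    e_hat = np.maximum(0.0, X / Rb - 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = 2.0 * (X * np.log1p(e_hat) - Rb * e_hat)
    lam = np.where(e_hat > 0, lam, 0.0)
    p = np.where(lam > 0, 0.5 * chi2.sf(lam, df=1), 1.0)
    return e_hat, lam, p


def profile_ci(X: float, Rb: float, e_hat: float) -> tuple[float, float]:
    """Profile-likelihood 95% CI for e: the set where the log-likelihood is
    within 3.84/2 of its maximum, truncated at e >= 0."""

    def drop(e: float) -> float:
        # 2*(l(e_hat) - l(e)) - 3.84, negative inside the interval
        le = X * math.log1p(e) - Rb * e
        lh = X * math.log1p(e_hat) - Rb * e_hat
        return 2.0 * (lh - le) - CHI2_95

    if drop(0.0) <= 0:
        lo = 0.0
    else:
        lo = brentq(drop, 0.0, e_hat, xtol=1e-10)
    hi = e_hat if e_hat > 0 else 0.0
    step = max(1.0, e_hat)
    upper = hi + step
    while drop(upper) <= 0:
        upper += step
        step *= 2
    hi = brentq(drop, max(hi, 1e-12), upper, xtol=1e-10)
    return float(lo), float(hi)


def base_test(
    x1: float, x2: float, b: float, r1: float = 1.0, r2: float = 1.0
) -> tuple[float, float, tuple[float, float]]:
    """Single-base test: returns (p-value, enrichment e_hat, 95% CI)."""
    if b <= 0:
        raise ValueError("background must be positive")
    X = x1 + x2
    Rb = (r1 + r2) * b
    e_hat, _, p = poisson_lrt(np.array([X]), np.array([Rb]))
    ci = profile_ci(X, Rb, float(e_hat[0]))
    return float(p[0]), float(e_hat[0]), ci


@dataclass
class Peak:
    """A called binding event; enrichment and CI evaluated at the center."""

    chrom: str
    start: int
    end: int
    center: int
    p: float
    enrichment: float
    ci_lo: float
    ci_hi: float
    x1: float
    x2: float
    y: float  # input coverage at center

    @property
    def ci_width(self) -> float:
        return self.ci_hi - self.ci_lo


def _merge_runs(positions: np.ndarray, gap: int) -> list[tuple[int, int]]:
    """Merge sorted significant positions into [start, end) runs allowing
    gaps of up to ``gap`` bases."""
    if len(positions) == 0:
        return []
    breaks = np.flatnonzero(np.diff(positions) > gap)
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(positions) - 1]))
    return [(int(positions[s]), int(positions[e]) + 1) for s, e in zip(starts, ends)]


def call_peaks(
    rep1: CoverageTrack,
    rep2: CoverageTrack,
    input_track: CoverageTrack,
    alpha: float = 1e-6,
    window: int = 10_000,
    merge_gap: int = 250,
) -> list[Peak]:
    """Call peaks as runs of bases with p < alpha (merged across gaps of up
    to ``merge_gap`` bp); the center is the smallest-p base, leftmost on
    ties, and enrichment/CI/counts are reported at the center."""
    bg = estimate_background(
        input_track,
        window,
        sample_totals=(rep1.total_fragments, rep2.total_fragments),
    )
    r1, r2 = bg.scale_factors
    peaks: list[Peak] = []
    for name in input_track.genome.names:
        x1 = rep1.values[name]
        x2 = rep2.values[name]
        b = bg.rates[name]
        X = x1 + x2
        Rb = (r1 + r2) * b
        _, _, p = poisson_lrt(X, Rb)
        sig = np.flatnonzero(p < alpha)
        for start, end in _merge_runs(sig, merge_gap):
            center = start + int(np.argmin(p[start:end]))
            e_hat = max(0.0, X[center] / Rb[center] - 1.0)
            ci = profile_ci(float(X[center]), float(Rb[center]), e_hat)
            peaks.append(
                Peak(
                    chrom=name,
                    start=start,
                    end=end,
                    center=center,
                    p=float(p[center]),
                    enrichment=e_hat,
                    ci_lo=ci[0],
                    ci_hi=ci[1],
                    x1=float(x1[center]),
                    x2=float(x2[center]),
                    y=float(input_track.values[name][center]),
                )
            )
    return peaks


@dataclass
class ForceCallResult:
    """Enrichment test of a sample in a fixed window."""

    chrom: str
    start: int
    end: int
    p: float
    enrichment: float
    input_reads: float
    defined: bool  # False when input reads in the window are too few


def force_call(
    intervals: IntervalSet,
    sample: CoverageTrack,
    input_track: CoverageTrack,
    window: int = 1_000,
    min_input_reads: float = 5.0,
    bg_window: int = 10_000,
) -> list[ForceCallResult]:
    """Force-call each interval: the Poisson LRT on counts summed over the
    ``window``-bp window centered on the interval midpoint.

    Input reads in the window are estimated as input coverage mass divided
    by the input's mean fragment length; results with <= ``min_input_reads``
    are flagged undefined.
    """
    bg = estimate_background(
        input_track, bg_window, sample_totals=(sample.total_fragments,)
    )
    r = bg.scale_factors[0]
    inp_mass = input_track.total_mass()
    mean_insert = inp_mass / max(input_track.total_fragments, 1)
    out: list[ForceCallResult] = []
    for chrom, s, e, _, _ in intervals.iter_records():
        if chrom not in sample.genome:
            raise ValueError(f"interval on unknown sequence {chrom!r}")
        n = sample.genome.length_of(chrom)
        if s < 0 or e > n:
            raise ValueError("interval outside genome")
        mid = (s + e) // 2
        lo = max(0, mid - window // 2)
        hi = min(n, mid + window // 2)
        X = float(sample.values[chrom][lo:hi].sum())
        Rb = r * float(bg.rates[chrom][lo:hi].sum())
        _, _, p = poisson_lrt(np.array([X]), np.array([Rb]))
        e_hat = max(0.0, X / Rb - 1.0)
        y_mass = float(input_track.values[chrom][lo:hi].sum())
        reads = y_mass / mean_insert if mean_insert > 0 else 0.0
        out.append(
            ForceCallResult(
                chrom=chrom,
                start=lo,
                end=hi,
                p=float(p[0]),
                enrichment=e_hat,
                input_reads=reads,
                defined=reads > min_input_reads,
            )
        )
    return out


def pseudo_replicates(
    frags: FragmentSet, seed: int
) -> tuple[FragmentSet, FragmentSet]:
    """Split a fragment set into two pseudo-replicates by a fair coin per
    fragment.  The union of the halves is the input set."""
    if len(frags) < 2:
        raise ValueError("need at least 2 fragments to split")
    rng = np.random.default_rng(seed)
    coin = rng.random(len(frags)) < 0.5
    return frags.subset(coin), frags.subset(~coin)


def filter_peaks_for_motifs(
    peaks: list[Peak],
    repeats: IntervalSet | None = None,
    max_p: float = 1e-10,
    min_enrichment: float = 2.0,
    max_ci_width: float = 50.0,
    min_chip_reads: float = 30.0,
    input_percentiles: tuple[float, float] = (10.0, 90.0),
    top_n: int = 5_000,
) -> list[Peak]:
    """Stringent selection of peaks for de novo motif finding.

    Applies the six criteria: p below ``max_p``; enrichment above
    ``min_enrichment``; enrichment-CI width at most ``max_ci_width``; no
    bases overlapping annotated repeats; input coverage at the center
    between the 10th and 90th percentile of the peak set; and at least
    ``min_chip_reads`` summed over the two ChIP replicates.  Survivors are
    ranked by enrichment and the top ``top_n`` retained.
    """
    if not peaks:
        return []
    y = np.array([pk.y for pk in peaks])
    lo, hi = np.percentile(y, input_percentiles)
    kept = []
    for pk in peaks:
        if pk.p >= max_p:
            continue
        if pk.enrichment <= min_enrichment:
            continue
        if pk.ci_width > max_ci_width:
            continue
        if pk.x1 + pk.x2 < min_chip_reads:
            continue
        if not (lo <= pk.y <= hi):
            continue
        if repeats is not None and _overlaps_any(pk, repeats):
            continue
        kept.append(pk)
    kept.sort(key=lambda pk: -pk.enrichment)
    return kept[:top_n]


def _overlaps_any(pk: Peak, ivals: IntervalSet) -> bool:
    mask = ivals.chroms == pk.chrom
    if not mask.any():
        return False
    s = ivals.starts[mask]
    e = ivals.ends[mask]
    return bool(np.any((s < pk.end) & (e > pk.start)))


def peaks_to_frame(peaks: list[Peak]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": pk.chrom,
                "start": pk.start,
                "end": pk.end,
                "center": pk.center,
                "p": pk.p,
                "E": pk.enrichment,
                "E_lo": pk.ci_lo,
                "E_hi": pk.ci_hi,
                "x1": pk.x1,
                "x2": pk.x2,
                "y": pk.y,
            }
            for pk in peaks
        ],
        columns=["chrom", "start", "end", "center", "p", "E", "E_lo", "E_hi", "x1", "x2", "y"],
    )


def write_peaks(peaks: list[Peak], path) -> None:
    df = peaks_to_frame(peaks)
    with open(path, "w") as fh:
        fh.write("# " + "\t".join(df.columns) + "\n")
        df.to_csv(fh, sep="\t", header=False, index=False)
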