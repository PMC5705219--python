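"""De novo motif discovery by an EM-fitted Bayesian mixture of PWMs.

Peak-centered sequences are modeled as draws from a mixture: with weight
``pi_0`` a sequence is pure background (an order-1 Markov chain fitted to
all input sequences), and with weight ``pi_k`` it carries exactly one
occurrence of motif *k* at a uniformly distributed start position on either
strand, the motif window's likelihood contribution replaced by the PWM
column probabilities (zero-or-one occurrence model).

Discovery proceeds in two stages.  *Seeding*: count all 10-mers (both
strands, collapsed to canonical form), take the top 50 by frequency, pick
the one most over-represented in the central 100 bp, soft-convert it to a
PWM (0.7 on the seed base, 0.1 elsewhere), refine it alone for 100 EM
iterations, then remove the sequences it matches (posterior > 0.5) and
repeat, up to 20 seeds.  *Joint refinement*: all surviving motifs are
refined together on the full sequence set for 200 iterations.  During
refinement a one-column extension on either flank is proposed every 10
iterations and accepted when the new column's expected information content
exceeds 0.05 bits.  Final motifs are filtered for centrality (>= 85% of
matches in the central 100 bp) and against degeneracy (mean information
content of the best 8-column window >= 0.5 bits).  Frozen models can be
force-scanned: a single E-step per sequence, reporting the best match with
posterior >= 0.75.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "MotifMixtureModel",
    "extract_peak_sequences",
    "fit_background",
    "seed_motif",
    "refine_motif",
    "discover_motifs",
    "filter_motifs",
    "force_scan",
    "information_content",
    "write_meme",
    "read_meme",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
PSEUDOCOUNT = 0.5  # Dirichlet pseudocount for PWM column updates
SEED_MATCH_P = 0.7  # soft probability on the seed base
DROP_WEIGHT = 1e-4  # motifs whose mixture weight falls below this are dropped
EXTEND_IC_BITS = 0.05  # flank-extension acceptance threshold
EXTEND_EVERY = 10
MAX_MOTIF_LEN = 26


def encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8).copy().view(np.uint8)


_LUT = np.full(256, -1, dtype=np.int8)
for _b, _i in _BASE_INDEX.items():
    _LUT[ord(_b)] = _i


def encode_sequences(seqs: list[str]) -> list[np.ndarray]:
    out = []
    for s in seqs:
        arr = _LUT[np.frombuffer(s.upper().encode(), dtype=np.uint8)]
        if (arr < 0).any():
            raise ValueError("sequence contains non-ACGT characters")
        out.append(arr.astype(np.int8))
    return out


def revcomp_pwm(pwm: np.ndarray) -> np.ndarray:
    return pwm[::-1, ::-1]


def information_content(pwm: np.ndarray) -> np.ndarray:
    """Per-column information content in bits relative to uniform."""
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(pwm > 0, pwm * np.log2(pwm), 0.0)
    return 2.0 + term.sum(axis=1)


@dataclass
class MotifMixtureModel:
    """K PWMs with mixture weights and an order-1 Markov background."""

    pwms: list[np.ndarray]
    weights: np.ndarray  # pi_1..pi_K
    bg_weight: float  # pi_0
    bg_init: np.ndarray  # stationary base probabilities (4,)
    bg_trans: np.ndarray  # transition matrix (4, 4), rows sum to 1
    names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if not self.names:
            self.names = [f"motif_{i + 1}" for i in range(len(self.pwms))]
        total = self.bg_weight + self.weights.sum()
        if abs(total - 1.0) > 1e-6:
            raise ValueError("mixture weights must sum to 1")

    @property
    def n_motifs(self) -> int:
        return len(self.pwms)


def fit_background(seq_arrays: list[np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    """Order-1 Markov background fitted to all sequences (pseudocount 1)."""
    init = np.ones(4)
    trans = np.ones((4, 4))
    for s in seq_arrays:
        init += np.bincount(s, minlength=4)
        if len(s) > 1:
            pairs = s[:-1].astype(np.int64) * 4 + s[1:]
            trans += np.bincount(pairs, minlength=16).reshape(4, 4)
    init /= init.sum()
    trans /= trans.sum(axis=1, keepdims=True)
    return init, trans


def extract_peak_sequences(
    centers: list[tuple[str, int]],
    genome_seqs: dict[str, str],
    width: int = 300,
) -> tuple[list[str], list[int]]:
    """Extract ``width``-bp sequences centered on peak centers.

    Returns (sequences, kept_indices).  Windows running off a sequence end
    and windows containing N are excluded; counts are logged.
    """
    half = width // 2
    out: list[str] = []
    kept: list[int] = []
    n_edge = n_amb = 0
    for i, (chrom, center) in enumerate(centers):
        seq = genome_seqs[chrom]
        lo, hi = center - half, center - half + width
        if lo < 0 or hi > len(seq):
            n_edge += 1
            continue
        sub = seq[lo:hi].upper()
        if any(c not in "ACGT" for c in sub):
            n_amb += 1
            continue
        out.append(sub)
        kept.append(i)
    if n_edge or n_amb:
        logger.info(
            "extract_peak_sequences: skipped %d edge window(s), %d with ambiguous bases",
            n_edge,
            n_amb,
        )
    return out, kept


# ---------------------------------------------------------------------------
# seeding


def _kmer_codes(arr: np.ndarray, k: int) -> np.ndarray:
    """Integer codes of all k-mers of one encoded sequence (base-4)."""
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    codes = np.zeros(n, dtype=np.int64)
    for c in range(k):
        codes = codes * 4 + arr[c : c + n]
    return codes


def _rc_code(codes: np.ndarray, k: int) -> np.ndarray:
    """Reverse-complement of base-4 k-mer codes."""
    rc = np.zeros_like(codes)
    tmp = codes.copy()
    for _ in range(k):
        rc = rc * 4 + (3 - (tmp % 4))
        tmp //= 4
    return rc


def _code_to_kmer(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


def seed_motif(sequences: list[str], k: int = 10, top: int = 50) -> np.ndarray:
    """Pick the seeding k-mer and soft-convert it to a PWM.

    Counts all k-mers on both strands collapsed to canonical form; among the
    ``top`` most frequent, chooses the one whose occurrences are most
    over-represented in the central 100 bp (start positions), the ratio
    normalized by 100 / (L - k + 1); converts the winner to a k-column PWM
    with probability 0.7 on the seed base and 0.1 elsewhere.
    """
    if len(sequences) < 100:
        raise ValueError("need at least 100 sequences to seed a motif")
    arrs = encode_sequences(sequences)
    all_canon = []
    centrals = []
    for a in arrs:
        codes = _kmer_codes(a, k)
        canon = np.minimum(codes, _rc_code(codes, k))
        all_canon.append(canon)
        L = len(a)
        c0 = L // 2 - 50
        central = np.zeros(len(canon), dtype=bool)
        central[max(0, c0) : min(len(canon), c0 + 100)] = True
        centrals.append(central)
    canon_cat = np.concatenate(all_canon)
    central_cat = np.concatenate(centrals)
    uniq, counts = np.unique(canon_cat, return_counts=True)
    order = np.argsort(-counts, kind="stable")
    top_codes = uniq[order[:top]]
    best_code, best_ratio = None, -np.inf
    npos_mean = np.mean([len(c) for c in all_canon])
    expected = 100.0 / npos_mean
    for code in top_codes:
        mask = canon_cat == code
        frac_central = central_cat[mask].mean()
        ratio = frac_central / expected
        if ratio > best_ratio:
            best_ratio, best_code = ratio, int(code)
    kmer = _code_to_kmer(best_code, k)
    pwm = np.full((k, 4), (1.0 - SEED_MATCH_P) / 3.0)
    for i, bchar in enumerate(kmer):
        pwm[i] = (1.0 - SEED_MATCH_P) / 3.0
        pwm[i, _BASE_INDEX[bchar]] = SEED_MATCH_P
    return pwm


# ---------------------------------------------------------------------------
# E-step machinery


class _Batch:
    """Sequences of equal length stacked into one matrix, with background
    log-factor cumulative sums precomputed."""

    def __init__(self, arrs: list[np.ndarray], indices: list[int], model: MotifMixtureModel):
        self.S = np.stack(arrs).astype(np.int64)
        self.indices = np.array(indices)
        n, L = self.S.shape
        logfac = np.empty((n, L))
        logfac[:, 0] = np.log(model.bg_init)[self.S[:, 0]]
        if L > 1:
            lt = np.log(model.bg_trans)
            logfac[:, 1:] = lt[self.S[:, :-1], self.S[:, 1:]]
        self.bgcum = np.concatenate(
            [np.zeros((n, 1)), np.cumsum(logfac, axis=1)], axis=1
        )

    @property
    def n(self) -> int:
        return self.S.shape[0]

    @property
    def L(self) -> int:
        return self.S.shape[1]


def _make_batches(arrs: list[np.ndarray], model: MotifMixtureModel) -> list[_Batch]:
    by_len: dict[int, tuple[list[np.ndarray], list[int]]] = {}
    for i, a in enumerate(arrs):
        by_len.setdefault(len(a), ([], []))
        by_len[len(a)][0].append(a)
        by_len[len(a)][1].append(i)
    return [_Batch(v[0], v[1], model) for _, v in sorted(by_len.items())]


def _window_scores(batch: _Batch, logpwm: np.ndarray) -> np.ndarray:
    """log PWM probability of every window: (n, npos) matrix."""
    Lm = logpwm.shape[0]
    npos = batch.L - Lm + 1
    scores = np.zeros((batch.n, npos))
    for c in range(Lm):
        scores += logpwm[c][batch.S[:, c : c + npos]]
    return scores


def _motif_log_weights(
    batch: _Batch, pwm: np.ndarray, weight: float
) -> tuple[np.ndarray, np.ndarray] | None:
    """Per-placement log posterior weights (fwd, rev), each (n, npos):
    log pi_k - log(2*npos) + log PWM(window) - log bg(window)."""
    Lm = len(pwm)
    npos = batch.L - Lm + 1
    if npos < 1 or weight <= 0:
        return None
    logpwm = np.log(pwm)
    bgwin = batch.bgcum[:, Lm:] - batch.bgcum[:, :-Lm]
    const = math.log(weight) - math.log(2 * npos)
    fwd = _window_scores(batch, logpwm) - bgwin + const
    rev = _window_scores(batch, np.log(revcomp_pwm(pwm))) - bgwin + const
    return fwd, rev


def _e_step(
    batches: list[_Batch], model: MotifMixtureModel
) -> tuple[float, np.ndarray, list[list[tuple[np.ndarray, np.ndarray] | None]]]:
    """Returns (log-likelihood up to the constant background term,
    per-sequence x per-motif posterior gamma, normalized placement
    responsibilities per batch per motif)."""
    n_total = sum(b.n for b in batches)
    K = model.n_motifs
    gamma = np.zeros((n_total, K))
    resp: list[list[tuple[np.ndarray, np.ndarray] | None]] = []
    ll = 0.0
    log_pi0 = math.log(model.bg_weight) if model.bg_weight > 0 else -np.inf
    for batch in batches:
        lws = [
            _motif_log_weights(batch, model.pwms[k], float(model.weights[k]))
            for k in range(K)
        ]
        # per-sequence max over background and all placements, for stability
        m = np.full(batch.n, log_pi0)
        for lw in lws:
            if lw is None:
                continue
            m = np.maximum(m, lw[0].max(axis=1))
            m = np.maximum(m, lw[1].max(axis=1))
        tot = np.exp(log_pi0 - m)
        sums = []
        for lw in lws:
            if lw is None:
                sums.append(None)
                continue
            wf = np.exp(lw[0] - m[:, None])
            wr = np.exp(lw[1] - m[:, None])
            sums.append((wf, wr))
            tot = tot + wf.sum(axis=1) + wr.sum(axis=1)
        ll += float((m + np.log(tot)).sum())
        batch_resp: list[tuple[np.ndarray, np.ndarray] | None] = []
        for k, s in enumerate(sums):
            if s is None:
                batch_resp.append(None)
                continue
            rf = s[0] / tot[:, None]
            rr = s[1] / tot[:, None]
            gamma[batch.indices, k] = rf.sum(axis=1) + rr.sum(axis=1)
            batch_resp.append((rf, rr))
        resp.append(batch_resp)
    return ll, gamma, resp


def _expected_counts(
    batches: list[_Batch],
    resp: list[list[tuple[np.ndarray, np.ndarray] | None]],
    k: int,
    Lm: int,
    offset_lo: int = 0,
    offset_hi: int | None = None,
) -> np.ndarray:
    """Expected base counts per PWM column (columns offset_lo..offset_hi of a
    length-``Lm`` motif; offsets outside [0, Lm) address flank columns)."""
    if offset_hi is None:
        offset_hi = Lm
    ncol = offset_hi - offset_lo
    counts = np.zeros((ncol, 4))
    for batch, batch_resp in zip(batches, resp):
        r = batch_resp[k]
        if r is None:
            continue
        rf, rr = r
        npos = rf.shape[1]
        for ci, c in enumerate(range(offset_lo, offset_hi)):
            # forward placements: PWM column c reads genome offset j + c
            lo, hi = c, c + npos
            if lo >= 0 and hi <= batch.L:
                seg = batch.S[:, lo:hi]
                w = rf
                if lo < 0:
                    pass
                counts[ci] += np.bincount(
                    seg.ravel(), weights=w.ravel(), minlength=4
                )[:4]
            elif 0 <= lo + 1 and hi <= batch.L + 1:
                # column off the edge for some placements: restrict j range
                jlo = max(0, -c)
                jhi = min(npos, batch.L - c)
                if jlo < jhi:
                    seg = batch.S[:, c + jlo : c + jhi]
                    counts[ci] += np.bincount(
                        seg.ravel(), weights=rf[:, jlo:jhi].ravel(), minlength=4
                    )[:4]
            # reverse placements: PWM column c reads the complement of genome
            # offset j + (Lm - 1 - c)
            cc = Lm - 1 - c
            jlo = max(0, -cc)
            jhi = min(npos, batch.L - cc)
            if jlo < jhi:
                seg = 3 - batch.S[:, cc + jlo : cc + jhi]
                counts[ci] += np.bincount(
                    seg.ravel(), weights=rr[:, jlo:jhi].ravel(), minlength=4
                )[:4]
    return counts


def _m_step(
    batches: list[_Batch],
    resp: list[list[tuple[np.ndarray, np.ndarray] | None]],
    gamma: np.ndarray,
    model: MotifMixtureModel,
) -> None:
    n_total = gamma.shape[0]
    for k in range(model.n_motifs):
        Lm = len(model.pwms[k])
        counts = _expected_counts(batches, resp, k, Lm) + PSEUDOCOUNT
        model.pwms[k] = counts / counts.sum(axis=1, keepdims=True)
    model.weights = gamma.sum(axis=0) / n_total
    model.bg_weight = max(1.0 - model.weights.sum(), 0.0)


def _try_extend(
    batches: list[_Batch],
    resp: list[list[tuple[np.ndarray, np.ndarray] | None]],
    model: MotifMixtureModel,
) -> bool:
    """Propose a one-column extension on each flank of each motif; accept
    when the candidate column's expected information content exceeds the
    threshold.  Returns True if any motif grew."""
    grew = False
    for k in range(model.n_motifs):
        Lm = len(model.pwms[k])
        if Lm >= MAX_MOTIF_LEN:
            continue
        for side, off in (("left", -1), ("right", Lm)):
            counts = _expected_counts(batches, resp, k, Lm, off, off + 1)[0]
            if counts.sum() <= 0:
                continue
            p = (counts + PSEUDOCOUNT) / (counts.sum() + 4 * PSEUDOCOUNT)
            ic = 2.0 + float(np.where(p > 0, p * np.log2(p), 0.0).sum())
            if ic > EXTEND_IC_BITS:
                col = p[None, :]
                if side == "left":
                    model.pwms[k] = np.vstack([col, model.pwms[k]])
                else:
                    model.pwms[k] = np.vstack([model.pwms[k], col])
                Lm += 1
                grew = True
                if Lm >= MAX_MOTIF_LEN:
                    break
    return grew


def _run_em(
    model: MotifMixtureModel,
    arrs: list[np.ndarray],
    iters: int,
    extend: bool = True,
    update: bool = True,
) -> tuple[MotifMixtureModel, list[float]]:
    batches = _make_batches(arrs, model)
    ll_trace: list[float] = []
    for it in range(iters):
        ll, gamma, resp = _e_step(batches, model)
        ll_trace.append(ll)
        if not update:
            break
        _m_step(batches, resp, gamma, model)
        # drop collapsed motifs
        alive = model.weights >= DROP_WEIGHT
        if not alive.all():
            for i in np.flatnonzero(~alive):
                logger.info("dropping motif %s (weight %.2g)", model.names[i], model.weights[i])
            model.pwms = [p for p, a in zip(model.pwms, alive) if a]
            model.names = [nm for nm, a in zip(model.names, alive) if a]
            lost = float(model.weights[~alive].sum())
            model.weights = model.weights[alive]
            model.bg_weight += lost
            if model.n_motifs == 0:
                break
        if extend and (it + 1) % EXTEND_EVERY == 0 and it + 1 < iters:
            _try_extend(batches, resp, model)
    return model, ll_trace


def refine_motif(
    model: MotifMixtureModel, sequences: list[str], iters: int = 100
) -> tuple[MotifMixtureModel, list[float]]:
    """Refine a (usually single-PWM) mixture by EM for ``iters`` iterations.

    Returns the refined model and the per-iteration observed-data
    log-likelihood trace (up to the constant full-background term), which
    is non-decreasing between extension points.
    """
    arrs = encode_sequences(sequences)
    return _run_em(model, arrs, iters, extend=True, update=True)


def _new_model(
    pwms: list[np.ndarray],
    bg: tuple[np.ndarray, np.ndarray],
    motif_weight: float = 0.5,
    names: list[str] | None = None,
) -> MotifMixtureModel:
    K = len(pwms)
    w = np.full(K, motif_weight / max(K, 1))
    return MotifMixtureModel(
        pwms=[p.copy() for p in pwms],
        weights=w,
        bg_weight=1.0 - w.sum(),
        bg_init=bg[0],
        bg_trans=bg[1],
        names=list(names) if names else [],
    )


def discover_motifs(
    sequences: list[str],
    max_seeds: int = 20,
    seed_iters: int = 100,
    joint_iters: int = 200,
    removal_posterior: float = 0.5,
    rng_seed: int = 0,
) -> MotifMixtureModel:
    """Full discovery: iterative seeding with sequence removal, then joint
    refinement of all surviving motifs on the full sequence set.

    ``rng_seed`` is recorded for provenance; the procedure itself is
    deterministic given the input sequences (ties in seeding and EM are
    broken by fixed ordering), so runs with different seeds verify
    consensus rather than explore randomness.
    """
    arrs = encode_sequences(sequences)
    bg = fit_background(arrs)
    remaining = list(sequences)
    found: list[np.ndarray] = []
    for round_i in range(max_seeds):
        if len(remaining) < 100:
            break
        try:
            seed_pwm = seed_motif(remaining)
        except ValueError:
            break
        model = _new_model([seed_pwm], bg, motif_weight=0.5)
        model, _ = _run_em(model, encode_sequences(remaining), seed_iters)
        if model.n_motifs == 0:
            continue
        found.append(model.pwms[0])
        # remove matched sequences (posterior > removal threshold)
        gamma = posterior_match(model, remaining)
        keep = gamma[:, 0] <= removal_posterior
        remaining = [s for s, k in zip(remaining, keep) if k]
        logger.info(
            "seed round %d: motif of length %d, %d sequences remain",
            round_i + 1,
            len(found[-1]),
            len(remaining),
        )
        if not remaining:
            break
    if not found:
        return _new_model([], bg, motif_weight=0.0)
    joint = _new_model(found, bg, motif_weight=0.5)
    joint, _ = _run_em(joint, arrs, joint_iters)
    return joint


def posterior_match(model: MotifMixtureModel, sequences: list[str]) -> np.ndarray:
    """Per-sequence posterior of carrying each motif: (n, K) matrix."""
    arrs = encode_sequences(sequences)
    batches = _make_batches(arrs, model)
    _, gamma, _ = _e_step(batches, model)
    return gamma


def force_scan(
    model: MotifMixtureModel,
    sequences: list[str],
    min_posterior: float = 0.75,
    seq_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Single E-step with frozen motifs; report the best (motif, start,
    strand) per sequence when its placement-summed posterior reaches
    ``min_posterior``.  Offset is the window start on the given strand's
    coordinates (mirrored automatically for minus-strand matches)."""
    if model.n_motifs < 1:
        raise ValueError("model has no motifs")
    if seq_ids is None:
        seq_ids = [f"seq{i}" for i in range(len(sequences))]
    arrs = encode_sequences(sequences)
    batches = _make_batches(arrs, model)
    _, gamma, resp = _e_step(batches, model)
    rows = []
    for batch, batch_resp in zip(batches, resp):
        for bi in range(batch.n):
            i = int(batch.indices[bi])
            k_best = int(np.argmax(gamma[i])) if gamma.shape[1] else 0
            g = float(gamma[i, k_best])
            if g < min_posterior:
                continue
            r = batch_resp[k_best]
            if r is None:
                continue
            rf, rr = r[0][bi], r[1][bi]
            if rf.max() >= rr.max():
                strand, start = "+", int(np.argmax(rf))
            else:
                strand, start = "-", int(np.argmax(rr))
            rows.append(
                {
                    "seq_id": seq_ids[i],
                    "motif": model.names[k_best],
                    "motif_index": k_best,
                    "start": start,
                    "strand": strand,
                    "posterior": g,
                }
            )
    return pd.DataFrame(
        rows, columns=["seq_id", "motif", "motif_index", "start", "strand", "posterior"]
    )


def filter_motifs(
    model: MotifMixtureModel,
    matches: pd.DataFrame,
    seq_length: int = 300,
    min_central: float = 0.85,
    min_ic_bits: float = 0.5,
    ic_window: int = 8,
) -> MotifMixtureModel:
    """Keep motifs with >= ``min_central`` of match midpoints inside the
    central 100 bp and best ``ic_window``-column mean information content of
    at least ``min_ic_bits`` bits; motifs without matches are dropped."""
    c0, c1 = seq_length // 2 - 50, seq_length // 2 + 50
    keep = []
    for k in range(model.n_motifs):
        pwm = model.pwms[k]
        sub = matches[matches["motif_index"] == k]
        if len(sub) == 0:
            continue
        mid = sub["start"].to_numpy() + len(pwm) // 2
        central = float(((mid >= c0) & (mid < c1)).mean())
        ic = information_content(pwm)
        if len(ic) >= ic_window:
            best = max(
                ic[i : i + ic_window].mean() for i in range(len(ic) - ic_window + 1)
            )
        else:
            best = ic.mean()
        if central >= min_central and best >= min_ic_bits:
            keep.append(k)
    pwms = [model.pwms[k] for k in keep]
    names = [model.names[k] for k in keep]
    w = model.weights[keep] if keep else np.zeros(0)
    return MotifMixtureModel(
        pwms=pwms,
        weights=w,
        bg_weight=1.0 - float(w.sum()),
        bg_init=model.bg_init,
        bg_trans=model.bg_trans,
        names=names,
    )


# ---------------------------------------------------------------------------
# MEME minimal motif format


def write_meme(model: MotifMixtureModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(
            "A {:.5f} C {:.5f} G {:.5f} T {:.5f}\n\n".format(*model.bg_init)
        )
        for name, pwm, w in zip(model.names, model.pwms, model.weights):
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                f"nsites= 0 E= 0 # weight {w:.6g}\n"
            )
            for row in pwm:
                fh.write(" ".join(f"{v:.6f}" for v in row) + "\n")
            fh.write("\n")


def read_meme(path: str | Path) -> MotifMixtureModel:
    """Read a minimal MEME motif file into a frozen mixture model (uniform
    weights over motifs, background from the frequency line)."""
    bg_init = np.full(4, 0.25)
    pwms: list[np.ndarray] = []
    names: list[str] = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            bg_init = np.array([float(parts[j]) for j in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            names.append(line.split()[1])
            i += 1
            while not lines[i].strip().startswith("letter-probability"):
                i += 1
            w = int(lines[i].split("w=")[1].split()[0])
            rows = []
            for j in range(w):
                rows.append([float(x) for x in lines[i + 1 + j].split()])
            pwms.append(np.array(rows))
            i += 1 + w
            continue
        i += 1
    K = len(pwms)
    weights = np.full(K, 0.5 / K) if K else np.zeros(0)
    trans = np.tile(bg_init, (4, 1))
    return MotifMixtureModel(
        pwms=pwms,
        weights=weights,
        bg_weight=1.0 - float(weights.sum()),
        bg_init=bg_init,
        bg_trans=trans,
        names=names,
    )
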