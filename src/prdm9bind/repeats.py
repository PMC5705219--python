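"""Repeat-family cis-modifier analysis.

A retrotransposon family (e.g. the 354-bp THE1B element) provides thousands
of nearly identical sequences perturbed by random mutations; regressing a
binary outcome (PRDM9 binding, hotspot formation) on k-mer presence across
copies dissects which short motifs modify the outcome.  The module covers:

* global affine-gap alignment of each copy to the family consensus, giving
  every base a consensus coordinate;
* the binary k-mer presence matrix (default k = 7), each retained k-mer
  annotated with its median consensus start;
* single and conditional logistic association (maximum likelihood, LRT
  p-values, Wald SEs; Firth-penalized fallback under separation);
* greedy forward selection under Bonferroni family-wise control, with
  collapse of shadow k-mers (presence correlation > 0.9 at overlapping
  consensus positions) onto the selected record;
* an additive DNA-based score per copy (sum of selected log-odds-ratios)
  with decile binning;
* the co-binding GLM: per-factor logistic effect of a binary co-binding
  regressor on hotspot probability, reported as log2-odds with 95% CI,
  factors with < 30 co-bound instances excluded.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align
from scipy.stats import chi2

logger = logging.getLogger(__name__)

__all__ = [
    "RepeatCopy",
    "AssociationRecord",
    "AdditiveScore",
    "align_to_consensus",
    "kmer_presence_matrix",
    "logistic_fit",
    "single_association",
    "forward_selection",
    "additive_score",
    "cobinding_glm",
    "woolf_estimates",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class RepeatCopy:
    """One repeat instance aligned to the family consensus."""

    copy_id: str
    chrom: str
    start: int
    end: int
    sequence: str
    consensus_coords: np.ndarray  # per-base consensus coordinate; -1 = insertion
    identity: float  # matching fraction over aligned columns
    usable: bool  # False when the copy is too short / diverged for positions


def align_to_consensus(
    copies: list[dict], consensus: str, min_length_fraction: float = 0.5
) -> list[RepeatCopy]:
    """Global alignment of each copy to the consensus with affine gaps
    (match +1, mismatch -1, open -5, extend -1); the first-reported
    (leftmost-gap) alignment is used on ties.

    Copies shorter than ``min_length_fraction`` of the consensus are
    flagged unusable and excluded from positional reporting.
    """
    if len(consensus) < 50:
        raise ValueError("consensus must be at least 50 bp")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -5
    aligner.extend_gap_score = -1
    out: list[RepeatCopy] = []
    for c in copies:
        seq = c["sequence"]
        usable = len(seq) >= min_length_fraction * len(consensus)
        coords = np.full(len(seq), -1, dtype=np.int64)
        identity = 0.0
        if usable:
            aln = aligner.align(consensus, seq)[0]
            matches = 0
            aligned_cols = 0
            for (cs, ce), (qs, qe) in zip(*aln.aligned):
                coords[qs:qe] = np.arange(cs, ce)
                block_c = consensus[cs:ce]
                block_q = seq[qs:qe]
                matches += sum(a == b for a, b in zip(block_c, block_q))
                aligned_cols += ce - cs
            identity = matches / aligned_cols if aligned_cols else 0.0
        out.append(
            RepeatCopy(
                copy_id=c.get("copy_id", f"copy{len(out)}"),
                chrom=c.get("chrom", "chr1"),
                start=int(c.get("start", 0)),
                end=int(c.get("end", len(seq))),
                sequence=seq,
                consensus_coords=coords,
                identity=identity,
                usable=usable,
            )
        )
    n_bad = sum(not rc.usable for rc in out)
    if n_bad:
        logger.warning("align_to_consensus: %d copy(ies) flagged unusable", n_bad)
    return out


def kmer_presence_matrix(
    copies: list[RepeatCopy], k: int = 7
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Binary presence matrix (copies x k-mers) on the consensus-oriented
    strand, k-mers absent from every copy dropped; returns the matrix and a
    map k-mer -> median consensus start over all its occurrences."""
    if not 5 <= k <= 12:
        raise ValueError("k must be in [5, 12]")
    lut = np.full(256, -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        lut[ord(b)] = i
    copy_codes: list[np.ndarray] = []
    all_codes: list[np.ndarray] = []
    all_pos: list[np.ndarray] = []
    for rc in copies:
        arr = lut[np.frombuffer(rc.sequence.encode(), dtype=np.uint8)]
        n = len(arr) - k + 1
        if n <= 0:
            copy_codes.append(np.empty(0, dtype=np.int64))
            continue
        codes = np.zeros(n, dtype=np.int64)
        for c in range(k):
            codes = codes * 4 + arr[c : c + n]
        copy_codes.append(np.unique(codes))
        cons_start = rc.consensus_coords[:n]
        ok = cons_start >= 0
        all_codes.append(codes[ok])
        all_pos.append(cons_start[ok])
    codes_cat = np.concatenate([c for c in copy_codes if len(c)]) if copy_codes else np.empty(0, np.int64)
    uniq = np.unique(codes_cat)
    col_of = {int(c): j for j, c in enumerate(uniq)}
    mat = np.zeros((len(copies), len(uniq)), dtype=bool)
    for i, codes in enumerate(copy_codes):
        if len(codes):
            mat[i, [col_of[int(c)] for c in codes]] = True
    kmers = [_decode(int(c), k) for c in uniq]
    positions: dict[str, int] = {}
    if all_codes:
        pos_codes = np.concatenate(all_codes)
        pos_vals = np.concatenate(all_pos)
        order = np.argsort(pos_codes, kind="stable")
        pos_codes, pos_vals = pos_codes[order], pos_vals[order]
        bounds = np.searchsorted(pos_codes, uniq)
        bounds = np.append(bounds, len(pos_codes))
        for j, km in enumerate(kmers):
            seg = pos_vals[bounds[j] : bounds[j + 1]]
            positions[km] = int(np.median(seg)) if len(seg) else -1
    df = pd.DataFrame(mat, columns=kmers, index=[rc.copy_id for rc in copies])
    return df, positions


def _decode(code: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(BASES[code % 4])
        code //= 4
    return "".join(reversed(out))


# ---------------------------------------------------------------------------
# logistic machinery


def logistic_fit(
    X: np.ndarray, y: np.ndarray, max_iter: int = 60, tol: float = 1e-10
) -> tuple[np.ndarray, float, np.ndarray, bool]:
    """Maximum-likelihood logistic regression by Newton-Raphson.

    Returns (beta, log-likelihood, covariance, converged).  ``X`` must
    include the intercept column.
    """
    n, p = X.shape
    beta = np.zeros(p)
    converged = False
    H = np.eye(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        H = (X * W[:, None]).T @ X
        try:
            step = np.linalg.solve(H + 1e-12 * np.eye(p), grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.abs(step).max() < tol:
            converged = True
            break
        if np.abs(beta).max() > 30:  # diverging: separation
            break
    eta = X @ beta
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    try:
        cov = np.linalg.inv(H + 1e-12 * np.eye(p))
    except np.linalg.LinAlgError:
        cov = np.full((p, p), np.nan)
    return beta, ll, cov, converged


def firth_fit(
    X: np.ndarray, y: np.ndarray, max_iter: int = 100, tol: float = 1e-8
) -> tuple[np.ndarray, float, np.ndarray]:
    """Firth-penalized logistic regression (Jeffreys-prior score
    adjustment), used as the fallback under complete separation."""
    n, p = X.shape
    beta = np.zeros(p)
    H = np.eye(p)
    for _ in range(max_iter):
        eta = X @ beta
        mu = 1.0 / (1.0 + np.exp(-eta))
        W = mu * (1.0 - mu)
        XW = X * W[:, None]
        H = XW.T @ X
        Hinv = np.linalg.inv(H + 1e-12 * np.eye(p))
        # leverages of the weighted hat matrix
        h = np.einsum("ij,jk,ik->i", X * np.sqrt(W)[:, None], Hinv, X * np.sqrt(W)[:, None])
        grad = X.T @ (y - mu + h * (0.5 - mu))
        step = Hinv @ grad
        beta = beta + np.clip(step, -5, 5)
        if np.abs(step).max() < tol:
            break
    eta = X @ beta
    mu = 1.0 / (1.0 + np.exp(-eta))
    W = mu * (1.0 - mu)
    H = (X * W[:, None]).T @ X
    sign, logdet = np.linalg.slogdet(H)
    ll = float(np.sum(y * eta - np.logaddexp(0.0, eta)) + 0.5 * logdet)
    cov = np.linalg.inv(H + 1e-12 * np.eye(p))
    return beta, ll, cov


@dataclass
class AssociationRecord:
    """One k-mer's conditional effect on a binary outcome."""

    kmer: str
    consensus_pos: int
    beta: float  # natural-log odds ratio
    se: float
    p: float  # likelihood-ratio p-value
    conditioning: tuple[str, ...] = ()
    collapsed: list[str] = field(default_factory=list)
    separated: bool = False

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.beta)

    @property
    def direction(self) -> int:
        return 1 if self.beta >= 0 else -1


def _design(
    presence: np.ndarray, covariates: np.ndarray | None
) -> tuple[np.ndarray, np.ndarray]:
    n = len(presence)
    cols = [np.ones(n), np.asarray(presence, dtype=float)]
    reduced = [np.ones(n)]
    if covariates is not None:
        cov = np.asarray(covariates, dtype=float).reshape(n, -1)
        for j in range(cov.shape[1]):
            cols.append(cov[:, j])
            reduced.append(cov[:, j])
    return np.column_stack(cols), np.column_stack(reduced)


def single_association(
    presence: np.ndarray,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
    kmer: str = "",
    consensus_pos: int = -1,
) -> AssociationRecord:
    """Logistic fit outcome ~ intercept + presence (+ covariates); the
    presence coefficient, Wald SE and LRT p-value are reported.  Complete
    separation is detected (non-convergence or exploding coefficient) and
    the record refit by Firth penalization with a flag."""
    y = np.asarray(outcome, dtype=float)
    if y.min() == y.max():
        raise ValueError("outcome must contain both classes")
    X, X0 = _design(np.asarray(presence), covariates)
    beta, ll, cov, converged = logistic_fit(X, y)
    separated = (not converged) and abs(beta[1]) > 15
    if separated:
        beta, ll, cov = firth_fit(X, y)
        b0, ll0, _ = firth_fit(X0, y)
    else:
        b0, ll0, _, _ = logistic_fit(X0, y)
    lam = max(0.0, 2.0 * (ll - ll0))
    p = float(chi2.sf(lam, df=1))
    se = float(np.sqrt(max(cov[1, 1], 0.0)))
    return AssociationRecord(
        kmer=kmer,
        consensus_pos=consensus_pos,
        beta=float(beta[1]),
        se=se,
        p=min(max(p, np.nextafter(0, 1)), 1.0),
        separated=separated,
    )


def _screen_2x2(presence: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Vectorized LRT p-values for single binary predictors with no
    covariates: the logistic MLE is the 2x2-table closed form, so the
    deviance is computed from observed vs expected cell counts."""
    n = presence.shape[0]
    y1 = float(y.sum())
    n1 = presence.sum(axis=0).astype(float)  # present
    a = y @ presence  # present & case
    b = n1 - a  # present & control
    c = y1 - a  # absent & case
    d = n - n1 - c  # absent & control
    obs = np.stack([a, b, c, d])
    # expected under independence
    e = np.stack(
        [n1 * y1 / n, n1 * (n - y1) / n, (n - n1) * y1 / n, (n - n1) * (n - y1) / n]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(obs > 0, obs * np.log(obs / e), 0.0)
    lam = 2.0 * terms.sum(axis=0)
    lam = np.maximum(lam, 0.0)
    # degenerate columns (all present / all absent) carry no information
    lam = np.where((n1 == 0) | (n1 == n), 0.0, lam)
    return chi2.sf(lam, df=1)


def forward_selection(
    matrix: pd.DataFrame,
    outcome: np.ndarray,
    covariates: np.ndarray | None = None,
    alpha_family: float = 0.05,
    positions: dict[str, int] | None = None,
    shadow_corr: float = 0.9,
    max_steps: int = 50,
) -> list[AssociationRecord]:
    """Greedy conditional selection of k-mers under Bonferroni control.

    At each step every remaining k-mer is tested conditional on all
    previously selected k-mers plus covariates; the minimum-p k-mer is
    selected while its p-value stays below alpha_family / (number of
    tested columns).  Afterwards, unselected k-mers whose presence
    correlates above ``shadow_corr`` with a selected k-mer and whose
    consensus positions overlap (within k bp) are collapsed into that
    record's annotation.
    """
    y = np.asarray(outcome, dtype=float)
    M = matrix.to_numpy(dtype=float)
    kmers = list(matrix.columns)
    m = M.shape[1]
    if m == 0:
        return []
    threshold = alpha_family / m
    positions = positions or {}
    k_len = len(kmers[0]) if kmers else 7
    selected: list[AssociationRecord] = []
    selected_idx: list[int] = []
    remaining = list(range(m))
    while remaining and len(selected) < max_steps:
        if not selected_idx and covariates is None:
            pvals = _screen_2x2(M[:, remaining], y)
        else:
            cov_cols = [M[:, j] for j in selected_idx]
            if covariates is not None:
                cov_cols.append(np.asarray(covariates, dtype=float).reshape(len(y), -1))
            base_cov = (
                np.column_stack([np.asarray(c).reshape(len(y), -1) for c in cov_cols])
                if cov_cols
                else None
            )
            pvals = np.array(
                [
                    single_association(M[:, j], y, covariates=base_cov).p
                    for j in remaining
                ]
            )
        best = int(np.argmin(pvals))
        if pvals[best] >= threshold:
            break
        j = remaining[best]
        cov_cols = [M[:, jj] for jj in selected_idx]
        if covariates is not None:
            cov_cols.append(np.asarray(covariates, dtype=float).reshape(len(y), -1))
        base_cov = (
            np.column_stack([np.asarray(c).reshape(len(y), -1) for c in cov_cols])
            if cov_cols
            else None
        )
        rec = single_association(
            M[:, j],
            y,
            covariates=base_cov,
            kmer=kmers[j],
            consensus_pos=positions.get(kmers[j], -1),
        )
        rec.conditioning = tuple(kmers[jj] for jj in selected_idx)
        selected.append(rec)
        selected_idx.append(j)
        remaining.remove(j)
    # collapse shadows
    for rec, j in zip(selected, selected_idx):
        pj = M[:, j]
        for jj in remaining:
            r = np.corrcoef(pj, M[:, jj])[0, 1]
            if not np.isfinite(r) or r <= shadow_corr:
                continue
            pos_a = positions.get(kmers[j], -1)
            pos_b = positions.get(kmers[jj], -1)
            if pos_a >= 0 and pos_b >= 0 and abs(pos_a - pos_b) <= k_len:
                rec.collapsed.append(kmers[jj])
    return selected


@dataclass
class AdditiveScore:
    scores: np.ndarray  # per-copy additive score
    bins: np.ndarray  # decile assignment per copy (0-9)
    bin_means: np.ndarray  # per-bin outcome frequency
    bin_se: np.ndarray  # binomial SE per bin


def additive_score(
    selected: list[AssociationRecord],
    matrix: pd.DataFrame,
    outcome: np.ndarray,
    n_bins: int = 10,
) -> AdditiveScore:
    """Per-copy score = sum of selected log-odds-ratios times presence;
    copies binned into score deciles, per-bin outcome frequency with
    binomial SEs.  Order-invariant in the selected records."""
    if not selected:
        raise ValueError("need at least one selected record")
    y = np.asarray(outcome, dtype=float)
    scores = np.zeros(len(matrix))
    for rec in selected:
        if rec.kmer in matrix.columns:
            scores += rec.beta * matrix[rec.kmer].to_numpy(dtype=float)
    if np.allclose(scores, scores[0]):
        logger.warning("all additive scores identical; single bin")
        bins = np.zeros(len(scores), dtype=int)
        n_bins = 1
    else:
        edges = np.quantile(scores, np.linspace(0, 1, n_bins + 1)[1:-1])
        bins = np.searchsorted(edges, scores, side="left")
    means = np.zeros(n_bins)
    ses = np.zeros(n_bins)
    for b in range(n_bins):
        mask = bins == b
        if mask.any():
            phat = y[mask].mean()
            means[b] = phat
            ses[b] = math.sqrt(max(phat * (1 - phat), 0.0) / mask.sum())
    return AdditiveScore(scores=scores, bins=bins, bin_means=means, bin_se=ses)


def cobinding_glm(
    outcome: np.ndarray,
    factors: dict[str, np.ndarray],
    min_instances: int = 30,
) -> pd.DataFrame:
    """Per-factor logistic effect of binary co-binding on hotspot odds.

    Returns a table of log2-odds effects with 95% Wald CIs; factors with
    fewer than ``min_instances`` co-bound instances are excluded, and
    separated fits flagged.
    """
    y = np.asarray(outcome, dtype=float)
    rows = []
    ln2 = math.log(2.0)
    for name, x in factors.items():
        x = np.asarray(x, dtype=float)
        if x.sum() < min_instances:
            continue
        rec = single_association(x, y, kmer=name)
        rows.append(
            {
                "factor": name,
                "n_cobound": int(x.sum()),
                "log2_odds": rec.beta / ln2,
                "ci_lo": (rec.beta - 1.959963984540054 * rec.se) / ln2,
                "ci_hi": (rec.beta + 1.959963984540054 * rec.se) / ln2,
                "p": rec.p,
                "separated": rec.separated,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["factor", "n_cobound", "log2_odds", "ci_lo", "ci_hi", "p", "separated"],
    )


def woolf_estimates(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """Closed-form 2x2 log-odds-ratio and Woolf SE: the independent oracle
    for the no-covariate logistic fit."""
    beta = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return beta, se
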