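"""Synthetic genomes, ChIP fragments, repeat families, and outcome labels.

Everything downstream of read alignment is exercised on data generated here
with a known truth table, emulating the structure of a PRDM9 ChIP-seq
experiment in an aneuploid cell line:

* an order-1 Markov background genome with GC content varying by block;
* planted binding sites drawn from ground-truth PWMs built from two
  half-motifs separated by a 2, 5, or 6 bp spacer (the three internal
  spacings observed for the zinc-finger array);
* two ChIP replicates of unequal depth plus a total-chromatin input, with
  fragment starts drawn from a per-base Poisson rate
  ``depth x ploidy x (1 + lambda * occupancy)`` near planted sites;
* a 354-bp retrotransposon-like repeat family mutated into thousands of
  copies, a subset carrying a planted PRDM9 motif and/or the 7-bp modifier
  ATCCATG, with binding and hotspot outcomes drawn from logistic models
  (the modifier multiplies hotspot odds, default OR 0.32).

All randomness flows through one :class:`numpy.random.Generator` per
operation, seeded from ``SimConfig.seed``; draws are consumed in a fixed,
documented order so identical seeds give byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import FragmentSet, GenomeIndex

__all__ = [
    "SimConfig",
    "TruthTable",
    "half_site_pwm",
    "truth_pwms",
    "simulate_genome",
    "simulate_chip",
    "simulate_repeat_family",
    "write_simconfig_toml",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# Half-sites of the ground-truth binding motif, bound on either side of the
# variably spaced region.  The pair is chosen to have low off-register
# self-similarity (no shared trigrams at lags up to the largest spacer
# difference), so that the three spacing variants are identifiable in
# principle: with self-similar half-sites, a 4-bp register shift can
# re-match one half and the variants collapse into one blurred motif for
# any inference method.
LEFT_HALF = "TCGACGCT"
RIGHT_HALF = "CGGGGCAA"
SPACERS = (2, 5, 6)
SPACER_PROBS = (0.5, 0.3, 0.2)


@dataclass
class SimConfig:
    """Resolved simulation parameters (defaults are the study conditions)."""

    genome_length: int = 5_000_000
    gc_block_length: int = 500_000
    gc_levels: tuple[float, ...] = (0.38, 0.46, 0.54)
    # (start, end, multiplier) regional coverage multipliers (aneuploidy)
    ploidy_blocks: tuple[tuple[int, int, float], ...] = (
        (1_000_000, 1_500_000, 1.5),
        (3_000_000, 3_500_000, 3.0),
    )
    depth_rep1: float = 0.030  # expected fragments per base, ChIP replicate 1
    depth_rep2: float = 0.020  # replicate 2 is shallower on purpose
    depth_input: float = 0.030
    frag_mean: float = 250.0
    frag_sd: float = 50.0
    enrichment_scale: float = 4.0  # lambda: rate multiplier at occupancy 1
    n_sites: int = 300
    consensus_match_prob: float = 0.95  # per-column PWM weight on consensus
    occupancy_slope: float = 0.6  # a in logistic(a * (score - b))
    occupancy_mid: float = 8.0  # b, in nats of PWM log-odds
    # repeat family
    n_repeat_copies: int = 3_000
    consensus_length: int = 354
    mutation_rate: float = 0.06  # per-base substitution rate vs consensus
    indel_rate: float = 0.002  # per-base 1-bp indel rate
    motif_window_start: int = 120  # consensus coordinate of planted PRDM9 motif
    motif_fraction: float = 0.4
    modifier_kmer: str = "ATCCATG"
    modifier_window_start: int = 260
    modifier_fraction: float = 0.35
    modifier_or: float = 0.32  # odds multiplier on hotspot formation
    bind_or: float = 5.0  # odds multiplier of binding on hotspot formation
    baseline_hotspot_prob: float = 0.15
    bind_slope: float = 0.4  # logistic slope of binding on motif score
    bind_mid: float = 18.0  # nats; planted instances score ~22, background ~9
    seed: int = 1

    def validate(self) -> None:
        if self.depth_rep1 <= 0 or self.depth_rep2 <= 0 or self.depth_input <= 0:
            raise ValueError("depths must be positive")
        if not 0 <= self.mutation_rate < 1:
            raise ValueError("mutation rate must be in [0, 1)")
        if self.modifier_or <= 0 or self.bind_or <= 0:
            raise ValueError("odds ratios must be positive")


@dataclass
class TruthTable:
    """Planted ground truth: every downstream answer is recoverable from it."""

    sites: pd.DataFrame  # position, motif_id, spacing, occupancy, strand
    repeats: pd.DataFrame  # copy_id, start, end, modifier, motif, bound, hotspot
    params: dict = field(default_factory=dict)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("# truth sites\n")
            self.sites.to_csv(fh, sep="\t", index=False)
            fh.write("# truth repeats\n")
            self.repeats.to_csv(fh, sep="\t", index=False)


def half_site_pwm(consensus: str, match_prob: float) -> np.ndarray:
    """PWM (L x 4) with ``match_prob`` on the consensus base per column."""
    off = (1.0 - match_prob) / 3.0
    pwm = np.full((len(consensus), 4), off)
    for i, b in enumerate(consensus):
        pwm[i, _BASE_INDEX[b]] = match_prob
    return pwm


def truth_pwms(cfg: SimConfig) -> dict[int, np.ndarray]:
    """One ground-truth PWM per spacer variant: sharp half-sites flanking a
    weakly specific spacer.  Keys are the spacer widths (2, 5, 6).

    The spacer columns mimic the variably spaced region contacted by weak,
    uncharged zinc fingers: mildly T-skewed (0.45/0.183), about 0.14 bits
    per column, versus near-saturated contact columns in the half-sites.
    """
    left = half_site_pwm(LEFT_HALF, cfg.consensus_match_prob)
    right = half_site_pwm(RIGHT_HALF, cfg.consensus_match_prob)
    spacer_col = np.array([(1 - 0.45) / 3] * 4)
    spacer_col[_BASE_INDEX["T"]] = 0.45
    out = {}
    for sp in SPACERS:
        spacer = np.tile(spacer_col, (sp, 1))
        out[sp] = np.vstack([left, spacer, right])
    return out


def _sample_from_pwm(pwm: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    u = rng.random(len(pwm))
    cdf = np.cumsum(pwm, axis=1)
    return (u[:, None] > cdf).sum(axis=1).astype(np.int8)


def _pwm_log_odds(pwm: np.ndarray, instance: np.ndarray) -> float:
    """Log-odds (nats) of the instance under the PWM vs uniform background."""
    probs = pwm[np.arange(len(instance)), instance]
    return float(np.log(probs).sum() - len(instance) * math.log(0.25))


def _markov_background(
    length: int, gc: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Order-1 Markov chain over ACGT with per-base target GC fraction.

    The stationary base probabilities follow the local GC level; a CpG
    depletion (G after C at half rate, renormalized) supplies the
    first-order structure seen in real genomes.

    Because only the post-C transition row differs from the generic row, the
    chain can be produced without a per-base Python loop: draw one uniform
    per base, precompute both candidate inverse-CDF outcomes (generic row
    and post-C row), then resolve the "previous base was C" indicator chain
    exactly with a reset/flip parity recurrence.
    """
    seq = np.empty(length, dtype=np.int8)
    boundaries = np.flatnonzero(np.diff(gc)) + 1
    starts = np.concatenate(([0], boundaries))
    ends = np.concatenate((boundaries, [length]))
    prev_is_c: bool | None = None
    C = 1
    for s, e in zip(starts, ends):
        level = gc[s]
        base_p = np.array([(1 - level) / 2, level / 2, level / 2, (1 - level) / 2])
        generic = base_p.copy()
        post_c = base_p.copy()
        post_c[2] *= 0.5  # CpG depletion
        post_c /= post_c.sum()
        u = rng.random(e - s)
        v0 = np.searchsorted(np.cumsum(generic), u, side="right").astype(np.int8)
        v1 = np.searchsorted(np.cumsum(post_c), u, side="right").astype(np.int8)
        # Resolve c_i = "base i is C": c_i = a_i if c_{i-1} else b_i,
        # where a = (v1 == C), b = (v0 == C).  Positions with a == b reset
        # the recurrence; positions with a=0,b=1 flip it; a=1,b=0 carry it.
        n = e - s
        a = v1 == C
        b = v0 == C
        reset = a == b
        flip = (~a) & b
        idx = np.arange(n)
        # seed the recurrence with the carried-over state of the previous block
        if prev_is_c is None:
            c_prev0 = bool(v0[0] == C)  # first base of genome: generic draw
        else:
            c_prev0 = bool((v1[0] if prev_is_c else v0[0]) == C)
        last_reset = np.maximum.accumulate(np.where(reset, idx, -1))
        cumflip = np.cumsum(flip)
        reset_val = np.where(last_reset >= 0, a[np.maximum(last_reset, 0)], False)
        flip_at_reset = np.where(last_reset >= 0, cumflip[np.maximum(last_reset, 0)], 0)
        parity = (cumflip - flip_at_reset) % 2 == 1
        c = np.where(last_reset >= 0, reset_val ^ parity, False)
        # positions before the first reset: evolve from c_prev0 by parity only
        pre = last_reset < 0
        if pre.any():
            # c_0 is special: determined by c_prev0 through a/b of position 0,
            # which the recurrence handles if we treat c_prev0 as c_{-1}.
            c0 = a[0] if c_prev0 else b[0]
            par0 = (cumflip - cumflip[0]) % 2 == 1
            c = np.where(pre, np.where(par0, ~c0, c0), c)
        # previous-base-is-C indicator, shifted by one
        prev_c = np.empty(n, dtype=bool)
        prev_c[0] = c_prev0
        prev_c[1:] = c[:-1]
        block = np.where(prev_c, v1, v0).astype(np.int8)
        seq[s:e] = block
        prev_is_c = bool(c[-1])
    return seq


def _indices_to_str(idx: np.ndarray) -> str:
    return "".join(BASES[i] for i in idx)


def _str_to_indices(s: str) -> np.ndarray:
    return np.array([_BASE_INDEX[b] for b in s], dtype=np.int8)


def revcomp(s: str) -> str:
    return "".join(_COMP[b] for b in reversed(s))


def simulate_genome(cfg: SimConfig) -> tuple[str, TruthTable]:
    """Background genome with planted binding sites.

    Draw order: (1) background chain, (2) site positions, (3) spacer variants,
    (4) PWM instances, (5) strands.  Occupancy of each planted site is
    ``logistic(slope * (PWM log-odds - mid))``, a monotone map from match
    strength to binding probability.
    """
    cfg.validate()
    pwms = truth_pwms(cfg)
    max_len = max(len(p) for p in pwms.values())
    if max_len > cfg.genome_length:
        raise ValueError("motif longer than genome")
    rng = np.random.default_rng(cfg.seed)
    n_blocks = math.ceil(cfg.genome_length / cfg.gc_block_length)
    gc = np.repeat(
        [cfg.gc_levels[i % len(cfg.gc_levels)] for i in range(n_blocks)],
        cfg.gc_block_length,
    )[: cfg.genome_length]
    seq = _markov_background(cfg.genome_length, gc, rng)

    # sites on a 2-kb grid so distinct binding events stay distinct
    margin = 1000
    min_separation = 2_000
    positions = np.sort(
        rng.choice(
            np.arange(margin, cfg.genome_length - margin, min_separation),
            size=cfg.n_sites,
            replace=False,
        )
    ) if cfg.n_sites > 0 else np.array([], dtype=int)
    spacers = rng.choice(SPACERS, size=cfg.n_sites, p=SPACER_PROBS)
    records = []
    for pos, sp in zip(positions, spacers):
        pwm = pwms[int(sp)]
        inst = _sample_from_pwm(pwm, rng)
        strand = "+" if rng.random() < 0.5 else "-"
        score = _pwm_log_odds(pwm, inst)
        occ = 1.0 / (1.0 + math.exp(-cfg.occupancy_slope * (score - cfg.occupancy_mid)))
        if strand == "-":
            inst_g = _str_to_indices(revcomp(_indices_to_str(inst)))
        else:
            inst_g = inst
        seq[pos : pos + len(inst_g)] = inst_g
        records.append(
            {
                "position": int(pos),
                "center": int(pos + len(inst_g) // 2),
                "motif_id": int(sp),
                "spacing": int(sp),
                "strand": strand,
                "occupancy": occ,
            }
        )
    sites = pd.DataFrame(
        records,
        columns=["position", "center", "motif_id", "spacing", "strand", "occupancy"],
    )
    truth = TruthTable(sites=sites, repeats=pd.DataFrame(), params=asdict(cfg))
    return _indices_to_str(seq), truth


def _ploidy_track(cfg: SimConfig) -> np.ndarray:
    mult = np.ones(cfg.genome_length)
    for start, end, m in cfg.ploidy_blocks:
        mult[start:end] = m
    return mult


def _site_rate_boost(cfg: SimConfig, truth: TruthTable) -> np.ndarray:
    """Rate multiplier 1 + lambda*occupancy for fragment starts whose
    fragment is expected to cover the planted site (start within one mean
    fragment length upstream of the site center).  Immunoprecipitation
    enriches fragments containing the bound site, so the resulting
    coverage bump is a triangle peaked exactly on the site and the
    ChIP/input coverage ratio at the site approaches 1 + lambda*occupancy."""
    boost = np.ones(cfg.genome_length)
    L = int(cfg.frag_mean)
    for _, row in truth.sites.iterrows():
        c = int(row["center"])
        lo, hi = max(0, c - L + 1), min(cfg.genome_length, c + 1)
        boost[lo:hi] = np.maximum(
            boost[lo:hi], 1.0 + cfg.enrichment_scale * row["occupancy"]
        )
    return boost


def _draw_fragments(
    rate: np.ndarray, cfg: SimConfig, rng: np.random.Generator, chrom: str = "chr1"
) -> FragmentSet:
    """Poisson fragment starts at the given per-base rate; lengths
    Normal(mean, sd) truncated to [50, 1000]; fragments clipped at the end."""
    counts = rng.poisson(rate)
    starts = np.repeat(np.flatnonzero(counts), counts[counts > 0])
    lengths = rng.normal(cfg.frag_mean, cfg.frag_sd, size=len(starts))
    lengths = np.clip(lengths, 50, 1000).round().astype(np.int64)
    ends = np.minimum(starts + lengths, cfg.genome_length)
    keep = ends > starts
    chroms = np.full(keep.sum(), chrom, dtype=object)
    return FragmentSet(chroms, starts[keep], ends[keep])


def simulate_chip(
    truth: TruthTable, cfg: SimConfig, chrom: str = "chr1"
) -> tuple[FragmentSet, FragmentSet, FragmentSet]:
    """Two ChIP replicates and one input sample for a single-sequence genome.

    Per-base fragment-start rate is ``depth * ploidy * boost`` with
    ``boost = 1 + lambda * occupancy`` near planted sites; the input sample
    uses lambda = 0.  Draw order: rep1 starts, rep1 lengths, rep2 starts,
    rep2 lengths, input starts, input lengths (one child generator each).
    """
    cfg.validate()
    ploidy = _ploidy_track(cfg)
    boost = _site_rate_boost(cfg, truth)
    root = np.random.default_rng(cfg.seed + 1)
    seeds = root.integers(0, 2**31 - 1, size=3)
    rep1 = _draw_fragments(
        cfg.depth_rep1 * ploidy * boost, cfg, np.random.default_rng(seeds[0]), chrom
    )
    rep2 = _draw_fragments(
        cfg.depth_rep2 * ploidy * boost, cfg, np.random.default_rng(seeds[1]), chrom
    )
    inp = _draw_fragments(
        cfg.depth_input * ploidy, cfg, np.random.default_rng(seeds[2]), chrom
    )
    return rep1, rep2, inp


_ASCII = np.frombuffer(b"ACGT", dtype=np.uint8)


def _indel_positions(
    L: int, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Candidate 1-bp indel positions, kept clear of the planted windows so
    positional truth stays exact."""
    protected = np.zeros(L, dtype=bool)
    mw = cfg.motif_window_start
    protected[mw : mw + 20] = True
    kw = cfg.modifier_window_start
    protected[kw : kw + len(cfg.modifier_kmer)] = True
    mask = (rng.random(L) < cfg.indel_rate) & ~protected
    return np.flatnonzero(mask)


def simulate_repeat_family(
    cfg: SimConfig,
) -> tuple[list[dict], TruthTable]:
    """Repeat copies derived from a random consensus, with planted PRDM9
    motifs and the modifier 7-mer, and logistic binding/hotspot outcomes.

    Outcome model (natural-log odds):

        bound   ~ Bernoulli(logistic(bind_slope * (motif score - bind_mid)))
        hotspot ~ Bernoulli(logistic(b0 + ln(bind_or) * bound
                                        + ln(modifier_or) * modifier))

    where ``modifier`` is the *realized* presence of the 7-mer anywhere in
    the copy (a planting destroyed or spontaneously created by mutation is
    scored as what the sequence actually contains).

    Draw order per run: consensus, then per-copy substitution matrix, motif
    plant flags, motif instances, modifier plant flags, indel masks, indel
    type/base draws, bound draws, hotspot draws.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 2)
    kmer = cfg.modifier_kmer
    L = cfg.consensus_length
    n = cfg.n_repeat_copies
    # consensus free of the modifier so presence is controlled by planting
    while True:
        consensus = rng.integers(0, 4, size=L).astype(np.int8)
        if kmer not in _indices_to_str(consensus):
            break
    pwm = truth_pwms(cfg)[5]  # the 5-bp-spacer variant is planted in repeats
    Lm = len(pwm)
    b0 = math.log(cfg.baseline_hotspot_prob / (1 - cfg.baseline_hotspot_prob))
    kmer_idx = _str_to_indices(kmer)

    # (1) substitutions for all copies at once
    seqs = np.tile(consensus, (n, 1))
    sub_mask = rng.random((n, L)) < cfg.mutation_rate
    shifts = rng.integers(1, 4, size=(n, L), dtype=np.int8)
    seqs = np.where(sub_mask, (seqs + shifts) % 4, seqs).astype(np.int8)
    # (2) planted PRDM9 motif instances
    plant_motif = rng.random(n) < cfg.motif_fraction
    n_m = int(plant_motif.sum())
    u = rng.random((n_m, Lm))
    cdf = np.cumsum(pwm, axis=1)
    instances = (u[:, :, None] > cdf[None, :, :]).sum(axis=2).astype(np.int8)
    seqs[plant_motif, cfg.motif_window_start : cfg.motif_window_start + Lm] = instances
    # (3) planted modifier
    plant_mod = rng.random(n) < cfg.modifier_fraction
    kw = cfg.modifier_window_start
    seqs[plant_mod, kw : kw + len(kmer)] = kmer_idx
    # (4) rare 1-bp indels, per copy (ragged result)
    final: list[np.ndarray] = []
    coords_list: list[np.ndarray] = []
    base_coords = np.arange(L)
    for i in range(n):
        pos = _indel_positions(L, cfg, rng)
        seq_i, coords_i = seqs[i], base_coords
        for p in pos[::-1]:
            if rng.random() < 0.5:  # deletion of this base
                seq_i = np.delete(seq_i, p)
                coords_i = np.delete(coords_i, p)
            else:  # insertion of a random base after it
                seq_i = np.insert(seq_i, p + 1, rng.integers(0, 4))
                coords_i = np.insert(coords_i, p + 1, -1)
        final.append(seq_i.astype(np.int8))
        coords_list.append(coords_i)
    # (5) realized modifier presence + best motif score, then outcomes
    strings = [_ASCII[s].tobytes().decode("ascii") for s in final]
    modifier = np.array([kmer in s for s in strings])
    scores = np.array([_best_pwm_score(s, pwm) for s in final])
    p_bound = 1.0 / (1.0 + np.exp(-cfg.bind_slope * (scores - cfg.bind_mid)))
    bound = rng.random(n) < p_bound
    logit = b0 + math.log(cfg.bind_or) * bound + math.log(cfg.modifier_or) * modifier
    hotspot = rng.random(n) < 1.0 / (1.0 + np.exp(-logit))

    spacing = 2 * L
    copies: list[dict] = []
    rows = []
    for i in range(n):
        start = 10_000 + i * spacing
        copies.append(
            {
                "copy_id": f"rep{i:05d}",
                "sequence": strings[i],
                "start": start,
                "end": start + len(strings[i]),
                "coords": coords_list[i],
            }
        )
        rows.append(
            {
                "copy_id": f"rep{i:05d}",
                "start": start,
                "end": start + len(strings[i]),
                "motif_planted": bool(plant_motif[i]),
                "modifier": bool(modifier[i]),
                "bound": bool(bound[i]),
                "hotspot": bool(hotspot[i]),
            }
        )
    truth = TruthTable(
        sites=pd.DataFrame(),
        repeats=pd.DataFrame(rows),
        params={**asdict(cfg), "consensus": _indices_to_str(consensus)},
    )
    return copies, truth


def _best_pwm_score(seq: np.ndarray, pwm: np.ndarray) -> float:
    """Best log-odds match of the PWM on the forward strand of the copy."""
    L = len(pwm)
    npos = len(seq) - L + 1
    if npos < 1:
        return -math.inf
    logp = np.log(pwm) - math.log(0.25)
    scores = np.zeros(npos)
    for c in range(L):
        scores += logp[c, seq[c : c + npos]]
    return float(scores.max())


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (tuple, list)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)}")


def write_simconfig_toml(cfg: SimConfig, path: str | Path) -> None:
    """Dump the resolved configuration as a flat TOML table."""
    with open(path, "w") as fh:
        fh.write("[simulation]\n")
        for k, v in asdict(cfg).items():
            fh.write(f"{k} = {_toml_value(v)}\n")


def genome_index_for(cfg: SimConfig, chrom: str = "chr1") -> GenomeIndex:
    return GenomeIndex((chrom,), (cfg.genome_length,))
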