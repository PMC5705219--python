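# prdm9bind

Tools for mapping where the meiotic zinc-finger protein PRDM9 binds a
genome and for dissecting what happens downstream of binding: which DNA
motifs it recognizes (including variably spaced ones), how often bound
sites overlap other feature sets beyond chance, and which short sequence
motifs inside repeat elements modify the odds that a bound site becomes a
recombination hotspot.

The package re-implements, as a tested reusable pipeline, the bespoke
computations behind a human PRDM9 ChIP-seq binding map:

* **Peak calling** (`prdm9bind.peaks`) — at each base, replicate fragment
  counts are modeled as `x_s ~ Poisson(r_s · b · (1 + e))`, where `b` is a
  local background rate (a 10-kb window mean of the total-chromatin input,
  which absorbs aneuploidy and coverage trends), `r_s` the sample/input
  depth ratio, and `e ≥ 0` a shared enrichment. The MLE is
  `ê = max(0, (x₁+x₂)/((r₁+r₂)·b) − 1)` — estimated signal over
  background, minus one, floored at zero — and the one-sided p-value uses
  the boundary mixture `½δ₀ + ½χ²₁` of the likelihood-ratio statistic.
  Peaks are runs of bases with `p < 10⁻⁶` (gaps ≤ 250 bp merged), centered
  on the smallest-p base, with profile-likelihood 95% CIs on `ê`.
  Fixed intervals can be *force-called* (same test on window-summed
  counts), and single samples split into pseudo-replicates.
* **Motif discovery** (`prdm9bind.motifs`) — a Bayesian mixture model in
  which each peak sequence is background (order-1 Markov) or carries one
  motif occurrence at a uniform position on either strand. Discovery
  seeds from over-represented central 10-mers, refines each seed by EM
  (100 iterations, with flank extension), removes matched sequences,
  repeats up to 20 times, then refines all motifs jointly (200
  iterations). Filters keep motifs with ≥ 85% central matches and
  non-degenerate information content. Frozen models force-scan any
  sequence set, reporting matches at posterior ≥ 0.75 in MEME format.
* **Overlap statistics** (`prdm9bind.overlap`) — the expected chance
  overlap between `n` query points and `t` intervals of widths `wᵢ` on a
  genome of size `g` is `c = Σᵢ (1 − ((g−wᵢ)/g)ⁿ)`, and the corrected
  overlap fraction solves `(1 − f/t) = (1 − o/t)(1 − c/t)`. A
  randomized-shift estimator (± 60 kb) covers interval-vs-interval
  comparisons.
* **Repeat-family association** (`prdm9bind.repeats`) — thousands of
  copies of a repeat family (e.g. the 354-bp THE1B retrotransposon) are
  aligned to their consensus; binary 7-mer presence is tested against
  binding/hotspot outcomes by conditional logistic regression with greedy
  forward selection under Bonferroni control, shadow-k-mer collapse,
  additive DNA scores, and a per-factor co-binding GLM reporting
  log₂-odds.
* **Profiles** (`prdm9bind.profiles`) — strand-aware aggregate signal
  around anchors, enrichment-quartile stratification, `ksmooth`-convention
  kernel smoothing, and edge-normalized ratio profiles.
* **Synthetic data** (`prdm9bind.simulate`) — a generator with full truth
  tables: Markov genomes with GC blocks and aneuploidy multipliers,
  planted PWM sites with 2/5/6-bp internal-spacing variants, Poisson
  fragment sampling for two unequal-depth ChIP replicates plus input, and
  a mutated repeat family carrying a planted modifier 7-mer (ATCCATG)
  whose presence multiplies hotspot odds by 0.32.

## Worked example

The `analysis/` directory holds the numbered study scripts; each is a thin
driver over the library. `01_simulate.py` writes a 5-Mb synthetic dataset
(seed 1) under `scratch/sim/`, and the rest analyze it:

```text
$ python analysis/01_simulate.py
fragments: rep1 198,454, rep2 132,601, input 187,766
repeats: 3,000 copies, modifier in 35.0%, hotspots at 17.1%

$ python analysis/02_call_peaks.py
300 peaks at p < 1e-6 (planted sites: 300)
  occupancy [0.99,1.01): 235 sites, recall@100bp 100.0%, median |offset| 8 bp
  occupancy [0.50,0.99):  63 sites, recall@100bp 100.0%, median |offset| 6 bp

$ python analysis/05_repeat_association.py
planted modifier ATCCATG @ consensus 260: OR 0.284 (truth 0.32),
    95% CI [0.220, 0.367], p 9.83e-26
  selected GATCCAT @ 259: log-OR -1.308 +- 0.137, p 6.41e-26,
    3 shadow k-mers collapsed
additive-score deciles: hotspot frequency 0.079 -> 0.216
```

The peak caller recovers every fully occupied planted site to within a
handful of bases; the association machinery recovers the planted modifier
effect (truth OR 0.32) through a 7-mer window overlapping the planted one
(`GATCCAT` starts one base upstream of `ATCCATG` and tags the same copies),
with correlated shadow k-mers collapsed rather than reported as
independent hits. `03_discover_motifs.py` additionally shows the 2-bp and
6-bp internal-spacing variants of the binding motif being recovered as two
distinct PWMs (per-column correlation 1.000 and 0.999 against truth) from
2,000 peak sequences.

A single end-to-end run on fresh synthetic data, with a manifest of output
hashes, is also available as a CLI:

```bash
prdm9bind demo --out scratch/demo --seed 1
```

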