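# Methods

This note records the models, parameter choices, and numerical decisions
behind `prdm9bind`, and what the synthetic-data experiments do and do not
demonstrate.

## Peak-calling model

At base *i*, replicate fragment counts are modeled as independent Poisson
draws, `x_s ~ Poisson(r_s · b_i · (1 + e_i))`, with a shared non-negative
enrichment `e_i` and per-sample scale factors `r_s` (sample total
fragments over input total fragments). The background `b_i` is the mean
input coverage in a `W_bg = 10,000` bp window centered on *i* (truncated
at sequence ends, floored at `0.5/W_bg`). A plain window mean is the
simplest estimator that absorbs regional copy-number multipliers
(aneuploidy) and slow coverage trends; it transitions across a
copy-number boundary over one window width, so calls within `W_bg/2` of
such a boundary inherit a biased background. The default window is
configurable; anything from a few kb upward behaves similarly on the
synthetic data.

The enrichment MLE is closed-form, `ê = max(0, Σx_s/(Σr_s·b) − 1)`, and
the one-sided test of `e > 0` uses `Λ = 2[ℓ(ê) − ℓ(0)]` with
`p = ½·P(χ²₁ ≥ Λ)` for `Λ > 0`, else 1 — the standard boundary mixture
for a parameter on the edge of its space. Confidence intervals are
profile-likelihood sets at a drop of 3.84 (95%), truncated at zero, found
by bracketed root-finding (`xtol` 1e-10).

Two calibration facts matter in practice. First, the `½χ²₁` tail is an
asymptotic approximation: on *discrete* counts it is intrinsically
slightly conservative, with an exact deficit (computable from the Poisson
tail) of roughly 1–2 × 10⁻³ at `α = 0.05` for per-base means of order
40–200, shrinking at smaller `α`. The calibration test therefore draws
its null over a heterogeneous background (rates uniform on 40–200, the
regime a windowed background produces on deep data), where the empirical
rejection rate sits within three binomial standard errors of nominal at
`α ∈ {0.05, 0.01, 10⁻³}` for 10⁵ bases; at very shallow coverage the test
is conservative, never anti-conservative. Second, per-base coverage
values at neighboring bases share fragments, so neighboring p-values are
dependent; the caller treats the per-base test as a scan statistic and
merges significant runs (gap ≤ 250 bp, below typical fragment length)
rather than interpreting each base independently. Peak centers take the
smallest-p base, leftmost on ties, for determinism.

Force-calling applies the same LRT to window-summed counts (default 1 kb)
and flags results with ≤ 5 input reads in the window as undefined; input
reads are estimated as window coverage mass divided by the input's mean
fragment length.

The stringent motif-calling subset applies six filters — `p < 10⁻¹⁰`,
enrichment > 2, enrichment-CI width ≤ 50, no repeat overlap, center input
coverage between the peak set's 10th and 90th percentiles, and ≥ 30
fragments summed over the ChIP replicates — then ranks by enrichment and
keeps the top 5,000. The CI-width filter is interpreted in enrichment
units (the quantity whose CI the caller reports); the threshold is a
parameter.

## Motif mixture model

Each sequence is either background or carries exactly one motif
occurrence (zero-or-one occurrence model), uniformly positioned, on
either strand with equal prior. Background is an order-1 Markov chain
fitted to all input sequences (pseudocount 1); under a placement, the
window's background factors are replaced by PWM column probabilities, so
each placement is scored by a likelihood ratio against the local
background. The E-step is exact (verified against exhaustive enumeration
to 10⁻⁹ on toy sequences); the M-step updates columns from
responsibility-weighted base counts with Dirichlet pseudocount 0.5 and
mixture weights from expected occupancy. The observed-data log-likelihood
is non-decreasing between model-dimension changes and is asserted so in
tests (tolerance 10⁻⁶).

Seeding counts canonical 10-mers on both strands; among the 50 most
frequent, the seed maximizes the fraction of its occurrences starting in
the central 100 bp, normalized by `100/(L−9)`; the winner becomes a PWM
with 0.7 on the seed base. Each seed is refined for 100 iterations, its
matched sequences (posterior > 0.5) removed, and the cycle repeats up to
20 times (a round needs ≥ 100 remaining sequences); all surviving motifs
are then refined jointly for 200 iterations on the full, re-admitted
sequence set. Motifs grow beyond 10 columns by flank extension: every 10
iterations, a one-column extension is accepted when the candidate
column's expected information content exceeds 0.05 bits (capped at 26
columns). Motifs whose weight falls below 10⁻⁴ are dropped. Final
filters require ≥ 85% of match midpoints in the central 100 bp and a mean
information content ≥ 0.5 bits/column over the best 8-column window.
Discovery is deterministic given the input sequences; the seed argument
is recorded so that repeated runs document consensus rather than explore
randomness.

## Overlap correction

For `n` single-base query points and `t` target intervals of widths `wᵢ`
on a genome of size `g`, the chance-overlap count is
`c = Σᵢ (1 − ((g−wᵢ)/g)ⁿ)`, evaluated as `−expm1(n·log1p(−w/g))` for
numerical stability at large `n`. The corrected overlap fraction
`o/t = 1 − (1−f/t)/(1−c/t)` assumes chance and systematic overlaps occur
independently; it is reported with a validity flag and is meaningful only
when `c < f`. For interval-vs-interval comparisons, chance overlaps are
estimated by shifting one set uniformly in ± 60 kb (one independent draw
per interval by default; a per-set mode is available), discarding
intervals shifted off their sequence. The closed form assumes uniform
point placement; on configurations with structure (e.g. points on a
regular grid), the shift estimator is the appropriate empirical null and
can differ from the closed form by a few percent.

## Repeat-family association

Copies are aligned to the family consensus by global affine-gap alignment
(match +1, mismatch −1, open −5, extend −1; biopython's PairwiseAligner,
first-reported alignment on ties), giving every base a consensus
coordinate (−1 for insertions). Copies shorter than half the consensus
are excluded from positional reporting. The presence matrix records
whether each 7-mer (k configurable in 5–12) occurs at least once in the
copy's oriented sequence; columns absent everywhere are dropped, and each
k-mer is annotated with the median consensus start of its occurrences.

Association uses maximum-likelihood logistic regression (Newton–Raphson,
LRT p-values, Wald SEs), with Firth's Jeffreys-prior penalization as the
flagged fallback under complete separation. With no covariates the fit
reduces to the 2×2-table closed form, which the tests verify against
Woolf estimates to 10⁻³ — and which the forward-selection screening step
exploits as a vectorized fast path (it is the exact MLE, not an
approximation). Forward selection tests every remaining k-mer conditional
on the selected set plus covariates, selects the minimum-p k-mer while
`p < α_family/m` (Bonferroni over the `m` tested columns, default
`α_family = 0.05`), and finally collapses unselected k-mers with presence
correlation > 0.9 and consensus positions within one k-mer length of a
selected record into that record's annotation. Because a k-mer
overlapping the causal one by k−1 bases can tag exactly the same copies,
the selected representative may be any member of the correlated block;
the collapse annotation, not the single selected string, is the unit of
interpretation. The additive score per copy is the sum of selected
log-odds-ratios times presence, binned into deciles; the co-binding GLM
reports per-factor effects as log₂-odds with 95% Wald CIs, excluding
factors with fewer than 30 co-bound instances.

## Profiles

Aggregate profiles average a signal track at each offset in
`[−halfwidth, +halfwidth]` across anchors, mirroring minus-strand anchors
by default when strands are given (so motif-anchored profiles read
5′→3′); anchors with clipped windows are dropped. Quartile
stratification cuts at the empirical 25/50/75 percentiles with ties to
the lower group. The smoother is Nadaraya–Watson with the classical
`ksmooth` bandwidth convention — kernels scaled so their quartiles sit at
± 0.25 × bandwidth (box kernel supported on ± bandwidth/2; normal kernel
σ = 0.25·bandwidth/0.6745) — so bandwidths 25 and 200 mean what they mean
in that tradition; edges renormalize over available support. Ratio
profiles floor the denominator at 10⁻⁶ and can normalize to 1 over the
outer 10% of offsets.

## Synthetic-data generator

The generator is the package's study system; its defaults are the
conditions under which every claim is tested.

*Genome*: 5 Mb, order-1 Markov background with GC fraction cycling over
500-kb blocks (0.38/0.46/0.54) and a CpG depletion (G after C at half
rate); two regional multipliers (1.5× and 3×) emulate aneuploidy. 300
sites are planted on a 2-kb grid so distinct binding events stay
distinct. Ground-truth PWMs are two 8-bp half-sites (0.95 on the
consensus base per column) flanking a weakly T-skewed spacer of 2, 5, or
6 bp (0.5/0.3/0.2), matching the three internal spacings observed for the
zinc-finger array: sharp contact columns around a weakly specific,
variably spaced region. The half-site pair is chosen for low
off-register self-similarity; with self-similar half-sites a 4-bp
register shift re-matches one half and the spacing variants become
unidentifiable *in principle* — no inference method could separate them.
Site occupancy is `logistic(0.6·(PWM log-odds − 8))`, the minimal
monotone map from match strength to binding probability.

*ChIP fragments*: per-base fragment-start rates are
`depth × ploidy × (1 + λ·occupancy)` for starts within one mean fragment
length upstream of a site center — i.e. for fragments expected to cover
the site, which is what immunoprecipitation enriches — yielding a
triangular coverage bump peaked on the site whose ChIP/input ratio
approaches `1 + λ·occupancy` (default λ = 4). Depths are 0.030, 0.020
(deliberately unequal) and 0.030 fragments/bp; lengths are
Normal(250, 50) truncated to [50, 1000]. Counts are drawn per base
(Poisson), so the model is count-level: no read sequences, mapping
ambiguity, duplicates, or GC amplification bias. Consequences: peak
calling, force-calling and profiles are tested under the model the caller
assumes (plus background heterogeneity), and passing tests demonstrate
correct inference under that model — not robustness to mapping artifacts,
which live upstream of this package.

*Repeat family*: a random 354-bp consensus (regenerated if it contains
the modifier 7-mer) mutated into copies at substitution rate 0.06 with
rare 1-bp indels (0.002/bp, kept clear of the planted windows so
positional truth stays exact). 40% of copies receive a PWM instance in a
fixed window (consensus position 120); 35% receive the modifier ATCCATG
at position 260. Binding is `Bernoulli(logistic(0.4·(best motif score −
18)))`; hotspot outcomes follow
`logit P = logit(0.15) + ln(5)·bound + ln(0.32)·modifier`, with the
modifier flag defined by *realized* presence (a planting destroyed, or a
spontaneous occurrence created, by mutation is scored as what the
sequence contains). The association analyses therefore recover OR 0.32
for the modifier and OR 5 for binding when conditioning correctly.

All randomness flows through seeded generators with documented draw
order, so identical seeds give byte-identical outputs.

## Problem sizes used in the test suite

Unit tests run on a 500-kb genome (60 sites, 400 repeat copies). The
end-to-end properties use: type-I calibration at 10⁵ null bases; recall
on the full 5-Mb genome; motif recovery on 2,000 sequences with the two
spacing variants at 60%/30% (discovery capped at 4 seeding rounds, ample
for two planted motifs plus background rounds); modifier-OR confidence
coverage over 50 families of 10,000 copies; family-wise error of the
forward selection over 500 null families of 1,000 copies × 500 k-mers.
The full suite runs in a few minutes on one CPU.

## Known limitations

* The peak caller assumes independent replicates and Poisson counts; true
  overdispersion (biological or amplification) would inflate significance
  and should be absorbed by a count-level dispersion model upstream of
  the LRT if needed.
* The two-class coverage model has no fragment-level duplicates or
  mappability structure; the 10-kb background window cannot follow
  copy-number changes sharper than the window.
* The motif model allows at most one occurrence per sequence; tandem or
  clustered motifs are reported as their single best placement.
* Forward selection is greedy; with heavily correlated predictors the
  selected representative of a block is arbitrary within the block (the
  collapse annotation carries the equivalence class).
* The shift-based chance estimator assumes approximate translation
  invariance within ± 60 kb; strong large-scale density gradients bias
  it like any permutation-by-shift scheme.
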