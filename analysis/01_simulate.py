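#!/usr/bin/env python
"""Generate the synthetic study dataset with known truth.

Produces a 5-Mb genome carrying 300 planted PRDM9 binding sites (three
internal-spacing variants, logistic occupancy), two ChIP replicates of
unequal depth plus a total-chromatin input over two aneuploidy blocks, and
a 3,000-copy 354-bp repeat family carrying the planted ATCCATG modifier
(OR 0.32 on hotspot odds).  All downstream analyses read these files.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from prdm9bind import genome as G
from prdm9bind import simulate as S

OUT = Path(__file__).resolve().parents[1] / "scratch" / "sim"
SEED = 1


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = S.SimConfig(seed=SEED)
    print(f"simulating {cfg.genome_length/1e6:.0f} Mb genome, {cfg.n_sites} sites, seed {SEED}")
    seq, truth = S.simulate_genome(cfg)
    with open(OUT / "genome.fa", "w") as fh:
        fh.write(">chr1\n")
        for i in range(0, len(seq), 80):
            fh.write(seq[i : i + 80] + "\n")
    rep1, rep2, inp = S.simulate_chip(truth, cfg)
    G.write_fragments(rep1, OUT / "chip_rep1.bed")
    G.write_fragments(rep2, OUT / "chip_rep2.bed")
    G.write_fragments(inp, OUT / "input.bed")
    print(f"fragments: rep1 {len(rep1):,}, rep2 {len(rep2):,}, input {len(inp):,}")
    copies, rtruth = S.simulate_repeat_family(cfg)
    with open(OUT / "repeat_copies.fa", "w") as fh:
        for c in copies:
            fh.write(f">{c['copy_id']}\n{c['sequence']}\n")
    with open(OUT / "repeat_consensus.fa", "w") as fh:
        fh.write(">consensus\n" + rtruth.params["consensus"] + "\n")
    rtruth.repeats.to_csv(OUT / "repeat_outcomes.tsv", sep="\t", index=False)
    truth.to_tsv(OUT / "truth_sites.tsv")
    S.write_simconfig_toml(cfg, OUT / "simconfig.toml")
    mod = rtruth.repeats.modifier.mean()
    hot = rtruth.repeats.hotspot.mean()
    print(f"repeats: {len(copies):,} copies, modifier in {mod:.1%}, hotspots at {hot:.1%}")
    print(f"wrote {OUT}")


if __name__ == "__main__":
    main()
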