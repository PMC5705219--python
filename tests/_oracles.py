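"""Independent brute-force oracles used by several test modules."""

import math

import numpy as np

from prdm9bind import motifs as M


def oracle_posteriors(model: M.MotifMixtureModel, seq: str) -> dict:
    """Exhaustive enumeration of the placement posterior for one sequence:
    background versus every (motif, start, strand) case."""
    arr = M.encode_sequences([seq])[0]
    terms = {("bg",): model.bg_weight}
    for k, pwm in enumerate(model.pwms):
        L = len(pwm)
        npos = len(arr) - L + 1
        if npos < 1:
            continue
        for j in range(npos):
            for strand in "+-":
                p = pwm if strand == "+" else M.revcomp_pwm(pwm)
                num = sum(math.log(p[c, arr[j + c]]) for c in range(L))
                den = 0.0
                for i in range(j, j + L):
                    den += (
                        math.log(model.bg_init[arr[i]])
                        if i == 0
                        else math.log(model.bg_trans[arr[i - 1], arr[i]])
                    )
                terms[(k, j, strand)] = model.weights[k] / (2 * npos) * math.exp(num - den)
    tot = sum(terms.values())
    return {key: v / tot for key, v in terms.items()}


def nw_affine_score(a, b, match=1, mismatch=-1, open_=-5, extend=-1):
    """Gotoh affine-gap global alignment score (full-matrix DP)."""
    n, m = len(a), len(b)
    NEG = -1e9
    Mm = np.full((n + 1, m + 1), NEG)
    Ix = np.full((n + 1, m + 1), NEG)  # gap in b (vertical)
    Iy = np.full((n + 1, m + 1), NEG)  # gap in a (horizontal)
    Mm[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = open_ + (i - 1) * extend
    for j in range(1, m + 1):
        Iy[0, j] = open_ + (j - 1) * extend
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            Mm[i, j] = max(Mm[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]) + s
            Ix[i, j] = max(Mm[i - 1, j] + open_, Ix[i - 1, j] + extend)
            Iy[i, j] = max(Mm[i, j - 1] + open_, Iy[i, j - 1] + extend)
    return max(Mm[n, m], Ix[n, m], Iy[n, m])
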