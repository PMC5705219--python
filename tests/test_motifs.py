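"""Mixture motif discovery: exact inference, EM behavior, scanning."""

import math

import numpy as np
import pytest
from _oracles import oracle_posteriors

from prdm9bind import motifs as M
from prdm9bind.simulate import SimConfig, truth_pwms, _sample_from_pwm, BASES

COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def revcomp(s: str) -> str:
    return "".join(COMP[c] for c in reversed(s))


def random_seqs(rng, n, length, p=(0.25, 0.25, 0.25, 0.25)):
    return ["".join(rng.choice(list("ACGT"), length, p=list(p))) for _ in range(n)]


@pytest.fixture(scope="module")
def toy_model():
    rng = np.random.default_rng(3)
    seqs = random_seqs(rng, 30, 8)
    bg = M.fit_background(M.encode_sequences(seqs))
    pwm1 = np.array([[0.7, 0.1, 0.1, 0.1], [0.1, 0.7, 0.1, 0.1],
                     [0.1, 0.1, 0.7, 0.1], [0.1, 0.1, 0.1, 0.7]])
    pwm2 = np.array([[0.4, 0.3, 0.2, 0.1]] * 5)
    model = M.MotifMixtureModel([pwm1, pwm2], np.array([0.3, 0.2]), 0.5, bg[0], bg[1])
    return model, seqs


class TestExactInference:
    def test_posteriors_match_enumeration_to_1e9(self, toy_model):
        """Mixture posteriors on <= 8-bp sequences equal brute-force
        enumeration over all (motif, position, strand) placements."""
        model, seqs = toy_model
        batches = M._make_batches(M.encode_sequences(seqs), model)
        _, gamma, resp = M._e_step(batches, model)
        for batch in batches:
            for bi in range(batch.n):
                i = int(batch.indices[bi])
                orc = oracle_posteriors(model, seqs[i])
                for k in range(model.n_motifs):
                    g_orc = sum(v for key, v in orc.items() if key[0] == k)
                    assert gamma[i, k] == pytest.approx(g_orc, abs=1e-9)
                    rf, rr = resp[0][k]
                    for j in range(rf.shape[1]):
                        assert rf[bi, j] == pytest.approx(orc[(k, j, "+")], abs=1e-9)
                        assert rr[bi, j] == pytest.approx(orc[(k, j, "-")], abs=1e-9)

    def test_log_likelihood_matches_enumeration(self, toy_model):
        model, seqs = toy_model
        batches = M._make_batches(M.encode_sequences(seqs), model)
        ll, _, _ = M._e_step(batches, model)
        # oracle: sum over seqs of log(total unnormalized weight)
        ll_orc = 0.0
        for s in seqs:
            arr = M.encode_sequences([s])[0]
            orc_total = 0.0
            post = oracle_posteriors(model, s)
            # rebuild the unnormalized total from the bg term
            bg_w = model.bg_weight
            orc_total = bg_w / post[("bg",)]
            ll_orc += math.log(orc_total)
        assert ll == pytest.approx(ll_orc, abs=1e-8)


class TestSeeding:
    def test_planted_central_kmer_selected(self, rng):
        planted = "ACGTTAGCAC"
        seqs = []
        for i in range(300):
            s = rng.choice(list("ACGT"), 300)
            if i % 2 == 0:
                pos = rng.integers(120, 160)
                s[pos : pos + 10] = list(planted)
            seqs.append("".join(s))
        pwm = M.seed_motif(seqs)
        consensus = "".join(BASES[i] for i in pwm.argmax(1))
        assert consensus in (planted, revcomp(planted))

    def test_seed_pwm_construction_rule(self, rng):
        seqs = []
        for i in range(150):
            s = rng.choice(list("ACGT"), 120)
            s[55:65] = list("ACGTACGTAC")
            seqs.append("".join(s))
        pwm = M.seed_motif(seqs)
        assert pwm.shape == (10, 4)
        assert sorted(pwm[0]) == pytest.approx([0.1, 0.1, 0.1, 0.7])

    def test_too_few_sequences_rejected(self, rng):
        with pytest.raises(ValueError):
            M.seed_motif(random_seqs(rng, 50, 100))


class TestRefinement:
    def test_noiseless_planted_seed_reaches_fixed_point(self, rng):
        planted = "GATTACAGGC"
        seqs = []
        for _ in range(200):
            s = rng.choice(list("ACGT"), 80)
            s[30:40] = list(planted)
            seqs.append("".join(s))
        bg = M.fit_background(M.encode_sequences(seqs))
        seed = M.seed_motif(seqs)
        model = M._new_model([seed], bg)
        model, trace = M.refine_motif(model, seqs, iters=30)
        probs = model.pwms[0].max(axis=1)
        core = probs[np.argmax(probs > 0.9) :][:10]
        assert (core >= 0.9).all()
        assert model.weights[0] > 0.9

    def test_log_likelihood_nondecreasing_between_extensions(self, rng):
        seqs = []
        for _ in range(150):
            s = rng.choice(list("ACGT"), 100)
            s[40:50] = list("CCGGAATTCC")
            seqs.append("".join(s))
        bg = M.fit_background(M.encode_sequences(seqs))
        model = M._new_model([M.seed_motif(seqs)], bg)
        _, trace = M.refine_motif(model, seqs, iters=35)
        diffs = np.diff(trace)
        # iterations right after an extension (multiples of EXTEND_EVERY)
        # may change the model dimension; all others must not decrease
        for i, d in enumerate(diffs):
            if (i + 1) % M.EXTEND_EVERY == 0:
                continue
            assert d >= -1e-6

    def test_background_only_yields_no_surviving_motif(self, rng):
        """On pure background the motif either collapses in weight or
        degenerates to near-uniform columns; either way it is dropped or
        removed by the degeneracy filter."""
        seqs = random_seqs(rng, 200, 100)
        bg = M.fit_background(M.encode_sequences(seqs))
        pwm = np.full((10, 4), 0.1)
        pwm[:, 0] = 0.7
        model = M._new_model([pwm], bg, motif_weight=0.4)
        model, _ = M._run_em(model, M.encode_sequences(seqs), 40)
        if model.n_motifs:
            ic = M.information_content(model.pwms[0])
            best8 = max(
                ic[i : i + 8].mean() for i in range(max(1, len(ic) - 7))
            )
            assert model.weights[0] < 0.05 or best8 < 0.5


@pytest.fixture(scope="module")
def planted_scan():
    rng = np.random.default_rng(8)
    pwm = truth_pwms(SimConfig())[2]
    consensus = "".join(BASES[i] for i in pwm.argmax(1))
    bg_seqs = random_seqs(rng, 400, 200)
    bg = M.fit_background(M.encode_sequences(bg_seqs))
    model = M.MotifMixtureModel([pwm], np.array([0.5]), 0.5, bg[0], bg[1])
    return model, consensus, bg_seqs, rng


class TestForceScan:
    def test_exact_consensus_matched_confidently(self, planted_scan):
        model, consensus, bg_seqs, _ = planted_scan
        s = bg_seqs[0][:90] + consensus + bg_seqs[0][90 + len(consensus):]
        out = M.force_scan(model, [s])
        assert len(out) == 1
        assert out.posterior[0] > 0.99
        assert out.start[0] == 90
        assert out.strand[0] == "+"

    def test_revcomp_embedding_mirrors_offset(self, planted_scan):
        model, consensus, bg_seqs, _ = planted_scan
        s = bg_seqs[1][:90] + consensus + bg_seqs[1][90 + len(consensus):]
        rc = revcomp(s)
        out = M.force_scan(model, [rc])
        assert out.strand[0] == "-"
        assert out.start[0] == len(s) - 90 - len(consensus)

    def test_background_rarely_matches(self, planted_scan):
        model, _, bg_seqs, _ = planted_scan
        out = M.force_scan(model, bg_seqs)
        assert len(out) / len(bg_seqs) < 0.01

    def test_empty_model_rejected(self, planted_scan):
        model, _, _, _ = planted_scan
        empty = M.MotifMixtureModel([], np.zeros(0), 1.0, model.bg_init, model.bg_trans)
        with pytest.raises(ValueError):
            M.force_scan(empty, ["ACGT"])


class TestStrandSymmetry:
    def test_discovery_invariant_under_reverse_complement(self, rng):
        pwm = truth_pwms(SimConfig())[2]
        seqs = []
        for i in range(400):
            s = rng.choice(list("ACGT"), 200)
            if i % 3 != 0:
                inst = "".join(BASES[b] for b in _sample_from_pwm(pwm, rng))
                pos = rng.integers(80, 105)
                s[pos : pos + len(inst)] = list(inst)
            seqs.append("".join(s))
        bg = M.fit_background(M.encode_sequences(seqs))
        m1 = M._new_model([M.seed_motif(seqs)], bg)
        m1, _ = M.refine_motif(m1, seqs, iters=40)
        rc_seqs = [revcomp(s) for s in seqs]
        bg2 = M.fit_background(M.encode_sequences(rc_seqs))
        m2 = M._new_model([M.seed_motif(rc_seqs)], bg2)
        m2, _ = M.refine_motif(m2, rc_seqs, iters=40)
        a, b = m1.pwms[0], m2.pwms[0]
        best = -2.0
        for cand in (b, M.revcomp_pwm(b)):
            for off in range(-5, 6):
                lo, hi = max(0, off), min(len(a), off + len(cand))
                if hi - lo < 8:
                    continue
                r = np.corrcoef(
                    a[lo:hi].ravel(), cand[lo - off : hi - off].ravel()
                )[0, 1]
                best = max(best, r)
        assert best > 0.95


class TestFilterMotifs:
    def _matches(self, starts, motif_index=0):
        import pandas as pd

        return pd.DataFrame(
            {
                "seq_id": [f"s{i}" for i in range(len(starts))],
                "motif": ["m"] * len(starts),
                "motif_index": [motif_index] * len(starts),
                "start": starts,
                "strand": ["+"] * len(starts),
                "posterior": [0.9] * len(starts),
            }
        )

    def _model(self, pwm):
        return M.MotifMixtureModel(
            [pwm], np.array([0.5]), 0.5, np.full(4, 0.25), np.full((4, 4), 0.25)
        )

    def test_sub_85_percent_centrality_removed(self):
        pwm = np.full((10, 4), 0.05)
        pwm[:, 2] = 0.85
        starts = [145] * 80 + [10] * 20  # 80% central
        out = M.filter_motifs(self._model(pwm), self._matches(starts))
        assert out.n_motifs == 0

    def test_degenerate_pwm_removed_despite_centrality(self):
        pwm = np.full((10, 4), 0.25)
        out = M.filter_motifs(self._model(pwm), self._matches([145] * 100))
        assert out.n_motifs == 0

    def test_sharp_central_motif_kept(self):
        pwm = np.full((10, 4), 0.05)
        pwm[:, 1] = 0.85
        starts = [145] * 95 + [10] * 5
        out = M.filter_motifs(self._model(pwm), self._matches(starts))
        assert out.n_motifs == 1


class TestMemeFormat:
    def test_round_trip(self, tmp_path, rng):
        pwms = [np.random.default_rng(1).dirichlet(np.ones(4), size=12)]
        model = M.MotifMixtureModel(
            pwms, np.array([0.4]), 0.6, np.array([0.3, 0.2, 0.2, 0.3]),
            np.full((4, 4), 0.25), names=["motif_1"],
        )
        path = tmp_path / "m.meme"
        M.write_meme(model, path)
        back = M.read_meme(path)
        assert back.names == ["motif_1"]
        assert np.allclose(back.pwms[0], pwms[0], atol=1e-6)
        assert np.allclose(back.bg_init, model.bg_init, atol=1e-5)


class TestExtractPeakSequences:
    def test_window_arithmetic(self):
        genome = {"chr1": "A" * 850 + "C" * 300 + "G" * 850}
        seqs, kept = M.extract_peak_sequences([("chr1", 1_000)], genome, width=300)
        assert kept == [0]
        assert seqs[0] == genome["chr1"][850:1150]

    def test_ambiguous_bases_excluded(self):
        genome = {"chr1": "A" * 400 + "N" + "A" * 400}
        seqs, kept = M.extract_peak_sequences([("chr1", 400)], genome, width=300)
        assert seqs == [] and kept == []

    def test_edge_windows_skipped(self):
        genome = {"chr1": "A" * 1_000}
        seqs, kept = M.extract_peak_sequences(
            [("chr1", 100), ("chr1", 500)], genome, width=300
        )
        assert kept == [1]
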