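"""Repeat-family association: alignment, presence matrix, logistic tests."""

import math

import numpy as np
import pandas as pd
import pytest

from prdm9bind.repeats import (
    additive_score,
    align_to_consensus,
    cobinding_glm,
    firth_fit,
    forward_selection,
    kmer_presence_matrix,
    logistic_fit,
    single_association,
    woolf_estimates,
)


from _oracles import nw_affine_score


def _copies(seqs):
    return [{"copy_id": f"c{i}", "sequence": s} for i, s in enumerate(seqs)]


CONS = "ACGTACGGTTCAGCATCGATCGGCTAGCTAGCATCGATTACGGATCGAGT" * 2  # 100 bp


class TestAlignment:
    def test_identity_alignment(self):
        out = align_to_consensus(_copies([CONS]), CONS)
        assert (out[0].consensus_coords == np.arange(len(CONS))).all()
        assert out[0].identity == 1.0

    def test_single_substitution_keeps_coordinates(self):
        mutated = CONS[:40] + ("A" if CONS[40] != "A" else "C") + CONS[41:]
        out = align_to_consensus(_copies([mutated]), CONS)
        assert (out[0].consensus_coords == np.arange(len(CONS))).all()
        assert out[0].identity == pytest.approx(1 - 1 / len(CONS))

    def test_deletion_skips_consensus_base(self):
        deleted = CONS[:60] + CONS[61:]
        out = align_to_consensus(_copies([deleted]), CONS)
        coords = out[0].consensus_coords
        assert 60 not in coords
        assert (np.diff(coords) > 0).all()

    def test_insertion_marked_minus_one(self):
        inserted = CONS[:50] + "T" + CONS[50:]
        out = align_to_consensus(_copies([inserted]), CONS)
        coords = out[0].consensus_coords
        assert (coords == -1).sum() == 1

    def test_scores_match_gotoh_oracle_on_toy_pairs(self):
        """PairwiseAligner scores equal an independent affine-gap DP."""
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -5
        aligner.extend_gap_score = -1
        rng = np.random.default_rng(4)
        for _ in range(12):
            a = "".join(rng.choice(list("ACGT"), 20))
            b = list(a)
            for pos in rng.integers(0, 19, 3):
                b[pos] = "ACGT"[rng.integers(4)]
            if rng.random() < 0.5:
                del b[int(rng.integers(0, len(b)))]
            b = "".join(b)
            assert aligner.score(a, b) == pytest.approx(nw_affine_score(a, b))

    def test_short_copy_flagged_unusable(self):
        out = align_to_consensus(_copies([CONS[:30]]), CONS)
        assert not out[0].usable

    def test_short_consensus_rejected(self):
        with pytest.raises(ValueError):
            align_to_consensus(_copies([CONS]), "ACGT")


class TestPresenceMatrix:
    def test_planted_kmer_column(self):
        seqs = [CONS, CONS[:20] + "ATCCATG" + CONS[27:], CONS]
        mat, pos = kmer_presence_matrix(align_to_consensus(_copies(seqs), CONS), 7)
        assert "ATCCATG" in mat.columns
        assert list(mat["ATCCATG"]) == [False, True, False]
        assert pos["ATCCATG"] == 20

    def test_identical_copies_identical_rows(self):
        mat, _ = kmer_presence_matrix(align_to_consensus(_copies([CONS] * 4), CONS), 7)
        assert (mat.to_numpy() == mat.to_numpy()[0]).all()

    def test_column_count_bounded_by_distinct_kmers(self):
        aligned = align_to_consensus(_copies([CONS, CONS[::-1]]), CONS)
        mat, _ = kmer_presence_matrix(aligned, 7)
        distinct = set()
        for rc in aligned:
            distinct |= {rc.sequence[i : i + 7] for i in range(len(rc.sequence) - 6)}
        assert mat.shape[1] <= len(distinct)

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            kmer_presence_matrix([], 4)


class TestLogistic:
    def test_2x2_matches_woolf_closed_form(self):
        """Spec worked example: OR 0.2593, beta -1.3499, SE 0.3984."""
        pres = np.r_[np.ones(100), np.zeros(100)]
        y = np.r_[np.ones(10), np.zeros(90), np.ones(30), np.zeros(70)]
        rec = single_association(pres, y)
        assert rec.beta == pytest.approx(-1.3499, abs=1e-3)
        assert rec.se == pytest.approx(0.3984, abs=1e-3)
        assert rec.odds_ratio == pytest.approx(0.2593, abs=1e-3)

    def test_matches_statsmodels_with_covariates(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(6)
        n = 500
        x = (rng.random(n) < 0.4).astype(float)
        z = rng.normal(size=n)
        p = 1 / (1 + np.exp(-(-0.5 + 0.8 * x + 0.5 * z)))
        y = (rng.random(n) < p).astype(float)
        rec = single_association(x, y, covariates=z)
        X = sm.add_constant(np.column_stack([x, z]))
        fit = sm.Logit(y, X).fit(disp=0)
        assert rec.beta == pytest.approx(fit.params[1], abs=1e-5)
        assert rec.se == pytest.approx(fit.bse[1], abs=1e-4)

    def test_single_class_outcome_rejected(self):
        with pytest.raises(ValueError):
            single_association(np.r_[1.0, 0.0], np.r_[1.0, 1.0])

    def test_null_p_values_roughly_uniform(self):
        rng = np.random.default_rng(11)
        ps = []
        for _ in range(60):
            x = (rng.random(300) < 0.3).astype(float)
            y = (rng.random(300) < 0.2).astype(float)
            ps.append(single_association(x, y).p)
        ps = np.array(ps)
        assert (ps < 0.05).sum() <= 8
        assert ps.mean() == pytest.approx(0.5, abs=0.15)

    def test_complete_separation_flagged_with_firth_fallback(self):
        x = np.r_[np.ones(20), np.zeros(20)]
        y = x.copy()
        rec = single_association(x, y)
        assert rec.separated
        assert np.isfinite(rec.beta) and np.isfinite(rec.se)
        assert rec.p < 0.01

    def test_firth_shrinks_relative_to_mle(self):
        x = np.r_[np.ones(30), np.zeros(30)]
        y = np.r_[np.ones(28), np.zeros(2), np.ones(5), np.zeros(25)]
        X = np.column_stack([np.ones(60), x])
        b_mle, *_ = logistic_fit(X, y)
        b_firth, *_ = firth_fit(X, y)
        assert abs(b_firth[1]) < abs(b_mle[1])


class TestForwardSelection:
    def _planted(self, rng, n=1_500, beta=math.log(0.32)):
        causal = (rng.random(n) < 0.4).astype(float)
        # nine shadows: same presence pattern with 1.5% flips, so every
        # pair within the block correlates above the collapse threshold
        shadows = []
        for _ in range(9):
            flip = rng.random(n) < 0.015
            shadows.append(np.where(flip, 1 - causal, causal))
        noise = [(rng.random(n) < 0.3).astype(float) for _ in range(30)]
        cols = [causal] + shadows + noise
        names = ["CAUSAL0"] + [f"SHADOW{i}" for i in range(9)] + [f"NOISE{i}" for i in range(30)]
        logit = -1.0 + beta * causal
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        mat = pd.DataFrame(np.column_stack(cols), columns=names)
        positions = {nm: 100 for nm in names[:10]}
        positions.update({nm: 300 for nm in names[10:]})
        return mat, y, positions

    def test_causal_kmer_selected_and_shadows_collapsed(self):
        rng = np.random.default_rng(13)
        mat, y, positions = self._planted(rng)
        sel = forward_selection(mat, y, positions=positions)
        assert len(sel) >= 1
        first = sel[0]
        assert first.kmer.startswith(("CAUSAL", "SHADOW"))
        assert first.beta < 0
        # the causal column or an equivalent shadow is selected; the rest of
        # the correlated block is absorbed, never reported as independent
        selected = {rec.kmer for rec in sel}
        collapsed = set().union(*(rec.collapsed for rec in sel))
        assert not any(k.startswith("NOISE") for k in selected)
        assert len(collapsed) >= 8
        assert selected | collapsed >= {"CAUSAL0"} | {f"SHADOW{i}" for i in range(9)} - selected

    def test_null_outcome_selects_nothing_in_most_seeds(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(700 + seed)
            mat = pd.DataFrame(
                (rng.random((400, 80)) < 0.3).astype(float),
                columns=[f"k{i}" for i in range(80)],
            )
            y = (rng.random(400) < 0.25).astype(float)
            hits += bool(forward_selection(mat, y))
        assert hits <= 3

    def test_two_independent_effects_recovered_with_signs(self):
        rng = np.random.default_rng(17)
        n = 4_000
        a = (rng.random(n) < 0.35).astype(float)
        b = (rng.random(n) < 0.35).astype(float)
        noise = [(rng.random(n) < 0.3).astype(float) for _ in range(20)]
        mat = pd.DataFrame(
            np.column_stack([a, b] + noise),
            columns=["DOWN", "UP"] + [f"n{i}" for i in range(20)],
        )
        logit = -1.2 + math.log(0.32) * a + math.log(2.0) * b
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        sel = forward_selection(mat, y)
        got = {rec.kmer: rec for rec in sel}
        assert "DOWN" in got and got["DOWN"].beta < 0
        assert "UP" in got and got["UP"].beta > 0


class TestAdditiveScore:
    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError):
            additive_score([], pd.DataFrame(), np.array([0.0, 1.0]))

    def test_single_motif_two_score_levels(self):
        from prdm9bind.repeats import AssociationRecord

        beta = math.log(0.32)
        rec = AssociationRecord("AAAAAAA", 10, beta, 0.1, 1e-5)
        mat = pd.DataFrame({"AAAAAAA": [True, False, True, False]})
        y = np.array([0.0, 1.0, 0.0, 1.0])
        out = additive_score([rec], mat, y)
        assert set(np.round(np.unique(out.scores), 4)) == {0.0, round(beta, 4)}

    def test_score_invariant_to_record_order(self):
        from prdm9bind.repeats import AssociationRecord

        rng = np.random.default_rng(23)
        mat = pd.DataFrame(
            (rng.random((200, 3)) < 0.5), columns=["A" * 7, "C" * 7, "G" * 7]
        )
        y = (rng.random(200) < 0.3).astype(float)
        recs = [
            AssociationRecord("A" * 7, 0, -1.1, 0.1, 1e-4),
            AssociationRecord("C" * 7, 0, 0.7, 0.1, 1e-4),
            AssociationRecord("G" * 7, 0, -0.4, 0.1, 1e-4),
        ]
        s1 = additive_score(recs, mat, y).scores
        s2 = additive_score(recs[::-1], mat, y).scores
        assert np.allclose(s1, s2)

    def test_generative_model_gives_monotone_bin_frequencies(self):
        rng = np.random.default_rng(29)
        n = 6_000
        from prdm9bind.repeats import AssociationRecord

        presence = (rng.random((n, 2)) < 0.5).astype(float)
        betas = np.array([-1.2, 0.9])
        logit = -1.0 + presence @ betas
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        mat = pd.DataFrame(presence.astype(bool), columns=["T" * 7, "G" * 7])
        recs = [
            AssociationRecord("T" * 7, 0, betas[0], 0.1, 1e-6),
            AssociationRecord("G" * 7, 0, betas[1], 0.1, 1e-6),
        ]
        out = additive_score(recs, mat, y, n_bins=4)
        occupied = [m for m, s in zip(out.bin_means, out.bin_se) if s > 0]
        diffs = np.diff(occupied)
        assert (diffs > -0.05).all() and diffs.sum() > 0


class TestCobindingGLM:
    def test_log2_conversion_exact(self):
        rng = np.random.default_rng(31)
        n = 2_000
        x = (rng.random(n) < 0.3).astype(float)
        logit = -1.0 - math.log(2.0) * x  # exact twofold odds reduction
        y = (rng.random(n) < 1 / (1 + np.exp(-logit))).astype(float)
        out = cobinding_glm(y, {"TRIM28": x})
        row = out.iloc[0]
        assert row.ci_lo <= -1.0 <= row.ci_hi
        assert row.log2_odds == pytest.approx(-1.0, abs=0.45)

    def test_factor_below_30_instances_excluded(self):
        y = np.r_[np.ones(50), np.zeros(50)]
        x29 = np.r_[np.ones(29), np.zeros(71)]
        x30 = np.r_[np.ones(30), np.zeros(70)]
        out = cobinding_glm(y, {"few": x29, "enough": x30})
        assert list(out.factor) == ["enough"]

    def test_natural_log_to_log2_identity(self):
        assert woolf_estimates(10, 10, 20, 10)[0] / math.log(2) == pytest.approx(
            math.log2((10 * 10) / (10 * 20))
        )
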