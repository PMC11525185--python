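"""Attribution (sampled integrated gradients), contribution blocks,
contribution-space motif scanning, motif-level summaries, NMF programs,
saturation effects and k-mer diversity."""

import numpy as np
import pandas as pd
import pytest

from credesign import nn
from credesign.interpret import (ContributionMap, ablate_blocks, call_blocks,
                                 contribution_motif_scan, cooccurrence,
                                 kmer_diversity, motif_ablation,
                                 motif_contribution_summary,
                                 motif_count_matrix, motif_embed_background,
                                 nmf_programs, pattern_to_pwm,
                                 sampled_integrated_gradients,
                                 saturation_effects, _window_pearson)
from credesign.seqcore import (MotifModel, encode_onehot, random_sequences,
                               reverse_complement)


def _sig_oracle(W, onehot, scale=8.0, n_alpha=4000):
    """Deterministic quadrature of the expected SIG integrand for a linear
    model: no sampling, dense midpoint rule over the path."""
    alphas = (np.arange(n_alpha) + 0.5) / n_alpha
    hyp = np.zeros((W.shape[2],) + onehot.shape)
    for c in range(W.shape[2]):
        w = W[:, :, c]
        for a in alphas:
            p = nn.softmax(a * scale * onehot, axis=-1)
            hyp[c] += nn.softmax_backward(p, w, axis=-1)
    return scale * hyp / n_alpha


class TestSampledIntegratedGradients:
    def test_matches_closed_form_on_linear_model(self, linear_scorer_factory):
        rng = np.random.default_rng(0)
        L, C = 24, 2
        W = rng.normal(0, 1, (L, 4, C))
        model = linear_scorer_factory(W)
        x = random_sequences(1, L, rng)[0]
        oracle = _sig_oracle(W, x)
        runs = [sampled_integrated_gradients(model, x, n_path_points=16,
                                             samples_per_point=16, seed=s).masked
                for s in range(4)]
        mean = np.mean(runs, axis=0)
        se = np.std(runs, axis=0, ddof=1) / np.sqrt(len(runs))
        diff = np.abs(mean - oracle * x[None])
        assert np.all(diff <= np.maximum(3 * se, 5e-3))

    def test_completeness_on_linear_model(self, linear_scorer_factory):
        rng = np.random.default_rng(1)
        L, C = 30, 2
        W = rng.normal(0, 1, (L, 4, C))
        model = linear_scorer_factory(W)
        x = random_sequences(1, L, rng)[0]
        cmap = sampled_integrated_gradients(model, x, n_path_points=24,
                                            samples_per_point=32, seed=2)
        fx = model.predict(x[None])[0]
        e_bg = W.mean(axis=1).sum(axis=0)  # uniform background expectation
        totals = cmap.masked.sum(axis=(1, 2))
        assert np.allclose(totals, fx - e_bg, atol=0.25)

    def test_constant_model_gives_zero_scores(self, linear_scorer_factory):
        model = linear_scorer_factory(np.zeros((20, 4, 2)))
        x = random_sequences(1, 20, np.random.default_rng(3))[0]
        cmap = sampled_integrated_gradients(model, x, seed=4)
        assert np.allclose(cmap.hypothetical, 0.0)

    def test_seed_reproducible(self, linear_scorer_factory):
        rng = np.random.default_rng(5)
        model = linear_scorer_factory(rng.normal(0, 1, (20, 4, 2)))
        x = random_sequences(1, 20, rng)[0]
        a = sampled_integrated_gradients(model, x, seed=9)
        b = sampled_integrated_gradients(model, x, seed=9)
        assert np.array_equal(a.hypothetical, b.hypothetical)

    def test_masked_is_hypothetical_times_onehot(self, linear_scorer_factory):
        rng = np.random.default_rng(6)
        model = linear_scorer_factory(rng.normal(0, 1, (20, 4, 2)))
        x = random_sequences(1, 20, rng)[0]
        cmap = sampled_integrated_gradients(model, x, seed=10)
        assert np.array_equal(cmap.masked, cmap.hypothetical * x[None])
        assert (np.count_nonzero(cmap.masked, axis=2) <= 1).all()


class TestCallBlocks:
    def test_zero_track_no_blocks(self):
        assert call_blocks(np.zeros(100)) == []

    def test_plateau_block_coverage(self):
        track = np.zeros(100)
        track[50:60] = 0.1
        blocks = call_blocks(track)
        assert len(blocks) == 1
        b = blocks[0]
        assert b.sign == "+" and b.start <= 51 and b.end >= 59

    def test_short_spike_rejected_by_min_run(self):
        track = np.zeros(100)
        track[50] = 0.05  # smoothed peak spans < 4 positions above threshold
        smoothed_hits = call_blocks(track, thresh=0.015)
        assert smoothed_hits == []

    def test_negative_blocks_symmetric(self):
        track = np.zeros(80)
        track[20:30] = -0.1
        blocks = call_blocks(track)
        assert len(blocks) == 1 and blocks[0].sign == "-"

    def test_translation_equivariance(self):
        rng = np.random.default_rng(7)
        track = np.zeros(200)
        track[40:55] = 0.08
        track[120:130] = -0.06
        b1 = call_blocks(track)
        b2 = call_blocks(np.roll(track, 10))
        assert [(b.start + 10, b.end + 10, b.sign) for b in b1] == \
            [(b.start, b.end, b.sign) for b in b2]


class TestAblateBlocks:
    def test_empty_blocks_empty_table(self, surrogate_model):
        x = random_sequences(1, 200, np.random.default_rng(8))[0]
        out = ablate_blocks(surrogate_model, x, [], mode="positive")
        assert len(out) == 0

    def test_positive_block_ablation_drops_target_activity(
            self, grammar, surrogate_model):
        """Disrupting positive-contribution blocks called from SIG maps
        lowers the predicted activity of the target cell (median < 0)."""
        rng = np.random.default_rng(9)
        deltas = []
        for i in range(25):
            seq = list("".join("ACGT"[b] for b in rng.integers(0, 4, 200)))
            for j, (m, _) in enumerate(grammar.activators["cellA"]):
                p = 40 + 60 * j
                seq[p:p + m.width] = list(m.consensus)
            x = encode_onehot("".join(seq))
            cmap = sampled_integrated_gradients(surrogate_model, x,
                                                n_path_points=8,
                                                samples_per_point=4, seed=i)
            blocks = call_blocks(cmap.per_position[0], cell="cellA")
            table = ablate_blocks(surrogate_model, x, blocks, mode="positive",
                                  seed=i)
            if len(table):
                deltas.append(table["delta_cellA"].sum())
        assert len(deltas) >= 15
        assert np.median(deltas) < 0

    def test_outside_mode_minimum_positions(self, surrogate_model):
        from credesign.interpret import ContributionBlock

        x = random_sequences(1, 200, np.random.default_rng(10))[0]
        blocks = [ContributionBlock(start=20, end=26, sign="+", mean_score=0.1)]
        out = ablate_blocks(surrogate_model, x, blocks, mode="outside", seed=0)
        assert len(out) == 1
        assert out["n_positions"].iloc[0] >= 5


class TestPatternToPwm:
    def test_argmax_preserved(self):
        rng = np.random.default_rng(11)
        pattern = rng.normal(0, 0.3, (8, 4))
        pattern[np.arange(8), rng.integers(0, 4, 8)] += 1.5
        motif = pattern_to_pwm(pattern, "positive")
        assert np.array_equal(motif.ppm.argmax(axis=1), pattern.argmax(axis=1))

    def test_scale_invariance(self):
        rng = np.random.default_rng(12)
        pattern = rng.normal(0, 1, (6, 4))
        a = pattern_to_pwm(pattern, "positive")
        b = pattern_to_pwm(3.7 * pattern, "positive")
        assert np.allclose(a.ppm, b.ppm)

    def test_uniform_rows_give_uniform_ppm(self):
        pattern = np.full((5, 4), 0.2)
        motif = pattern_to_pwm(pattern, "positive")
        assert np.allclose(motif.ppm, 0.25)

    def test_negative_polarity_flips_negative_rows(self):
        pattern = np.zeros((4, 4))
        pattern[:2, 0] = 0.5          # positive portion prefers A
        pattern[2:, 3] = -0.5         # negative portion: repressive T
        motif = pattern_to_pwm(pattern, "negative")
        assert motif.ppm[2:, 3].argmax() == 0 or motif.ppm[2:].argmax(axis=1).tolist() == [3, 3]
        # the flipped rows now carry the largest magnitude (x1.2)
        assert np.abs(motif.cwm).max() == pytest.approx(0.5)

    def test_all_zero_pattern_rejected(self):
        with pytest.raises(ValueError):
            pattern_to_pwm(np.zeros((5, 4)))


def _map_from_track(hyp, cells=("c0",)):
    return ContributionMap(hypothetical=hyp, masked=hyp, seq_id="s",
                           cell_names=tuple(cells))


class TestContributionScan:
    def test_exact_window_is_hit(self):
        rng = np.random.default_rng(13)
        cwm = rng.normal(0, 1, (8, 4))
        motif = MotifModel(np.full((8, 4), 0.25), id="m", cwm=cwm)
        hyp = np.zeros((1, 60, 4))
        hyp[0, 20:28] = cwm
        hyp += rng.normal(0, 0.01, hyp.shape)
        cmap = ContributionMap(hypothetical=hyp, masked=hyp, seq_id="s0",
                               cell_names=("c0",))
        hits = contribution_motif_scan([motif], [cmap], sample_n=1000, seed=0)
        assert len(hits) >= 1
        top = hits.sort_values("r", ascending=False).iloc[0]
        assert top["start"] == 20 and top["strand"] == "+"
        assert top["r"] > 0.99

    def test_window_pearson_matches_brute_force(self):
        rng = np.random.default_rng(14)
        for _ in range(20):
            w = int(rng.integers(4, 9))
            cwm = rng.normal(0, 1, (w, 4))
            maps = rng.normal(0, 1, (3, 30, 4))
            r = _window_pearson(maps, cwm)
            for n in range(3):
                for p in range(30 - w + 1):
                    window = maps[n, p:p + w].ravel()
                    expected = np.corrcoef(window, cwm.ravel())[0, 1]
                    assert r[n, p] == pytest.approx(expected, abs=1e-9)

    def test_zero_variance_window_excluded(self):
        cwm = np.ones((4, 4))
        r = _window_pearson(np.zeros((1, 10, 4)), cwm + np.random.default_rng(0).random((4, 4)))
        assert np.isnan(r).all()

    def test_reverse_complement_orientation_found(self):
        rng = np.random.default_rng(15)
        cwm = rng.normal(0, 1, (8, 4))
        motif = MotifModel(np.full((8, 4), 0.25), id="m", cwm=cwm)
        hyp = np.zeros((1, 60, 4))
        hyp[0, 30:38] = reverse_complement(cwm)
        cmap = ContributionMap(hypothetical=hyp, masked=hyp, seq_id="s0",
                               cell_names=("c0",))
        hits = contribution_motif_scan([motif], [cmap], sample_n=1000, seed=0)
        minus = hits[hits["strand"] == "-"]
        assert len(minus) >= 1 and minus.iloc[0]["start"] == 30


class TestMotifProbes:
    def test_embed_uniform_motif_no_effect(self, surrogate_model):
        motif = MotifModel(np.full((10, 4), 0.25), id="uniform")
        out = motif_embed_background(surrogate_model, motif, n=400, seed=0)
        assert np.all(np.abs(out["delta"]) < 3 * out["se"] + 0.05)

    def test_embed_activator_raises_target_cell(self, grammar, surrogate_model):
        motif = grammar.activators["cellA"][0][0]
        out = motif_embed_background(surrogate_model, motif, n=400, seed=1)
        assert out["delta"][0] > 0.3

    def test_ablation_requires_hits(self, surrogate_model):
        out = motif_ablation(surrogate_model, {}, pd.DataFrame(
            columns=["seq_id", "start", "end"]))
        assert len(out) == 0

    def test_ablating_planted_activator_lowers_target(self, grammar,
                                                      surrogate_model):
        rng = np.random.default_rng(16)
        motif = grammar.activators["cellB"][0][0]
        seqs, hits = {}, []
        for i in range(30):
            seq = list("".join("ACGT"[b] for b in rng.integers(0, 4, 200)))
            p = int(rng.integers(0, 190))
            seq[p:p + motif.width] = list(motif.consensus)
            sid = f"s{i}"
            seqs[sid] = encode_onehot("".join(seq)).matrix
            hits.append({"seq_id": sid, "start": p, "end": p + motif.width})
        out = motif_ablation(surrogate_model, seqs, pd.DataFrame(hits),
                             n_random=3, seed=2)
        assert len(out) == 30
        assert out["delta_cellB"].median() < 0


class TestContributionSummary:
    def test_single_instance_equals_span_sum(self):
        hyp = np.zeros((1, 20, 4))
        hyp[0, 5:9, 1] = 0.25
        cmap = ContributionMap(hypothetical=hyp, masked=hyp, seq_id="s0",
                               cell_names=("c0",))
        hits = pd.DataFrame([{"seq_id": "s0", "cell": "c0", "motif_id": "m",
                              "start": 5, "end": 9, "strand": "+", "r": 0.9}])
        out = motif_contribution_summary(hits, {"s0": cmap})
        assert out["contribution_c0"].iloc[0] == pytest.approx(1.0)
        assert out["directionality"].iloc[0] == "activator"

    def test_negative_sums_give_repressor(self):
        hyp = np.zeros((1, 20, 4))
        hyp[0, 5:9, 1] = -0.25
        cmap = ContributionMap(hypothetical=hyp, masked=hyp, seq_id="s0",
                               cell_names=("c0",))
        hits = pd.DataFrame([{"seq_id": "s0", "cell": "c0", "motif_id": "m",
                              "start": 5, "end": 9, "strand": "+", "r": 0.9}])
        out = motif_contribution_summary(hits, {"s0": cmap})
        assert out["directionality"].iloc[0] == "repressor"


class TestCooccurrence:
    def _hits(self):
        rows = []
        # s1 has m1+m2, s2 has m1, s3 has m2, s4 has none
        for sid, motifs in [("s1", ["m1", "m2"]), ("s2", ["m1"]),
                            ("s3", ["m2"]), ("s4", [])]:
            for m in motifs:
                rows.append({"seq_id": sid, "cell": "c", "motif_id": m,
                             "start": 0, "end": 5, "strand": "+", "r": 1.0})
        return pd.DataFrame(rows)

    def test_exact_percentages(self):
        out = cooccurrence(self._hits(), {"all": ["s1", "s2", "s3", "s4"]})
        mat = out["all"]
        assert mat.loc["m1", "m1"] == pytest.approx(50.0)   # s1, s2
        assert mat.loc["m1", "m2"] == pytest.approx(25.0)   # s1 only
        assert mat.loc["m2", "m1"] == mat.loc["m1", "m2"]

    def test_motif_in_every_sequence_self_100(self):
        hits = pd.DataFrame([{"seq_id": s, "cell": "c", "motif_id": "m",
                              "start": 0, "end": 4, "strand": "+", "r": 1.0}
                             for s in ["a", "b"]])
        out = cooccurrence(hits, {"g": ["a", "b"]})
        assert out["g"].loc["m", "m"] == pytest.approx(100.0)

    def test_empty_group_warns_nan(self):
        with pytest.warns(UserWarning):
            out = cooccurrence(self._hits(), {"empty": []})
        assert out["empty"].isna().all().all()


class TestNmfPrograms:
    def test_block_structure_support_recovery(self):
        rng = np.random.default_rng(17)
        X = np.zeros((60, 8))
        X[:30, :4] = rng.poisson(3, (30, 4))
        X[30:, 4:] = rng.poisson(3, (30, 4))
        dec = nmf_programs(X, k=2, seed=0)
        top = [set(np.argsort(-dec.H[i])[:4]) for i in range(2)]
        assert {frozenset(t) for t in top} == {frozenset({0, 1, 2, 3}),
                                              frozenset({4, 5, 6, 7})}

    def test_error_nesting_in_k(self):
        rng = np.random.default_rng(18)
        X = rng.poisson(2, (40, 6)).astype(float)
        e1 = nmf_programs(X, k=1, seed=0).reconstruction_error
        e6 = nmf_programs(X, k=6, seed=0).reconstruction_error
        assert e6 <= e1

    def test_deterministic(self):
        rng = np.random.default_rng(19)
        X = rng.poisson(2, (30, 6)).astype(float)
        a = nmf_programs(X, k=3, seed=5)
        b = nmf_programs(X, k=3, seed=5)
        assert np.allclose(a.W, b.W) and np.allclose(a.H, b.H)

    def test_k_too_large_rejected(self):
        with pytest.raises(ValueError):
            nmf_programs(np.ones((4, 3)), k=5)

    def test_normalized_rows_and_program_function_clip(self):
        rng = np.random.default_rng(20)
        X = rng.poisson(2, (20, 5)).astype(float)
        contrib = np.array([[10.0, -1.0]] * 5)  # clipped to 3 upstream
        dec = nmf_programs(X, k=2, seed=0, motif_contributions=contrib)
        sums = dec.W_normalized.sum(axis=1)
        assert np.all((np.isclose(sums, 1.0)) | (sums == 0))
        assert dec.program_function.max() <= 3.0 + 1e-9

    def test_count_matrix_construction(self):
        hits = pd.DataFrame([
            {"seq_id": "a", "cell": "c0", "motif_id": "m1", "start": 0,
             "end": 5, "strand": "+", "r": 1.0},
            {"seq_id": "a", "cell": "c1", "motif_id": "m1", "start": 0,
             "end": 5, "strand": "+", "r": 1.0},   # same locus, other cell
            {"seq_id": "a", "cell": "c0", "motif_id": "m1", "start": 9,
             "end": 14, "strand": "+", "r": 1.0},
        ])
        X, ids = motif_count_matrix(hits, ["a", "b"])
        assert ids == ["m1"]
        assert X[0, 0] == 2 and X[1, 0] == 0


class TestSaturation:
    def _variants(self, length=10, effect=0.0):
        rows = []
        for p in range(length):
            for alt in range(3):
                rows.append({"position": p, "alt": "ACG"[alt],
                             "activity": 1.0 + effect})
        return pd.DataFrame(rows)

    def test_all_equal_reference_zero_effects(self):
        effects, summary = saturation_effects(1.0, self._variants(), length=10)
        assert np.allclose(effects["effect"], 0.0)
        assert np.allclose(summary, 0.0)

    def test_sign_convention(self):
        effects, summary = saturation_effects(1.0, self._variants(effect=-2.0),
                                              length=10)
        assert np.allclose(summary, 2.0)  # drops plot upward

    def test_incomplete_table_reports_positions(self):
        v = self._variants().iloc[:-2]
        with pytest.raises(ValueError, match="9"):
            saturation_effects(1.0, v, length=10)


class TestKmerDiversity:
    def test_identical_sequences_zero(self):
        seqs = ["ACGTACGTAC" * 4] * 6
        assert np.allclose(kmer_diversity(seqs), 0.0)

    def test_single_substitution_bounded_distance(self):
        base = "ACGTACGTACGTACGTACGT" * 2
        variant = base[:10] + ("A" if base[10] != "A" else "C") + base[11:]
        seqs = [base, variant] + [base] * 4
        d = kmer_diversity(seqs, k=4, n_neighbors=1)
        # one substitution changes at most k k-mers each way
        assert d[1] <= 2 * 4

    def test_order_invariance(self):
        rng = np.random.default_rng(21)
        seqs = ["".join("ACGT"[b] for b in rng.integers(0, 4, 50))
                for _ in range(8)]
        d1 = kmer_diversity(seqs)
        perm = [5, 2, 7, 0, 3, 6, 1, 4]
        d2 = kmer_diversity([seqs[i] for i in perm])
        assert np.allclose(d1[perm], d2)

    def test_too_few_sequences_rejected(self):
        with pytest.raises(ValueError):
            kmer_diversity(["ACGTACGT"] * 3, n_neighbors=4)
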