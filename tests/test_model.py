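"""Strength models: k-mer lasso, DenseNet structure, evolution, attribution."""

import numpy as np
import pytest

from termstarr import model, nn, synthio
from termstarr.features import count_kmers, kmer_universe
from termstarr.model import DenseNetConfig


class TestChannelSchedule:
    def test_default_concatenation_arithmetic(self):
        sched = model.channel_schedule(DenseNetConfig())
        assert sched[0]["channels_after_block"] == 128 + 6 * 12 == 200
        assert sched[0]["channels_after_transition"] == 100
        assert sched[1]["channels_after_block"] == 100 + 12 * 12
        assert sched[3]["channels_after_block"] == sched[2]["channels_after_transition"] + 16 * 12

    def test_matches_hand_recursion_any_config(self):
        cfg = DenseNetConfig(initial_filters=20, block_layers=(3, 5),
                             growth_filters=7)
        sched = model.channel_schedule(cfg)
        c = 20
        for stage, n_layers in zip(sched, (3, 5)):
            c_after = c + n_layers * 7
            assert stage["channels_after_block"] == c_after
            c = stage["channels_after_transition"]

    def test_vanishing_feature_map_errors(self):
        cfg = DenseNetConfig(input_length=4, block_layers=(1, 1, 1, 1, 1),
                             transition_pool=4)
        with pytest.raises(ValueError, match="block"):
            model.channel_schedule(cfg)

    def test_outputs_dimension_two(self):
        assert DenseNetConfig().outputs == 2


class TestDenseNetForward:
    def test_smoke_two_finite_outputs(self):
        m = model.build_densenet(DenseNetConfig(), seed=0)
        out = m.forward(model.one_hot(["A" * 170]))
        assert out.shape == (1, 2)
        assert np.isfinite(out).all()

    def test_structural_channels_observed_at_runtime(self):
        # probe the actual first block + transition of the default network
        m = model.build_densenet(DenseNetConfig(), seed=0)
        x = model.one_hot(["ACGT" * 42 + "AC"])
        h = m.net.layers[0].forward(x, False)
        assert h.shape[1] == 128
        h = m.net.layers[1].forward(h, False)      # dense block 1
        assert h.shape[1] == 200
        for layer in m.net.layers[2:6]:            # BN, ReLU, conv1x1, pool
            h = layer.forward(h, False)
        assert h.shape[1] == 100
        assert h.shape[2] == 85

    def test_predict_rejects_bad_input(self):
        m = model.build_densenet(DenseNetConfig(initial_filters=8,
                                                block_layers=(1,),
                                                growth_filters=4), seed=0)
        with pytest.raises(ValueError, match="length"):
            m.predict(["ACGT"])
        with pytest.raises(ValueError, match="invalid base"):
            m.predict(["N" * 170])

    def test_predict_deterministic(self):
        m = model.build_densenet(DenseNetConfig(initial_filters=8,
                                                block_layers=(1,),
                                                growth_filters=4), seed=0)
        seqs = ["ACGT" * 42 + "AC", "A" * 170]
        a = m.predict(seqs)
        b = m.predict(seqs)
        assert np.array_equal(a, b)
        assert a.shape == (2, 2)


class TestGradients:
    def test_finite_difference_small_net(self, rng):
        # ReLU omitted: its kink makes central differences unreliable at the
        # step sizes single precision supports
        net = nn.Sequential([
            nn.Conv1d(4, 5, 3, rng), nn.DenseBlock(5, 2, 3, 3, rng),
            nn.BatchNorm1d(11), nn.AvgPool1d(2), nn.Flatten(),
            nn.Linear(11 * 5, 2, rng)])
        X = rng.normal(size=(4, 4, 10)).astype(nn.DTYPE)
        Y = rng.normal(size=(4, 2)).astype(nn.DTYPE)

        def loss():
            z = net.forward(X, True)
            return float(((z - Y) ** 2).sum())

        for _, g in net.params():
            g[...] = 0
        z = net.forward(X, True)
        net.backward((2 * (z - Y)).astype(nn.DTYPE))
        checked = 0
        for p, g in net.params():
            for _ in range(2):
                i = tuple(rng.integers(s) for s in p.shape)
                if abs(g[i]) < 1e-2:
                    continue  # conv biases into BN have exact-zero gradients
                eps = 3e-2
                old = p[i]
                p[i] = old + eps
                lp = loss()
                p[i] = old - eps
                lm = loss()
                p[i] = old
                num = (lp - lm) / (2 * eps)
                # single precision and in-block ReLU kinks limit the
                # attainable finite-difference accuracy
                assert num == pytest.approx(float(g[i]), rel=0.25, abs=3e-2)
                checked += 1
        assert checked >= 5


class TestKmerLasso:
    def test_planted_linear_recovery(self, rng):
        k = 4
        seqs = ["".join("ACGT"[i] for i in rng.integers(4, size=60))
                for _ in range(400)]
        X = count_kmers(seqs, k=k).counts.astype(float)
        universe = kmer_universe(k)
        causal = [universe.index(m) for m in ("AATA", "TGTA", "GGGG")]
        weights = np.array([2.0, -1.5, 1.0])
        y = X[:, causal] @ weights
        fit = model.fit_kmer_lasso(seqs, {"tobacco": y, "maize": y}, k=k,
                                   split_seed=1)
        assert fit.heldout_r2["tobacco"] >= 0.99
        coefs = np.abs(fit.coefficients["tobacco"])
        top3 = set(np.argsort(coefs)[-3:])
        assert top3 == set(causal)

    def test_constant_response_errors(self, rng):
        seqs = ["".join("ACGT"[i] for i in rng.integers(4, size=30))
                for _ in range(120)]
        with pytest.raises(ValueError, match="constant"):
            model.fit_kmer_lasso(seqs, {"tobacco": np.ones(120)}, k=3)

    def test_too_few_sequences_errors(self):
        with pytest.raises(ValueError, match="100"):
            model.fit_kmer_lasso(["ACGTAC"] * 10, {"tobacco": np.arange(10.0)})

    def test_infinite_penalty_shrinks_to_intercept(self, rng):
        from sklearn.linear_model import Lasso

        seqs = ["".join("ACGT"[i] for i in rng.integers(4, size=30))
                for _ in range(150)]
        X = count_kmers(seqs, k=3).counts.astype(float)
        y = rng.normal(size=150)
        las = Lasso(alpha=1e9).fit(X, y)
        assert np.allclose(las.coef_, 0.0)


class TestTrainDensenet:
    CFG = DenseNetConfig(initial_filters=12, initial_kernel=5,
                         block_layers=(1,), growth_filters=6)

    def test_smoke_and_split_fractions(self):
        lib = synthio.make_library(150, seed=5)
        seqs = [r.sequence for r in lib]
        targets = np.array(
            [[np.log2(synthio.true_strength(s, "tobacco")),
              np.log2(synthio.true_strength(s, "maize"))] for s in seqs])
        res = model.train_densenet(seqs, targets, cfg=self.CFG, seed=0,
                                   max_epochs=3, patience=2)
        assert set(res.test_r2) == {"tobacco", "maize"}
        assert len(res.split_indices["train"]) == round(0.81 * 150)
        assert len(res.split_indices["val"]) == round(0.09 * 150)
        assert len(res.split_indices["test"]) == 150 - round(0.81 * 150) - round(0.09 * 150)

    def test_shuffled_labels_no_predictive_power(self, rng):
        lib = synthio.make_library(200, seed=6)
        seqs = [r.sequence for r in lib]
        targets = np.array(
            [[np.log2(synthio.true_strength(s, "tobacco")),
              np.log2(synthio.true_strength(s, "maize"))] for s in seqs])
        targets = targets[rng.permutation(len(targets))]
        res = model.train_densenet(seqs, targets, cfg=self.CFG, seed=0,
                                   max_epochs=8, patience=3)
        assert res.test_r2["tobacco"] < 0.15
        assert res.test_r2["maize"] < 0.15

    def test_bad_split_errors(self):
        with pytest.raises(ValueError, match="sum to 1"):
            model.train_densenet(["A" * 170] * 10, np.zeros((10, 2)),
                                 split=(0.5, 0.4, 0.2))


class TestEvolve:
    @staticmethod
    def a_count_scorer(seqs):
        return np.array([[s.count("A")] for s in seqs], dtype=float)

    def test_a_count_gains_one_per_round(self):
        start = "C" * 170
        traj = model.evolve(start, self.a_count_scorer, objective="tobacco",
                            rounds=3)
        objs = [s.objective for s in traj]
        assert objs == [0.0, 1.0, 2.0, 3.0]
        # lexicographic tie-break: first positions, base A
        assert [s.edited_position for s in traj[1:]] == [1, 2, 3]
        assert all(s.substituted_base == "A" for s in traj[1:])

    def test_zero_rounds_start_only(self):
        traj = model.evolve("A" * 170, self.a_count_scorer, objective="tobacco",
                            rounds=0)
        assert len(traj) == 1 and traj[0].sequence == "A" * 170

    def test_monotone_with_keep_current(self, rng):
        def gc_scorer(seqs):
            return np.array([[(s.count("G") + s.count("C")) / len(s)]
                             for s in seqs])

        for _ in range(5):
            start = "".join("ACGT"[i] for i in rng.integers(4, size=170))
            traj = model.evolve(start, gc_scorer, objective="tobacco",
                                rounds=5, keep_current=True)
            objs = [s.objective for s in traj]
            assert all(b >= a for a, b in zip(objs, objs[1:]))

    def test_edit_count_bounded_by_rounds(self, rng):
        start = "".join("ACGT"[i] for i in rng.integers(4, size=170))
        traj = model.evolve(start, self.a_count_scorer, objective="tobacco",
                            rounds=4)
        final = traj[-1].sequence
        assert sum(a != b for a, b in zip(start, final)) <= 4
        for prev, cur in zip(traj, traj[1:]):
            assert sum(a != b for a, b in zip(prev.sequence, cur.sequence)) <= 1

    def test_true_strength_evolution_gains_motifs(self):
        # starts scrubbed of all motifs; the strength surface rewards gaining
        # one, and single substitutions can complete near-motifs
        starts = synthio.make_library(10, seed=9, motif_prob=0.0,
                                      plant_cleavage_ca=False)

        def scorer(seqs):
            return np.array([[synthio.true_strength(s, "tobacco"),
                              synthio.true_strength(s, "maize")] for s in seqs])

        gained = 0
        for rec in starts:
            traj = model.evolve(rec.sequence, scorer, objective="both",
                                rounds=10, keep_current=True)
            final = traj[-1].sequence
            if any(synthio.has_motif(final, m) for m in
                   ("AAUAAA", "UGUA", "UG_rich")):
                gained += 1
        assert gained >= 8

    def test_negative_rounds_error(self):
        with pytest.raises(ValueError):
            model.evolve("A" * 170, self.a_count_scorer, rounds=-1)


class TestIsmAttribution:
    def test_linear_model_closed_form(self, rng):
        k = 3
        universe = kmer_universe(k)
        coef = rng.normal(size=len(universe))
        lin = model.KmerLassoModel(
            k=k, coefficients={"tobacco": coef, "maize": coef},
            intercepts={"tobacco": 0.0, "maize": 0.0},
            penalties={"tobacco": 0.0, "maize": 0.0},
            split_seed=0, heldout_r2={})
        seq = "".join("ACGT"[i] for i in rng.integers(4, size=30))
        delta = model.ism_attribution(lin, seq)
        assert delta.shape == (30, 4)
        # reference base deltas are zero
        for p, b in enumerate(seq):
            assert delta[p, "ACGT".index(b)] == 0.0
        # closed form: difference of summed k-mer coefficients
        base_counts = count_kmers([seq], k=k).counts[0]
        base_score = base_counts @ coef
        for p in (0, 7, 29):
            for bi, b in enumerate("ACGT"):
                if b == seq[p]:
                    continue
                mut = seq[:p] + b + seq[p + 1:]
                expected = count_kmers([mut], k=k).counts[0] @ coef - base_score
                assert delta[p, bi] == pytest.approx(expected)
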