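"""The four pre-training losses against explicit-loop oracles and closed forms."""

import numpy as np
import pytest

from molimage import nn
from molimage.encoders import GINConfig, GraphEncoder
from molimage.graphs import AttributeVocabulary, mask_graph
from molimage.nn import Tensor
from molimage.objectives import (EmbeddingPairBatch, FusionHead, GMHeads,
                                 LossReport, MatchBatch, MgmHead, gaussian_kl,
                                 gic_loss, gim_loss, gm_loss, mgm_loss,
                                 sample_hard_negatives, similarity_matrix,
                                 total_loss)

from conftest import check_gradients, make_chain, rel_err


def loop_info_nce(zg, zi, tau, kind="cosine", literal=False):
    """Brute-force symmetric InfoNCE by explicit loops (the oracle)."""
    def sim(a, b):
        if kind == "cosine":
            return float(a @ b / (np.linalg.norm(a) * np.linalg.norm(b)))
        return -float(np.sum((a - b) ** 2))

    k = len(zg)
    total = 0.0
    for mats in ((zg, zi), (zi, zg)):
        a, b = mats
        for i in range(k):
            pos = np.exp(sim(a[i], b[i]) / tau)
            if literal:
                denom = sum(np.exp(sim(a[i], b[j])) for j in range(k) if j != i)
            else:
                denom = sum(np.exp(sim(a[i], b[j]) / tau) for j in range(k))
            total += -np.log(pos / denom)
    return total / (2 * k)


class TestGIC:
    def test_uniform_similarity_equals_log_k(self):
        z = np.ones((4, 3))
        loss = gic_loss(EmbeddingPairBatch(z, z, temperature=1.0))
        assert np.isclose(loss.data, np.log(4), atol=1e-9)

    def test_two_pair_identity_similarity(self):
        loss = gic_loss(EmbeddingPairBatch(np.eye(2), np.eye(2),
                                           temperature=1.0))
        assert np.isclose(loss.data, -np.log(np.e / (np.e + 1)), atol=1e-9)

    def test_separated_pairs_small_temperature(self):
        z = np.eye(4)
        loss = gic_loss(EmbeddingPairBatch(z, z, temperature=0.01))
        assert loss.data < 1e-6

    @pytest.mark.parametrize("kind", ["cosine", "euclidean"])
    @pytest.mark.parametrize("literal", [False, True])
    def test_matches_explicit_loop_oracle(self, kind, literal):
        rng = np.random.default_rng(0)
        for k in (2, 5, 8):
            zg = rng.normal(size=(k, 4))
            zi = rng.normal(size=(k, 4))
            ours = gic_loss(EmbeddingPairBatch(zg, zi, 0.3, kind),
                            literal_denominator=literal).data
            oracle = loop_info_nce(zg, zi, 0.3, kind, literal)
            assert rel_err(float(ours), oracle) < 1e-6

    def test_symmetric_in_modalities(self):
        rng = np.random.default_rng(1)
        zg, zi = rng.normal(size=(5, 3)), rng.normal(size=(5, 3))
        a = gic_loss(EmbeddingPairBatch(zg, zi, 0.2)).data
        b = gic_loss(EmbeddingPairBatch(zi, zg, 0.2)).data
        assert np.isclose(float(a), float(b), atol=1e-12)

    def test_raising_matched_similarity_lowers_loss(self):
        rng = np.random.default_rng(2)
        zg, zi = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        base = gic_loss(EmbeddingPairBatch(zg, zi, 0.5, "euclidean")).data
        zi2 = zi.copy()
        zi2[0] = zi[0] * 0.5 + zg[0] * 0.5  # move matched image toward graph
        closer = gic_loss(EmbeddingPairBatch(zg, zi2, 0.5, "euclidean")).data
        assert closer < base

    def test_nonnegative_default_form(self):
        rng = np.random.default_rng(3)
        for s in range(5):
            zg = rng.normal(size=(6, 4))
            zi = rng.normal(size=(6, 4))
            assert gic_loss(EmbeddingPairBatch(zg, zi, 0.1)).data >= 0

    def test_domain_errors(self):
        with pytest.raises(ValueError, match="K >= 2"):
            gic_loss(EmbeddingPairBatch(np.ones((1, 2)), np.ones((1, 2))))
        with pytest.raises(ValueError, match="temperature"):
            EmbeddingPairBatch(np.ones((2, 2)), np.ones((2, 2)),
                               temperature=0.0)

    def test_gradient(self):
        rng = np.random.default_rng(4)
        zg = Tensor(rng.normal(size=(4, 3)), requires_grad=True)
        zi = Tensor(rng.normal(size=(4, 3)), requires_grad=True)
        check_gradients(lambda: gic_loss(EmbeddingPairBatch(zg, zi, 0.2)),
                        {"zg": zg, "zi": zi})


class TestMGM:
    @pytest.fixture
    def setup(self):
        vocab = AttributeVocabulary((6,), (3,))
        enc = GraphEncoder(GINConfig(2, 5, vocab, seed=0))
        head = MgmHead(5, 4, vocab.node_vocab_sizes, vocab.edge_vocab_sizes,
                       hidden=6, seed=1)
        graphs, specs = [], []
        for s in range(3):
            g = make_chain(5, atom=s + 1, bond=s % 3)
            m, sp = mask_graph(g, 0.6, vocab, seed=s + 10)
            graphs.append(m)
            specs.append(sp)
        zi = np.random.default_rng(2).normal(size=(3, 4))
        return vocab, enc, head, graphs, specs, zi

    def test_matches_explicit_loop_oracle(self, setup):
        vocab, enc, head, graphs, specs, zi = setup
        ours = float(mgm_loss(graphs, specs, Tensor(zi), enc, head).data)

        # oracle: per-graph forward, explicit softmax per masked position
        def softmax(v):
            e = np.exp(v - v.max())
            return e / e.sum()

        def mlp_np(mlp, x):
            for i, layer in enumerate(mlp.layers):
                x = x @ layer.weight.data + layer.bias.data
                if i < len(mlp.layers) - 1:
                    x = np.maximum(x, 0)
            return x

        total, count = 0.0, 0
        from molimage.encoders import GraphBatch
        for gi, (g, sp) in enumerate(zip(graphs, specs)):
            h = enc.node_embeddings(GraphBatch([g])).data
            for idx, tgt in zip(sp.masked_node_indices, sp.node_targets):
                ctx = np.concatenate([h[idx], zi[gi]])
                p = softmax(mlp_np(head.node_heads[0], ctx))
                total += -np.log(p[tgt[0]])
                count += 1
            arcs = sp.masked_edge_indices.reshape(-1, 2)[:, 0] \
                if len(sp.masked_edge_indices) else []
            for a, tgt in zip(arcs, sp.edge_targets[::2]):
                u, v = g.edge_index[a]
                ctx = np.concatenate([h[u] + h[v], zi[gi]])
                p = softmax(mlp_np(head.edge_heads[0], ctx))
                total += -np.log(p[tgt[0]])
                count += 1
        assert rel_err(ours, total / count) < 1e-6

    def test_uniform_head_gives_log_vocab(self):
        """Zeroed head weights -> uniform predictive distribution."""
        vocab = AttributeVocabulary((6,), (3,))
        enc = GraphEncoder(GINConfig(1, 4, vocab, seed=0))
        head = MgmHead(4, 3, (6,), (3,), hidden=5, seed=0)
        for p in head.params().values():
            p.data[:] = 0.0
        g = make_chain(4, atom=1)
        masked, spec = mask_graph(g, 1.0, vocab, seed=0)
        zi = np.zeros((1, 3))
        loss = mgm_loss([masked], [spec], Tensor(zi), enc, head).data
        # 4 node positions at log 6 and 3 bond positions at log 3
        expected = (4 * np.log(6) + 3 * np.log(3)) / 7
        assert np.isclose(float(loss), expected, atol=1e-9)

    def test_empty_mask_rejected(self, setup):
        vocab, enc, head, graphs, _specs, zi = setup
        _, empty = mask_graph(graphs[0], 0.0, vocab, 0)
        with pytest.raises(ValueError, match="mask"):
            mgm_loss([graphs[0]], [empty], Tensor(zi[:1]), enc, head)

    def test_gradient(self, setup):
        _vocab, enc, head, graphs, specs, zi = setup
        params = {**enc.params(), **head.params()}
        check_gradients(
            lambda: mgm_loss(graphs, specs, Tensor(zi), enc, head),
            params, n_coords=1)


class TestHardNegatives:
    def test_matched_index_excluded(self):
        rng = np.random.default_rng(0)
        sim = rng.normal(size=(6, 6))
        for seed in range(20):
            neg = sample_hard_negatives(sim, seed)
            assert np.all(neg != np.arange(6))

    def test_deterministic_given_seed(self):
        sim = np.random.default_rng(1).normal(size=(5, 5))
        assert np.array_equal(sample_hard_negatives(sim, 42),
                              sample_hard_negatives(sim, 42))

    def test_frequencies_follow_softmax(self):
        """Row (., 10, 0, 0): the similar negative dominates per its weight."""
        sim = np.array([[0.0, 10.0, 0.0, 0.0]] * 4)
        np.fill_diagonal(sim, 0.0)
        draws = 10_000
        rng = np.random.default_rng(7)
        counts = np.zeros(4)
        for _ in range(draws):
            counts[sample_hard_negatives(sim, rng)[0]] += 1
        w = np.exp([10.0, 0.0, 0.0])
        p_hard = w[0] / w.sum()
        se = np.sqrt(p_hard * (1 - p_hard) / draws)
        assert abs(counts[1] / draws - p_hard) < 3 * se

    def test_uniform_similarities_uniform_frequencies(self):
        sim = np.zeros((4, 4))
        rng = np.random.default_rng(8)
        counts = np.zeros(4)
        draws = 9_000
        for _ in range(draws):
            counts[sample_hard_negatives(sim, rng)[0]] += 1
        se = np.sqrt((1 / 3) * (2 / 3) / draws)
        assert np.all(np.abs(counts[1:] / draws - 1 / 3) < 3 * se)

    def test_too_small_batch(self):
        with pytest.raises(ValueError):
            sample_hard_negatives(np.zeros((1, 1)), 0)


class TestGIM:
    def test_perfect_predictions_near_zero(self):
        batch = MatchBatch(Tensor(np.array([1.0, 1.0, 0.0, 0.0])),
                           np.array([1.0, 1.0, 0.0, 0.0]))
        assert gim_loss(batch).data < 1e-5

    def test_coin_flip_gives_log_two(self):
        batch = MatchBatch(Tensor(np.full(6, 0.5)),
                           np.array([1, 1, 1, 0, 0, 0], dtype=float))
        assert np.isclose(gim_loss(batch).data, np.log(2), atol=1e-12)

    def test_hand_evaluated_two_two(self):
        probs = np.array([0.9, 0.8, 0.3, 0.1])
        labels = np.array([1.0, 1.0, 0.0, 0.0])
        expected = -0.25 * (np.log(0.9) + np.log(0.8) + np.log(0.7)
                            + np.log(0.9))
        assert np.isclose(gim_loss(MatchBatch(Tensor(probs), labels)).data,
                          expected, atol=1e-12)
        assert np.isclose(expected, 0.19763, atol=5e-5)

    def test_clamping_keeps_loss_finite(self):
        batch = MatchBatch(Tensor(np.array([0.0, 1.0])),
                           np.array([1.0, 0.0]))
        val = float(gim_loss(batch).data)
        assert np.isfinite(val) and val > 10

    def test_needs_both_classes(self):
        with pytest.raises(ValueError, match="positive"):
            MatchBatch(Tensor(np.array([0.5, 0.5])), np.array([1.0, 1.0]))

    def test_fusion_head_probability_and_gradient(self):
        head = FusionHead(3, hidden=4, seed=0)
        rng = np.random.default_rng(1)
        pg = Tensor(rng.normal(size=(4, 3)), requires_grad=True)
        pi = Tensor(rng.normal(size=(4, 3)), requires_grad=True)
        p = head.match_probability(pg, pi)
        assert np.all((p.data > 0) & (p.data < 1))
        labels = np.array([1.0, 1.0, 0.0, 0.0])
        params = {**head.params(), "pg": pg, "pi": pi}
        check_gradients(
            lambda: gim_loss(MatchBatch(head.match_probability(pg, pi),
                                        labels)), params, n_coords=2)


class TestGM:
    def test_per_dimension_kl_closed_form(self):
        # KL(N(1,1) || N(0,1)) = 0.5(mu^2 + s^2 - 1 - ln s^2) = 0.5
        kl = gaussian_kl(Tensor(np.ones((1, 1))), Tensor(np.zeros((1, 1))))
        assert np.isclose(kl.data, 0.5, atol=1e-12)

    def test_kl_matches_monte_carlo(self):
        rng = np.random.default_rng(0)
        mu = rng.normal(size=(1, 4))
        logvar = rng.normal(scale=0.5, size=(1, 4))
        closed = float(gaussian_kl(Tensor(mu), Tensor(logvar)).data)
        n = 100_000
        sd = np.exp(0.5 * logvar)
        x = mu + sd * rng.standard_normal((n, 4))
        log_q = (-0.5 * ((x - mu) / sd) ** 2 - np.log(sd)
                 - 0.5 * np.log(2 * np.pi)).sum(axis=1)
        log_p = (-0.5 * x ** 2 - 0.5 * np.log(2 * np.pi)).sum(axis=1)
        samples = log_q - log_p
        mc = samples.mean()
        se = samples.std() / np.sqrt(n)
        assert abs(closed - mc) < 3 * se

    def test_posterior_equal_prior_leaves_reconstruction_only(self):
        heads = GMHeads(3, 3, hidden=4, seed=0)
        for p in heads.params().values():
            p.data[:] = 0.0  # posteriors become N(0, I)
        rng = np.random.default_rng(1)
        zg, zi = rng.normal(size=(4, 3)), rng.normal(size=(4, 3))
        noise = (np.zeros((4, 3)), np.zeros((4, 3)))
        loss = float(gm_loss(zg, zi, heads, lambda_kl=5.0, noise=noise).data)
        # decoders also output zero, so loss = mean of 0.5*||z||^2 terms
        expected = 0.25 * ((zg ** 2).sum(1).mean() + (zi ** 2).sum(1).mean())
        assert np.isclose(loss, expected, atol=1e-12)

    def test_lambda_zero_is_pure_reconstruction(self):
        heads = GMHeads(2, 2, hidden=3, seed=1)
        rng = np.random.default_rng(2)
        zg, zi = rng.normal(size=(3, 2)), rng.normal(size=(3, 2))
        noise = (rng.standard_normal((3, 2)), rng.standard_normal((3, 2)))
        l0 = float(gm_loss(zg, zi, heads, 0.0, noise=noise).data)

        def mlp_np(mlp, x):
            for i, layer in enumerate(mlp.layers):
                x = x @ layer.weight.data + layer.bias.data
                if i < len(mlp.layers) - 1:
                    x = np.maximum(x, 0)
            return x

        # oracle: explicit per-sample reconstruction error, no KL
        total = 0.0
        for src, tgt, enc, dec, eps in ((zg, zg, heads.enc_g2i, heads.dec_i2g,
                                         noise[0]),
                                        (zi, zi, heads.enc_i2g, heads.dec_g2i,
                                         noise[1])):
            stats = mlp_np(enc, src)
            d = tgt.shape[1]
            mu, logvar = stats[:, :d], stats[:, d:]
            sample = mu + np.exp(0.5 * logvar) * eps
            recon = mlp_np(dec, sample)
            total += 0.5 * ((recon - tgt) ** 2).sum(axis=1).mean()
        assert rel_err(l0, total / 2) < 1e-9

    def test_gradient_with_fixed_noise(self):
        heads = GMHeads(3, 3, hidden=4, seed=2)
        rng = np.random.default_rng(3)
        zg = Tensor(rng.normal(size=(3, 3)), requires_grad=True)
        zi = Tensor(rng.normal(size=(3, 3)), requires_grad=True)
        noise = (rng.standard_normal((3, 3)), rng.standard_normal((3, 3)))
        params = {**heads.params(), "zg": zg, "zi": zi}
        check_gradients(lambda: gm_loss(zg, zi, heads, 0.1, noise=noise),
                        params, n_coords=2)


class TestTotal:
    def test_zero_components(self):
        total, report = total_loss({})
        assert total.data == 0.0 and report.total == 0.0

    def test_unit_weights_sum(self):
        total, report = total_loss({"gic": 1.0, "mgm": 2.0, "gim": 3.0,
                                    "gm": 4.0})
        assert total.data == 10.0 and report.total == 10.0

    def test_weighted_sum(self):
        total, _ = total_loss({"gic": 2.0, "mgm": 2.0, "gim": 1.0, "gm": 10.0},
                              {"gic": 1.0, "mgm": 0.5, "gim": 1.0, "gm": 0.1})
        assert np.isclose(total.data, 5.0)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="nonnegative"):
            total_loss({"gic": 1.0}, {"gic": -1.0})

    def test_nonfinite_component_diagnosed(self):
        with pytest.raises(FloatingPointError, match="mgm"):
            LossReport(gic=1.0, mgm=float("nan"), gim=0.0, gm=0.0)

    def test_toy_batch_optimization_separates_pairs(self):
        """Free embeddings under the contrastive objective develop a margin."""
        rng = np.random.default_rng(0)
        zg = Tensor(rng.normal(size=(16, 8)), requires_grad=True)
        zi = Tensor(rng.normal(size=(16, 8)), requires_grad=True)
        opt = nn.Adam({"zg": zg, "zi": zi}, lr=0.05)
        for _ in range(500):
            loss, _ = total_loss({"gic": gic_loss(
                EmbeddingPairBatch(zg, zi, 0.1))})
            opt.zero_grad()
            loss.backward()
            opt.step()
        sim = similarity_matrix(zg, zi).data
        matched = np.diag(sim)
        off = sim - np.eye(16) * 1e9
        assert np.min(matched - off.max(axis=1)) > 0
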