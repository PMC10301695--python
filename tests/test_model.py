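"""VAE objective, masked decoder forward/backward, training contracts, persistence."""

import numpy as np
import pytest

import pathvae as pv
from pathvae._nn import MaskedVAE, kl_closed_form

from _oracles import dense_decoder_forward, monte_carlo_kl
from conftest import random_trimmed


def chain_model(k: int = 1, seed: int = 0) -> tuple[pv.TrimmedOntology, MaskedVAE]:
    g = pv.OntologyGraph(term_ids=["A", "B"], edges={("A", "B")},
                         direct_annotations={"A": {"g1"}, "B": {"g2"}})
    onto = pv.trim_ontology(g, 0, 10)
    pv.compile_ontology(onto, k)
    net = MaskedVAE(onto.masks, n_genes=2, latent_dim=k, hidden=4,
                    rng=np.random.default_rng(seed))
    return onto, net


class TestKL:
    def test_zero_when_posterior_is_prior(self):
        assert kl_closed_form(np.zeros(5), np.zeros(5)) == 0.0

    def test_unit_mean_shift(self):
        assert kl_closed_form([1.0], [0.0]) == pytest.approx(0.5)

    def test_nonfinite_raises(self):
        with pytest.raises(FloatingPointError):
            kl_closed_form([np.nan], [0.0])

    def test_matches_monte_carlo(self):
        rng = np.random.default_rng(0)
        mu = rng.normal(size=4)
        lv = rng.normal(scale=0.5, size=4)
        mc, se = monte_carlo_kl(mu, lv, n_draws=200_000, seed=1)
        assert kl_closed_form(mu, lv) == pytest.approx(mc, abs=3 * se)


class TestInit:
    def test_same_seed_bit_identical(self, small_training_setup):
        onto, data = small_training_setup
        a = pv.OntologyVAE(data.expression, onto).init_model(seed=5)
        b = pv.OntologyVAE(data.expression, onto).init_model(seed=5)
        for k in a.net.params:
            assert a.net.params[k].tobytes() == b.net.params[k].tobytes()

    def test_latent_dimension(self, small_training_setup):
        onto, data = small_training_setup
        res = pv.OntologyVAE(data.expression, onto, neurons_per_term=3).init_model()
        assert res.net.latent_dim == 3 * len(onto.root_terms)

    def test_initial_weights_masked_nonnegative(self, small_training_setup):
        onto, data = small_training_setup
        net = pv.OntologyVAE(data.expression, onto).init_model().net
        for name, m in zip(net.decoder_weight_names(), net.dec_masks + [net.recon_mask]):
            W = net.params[name]
            assert W.min() >= 0
            assert np.all(W[m == 0] == 0)

    def test_empty_latent_rejected(self):
        with pytest.raises(ValueError, match="latent"):
            MaskedVAE([np.zeros((1, 0))], n_genes=1, latent_dim=0, hidden=2,
                      rng=np.random.default_rng(0))

    def test_bad_hyperparameters_rejected(self, small_training_setup):
        onto, data = small_training_setup
        with pytest.raises(ValueError):
            pv.OntologyVAE(data.expression, onto, validation_fraction=1.5)
        with pytest.raises(TypeError):
            pv.OntologyVAE(data.expression, onto, no_such_knob=1)


class TestDecode:
    def test_zero_weights_zero_reconstruction(self):
        _, net = chain_model(k=1)
        for k in net.params:
            net.params[k] = np.zeros_like(net.params[k])
        _, recon = net.decode(np.array([[3.0], [7.0]]))
        np.testing.assert_array_equal(recon, np.zeros((2, 2)))

    def test_hand_set_chain_weights(self):
        # decoder A -> B, k=1, all usable weights 1, biases 0:
        # out_B = z_A; recon = [g1 <- A, g2 <- B] = [z_A, z_A]
        _, net = chain_model(k=1)
        net.params["Wd1"] = np.ones((1, 1))
        net.params["bd1"] = np.zeros(1)
        net.params["Wr"] = net.recon_mask.copy()
        net.params["br"] = np.zeros(2)
        outs, recon = net.decode(np.array([[2.0]]))
        assert outs[1][0, 0] == pytest.approx(2.0)
        np.testing.assert_allclose(recon, [[2.0, 2.0]])

    def test_pencil_and_paper_loss(self):
        # 2 samples x 2 genes, z = mu (eval mode), hand-set linear maps
        _, net = chain_model(k=1)
        net.params["W1"] = np.zeros((2, 4))
        net.params["b1"] = np.zeros(4)
        net.params["Wm"] = np.zeros((4, 1))
        net.params["bm"] = np.array([1.0])   # mu = 1 for every sample
        net.params["Wv"] = np.zeros((4, 1))
        net.params["bv"] = np.array([0.0])   # sigma^2 = 1
        net.params["Wd1"] = np.array([[2.0]])
        net.params["bd1"] = np.array([0.5])  # out_B = 2 z + 0.5
        net.params["Wr"] = net.recon_mask * 1.0
        net.params["br"] = np.zeros(2)
        X = np.array([[1.0, 2.0], [0.0, 3.0]])
        beta = 0.25
        report, _ = net.forward(X, beta, training=False)
        # z = 1 -> recon = [1, 2.5] for both rows
        # row errors: (0^2 + .5^2) = .25 ; (1 + .25) = 1.25 -> mean 0.75
        assert report.reconstruction_term == pytest.approx(0.75)
        # KL per sample = 0.5 * (1 + 1 - 1 - 0) = 0.5
        assert report.kl_term == pytest.approx(0.5)
        assert report.total_loss == pytest.approx(0.75 + beta * 0.5)
        assert report.elbo_objective == pytest.approx(-(0.75 + beta * 0.5))

    def test_beta_zero_loss_is_mse_only(self):
        _, net = chain_model(k=1)
        X = np.random.default_rng(0).normal(size=(6, 2))
        report, _ = net.forward(X, 0.0, training=False)
        assert report.total_loss == report.reconstruction_term

    def test_repeat_with_fixed_rng_identical(self):
        _, net = chain_model(k=1)
        X = np.random.default_rng(1).normal(size=(5, 2))
        r1, _ = net.forward(X, 1e-4, np.random.default_rng(9), training=True)
        r2, _ = net.forward(X, 1e-4, np.random.default_rng(9), training=True)
        assert r1.total_loss == r2.total_loss

    def test_wrong_latent_width_rejected(self):
        _, net = chain_model(k=1)
        with pytest.raises(ValueError):
            net.decode(np.zeros((1, 3)))

    @pytest.mark.parametrize("seed", range(4))
    def test_equals_dense_block_oracle(self, seed):
        onto = random_trimmed(seed, n_terms=20, k=2)
        net = MaskedVAE(onto.masks, n_genes=len(onto.genes),
                        latent_dim=2 * len(onto.root_terms), hidden=8,
                        rng=np.random.default_rng(seed))
        z = np.random.default_rng(seed + 50).normal(size=(6, net.latent_dim))
        _, recon = net.decode(z)
        np.testing.assert_allclose(recon, dense_decoder_forward(net, z), atol=1e-6)

    def test_monotone_propagation(self):
        # non-negative weights, zero biases: raising one latent coordinate
        # can never decrease any downstream activation
        onto = random_trimmed(3, n_terms=20, k=2)
        net = MaskedVAE(onto.masks, n_genes=len(onto.genes),
                        latent_dim=2 * len(onto.root_terms), hidden=8,
                        rng=np.random.default_rng(3))
        for d in range(1, len(net.dec_masks) + 1):
            net.params[f"bd{d}"][:] = 0
        net.params["br"][:] = 0
        rng = np.random.default_rng(7)
        z = rng.normal(size=(1, net.latent_dim))
        outs, recon = net.decode(z)
        base = np.concatenate([o.ravel() for o in outs] + [recon.ravel()])
        for j in range(net.latent_dim):
            z2 = z.copy()
            z2[0, j] += 1.0
            outs2, recon2 = net.decode(z2)
            bumped = np.concatenate([o.ravel() for o in outs2] + [recon2.ravel()])
            assert np.all(bumped >= base - 1e-12)


class TestGradients:
    def test_backward_matches_finite_differences(self):
        rng = np.random.default_rng(0)
        k = 2
        m1 = (rng.random((k * 2, k * 2)) < 0.6).astype(float)
        m2 = (rng.random((k * 1, k * 4)) < 0.6).astype(float)
        mr = (rng.random((7, k * 5)) < 0.5).astype(float)
        net = MaskedVAE([m1, m2, mr], n_genes=7, latent_dim=4, hidden=9, rng=rng)
        X = rng.normal(size=(5, 7))
        beta = 0.3

        def loss_at():
            r, _ = net.forward(X, beta, np.random.default_rng(42), training=True)
            return r.total_loss

        _, cache = net.forward(X, beta, np.random.default_rng(42), training=True)
        grads = net.backward(cache, beta)
        h = 1e-6
        check = np.random.default_rng(1)
        for name, g in grads.items():
            flat = net.params[name].reshape(-1)
            for idx in check.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + h
                lp = loss_at()
                flat[idx] = orig - h
                lm = loss_at()
                flat[idx] = orig
                fd = (lp - lm) / (2 * h)
                assert g.reshape(-1)[idx] == pytest.approx(fd, rel=1e-4, abs=1e-7), name


class TestTraining:
    def test_descent_constraints_determinism(self, small_training_setup):
        onto, data = small_training_setup
        model = pv.OntologyVAE(data.expression, onto, encoder_hidden_width=32)

        seen = []

        def check(epoch, net, row):
            seen.append(epoch)
            for name, m in zip(net.decoder_weight_names(), net.dec_masks + [net.recon_mask]):
                W = net.params[name]
                assert W.min() >= 0
                assert np.all(W[m == 0] == 0)

        res = model.fit(seed=4, max_epochs=40, on_epoch_end=check)
        assert seen == list(range(40))
        hist = res.history
        assert hist.val_loss.min() < hist.val_loss.iloc[0]
        assert res.best_epoch == int(hist.val_loss.idxmin())

        res2 = pv.OntologyVAE(data.expression, onto, encoder_hidden_width=32).fit(
            seed=4, max_epochs=40)
        assert res2.history.val_loss.min() == hist.val_loss.min()

    def test_beta_zero_identity_capable_mse_approaches_zero(self):
        # one term, one gene, beta = 0: the model can represent the identity,
        # so training reconstruction error should shrink dramatically
        g = pv.OntologyGraph(term_ids=["A"], edges=set(),
                             direct_annotations={"A": {"g1"}})
        onto = pv.trim_ontology(g, 0, 10)
        pv.compile_ontology(onto, 1)
        rng = np.random.default_rng(0)
        X = rng.uniform(0.5, 2.0, size=(40, 1))
        model = pv.OntologyVAE(X, onto, neurons_per_term=1,
                               encoder_hidden_width=16, kl_weight=0.0,
                               dropout_hidden=0.0, dropout_latent=0.0,
                               batch_size=32)
        res = model.fit(seed=0, max_epochs=2500)
        hist = res.history.train_loss
        assert hist.iloc[-1] < 0.05 * hist.iloc[0]
        # loss trend is downward overall (smoothed monotonicity)
        smoothed = hist.rolling(100).mean().dropna()
        assert smoothed.iloc[-1] < smoothed.iloc[0]

    def test_too_few_samples_rejected(self, small_training_setup):
        onto, data = small_training_setup
        with pytest.raises(ValueError):
            pv.OntologyVAE(data.expression.iloc[:1], onto)

    def test_zero_gene_overlap_rejected(self, small_training_setup):
        onto, data = small_training_setup
        bad = data.expression.rename(columns=lambda c: "x" + c)
        with pytest.raises(ValueError, match="overlap"):
            pv.OntologyVAE(bad, onto)


class TestPersistence:
    def test_round_trip_bit_identical_decode(self, tmp_path, small_training_setup):
        onto, data = small_training_setup
        res = pv.OntologyVAE(data.expression, onto, encoder_hidden_width=16).fit(
            seed=0, max_epochs=3)
        z = np.random.default_rng(0).normal(size=(4, res.net.latent_dim))
        _, before = res.decode(z)
        p = tmp_path / "model.pathvae"
        res.save(p)
        loaded = pv.OntologyVAEResults.load(p)
        _, after = loaded.decode(z)
        assert before.tobytes() == after.tobytes()
        assert loaded.best_epoch == res.best_epoch

    def test_ontology_hash_mismatch(self, tmp_path, small_training_setup, toy_graph):
        onto, data = small_training_setup
        res = pv.OntologyVAE(data.expression, onto, encoder_hidden_width=16).fit(
            seed=0, max_epochs=2)
        p = tmp_path / "model.pathvae"
        res.save(p)
        other = pv.trim_ontology(toy_graph, 0, 10 ** 9)
        with pytest.raises(ValueError, match="hash"):
            pv.OntologyVAEResults.load(p, ontology=other)

    def test_truncated_file_rejected(self, tmp_path, small_training_setup):
        onto, data = small_training_setup
        res = pv.OntologyVAE(data.expression, onto, encoder_hidden_width=16).fit(
            seed=0, max_epochs=2)
        p = tmp_path / "model.pathvae"
        res.save(p)
        (tmp_path / "trunc.pathvae").write_bytes(p.read_bytes()[:100])
        with pytest.raises(ValueError, match="truncated|unreadable"):
            pv.OntologyVAEResults.load(tmp_path / "trunc.pathvae")
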