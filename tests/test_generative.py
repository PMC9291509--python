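"""Variational models: losses, gradients, encode/decode contracts, training."""

import numpy as np
import pytest
from scipy import integrate, stats

from delmol.fixtures import FixtureSpec, generate_fixtures
from delmol.generative import (ModelConfig, OutOfVocabularyError, SequenceVAE,
                               elbo_loss, finetune, jtvae_reconstruction,
                               kl_gaussian, pretrain)
from delmol.nn import softmax, zeros_like_params


class TestLossFunctions:
    def test_kl_zero_for_standard_normal(self):
        assert kl_gaussian(np.zeros(4), np.zeros(4)) == 0.0

    def test_kl_mean_shift(self):
        assert kl_gaussian(np.array([1.0]), np.array([0.0])) == pytest.approx(0.5)

    def test_kl_against_quadrature(self):
        """1D KL via numeric integration of p log(p/q)."""
        rng = np.random.default_rng(0)
        for _ in range(5):
            mu, lv = rng.normal(), rng.normal(scale=0.5)
            sd = np.exp(lv / 2)

            def integrand(x):
                p = stats.norm.pdf(x, mu, sd)
                q = stats.norm.pdf(x, 0.0, 1.0)
                return np.where(p > 0, p * (np.log(p + 1e-300) - np.log(q + 1e-300)), 0.0)

            expected, _ = integrate.quad(integrand, mu - 12 * sd - 12, mu + 12 * sd + 12)
            assert kl_gaussian(np.array([mu]), np.array([lv])) == pytest.approx(
                expected, abs=1e-6)

    def test_kl_length_mismatch(self):
        with pytest.raises(ValueError):
            kl_gaussian(np.zeros(2), np.zeros(3))

    def test_elbo_arithmetic(self):
        assert elbo_loss(1.0, 2.0, 3.0, beta=0.1, alpha=0.5).total == pytest.approx(2.7)
        assert elbo_loss(1.7, 9.0, 4.0, beta=0.0, alpha=0.0).total == 1.7
        lb = elbo_loss(2.0, 3.0, 7.0, beta=1.0, alpha=0.0)
        assert lb.total == lb.reconstruction + lb.kl

    def test_elbo_rejects_negative_weights(self):
        with pytest.raises(ValueError):
            elbo_loss(1.0, 1.0, 1.0, beta=-0.1, alpha=0.0)

    def test_tree_reconstruction_sum(self):
        assert jtvae_reconstruction(0, 0, 0, 0) == 0.0
        assert jtvae_reconstruction(1, 2, 3, 0) == 6.0
        with pytest.raises(ValueError):
            jtvae_reconstruction(-1, 0, 0, 0)


def _manual_total_loss(model, m, ids, y, eps):
    """Independent forward pass mirroring the training objective."""
    p = model.params
    feats = model._features(m, ids)
    parts = [("encT", feats["xT"])]
    if model.kind == "jtvae":
        parts.append(("encG", feats["xG"]))
    mus, lvs = [], []
    for prefix, x in parts:
        mu, lv, _ = model._encode_part(prefix, x)
        mus.append(mu)
        lvs.append(lv)
    mu, lv = np.concatenate(mus), np.concatenate(lvs)
    z = mu + np.exp(lv / 2) * eps
    kl = kl_gaussian(mu, lv)
    z_dec = z[: model.lt] if model.kind == "jtvae" else z
    s = np.tanh(p["dec_Wz"] @ z_dec + p["dec_bz"])
    inputs = [model.sos_row] + list(ids)
    recon = 0.0
    for t in range(len(ids) + 1):
        x = p["dec_emb"][inputs[t]]
        s = np.tanh(p["dec_Whh"] @ s + p["dec_Wxh"] @ x + p["dec_bh"])
        if model.kind == "jtvae":
            a = float(p["dec_topo_w"] @ s + p["dec_topo_b"][0])
            tgt = 1.0 if t < len(ids) else 0.0
            recon += max(a, 0.0) - a * tgt + np.log1p(np.exp(-abs(a)))
            if t < len(ids):
                pr = softmax(p["dec_Wo"] @ s + p["dec_bo"])
                recon += -np.log(max(pr[ids[t]], 1e-12))
        else:
            pr = softmax(p["dec_Wo"] @ s + p["dec_bo"])
            tgt = ids[t] if t < len(ids) else model.eos_id
            recon += -np.log(max(pr[tgt], 1e-12))
    hp = np.tanh(p["prop_W1"] @ z + p["prop_b1"])
    yhat = p["prop_W2"] @ hp + p["prop_b2"]
    se = float((yhat - y) @ (yhat - y))
    return recon + model.config.beta * kl + model.config.alpha * se


@pytest.mark.parametrize("kind", ["jtvae", "fragvae"])
def test_gradients_match_finite_differences(kind, library20):
    """Analytic backward pass agrees with central differences."""
    model = SequenceVAE.from_dataset(library20, ModelConfig.tiny(),
                                     kind=kind, seed=0)
    m = library20[0]
    ids = model.tokenize(m)
    y = np.array([0.3, -0.2, 0.5])
    eps = np.random.default_rng(7).standard_normal(model.config.latent_size)

    class FixedEps:
        def standard_normal(self, shape):
            return eps

    grads = zeros_like_params(model.params)
    model._example_grads(m, ids, y, grads, w_recon=1.0,
                         w_kl=model.config.beta, w_se=model.config.alpha,
                         rng=FixedEps())
    rng = np.random.default_rng(11)
    for name, g in grads.items():
        for fi in rng.choice(g.size, size=min(4, g.size), replace=False):
            idx = np.unravel_index(fi, g.shape)
            h = 1e-5
            orig = model.params[name][idx]
            model.params[name][idx] = orig + h
            lp = _manual_total_loss(model, m, ids, y, eps)
            model.params[name][idx] = orig - h
            lm = _manual_total_loss(model, m, ids, y, eps)
            model.params[name][idx] = orig
            num = (lp - lm) / (2 * h)
            assert abs(num - g[idx]) / max(1.0, abs(num)) < 1e-5, name


class TestEncode:
    def test_mean_deterministic_and_sized(self, trained_jtvae, library20):
        m = library20[0]
        out1, out2 = trained_jtvae.encode(m), trained_jtvae.encode(m)
        assert np.array_equal(out1.mean, out2.mean)
        assert out1.mean.shape == (trained_jtvae.config.latent_size,)
        # reparameterized sample is reconstructible from the recorded noise
        assert np.allclose(
            out1.sample,
            out1.mean + np.exp(out1.log_variance / 2) * out1.epsilon)

    def test_out_of_vocabulary_named(self, trained_jtvae):
        with pytest.raises(OutOfVocabularyError):
            trained_jtvae.encode("BrC(Br)(Br)C1CC1Br")

    def test_posterior_aggregate_near_standard_normal(self, trained_jtvae,
                                                      library200):
        """Pooled encoder samples should be close to N(0,1) after training."""
        samples = np.concatenate([trained_jtvae.encode(m).sample
                                  for m in library200])
        assert stats.kstest(samples, "norm").pvalue > 0.01


class TestDecode:
    def test_decode_is_deterministic(self, trained_jtvae):
        z = np.random.default_rng(5).standard_normal(
            trained_jtvae.config.latent_size)
        m1, m2 = trained_jtvae.decode(z), trained_jtvae.decode(z)
        assert m1.smiles == m2.smiles

    def test_junction_tree_decoding_always_valid(self, trained_jtvae):
        mols = trained_jtvae.sample_prior(300, seed=9)
        assert all(m.valid for m in mols)

    def test_sample_prior_contracts(self, trained_jtvae):
        assert trained_jtvae.sample_prior(0, seed=1) == []
        a = [m.smiles for m in trained_jtvae.sample_prior(20, seed=4)]
        b = [m.smiles for m in trained_jtvae.sample_prior(20, seed=4)]
        c = [m.smiles for m in trained_jtvae.sample_prior(20, seed=5)]
        assert a == b
        assert a != c

    def test_memorized_set_reconstructs(self):
        """A tiny overfit model reproduces >= 8/10 training molecules."""
        mols = generate_fixtures(FixtureSpec(n_molecules=10, seed=5))
        model = SequenceVAE.from_dataset(
            mols, ModelConfig.tiny(learning_rate=5e-3), kind="fragvae", seed=0)
        model.fit(mols, epochs=300)
        hits = 0
        for m in mols:
            out = model.decode(model.encode(m).mean)
            hits += out is not None and out.valid and out.smiles == m.smiles
        assert hits >= 8


class TestTraining:
    def test_loss_decreases(self, library200):
        model, log = pretrain(library200, ModelConfig.tiny(), epochs=8,
                              kind="jtvae", seed=3)
        assert log[-1]["total"] < log[0]["total"]
        assert all(np.isfinite(row["total"]) for row in log)

    def test_annealed_learning_rate(self, trained_fragvae, library20):
        log = finetune(trained_fragvae, library20, epochs=1, generation=2,
                       annealing_rate=0.8)
        assert log[0]["lr"] == pytest.approx(
            trained_fragvae.config.learning_rate * 0.8 ** 2)

    def test_property_regularizer_reduces_prediction_error(self, library200):
        from delmol.objectives import evaluate_objectives, surrogate_bas

        recs = evaluate_objectives(library200[:80], surrogate_bas)
        targets = {r.smiles: r.objectives for r in recs}
        se = {}
        for alpha in (0.0, 1.0):
            cfg = ModelConfig.tiny(alpha=alpha)
            _, log = pretrain(library200[:80], cfg, epochs=15, kind="fragvae",
                              seed=2, targets=targets)
            se[alpha] = log[-1]["property_se"]
        assert se[1.0] < se[0.0]

    def test_seeded_reproducibility(self, library20):
        logs = []
        for _ in range(2):
            _, log = pretrain(library20, ModelConfig.tiny(), epochs=3,
                              kind="jtvae", seed=11)
            logs.append([row["total"] for row in log])
        assert logs[0] == logs[1]

    def test_empty_training_set_rejected(self, trained_jtvae):
        with pytest.raises(ValueError):
            trained_jtvae.fit([], epochs=1)


class TestCheckpoint:
    def test_round_trip(self, trained_jtvae, tmp_path):
        path = tmp_path / "model.npz"
        trained_jtvae.save(path)
        clone = SequenceVAE.load(path)
        assert clone.vocab == trained_jtvae.vocab
        for k, v in trained_jtvae.params.items():
            assert np.array_equal(clone.params[k], v)
        z = np.random.default_rng(3).standard_normal(clone.config.latent_size)
        assert clone.decode(z).smiles == trained_jtvae.decode(z).smiles
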