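import numpy as np
import pytest

import stdgcc
from stdgcc import _autograd as ag
from stdgcc.data_io import preprocess
from stdgcc.errors import ParameterError
from stdgcc.graph import build_spatial_graph, corrupt_features
from stdgcc.network import decode, encode, init_params, readout
from stdgcc.objectives import (contrastive_loss, kl_loss_from_logsigma,
                               reconstruction_loss, total_loss)
from stdgcc.training import TrainConfig, ablate, train


def toy_problem(seed=0):
    """6 spots, 5 genes, latent width 3: small enough for finite differences."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(6, 5))
    graph = build_spatial_graph(rng.uniform(0, 4, size=(6, 2)), delta=2.5,
                                lam=0.8)
    params = init_params(5, widths=(4, 3), latent_dim=3, seed=seed)
    noise = rng.standard_normal((6, 3))
    perm = rng.permutation(6)
    return X, graph, params, noise, perm


def toy_loss(X, graph, params, noise, perm):
    """Deterministic full objective on the toy problem (fixed noise/perm)."""
    st = encode(X, graph.Anorm, params, noise=noise)
    L_kl = kl_loss_from_logsigma(st.mu, ag.log(st.sigma))
    L_r = reconstruction_loss(X, decode(st.H, params))
    stb = encode(X[perm], graph.Anorm, params, noise=noise)
    s = readout(st.H)
    _, _, _, L_c = contrastive_loss(st.H, stb.H, s, params.disc_bilinear)
    return total_loss(L_c, L_r, L_kl)


class TestGradientIntegrity:
    def test_analytic_gradients_match_central_differences(self):
        X, graph, params, noise, perm = toy_problem()
        tensors = params.all_params()
        loss = toy_loss(X, graph, params, noise, perm)
        loss.backward()
        analytic = [t.grad.copy() for t in tensors]

        h = 1e-6
        for t, g in zip(tensors, analytic):
            flat = t.data.reshape(-1)
            gflat = np.asarray(g).reshape(-1)
            for idx in range(flat.size):
                orig = flat[idx]
                flat[idx] = orig + h
                up = float(ag.value(toy_loss(X, graph, params, noise, perm)))
                flat[idx] = orig - h
                dn = float(ag.value(toy_loss(X, graph, params, noise, perm)))
                flat[idx] = orig
                fd = (up - dn) / (2 * h)
                denom = max(abs(fd), abs(gflat[idx]), 1e-4)
                assert abs(fd - gflat[idx]) / denom < 1e-4, (
                    f"param shape {t.data.shape} index {idx}: "
                    f"fd={fd} analytic={gflat[idx]}")


class TestTrainLoop:
    def test_single_epoch_updates_parameters(self, tiny_dataset, tiny_config):
        from dataclasses import replace
        cfg = replace(tiny_config, epochs=1)
        fm = preprocess(tiny_dataset.dataset, hvg_t=cfg.hvg_t)
        graph = build_spatial_graph(tiny_dataset.dataset.coords,
                                    delta=cfg.delta, lam=cfg.lam)
        res = train(fm, graph, cfg)
        assert len(res.history) == 1
        init_seed = int(np.random.default_rng(cfg.seed).integers(2**31))
        fresh = init_params(fm.n_features, widths=cfg.widths,
                            latent_dim=cfg.latent_dim, seed=init_seed)
        moved = any(
            not np.array_equal(a.data, b.data)
            for a, b in zip(res.params.all_params(), fresh.all_params()))
        assert moved

    def test_identical_seed_reproduces_history_exactly(self, tiny_dataset,
                                                       tiny_config):
        fm = preprocess(tiny_dataset.dataset, hvg_t=tiny_config.hvg_t)
        graph = build_spatial_graph(tiny_dataset.dataset.coords,
                                    delta=tiny_config.delta,
                                    lam=tiny_config.lam)
        a = train(fm, graph, tiny_config)
        b = train(fm, graph, tiny_config)
        assert [x.L_total for x in a.history] == [x.L_total for x in b.history]
        np.testing.assert_array_equal(a.final_embedding, b.final_embedding)

    def test_final_embedding_is_noise_free_and_deterministic(
            self, tiny_dataset, tiny_config):
        fm = preprocess(tiny_dataset.dataset, hvg_t=tiny_config.hvg_t)
        graph = build_spatial_graph(tiny_dataset.dataset.coords,
                                    delta=tiny_config.delta,
                                    lam=tiny_config.lam)
        res = train(fm, graph, tiny_config)
        st = encode(fm.X, graph.Anorm, res.params, noise=None)
        np.testing.assert_array_equal(res.final_embedding, ag.value(st.H))


class TestAblation:
    def test_mode_switch_and_validation(self):
        cfg = TrainConfig()
        assert ablate(cfg, "no_vgcn").ablation == "no_vgcn"
        with pytest.raises(ParameterError):
            ablate(cfg, "bogus")

    @pytest.mark.parametrize("mode,active", [
        ("full", {"contrastive", "reconstruction", "kl"}),
        ("no_vgcn", {"contrastive", "reconstruction"}),
        ("no_decoder", {"contrastive", "kl"}),
        ("no_contrastive", {"reconstruction", "kl"}),
    ])
    def test_loss_terms_masked_per_mode(self, mode, active, tiny_dataset,
                                        tiny_config):
        from dataclasses import replace
        cfg = replace(tiny_config, epochs=2, ablation=mode)
        fm = preprocess(tiny_dataset.dataset, hvg_t=cfg.hvg_t)
        graph = build_spatial_graph(tiny_dataset.dataset.coords,
                                    delta=cfg.delta, lam=cfg.lam)
        res = train(fm, graph, cfg)
        b = res.history[-1]
        alpha, beta, gamma = b.weights
        assert (alpha > 0) == ("contrastive" in active)
        assert (beta > 0) == ("reconstruction" in active)
        assert (gamma > 0) == ("kl" in active)
        assert b.L_total == pytest.approx(
            alpha * b.L_c + beta * b.L_r + gamma * b.L_KL, rel=1e-12)
        if "contrastive" not in active:
            assert b.L_c == 0.0
        if "reconstruction" not in active:
            assert b.L_r == 0.0
        if "kl" not in active:
            assert b.L_KL == 0.0

    @pytest.mark.parametrize("mode,branch", [
        ("no_contrastive", "discriminator"),
        ("no_decoder", "decoder"),
        ("no_vgcn", "sigma"),
    ])
    def test_masked_branch_parameters_stay_at_init(self, mode, branch,
                                                   tiny_dataset, tiny_config):
        from dataclasses import replace
        cfg = replace(tiny_config, epochs=5, ablation=mode)
        fm = preprocess(tiny_dataset.dataset, hvg_t=cfg.hvg_t)
        graph = build_spatial_graph(tiny_dataset.dataset.coords,
                                    delta=cfg.delta, lam=cfg.lam)
        res = train(fm, graph, cfg)
        init_seed = int(np.random.default_rng(cfg.seed).integers(2**31))
        fresh = init_params(fm.n_features, widths=cfg.widths,
                            latent_dim=cfg.latent_dim, seed=init_seed)
        for trained, init in zip(res.params.params_of(branch),
                                 fresh.params_of(branch)):
            np.testing.assert_array_equal(trained.data, init.data)
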