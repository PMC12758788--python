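"""Training loop: presets, samplers, pseudo-labels, stopping rules."""

import numpy as np
import pytest

from modalign.io_prep import ExpressionMatrix, log_normalize
from modalign.synthetic import SyntheticSpec, generate_paired_domains
from modalign.train import (
    SGD,
    ScenarioConfig,
    _StreamSampler,
    assign_pseudo_labels,
    fit,
    prepare,
    sample_minibatches,
    scenario_preset,
)


class TestScenarioPresets:
    @pytest.mark.parametrize(
        "name,alpha,beta,gamma,tau,cap",
        [
            ("matched_rna_atac", 0.06, 0.05, 0.01, 0.04, 3000),
            ("unmatched_rna_atac", 1.2, 0.05, 0.01, 0.8, 3000),
            ("rna_to_rna", 0.1, 0.0, 0.1, 0.8, 200),
            ("atac_to_atac", 0.1, 0.0, 0.001, 0.8, 200),
        ],
    )
    def test_published_presets(self, name, alpha, beta, gamma, tau, cap):
        cfg = scenario_preset(name)
        assert (cfg.alpha, cfg.beta, cfg.gamma, cfg.tau) == (alpha, beta, gamma, tau)
        assert cfg.max_iterations == cap
        assert cfg.batch_size == 512
        assert cfg.learning_rate == 0.001
        assert cfg.confidence_threshold == 0.95
        assert cfg.patience == 20

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError, match="unknown scenario"):
            scenario_preset("matched_rna_rna")

    def test_overrides_take_precedence(self):
        cfg = scenario_preset("rna_to_rna", max_iterations=5, seed=9)
        assert cfg.max_iterations == 5 and cfg.seed == 9 and cfg.alpha == 0.1

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ScenarioConfig(tau=0.0)
        with pytest.raises(ValueError):
            ScenarioConfig(confidence_threshold=1.0)
        with pytest.raises(ValueError):
            ScenarioConfig(max_iterations=0)


class TestMinibatchSampling:
    def test_fixed_rng_reproduces_batch_sequence(self):
        seqs = []
        for _ in range(2):
            rng = np.random.default_rng(5)
            s_r, s_q = _StreamSampler(40, rng), _StreamSampler(25, rng)
            seqs.append([sample_minibatches(s_r, s_q, 10) for _ in range(6)])
        for (r1, q1), (r2, q2) in zip(*seqs):
            np.testing.assert_array_equal(r1, r2)
            np.testing.assert_array_equal(q1, q2)

    def test_recycling_keeps_batches_equal_size(self):
        rng = np.random.default_rng(0)
        s_r, s_q = _StreamSampler(7, rng), _StreamSampler(100, rng)
        b_r, b_q = sample_minibatches(s_r, s_q, 20)
        assert len(b_r) == len(b_q) == 20
        assert set(b_r) <= set(range(7))

    def test_every_cell_appears_within_an_epoch(self):
        rng = np.random.default_rng(1)
        sampler = _StreamSampler(30, rng)
        seen = np.concatenate([sampler.draw(10) for _ in range(3)])
        assert set(seen) == set(range(30))


def _toy_datasets(n=60, f=12, K=3, seed=0):
    spec = SyntheticSpec(n_ref=n, n_query=n, n_features=f, K=K, separation=2.0,
                         shift_strength=0.2, dropout_rate=0.1, seed=seed)
    ref, query = generate_paired_domains(spec)
    cfg = ScenarioConfig(alpha=0.1, beta=0.05, gamma=0.05, tau=0.5, batch_size=16,
                         hidden_dims=[8], m=6, e_dim=4, warmup_iterations=5,
                         max_iterations=10, seed=seed)
    ref_n, query_n, graph = prepare(ref, query, cfg)
    return ref_n, query_n, graph, cfg


class TestFit:
    def test_single_iteration_cap(self):
        ref_n, query_n, graph, cfg = _toy_datasets()
        cfg.max_iterations = 1
        model, state, log = fit(ref_n, query_n, cfg, graph=graph)
        assert state.iteration == 1 and len(log) == 1

    def test_loss_breakdown_satisfies_combination_rule(self):
        ref_n, query_n, graph, cfg = _toy_datasets()
        _, _, log = fit(ref_n, query_n, cfg, graph=graph)
        recomputed = log.l_ce + 0.1 * log.l_pr + cfg.alpha * log.l_cl + cfg.beta * log.l_fa + cfg.gamma * log.l_sc
        np.testing.assert_allclose(log.total, recomputed, atol=1e-6)

    def test_identical_seeds_identical_traces(self):
        ref_n, query_n, graph, cfg = _toy_datasets()
        _, _, log1 = fit(ref_n, query_n, cfg, graph=graph)
        _, _, log2 = fit(ref_n, query_n, cfg, graph=graph)
        np.testing.assert_array_equal(log1.total.to_numpy(), log2.total.to_numpy())

    def test_requires_labels_and_matching_features(self):
        ref_n, query_n, graph, cfg = _toy_datasets()
        unlabeled = ExpressionMatrix(ref_n.values, ref_n.cell_ids, ref_n.feature_names)
        with pytest.raises(ValueError, match="labels"):
            fit(unlabeled, query_n, cfg, graph=graph)

    def test_sc_plateau_stops_before_cap(self):
        # all cells identical and lr=0: the SC loss is exactly flat from the
        # first step, so the plateau rule must fire at patience iterations
        values = np.tile([[3.0, 1.0, 2.0, 4.0]], (30, 1))
        ref = ExpressionMatrix(values, [f"r{i}" for i in range(30)], list("abcd"),
                               labels=["T"] * 15 + ["B"] * 15)
        query = ExpressionMatrix(values.copy(), [f"q{i}" for i in range(30)], list("abcd"))
        cfg = ScenarioConfig(alpha=0.1, beta=0.0, gamma=0.1, tau=0.5, batch_size=8,
                             hidden_dims=[4], m=3, e_dim=2, learning_rate=0.0,
                             max_iterations=200, patience=5, warmup_iterations=0, seed=0)
        _, state, log = fit(log_normalize(ref), log_normalize(query), cfg)
        assert len(log) < 200
        assert len(log) >= cfg.patience

    def test_gamma_zero_disables_plateau_rule(self):
        values = np.tile([[3.0, 1.0, 2.0, 4.0]], (20, 1))
        ref = ExpressionMatrix(values, [f"r{i}" for i in range(20)], list("abcd"),
                               labels=["T"] * 10 + ["B"] * 10)
        query = ExpressionMatrix(values.copy(), [f"q{i}" for i in range(20)], list("abcd"))
        cfg = ScenarioConfig(alpha=0.1, beta=0.0, gamma=0.0, tau=0.5, batch_size=8,
                             hidden_dims=[4], m=3, e_dim=2, learning_rate=0.0,
                             max_iterations=30, patience=5, warmup_iterations=0, seed=0)
        _, state, log = fit(log_normalize(ref), log_normalize(query), cfg)
        assert len(log) == 30  # runs to the cap


class TestPseudoLabels:
    def test_symmetric_classifier_confidences_are_uniform(self):
        ref_n, query_n, graph, cfg = _toy_datasets()
        cfg.max_iterations = 1
        model, state, _ = fit(ref_n, query_n, cfg, graph=graph)
        # a symmetric (all-zero) classifier head cannot prefer any class
        model.c_head.W.data[:] = 0.0
        model.c_head.b.data[:] = 0.0
        state = assign_pseudo_labels(model, query_n.values, state)
        K = len(model.class_names)
        np.testing.assert_allclose(state.pseudo_confidence, 1.0 / K, atol=1e-9)

    def test_partial_rescoring_touches_only_requested_cells(self):
        ref_n, query_n, graph, cfg = _toy_datasets()
        model, state, _ = fit(ref_n, query_n, cfg, graph=graph)
        state = assign_pseudo_labels(model, query_n.values, state)
        before = state.pseudo_labels.copy()
        state.pseudo_labels[:] = -1
        state = assign_pseudo_labels(model, query_n.values, state, indices=np.array([0, 2]))
        assert state.pseudo_labels[0] == before[0] and state.pseudo_labels[2] == before[2]
        assert np.all(state.pseudo_labels[np.r_[1, 3:len(before)]] == -1)


class TestSGD:
    def test_momentum_accumulates_velocity(self):
        from modalign._autodiff import Tensor

        p = Tensor(np.array([0.0]), requires_grad=True)
        opt = SGD([p], lr=0.1, momentum=0.5)
        p.grad = np.array([1.0])
        opt.step()
        np.testing.assert_allclose(p.data, [-0.1])
        p.grad = np.array([1.0])
        opt.step()
        # v = 0.5*(-0.1) - 0.1 = -0.15 -> p = -0.25
        np.testing.assert_allclose(p.data, [-0.25])
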