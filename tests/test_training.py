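"""Losses, metric suite, and joint-training contracts on tiny problems."""

import numpy as np
import pytest
from scipy import stats

from pocketdta import (ConvConfig, SamplerConfig, TrainConfig,
                       concordance_index, joint_loss, metrics_report,
                       mse_loss, rm2_metric, auroc_score, auprc_score,
                       classification_metrics, train, save_checkpoint,
                       load_checkpoint)
from pocketdta.fixtures import FixtureConfig, make_fixture_set


class TestMseLoss:
    def test_zero_when_equal(self):
        assert mse_loss([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_hand_value(self):
        assert mse_loss([2.0, 0.0], [0.0, 0.0]) == pytest.approx(2.0)

    def test_quadratic_homogeneity(self):
        rng = np.random.default_rng(0)
        p, t = rng.normal(size=10), rng.normal(size=10)
        base = mse_loss(p, t)
        scaled = mse_loss(t + 3 * (p - t), t)
        assert scaled == pytest.approx(9 * base)

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            mse_loss([], [])


class TestJointLoss:
    def test_paper_beta(self):
        rep = joint_loss(0.4, 0.2, beta=0.5)
        assert rep.total == pytest.approx(0.5)

    def test_single_task_limit(self):
        assert joint_loss(0.7, 123.0, beta=0.0).total == pytest.approx(0.7)

    def test_random_components_reconstruct(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            m, b, beta = rng.uniform(0, 3, 3)
            rep = joint_loss(m, b, beta)
            assert rep.total == pytest.approx(m + beta * b, abs=1e-12)

    def test_negative_inputs_error(self):
        with pytest.raises(ValueError):
            joint_loss(-0.1, 0.2)


class TestConcordanceIndex:
    def test_perfect_and_reversed(self):
        t = [1.0, 2.0, 3.0, 4.0]
        assert concordance_index(t, t) == 1.0
        assert concordance_index(t[::-1], t) == 0.0

    def test_tie_case(self):
        # pairs: (1,2): tie->1/2, (1,3): 2>1 ok, (2,3): ok
        assert concordance_index([1, 1, 2], [1, 2, 3]) == pytest.approx(5 / 6)

    def test_matches_exhaustive_oracle(self):
        rng = np.random.default_rng(0)
        p, t = rng.normal(size=10), rng.normal(size=10)
        num = den = 0.0
        for i in range(10):
            for j in range(10):
                if t[i] > t[j]:
                    den += 1
                    num += 1.0 if p[i] > p[j] else 0.5 if p[i] == p[j] else 0.0
        assert concordance_index(p, t) == pytest.approx(num / den)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(1)
        p, t = rng.normal(size=15), rng.normal(size=15)
        assert concordance_index(np.exp(p), t) == concordance_index(p, t)

    def test_all_equal_truth_errors(self):
        with pytest.raises(ValueError):
            concordance_index([1.0, 2.0], [3.0, 3.0])


class TestRm2:
    def test_perfect_prediction(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert rm2_metric(t, t) == pytest.approx(1.0)

    def test_shift_penalized(self):
        t = np.array([1.0, 2.0, 3.0, 4.0])
        assert rm2_metric(t + 2.0, t) < 1.0

    def test_matches_step_by_step_oracle(self):
        rng = np.random.default_rng(0)
        x = rng.normal(2, 1, 10)
        y = x + rng.normal(0, 0.5, 10)
        r2 = stats.pearsonr(x, y)[0] ** 2
        k = (x * y).sum() / (x * x).sum()
        r02 = 1 - ((y - k * x) ** 2).sum() / ((y - y.mean()) ** 2).sum()
        expected = np.clip(r2 * (1 - np.sqrt(abs(r2 - r02))), 0, 1)
        assert rm2_metric(x, y) == pytest.approx(expected, abs=1e-12)

    def test_constant_inputs_error(self):
        with pytest.raises(ValueError):
            rm2_metric([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestClassificationMetrics:
    def test_perfect_separation(self):
        auroc, auprc = classification_metrics([0, 0, 1, 1],
                                              [0.1, 0.2, 0.8, 0.9])
        assert auroc == 1.0 and auprc == 1.0

    def test_fully_wrong_ranking(self):
        assert auroc_score([1, 0], [0.4, 0.6]) == 0.0

    def test_auroc_matches_pairwise_oracle(self):
        rng = np.random.default_rng(0)
        y = np.array([0, 1, 0, 1, 1, 0, 0, 1])
        s = rng.uniform(0, 1, 8)
        num = den = 0.0
        for i in np.flatnonzero(y == 1):
            for j in np.flatnonzero(y == 0):
                den += 1
                num += 1.0 if s[i] > s[j] else 0.5 if s[i] == s[j] else 0.0
        assert auroc_score(y, s) == pytest.approx(num / den, abs=1e-5)

    def test_single_class_contracts(self):
        with pytest.raises(ValueError):
            auroc_score([1, 1, 1], [0.1, 0.2, 0.3])
        with pytest.warns(UserWarning, match="prevalence"):
            assert auprc_score([1, 1], [0.5, 0.6]) == 1.0

    def test_report_invariants(self):
        rng = np.random.default_rng(1)
        p, t = rng.normal(size=12), rng.normal(size=12)
        rep = metrics_report(p, t)
        assert rep.rmse == pytest.approx(np.sqrt(rep.mse), abs=1e-9)
        assert -1 <= rep.spearman <= 1 and -1 <= rep.pearson <= 1
        assert 0 <= rep.ci <= 1


@pytest.fixture(scope="module")
def tiny_task():
    """2 small proteins, 24 pairs: enough to exercise the training loop."""
    cfg = FixtureConfig(n_residues=40, n_proteins=2, n_pairs=24,
                        affinity_noise_sd=0.0, seed=4)
    proteins, records, manifest = make_fixture_set(cfg)
    return proteins, records


def _tiny_train_config(epochs=2):
    return TrainConfig(epochs=epochs, batch_size=8, encoder_hidden=16,
                       predictor_hidden=(16, 8, 8), provider_dim=16,
                       conv=ConvConfig(hidden_dim=8),
                       sampler=SamplerConfig(n_per_residue=10, grid_cell=1.5))


class TestTrainContracts:
    def test_bitwise_deterministic_checkpoints(self, tiny_task):
        proteins, records = tiny_task
        runs = []
        for _ in range(2):
            _, hist = train(records, proteins, mode="normal", task="multi",
                            config=_tiny_train_config(1), seed=7)
            runs.append(hist["checkpoint"])
        assert runs[0].keys() == runs[1].keys()
        for key in runs[0]:
            np.testing.assert_array_equal(runs[0][key], runs[1][key])

    def test_fine_tune_freezes_pod(self, tiny_task):
        proteins, records = tiny_task
        model, hist = train(records, proteins, mode="fine_tune", task="multi",
                            config=_tiny_train_config(2), seed=3)
        from pocketdta.training import JointModel
        reference = JointModel(_tiny_train_config(2), seed=3)
        for key, t in reference.params["pod"].items():
            if key.startswith("head."):
                continue  # the pocket head may move in multi-task mode
            np.testing.assert_array_equal(model.params["pod"][key].data,
                                          t.data)

    def test_fine_tune_single_freezes_entire_pod(self, tiny_task):
        proteins, records = tiny_task
        model, _ = train(records, proteins, mode="fine_tune", task="single",
                         config=_tiny_train_config(1), seed=3)
        from pocketdta.training import JointModel
        reference = JointModel(_tiny_train_config(1), seed=3)
        for key, t in reference.params["pod"].items():
            np.testing.assert_array_equal(model.params["pod"][key].data,
                                          t.data)

    def test_beta_zero_matches_single_task_trace(self, tiny_task):
        proteins, records = tiny_task
        cfg0 = _tiny_train_config(2)
        cfg0.beta = 0.0
        _, h_multi = train(records, proteins, mode="normal", task="multi",
                           config=cfg0, seed=5)
        _, h_single = train(records, proteins, mode="normal", task="single",
                            config=_tiny_train_config(2), seed=5)
        mse_multi = [s.mse for s in h_multi["steps"]]
        mse_single = [s.mse for s in h_single["steps"]]
        np.testing.assert_allclose(mse_multi, mse_single, atol=1e-12)

    def test_loss_decomposition_every_step(self, tiny_task):
        proteins, records = tiny_task
        _, hist = train(records, proteins, mode="normal", task="multi",
                        config=_tiny_train_config(2), seed=9)
        assert hist["steps"]
        for step in hist["steps"]:
            assert step.total == pytest.approx(step.mse + 0.5 * step.bce,
                                               abs=1e-9)
            assert step.mse >= 0 and step.bce >= 0

    def test_multi_task_without_labels_errors(self, tiny_task):
        proteins, records = tiny_task
        stripped = {pid: (cloud, None) for pid, (cloud, _) in proteins.items()}
        with pytest.raises(ValueError, match="labels"):
            train(records, stripped, mode="normal", task="multi",
                  config=_tiny_train_config(1), seed=0)

    def test_modality_ablation_runs(self, tiny_task):
        proteins, records = tiny_task
        cfg = _tiny_train_config(1)
        cfg.modalities = ("drug_seq", "prot_seq", "prot_surf")
        _, hist = train(records, proteins, mode="normal", task="multi",
                        config=cfg, seed=1)
        assert np.isfinite(hist["steps"][-1].total)

    def test_empty_train_split_errors(self, tiny_task):
        proteins, records = tiny_task
        test_only = [r for r in records if r.split == "test"]
        with pytest.raises(ValueError, match="train"):
            train(test_only, proteins, config=_tiny_train_config(1))


class TestCheckpointIO:
    def test_roundtrip(self, tmp_path):
        state = {"pod/head.W": np.arange(6.0).reshape(3, 2),
                 "pred/fc0.b": np.zeros(4)}
        path = tmp_path / "ckpt.npz"
        save_checkpoint(path, state, meta={"task": "multi"})
        back, meta = load_checkpoint(path)
        assert meta == {"task": "multi"}
        for key in state:
            np.testing.assert_array_equal(back[key], state[key])
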