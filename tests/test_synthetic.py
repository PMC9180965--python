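"""Synthetic generator: determinism, analytic oracles, parameter recovery."""

import itertools

import numpy as np
import pytest

from drconcord import (
    AgreementClass3,
    GradingConcordance,
    SimConfig,
    analytic_kappa,
    banded_confusion,
    default_config,
    expected_agreement_frequencies,
    simulate_dataset,
)


def identity_config(n=60, seed=3, quality=0.0):
    eye5 = np.eye(5)
    return SimConfig(
        n_patients=n,
        grader_confusions={g: eye5.copy() for g in ("g1", "g2", "g3")},
        quality_fail={g: quality for g in ("g1", "g2", "g3")},
        ai_confusion=np.eye(4),
        ai_ungradable=0.0,
        seed=seed,
    ).validate()


class TestConfig:
    def test_validation_happens_before_sampling(self):
        cfg = SimConfig(prevalence=(0.5, 0.5, 0.2, 0, 0))
        with pytest.raises(ValueError):
            simulate_dataset(cfg)
        with pytest.raises(ValueError):
            SimConfig(inter_eye_concordance=1.5).validate()
        with pytest.raises(ValueError):
            SimConfig(adjudication_policy="vote").validate()
        with pytest.raises(ValueError):
            SimConfig(images_per_eye=(3, 2)).validate()
        with pytest.raises(ValueError):
            SimConfig(quality_fail={"only_one": 0.1}).validate()

    def test_yaml_round_trip(self, tmp_path):
        cfg = default_config(n_patients=10, seed=5)
        cfg.to_yaml(tmp_path / "sim.yaml")
        back = SimConfig.from_yaml(tmp_path / "sim.yaml")
        assert back.to_dict() == cfg.to_dict()

    def test_banded_confusion_rows_stochastic(self):
        m = banded_confusion(0.8, 5)
        assert np.allclose(m.sum(axis=1), 1.0)
        assert np.allclose(np.diag(m), 0.8)


class TestSimulateDataset:
    def test_fixed_seed_is_byte_identical(self, tmp_path):
        cfg = default_config(n_patients=40, seed=9)
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_dataset(cfg).write(d1)
        simulate_dataset(default_config(n_patients=40, seed=9)).write(d2)
        for name in ("grades.csv", "ai.csv", "adjudications.csv", "truth.csv"):
            assert (d1 / name).read_bytes() == (d2 / name).read_bytes()

    def test_identity_graders_are_unanimous_with_unit_kappas(self):
        sim = simulate_dataset(identity_config())
        res = GradingConcordance.from_simulation(sim).fit()
        eyes = res.agreement3_eye_counts
        assert eyes["MAJORITY_2_1"] == 0 and eyes["DISCORDANT_1_1_1"] == 0
        assert set(res.kappa_vs_final.values()) == {1.0}
        assert set(res.kappa_mean_pairwise.values()) == {1.0}

    def test_degenerate_prevalence_gives_all_zero_grades(self):
        cfg = identity_config(n=30)
        cfg.prevalence = (1.0, 0.0, 0.0, 0.0, 0.0)
        sim = simulate_dataset(cfg.validate())
        assert (sim.grades["grade"] == 0).all()
        assert (sim.ai["ai_grade"] == 0).all()

    def test_adjudication_truth_policy_resolves_discordant_eyes_to_truth(self):
        cfg = default_config(n_patients=400, seed=21)
        sim = simulate_dataset(cfg)
        truth = sim.truth.patients.set_index("patient_id")
        adj = sim.adjudications.set_index(["patient_id", "laterality"])["final_grade"]
        for (pid, lat), final in adj.items():
            col = "true_od" if lat == "OD" else "true_os"
            assert final == truth.loc[pid, col]

    def test_adding_a_grader_does_not_perturb_existing_streams(self):
        cfg = default_config(n_patients=50, seed=13)
        sim3 = simulate_dataset(cfg)
        cfg4 = default_config(n_patients=50, seed=13)
        cfg4.grader_confusions = dict(cfg4.grader_confusions)
        cfg4.grader_confusions["grader4"] = banded_confusion(0.85)
        cfg4.quality_fail = {**cfg4.quality_fail, "grader4": 0.025}
        sim4 = simulate_dataset(cfg4.validate())
        old = sim4.grades[sim4.grades.grader_id != "grader4"].reset_index(drop=True)
        assert old.equals(sim3.grades)
        assert sim4.ai.equals(sim3.ai)
        assert sim4.truth.patients.equals(sim3.truth.patients)


class TestAnalyticKappa:
    def test_identity_raters(self):
        eye = np.eye(5)
        assert analytic_kappa([0.2] * 5, eye, eye) == pytest.approx(1.0)

    def test_truth_ignoring_raters_have_zero_kappa(self):
        pi = np.array([0.4, 0.3, 0.15, 0.1, 0.05])
        flat = np.tile(pi, (5, 1))
        assert analytic_kappa(pi, flat, flat) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_triple_summation(self):
        pi = np.array([0.5, 0.2, 0.15, 0.1, 0.05])
        a = banded_confusion(0.7)
        b = banded_confusion(0.85)
        joint = np.zeros((5, 5))
        for t, i, j in itertools.product(range(5), repeat=3):
            joint[i, j] += pi[t] * a[t, i] * b[t, j]
        p_o = joint.trace()
        p_e = joint.sum(1) @ joint.sum(0)
        expected = (p_o - p_e) / (1 - p_e)
        assert analytic_kappa(pi, a, b) == pytest.approx(expected, abs=1e-12)


class TestExpectedAgreementFrequencies:
    def test_identity_graders(self):
        freq = expected_agreement_frequencies(identity_config())
        assert freq[AgreementClass3.UNANIMOUS_3_0] == pytest.approx(1.0)
        assert freq[AgreementClass3.DISCORDANT_1_1_1] == pytest.approx(0.0)

    def test_binary_scale_has_no_full_discordance(self):
        pi = [0.7, 0.3]
        mats = [np.array([[0.9, 0.1], [0.2, 0.8]])] * 3
        freq = expected_agreement_frequencies(true_dist=pi, confusions=mats)
        assert freq[AgreementClass3.DISCORDANT_1_1_1] == pytest.approx(0.0)

    def test_frequencies_sum_to_one(self):
        freq = expected_agreement_frequencies(default_config())
        assert sum(freq.values()) == pytest.approx(1.0, abs=1e-12)


def _kappa_mc_se(pi, a, b, n):
    """Large-sample standard error of Cohen's kappa under the implied joint."""
    k = len(pi)
    bmat = np.eye(k) if b is None else b
    joint = np.einsum("t,ti,tj->ij", np.asarray(pi, float), a, bmat)
    p_o = joint.trace()
    p_e = joint.sum(1) @ joint.sum(0)
    return np.sqrt(p_o * (1 - p_o) / (n * (1 - p_e) ** 2))


@pytest.fixture(scope="module")
def big():
    cfg = default_config(n_patients=20_000, seed=20240)
    sim = simulate_dataset(cfg)
    res = GradingConcordance.from_simulation(sim).fit()
    return cfg, res


class TestParameterRecovery:
    """Large-sample recovery of the generating parameters (fixed seed)."""

    def test_kappa_vs_truth_within_three_mc_ses(self, big):
        cfg, res = big
        n = res.n_analyzed  # conservative: eyes within a patient are correlated
        for gid in cfg.grader_ids:
            a = cfg.grader_confusions[gid]
            expected = analytic_kappa(cfg.prevalence, a)
            se = _kappa_mc_se(cfg.prevalence, a, None, n)
            assert abs(res.kappa_vs_final[gid] - expected) < 3 * se

    def test_pairwise_kappa_within_three_mc_ses(self, big):
        cfg, res = big
        n = res.n_analyzed
        for (ga, gb), value in res.kappa_pairwise.items():
            a, b = cfg.grader_confusions[ga], cfg.grader_confusions[gb]
            expected = analytic_kappa(cfg.prevalence, a, b)
            se = _kappa_mc_se(cfg.prevalence, a, b, n)
            assert abs(value - expected) < 3 * se

    def test_agreement_class_frequencies_within_binomial_tolerance(self, big):
        cfg, res = big
        freq = expected_agreement_frequencies(cfg)
        eyes = res.agreement3_eye_counts
        total = sum(eyes.values())
        n = res.n_analyzed
        for cls, p in freq.items():
            se = np.sqrt(p * (1 - p) / n)
            assert abs(eyes[cls.name] / total - p) < 4 * se

    def test_exclusion_rate_matches_independent_flags(self, big):
        cfg, res = big
        q = list(cfg.quality_fail.values())
        p_keep = np.prod([(1 - qi) ** 2 for qi in q]) * (1 - cfg.ai_ungradable)
        se = np.sqrt(p_keep * (1 - p_keep) / cfg.n_patients)
        assert abs(res.n_analyzed / cfg.n_patients - p_keep) < 4 * se
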