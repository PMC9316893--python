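"""Boosted committees, balanced subset draws, and the voting rule."""

import numpy as np
import pytest
from sklearn.ensemble import RandomForestClassifier

from spiderens import (
    BaseLearnerSpec,
    BoostedCommittee,
    GeneratorConfig,
    LabeledDataset,
    VotingEnsemble,
    boost_fit,
    committee_predict_proba,
    draw_balanced_subset,
    fit_ensemble,
    load_model,
    make_imbalanced,
    save_model,
)


def balanced_toy(seed=0, n=30, sep=3.0):
    rng = np.random.default_rng(seed)
    half = n // 2
    x = np.vstack([rng.normal(0, 1, (half, 4)), rng.normal(sep, 1, (half, 4))])
    y = np.array([0] * half + [1] * half)
    return LabeledDataset(x, y, list("abcd"), [f"s{i}" for i in range(n)])


class TestDrawBalancedSubset:
    def test_exact_balance_by_construction(self):
        data = balanced_toy(n=100)
        subset = draw_balanced_subset(data, np.ones(100), 5, rng_seed=1)
        assert subset.class_counts() == (5, 5)

    def test_degenerate_weight_always_selected(self):
        data = balanced_toy(n=20)
        w = np.zeros(20)
        w[3] = 1.0   # all class-0 weight on s3
        w[data.labels == 1] = 1.0
        for seed in range(10):
            subset = draw_balanced_subset(data, w, 1, rng_seed=seed)
            assert "s3" in subset.sample_ids

    def test_inclusion_frequency_tracks_weights(self):
        # per-class draw of 1: inclusion probability equals normalized weight
        data = balanced_toy(n=10)
        w = np.array([0.5, 0.1, 0.1, 0.1, 0.2] * 2)
        counts = np.zeros(10)
        for seed in range(2000):
            subset = draw_balanced_subset(data, w, 1, rng_seed=seed)
            for sid in subset.sample_ids:
                counts[int(sid[1:])] += 1
        freq = counts / 2000
        for c in (0, 1):
            idx = np.flatnonzero(data.labels == c)
            expected = w[idx] / w[idx].sum()
            assert np.abs(freq[idx] - expected).max() < 0.03

    def test_zero_class_weight_errors(self):
        data = balanced_toy(n=10)
        w = np.ones(10)
        w[data.labels == 1] = 0.0
        with pytest.raises(ValueError, match="zero total weight"):
            draw_balanced_subset(data, w, 2, rng_seed=0)

    def test_with_replacement_when_class_small(self):
        data = balanced_toy(n=10)
        subset = draw_balanced_subset(data, np.ones(10), 8, rng_seed=0)
        assert subset.class_counts() == (8, 8)


class TestBoostFit:
    def test_single_round_single_member(self):
        data = balanced_toy(sep=1.0)
        committee = boost_fit(BaseLearnerSpec(family="svm", seed=0), data,
                              rounds=1, seed=0)
        assert len(committee.members) == len(committee.member_weights) == 1
        assert committee.member_weights[0] >= 0

    def test_separable_data_terminates_with_one_member(self):
        data = balanced_toy(sep=8.0)  # trivially separable
        committee = boost_fit(BaseLearnerSpec(family="random_forest", seed=0),
                              data, rounds=10, seed=0)
        assert len(committee.members) == 1
        assert np.isfinite(committee.member_weights[0])

    def test_alphas_finite_and_bounded(self):
        data = balanced_toy(sep=0.5, n=60)
        committee = boost_fit(BaseLearnerSpec(family="svm", seed=1), data,
                              rounds=5, seed=1)
        alphas = np.array(committee.member_weights)
        assert np.isfinite(alphas).all() and (alphas >= 0).all()
        assert len(committee.members) <= 5

    def test_boosting_beats_single_round_on_hard_data(self):
        # moderate overlap, moderate imbalance: committees should not be
        # worse on average than their first member
        accs_1, accs_10 = [], []
        for seed in range(10):
            cfg = dict(n_majority=125, n_minority=25, n_features=10,
                       n_informative=4, effect=1.0)
            train, _ = make_imbalanced(GeneratorConfig(**cfg, seed=seed))
            test, _ = make_imbalanced(GeneratorConfig(**cfg, seed=500 + seed))
            for rounds, acc_list in ((1, accs_1), (10, accs_10)):
                committee = boost_fit(BaseLearnerSpec(family="random_forest",
                                                      seed=seed),
                                      train, rounds=rounds, seed=seed)
                acc_list.append((committee.predict(test.features) == test.labels).mean())
        assert np.mean(accs_10) >= np.mean(accs_1) - 0.01


class TestCommitteeProba:
    def _stub(self, proba):
        class Stub:
            classes_ = np.array([0, 1])

            def __init__(self, p):
                self.p = np.asarray(p, dtype=float)

            def predict_proba(self, x):
                return np.tile(self.p, (len(x), 1))

        return Stub(proba)

    def test_single_member_identity(self):
        c = BoostedCommittee(spec=BaseLearnerSpec(), members=[self._stub([0.8, 0.2])],
                             member_weights=[2.0], rounds=1, subset_size=1)
        out = committee_predict_proba(c, np.zeros((3, 2)))
        np.testing.assert_allclose(out, [[0.8, 0.2]] * 3)

    def test_equal_weights_average(self):
        c = BoostedCommittee(
            spec=BaseLearnerSpec(),
            members=[self._stub([0.8, 0.2]), self._stub([0.6, 0.4])],
            member_weights=[1.0, 1.0], rounds=2, subset_size=1)
        out = committee_predict_proba(c, np.zeros((1, 2)))
        np.testing.assert_allclose(out, [[0.7, 0.3]])

    def test_all_zero_alpha_uses_uniform(self):
        c = BoostedCommittee(
            spec=BaseLearnerSpec(),
            members=[self._stub([1.0, 0.0]), self._stub([0.0, 1.0])],
            member_weights=[0.0, 0.0], rounds=2, subset_size=1)
        out = committee_predict_proba(c, np.zeros((1, 2)))
        np.testing.assert_allclose(out, [[0.5, 0.5]])


class TestVotingEnsemble:
    def _arm(self, proba, family):
        class Stub:
            classes_ = np.array([0, 1])

            def __init__(self, p):
                self.p = np.asarray(p, dtype=float)

            def predict_proba(self, x):
                return np.tile(self.p, (len(x), 1))

        return BoostedCommittee(spec=BaseLearnerSpec(family=family),
                                members=[Stub(proba)], member_weights=[1.0],
                                rounds=1, subset_size=1)

    def test_probability_averaging(self):
        ens = VotingEnsemble(arms=[self._arm([0.9, 0.1], "random_forest"),
                                   self._arm([0.7, 0.3], "svm")])
        np.testing.assert_allclose(ens.predict_proba(np.zeros((1, 2))), [[0.8, 0.2]])
        assert ens.predict(np.zeros((1, 2))).tolist() == [0]

    def test_exact_tie_goes_to_minority(self):
        ens = VotingEnsemble(arms=[self._arm([0.6, 0.4], "random_forest"),
                                   self._arm([0.4, 0.6], "svm")])
        assert ens.predict(np.zeros((1, 2))).tolist() == [1]
        ens_maj = VotingEnsemble(arms=ens.arms, tie_rule="majority")
        assert ens_maj.predict(np.zeros((1, 2))).tolist() == [0]

    def test_duplicate_families_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            VotingEnsemble(arms=[self._arm([0.5, 0.5], "svm"),
                                 self._arm([0.5, 0.5], "svm")])

    def test_probabilities_conserved(self):
        data, _ = make_imbalanced(GeneratorConfig(n_majority=40, n_minority=20,
                                                  n_features=6, n_informative=3,
                                                  effect=2.0, seed=2))
        ens = fit_ensemble(data, rounds=2, seed=2, resample_first=False)
        proba = ens.predict_proba(data.features)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0)
        assert (proba >= 0).all() and (proba <= 1).all()


class TestFitEnsemble:
    def test_two_arms_single_round(self):
        data = balanced_toy(n=40, sep=2.0)
        ens = fit_ensemble(data, rounds=1, resample_first=False, seed=0)
        assert len(ens.arms) == 2
        assert {a.spec.family for a in ens.arms} == {"random_forest", "svm"}

    def test_determinism_full_path(self):
        data, _ = make_imbalanced(GeneratorConfig(n_majority=60, n_minority=15,
                                                  n_features=8, n_informative=4,
                                                  effect=1.5, seed=4))
        test, _ = make_imbalanced(GeneratorConfig(n_majority=20, n_minority=5,
                                                  n_features=8, n_informative=4,
                                                  effect=1.5, seed=900))
        p1 = fit_ensemble(data, rounds=3, seed=4).predict_proba(test.features)
        p2 = fit_ensemble(data, rounds=3, seed=4).predict_proba(test.features)
        np.testing.assert_array_equal(p1, p2)

    def test_rf_arm_oracle_equivalence(self):
        # rounds=1, full-size balanced subset, no resampling: the RF arm's
        # member is exactly a directly trained forest on the same rows
        data = balanced_toy(n=40, sep=1.0)
        spec = BaseLearnerSpec(family="random_forest", seed=123)
        committee = boost_fit(spec, data, rounds=1, per_class_size=20, seed=123)
        direct = RandomForestClassifier(n_estimators=spec.rf_trees,
                                        max_features=min(10, data.n_features),
                                        random_state=123, n_jobs=1)
        direct.fit(data.features, data.labels)
        probe = balanced_toy(seed=77, n=30, sep=1.0).features
        np.testing.assert_array_equal(committee.predict(probe), direct.predict(probe))

    def test_optional_gbt_arm(self):
        data = balanced_toy(n=30, sep=2.0)
        ens = fit_ensemble(data, rounds=1, resample_first=False, seed=0,
                           with_gbt_arm=True)
        assert len(ens.arms) == 3

    def test_model_round_trip_and_version_guard(self, tmp_path):
        data = balanced_toy(n=30, sep=2.0)
        ens = fit_ensemble(data, rounds=1, resample_first=False, seed=0)
        path = tmp_path / "model.bin"
        save_model(ens, path)
        again = load_model(path)
        np.testing.assert_array_equal(again.predict(data.features),
                                      ens.predict(data.features))
        bad = tmp_path / "bad.bin"
        import pickle
        bad.write_bytes(pickle.dumps({"format": "spiderens-model", "version": 99}))
        with pytest.raises(ValueError, match="version"):
            load_model(bad)
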