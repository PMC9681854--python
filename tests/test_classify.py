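"""Dual random-forest lifestyle classifier and consensus calling."""

import numpy as np
import pytest
from sklearn.metrics import f1_score

from plankshift.classify import (
    CONSENSUS_BENTHIC,
    CONSENSUS_PLANKTONIC,
    CONSENSUS_UNRESOLVED,
    FeatureSet,
    LifestyleCall,
    build_training,
    evaluate,
    predict_consensus,
    train_model,
)
from plankshift.occurrence import LogisticFit, StationPresence
from plankshift.types import (
    Assignment,
    LIFESTYLE_BENTHIC,
    LIFESTYLE_PLANKTONIC,
)


def _presence(rows, distances=None):
    motus = [f"M{i}" for i in range(len(rows))]
    stations = [f"S{j}" for j in range(len(rows[0]))]
    return StationPresence(
        motu_ids=motus, station_ids=stations,
        presence=np.array(rows, dtype=np.int8),
        station_distance=np.asarray(
            distances if distances is not None else np.arange(1, len(stations) + 1),
            dtype=float,
        ),
    )


def _fit(motu_id, beta0=0.0, beta1=0.0, estimable=True):
    return LogisticFit(
        motu_id=motu_id, beta0=beta0, beta1=beta1, se_beta1=0.1,
        converged=True, estimable=estimable, penalized=False,
        trend="constant",
    )


def _asg(motu_id, category):
    return Assignment(motu_id, "r", 1.0, category, True)


class TestBuildTraining:
    def _world(self, n_stations_present):
        """One Spinose, one Monothalamea, one Globothalamea MOTU; the
        Globothalamea row controls the station-filter boundary."""
        base = [1] * 10
        globo = [1] * n_stations_present + [0] * (10 - n_stations_present)
        pres = _presence([base, base, globo])
        asg = [
            _asg("M0", "Spinose"), _asg("M1", "Monothalamea"),
            _asg("M2", "Globothalamea"),
        ]
        fits = [_fit("M0"), _fit("M1"), _fit("M2")]
        return asg, pres, fits

    def test_four_stations_excluded(self):
        asg, pres, fits = self._world(4)
        training, pred = build_training(asg, pres, fits, min_stations=5)
        assert pred.motu_ids == []

    def test_five_stations_included(self):
        asg, pres, fits = self._world(5)
        training, pred = build_training(asg, pres, fits, min_stations=5)
        assert pred.motu_ids == ["M2"]
        assert sorted(training.motu_ids) == ["M0", "M1"]

    def test_empty_training_class_rejected(self):
        pres = _presence([[1] * 10, [1] * 10])
        asg = [_asg("M0", "Spinose"), _asg("M1", "Globothalamea")]
        fits = [_fit("M0"), _fit("M1")]
        with pytest.raises(ValueError, match="benthic"):
            build_training(asg, pres, fits)

    def test_non_estimable_fit_kept_for_profile_only(self):
        pres = _presence([[1] * 10, [1] * 10, [1] * 10])
        asg = [_asg("M0", "Spinose"), _asg("M1", "Monothalamea"),
               _asg("M2", "Globothalamea")]
        fits = [_fit("M0"), _fit("M1"), _fit("M2", estimable=False)]
        _, pred = build_training(asg, pres, fits)
        assert pred.motu_ids == ["M2"]
        assert not pred.coeff_ok[0]
        assert pred.profile_features.shape == (1, 10)

    def test_sizes_match_generator_counts(
        self, small_world, small_classification
    ):
        _, _, training, pred = small_classification
        labeled = {
            m for m, t in small_world.truth.items()
            if t.source_category != "Globothalamea"
        }
        globo = set(small_world.truth) - labeled
        assert set(training.motu_ids) <= labeled
        assert set(pred.motu_ids) <= globo

    def test_min_stations_monotonicity(
        self, small_assignments, small_presence, small_fits
    ):
        sizes = []
        for ms in (5, 10, 20):
            tr, pred = build_training(
                small_assignments, small_presence, small_fits, min_stations=ms
            )
            sizes.append((len(tr), len(pred)))
        assert sizes[0] >= sizes[1] >= sizes[2]


class TestTrainModel:
    def _separable(self, rng, n=50):
        b1 = np.concatenate([rng.uniform(-0.02, -0.005, n), rng.uniform(0.005, 0.02, n)])
        b0 = rng.normal(0, 1, 2 * n)
        X = np.column_stack([b0, b1])
        y = np.array([LIFESTYLE_BENTHIC] * n + [LIFESTYLE_PLANKTONIC] * n)
        return X, y

    def test_separable_resubstitution_accuracy(self, rng):
        X, y = self._separable(rng)
        clf = train_model(X, y, n_trees=200, seed=0)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_seeded_determinism(self, rng):
        X, y = self._separable(rng)
        X2 = X + rng.normal(0, 0.5, X.shape)  # noisy, non-trivial
        p1 = train_model(X2, y, n_trees=100, seed=3).predict(X2)
        p2 = train_model(X2, y, n_trees=100, seed=3).predict(X2)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            train_model(np.zeros((4, 2)), ["benthic"] * 4)

    def test_permuted_labels_score_at_chance(self, rng):
        """With labels shuffled, CV accuracy sits at the majority-class
        rate within Monte-Carlo noise."""
        X = rng.normal(size=(60, 2))
        y = np.array([LIFESTYLE_BENTHIC] * 20 + [LIFESTYLE_PLANKTONIC] * 40)
        accs = []
        for rep in range(8):
            yp = rng.permutation(y)
            rep_acc = evaluate(
                X, yp, "coeff", n_trees=100, seed=rep, n_repeats=2
            ).accuracy
            accs.append(rep_acc)
        majority = 40 / 60
        mc_sd = np.std(accs, ddof=1)
        assert abs(np.mean(accs) - majority) < 3 * max(mc_sd, 0.02)


class TestEvaluate:
    def test_separable_perfect_scores(self, rng):
        b1 = np.concatenate([rng.uniform(-0.02, -0.01, 30), rng.uniform(0.01, 0.02, 30)])
        X = np.column_stack([np.zeros(60), b1])
        y = np.array([LIFESTYLE_BENTHIC] * 30 + [LIFESTYLE_PLANKTONIC] * 30)
        rep = evaluate(X, y, "coeff", n_trees=100, seed=0, n_repeats=2)
        assert rep.accuracy == 1.0 and rep.f1 == 1.0

    def test_stratification_error_when_class_too_small(self, rng):
        X = rng.normal(size=(10, 2))
        y = np.array([LIFESTYLE_BENTHIC] * 3 + [LIFESTYLE_PLANKTONIC] * 7)
        with pytest.raises(ValueError, match="strat"):
            evaluate(X, y, "coeff", n_splits=5)

    def test_minority_f1_below_accuracy_when_errors_hit_minority(self):
        """Constructed confusion matrix: errors concentrated in the
        minority (benthic) class push its F1 under the accuracy."""
        y_true = np.array([LIFESTYLE_BENTHIC] * 10 + [LIFESTYLE_PLANKTONIC] * 90)
        y_pred = y_true.copy()
        y_pred[:4] = LIFESTYLE_PLANKTONIC  # 4 benthic misread as planktonic
        acc = (y_true == y_pred).mean()
        f1 = f1_score(y_true, y_pred, pos_label=LIFESTYLE_BENTHIC)
        # F1 = 2*6 / (2*6 + 0 + 4) = 0.75 against accuracy 0.96
        assert f1 == pytest.approx(0.75)
        assert f1 <= acc


class TestConsensus:
    def _models_and_set(self, rng, votes):
        """Train stub forests on cleanly separable features, then craft a
        prediction set whose features force the requested votes."""
        n = 30
        b1 = np.concatenate([rng.uniform(-0.02, -0.01, n), rng.uniform(0.01, 0.02, n)])
        X = np.column_stack([np.zeros(2 * n), b1])
        y = np.array([LIFESTYLE_BENTHIC] * n + [LIFESTYLE_PLANKTONIC] * n)
        coeff = train_model(X, y, n_trees=100, seed=0)
        prof_X = np.zeros((2 * n, 6), dtype=np.int8)
        prof_X[n:, :3] = 1  # planktonic occupy stations 0-2
        prof_X[:n, 3:] = 1
        profile = train_model(prof_X, y, n_trees=100, seed=0)
        ids = [f"G{i}" for i in range(len(votes))]
        coeff_feats = np.array(
            [[0.0, -0.015] if v[0] == "b" else [0.0, 0.015] for v in votes]
        )
        prof_feats = np.array(
            [[0, 0, 0, 1, 1, 1] if v[1] == "b" else [1, 1, 1, 0, 0, 0] for v in votes],
            dtype=np.int8,
        )
        fs = FeatureSet(
            motu_ids=ids, station_ids=[f"S{j}" for j in range(6)],
            coeff_features=coeff_feats, profile_features=prof_feats,
            coeff_ok=np.ones(len(votes), dtype=bool),
        )
        return coeff, profile, fs

    def test_vote_combinations(self, rng):
        coeff, profile, fs = self._models_and_set(
            rng, votes=["pp", "bb", "pb", "bp"]
        )
        res = predict_consensus(coeff, profile, fs)
        assert [c.consensus for c in res.calls] == [
            CONSENSUS_PLANKTONIC, CONSENSUS_BENTHIC,
            CONSENSUS_UNRESOLVED, CONSENSUS_UNRESOLVED,
        ]
        assert res.agreement_rate == pytest.approx(0.5)

    def test_missing_coeff_features_unresolved(self, rng):
        coeff, profile, fs = self._models_and_set(rng, votes=["pp"])
        fs.coeff_ok[:] = False
        res = predict_consensus(coeff, profile, fs)
        assert res.calls[0].pred_coeff is None
        assert res.calls[0].consensus == CONSENSUS_UNRESOLVED

    def test_lifestylecall_invariant_enforced(self):
        with pytest.raises(ValueError):
            LifestyleCall("X", LIFESTYLE_PLANKTONIC, LIFESTYLE_BENTHIC,
                          CONSENSUS_PLANKTONIC)

    def test_consensus_subset_of_each_model(self, small_classification):
        consensus, _, _, _ = small_classification
        pp = set(consensus.putative_planktonic_ids)
        coeff_p = {c.motu_id for c in consensus.calls
                   if c.pred_coeff == LIFESTYLE_PLANKTONIC}
        prof_p = {c.motu_id for c in consensus.calls
                  if c.pred_profile == LIFESTYLE_PLANKTONIC}
        assert pp <= coeff_p and pp <= prof_p

    def test_end_to_end_recovery(self, small_world, small_classification):
        """Truly planktonic-type Globothalamea are recovered as putative
        planktonic; truly benthic-type rarely are."""
        consensus, reports, _, _ = small_classification
        for rep in reports:
            assert rep.accuracy >= 0.85
        tp = fp = np = nb = 0
        for c in consensus.calls:
            truly_p = small_world.truth[c.motu_id].lifestyle == LIFESTYLE_PLANKTONIC
            called_p = c.consensus == CONSENSUS_PLANKTONIC
            if truly_p:
                np += 1
                tp += called_p
            else:
                nb += 1
                fp += called_p
        assert tp / np >= 0.85
        assert fp / nb <= 0.10

    def test_stage_determinism(
        self, small_assignments, small_presence, small_fits
    ):
        from plankshift.classify import classify_lifestyles

        r1 = classify_lifestyles(
            small_assignments, small_presence, small_fits,
            n_trees=100, seed=11, evaluate_models=False,
        )
        r2 = classify_lifestyles(
            small_assignments, small_presence, small_fits,
            n_trees=100, seed=11, evaluate_models=False,
        )
        assert [c.consensus for c in r1[0].calls] == [c.consensus for c in r2[0].calls]
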