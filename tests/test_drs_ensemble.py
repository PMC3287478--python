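import numpy as np
import pandas as pd
import pytest

from pairdrs import pair_engine
from pairdrs.drs_ensemble import (DRSEnsemble, DRSScore, RFParams,
                                  holdout_split, oob_validation_scores,
                                  rescale_unit, score_features, score_pair,
                                  score_pairs, train_ensemble)
from pairdrs.evaluation import sensitivity_specificity_curve
from pairdrs.negative_sampling import NegativeSampleSet


def _toy_training(seed=0, n=40, k=3):
    """Separable toy problem: positives have small E components."""
    rng = np.random.default_rng(seed)
    ids = [f"D{i:03d}" for i in range(n)]
    scores = pd.DataFrame(rng.normal(size=(n, k)), index=ids)
    pairs = pair_engine.enumerate_pairs(ids)
    rng.shuffle(pairs)
    positives = pairs[:60]
    # pull positive members together so E is small
    for a, b in positives:
        scores.loc[b] = scores.loc[a] + rng.normal(0, 0.05, size=k)
    neg_sets = [NegativeSampleSet(pairs=pairs[60 + 60 * i:120 + 60 * i],
                                  seed=seed, set_index=i + 1)
                for i in range(2)]
    return positives, neg_sets, scores


class TestTrainEnsemble:
    def test_single_set_degenerates_to_one_forest(self):
        positives, neg_sets, scores = _toy_training()
        ens = train_ensemble(positives, neg_sets[:1], scores,
                             RFParams(n_trees=25), seed=1)
        assert ens.n_sets == 1
        assert ens.k == scores.shape[1]

    def test_retraining_with_same_seed_is_bitwise_identical(self):
        positives, neg_sets, scores = _toy_training()
        params = RFParams(n_trees=40)
        e1 = train_ensemble(positives, neg_sets, scores, params, seed=5)
        e2 = train_ensemble(positives, neg_sets, scores, params, seed=5)
        probe = np.random.default_rng(0).normal(size=(50, 2 * e1.k))
        assert np.array_equal(score_features(e1, probe),
                              score_features(e2, probe))
        for v1, v2 in zip(e1.oob_votes, e2.oob_votes):
            assert np.array_equal(v1, v2, equal_nan=True)

    def test_empty_positives_rejected(self):
        _, neg_sets, scores = _toy_training()
        with pytest.raises(ValueError, match="positive"):
            train_ensemble([], neg_sets, scores, RFParams(n_trees=5), seed=0)

    def test_mismatched_negative_set_size_rejected(self):
        positives, neg_sets, scores = _toy_training()
        bad = NegativeSampleSet(pairs=neg_sets[0].pairs[:10], seed=0,
                                set_index=1)
        with pytest.raises(ValueError, match="expected"):
            train_ensemble(positives, [bad], scores, RFParams(n_trees=5),
                           seed=0)


class TestScoring:
    def test_scores_bounded_and_symmetric(self):
        positives, neg_sets, scores = _toy_training()
        ens = train_ensemble(positives, neg_sets, scores, RFParams(n_trees=30),
                             seed=2)
        rng = np.random.default_rng(3)
        for _ in range(100):
            a = rng.normal(size=ens.k)
            b = rng.normal(size=ens.k)
            sab = score_pair(ens, np.concatenate(pair_engine.make_pair_vector(a, b)))
            sba = score_pair(ens, np.concatenate(pair_engine.make_pair_vector(b, a)))
            assert sab.value == sba.value
            assert -1.0 <= sab.value <= 1.0

    def test_score_pairs_matches_feature_path(self):
        positives, neg_sets, scores = _toy_training()
        ens = train_ensemble(positives, neg_sets, scores, RFParams(n_trees=30),
                             seed=2)
        pairs = positives[:10]
        via_ids = score_pairs(ens, pairs, scores)
        via_X = score_features(ens, pair_engine.pair_features(pairs, scores))
        assert np.array_equal(via_ids, via_X)

    def test_length_mismatch_rejected(self):
        positives, neg_sets, scores = _toy_training()
        ens = train_ensemble(positives, neg_sets[:1], scores,
                             RFParams(n_trees=5), seed=0)
        with pytest.raises(ValueError, match="2k"):
            score_pair(ens, np.zeros(2 * ens.k + 1))

    def test_half_ensembles_agree_on_synthetic_data(self, preset_study):
        # averaging reduces variance: two disjoint 5-forest halves must
        # rank pairs almost identically
        ens = preset_study.ensemble
        halves = []
        for sl in (slice(0, 5), slice(5, 10)):
            halves.append(DRSEnsemble(
                classifiers=ens.classifiers[sl], k=ens.k,
                rf_params=ens.rf_params))
        pairs = preset_study.test_pairs[:2000]
        s1 = score_pairs(halves[0], pairs, preset_study.pc_scores)
        s2 = score_pairs(halves[1], pairs, preset_study.pc_scores)
        assert np.corrcoef(s1, s2)[0, 1] > 0.9


class TestRescale:
    @pytest.mark.parametrize("drs,unit", [(-1.0, 0.0), (0.0, 0.5),
                                          (0.54, 0.77), (1.0, 1.0)])
    def test_linear_map(self, drs, unit):
        assert rescale_unit(DRSScore(drs)) == pytest.approx(unit)

    def test_out_of_range_score_rejected(self):
        with pytest.raises(ValueError):
            DRSScore(1.5)


class TestOOB:
    def test_single_tree_leaves_about_a_third_out(self):
        positives, neg_sets, scores = _toy_training(n=60)
        ens = train_ensemble(positives, neg_sets[:1], scores,
                             RFParams(n_trees=1), seed=4)
        oob_s, oob_y = oob_validation_scores(ens, 1)
        frac_oob = len(oob_y) / (2 * len(positives))
        assert 0.2 < frac_oob < 0.5  # about one-third of samples

    def test_oob_scores_are_rescaled_and_labelled(self):
        positives, neg_sets, scores = _toy_training()
        ens = train_ensemble(positives, neg_sets, scores, RFParams(n_trees=50),
                             seed=5)
        oob_s, oob_y = oob_validation_scores(ens, 2)
        assert ((oob_s >= -1) & (oob_s <= 1)).all()
        assert set(np.unique(oob_y)) <= {0, 1}
        assert len(oob_s) == len(oob_y)

    def test_classifier_index_out_of_range(self):
        positives, neg_sets, scores = _toy_training()
        ens = train_ensemble(positives, neg_sets[:1], scores,
                             RFParams(n_trees=5), seed=0)
        with pytest.raises(IndexError):
            oob_validation_scores(ens, 2)

    def test_oob_tracks_external_holdout(self, preset_study):
        # internal OOB balanced accuracy at threshold zero should agree
        # with the external-holdout estimate on the same generator
        oob_s, oob_y = oob_validation_scores(preset_study.ensemble, 1)
        c_in = sensitivity_specificity_curve(oob_s, oob_y,
                                             thresholds=[0.0]).iloc[0]
        c_ex = sensitivity_specificity_curve(preset_study.test_scores,
                                             preset_study.test_labels,
                                             thresholds=[0.0]).iloc[0]
        bal_in = (c_in.sensitivity + c_in.specificity) / 2
        bal_ex = (c_ex.sensitivity + c_ex.specificity) / 2
        assert abs(bal_in - bal_ex) < 0.05


class TestHoldoutSplit:
    def test_no_training_pair_touches_holdout(self):
        ids = [f"D{i:03d}" for i in range(200)]
        train, test = holdout_split(ids, n_holdout=50, seed=8)
        assert len(test) == 50
        assert not set(train) & set(test)
        assert sorted(train + test) == sorted(ids)
        train_pairs = pair_engine.enumerate_pairs(train)
        assert all(a not in set(test) and b not in set(test)
                   for a, b in train_pairs)

    def test_deterministic_given_seed(self):
        ids = [f"D{i}" for i in range(30)]
        assert holdout_split(ids, 10, seed=1) == holdout_split(ids, 10, seed=1)
        assert holdout_split(ids, 10, seed=1) != holdout_split(ids, 10, seed=2)

    def test_oversized_holdout_rejected(self):
        with pytest.raises(ValueError):
            holdout_split(["a", "b"], n_holdout=2, seed=0)


def test_ensemble_save_load_round_trip(tmp_path):
    positives, neg_sets, scores = _toy_training()
    ens = train_ensemble(positives, neg_sets, scores, RFParams(n_trees=20),
                         seed=6, space_signature=("sig", 3))
    path = tmp_path / "model.joblib"
    ens.save(path)
    back = DRSEnsemble.load(path)
    probe = np.random.default_rng(1).normal(size=(20, 2 * ens.k))
    assert np.array_equal(score_features(ens, probe),
                          score_features(back, probe))
    assert back.space_signature == ("sig", 3)
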