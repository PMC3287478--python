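"""The Random Forest ensemble behind the drug-drug relationship score.

Ten forests (by default) are trained on the same positive pairs against ten
independently under-sampled negative sets. The score of a pair is the
positive-class vote fraction averaged over the forests, rescaled linearly
to [-1, 1]; zero corresponds to a majority vote at parity. Internal
validation uses the out-of-bag votes of a single forest, so its estimates
come from data unseen by the trees that produced them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .negative_sampling import NegativeSampleSet
from .pair_engine import pair_features

logger = logging.getLogger(__name__)


@dataclass
class RFParams:
    """Breiman-default forest hyperparameters; all overridable."""

    n_trees: int = 500
    features_per_split: int | str = "sqrt"  # floor(sqrt(2k)) when "sqrt"
    min_leaf: int = 1


@dataclass
class DRSScore:
    """A drug-drug relationship score: 2 * mean vote fraction - 1."""

    value: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.value <= 1.0:
            raise ValueError(f"DRS {self.value} outside [-1, 1]")


def rescale_unit(drs: "DRSScore | float") -> float:
    """Map a [-1, 1] score to the [0, 1] scale of structural similarity."""
    value = drs.value if isinstance(drs, DRSScore) else float(drs)
    return (value + 1.0) / 2.0


@dataclass
class DRSEnsemble:
    """Trained forests plus the OOB records needed for internal validation."""

    classifiers: list[RandomForestClassifier]
    k: int  # component count; features are [M | E] of length 2k
    rf_params: RFParams
    training_manifest: dict = field(default_factory=dict)
    oob_votes: list[np.ndarray] = field(default_factory=list)
    oob_labels: list[np.ndarray] = field(default_factory=list)
    space_signature: tuple | None = None

    @property
    def n_sets(self) -> int:
        return len(self.classifiers)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "DRSEnsemble":
        obj = joblib.load(path)
        if not isinstance(obj, cls):
            raise TypeError(f"{path} does not hold a DRSEnsemble")
        return obj


def train_ensemble(positives: Sequence[tuple[str, str]],
                   negative_sets: Sequence[NegativeSampleSet],
                   pc_scores: pd.DataFrame,
                   rf_params: RFParams | None = None,
                   seed: int = 0,
                   space_signature: tuple | None = None) -> DRSEnsemble:
    """Train one forest per negative set against the shared positives.

    Per-forest out-of-bag vote fractions are retained for
    :func:`oob_validation_scores`.
    """
    if not positives:
        raise ValueError("no positive pairs to train on")
    rf_params = rf_params or RFParams()
    n_pos = len(positives)
    X_pos = pair_features(positives, pc_scores)
    k = pc_scores.shape[1]
    max_features = (rf_params.features_per_split
                    if isinstance(rf_params.features_per_split, int)
                    else "sqrt")
    classifiers, oob_votes, oob_labels = [], [], []
    rng = np.random.default_rng(seed)
    for i, neg_set in enumerate(negative_sets):
        if len(neg_set.pairs) != n_pos:
            raise ValueError(
                f"negative set {i + 1} has {len(neg_set.pairs)} pairs; "
                f"expected the positive count {n_pos}")
        X_neg = pair_features(neg_set.pairs, pc_scores)
        X = np.vstack([X_pos, X_neg])
        y = np.concatenate([np.ones(n_pos, dtype=int),
                            np.zeros(n_pos, dtype=int)])
        clf = RandomForestClassifier(
            n_estimators=rf_params.n_trees,
            max_features=max_features,
            min_samples_leaf=rf_params.min_leaf,
            oob_score=True,
            bootstrap=True,
            random_state=int(rng.integers(0, 2**31 - 1)),
            n_jobs=1,
        )
        with warnings.catch_warnings():
            # tiny tree counts can leave samples never-OOB; handled below
            warnings.filterwarnings("ignore",
                                    message="Some inputs do not have OOB")
            clf.fit(X, y)
        pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
        decision = clf.oob_decision_function_
        # never-OOB samples surface as all-zero (or NaN) rows; mark NaN
        never_oob = ~(np.nansum(decision, axis=1) > 0)
        votes = decision[:, pos_col].copy()
        votes[never_oob] = np.nan
        oob_votes.append(votes)
        oob_labels.append(y)
        classifiers.append(clf)
    manifest = {
        "n_positive": n_pos,
        "n_sets": len(negative_sets),
        "seed": seed,
        "set_seeds": [s.seed for s in negative_sets],
        "rf_params": vars(rf_params),
    }
    return DRSEnsemble(classifiers=classifiers, k=k, rf_params=rf_params,
                       training_manifest=manifest, oob_votes=oob_votes,
                       oob_labels=oob_labels, space_signature=space_signature)


def _check_width(ensemble: DRSEnsemble, X: np.ndarray) -> None:
    if X.ndim != 2 or X.shape[1] != 2 * ensemble.k:
        raise ValueError(
            f"feature width {X.shape[-1]} does not match 2k = {2 * ensemble.k}")


def score_features(ensemble: DRSEnsemble, X: np.ndarray) -> np.ndarray:
    """DRS for rows of an [M | E] feature matrix."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    _check_width(ensemble, X)
    votes = np.zeros(X.shape[0])
    for clf in ensemble.classifiers:
        pos_col = int(np.flatnonzero(clf.classes_ == 1)[0])
        votes += clf.predict_proba(X)[:, pos_col]
    return 2.0 * votes / ensemble.n_sets - 1.0


def score_pair(ensemble: DRSEnsemble, pair_vector: np.ndarray) -> DRSScore:
    """DRS of a single pair vector of length 2k."""
    vec = np.asarray(pair_vector, dtype=float).ravel()
    if vec.size != 2 * ensemble.k:
        raise ValueError(
            f"pair vector length {vec.size} does not match 2k = {2 * ensemble.k}")
    return DRSScore(float(score_features(ensemble, vec[None, :])[0]))


def score_pairs(ensemble: DRSEnsemble,
                pairs: Sequence[tuple[str, str]],
                pc_scores: pd.DataFrame) -> np.ndarray:
    """DRS for a list of drug-id pairs given their component scores."""
    if not pairs:
        return np.empty(0)
    return score_features(ensemble, pair_features(pairs, pc_scores))


def oob_validation_scores(ensemble: DRSEnsemble,
                          which_classifier: int = 1
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Out-of-bag scores (rescaled to [-1, 1]) and labels for one forest.

    ``which_classifier`` is 1-based. Pairs that were never out-of-bag (only
    possible at tiny tree counts) are omitted, with the count logged.
    """
    if not 1 <= which_classifier <= ensemble.n_sets:
        raise IndexError(f"classifier index {which_classifier} out of range "
                         f"1..{ensemble.n_sets}")
    votes = ensemble.oob_votes[which_classifier - 1]
    labels = ensemble.oob_labels[which_classifier - 1]
    valid = ~np.isnan(votes)
    n_skipped = int((~valid).sum())
    if n_skipped:
        logger.info("omitting %d pair(s) that were never out-of-bag",
                    n_skipped)
    return 2.0 * votes[valid] - 1.0, labels[valid]


def holdout_split(drug_ids: Sequence[str], n_holdout: int = 50,
                  seed: int = 0) -> tuple[list[str], list[str]]:
    """Randomly hold out drugs for external validation.

    Every pair touching a held-out drug belongs to the external test set
    and must be excluded from training.
    """
    ids = sorted(drug_ids)
    if n_holdout >= len(ids):
        raise ValueError("n_holdout must be smaller than the number of drugs")
    rng = np.random.default_rng(seed)
    test_idx = rng.choice(len(ids), size=n_holdout, replace=False)
    test = sorted(ids[i] for i in test_idx)
    test_set = set(test)
    train = [d for d in ids if d not in test_set]
    return train, test
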