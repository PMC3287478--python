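"""End-to-end wiring of the scoring study.

Glue used by the command-line interface and the experiment scripts: clean
descriptors, fit the component space, enumerate and label pairs, draw the
under-sampled negative sets, train the ensemble, and score pair universes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import drs_ensemble, feature_space, negative_sampling, pair_engine
from .data_io import DescriptorMatrix, FingerprintSet, InteractionMap
from .drs_ensemble import DRSEnsemble, RFParams
from .feature_space import PCSpace
from .synthetic_data import SyntheticBundle


def build_feature_space(descriptors: DescriptorMatrix,
                        variance_target: float = 0.9,
                        standardize: bool = True
                        ) -> tuple[PCSpace, pd.DataFrame]:
    """Clean, fit and project in one step; returns (space, drug scores)."""
    cleaned, _ = feature_space.clean_descriptors(descriptors)
    space = feature_space.fit_pc_space(cleaned, variance_target=variance_target,
                                       standardize=standardize)
    scores = feature_space.project(cleaned, space)
    return space, scores


@dataclass
class TrainedStudy:
    """Everything produced by one train/holdout run on a dataset."""

    space: PCSpace
    pc_scores: pd.DataFrame
    train_drugs: list[str]
    test_drugs: list[str]
    positives: list[tuple[str, str]]
    negatives: list[tuple[str, str]]
    negative_sims: np.ndarray
    negative_sets: list
    ensemble: DRSEnsemble
    test_pairs: list[tuple[str, str]] = field(default_factory=list)
    test_labels: np.ndarray = field(default_factory=lambda: np.empty(0))
    test_scores: np.ndarray = field(default_factory=lambda: np.empty(0))


def train_study(descriptors: DescriptorMatrix,
                fingerprints: FingerprintSet,
                interactions: InteractionMap,
                n_sets: int = 10,
                rf_params: RFParams | None = None,
                n_holdout: int = 0,
                variance_target: float = 0.9,
                density_method: str = "histogram",
                seed: int = 0) -> TrainedStudy:
    """Run the full training pipeline, optionally with a drug-level holdout.

    With ``n_holdout`` > 0, that many drugs are held out before training
    and every pair touching one of them becomes the external test set,
    scored by the full ensemble.
    """
    space, pc_scores = build_feature_space(descriptors,
                                           variance_target=variance_target)
    all_drugs = list(pc_scores.index)
    if n_holdout > 0:
        train_drugs, test_drugs = drs_ensemble.holdout_split(
            all_drugs, n_holdout=n_holdout, seed=seed)
    else:
        train_drugs, test_drugs = sorted(all_drugs), []

    train_pairs = pair_engine.enumerate_pairs(train_drugs)
    labels = pair_engine.label_pairs(train_pairs, interactions)
    positives = [p for p, l in zip(train_pairs, labels)
                 if l == pair_engine.POSITIVE]
    negatives = [p for p, l in zip(train_pairs, labels)
                 if l == pair_engine.NEGATIVE]
    if not positives or not negatives:
        raise ValueError("training universe lacks positives or negatives")

    sims = negative_sampling.pairwise_tanimoto(fingerprints, negatives)
    neg_sets = negative_sampling.sample_negative_sets(
        negatives, sims, n_sets=n_sets, set_size=len(positives),
        seed=seed, method=density_method)
    ensemble = drs_ensemble.train_ensemble(
        positives, neg_sets, pc_scores, rf_params=rf_params, seed=seed,
        space_signature=space.signature)

    study = TrainedStudy(space=space, pc_scores=pc_scores,
                         train_drugs=train_drugs, test_drugs=test_drugs,
                         positives=positives, negatives=negatives,
                         negative_sims=sims, negative_sets=neg_sets,
                         ensemble=ensemble)
    if test_drugs:
        test_set = set(test_drugs)
        all_pairs = pair_engine.enumerate_pairs(all_drugs)
        test_pairs = [p for p in all_pairs
                      if p[0] in test_set or p[1] in test_set]
        test_labels = pair_engine.label_pairs(test_pairs, interactions)
        keep = test_labels != pair_engine.UNKNOWN
        study.test_pairs = [p for p, k in zip(test_pairs, keep) if k]
        study.test_labels = test_labels[keep]
        study.test_scores = drs_ensemble.score_pairs(
            ensemble, study.test_pairs, pc_scores)
    return study


def drs_matrix(ensemble: DRSEnsemble, pc_scores: pd.DataFrame,
               drug_ids: list[str] | None = None) -> pd.DataFrame:
    """Symmetric drugs x drugs DRS frame (diagonal NaN)."""
    ids = sorted(drug_ids) if drug_ids is not None else list(pc_scores.index)
    pairs = pair_engine.enumerate_pairs(ids)
    scores = drs_ensemble.score_pairs(ensemble, pairs, pc_scores)
    mat = pd.DataFrame(np.nan, index=ids, columns=ids)
    for (a, b), s in zip(pairs, scores):
        mat.loc[a, b] = s
        mat.loc[b, a] = s
    return mat


def train_study_from_bundle(bundle: SyntheticBundle, **kwargs) -> TrainedStudy:
    return train_study(bundle.descriptors, bundle.fingerprints,
                       bundle.interactions, **kwargs)
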