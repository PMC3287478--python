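import numpy as np
import pandas as pd
import pytest

from pairdrs import drs_ensemble, negative_sampling, pipeline, synthetic_data
from pairdrs import pair_engine


@pytest.fixture(scope="session")
def small_bundle():
    cfg = synthetic_data.SyntheticConfig(
        n_drugs=60, n_targets=8, n_descriptors=30, n_bits=64, seed=11)
    return synthetic_data.generate(cfg)


@pytest.fixture(scope="session")
def small_study(small_bundle):
    return pipeline.train_study_from_bundle(
        small_bundle, n_sets=3,
        rf_params=drs_ensemble.RFParams(n_trees=60),
        n_holdout=15, seed=3)


@pytest.fixture(scope="session")
def preset_bundle():
    """The default study preset: 200 drugs, 20 targets, seed 7."""
    return synthetic_data.generate(synthetic_data.SyntheticConfig())


@pytest.fixture(scope="session")
def preset_study(preset_bundle):
    """Full ensemble (10 x 200 trees) with a 50-drug external holdout."""
    return pipeline.train_study_from_bundle(
        preset_bundle, n_sets=10,
        rf_params=drs_ensemble.RFParams(n_trees=200),
        n_holdout=50, seed=7)


@pytest.fixture(scope="session")
def preset_drs_matrix(preset_bundle, preset_study):
    return pipeline.drs_matrix(preset_study.ensemble, preset_study.pc_scores)


@pytest.fixture(scope="session")
def preset_tanimoto_matrix(preset_bundle):
    ids = preset_bundle.descriptors.drug_ids
    pairs = pair_engine.enumerate_pairs(ids)
    sims = negative_sampling.pairwise_tanimoto(preset_bundle.fingerprints,
                                               pairs)
    mat = pd.DataFrame(np.nan, index=sorted(ids), columns=sorted(ids))
    for (a, b), s in zip(pairs, sims):
        mat.loc[a, b] = s
        mat.loc[b, a] = s
    return mat
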