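"""Drug-pair enumeration, target-sharing labels and (M, E) pair vectors.

A pair of drugs is encoded by two vectors over the principal components:
M, the per-component mean (the pair's basal chemistry), and E, the
per-component squared difference (its internal dissimilarity). The
classifier input is the concatenation [M | E], which is invariant to the
order of the two drugs.
"""

from __future__ import annotations

from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .data_io import InteractionMap

POSITIVE = "positive"
NEGATIVE = "negative"
UNKNOWN = "unknown"


def canonical_pair(a: str, b: str) -> tuple[str, str]:
    """Order a pair lexicographically so stored artifacts are deterministic."""
    if a == b:
        raise ValueError(f"self-pair {a!r}")
    return (a, b) if a < b else (b, a)


def enumerate_pairs(drug_ids: Sequence[str]) -> list[tuple[str, str]]:
    """All n(n-1)/2 unordered pairs in canonical (lexicographic) order."""
    ids = sorted(drug_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("drug ids must be unique")
    return list(combinations(ids, 2))


def label_pair(pair: tuple[str, str], interactions: InteractionMap) -> str:
    """positive = shared target; negative = disjoint non-empty target sets;
    unknown = either drug lacks target annotation."""
    a, b = pair
    if a not in interactions or b not in interactions:
        return UNKNOWN
    if interactions.targets_of(a) & interactions.targets_of(b):
        return POSITIVE
    return NEGATIVE


def label_pairs(pairs: Iterable[tuple[str, str]],
                interactions: InteractionMap) -> np.ndarray:
    return np.array([label_pair(p, interactions) for p in pairs], dtype=object)


def make_pair_vector(pc_a: np.ndarray,
                     pc_b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """m[i] = (a[i] + b[i]) / 2;  e[i] = (a[i] - b[i])**2."""
    a = np.asarray(pc_a, dtype=float)
    b = np.asarray(pc_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"component length mismatch: {a.shape} vs {b.shape}")
    return (a + b) / 2.0, (a - b) ** 2


def pair_features(pairs: Sequence[tuple[str, str]],
                  pc_scores: pd.DataFrame) -> np.ndarray:
    """Build the (n_pairs, 2k) feature matrix [M | E] for a pair list.

    ``pc_scores`` is the drugs x k component-score frame from
    :func:`pairdrs.feature_space.project`.
    """
    if not pairs:
        return np.empty((0, 2 * pc_scores.shape[1]))
    a_ids = [p[0] for p in pairs]
    b_ids = [p[1] for p in pairs]
    missing = set(a_ids + b_ids) - set(pc_scores.index)
    if missing:
        raise KeyError(f"drug(s) without component scores: {sorted(missing)}")
    A = pc_scores.loc[a_ids].to_numpy()
    B = pc_scores.loc[b_ids].to_numpy()
    return np.hstack([(A + B) / 2.0, (A - B) ** 2])


def pair_table(pairs: Sequence[tuple[str, str]],
               interactions: InteractionMap) -> pd.DataFrame:
    """Canonical pair table: drug_a, drug_b, label."""
    labels = label_pairs(pairs, interactions)
    return pd.DataFrame({
        "drug_a": [p[0] for p in pairs],
        "drug_b": [p[1] for p in pairs],
        "label": labels,
    })
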