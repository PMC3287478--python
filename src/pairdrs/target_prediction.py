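"""Target ranking by relationship-score transfer.

A query drug inherits candidate targets from database drugs: each target's
score is the maximum DRS between the query and any database drug annotated
with that target. Score ties break by how often the target's binders score
above a fixed threshold (default 0.5), then lexicographically. Evidence
can be split by source: database drugs that share a known target with the
query (annotation transfer) versus those that share none (new predictions).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .data_io import InteractionMap

SHARED = "shared_target"
NEW = "new_prediction"

_COLUMNS = ["target_id", "score", "frequency", "source", "rank"]


def _rank_table(rows: list[tuple[str, float, int, str]]) -> pd.DataFrame:
    table = pd.DataFrame(rows, columns=_COLUMNS[:4])
    table = table.sort_values(
        ["score", "frequency", "target_id"],
        ascending=[False, False, True]).reset_index(drop=True)
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def _build(db_drugs: list[str], scores: np.ndarray,
           interactions: InteractionMap, tie_threshold: float,
           source: str) -> pd.DataFrame:
    by_target: dict[str, list[float]] = {}
    for drug, s in zip(db_drugs, scores):
        for t in interactions.targets_of(drug):
            by_target.setdefault(t, []).append(float(s))
    rows = [(t, max(vals), sum(v > tie_threshold for v in vals), source)
            for t, vals in by_target.items()]
    return _rank_table(rows)


def predict_targets(query: str,
                    db_drugs: Sequence[str],
                    drs_scores: Mapping[str, float] | Sequence[float],
                    interactions: InteractionMap,
                    tie_threshold: float = 0.5,
                    split_by_source: bool = True
                    ) -> pd.DataFrame | dict[str, pd.DataFrame]:
    """Rank candidate targets for ``query`` from scored database drugs.

    ``drs_scores`` maps each database drug to its DRS against the query
    (or is a sequence aligned with ``db_drugs``). Every database drug must
    carry target annotations. With ``split_by_source`` the result is a dict
    with a ``shared_target`` and a ``new_prediction`` table; otherwise a
    single table with source ``all``.
    """
    db_drugs = [d for d in db_drugs if d != query]
    if isinstance(drs_scores, Mapping):
        missing = [d for d in db_drugs if d not in drs_scores]
        if missing:
            raise KeyError(f"database drug(s) without a score: {missing}")
        scores = np.array([drs_scores[d] for d in db_drugs], dtype=float)
    else:
        scores = np.asarray(drs_scores, dtype=float)
        if scores.size != len(db_drugs):
            raise ValueError("scores must align with db_drugs")
    unannotated = [d for d in db_drugs if d not in interactions]
    if unannotated:
        raise ValueError(
            f"database drug(s) without target annotation: {unannotated}")
    if not split_by_source:
        return _build(db_drugs, scores, interactions, tie_threshold, "all")
    query_targets = interactions.targets_of(query)
    shares = np.array([bool(interactions.targets_of(d) & query_targets)
                       for d in db_drugs])
    return {
        SHARED: _build([d for d, s in zip(db_drugs, shares) if s],
                       scores[shares], interactions, tie_threshold, SHARED),
        NEW: _build([d for d, s in zip(db_drugs, shares) if not s],
                    scores[~shares], interactions, tie_threshold, NEW),
    }


def known_target_recovery(drs_matrix: pd.DataFrame,
                          interactions: InteractionMap,
                          max_rank: int = 10,
                          tie_threshold: float = 0.5,
                          source: str | None = SHARED) -> pd.Series:
    """Leave-one-drug-out success rate of known-target identification.

    ``drs_matrix`` is a symmetric drugs x drugs DRS frame. For each
    annotated drug, its own interaction rows are masked (it is removed from
    the database) and we ask whether any of its known targets appears
    within rank r of the prediction table built from the remaining drugs.
    ``source`` selects the evidence table (``shared_target``,
    ``new_prediction`` or None for the unsplit table). Returns the success
    fraction indexed by rank 1..max_rank (monotone non-decreasing).
    """
    drugs = [d for d in drs_matrix.index if d in interactions]
    if len(drugs) < 2:
        warnings.warn("need at least two annotated drugs for recovery",
                      stacklevel=2)
        return pd.Series(dtype=float, name="success_rate")
    hits = np.zeros(max_rank)
    n_eval = 0
    for q in drugs:
        db = [d for d in drugs if d != q]
        scores = drs_matrix.loc[q, db].to_dict()
        result = predict_targets(q, db, scores, interactions,
                                 tie_threshold=tie_threshold,
                                 split_by_source=source is not None)
        table = result if source is None else result[source]
        truth = interactions.targets_of(q)
        ranks = table.loc[table["target_id"].isin(truth), "rank"]
        n_eval += 1
        if len(ranks):
            best = int(ranks.min())
            if best <= max_rank:
                hits[best - 1:] += 1
    return pd.Series(hits / n_eval, index=pd.RangeIndex(1, max_rank + 1,
                                                        name="rank"),
                     name="success_rate")
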