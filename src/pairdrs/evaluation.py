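"""Evaluation statistics: sensitivity/specificity sweeps, fingerprint
baselines, domain-matching ratios and ATC pharmacology-match curves."""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import AnnotationMap, FingerprintSet, InteractionMap
from .negative_sampling import pairwise_tanimoto
from .pair_engine import POSITIVE

_ATC_PREFIX_LEN = {1: 1, 2: 3, 3: 4}


def default_thresholds(n: int = 201) -> np.ndarray:
    """Evenly spaced score thresholds spanning the [-1, 1] DRS range."""
    return np.linspace(-1.0, 1.0, n)


def _binary_labels(labels: Sequence) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "OUS":
        return (arr == POSITIVE).astype(bool)
    return arr.astype(bool)


def sensitivity_specificity_curve(scores: Sequence[float],
                                  labels: Sequence,
                                  thresholds: Sequence[float] | None = None
                                  ) -> pd.DataFrame:
    """Confusion counts and rates over a threshold sweep.

    A pair is called positive when its score >= threshold. Sensitivity =
    TP/(TP+FN); specificity = TN/(TN+FP). Labels may be booleans/0-1 or the
    ``positive``/``negative`` strings.
    """
    scores = np.asarray(scores, dtype=float)
    y = _binary_labels(labels)
    if y.all() or not y.any():
        raise ValueError("need at least one positive and one negative label")
    if thresholds is None:
        thresholds = default_thresholds()
    thresholds = np.asarray(thresholds, dtype=float)
    pos = np.sort(scores[y])
    neg = np.sort(scores[~y])
    # counts of scores >= tau via searchsorted on the sorted score arrays
    tp = len(pos) - np.searchsorted(pos, thresholds, side="left")
    fp = len(neg) - np.searchsorted(neg, thresholds, side="left")
    fn = len(pos) - tp
    tn = len(neg) - fp
    return pd.DataFrame({
        "threshold": thresholds,
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "sensitivity": tp / (tp + fn),
        "specificity": tn / (tn + fp),
    })


def sensitivity_at_specificity(scores: Sequence[float], labels: Sequence,
                               specificity: float = 0.8) -> float:
    """Highest sensitivity achievable at or above the given specificity."""
    scores = np.asarray(scores, dtype=float)
    thresholds = np.unique(scores)
    curve = sensitivity_specificity_curve(scores, labels, thresholds)
    ok = curve["specificity"] >= specificity
    if not ok.any():
        return 0.0
    return float(curve.loc[ok, "sensitivity"].max())


def fingerprint_baseline(pairs: Sequence[tuple[str, str]],
                         fingerprint_sets: Sequence[FingerprintSet]
                         ) -> dict[str, np.ndarray]:
    """Tanimoto score list per fingerprint kind, for baseline curves."""
    return {fps.kind: pairwise_tanimoto(fps, pairs)
            for fps in fingerprint_sets}


def _drug_domains(drug: str, interactions: InteractionMap,
                  domain_map: AnnotationMap) -> frozenset[str]:
    out: set[str] = set()
    for t in interactions.targets_of(drug):
        out |= domain_map.get(t)
    return frozenset(out)


def domain_match_ratio(negative_pairs: Sequence[tuple[str, str]],
                       scores: Sequence[float],
                       target_map: InteractionMap,
                       domain_map: AnnotationMap,
                       thresholds: Sequence[float] | None = None
                       ) -> tuple[pd.DataFrame, float]:
    """Fraction of high-scoring negative pairs whose targets share a domain.

    For each threshold tau, among negative (non-target-sharing) pairs with
    score >= tau, the fraction for which some target of one drug and some
    target of the other share at least one domain. Returns the per-threshold
    table (ratio is NaN where no pair clears tau) and the unconditional base
    rate over all supplied pairs.
    """
    if domain_map.kind != "domain":
        raise ValueError("domain_map must have kind='domain'")
    scores = np.asarray(scores, dtype=float)
    if len(negative_pairs) != scores.size:
        raise ValueError("scores must align with negative_pairs")
    if thresholds is None:
        thresholds = default_thresholds()
    cache: dict[str, frozenset[str]] = {}
    matches = np.empty(len(negative_pairs), dtype=bool)
    for i, (a, b) in enumerate(negative_pairs):
        for d in (a, b):
            if d not in cache:
                cache[d] = _drug_domains(d, target_map, domain_map)
        matches[i] = bool(cache[a] & cache[b])
    base_rate = float(matches.mean()) if matches.size else float("nan")
    rows = []
    for tau in np.asarray(thresholds, dtype=float):
        sel = scores >= tau
        n = int(sel.sum())
        ratio = float(matches[sel].mean()) if n else float("nan")
        rows.append((tau, n, ratio))
    table = pd.DataFrame(rows, columns=["threshold", "n_pairs", "ratio"])
    return table, base_rate


def atc_codes_match(codes_a: set[str], codes_b: set[str], level: int) -> bool:
    """True when any code pair agrees through the requested ATC level.

    Level 2 compares the first 3 characters, level 3 the first 4 (standard
    WHO ATC prefix arithmetic). Drugs with multiple codes match if any pair
    matches.
    """
    if level not in _ATC_PREFIX_LEN:
        raise ValueError(f"unsupported ATC level {level}")
    n = _ATC_PREFIX_LEN[level]
    prefixes_a = {c[:n] for c in codes_a if len(c) >= n}
    prefixes_b = {c[:n] for c in codes_b if len(c) >= n}
    return bool(prefixes_a & prefixes_b)


def atc_match_curve(test_drugs: Sequence[str],
                    partner_rankings: Mapping[str, Sequence[str]],
                    atc_map: AnnotationMap,
                    level: int = 2,
                    max_rank: int = 10) -> pd.Series:
    """Mean number of ATC-matching partners within the top r ranks.

    ``partner_rankings`` gives, per test drug, its partner drugs sorted
    best-first by the similarity measure under study. The curve value at
    rank r is the mean (over test drugs) count of partners within the top r
    whose ATC codes match the test drug's at the requested level; it is
    monotone non-decreasing in r.
    """
    if atc_map.kind != "atc":
        raise ValueError("atc_map must have kind='atc'")
    counts = np.zeros(max_rank)
    for drug in test_drugs:
        own = atc_map.get(drug)
        partners = list(partner_rankings[drug])[:max_rank]
        match = np.zeros(max_rank)
        for r, partner in enumerate(partners):
            if atc_codes_match(own, atc_map.get(partner), level):
                match[r] = 1
        counts += np.cumsum(match)
    return pd.Series(counts / len(test_drugs),
                     index=pd.RangeIndex(1, max_rank + 1, name="rank"),
                     name=f"mean_atc_level{level}_matches")


def score_correlation(scores_a: Sequence[float], scores_b: Sequence[float],
                      group_labels: Sequence | None = None) -> pd.DataFrame:
    """Per-group Pearson correlation between two paired score lists.

    Groups with a constant score vector get NaN (undefined correlation);
    each group needs at least three pairs.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.size != b.size:
        raise ValueError("score lists must have equal length")
    groups = (np.asarray(group_labels) if group_labels is not None
              else np.zeros(a.size, dtype=int))
    rows = []
    for g in pd.unique(groups):
        sel = groups == g
        n = int(sel.sum())
        if n < 3:
            raise ValueError(f"group {g!r} has {n} pairs; need >= 3")
        if np.ptp(a[sel]) == 0 or np.ptp(b[sel]) == 0:
            rows.append((g, n, float("nan"), float("nan")))
        else:
            r, p = stats.pearsonr(a[sel], b[sel])
            rows.append((g, n, float(r), float(p)))
    return pd.DataFrame(rows, columns=["group", "n", "r", "p"])
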