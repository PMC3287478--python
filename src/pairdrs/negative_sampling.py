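"""Tanimoto similarity, similarity-density estimation and the
inverse-density under-sampler for negative drug pairs.

Negative (non-target-sharing) pairs vastly outnumber positives, so balanced
training sets are drawn by weighting each negative pair inversely to the
density of its structural (Tanimoto) similarity. Structurally unusual pairs
are thereby over-represented, keeping the negative sample diverse rather
than dominated by the bulk of the similarity distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import gaussian_kde

from .data_io import FingerprintSet


def tanimoto(fp_a: np.ndarray, fp_b: np.ndarray) -> float:
    """|a AND b| / |a OR b| over set bits; 0 when both vectors are all-zero."""
    a = np.asarray(fp_a).astype(bool)
    b = np.asarray(fp_b).astype(bool)
    if a.shape != b.shape:
        raise ValueError(f"bit-length mismatch: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        return 0.0
    return np.count_nonzero(a & b) / union


def pairwise_tanimoto(fps: FingerprintSet,
                      pairs: Sequence[tuple[str, str]]) -> np.ndarray:
    """Vectorized Tanimoto for a list of drug-id pairs."""
    index = {d: i for i, d in enumerate(fps.drug_ids)}
    missing = {d for p in pairs for d in p if d not in index}
    if missing:
        raise KeyError(f"drug(s) absent from fingerprint set: {sorted(missing)}")
    ia = np.array([index[a] for a, _ in pairs], dtype=int)
    ib = np.array([index[b] for _, b in pairs], dtype=int)
    A = fps.bits.astype(bool)[ia]
    B = fps.bits.astype(bool)[ib]
    inter = np.count_nonzero(A & B, axis=1).astype(float)
    union = np.count_nonzero(A | B, axis=1).astype(float)
    out = np.zeros(len(pairs))
    nz = union > 0
    out[nz] = inter[nz] / union[nz]
    return out


@dataclass
class SimilarityDensity:
    """A normalized density over Tanimoto similarities in [0, 1].

    Stored as probability mass per grid cell (summing to 1) with a strictly
    positive floor, so inverse-density weights are always finite.
    """

    grid: np.ndarray  # cell edges, length n_cells + 1
    density: np.ndarray  # probability mass per cell, length n_cells
    method: str
    bandwidth_or_bins: float

    def __post_init__(self) -> None:
        if (self.density <= 0).any():
            raise ValueError("density must be strictly positive (floored)")
        if not np.isclose(self.density.sum(), 1.0):
            raise ValueError("density must sum to 1")

    def evaluate(self, similarities: np.ndarray) -> np.ndarray:
        """Probability mass of the cell containing each similarity value."""
        x = np.asarray(similarities, dtype=float)
        if ((x < 0) | (x > 1)).any():
            raise ValueError("similarities must lie in [0, 1]")
        cells = np.clip(np.searchsorted(self.grid, x, side="right") - 1,
                        0, len(self.density) - 1)
        return self.density[cells]


def estimate_similarity_density(similarities: Sequence[float],
                                method: str = "histogram",
                                parameter: float | None = None
                                ) -> SimilarityDensity:
    """Estimate the density of pairwise similarities on [0, 1].

    ``histogram`` (default) bins into ``parameter`` equal cells (default 50);
    ``kde`` uses a Gaussian kernel (Silverman bandwidth unless ``parameter``
    gives one) evaluated on a 512-cell grid. A floor of 1/(10 n) is added to
    every cell before normalization so empty regions keep finite weight.
    """
    sims = np.asarray(similarities, dtype=float)
    if sims.size == 0:
        raise ValueError("need at least one similarity value")
    if ((sims < 0) | (sims > 1)).any():
        raise ValueError("similarities must lie in [0, 1]")
    floor = 1.0 / (10.0 * sims.size)
    if method == "histogram":
        n_bins = int(parameter) if parameter else 50
        edges = np.linspace(0.0, 1.0, n_bins + 1)
        counts, _ = np.histogram(sims, bins=edges)
        mass = counts / counts.sum() + floor
    elif method == "kde":
        n_cells = 512
        edges = np.linspace(0.0, 1.0, n_cells + 1)
        centers = (edges[:-1] + edges[1:]) / 2.0
        if np.ptp(sims) == 0:
            # degenerate sample: all mass in the one occupied cell
            counts = np.zeros(n_cells)
            counts[np.clip(np.searchsorted(edges, sims[0], side="right") - 1,
                           0, n_cells - 1)] = 1.0
            mass = counts + floor
        else:
            kde = gaussian_kde(sims, bw_method=parameter)
            pdf = kde(centers)
            mass = pdf / pdf.sum() + floor
    else:
        raise ValueError(f"unknown density method {method!r}")
    mass = mass / mass.sum()
    return SimilarityDensity(grid=edges, density=mass, method=method,
                             bandwidth_or_bins=float(parameter or 0.0))


@dataclass
class NegativeSampleSet:
    """One balanced negative training set drawn by inverse-density weights."""

    pairs: list[tuple[str, str]]
    seed: int
    set_index: int  # 1-based

    def __post_init__(self) -> None:
        if len(set(self.pairs)) != len(self.pairs):
            raise ValueError("duplicate pairs within a negative sample set")


def inverse_density_weights(similarities: np.ndarray,
                            density: SimilarityDensity) -> np.ndarray:
    """Normalized sampling weights proportional to 1 / density(similarity)."""
    w = 1.0 / density.evaluate(similarities)
    return w / w.sum()


def sample_negative_sets(negative_pairs: Sequence[tuple[str, str]],
                         similarities: Sequence[float],
                         n_sets: int = 10,
                         set_size: int | None = None,
                         seed: int = 0,
                         density: SimilarityDensity | None = None,
                         method: str = "histogram",
                         parameter: float | None = None
                         ) -> list[NegativeSampleSet]:
    """Draw ``n_sets`` independent negative sets without replacement.

    Each set has ``set_size`` pairs drawn with probability inversely
    proportional to the density of the pair's structural similarity
    (weighted sampling without replacement via exponential keys, which is
    equivalent in distribution to sequential draws with renormalization).
    Sets are drawn independently and may overlap one another.
    """
    pairs = list(negative_pairs)
    sims = np.asarray(similarities, dtype=float)
    if len(pairs) != sims.size:
        raise ValueError("similarities must align with negative_pairs")
    if set_size is None:
        raise ValueError("set_size is required (use the positive-pair count)")
    if set_size > len(pairs):
        raise ValueError(
            f"set_size {set_size} exceeds available negatives {len(pairs)}")
    if density is None:
        density = estimate_similarity_density(sims, method=method,
                                              parameter=parameter)
    weights = inverse_density_weights(sims, density)
    rng = np.random.default_rng(seed)
    sets = []
    for i in range(n_sets):
        if set_size == len(pairs):
            chosen = np.arange(len(pairs))
        else:
            keys = rng.exponential(size=len(pairs)) / weights
            chosen = np.argpartition(keys, set_size)[:set_size]
        chosen = np.sort(chosen)
        sets.append(NegativeSampleSet(pairs=[pairs[j] for j in chosen],
                                      seed=seed, set_index=i + 1))
    return sets
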