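"""Descriptor cleaning and the principal-component drug representation.

Drugs are represented by the smallest number of principal components whose
cumulative explained variance reaches a target fraction (default 90%).
Descriptors are z-scored before the decomposition by default, since raw
descriptor scales differ by orders of magnitude.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .data_io import DescriptorMatrix

_SCHEMA_VERSION = 1


@dataclass
class PCSpace:
    """A fitted principal-component transform.

    ``k`` is minimal: the cumulative explained-variance fraction over the
    first ``k`` components reaches ``variance_target`` while ``k - 1``
    components fall short. Loading columns follow a deterministic sign
    convention (largest-magnitude element positive).
    """

    descriptor_names_used: list[str]
    center: np.ndarray
    scale: np.ndarray
    loadings: np.ndarray  # descriptors x k
    explained_fraction: np.ndarray  # length k
    k: int
    variance_target: float

    def save(self, path: str | Path) -> None:
        np.savez(
            path,
            schema_version=_SCHEMA_VERSION,
            descriptor_names_used=np.array(self.descriptor_names_used),
            center=self.center,
            scale=self.scale,
            loadings=self.loadings,
            explained_fraction=self.explained_fraction,
            k=self.k,
            variance_target=self.variance_target,
        )

    @classmethod
    def load(cls, path: str | Path) -> "PCSpace":
        with np.load(path, allow_pickle=False) as data:
            if int(data["schema_version"]) != _SCHEMA_VERSION:
                raise ValueError("unsupported PCSpace schema version")
            return cls(
                descriptor_names_used=[str(n) for n in
                                       data["descriptor_names_used"]],
                center=data["center"],
                scale=data["scale"],
                loadings=data["loadings"],
                explained_fraction=data["explained_fraction"],
                k=int(data["k"]),
                variance_target=float(data["variance_target"]),
            )

    @property
    def signature(self) -> tuple:
        """Identity of the feature space, for model/space compatibility checks."""
        return (tuple(self.descriptor_names_used), self.k)


def clean_descriptors(D: DescriptorMatrix,
                      near_constant_frac: float = 0.9
                      ) -> tuple[DescriptorMatrix, dict[str, str]]:
    """Drop descriptor columns with errors or near-constant values.

    A column goes if (a) any cell is flagged missing/erroneous, or (b) its
    modal value occurs in strictly more than ``near_constant_frac`` of the
    drugs. Returns the surviving matrix and a report mapping each dropped
    column name to its reason (``error`` or ``near_constant``).
    """
    if D.values.size == 0:
        raise ValueError("empty descriptor matrix")
    n = len(D.drug_ids)
    report: dict[str, str] = {}
    keep: list[str] = []
    for j, name in enumerate(D.descriptor_names):
        if D.missing_mask[:, j].any():
            report[name] = "error"
            continue
        _, counts = np.unique(D.values[:, j], return_counts=True)
        if counts.max() > near_constant_frac * n:
            report[name] = "near_constant"
            continue
        keep.append(name)
    if not keep:
        raise ValueError("all descriptor columns were dropped by cleaning")
    return D.select_columns(keep), report


def fit_pc_space(D: DescriptorMatrix, variance_target: float = 0.9,
                 standardize: bool = True) -> PCSpace:
    """Fit the PCA representation with the minimal component count.

    The number of components ``k`` is the smallest for which the cumulative
    explained-variance fraction reaches ``variance_target``.
    """
    if not 0.0 < variance_target <= 1.0:
        raise ValueError("variance_target must lie in (0, 1]")
    if D.missing_mask.any():
        raise ValueError("descriptor matrix contains missing cells; "
                         "run clean_descriptors first")
    X = D.values.astype(float)
    n, d = X.shape
    if n < 2:
        raise ValueError("need at least 2 drugs to fit a PC space")
    center = X.mean(axis=0)
    if standardize:
        scale = X.std(axis=0, ddof=1)
        if (scale == 0).any():
            zero = [D.descriptor_names[j] for j in np.flatnonzero(scale == 0)]
            raise ValueError(
                f"zero-variance column(s) {zero}; run clean_descriptors first")
    else:
        scale = np.ones(d)
    Z = (X - center) / scale
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    var = s ** 2
    total = var.sum()
    frac = var / total
    cumulative = np.cumsum(frac)
    # numerical rank guard: components beyond machine-zero variance are noise
    rank = int((s > s[0] * max(n, d) * np.finfo(float).eps).sum())
    k = int(np.searchsorted(cumulative, variance_target - 1e-12) + 1)
    k = min(k, rank)
    loadings = vt[:k].T.copy()
    # deterministic sign: largest-|.| element of each loading column positive
    for j in range(k):
        col = loadings[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, j] = -col
    return PCSpace(
        descriptor_names_used=list(D.descriptor_names),
        center=center,
        scale=scale,
        loadings=loadings,
        explained_fraction=frac[:k],
        k=k,
        variance_target=variance_target,
    )


def project(D: DescriptorMatrix, space: PCSpace) -> pd.DataFrame:
    """Project drugs into the fitted component space.

    Returns a drugs x k DataFrame (columns ``PC1..PCk``). Every descriptor
    the space was fitted on must be present; extra columns are ignored.
    """
    missing = [n for n in space.descriptor_names_used
               if n not in D.descriptor_names]
    if missing:
        raise ValueError(f"descriptor column(s) required by the PC space are "
                         f"absent: {missing}")
    sub = D.select_columns(space.descriptor_names_used)
    if sub.missing_mask.any():
        raise ValueError("missing cells in required descriptor columns")
    Z = (sub.values - space.center) / space.scale
    scores = Z @ space.loadings
    return pd.DataFrame(scores, index=D.drug_ids,
                        columns=[f"PC{i + 1}" for i in range(space.k)])


def backproject(scores: np.ndarray, space: PCSpace) -> np.ndarray:
    """Map component scores back to the standardized descriptor space."""
    return np.asarray(scores) @ space.loadings.T
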