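"""Self-contained synthetic drug-target benchmark generator.

Emulates the statistical structure the relationship score relies on: drugs
binding a common target cluster in descriptor space, fingerprints correlate
with (but do not equal) descriptor proximity, targets that share a protein
domain sit in nearby clusters, and ATC pharmacology codes follow the
cluster structure. A configurable fraction of promiscuous drugs also binds
a structurally unrelated target, planting the dissimilar common-target
pairs that plain structural similarity misses.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .data_io import (AnnotationMap, DescriptorMatrix, FingerprintSet,
                      InteractionMap, write_annotations,
                      write_descriptor_table, write_fingerprints,
                      write_interactions)

_ATC_LETTERS = "ABCDGHJLMNPRSV"


@dataclass
class SyntheticConfig:
    """Knobs of the generator; defaults define the standard study preset.

    ``cluster_sd`` is the within-target descriptor spread and ``noise_sd``
    the spread of target centroids; a learnable regime needs
    ``cluster_sd < noise_sd``. ``domain_groups`` is the number of targets
    per shared-domain group (grouped targets get correlated centroids).
    ``promiscuity`` is the fraction of drugs binding one extra unrelated
    target that does not shape their chemistry.
    """

    n_drugs: int = 200
    n_targets: int = 20
    n_descriptors: int = 60
    n_bits: int = 128
    cluster_sd: float = 0.3
    noise_sd: float = 1.0
    mean_targets_per_drug: float = 1.5
    domain_groups: int = 2
    promiscuity: float = 0.1
    seed: int = 7

    def __post_init__(self) -> None:
        for name in ("n_drugs", "n_targets", "n_descriptors", "n_bits",
                     "domain_groups"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.cluster_sd >= self.noise_sd:
            raise ValueError("cluster_sd must be smaller than noise_sd "
                             "for a learnable signal regime")
        if self.mean_targets_per_drug < 1:
            raise ValueError("mean_targets_per_drug must be >= 1")
        if not 0 <= self.promiscuity <= 1:
            raise ValueError("promiscuity must lie in [0, 1]")


@dataclass
class SyntheticBundle:
    """A full generated dataset plus the ground truth that produced it."""

    config: SyntheticConfig
    descriptors: DescriptorMatrix
    fingerprints: FingerprintSet
    interactions: InteractionMap
    domains: AnnotationMap  # target -> domain ids
    atc: AnnotationMap  # drug -> ATC codes
    truth: dict = field(default_factory=dict)


def _atc_code(group: int, member: int, target: int) -> str:
    # level-2 class (letter + 2 digits) unique per domain group
    letter = _ATC_LETTERS[group % len(_ATC_LETTERS)]
    return (f"{letter}{10 + group % 85:02d}"
            f"{chr(ord('A') + member % 26)}A{target % 100:02d}")


def generate(config: SyntheticConfig) -> SyntheticBundle:
    """Generate a descriptor/fingerprint/interaction/annotation bundle.

    Target centroids are drawn iid normal (sd ``noise_sd``) around a shared
    group centroid for targets in the same domain group (within-group sd
    0.4 * noise_sd). Each drug binds 1 + Poisson(mean - 1) targets and its
    descriptors scatter around the mean of those targets' centroids with sd
    ``cluster_sd``; promiscuous drugs additionally bind one unrelated
    target that leaves their descriptors untouched. Fingerprint bits are
    noisy thresholded random projections of the descriptors. The final two
    descriptor columns are near-constant probe columns for the cleaning
    stage. Fully deterministic for a given config (including its seed).
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    drugs = [f"D{i:04d}" for i in range(cfg.n_drugs)]
    targets = [f"T{i:03d}" for i in range(cfg.n_targets)]

    # --- domain groups and correlated target centroids
    n_groups = int(np.ceil(cfg.n_targets / cfg.domain_groups))
    group_of = np.arange(cfg.n_targets) // cfg.domain_groups
    group_centroids = rng.normal(0.0, cfg.noise_sd,
                                 size=(n_groups, cfg.n_descriptors))
    within_sd = 0.4 * cfg.noise_sd
    centroids = (group_centroids[group_of]
                 + rng.normal(0.0, within_sd,
                              size=(cfg.n_targets, cfg.n_descriptors)))

    # --- drug-target assignments: shifted Poisson degree, >= 1 target each
    degree = 1 + rng.poisson(cfg.mean_targets_per_drug - 1.0,
                             size=cfg.n_drugs)
    degree = np.minimum(degree, cfg.n_targets)
    assignments: list[list[int]] = [
        sorted(rng.choice(cfg.n_targets, size=int(d), replace=False))
        for d in degree
    ]

    # --- descriptors around the mean of the assigned targets' centroids
    X = np.empty((cfg.n_drugs, cfg.n_descriptors))
    for i, tlist in enumerate(assignments):
        mean = centroids[tlist].mean(axis=0)
        X[i] = mean + rng.normal(0.0, cfg.cluster_sd, size=cfg.n_descriptors)

    # --- promiscuous extra targets (chemistry untouched)
    promiscuous = rng.random(cfg.n_drugs) < cfg.promiscuity
    extras: dict[str, int] = {}
    for i in np.flatnonzero(promiscuous):
        candidates = np.setdiff1d(np.arange(cfg.n_targets), assignments[i])
        if candidates.size:
            extras[drugs[i]] = int(rng.choice(candidates))

    # --- heterogeneous descriptor scales + near-constant probe columns
    scales = np.exp(rng.normal(0.0, 1.0, size=cfg.n_descriptors))
    X = X * scales
    n_probe = min(2, cfg.n_descriptors - 1)
    for j in range(cfg.n_descriptors - n_probe, cfg.n_descriptors):
        col = np.full(cfg.n_drugs, 5.0)
        jitter = rng.random(cfg.n_drugs) < 0.03
        col[jitter] += rng.normal(0.0, 0.1, size=int(jitter.sum()))
        X[:, j] = col

    descriptors = DescriptorMatrix(
        drug_ids=drugs,
        descriptor_names=[f"desc{j:03d}" for j in range(cfg.n_descriptors)],
        values=X,
        missing_mask=np.zeros_like(X, dtype=bool),
    )

    # --- fingerprints: noisy thresholded random projection of descriptors
    Z = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    W = rng.normal(0.0, 1.0, size=(cfg.n_descriptors, cfg.n_bits))
    proj = Z @ W / np.sqrt(cfg.n_descriptors)
    proj = proj + rng.normal(0.0, 0.6, size=proj.shape)
    q = rng.uniform(0.55, 0.85, size=cfg.n_bits)
    thresholds = np.quantile(proj, q, axis=0).diagonal()
    bits = (proj > thresholds).astype(np.uint8)
    fingerprints = FingerprintSet(drug_ids=drugs, n_bits=cfg.n_bits,
                                  bits=bits, kind="projected-synthetic")

    # --- interactions
    mapping = {}
    for i, d in enumerate(drugs):
        tset = {targets[t] for t in assignments[i]}
        if d in extras:
            tset.add(targets[extras[d]])
        mapping[d] = tset
    interactions = InteractionMap(mapping)

    # --- domain annotations: shared per group + one target-specific domain
    domains = AnnotationMap(kind="domain", mapping={
        targets[t]: {f"PF{group_of[t]:05d}", f"PFX{t:04d}"}
        for t in range(cfg.n_targets)
    })

    # --- ATC codes: one code per bound target; level-2 class per domain group
    member_in_group = np.arange(cfg.n_targets) % cfg.domain_groups
    atc_of_target = {
        targets[t]: _atc_code(int(group_of[t]), int(member_in_group[t]), t)
        for t in range(cfg.n_targets)
    }
    atc = AnnotationMap(kind="atc", mapping={
        d: {atc_of_target[t] for t in mapping[d]} for d in drugs
    })

    truth = {
        "target_centroids": centroids,
        "group_of_target": group_of,
        "assignments": {drugs[i]: [targets[t] for t in assignments[i]]
                        for i in range(cfg.n_drugs)},
        "promiscuous_extras": {d: targets[t] for d, t in extras.items()},
        "atc_of_target": atc_of_target,
    }
    return SyntheticBundle(config=cfg, descriptors=descriptors,
                           fingerprints=fingerprints,
                           interactions=interactions, domains=domains,
                           atc=atc, truth=truth)


def expected_positive_fraction(config: SyntheticConfig,
                               n_montecarlo: int = 20000,
                               seed: int = 12345) -> float:
    """Closed-form-by-simulation expectation of the positive-pair fraction.

    Monte-Carlo over the degree distribution alone (independent of the
    descriptor model): two drugs with uniformly chosen target sets share a
    target with probability 1 - C(T-d1, d2)/C(T, d2).
    """
    from scipy.special import comb

    rng = np.random.default_rng(seed)
    T = config.n_targets
    d1 = 1 + rng.poisson(config.mean_targets_per_drug - 1.0, n_montecarlo)
    d2 = 1 + rng.poisson(config.mean_targets_per_drug - 1.0, n_montecarlo)
    d1 = np.minimum(d1, T)
    d2 = np.minimum(d2, T)
    p_disjoint = comb(T - d1, d2) / comb(T, d2)
    return float(1.0 - p_disjoint.mean())


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> None:
    """Write the five standard TSVs plus a ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_descriptor_table(bundle.descriptors, outdir / "descriptors.tsv")
    write_fingerprints(bundle.fingerprints, outdir / "fingerprints.tsv")
    write_interactions(bundle.interactions, outdir / "interactions.tsv")
    write_annotations(bundle.domains, outdir / "target_domains.tsv")
    write_annotations(bundle.atc, outdir / "drug_atc.tsv")
    truth = {
        "config": asdict(bundle.config),
        "assignments": bundle.truth["assignments"],
        "promiscuous_extras": bundle.truth["promiscuous_extras"],
        "atc_of_target": bundle.truth["atc_of_target"],
        "group_of_target": bundle.truth["group_of_target"].tolist(),
    }
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2))
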