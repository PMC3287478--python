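import numpy as np
import pytest
from scipy import stats

from pairdrs.negative_sampling import (NegativeSampleSet, SimilarityDensity,
                                       estimate_similarity_density,
                                       inverse_density_weights,
                                       pairwise_tanimoto,
                                       sample_negative_sets, tanimoto)


class TestTanimoto:
    def test_identity_of_nonzero_vector(self):
        a = np.array([1, 0, 1, 1, 0])
        assert tanimoto(a, a) == 1.0

    def test_shared_bits_oracle_example(self):
        # bits {1,2,3} vs {2,3,4}: 2 shared / 4 in the union
        a = np.zeros(8, dtype=int)
        b = np.zeros(8, dtype=int)
        a[[1, 2, 3]] = 1
        b[[2, 3, 4]] = 1
        assert tanimoto(a, b) == 0.5

    def test_all_zero_convention(self):
        z = np.zeros(16, dtype=int)
        assert tanimoto(z, z) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            tanimoto(np.ones(4), np.ones(5))

    def test_popcount_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            a = rng.integers(0, 2, size=128)
            b = rng.integers(0, 2, size=128)
            inter = sum(int(x) & int(y) for x, y in zip(a, b))
            union = sum(int(x) | int(y) for x, y in zip(a, b))
            expected = inter / union if union else 0.0
            assert tanimoto(a, b) == expected

    def test_symmetry_and_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            a = rng.integers(0, 2, size=64)
            b = rng.integers(0, 2, size=64)
            s = tanimoto(a, b)
            assert s == tanimoto(b, a)
            assert 0.0 <= s <= 1.0

    def test_pairwise_matches_scalar(self, small_bundle):
        fps = small_bundle.fingerprints
        pairs = [(fps.drug_ids[i], fps.drug_ids[j])
                 for i in range(6) for j in range(i + 1, 6)]
        vec = pairwise_tanimoto(fps, pairs)
        for (a, b), s in zip(pairs, vec):
            assert s == tanimoto(fps.row(a), fps.row(b))


class TestSimilarityDensity:
    def test_degenerate_sample_concentrates_mass(self):
        density = estimate_similarity_density([0.3] * 100,
                                              method="histogram",
                                              parameter=20)
        peak = np.argmax(density.density)
        assert density.grid[peak] <= 0.3 < density.grid[peak + 1]
        assert density.density[peak] > 0.9

    def test_uniform_sample_is_near_flat(self):
        sims = np.linspace(0, 1, 10000, endpoint=False) + 5e-5
        density = estimate_similarity_density(sims, parameter=50)
        assert density.density.max() / density.density.min() < 1.5

    def test_bimodal_interior_bins_at_floor(self):
        rng = np.random.default_rng(0)
        sims = np.concatenate([
            np.clip(rng.normal(0.1, 0.01, 500), 0, 1),
            np.clip(rng.normal(0.9, 0.01, 500), 0, 1)])
        density = estimate_similarity_density(sims, parameter=50)
        # every empty interior bin carries exactly the (normalized) floor
        interior = density.density[20:30]
        assert np.allclose(interior, interior[0])
        assert interior[0] < 1e-3
        assert density.evaluate([0.5])[0] == interior[0]

    def test_density_sums_to_one(self):
        rng = np.random.default_rng(1)
        for method in ("histogram", "kde"):
            density = estimate_similarity_density(rng.random(500),
                                                  method=method)
            assert density.density.sum() == pytest.approx(1.0)
            assert (density.density > 0).all()

    def test_out_of_range_values_rejected(self):
        with pytest.raises(ValueError):
            estimate_similarity_density([0.5, 1.2])
        density = estimate_similarity_density([0.5])
        with pytest.raises(ValueError):
            density.evaluate([-0.1])


def _fake_pairs(n):
    return [(f"A{i:05d}", f"B{i:05d}") for i in range(n)]


class TestSampleNegativeSets:
    def test_exhaustive_case_returns_all_pairs(self):
        pairs = _fake_pairs(100)
        rng = np.random.default_rng(0)
        sets = sample_negative_sets(pairs, rng.random(100), n_sets=3,
                                    set_size=100, seed=5)
        for s in sets:
            assert sorted(s.pairs) == sorted(pairs)

    def test_set_invariants_across_seeds(self):
        pairs = _fake_pairs(500)
        rng = np.random.default_rng(2)
        sims = rng.random(500)
        for seed in (0, 1, 2):
            sets = sample_negative_sets(pairs, sims, n_sets=4, set_size=120,
                                        seed=seed)
            assert len(sets) == 4
            for i, s in enumerate(sets):
                assert s.set_index == i + 1
                assert len(s.pairs) == 120
                assert len(set(s.pairs)) == 120
                assert set(s.pairs) <= set(pairs)

    def test_reproducible_from_seed(self):
        pairs = _fake_pairs(300)
        rng = np.random.default_rng(3)
        sims = rng.random(300)
        a = sample_negative_sets(pairs, sims, n_sets=2, set_size=50, seed=9)
        b = sample_negative_sets(pairs, sims, n_sets=2, set_size=50, seed=9)
        assert [s.pairs for s in a] == [s.pairs for s in b]

    def test_oversized_request_rejected(self):
        pairs = _fake_pairs(10)
        with pytest.raises(ValueError, match="exceeds"):
            sample_negative_sets(pairs, np.zeros(10) + 0.5, set_size=11,
                                 seed=0)

    def test_flat_density_samples_uniformly(self):
        # with a flat density every pair is equally likely: chi-square on
        # inclusion counts over many draws must not reject uniformity
        n = 200
        pairs = _fake_pairs(n)
        sims = np.full(n, 0.4)
        flat = SimilarityDensity(grid=np.array([0.0, 1.0]),
                                 density=np.array([1.0]), method="histogram",
                                 bandwidth_or_bins=1)
        sets = sample_negative_sets(pairs, sims, n_sets=200, set_size=50,
                                    seed=7, density=flat)
        counts = np.zeros(n)
        index = {p: i for i, p in enumerate(pairs)}
        for s in sets:
            for p in s.pairs:
                counts[index[p]] += 1
        expected = 200 * 50 / n
        chi2 = ((counts - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=n - 1) > 0.001

    def test_rare_similarity_pairs_over_included(self):
        # 9,000 common pairs near 0.2 and 1,000 rare near 0.8: the rare
        # group's inclusion must beat its 10% base rate, and match the
        # expectation implied by the normalized inverse-density weights
        rng = np.random.default_rng(11)
        sims = np.concatenate([
            np.clip(rng.normal(0.2, 0.02, 9000), 0, 1),
            np.clip(rng.normal(0.8, 0.02, 1000), 0, 1)])
        pairs = _fake_pairs(10000)
        sets = sample_negative_sets(pairs, sims, n_sets=10, set_size=1000,
                                    seed=13)
        rare = {p for p, s in zip(pairs, sims) if s > 0.5}
        rare_frac = np.mean([len(rare & set(s.pairs)) / 1000 for s in sets])
        assert rare_frac > 0.25  # well above the 10% base rate
        density = estimate_similarity_density(sims)
        w = inverse_density_weights(sims, density)
        assert w[sims > 0.5].sum() > 0.3  # the weights say why

    def test_inclusion_monotone_decreasing_in_density(self):
        # planted bimodal fixture: Spearman correlation between a pair's
        # density and its inclusion frequency must be negative
        rng = np.random.default_rng(17)
        sims = np.concatenate([
            np.clip(rng.normal(0.25, 0.05, 800), 0, 1),
            np.clip(rng.normal(0.75, 0.05, 200), 0, 1)])
        pairs = _fake_pairs(1000)
        density = estimate_similarity_density(sims)
        sets = sample_negative_sets(pairs, sims, n_sets=200, set_size=100,
                                    seed=19, density=density)
        counts = np.zeros(1000)
        index = {p: i for i, p in enumerate(pairs)}
        for s in sets:
            for p in s.pairs:
                counts[index[p]] += 1
        rho, p = stats.spearmanr(density.evaluate(sims), counts)
        assert rho < 0
        assert p < 0.01

    def test_duplicate_pairs_within_set_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            NegativeSampleSet(pairs=[("a", "b"), ("a", "b")], seed=0,
                              set_index=1)
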