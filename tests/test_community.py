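"""Community statistics: rarefaction, Bray-Curtis, NMDS, correlations, tracing."""

import itertools

import numpy as np
import pytest

from sedmix.community import (DissimilarityMatrix, bray_curtis,
                              bray_curtis_matrix, depth_correlation, nmds,
                              rarefy, top_otus, trace_persisters,
                              adjust_pvalues_bh)
from sedmix.profiles import DepthProfile, OtuTable


# ---------------------------------------------------------------------------
# oracles


def average_ranks(v):
    """Brute-force average ranks with ties."""
    v = list(v)
    ranks = []
    for x in v:
        less = sum(1 for y in v if y < x)
        equal = sum(1 for y in v if y == x)
        ranks.append(less + (equal + 1) / 2.0)
    return np.array(ranks)


def spearman_oracle(x, y):
    """Pearson correlation of brute-force ranks."""
    rx, ry = average_ranks(x), average_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


def exact_perm_p(x, y, rho_obs):
    """Enumerate every ordering of y; two-sided tail of |rho|."""
    y = np.asarray(y, dtype=float)
    rhos = [spearman_oracle(x, y[list(perm)])
            for perm in itertools.permutations(range(len(y)))]
    rhos = np.array(rhos)
    return float(np.mean(np.abs(rhos) >= abs(rho_obs) - 1e-12))


# ---------------------------------------------------------------------------


class TestRarefy:
    def test_full_draw_is_identity(self, toy_otus):
        totals = toy_otus.sample_totals()
        assert len(set(totals)) == 1
        out = rarefy(toy_otus, int(totals[0]), seed=1)
        assert np.array_equal(out.counts, toy_otus.counts)

    def test_every_sample_sums_to_depth(self, toy_otus):
        out = rarefy(toy_otus, 40, seed=2)
        assert np.all(out.sample_totals() == 40)

    def test_never_invents_counts(self, toy_otus):
        out = rarefy(toy_otus, 40, seed=3)
        assert np.all(out.counts[toy_otus.counts == 0] == 0)
        assert np.all(out.counts <= toy_otus.counts)

    def test_seed_reproducible(self, toy_otus):
        a = rarefy(toy_otus, 40, seed=9)
        b = rarefy(toy_otus, 40, seed=9)
        assert np.array_equal(a.counts, b.counts)

    def test_shallow_samples_dropped_with_warning(self, toy_otus):
        counts = toy_otus.counts.copy()
        counts[0] = [1, 0, 0, 0, 0, 0]
        small = OtuTable(counts=counts, otu_ids=toy_otus.otu_ids,
                         taxonomy=toy_otus.taxonomy, sample_ids=toy_otus.sample_ids,
                         sample_depth=toy_otus.sample_depth)
        with pytest.warns(UserWarning, match="s3"):
            out = rarefy(small, 40, seed=0)
        assert out.n_samples == 3

    def test_expected_counts_match_hypergeometric_mean(self, toy_otus):
        """Mean rarefied count over replicates = depth x original fraction."""
        depth = 40
        reps = 1000
        sums = np.zeros(toy_otus.n_otus)
        for seed in range(reps):
            sums += rarefy(toy_otus, depth, seed=seed).counts[0]
        mean = sums / reps
        frac = toy_otus.counts[0] / toy_otus.counts[0].sum()
        expected = depth * frac
        # hypergeometric sd per draw
        n_tot = toy_otus.counts[0].sum()
        var = depth * frac * (1 - frac) * (n_tot - depth) / (n_tot - 1)
        se = np.sqrt(var / reps)
        assert np.all(np.abs(mean - expected) <= 3 * np.maximum(se, 1e-9))


class TestBrayCurtis:
    def test_identical_vectors_zero(self):
        assert bray_curtis([3, 1, 4], [3, 1, 4]) == 0.0

    def test_disjoint_supports_one(self):
        assert bray_curtis([5, 0, 0], [0, 2, 7]) == pytest.approx(1.0)

    def test_hand_example(self):
        assert bray_curtis([2, 1, 0], [0, 1, 3]) == pytest.approx(5 / 7)

    def test_both_zero_rejected(self):
        with pytest.raises(ValueError):
            bray_curtis([0, 0], [0, 0])

    def test_matrix_properties(self, toy_otus):
        d = bray_curtis_matrix(toy_otus)
        assert np.allclose(d.matrix, d.matrix.T)
        assert np.allclose(np.diag(d.matrix), 0)
        assert np.all((d.matrix >= 0) & (d.matrix <= 1))


@pytest.fixture(scope="module")
def planar():
    rng = np.random.default_rng(5)
    pts = rng.uniform(0, 10, size=(12, 2))
    d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
    return DissimilarityMatrix(matrix=d,
                               sample_ids=tuple(f"p{i}" for i in range(12)),
                               sample_depth=np.arange(12.0))


class TestNmds:
    def test_planar_configuration_near_zero_stress(self, planar):
        res = nmds(planar, k=2, seed=0, restarts=8)
        assert res.stress < 0.01

    def test_monotone_transform_invariance(self, planar):
        res1 = nmds(planar, k=2, seed=0, restarts=8)
        transformed = DissimilarityMatrix(matrix=np.sqrt(planar.matrix) * 3.0,
                                          sample_ids=planar.sample_ids,
                                          sample_depth=planar.sample_depth)
        res2 = nmds(transformed, k=2, seed=0, restarts=8)
        assert abs(res1.stress - res2.stress) < 0.01

    def test_stress_non_increasing_within_run(self, planar):
        res = nmds(planar, k=2, seed=0, restarts=1)
        hist = np.array(res.stress_history)
        assert np.all(np.diff(hist) <= 1e-6)

    def test_same_seed_bit_reproducible(self, planar):
        a = nmds(planar, k=2, seed=4, restarts=5)
        b = nmds(planar, k=2, seed=4, restarts=5)
        assert a.stress == b.stress
        assert np.array_equal(a.coordinates, b.coordinates)

    def test_coordinates_centered(self, planar):
        res = nmds(planar, k=2, seed=0, restarts=3)
        np.testing.assert_allclose(res.coordinates.mean(axis=0), 0, atol=1e-9)

    def test_stress_stable_across_seeds(self, planar):
        stresses = [nmds(planar, k=2, seed=s, restarts=5).stress for s in range(3)]
        assert max(stresses) <= max(min(stresses) * 1.1, min(stresses) + 1e-3)

    def test_too_few_samples_rejected(self):
        d = DissimilarityMatrix(matrix=np.zeros((3, 3)), sample_ids=("a", "b", "c"),
                                sample_depth=np.arange(3.0))
        with pytest.raises(ValueError):
            nmds(d, k=2)

    def test_matches_independent_smacof_implementation(self, planar):
        """Cross-check final stress against scikit-learn's non-metric MDS."""
        sklearn = pytest.importorskip("sklearn.manifold")
        mds = sklearn.MDS(n_components=2, metric_mds=False, metric="precomputed",
                          init="random", n_init=8, random_state=0,
                          normalized_stress=True, eps=1e-9, max_iter=500)
        mds.fit(planar.matrix)
        ours = nmds(planar, k=2, seed=0, restarts=8).stress
        assert ours <= mds.stress_ + 0.01


class TestDepthCorrelation:
    def make_profile(self, values):
        tops = np.arange(len(values), dtype=float)
        return DepthProfile(bin_top=tops, bin_bottom=tops + 1, value=values)

    def test_strictly_monotone_extremes(self):
        rho, _ = depth_correlation(self.make_profile([1, 2, 3, 4, 5, 6]))
        assert rho == pytest.approx(1.0)
        rho, _ = depth_correlation(self.make_profile([6, 5, 4, 3, 2, 1]))
        assert rho == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            depth_correlation(self.make_profile([2, 2, 2, 2, 2]))

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            depth_correlation(self.make_profile([1, 2, 3]))

    @pytest.mark.parametrize("n", [5, 6, 7])
    def test_matches_exhaustive_rank_oracle(self, n):
        """rho equals the brute-force tied-rank computation for all small inputs."""
        rng = np.random.default_rng(n)
        for _ in range(8):
            vals = rng.integers(0, 4, size=n).astype(float)  # heavy ties
            if np.ptp(vals) == 0:
                continue
            prof = self.make_profile(vals)
            rho, p = depth_correlation(prof)
            oracle = spearman_oracle(prof.midpoint, vals)
            assert rho == pytest.approx(oracle, abs=1e-12)
            assert p == pytest.approx(exact_perm_p(prof.midpoint, vals, oracle),
                                      abs=1e-12)

    def test_bh_adjustment_monotone(self):
        raw = np.array([0.001, 0.04, 0.03, 0.8])
        adj = adjust_pvalues_bh(raw)
        assert np.all(adj >= raw - 1e-15)
        assert np.all(adj <= 1.0)


class TestPersistersAndRanking:
    def test_persisters_hand_count(self, toy_otus):
        res = trace_persisters(toy_otus)
        assert set(res.otu_ids) == {"otu_a", "otu_b", "otu_c"}
        # deepest sample s50: persisters hold 10+5+45 of 100 reads
        assert res.read_share_deepest == pytest.approx(0.60)
        assert res.richness_share_deepest == pytest.approx(3 / 4)

    def test_absence_in_one_sample_excludes(self, toy_otus):
        assert "otu_d" not in trace_persisters(toy_otus).otu_ids
        assert "otu_f" not in trace_persisters(toy_otus).otu_ids

    def test_min_count_threshold(self, toy_otus):
        res = trace_persisters(toy_otus, min_count=10)
        assert set(res.otu_ids) == {"otu_a", "otu_c"}

    def test_top_otus_matches_sort_oracle(self, toy_otus):
        got = top_otus(toy_otus, 3, "s50")
        oracle = sorted(zip(toy_otus.otu_ids, toy_otus.counts[3]),
                        key=lambda t: (-t[1], t[0]))[:3]
        assert [(o, c) for o, c, _ in got] == [(o, int(c)) for o, c in oracle]
        assert got[0][0] == "otu_c"

    def test_top_fractions_sum_below_one(self, toy_otus):
        got = top_otus(toy_otus, 3, "s3")
        assert sum(f for _, _, f in got) <= 1.0 + 1e-12

    def test_unknown_sample_rejected(self, toy_otus):
        with pytest.raises(KeyError):
            top_otus(toy_otus, 1, "nope")

    def test_n_larger_than_table_rejected(self, toy_otus):
        with pytest.raises(ValueError):
            top_otus(toy_otus, 99, "s3")
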