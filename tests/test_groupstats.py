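import numpy as np
import pytest
from scipy import stats

from wsdm.groupstats import (
    ReproducibilityResult,
    compare_slopes,
    conjunction,
    extent_filter,
    one_sample_tmap,
    reproducibility,
    two_sample_tmap,
)
from wsdm.seedmap import ConnectivityMap

SHAPE = (8, 8, 4)


def _maps(values_list, mask=None):
    mask = np.ones(SHAPE, bool) if mask is None else mask
    return [ConnectivityMap(values=v, mask=mask, measure="wsdm") for v in values_list]


def _noise_maps(rng, n, loc=0.0, scale=1.0):
    return _maps([loc + scale * rng.standard_normal(SHAPE) for _ in range(n)])


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


class TestOneSample:
    def test_constant_positive_maps_all_significant_pre_extent(self):
        maps = _maps([np.full(SHAPE, 0.5)] * 5)
        res = one_sample_tmap(maps, extent=1)
        assert res.significant.all()
        assert np.isfinite(res.t_values).all()

    def test_uncorrected_null_rate_near_alpha(self, rng):
        counts = []
        for _ in range(50):
            res = one_sample_tmap(_noise_maps(rng, 10), alpha=0.05,
                                  correction="none", extent=1)
            counts.append(res.significant.sum())
        n_vox = np.prod(SHAPE)
        rate = np.sum(counts) / (50 * n_vox)
        assert rate == pytest.approx(0.05, abs=0.015)

    def test_bonferroni_with_extent_kills_null_maps(self, rng):
        res = one_sample_tmap(_noise_maps(rng, 10), alpha=0.05, extent=30)
        assert res.significant.sum() == 0

    def test_max_t_close_to_bonferroni_for_independent_voxels(self, rng):
        maps = _noise_maps(rng, 12, loc=0.8)
        bon = one_sample_tmap(maps, extent=1)
        per = one_sample_tmap(maps, extent=1, correction="max_t",
                              n_permutations=500, rng=3)
        # same data, comparable FWE thresholds: masks overlap heavily
        agree = (bon.significant == per.significant).mean()
        assert agree > 0.9

    def test_needs_three_subjects(self, rng):
        with pytest.raises(ValueError):
            one_sample_tmap(_noise_maps(rng, 2))


class TestExtentFilter:
    def test_small_cluster_removed(self):
        sig = np.zeros(SHAPE, bool)
        sig[0:5, 0, 0] = True  # 5-voxel component
        sig[3:7, 3:7, 1:3] = True  # 32-voxel component
        out = extent_filter(sig, 30)
        assert not out[0:5, 0, 0].any()
        assert out[3:7, 3:7, 1:3].all()

    def test_never_adds_voxels(self, rng):
        sig = rng.random(SHAPE) > 0.7
        out = extent_filter(sig, 10)
        assert not (out & ~sig).any()

    def test_diagonal_touch_counts_as_connected(self):
        sig = np.zeros(SHAPE, bool)
        sig[0, 0, 0] = sig[1, 1, 1] = True  # 26-connected pair
        assert extent_filter(sig, 2).sum() == 2


class TestTwoSample:
    def test_identical_groups_not_significant(self, rng):
        res = two_sample_tmap(_noise_maps(rng, 8), _noise_maps(rng, 8))
        assert res.significant.sum() == 0

    def test_planted_hypoconnectivity_recovered(self, rng):
        region = np.zeros(SHAPE, bool)
        region[1:6, 1:6, 1:3] = True  # 50 voxels
        effect = np.where(region, 1.5, 0.0)  # Cohen's d = 1.5 against unit noise
        hc = _maps([effect + rng.standard_normal(SHAPE) for _ in range(20)])
        pt = _maps([rng.standard_normal(SHAPE) for _ in range(20)])
        res = two_sample_tmap(hc, pt, alpha=0.001, extent=30)
        sensitivity = (res.significant & region).sum() / region.sum()
        assert sensitivity >= 0.5
        fp = (res.significant & ~region).sum()
        assert fp <= 5

    def test_contrast_reversal_swaps_roles(self, rng):
        region = np.zeros(SHAPE, bool)
        region[2:6, 2:6, :] = True
        hi = _maps([np.where(region, 2.0, 0.0) + rng.standard_normal(SHAPE) for _ in range(15)])
        lo = _maps([rng.standard_normal(SHAPE) for _ in range(15)])
        fwd = two_sample_tmap(hi, lo, contrast="controls>patients")
        rev = two_sample_tmap(lo, hi, contrast="patients>controls")
        np.testing.assert_array_equal(fwd.significant, rev.significant)
        assert fwd.significant.sum() > 0

    def test_pre_extent_false_positive_rate_matches_alpha(self, rng):
        """Under a true null, the one-sided voxel test rejects at nominal rate."""
        alpha, hits, total = 0.01, 0, 0
        for _ in range(200):
            res = two_sample_tmap(_noise_maps(rng, 6), _noise_maps(rng, 6),
                                  alpha=alpha, extent=1)
            hits += int(res.significant.sum())
            total += int(res.mask.sum())
        rate = hits / total
        bound = 3 * np.sqrt(alpha * (1 - alpha) / total)
        assert abs(rate - alpha) < max(bound, 0.002)


class TestConjunction:
    def test_idempotent_commutative_disjoint(self, rng):
        a = one_sample_tmap(_noise_maps(rng, 8, loc=1.0), extent=1)
        b = one_sample_tmap(_noise_maps(rng, 8, loc=1.0), extent=1)
        np.testing.assert_array_equal(conjunction(a, a), a.significant)
        np.testing.assert_array_equal(conjunction(a, b), conjunction(b, a))
        empty = one_sample_tmap(_noise_maps(rng, 8, loc=-5.0), extent=1)
        assert not conjunction(a, empty).any()


class TestReproducibility:
    def test_perfect_and_inverted_agreement(self, rng):
        a = one_sample_tmap(_noise_maps(rng, 10), extent=1)
        b_vals = type(a)(t_values=-a.t_values, df=a.df, significant=a.significant,
                         mask=a.mask, contrast=a.contrast, alpha=a.alpha, extent=a.extent)
        assert reproducibility(a, a).rho == pytest.approx(1.0)
        assert reproducibility(a, b_vals).rho == pytest.approx(-1.0)

    def test_independent_maps_uncorrelated(self, rng):
        a = one_sample_tmap(_noise_maps(rng, 10), extent=1)
        b = one_sample_tmap(_noise_maps(rng, 10), extent=1)
        res = reproducibility(a, b)
        assert abs(res.rho) < 0.2
        assert res.p_value > 0.001
        assert res.n_voxels == int(np.prod(SHAPE))

    def test_pearson_option(self, rng):
        a = one_sample_tmap(_noise_maps(rng, 10), extent=1)
        assert reproducibility(a, a, method="pearson").rho == pytest.approx(1.0)


class TestCompareSlopes:
    @staticmethod
    def _fit(rng, slope, n=1000, noise=1.0):
        x = rng.standard_normal(n)
        y = slope * x + noise * rng.standard_normal(n)
        ols = stats.linregress(x, y)
        rho, p = stats.spearmanr(x, y)
        return ReproducibilityResult(rho=rho, p_value=p, slope=ols.slope,
                                     slope_se=ols.stderr, intercept=ols.intercept,
                                     n_voxels=n)

    def test_identical_inputs_give_zero(self, rng):
        r = self._fit(rng, 0.8)
        t, p = compare_slopes(r, r)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_separated_slopes_significant(self, rng):
        r1 = self._fit(rng, 1.0, noise=0.01)
        r2 = self._fit(rng, 0.0, noise=0.01)
        t, p = compare_slopes(r1, r2)
        assert abs(t) > 10
        assert p < 0.001

    def test_known_slopes_point_eight_vs_point_two(self, rng):
        t, p = compare_slopes(self._fit(rng, 0.8), self._fit(rng, 0.2))
        assert p < 0.001
        assert t > 0

    def test_mismatched_pairings_rejected(self, rng):
        r1 = self._fit(rng, 0.5, n=1000)
        r2 = self._fit(rng, 0.5, n=900)
        with pytest.raises(ValueError):
            compare_slopes(r1, r2)
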