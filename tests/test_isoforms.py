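import numpy as np
import pandas as pd
import pytest
from itertools import combinations
from math import comb
from scipy import stats as sps
from scipy.stats import rankdata

from isoniche import (ConfigError, DSConfig, bonferroni, class_distribution,
                      classify_pattern, classify_spatial, differential_splicing,
                      log_normalize, wilcoxon_rank_sum)

from conftest import make_matrix


def exact_wilcoxon_oracle(x, y):
    """Full enumeration of the two-sided rank-sum p (independent of the
    implementation's own exact path: no shared code)."""
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled, method="average")
    nx, N = len(x), len(pooled)
    W = ranks[:nx].sum()
    mu = nx * (N + 1) / 2
    hits = sum(
        1
        for idx in combinations(range(N), nx)
        if abs(ranks[list(idx)].sum() - mu) >= abs(W - mu) - 1e-9
    )
    return hits / comb(N, nx)


def _iso_matrix(counts, genes, spots=None):
    n_f = counts.shape[1]
    features = [f"iso{j}" for j in range(n_f)]
    iso2gene = {f: g for f, g in zip(features, genes)}
    return make_matrix(counts, spots=spots, features=features, level="isoform",
                       iso2gene=iso2gene)


class TestClassifySpatial:
    def _setup(self):
        # 8 spots over 4 niches (2 spots each); columns = isoforms
        niches = {f"s{i}": i // 2 for i in range(8)}
        counts = np.zeros((8, 5), dtype=int)
        counts[:, 0] = 1                      # iso0: geneA sole isoform, everywhere
        counts[:, 1] = 1                      # iso1: geneB, all 4 niches
        counts[4:6, 2] = 3                    # iso2: geneB, only niche 2
        counts[0:2, 3] = 2                    # iso3: geneC, niches {0, 2}
        counts[4:6, 3] = 2
        # iso4: geneC, detected nowhere
        genes = ["geneA", "geneB", "geneB", "geneC", "geneC"]
        return _iso_matrix(counts, genes), niches

    def test_four_way_definition(self):
        m, niches = self._setup()
        cls = classify_spatial(m, niches)["spatial_class"]
        assert cls["iso0"] == "single"      # sole isoform of its gene
        assert cls["iso1"] == "multi_all"   # all K=4 niches
        assert cls["iso2"] == "multi_one"   # support {2}
        assert cls["iso3"] == "multi_others"  # support {0, 2}
        assert cls["iso4"] == "undetected"

    def test_sole_isoform_single_regardless_of_support(self):
        niches = {f"s{i}": i // 2 for i in range(8)}
        counts = np.zeros((8, 1), dtype=int)
        counts[0, 0] = 5  # detected in a single niche only
        m = _iso_matrix(counts, ["geneA"])
        assert classify_spatial(m, niches)["spatial_class"]["iso0"] == "single"

    def test_support_enumeration_against_definition(self, rng):
        # enumerate random support sets; check class from |support| directly
        K = 5
        niches = {f"s{i}": i % K for i in range(3 * K)}
        for _ in range(30):
            size = int(rng.integers(0, K + 1))
            support = sorted(rng.choice(K, size=size, replace=False))
            counts = np.zeros((3 * K, 2), dtype=int)
            for i in range(3 * K):
                if i % K in support:
                    counts[i, 0] = 1
            counts[0, 1] = 1  # second isoform so the gene is multi-isoform
            m = _iso_matrix(counts, ["g", "g"])
            got = classify_spatial(m, niches)["spatial_class"]["iso0"]
            if size == 0:
                expected = "undetected"
            elif size == K:
                expected = "multi_all"
            elif size == 1:
                expected = "multi_one"
            else:
                expected = "multi_others"
            assert got == expected

    def test_detection_min_spots_threshold(self):
        niches = {f"s{i}": i // 2 for i in range(4)}
        counts = np.array([[1, 1], [0, 1], [0, 0], [0, 0]])
        m = _iso_matrix(counts, ["g", "g"])
        # with threshold 2, iso0 (one positive spot in niche 0) is undetected
        cls = classify_spatial(m, niches, detection_min_spots=2)["spatial_class"]
        assert cls["iso0"] == "undetected" and cls["iso1"] == "multi_one"

    def test_classes_partition_detected_isoforms(self, rng):
        niches = {f"s{i}": i % 3 for i in range(30)}
        counts = rng.poisson(0.7, size=(30, 40))
        genes = [f"g{j // 2}" for j in range(40)]
        m = _iso_matrix(counts, genes)
        classes = classify_spatial(m, niches)
        dist = class_distribution(classes)
        assert sum(dist["counts"].values()) == dist["n_detected"]
        assert dist["n_detected"] + dist["n_undetected"] == 40

    def test_invariant_to_niche_label_permutation(self, rng):
        niches = {f"s{i}": i % 4 for i in range(20)}
        permuted = {s: (v + 2) % 4 for s, v in niches.items()}
        counts = rng.poisson(1.0, size=(20, 10))
        m = _iso_matrix(counts, [f"g{j // 2}" for j in range(10)])
        a = classify_spatial(m, niches)["spatial_class"]
        b = classify_spatial(m, permuted)["spatial_class"]
        assert (a == b).all()


class TestClassifyPattern:
    def _trio(self, before, after, after_ln):
        mats = {}
        for key, col in (("before", before), ("after", after), ("after_ln", after_ln)):
            mats[key] = _iso_matrix(np.array(col).reshape(-1, 1), ["g"])
        return mats

    def test_metastasis_positive(self):
        # AfterLN mean is 3x After mean, threshold 1.5
        mats = self._trio([2, 2], [2, 2], [6, 6])
        res = classify_pattern(mats)
        assert res.loc["iso0", "pattern"] == "metastasis_positive"

    def test_identical_means_everywhere_none(self):
        mats = self._trio([3, 3], [3, 3], [3, 3])
        assert classify_pattern(mats).loc["iso0", "pattern"] == "none"

    def test_multi_label_both_contrasts(self):
        # After = 0.5 * Before and AfterLN = 2 * After
        mats = self._trio([4, 4], [2, 2], [4, 4])
        res = classify_pattern(mats)
        assert set(res.loc["iso0", "labels"]) == {"treatment_target", "metastasis_positive"}

    def test_all_zero_contrast_gives_none(self):
        mats = self._trio([0, 0], [0, 0], [0, 0])
        assert classify_pattern(mats).loc["iso0", "pattern"] == "none"

    def test_headline_is_largest_fold_change(self):
        # resistance fc 4 beats metastasis fc 2
        mats = self._trio([1, 1], [4, 4], [8, 8])
        assert classify_pattern(mats).loc["iso0", "pattern"] == "resistance"

    def test_invariant_to_spot_order(self, rng):
        counts = rng.poisson(4, size=(6, 3))
        genes = ["g0", "g0", "g1"]
        perm = rng.permutation(6)
        mats_a, mats_b = {}, {}
        for key, mult in (("before", 1), ("after", 2), ("after_ln", 3)):
            mats_a[key] = _iso_matrix(counts * mult, genes)
            mats_b[key] = _iso_matrix(
                (counts * mult)[perm], genes,
                spots=[f"s{i}" for i in perm])
        pd.testing.assert_frame_equal(classify_pattern(mats_a), classify_pattern(mats_b))


class TestWilcoxon:
    def test_exact_small_sample(self):
        # all C(4,2)=6 rank splits; |W-5|>=2 for W in {3,7} -> p = 2/6
        _, p = wilcoxon_rank_sum([1, 2], [3, 4])
        assert p == pytest.approx(1 / 3)

    def test_identical_groups_p1(self):
        _, p = wilcoxon_rank_sum([2, 2, 2], [2, 2])
        assert p == 1.0

    def test_exact_matches_enumeration_oracle(self, rng):
        for _ in range(25):
            x = rng.integers(0, 6, int(rng.integers(2, 7))).astype(float)
            y = rng.integers(0, 6, int(rng.integers(2, 7))).astype(float)
            _, p = wilcoxon_rank_sum(x, y)
            assert p == pytest.approx(exact_wilcoxon_oracle(x, y))

    def test_normal_approx_close_to_exact_at_8_plus_8(self, rng):
        # force the approximation on sizes where enumeration is feasible
        for _ in range(40):
            x = rng.normal(0, 1, 8)
            y = rng.normal(0.5, 1, 8)
            _, p_approx = wilcoxon_rank_sum(x, y, exact_max_n=0)
            p_exact = exact_wilcoxon_oracle(x, y)
            assert abs(p_approx - p_exact) < 0.02

    def test_matches_scipy_large_sample(self, rng):
        x = rng.normal(0, 1, 40)
        y = rng.normal(0.4, 1, 35)
        _, p = wilcoxon_rank_sum(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestBonferroni:
    def test_arithmetic_and_cap(self):
        np.testing.assert_allclose(bonferroni([0.01], m=5), [0.05])
        np.testing.assert_allclose(bonferroni([0.5], m=10), [1.0])
        np.testing.assert_allclose(bonferroni([0.2]), [0.2])  # m=1 identity

    def test_family_size_from_vector(self):
        np.testing.assert_allclose(bonferroni([0.01, 0.02]), [0.02, 0.04])

    def test_adjustment_below_alpha_fails_at_stated_family_size(self):
        assert bonferroni([0.0004], m=200)[0] == pytest.approx(0.08)


class TestDifferentialSplicing:
    def _planted(self, rng, n_spots=90, boost=10.0):
        """Three niches; gene g0 has a niche-0-specific minority isoform."""
        niches = {f"s{i}": i % 3 for i in range(n_spots)}
        niche_idx = np.array([i % 3 for i in range(n_spots)])
        counts = rng.poisson(2.0, size=(n_spots, 6))
        counts[:, 0] = rng.poisson(np.where(niche_idx == 0, 2.0 * boost, 0.2))
        counts[:, 1] = rng.poisson(8.0, n_spots)  # majority isoform of g0
        genes = ["g0", "g0", "g1", "g1", "g2", "g2"]
        return _iso_matrix(counts, genes), niches

    def test_planted_minority_isoform_passes_in_its_niche(self, rng):
        m, niches = self._planted(rng)
        res = differential_splicing(m, niches)
        hit = res[(res.isoform_id == "iso0") & (res.niche == 0)]
        assert bool(hit["pass"].iloc[0])
        assert hit["log_fc"].iloc[0] > 0.25

    def test_majority_isoform_never_passes(self, rng):
        m, niches = self._planted(rng)
        res = differential_splicing(m, niches)
        majority = res[res.isoform_id == "iso1"]
        assert majority["is_majority"].all()
        assert not majority["pass"].any()

    def test_single_isoform_genes_not_tested(self, rng):
        niches = {f"s{i}": i % 2 for i in range(20)}
        counts = rng.poisson(3, size=(20, 3))
        m = _iso_matrix(counts, ["g0", "g0", "g1"])  # g1 sole isoform
        res = differential_splicing(m, niches)
        assert "iso2" not in set(res.isoform_id)

    def test_bonferroni_family_is_tests_performed(self, rng):
        m, niches = self._planted(rng)
        res = differential_splicing(m, niches)
        np.testing.assert_allclose(
            res["p_adj"], np.minimum(1.0, res["pvalue"] * len(res))
        )

    def test_small_niche_skipped_with_warning(self, rng):
        niches = {f"s{i}": (0 if i < 2 else 1) for i in range(20)}
        counts = rng.poisson(3, size=(20, 2)) + 1
        m = _iso_matrix(counts, ["g0", "g0"])
        with pytest.warns(UserWarning, match="fewer than 3"):
            res = differential_splicing(m, niches)
        assert set(res.niche) == set()  # niche 0 too small, rest of niche 1 too small

    def test_null_data_pass_rate_controlled(self):
        # no niche effect: expect <= 5% of isoforms to pass at alpha 0.05
        rng = np.random.default_rng(31)
        rates = []
        for _ in range(50):
            niches = {f"s{i}": i % 3 for i in range(60)}
            counts = rng.poisson(2.0, size=(60, 20)) + (rng.random((60, 20)) < 0.5)
            m = _iso_matrix(counts.astype(int), [f"g{j // 2}" for j in range(20)])
            res = differential_splicing(m, niches)
            rates.append(res.groupby("isoform_id")["pass"].any().mean())
        assert np.mean(rates) <= 0.05

    def test_normalized_input_rejected(self, rng):
        m, niches = self._planted(rng)
        with pytest.raises(ConfigError, match="raw"):
            differential_splicing(log_normalize(m), niches)
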