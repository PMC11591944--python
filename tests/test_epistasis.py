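"""MI estimators, background correction and pair detection."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from snp2tf.epistasis import (
    apc_correct,
    detect_epistasis,
    mi_discrete,
    mi_mixed,
    pair_mi,
)
from snp2tf.simulate import SimConfig, simulate_genotypes, simulate_phenotype


def mi_double_sum_oracle(x, y):
    """Direct double sum over the 2-way contingency table, log base 2."""
    xv, yv = np.unique(x), np.unique(y)
    n = len(x)
    total = 0.0
    for a in xv:
        for b in yv:
            p_ab = np.mean((x == a) & (y == b))
            if p_ab > 0:
                total += p_ab * np.log2(p_ab / (np.mean(x == a) * np.mean(y == b)))
    return total


class TestMIDiscrete:
    def test_identity_uniform_three_levels(self):
        x = np.repeat([0, 1, 2], 40)
        assert mi_discrete(x, x) == pytest.approx(np.log2(3), abs=1e-12)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_matches_double_sum_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 60))
        x = rng.integers(0, rng.integers(2, 4), size=n)
        y = rng.integers(0, rng.integers(2, 4), size=n)
        if np.unique(x).size < 2 or np.unique(y).size < 2:
            return
        assert mi_discrete(x, y) == pytest.approx(mi_double_sum_oracle(x, y), abs=1e-12)

    def test_too_few_observations(self):
        with pytest.raises(ValueError):
            mi_discrete(np.array([0, 1] * 4), np.array([0, 1] * 4))


class TestMIMixed:
    def test_near_deterministic_equals_genotype_entropy(self):
        rng = np.random.default_rng(0)
        x = rng.integers(0, 3, size=4000)
        y = x + 1e-6 * rng.normal(size=x.size)
        p = np.bincount(x) / x.size
        h = -(p * np.log2(p)).sum()
        assert mi_mixed(x, y, k=3, seed=1) == pytest.approx(h, abs=0.05)

    def test_scale_invariance(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, size=800)
        y = x + rng.normal(0, 0.7, size=x.size)
        assert mi_mixed(x, 1000.0 * y, k=3, seed=2) == pytest.approx(
            mi_mixed(x, y, k=3, seed=2), abs=1e-6
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        x = rng.integers(0, 3, size=1500)
        y = x + rng.normal(0, 1.0, size=x.size)
        a = mi_mixed(x, y, k=3, seed=3)
        b = mi_mixed(x, np.exp(y / 3.0), k=3, seed=3)
        assert b == pytest.approx(a, abs=0.02)

    def test_cross_check_against_sklearn(self):
        """Independent reference: sklearn's mixed-data k-NN MI estimator."""
        from sklearn.feature_selection import mutual_info_regression

        rng = np.random.default_rng(3)
        x = rng.integers(0, 3, size=2000)
        y = 0.8 * x + rng.normal(0, 1.0, size=x.size)
        mine = mi_mixed(x, y, k=3, seed=4)
        ref = mutual_info_regression(
            x.reshape(-1, 1), y, discrete_features=[True], n_neighbors=3,
            random_state=0,
        )[0] / np.log(2)
        assert mine == pytest.approx(ref, abs=0.02)

    def test_constant_genotype_raises(self):
        with pytest.raises(ValueError):
            mi_mixed(np.zeros(100, int), np.random.default_rng(0).normal(size=100))


class TestPairMI:
    def test_self_pair_equals_single(self):
        rng = np.random.default_rng(4)
        x = rng.integers(0, 3, size=600)
        y = x + rng.normal(0, 0.8, size=x.size)
        assert pair_mi(x, x, y, seed=5) == pytest.approx(
            mi_mixed(x, y, seed=5), abs=1e-12
        )

    def test_xor_pair_one_bit(self):
        """Noiseless 2-class xor at MAF 0.5: pair MI is analytically 1 bit
        (phenotype = sign of the xor indicator, a balanced binary variable
        fully determined by the composite genotype)."""
        cfg = SimConfig(n_animals=2000, n_snps=6, maf_range=(0.5, 0.5),
                        missing_rate=0.0, n_additive=0, n_epistatic_pairs=1,
                        epistasis_model="xor", heritability=1.0, seed=8)
        G = simulate_genotypes(cfg)
        y, truth = simulate_phenotype(G, cfg)
        ids = list(G.snps["snp_id"])
        ja, jb = (ids.index(s) for s in truth["epistatic_pairs"][0])
        got = pair_mi(G.codes[:, ja], G.codes[:, jb], y.to_numpy(), seed=6)
        assert got == pytest.approx(1.0, abs=0.05)
        for j in (ja, jb):
            assert abs(mi_mixed(G.codes[:, j], y.to_numpy(), seed=6)) < 0.05

    def test_pair_at_least_max_single_on_additive(self, additive_cohort):
        G, y, truth = additive_cohort
        ids = list(G.snps["snp_id"])
        ja, jb = (ids.index(s) for s in truth["additive_snps"][:2])
        singles = [mi_mixed(G.codes[:, j], y.to_numpy(), seed=7) for j in (ja, jb)]
        joint = pair_mi(G.codes[:, ja], G.codes[:, jb], y.to_numpy(), seed=7)
        assert joint >= max(singles) - 0.05


class TestAPC:
    def test_uniform_background_annihilated(self):
        pairs = {(f"s{i}", f"s{j}"): 0.4 for i, j in itertools.combinations(range(6), 2)}
        corrected = apc_correct(pairs)
        assert all(abs(v) < 1e-12 for v in corrected.values())

    def test_single_pair_zero_by_convention(self):
        assert apc_correct({("a", "b"): 1.7}) == {("a", "b"): 0.0}

    def test_elevated_pair_has_max_corrected(self):
        snps = [f"s{i}" for i in range(5)]
        pairs = {p: 0.2 for p in itertools.combinations(snps, 2)}
        pairs[("s1", "s3")] = 1.2
        corrected = apc_correct(pairs)
        assert max(corrected, key=corrected.get) == ("s1", "s3")

    def test_rank_one_matrix_sums_near_zero(self):
        rng = np.random.default_rng(5)
        a = rng.uniform(0.5, 1.5, size=30)
        pairs = {
            (f"s{i:02d}", f"s{j:02d}"): a[i] * a[j]
            for i, j in itertools.combinations(range(30), 2)
        }
        corrected = apc_correct(pairs)
        total = sum(corrected.values())
        scale = sum(abs(v) for v in pairs.values())
        assert abs(total) < 0.02 * scale


class TestDetectEpistasis:
    def test_all_pairs_when_screen_keeps_everything(self):
        rng = np.random.default_rng(6)
        X = rng.integers(0, 3, size=(200, 10))
        y = rng.normal(size=200)
        pairs, _ = detect_epistasis(
            X, y, [f"s{j}" for j in range(10)], screen_fraction=1.0,
            min_screen=10, ifs_max_k=None, seed=9,
        )
        assert len(pairs) == 45  # C(10, 2)
        assert all(p.snp_a < p.snp_b for p in pairs)

    def test_null_corrected_scores_centred(self):
        rng = np.random.default_rng(7)
        X = rng.integers(0, 3, size=(400, 20))
        y = rng.normal(size=400)
        pairs, _ = detect_epistasis(
            X, y, [f"s{j:02d}" for j in range(20)], screen_fraction=1.0,
            min_screen=20, ifs_max_k=None, seed=10,
        )
        scores = np.array([p.corrected for p in pairs])
        assert abs(scores.mean()) < 0.02

    def test_screen_too_small_raises(self):
        X = np.random.default_rng(8).integers(0, 3, size=(100, 1))
        with pytest.raises(ValueError):
            detect_epistasis(X, np.random.default_rng(9).normal(size=100),
                             ["s0"], screen_fraction=1.0, min_screen=1)
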