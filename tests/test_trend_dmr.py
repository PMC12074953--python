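import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from enhmeth.core_io import BetaMatrix, FeatureLevel, SampleMetadata
from enhmeth.errors import CapacityError, InsufficientDataError
from enhmeth.synthetic_data import SimulationConfig, simulate_methylation_cohort
from enhmeth.blocks import block_beta
from enhmeth.trend_dmr import (
    call_trend_dmrs,
    context_enrichment,
    jt_null_moments,
    jt_statistic,
    jt_test,
)


def brute_force_u(groups):
    u = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            for x in groups[i]:
                for y in groups[j]:
                    u += 1.0 if y > x else (0.5 if y == x else 0.0)
    return u


class TestStatistic:
    def test_three_singletons(self):
        assert jt_statistic([[1], [2], [3]]) == 3.0

    def test_all_tied_equals_null_mean(self):
        groups = [[0, 0], [0, 0], [0, 0]]
        assert jt_statistic(groups) == 6.0
        mean, _, _ = jt_null_moments(groups)
        assert mean == 6.0

    def test_matches_pair_count_oracle(self, rng):
        for _ in range(500):
            groups = [
                rng.integers(0, 5, size=rng.integers(1, 7)).astype(float)
                for _ in range(3)
            ]
            assert jt_statistic(groups) == brute_force_u(groups)

    def test_empty_group_rejected(self):
        with pytest.raises(InsufficientDataError):
            jt_statistic([[1.0], []])


class TestTest:
    def test_exact_enumeration_example(self):
        z, p = jt_test([[1], [2], [3]], method="exact_enum")
        assert p == pytest.approx(1 / 3)

    def test_constant_groups(self):
        z, p = jt_test([[0, 0], [0, 0], [0, 0]])
        assert (z, p) == (0.0, 1.0)

    def test_normal_matches_exact_333(self, rng):
        worst = 0.0
        for _ in range(100):
            groups = [rng.normal(size=3) for _ in range(3)]
            _, pn = jt_test(groups, "normal_approx")
            _, pe = jt_test(groups, "exact_enum")
            worst = max(worst, abs(pn - pe))
        assert worst <= 0.01

    def test_permutation_agrees_with_exact(self, rng):
        groups = [rng.normal(size=3) for _ in range(3)]
        _, pe = jt_test(groups, "exact_enum")
        _, pp = jt_test(groups, "permutation", n_perm=4000, seed=1)
        assert abs(pp - pe) < 0.05

    def test_capacity_error(self):
        groups = [np.arange(12.0), np.arange(12.0), np.arange(12.0)]
        with pytest.raises(CapacityError):
            jt_test(groups, method="exact_enum")

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_antisymmetry(self, seed):
        """Reversing group order maps U to max_pairs - U and keeps the
        two-sided p unchanged."""
        rng = np.random.default_rng(seed)
        groups = [rng.integers(0, 6, size=rng.integers(2, 6)).astype(float)
                  for _ in range(3)]
        u = jt_statistic(groups)
        _, _, max_pairs = jt_null_moments(groups)
        rev = groups[::-1]
        assert jt_statistic(rev) == pytest.approx(max_pairs - u)
        _, p = jt_test(groups)
        _, p_rev = jt_test(rev)
        assert p == pytest.approx(p_rev, abs=1e-12)


def cohort_dmrs(seed, n_hyper, n_hypo, n_blocks=5000):
    config = SimulationConfig(
        seed=seed, n_blocks=n_blocks, n_hyper=n_hyper, n_hypo=n_hypo,
        n_marker=0, type2_bias=0.0,
    )
    matrix, ann, meta, truth, blocks = simulate_methylation_cohort(config)
    bm = block_beta(matrix, blocks)
    return call_trend_dmrs(bm, meta), truth


class TestCallTrendDmrs:
    def test_null_level(self):
        res, _ = cohort_dmrs(seed=101, n_hyper=0, n_hypo=0)
        frac = (res["p"] < 0.01).mean()
        assert 0.004 <= frac <= 0.02

    def test_planted_recovery(self):
        res, truth = cohort_dmrs(seed=102, n_hyper=200, n_hypo=0, n_blocks=5000)
        hyper = set(res.loc[res["direction"] == "hyper", "block_id"])
        planted = set(truth.hyper_block_ids)
        assert len(hyper & planted) / len(planted) >= 0.8
        null_ids = set(res["block_id"]) - planted
        called_null = (hyper - planted) | set(
            res.loc[res["direction"] == "hypo", "block_id"]
        )
        assert len(called_null & null_ids) / len(null_ids) <= 0.02

    def test_constant_matrix_no_dmrs(self):
        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "sample_id": [f"s{i}" for i in range(9)],
                    "group": ["normal_adipose"] * 3 + ["WDLPS"] * 3 + ["DDLPS"] * 3,
                }
            )
        )
        m = BetaMatrix(
            pd.DataFrame(
                np.full((20, 9), 0.4),
                index=[f"b{i}" for i in range(20)],
                columns=[f"s{i}" for i in range(9)],
            ),
            FeatureLevel.block,
        )
        res = call_trend_dmrs(m, meta)
        assert (res["direction"] == "none").all()
        assert (res["p"] == 1.0).all()

    def test_hyper_hypo_disjoint_subset_significant(self):
        res, _ = cohort_dmrs(seed=103, n_hyper=50, n_hypo=50, n_blocks=1000)
        hyper = set(res.loc[res["direction"] == "hyper", "block_id"])
        hypo = set(res.loc[res["direction"] == "hypo", "block_id"])
        sig = set(res.loc[res["p"] < 0.01, "block_id"])
        assert not (hyper & hypo)
        assert hyper <= sig and hypo <= sig

    def test_sparse_group_gives_na(self):
        meta = SampleMetadata(
            pd.DataFrame(
                {
                    "sample_id": ["a", "b", "c", "d", "e"],
                    "group": ["normal_adipose", "normal_adipose", "WDLPS", "WDLPS", "DDLPS"],
                }
            )
        )
        m = BetaMatrix(
            pd.DataFrame(
                [[0.1, 0.2, 0.4, 0.5, 0.9]],
                index=["b0"], columns=["a", "b", "c", "d", "e"],
            ),
            FeatureLevel.block,
        )
        res = call_trend_dmrs(m, meta)  # DDLPS has a single sample
        assert np.isnan(res["p"].iloc[0])
        assert res["direction"].iloc[0] == "none"


class TestContextEnrichment:
    def test_two_by_two_exact_example(self):
        universe = {"a", "b", "c", "d"}
        cat = {"a": "X", "b": "X", "c": "Y", "d": "Y"}
        res = context_enrichment({"a", "b"}, universe, cat)
        px = res.loc[res["category"] == "X", "p"].iloc[0]
        assert px == pytest.approx(1 / 3)

    def test_dmr_equals_universe(self):
        universe = {f"b{i}" for i in range(10)}
        cat = {b: ("X" if i < 4 else "Y") for i, b in enumerate(sorted(universe))}
        res = context_enrichment(universe, universe, cat)
        assert np.allclose(res["fraction_dmr"], res["fraction_universe"])
        assert (res["p"] == 1.0).all()

    def test_null_p_uniform(self, rng):
        """Under random label assignment the enrichment p-value is
        approximately uniform."""
        from scipy.stats import kstest

        universe = [f"b{i}" for i in range(200)]
        ps = []
        for _ in range(1000):
            labels = {b: ("X" if rng.random() < 0.3 else "Y") for b in universe}
            dmr = set(rng.choice(universe, size=40, replace=False))
            res = context_enrichment(dmr, set(universe), labels)
            ps.append(res.loc[res["category"] == "X", "p"].iloc[0])
        # discrete conservativeness: compare to uniform with KS tolerance
        stat = kstest(ps, "uniform").statistic
        assert stat < 0.25  # Fisher p is super-uniform (conservative), never anti-conservative
        assert (np.asarray(ps) < 0.01).mean() <= 0.015

    def test_empty_dmr_set_rejected(self):
        with pytest.raises(InsufficientDataError):
            context_enrichment(set(), {"a"}, {"a": "X"})
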