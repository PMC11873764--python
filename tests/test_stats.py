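"""COI statistics: paired tests, BH-FDR, z-conversion, group contrast."""

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from neofc import (
    Connectome,
    GroupDiffConfig,
    StatsConfig,
    bh_fdr,
    define_coi,
    group_z_difference,
    music_effect_test,
    paired_edge_ttest,
    pval_to_z,
)

# The 12 smallest raw p-values of the published 55-edge family
# (printed to 4 decimals / 2 significant figures).
PRINTED_RAW_P = [
    5.40e-05, 0.0005, 0.0006, 0.0015, 0.0020, 0.0023,
    0.0042, 0.0048, 0.0064, 0.0067, 0.0081, 0.0088,
]


def _connectome(edge_value: float, labels=("a", "b"), subject=None) -> Connectome:
    n = len(labels)
    m = np.full((n, n), np.nan)
    iu = np.triu_indices(n, 1)
    m[iu] = edge_value
    m[(iu[1], iu[0])] = edge_value
    return Connectome(matrix=m, network_labels=list(labels), subject_id=subject)


def _paired_sets(diffs, base=0.2):
    """Per-subject connectome pairs whose single-edge difference is given."""
    t1 = {f"s{i}": _connectome(base, subject=f"s{i}") for i in range(len(diffs))}
    t2 = {
        f"s{i}": _connectome(base + d, subject=f"s{i}")
        for i, d in enumerate(diffs)
    }
    return t1, t2


class TestPairedEdgeTtest:
    def test_hand_computed_t_and_p(self):
        """Differences (0.1, 0.2, 0.3): t = 0.2/(0.1/sqrt(3)) = 3.4641,
        df = 2, two-sided p ~ 0.0742."""
        t1, t2 = _paired_sets([0.1, 0.2, 0.3])
        table = paired_edge_ttest(t1, t2)
        assert table.loc[0, "t_statistic"] == pytest.approx(3.4641, abs=1e-4)
        assert table.loc[0, "p_raw"] == pytest.approx(0.0742, abs=1e-4)
        assert table.loc[0, "ewd"] == pytest.approx(0.2)
        assert table.loc[0, "n_pairs"] == 3

    def test_swapping_sessions_negates_t(self):
        t1, t2 = _paired_sets([0.05, 0.15, 0.1, 0.2])
        fwd = paired_edge_ttest(t1, t2)
        rev = paired_edge_ttest(t2, t1)
        assert rev.loc[0, "t_statistic"] == pytest.approx(
            -fwd.loc[0, "t_statistic"]
        )

    def test_zero_variance_differences_flagged_undefined(self):
        t1, t2 = _paired_sets([0.1, 0.1, 0.1])
        table = paired_edge_ttest(t1, t2)
        assert np.isnan(table.loc[0, "p_raw"])
        assert not table.loc[0, "in_coi"]

    def test_unpaired_subject_rejected_with_ids(self):
        t1, t2 = _paired_sets([0.1, 0.2, 0.3])
        del t2["s1"]
        t2["extra"] = _connectome(0.5)
        with pytest.raises(ValueError, match="extra.*s1|s1.*extra"):
            paired_edge_ttest(t1, t2)

    def test_undefined_edges_dropped_from_family(self):
        t1, t2 = _paired_sets([0.1, 0.2, 0.3], base=0.2)
        # make one subject's edge undefined at session 2
        nan_conn = _connectome(np.nan)
        t2["s1"] = nan_conn
        table = paired_edge_ttest(t1, t2)
        assert np.isnan(table.loc[0, "p_raw"])


class TestBhFdr:
    def test_published_family_recomputation(self):
        """The 12 printed raw p-values as the smallest of m = 55 tests:
        raw 0.0088 adjusts to 0.0403, raw 0.0067 to 0.0368, and all 12
        survive at alpha = 0.05."""
        p_fdr, survivors = bh_fdr(np.array(PRINTED_RAW_P), m=55, alpha=0.05)
        by_raw = dict(zip(PRINTED_RAW_P, p_fdr))
        # 55*0.0088/12 = 0.040333...; min(55*0.0067/10, ranks 11-12) = 0.03685,
        # printed as 0.0368 (half-even at the exact decimal midpoint)
        assert by_raw[0.0088] == pytest.approx(0.0403333, abs=1e-6)
        assert by_raw[0.0067] == pytest.approx(0.03685, abs=1e-6)
        assert len(survivors) == 12

    def test_stepup_hand_example(self):
        p_fdr, _ = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(p_fdr, 0.04)

    def test_single_p_is_identity(self):
        p_fdr, _ = bh_fdr(np.array([0.3]), m=1)
        assert p_fdr[0] == pytest.approx(0.3)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_fdr(np.array([0.5, 1.2]))

    def test_family_smaller_than_vector_rejected(self):
        with pytest.raises(ValueError, match="smaller"):
            bh_fdr(np.array([0.1, 0.2]), m=1)

    def test_matches_brute_force_stepup_oracle(self):
        """1000 random p-vectors against an O(n^2) step-up oracle."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(1, 30))
            m = n + int(rng.integers(0, 10))
            p = np.round(rng.uniform(0, 1, n), 3)  # ties on purpose
            p_fdr, survivors = bh_fdr(p, m=m, alpha=0.05)
            order = np.argsort(p, kind="stable")
            expected = np.empty(n)
            for pos, idx in enumerate(order):
                candidates = [
                    m * p[order[j]] / (j + 1) for j in range(pos, n)
                ]
                expected[idx] = min(1.0, min(candidates))
            np.testing.assert_allclose(p_fdr, expected, atol=1e-12)
            assert set(survivors) == set(np.flatnonzero(expected <= 0.05))

    def test_matches_statsmodels_when_family_complete(self):
        rng = np.random.default_rng(77)
        for _ in range(50):
            p = rng.uniform(0, 1, int(rng.integers(2, 40)))
            p_fdr, _ = bh_fdr(p)
            _, sm_adj, _, _ = multipletests(p, method="fdr_bh")
            np.testing.assert_allclose(p_fdr, sm_adj, atol=1e-12)

    def test_adjustment_preserves_raw_order(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(0, 1, 30)
        p_fdr, _ = bh_fdr(p, m=55)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(p_fdr[order]) >= -1e-15)
        assert np.all(p_fdr >= p)


class TestDefineCoi:
    def _table(self, p_raw, m=None):
        p_raw = np.asarray(p_raw, dtype=float)
        config = StatsConfig(n_edges=m)
        p_fdr, _ = bh_fdr(p_raw, m=m if m else len(p_raw), alpha=config.alpha)
        return pd.DataFrame(
            {
                "region_1": [f"r{i}" for i in range(len(p_raw))],
                "region_2": ["x"] * len(p_raw),
                "t_statistic": 1.0,
                "p_raw": p_raw,
                "p_fdr": p_fdr,
                "ewd": 0.1,
            }
        )

    def test_published_family_gives_twelve_survivors(self):
        coi = define_coi(self._table(PRINTED_RAW_P, m=55))
        assert len(coi) == 12

    def test_all_null_gives_empty_coi_with_warning(self):
        with pytest.warns(UserWarning, match="empty COI"):
            coi = define_coi(self._table(np.ones(5)))
        assert coi.empty

    def test_alpha_one_keeps_every_edge(self):
        table = self._table([0.2, 0.99, 0.5])
        coi = define_coi(table, StatsConfig(alpha=0.999999))
        assert len(coi) == 3

    def test_sorted_by_region_labels(self):
        coi = define_coi(self._table([0.001, 0.0001, 0.002]))
        assert list(coi["region_1"]) == sorted(coi["region_1"])


class TestZConversion:
    def test_median_maps_to_zero(self):
        assert pval_to_z(0.5) == pytest.approx(0.0, abs=1e-12)

    def test_p01_maps_to_published_threshold(self):
        z = pval_to_z(0.1)
        assert z == pytest.approx(1.2816, abs=5e-5)
        assert round(z, 1) == 1.3

    def test_antisymmetric_around_half(self):
        assert pval_to_z(0.9) == pytest.approx(-pval_to_z(0.1))

    def test_monotone_decreasing(self):
        ps = np.linspace(0.01, 0.99, 25)
        zs = [pval_to_z(p) for p in ps]
        assert all(a > b for a, b in zip(zs, zs[1:]))

    def test_tiny_p_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            z = pval_to_z(1e-300)
        assert np.isfinite(z)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            pval_to_z(1.5)


class TestGroupZDifference:
    def test_equal_scores_give_zero(self):
        z, p = group_z_difference(1.7, 1.7)
        assert z == 0.0
        assert p == pytest.approx(0.5)

    def test_hand_example_sqrt2_standardization(self):
        z, _ = group_z_difference(1.838477, 0.0)
        assert round(z, 4) == 1.3

    def test_swapping_groups_negates(self):
        z_ab, _ = group_z_difference(2.0, 0.5)
        z_ba, _ = group_z_difference(0.5, 2.0)
        assert z_ab == pytest.approx(-z_ba)

    def test_threshold_config_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            GroupDiffConfig(z_threshold=2.5, p_threshold=0.1)


class TestMusicEffectTest:
    def test_identical_groups_are_null(self):
        rng = np.random.default_rng(12)
        diffs = rng.uniform(0.0, 0.2, 5)
        m1, m2 = _paired_sets(diffs)
        c1 = {f"s{i}": _connectome(m1[f"s{i}"].matrix[0, 1]) for i in range(5)}
        c2 = {f"s{i}": _connectome(m2[f"s{i}"].matrix[0, 1]) for i in range(5)}
        result = music_effect_test(m1, m2, c1, c2, [("a", "b")])
        assert result.loc[0, "z_diff"] == pytest.approx(0.0, abs=1e-10)
        assert not result.loc[0, "significant"]

    def test_empty_coi_rejected(self):
        m1, m2 = _paired_sets([0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="empty"):
            music_effect_test(m1, m2, m1, m2, [])

    def test_unknown_coi_edge_rejected(self):
        m1, m2 = _paired_sets([0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="unknown region"):
            music_effect_test(m1, m2, m1, m2, [("a", "nope")])


class TestConfigs:
    def test_stats_config_validates_alpha(self):
        with pytest.raises(ValueError):
            StatsConfig(alpha=0.0)

    def test_stats_config_validates_sides(self):
        with pytest.raises(ValueError):
            StatsConfig(coi_test_sides="lower")
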