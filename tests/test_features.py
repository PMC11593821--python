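import itertools
import math

import numpy as np
import pandas as pd
import pytest

from hyperflux.features import (
    build_feature_table,
    compare_all_groups,
    mann_whitney_u,
    redox_ratio,
    roi_mean_abundances,
    significance_stars,
)
from hyperflux.io_core import Group
from hyperflux.segment import LabelMask
from hyperflux.unmix import AbundanceMaps


def exact_mw_p(a, b):
    """Full-enumeration two-sided Mann-Whitney p (tie-free samples).

    Enumerates every split of the pooled sample, builds the exact null
    distribution of U, and doubles the smaller tail (capped at 1).
    """
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = {v: r for r, v in enumerate(sorted(pooled), start=1)}
    u_null = []
    for combo in itertools.combinations(range(len(pooled)), n_a):
        r_sum = sum(ranks[pooled[i]] for i in combo)
        u_null.append(r_sum - n_a * (n_a + 1) / 2)
    u_null = np.array(u_null)
    r_obs = sum(ranks[v] for v in a)
    u_obs = r_obs - n_a * (n_a + 1) / 2
    p_le = np.mean(u_null <= u_obs)
    p_ge = np.mean(u_null >= u_obs)
    return min(1.0, 2.0 * min(p_le, p_ge))


class TestRoiMeans:
    def _maps(self, values):
        return AbundanceMaps(maps=values, names=["NAD(P)H", "flavins", "collagen"], normalisation="raw")

    def test_constant_roi_mean(self):
        maps = self._maps(np.full((3, 4, 4), 0.4))
        labels = np.zeros((4, 4), dtype=np.int32)
        labels[1:3, 1:3] = 1
        out = roi_mean_abundances(maps, LabelMask(labels=labels, kind="cell"))
        assert out.loc[1, "NAD(P)H"] == pytest.approx(0.4)

    def test_two_pixel_mean(self):
        vals = np.zeros((3, 1, 2))
        vals[0, 0, :] = [0.2, 0.6]
        labels = np.ones((1, 2), dtype=np.int32)
        out = roi_mean_abundances(self._maps(vals), LabelMask(labels=labels, kind="cell"))
        assert out.loc[1, "NAD(P)H"] == pytest.approx(0.4)

    def test_shape_mismatch_rejected(self):
        maps = self._maps(np.zeros((3, 4, 4)))
        with pytest.raises(ValueError):
            roi_mean_abundances(maps, LabelMask(labels=np.zeros((5, 5), dtype=np.int32), kind="cell"))


class TestRedoxRatio:
    @pytest.mark.parametrize("a,f,expected", [(0.6, 0.3, 2.0), (0.5, 0.5, 1.0)])
    def test_ratio_arithmetic(self, a, f, expected):
        value, valid = redox_ratio(a, f)
        assert valid and value == pytest.approx(expected)

    def test_zero_flavins_flagged_excluded(self):
        value, valid = redox_ratio(0.4, 0.0)
        assert not valid and math.isnan(value)

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            redox_ratio(-0.1, 0.5)


class TestFeatureTable:
    def _patient(self, pid, group, n_cells, n_fibres, rng):
        size = 12
        maps = AbundanceMaps(
            maps=rng.uniform(0.1, 0.4, (3, size, size)),
            names=["NAD(P)H", "flavins", "collagen"],
            normalisation="raw",
        )
        cell_labels = np.zeros((size, size), dtype=np.int32)
        for k in range(n_cells):
            cell_labels[k, 0:2] = k + 1
        fibre_labels = np.zeros((size, size), dtype=np.int32)
        for k in range(n_fibres):
            fibre_labels[k, 4:7] = k + 1
        masks = {
            "cell": LabelMask(labels=cell_labels, kind="cell"),
            "fibre": LabelMask(labels=fibre_labels, kind="fibre"),
        }
        return (pid, group, maps, masks)

    def test_record_counts_per_kind(self, rng):
        table = build_feature_table([self._patient("P1", Group.IA_LOW, 5, 3, rng)])
        assert len(table) == 8
        assert (table["kind"] == "cell").sum() == 5
        assert (table["kind"] == "fibre").sum() == 3

    def test_total_records_equal_total_rois(self, rng):
        patients = [
            self._patient("P1", Group.IA_LOW, 4, 2, rng),
            self._patient("P2", Group.RA_HIGH, 3, 5, rng),
        ]
        table = build_feature_table(patients)
        assert len(table) == 4 + 2 + 3 + 5

    def test_patient_without_rois_skipped_with_warning(self, rng):
        patients = [self._patient("P1", Group.IA_LOW, 0, 0, rng)]
        with pytest.warns(UserWarning, match="no ROIs"):
            table = build_feature_table(patients)
        assert table.empty

    def test_invariant_to_roi_label_order(self, rng):
        pid, group, maps, masks = self._patient("P1", Group.IA_LOW, 4, 0, rng)
        relabelled = masks["cell"].labels.copy()
        for old, new in zip((1, 2, 3, 4), (4, 3, 2, 1)):
            relabelled[masks["cell"].labels == old] = new
        masks2 = {"cell": LabelMask(labels=relabelled, kind="cell"), "fibre": masks["fibre"]}
        t1 = build_feature_table([(pid, group, maps, masks)])
        t2 = build_feature_table([(pid, group, maps, masks2)])
        cols = ["a_nadph", "a_flavins", "a_collagen"]
        assert np.allclose(
            np.sort(t1[cols].to_numpy(), axis=0), np.sort(t2[cols].to_numpy(), axis=0)
        )


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        comp = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert comp.u_statistic == 0.0
        assert comp.p_value == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples(self):
        a = [1.0, 2.0, 3.0, 4.0]
        comp = mann_whitney_u(a, a)
        assert comp.u_statistic == pytest.approx(len(a) ** 2 / 2)
        assert comp.p_value == pytest.approx(1.0)

    def test_exact_p_matches_enumeration_oracle(self, rng):
        for _ in range(40):
            n_a = int(rng.integers(2, 7))
            n_b = int(rng.integers(2, 7))
            pooled = rng.permutation(np.arange(1.0, n_a + n_b + 1.0) * rng.uniform(0.5, 2.0))
            a, b = pooled[:n_a], pooled[n_a:]
            comp = mann_whitney_u(a, b)
            assert comp.p_value == pytest.approx(exact_mw_p(a, b), abs=1e-12)

    def test_exact_and_asymptotic_agree_at_eight_per_group(self, rng):
        # the continuity correction itself shifts mid-range p by up to
        # ~0.011 at n=8+8, which bounds the achievable agreement
        from scipy import stats

        for _ in range(20):
            pooled = rng.normal(size=16)
            a, b = pooled[:8], pooled[8:]
            exact = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
            approx = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue
            assert abs(exact - approx) < 0.011

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    @pytest.mark.parametrize(
        "p,stars", [(0.04, "*"), (0.009, "**"), (0.0009, "***"), (0.2, "ns")]
    )
    def test_significance_stars(self, p, stars):
        assert significance_stars(p) == stars


class TestGroupComparisons:
    def _table(self, rng):
        rows = []
        for g, shift in (("IA_LOW", 0.0), ("IA_MID", 0.05), ("RA_MID", 0.2), ("RA_HIGH", 0.25)):
            for i in range(10):
                a_n = 0.3 + shift + rng.normal(0, 0.02)
                a_f = 0.3 - shift / 2 + rng.normal(0, 0.02)
                rows.append(
                    {
                        "patient_id": f"{g}_{i // 5}",
                        "roi_id": i,
                        "kind": "cell",
                        "a_nadph": a_n,
                        "a_flavins": a_f,
                        "a_collagen": 0.2,
                        "redox_ratio": a_n / a_f,
                        "redox_valid": True,
                        "group": g,
                    }
                )
        return pd.DataFrame(rows)

    def test_four_groups_four_features_gives_24_comparisons(self, rng):
        comp = compare_all_groups(self._table(rng), "cell")
        assert len(comp) == 24

    def test_single_stratum_requirement(self, rng):
        table = self._table(rng)
        table["group"] = "IA_LOW"
        with pytest.raises(ValueError):
            compare_all_groups(table, "cell")

    def test_clear_separation_is_significant(self, rng):
        comp = compare_all_groups(self._table(rng), "cell")
        row = comp[
            (comp.feature == "a_nadph")
            & (comp.group_a == "IA_LOW")
            & (comp.group_b == "RA_HIGH")
        ].iloc[0]
        assert row.p < 0.001

    def test_cohort_redox_direction_reproduced(self, cohort_table):
        """Mean redox ratio higher in active (RA) than inactive groups, both strata."""
        for kind in ("cell", "fibre"):
            sub = cohort_table[(cohort_table.kind == kind) & cohort_table.redox_valid]
            means = sub.groupby("group")["redox_ratio"].mean()
            assert min(means["RA_MID"], means["RA_HIGH"]) > max(
                means["IA_LOW"], means["IA_MID"]
            )

    def test_single_patient_group_still_compared(self, cohort_table):
        comp = compare_all_groups(cohort_table, "cell")
        ia_mid = comp[(comp.group_a == "IA_MID") | (comp.group_b == "IA_MID")]
        assert len(ia_mid) > 0
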