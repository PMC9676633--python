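import math

import numpy as np
import pandas as pd
import pytest

from cladediv.indices import (
    GlobalFloor,
    HousekeepingBaseline,
    NON_DIVERGING,
    aggregate_global,
    aggregate_population,
    compute_global_floor,
    filter_diverging_markers,
    housekeeping_baseline,
    log_ratio_index,
    sample_indices,
    validate_baselines,
)
from cladediv.markers import MarkerCatalog
from cladediv.profiling import CohortMetadata


@pytest.fixture()
def catalog():
    return MarkerCatalog(
        markers={"A": ["mA0", "mA1", "mA2"]},
        housekeeping=["hk0", "hk1"],
        core=["c0"],
        sequences={},
    )


def stats_frame(rows):
    return pd.DataFrame(
        rows,
        columns=["sample_id", "gene_id", "snp_count", "length_bp", "snp_per_base",
                 "dn", "ds", "omega", "omega_valid"],
    )


class TestLogRatioIndex:
    def test_equal_nonzero_arguments_give_zero(self):
        assert log_ratio_index(0.01, 0.01).value == 0.0

    def test_both_zero_rule(self):
        res = log_ratio_index(0.0, 0.0)
        assert res.value == 0.0 and res.flag == "both_zero"

    def test_denominator_zero_uses_floor(self):
        res = log_ratio_index(0.03, 0.0, floor=0.01)
        assert res.value == pytest.approx(math.log(3))
        assert res.flag == "floor_substituted"

    def test_denominator_zero_without_floor_is_an_error(self):
        with pytest.raises(ValueError, match="floor"):
            log_ratio_index(0.03, 0.0)

    def test_numerator_zero_is_non_diverging_sentinel(self):
        res = log_ratio_index(0.0, 0.01)
        assert res.value == NON_DIVERGING and res.flag == "non_diverging"

    @pytest.mark.parametrize("num,den", [(0.02, 0.01), (0.01, 0.02), (1.0, 1.0),
                                         (0.5, 0.001), (1e-6, 1e-3)])
    def test_sign_matches_log_ratio(self, num, den):
        v = log_ratio_index(num, den).value
        assert np.sign(v) == np.sign(math.log(num / den))

    def test_negative_rates_rejected(self):
        with pytest.raises(ValueError):
            log_ratio_index(-0.1, 0.1)

    def test_monotone_in_numerator(self):
        values = [log_ratio_index(x, 0.01).value for x in (0.005, 0.01, 0.02, 0.04)]
        assert values == sorted(values)
        assert all(values[i] < values[i + 1] for i in range(len(values) - 1))


class TestHousekeepingBaseline:
    def test_median_and_mean_of_valid_omegas(self, catalog):
        rows = [
            ("s1", "hk0", 1, 1000, 0.001, 0.1, 0.2, 0.1, True),
            ("s1", "hk1", 1, 1000, 0.001, 0.1, 0.2, 0.3, True),
        ]
        bl = housekeeping_baseline(stats_frame(rows), catalog, "s1")
        assert bl.M_H == 0.001
        assert bl.mu_H == pytest.approx(0.2)
        assert bl.n_hk_used == 2

    def test_invalid_omegas_excluded_from_mean(self, catalog):
        rows = [
            ("s1", "hk0", 0, 1000, 0.0, 0.0, 0.0, float("nan"), False),
            ("s1", "hk1", 1, 1000, 0.002, 0.1, 0.2, 0.4, True),
        ]
        bl = housekeeping_baseline(stats_frame(rows), catalog, "s1")
        assert bl.mu_H == pytest.approx(0.4)

    def test_all_zero_rates_give_zero_MH(self, catalog):
        rows = [("s1", g, 0, 1000, 0.0, 0.0, 0.0, float("nan"), False)
                for g in ("hk0", "hk1")]
        bl = housekeeping_baseline(stats_frame(rows), catalog, "s1")
        assert bl.M_H == 0.0

    def test_missing_housekeeping_stats_is_an_error(self, catalog):
        with pytest.raises(ValueError, match="housekeeping"):
            housekeeping_baseline(stats_frame([]), catalog, "s1")


class TestGlobalFloor:
    def test_smallest_nonzero_values(self):
        floors = compute_global_floor([
            HousekeepingBaseline("s1", 0.0, 0.5, 10),
            HousekeepingBaseline("s2", 0.003, 0.2, 10),
            HousekeepingBaseline("s3", 0.001, float("nan"), 10),
        ])
        assert floors.min_MH == 0.001
        assert floors.min_muH == 0.2


class TestSampleIndices:
    def _baseline(self):
        return HousekeepingBaseline("s1", 0.002, 0.2, 2)

    def test_equal_rates_give_zero_and_ln2_case(self, catalog):
        rows = [
            ("s1", "mA0", 2, 1000, 0.002, 0.05, 0.2, 0.4, True),
            ("s1", "hk0", 2, 1000, 0.002, 0.02, 0.2, 0.2, True),
            ("s1", "hk1", 2, 1000, 0.002, 0.02, 0.2, 0.2, True),
        ]
        table = sample_indices(stats_frame(rows), self._baseline(), catalog,
                               GlobalFloor(0.001, 0.1))
        gene_row = table[(table.level == "gene") & (table.key == "mA0")].iloc[0]
        assert gene_row.DRI == pytest.approx(0.0)        # M_G = M_H
        assert gene_row.NDRI == pytest.approx(math.log(2))  # 0.4 / 0.2
        clade_row = table[(table.level == "clade") & (table.key == "A")].iloc[0]
        assert clade_row.DRI == pytest.approx(0.0)

    def test_unobserved_clade_flagged_missing_not_zero(self, catalog):
        rows = [("s1", "hk0", 2, 1000, 0.002, 0.02, 0.2, 0.2, True)]
        table = sample_indices(stats_frame(rows), self._baseline(), catalog,
                               GlobalFloor(0.001, 0.1))
        clade_row = table[(table.level == "clade") & (table.key == "A")].iloc[0]
        assert clade_row.DRI_flag == "missing" and math.isnan(clade_row.DRI)

    def test_scale_invariance_of_indices(self, catalog):
        rows = [
            ("s1", "mA0", 4, 1000, 0.004, 0.05, 0.2, 0.4, True),
            ("s1", "mA1", 6, 1000, 0.006, 0.05, 0.2, 0.4, True),
            ("s1", "hk0", 2, 1000, 0.002, 0.02, 0.2, 0.2, True),
            ("s1", "hk1", 3, 1000, 0.003, 0.02, 0.2, 0.2, True),
        ]
        base = stats_frame(rows)
        scaled = base.copy()
        scaled["snp_per_base"] *= 7.0
        from cladediv.indices import housekeeping_baseline as hb

        t1 = sample_indices(base, hb(base, catalog, "s1"), catalog, GlobalFloor(1e-4, 0.1))
        t2 = sample_indices(scaled, hb(scaled, catalog, "s1"), catalog, GlobalFloor(1e-4, 0.1))
        pd.testing.assert_series_equal(t1["DRI"], t2["DRI"], atol=1e-12)


class TestAggregation:
    def _table(self, rows):
        return pd.DataFrame(
            rows, columns=["sample_id", "level", "key", "clade",
                           "DRI", "DRI_flag", "NDRI", "NDRI_flag"],
        )

    def test_median_of_symmetric_values_is_zero(self):
        table = self._table([
            (f"s{i}", "gene", "g1", "A", v, "ok", v, "ok")
            for i, v in enumerate([-1.0, 0.0, 1.0])
        ])
        out = aggregate_global(table)
        assert out.iloc[0].median_DRI == 0.0

    def test_single_sample_equals_global(self):
        table = self._table([("s0", "clade", "A", "A", 0.7, "ok", 0.3, "ok")])
        out = aggregate_global(table)
        assert out.iloc[0].median_DRI == 0.7 and out.iloc[0].median_NDRI == 0.3

    def test_order_invariance(self):
        rows = [(f"s{i}", "gene", "g1", "A", float(i), "ok", float(-i), "ok")
                for i in range(7)]
        a = aggregate_global(self._table(rows))
        b = aggregate_global(self._table(rows[::-1]))
        pd.testing.assert_frame_equal(a, b)

    def test_population_aggregation_recovers_planted_multipliers(self):
        rows = []
        for i in range(20):
            pop_val = 1.0 if i % 2 == 0 else 0.0  # planted ln-ratios e vs 1
            rows.append((f"s{i}", "clade", "A", "A", pop_val, "ok", pop_val, "ok"))
        table = self._table(rows)
        meta = CohortMetadata.from_frame(pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(20)],
            "population": ["fast" if i % 2 == 0 else "slow" for i in range(20)],
            "lifestyle": ["rural"] * 20,
            "age_group": ["adult"] * 20,
        }))
        out = aggregate_population(table, meta)
        fast = out[out.population == "fast"].iloc[0]
        slow = out[out.population == "slow"].iloc[0]
        assert fast.median_DRI == pytest.approx(1.0)
        assert slow.median_DRI == pytest.approx(0.0)
        # one population == global aggregation
        solo = table[table.sample_id.isin([f"s{i}" for i in range(0, 20, 2)])]
        g = aggregate_global(solo)
        assert g.iloc[0].median_DRI == fast.median_DRI

    def test_non_diverging_sentinel_participates_as_lowest_rank(self):
        table = self._table([
            ("s0", "gene", "g1", "A", NON_DIVERGING, "non_diverging", 0.1, "ok"),
            ("s1", "gene", "g1", "A", 0.5, "ok", 0.1, "ok"),
            ("s2", "gene", "g1", "A", 0.9, "ok", 0.1, "ok"),
        ])
        out = aggregate_global(table)
        assert out.iloc[0].median_DRI == 0.5  # sentinel ranks lowest


class TestDivergingFilter:
    def _global(self, rows):
        return pd.DataFrame(
            rows, columns=["level", "key", "clade", "median_DRI", "median_NDRI"],
        )

    def test_strict_positivity(self):
        table = self._global([
            ("gene", "g1", "A", 0.5, 0.0),   # excluded: NDRIg not > 0
            ("gene", "g2", "A", 0.5, 0.2),   # included
            ("gene", "g3", "A", 0.0, 0.2),   # excluded: DRIg not > 0
            ("gene", "g4", "B", -0.1, 0.5),  # excluded
            ("clade", "A", "A", 1.0, 1.0),   # not a gene row
        ])
        out = filter_diverging_markers(table)
        assert list(out.gene_id) == ["g2"]
        assert list(out.clade) == ["A"]


class TestValidateBaselines:
    def _baselines(self, mh):
        return [HousekeepingBaseline(f"s{i}", m, 0.2 + 0.01 * i, 10)
                for i, m in enumerate(mh)]

    def test_perfect_correlation_detected(self):
        lengths = np.arange(10) * 1e8 + 1e9
        mh = lengths * 1e-12
        manifests = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(10)],
            "metagenome_size_bp": lengths,
        })
        out = validate_baselines(self._baselines(mh), manifests)
        row = out[(out.metric == "M_H") & (out.against == "metagenome_length")].iloc[0]
        assert row.r == pytest.approx(1.0)
        assert row.bias_warning

    def test_constant_baseline_reports_zero_variance(self):
        manifests = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(5)],
            "metagenome_size_bp": np.arange(5) * 1e8 + 1e9,
        })
        out = validate_baselines(self._baselines([0.001] * 5), manifests)
        row = out[(out.metric == "M_H")].iloc[0]
        assert row.note == "zero_variance" and not row.bias_warning

    def test_too_few_samples_is_an_error(self):
        manifests = pd.DataFrame({
            "sample_id": ["s0"], "metagenome_size_bp": [1e9],
        })
        with pytest.raises(ValueError):
            validate_baselines(self._baselines([0.001]), manifests)
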