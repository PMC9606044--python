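import numpy as np
import pandas as pd
import pytest
from scipy import stats

from ambarpet.defects import classify_defects
from ambarpet.regional import (
    cross_sectional_group_tests,
    extract_regional_metrics,
    longitudinal_region_tests,
    percentage_of_regions,
)

from conftest import make_volume
from _oracles import regional_loop


@pytest.mark.parametrize(
    "count,total,expected",
    [
        (21, 116, 18.1),
        (58, 116, 50.0),
        (44, 116, 37.9),
        (29, 116, 25.0),
        (36, 116, 31.0),
        (47, 116, 40.5),
        (4, 15, 26.7),
        (9, 15, 60.0),
        (8, 15, 53.3),
        (3, 15, 20.0),
    ],
)
def test_count_to_percentage_arithmetic(count, total, expected):
    assert percentage_of_regions(count, total) == expected


class TestExtraction:
    def test_fully_masked_region_is_missing_not_zero(self, small_phantom, rng):
        atlas, uptake, _ = small_phantom
        z = uptake.like(rng.normal(-1, 1, uptake.shape))
        mask = ~atlas.region_mask([5])  # region 5 entirely excluded
        dm = classify_defects(z, mask)
        df = extract_regional_metrics(dm, uptake, atlas).set_index("region_id")
        assert np.isnan(df.loc[5, "metabolism_intensity"])
        assert np.isnan(df.loc[5, "defect_extension"])
        assert df.loc[5, "n_voxels"] == 0

    def test_defect_extension_arithmetic(self):
        labels = np.ones((5, 5, 4), dtype=np.int32)  # 100-voxel single region
        regions = pd.DataFrame(
            {"region_id": [1], "name": ["r1"], "lobe": ["o"], "cerebellum_flag": [True]}
        )
        from ambarpet.core import AtlasParcellation

        atlas = AtlasParcellation(labels, regions, (4.0, 4.0, 4.0))
        z = np.zeros((5, 5, 4))
        z.ravel()[:25] = -2.5  # exactly 25 defect voxels
        dm = classify_defects(make_volume(z), np.ones(z.shape, bool))
        df = extract_regional_metrics(dm, make_volume(np.ones(z.shape)), atlas)
        assert df.loc[0, "defect_extension"] == pytest.approx(25.0)

    def test_matches_per_region_voxel_loop(self, small_phantom, rng):
        atlas, uptake, gm = small_phantom
        z = uptake.like(rng.normal(-1.5, 1.2, uptake.shape))
        mask = gm.data >= 0.5
        dm = classify_defects(z, mask)
        scan = uptake.like(rng.uniform(0.5, 1.5, uptake.shape))
        df = extract_regional_metrics(dm, scan, atlas).set_index("region_id")
        oracle = regional_loop(atlas.labels, mask, scan.data, dm.defect, dm.severity, atlas.region_ids)
        for rid, (mi, de, di) in oracle.items():
            row = df.loc[rid]
            if np.isnan(mi):
                assert np.isnan(row["metabolism_intensity"])
            else:
                assert row["metabolism_intensity"] == pytest.approx(mi, abs=1e-12)
                assert row["defect_extension"] == pytest.approx(de, abs=1e-12)
                assert row["defect_intensity"] == pytest.approx(di, abs=1e-12)


def _tidy(values: dict[str, dict[int, float]], visit: str) -> pd.DataFrame:
    rows = []
    for subj, per_region in values.items():
        for rid, v in per_region.items():
            rows.append((subj, visit, rid, v, 0.0, 0.0, 10))
    return pd.DataFrame(
        rows,
        columns=["subject", "visit", "region_id", "metabolism_intensity",
                 "defect_extension", "defect_intensity", "n_voxels"],
    )


class TestLongitudinalTests:
    def test_no_change_means_no_significant_regions(self):
        vals = {f"s{i}": {1: 1.0, 2: 2.0, 3: 3.0} for i in range(6)}
        summ = longitudinal_region_tests(_tidy(vals, "M0"), _tidy(vals, "M14"), "metabolism_intensity")
        assert summ.n_significant == 0
        assert summ.pct_of_regions == 0.0

    def test_known_paired_t_per_region(self, rng):
        t0 = {f"s{i}": {1: 1.0, 2: 1.0} for i in range(8)}
        t1 = {f"s{i}": {1: 1.0 - 0.2 - 0.01 * rng.standard_normal(), 2: 1.0 + 0.01 * rng.standard_normal()}
              for i in range(8)}
        a, b = _tidy(t0, "M0"), _tidy(t1, "M14")
        summ = longitudinal_region_tests(a, b, "metabolism_intensity")
        d1 = np.array([t1[f"s{i}"][1] - 1.0 for i in range(8)])
        expected_p = stats.ttest_rel(d1, np.zeros(8)).pvalue
        assert summ.p_values[1] == pytest.approx(expected_p, rel=1e-12)
        assert 1 in summ.significant_region_ids

    def test_too_few_pairs_rejected(self):
        vals = {f"s{i}": {1: 1.0} for i in range(2)}
        with pytest.raises(ValueError, match="paired subjects"):
            longitudinal_region_tests(_tidy(vals, "M0"), _tidy(vals, "M14"), "metabolism_intensity")


class TestCrossSectionalAnova:
    def test_two_group_f_equals_squared_t(self, rng):
        a = {f"a{i}": {1: float(rng.normal(1.0, 0.1))} for i in range(8)}
        b = {f"b{i}": {1: float(rng.normal(1.0, 0.1))} for i in range(8)}
        res = cross_sectional_group_tests(
            {"armA": _tidy(a, "M0"), "armB": _tidy(b, "M0")}, "metabolism_intensity"
        )
        xa = np.array([v[1] for v in a.values()])
        xb = np.array([v[1] for v in b.values()])
        t = stats.ttest_ind(xa, xb).statistic
        assert res.loc[0, "F"] == pytest.approx(t**2, abs=1e-10)

    def test_type_one_error_rate_under_permutation(self, rng):
        pooled = rng.normal(1.0, 0.1, size=(200, 16))
        rejections = 0
        for rep in range(200):
            x = pooled[rep]
            a = {f"a{i}": {1: float(x[i])} for i in range(8)}
            b = {f"b{i}": {1: float(x[8 + i])} for i in range(8)}
            res = cross_sectional_group_tests(
                {"armA": _tidy(a, "M0"), "armB": _tidy(b, "M0")}, "metabolism_intensity"
            )
            rejections += int(res.loc[0, "significant"])
        rate = rejections / 200
        se = np.sqrt(0.05 * 0.95 / 200)
        assert abs(rate - 0.05) < 3 * se + 1e-9

    def test_single_arm_rejected(self):
        vals = {f"s{i}": {1: 1.0} for i in range(4)}
        with pytest.raises(ValueError):
            cross_sectional_group_tests({"only": _tidy(vals, "M0")}, "metabolism_intensity")
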