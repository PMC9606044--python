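import numpy as np
import pytest

from ambarpet.cohort import ArmSpec, CohortSpec, StratumSpec, sample_patient_series
from ambarpet.defects import (
    CLASS_IMPROVED,
    CLASS_MAINTAINED,
    CLASS_OUTSIDE,
    CLASS_WORSENED,
    baseline_group_pattern,
    build_correction_mask,
    classify_defects,
    classify_longitudinal,
    compute_zmap,
)
from ambarpet.template import build_template

from conftest import make_volume
from _oracles import severity_loop, zmap_loop


def _make_template(mean_val, sd_val, shape=(6, 6, 6)):
    from ambarpet.template import NormalTemplate

    mean = make_volume(np.full(shape, mean_val))
    sd = make_volume(np.full(shape, sd_val))
    return NormalTemplate(mean=mean, sd=sd, n_controls=48, fwhm_mm=8.0, sd_floor=sd_val)


class TestZMap:
    def test_arithmetic(self):
        tpl = _make_template(1.0, 0.1)
        scan = make_volume(np.full((6, 6, 6), 0.8))
        z = compute_zmap(scan, tpl)
        assert np.allclose(z.data, -2.0)

    def test_identity_gives_zero(self):
        tpl = _make_template(1.0, 0.1)
        z = compute_zmap(tpl.mean, tpl)
        assert np.allclose(z.data, 0.0)

    def test_matches_voxel_loop_oracle(self, rng):
        shape = (10, 10, 10)
        mean = rng.uniform(0.5, 1.5, shape)
        mean[rng.random(shape) < 0.2] = 0.0  # out-of-brain voxels
        sd = rng.uniform(0.05, 0.2, shape)
        from ambarpet.template import NormalTemplate

        tpl = NormalTemplate(make_volume(mean), make_volume(sd), 10, 8.0, 0.05)
        scan = make_volume(rng.uniform(0.3, 1.6, shape))
        z = compute_zmap(scan, tpl)
        assert np.array_equal(z.data, zmap_loop(scan.data, mean, sd))

    def test_grid_mismatch_rejected(self):
        tpl = _make_template(1.0, 0.1)
        with pytest.raises(ValueError, match="shape"):
            compute_zmap(make_volume(np.zeros((5, 5, 5))), tpl)


class TestCorrectionMask:
    def test_full_probability_gives_full_mask(self):
        assert build_correction_mask(make_volume(np.ones((4, 4, 4)))).all()

    def test_boundary_convention_is_inclusive(self):
        p = np.full((4, 4, 4), 0.5)
        p[0, 0, 0] = 0.49
        mask = build_correction_mask(make_volume(p), 0.5)
        assert not mask[0, 0, 0]
        assert mask.sum() == 63

    def test_out_of_range_probability_rejected(self):
        with pytest.raises(ValueError, match=r"\[0,1\]"):
            build_correction_mask(make_volume(np.full((2, 2, 2), 1.2)))

    def test_atrophy_strictly_shrinks_mask(self, small_spec, small_phantom):
        cohort = CohortSpec(
            arms=(ArmSpec("placebo", 0.0, 2),),
            severity_strata={"mild": StratumSpec(1.0, 0.0)},
            atrophy_rate=0.08,
            seed=5,
        )
        records, _ = sample_patient_series(small_spec, cohort, small_phantom)
        counts = [
            int(build_correction_mask(records[0].gm_maps[v]).sum())
            for v in cohort.visits
        ]
        assert all(a > b for a, b in zip(counts, counts[1:]))


class TestDefectClassification:
    def test_boundary_z_is_a_defect(self):
        z = make_volume(np.array([[[-2.0, -1.99, -3.0, -4.0, 0.0]]]))
        dm = classify_defects(z, np.ones(z.shape, bool))
        assert dm.defect[0, 0, 0] and dm.severity[0, 0, 0] == 1
        assert not dm.defect[0, 0, 1] and dm.severity[0, 0, 1] == 0
        assert dm.severity[0, 0, 2] == 2
        assert dm.severity[0, 0, 3] == 3

    def test_histogram_matches_brute_force_binning(self, rng):
        z = make_volume(rng.normal(-1.5, 1.5, (12, 12, 12)))
        mask = rng.random((12, 12, 12)) > 0.3
        dm = classify_defects(z, mask)
        oracle = severity_loop(z.data, mask, (-2.0, -3.0, -4.0))
        assert np.array_equal(dm.severity.astype(int), oracle)
        assert np.array_equal(dm.defect, (z.data <= -2.0) & mask)

    def test_severity_zero_outside_mask(self, rng):
        z = make_volume(np.full((4, 4, 4), -5.0))
        mask = np.zeros((4, 4, 4), bool)
        dm = classify_defects(z, mask)
        assert not dm.defect.any() and not dm.severity.any()

    def test_severity_anti_monotone_in_z(self, rng):
        z = make_volume(rng.uniform(-6, 1, (8, 8, 8)))
        dm = classify_defects(z, np.ones(z.shape, bool))
        flat_z = z.data.ravel()
        flat_s = dm.severity.ravel()
        order = np.argsort(flat_z)
        assert np.all(np.diff(flat_s[order].astype(int)) <= 0)

    def test_non_monotone_bins_rejected(self):
        z = make_volume(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError, match="decreasing"):
            classify_defects(z, np.ones(z.shape, bool), severity_bins=(-2.0, -1.5))
        with pytest.raises(ValueError, match="start"):
            classify_defects(z, np.ones(z.shape, bool), severity_bins=(-3.0, -4.0))

    def test_shrinking_mask_never_increases_defect_count(self, rng):
        z = make_volume(rng.normal(-2, 1, (10, 10, 10)))
        big = rng.random((10, 10, 10)) > 0.2
        small = big & (rng.random((10, 10, 10)) > 0.3)
        n_big = classify_defects(z, big).defect.sum()
        n_small = classify_defects(z, small).defect.sum()
        assert n_small <= n_big


class TestGroupPattern:
    def test_single_subject_identity(self, rng):
        z = make_volume(rng.normal(-2, 1, (6, 6, 6)))
        dm = classify_defects(z, np.ones(z.shape, bool))
        pattern = baseline_group_pattern([dm])
        assert np.array_equal(pattern.data, dm.severity.astype(float))

    def test_mean_of_two(self):
        z1 = make_volume(np.full((3, 3, 3), -3.5))  # severity 2
        z2 = make_volume(np.zeros((3, 3, 3)))  # severity 0
        m = np.ones((3, 3, 3), bool)
        pattern = baseline_group_pattern([classify_defects(z1, m), classify_defects(z2, m)])
        assert np.allclose(pattern.data, 1.0)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            baseline_group_pattern([])


class TestLongitudinalClassification:
    def _map(self, z_data, mask=None, visit="M0"):
        z = make_volume(np.asarray(z_data, dtype=float))
        if mask is None:
            mask = np.ones(z.shape, bool)
        return classify_defects(z, mask, visit=visit)

    def test_defect_resolution_wins_over_small_dz(self):
        # defect at baseline, normal at follow-up, dz only +0.3 -> improved
        m0 = self._map(np.full((2, 2, 2), -2.1))
        m1 = self._map(np.full((2, 2, 2), -1.8), visit="M14")
        out = classify_longitudinal(m0, m1)
        assert np.all(out.classes == CLASS_IMPROVED)

    def test_worsening_boundary_is_inclusive(self):
        m0 = self._map(np.zeros((2, 2, 2)))
        m1 = self._map(np.full((2, 2, 2), -0.5), visit="M14")
        out = classify_longitudinal(m0, m1)
        assert np.all(out.classes == CLASS_WORSENED)

    def test_improvement_boundary_is_strict(self):
        m0 = self._map(np.zeros((2, 2, 2)))
        m1 = self._map(np.full((2, 2, 2), 0.5), visit="M14")
        out = classify_longitudinal(m0, m1)
        assert np.all(out.classes == CLASS_MAINTAINED)

    def test_outside_where_mask_absent(self):
        mask = np.ones((2, 2, 2), bool)
        mask[0, 0, 0] = False
        m0 = self._map(np.zeros((2, 2, 2)), mask)
        m1 = self._map(np.zeros((2, 2, 2)), visit="M14")
        out = classify_longitudinal(m0, m1)
        assert out.classes[0, 0, 0] == CLASS_OUTSIDE
        assert (out.classes != CLASS_OUTSIDE).sum() == 7

    def test_status_change_precedence_counts_conflicts(self):
        # became a defect although its Z-score rose by > 0.5: status wins
        m0 = self._map(np.full((1, 1, 1), -2.5))
        m1 = self._map(np.full((1, 1, 1), -1.0), visit="M14")
        # -2.5 -> -1.0 is both a defect resolution and dz=+1.5: consistent
        out = classify_longitudinal(m0, m1)
        assert out.n_rule_conflicts == 0
        # defect appearing while dz > +0.5 is impossible with one template,
        # so engineer it with differing masks is not needed: use dz <= -0.5
        # with defect resolution instead (mask change makes this reachable)
        z0 = np.array([[[-2.1]]])
        z1 = np.array([[[-2.7]]])
        m0 = self._map(z0)
        dm1 = classify_defects(make_volume(z1), np.ones((1, 1, 1), bool), z_threshold=3.0,
                               severity_bins=(-3.0, -4.0), visit="M14")
        out = classify_longitudinal(m0, dm1)
        assert out.classes[0, 0, 0] == CLASS_IMPROVED  # defect -> not-defect wins
        assert out.n_rule_conflicts == 1

    def test_null_arm_symmetry_between_improved_and_worsened(self, small_spec, small_phantom):
        """With no seeded decline, improvement and worsening are exchangeable:
        their voxel fractions agree within sampling error over 20 seeds."""
        from ambarpet.cohort import sample_control_scans
        from ambarpet.preprocess import preprocess_scan

        atlas, uptake, gm = small_phantom
        mask = build_correction_mask(gm)
        controls = [
            preprocess_scan(c, atlas)
            for c in sample_control_scans(uptake, 16, 5.0, seed=99)
        ]
        tpl = build_template(controls)
        fracs = []
        for seed in range(20):
            scans = sample_control_scans(uptake, 2, 5.0, seed=1000 + seed)
            maps = [
                classify_defects(compute_zmap(preprocess_scan(s, atlas), tpl), mask, visit=v)
                for s, v in zip(scans, ("M0", "M14"))
            ]
            out = classify_longitudinal(maps[0], maps[1])
            fracs.append((out.fraction(CLASS_IMPROVED), out.fraction(CLASS_WORSENED)))
        imp = np.mean([f[0] for f in fracs])
        wor = np.mean([f[1] for f in fracs])
        assert imp == pytest.approx(wor, abs=0.02)

    def test_invalid_delta_threshold(self):
        m0 = self._map(np.zeros((2, 2, 2)))
        with pytest.raises(ValueError):
            classify_longitudinal(m0, m0, delta_threshold=0.0)
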