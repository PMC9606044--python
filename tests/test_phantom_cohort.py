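import numpy as np
import pytest
from scipy import ndimage

from ambarpet.cohort import (
    ArmSpec,
    CohortSpec,
    StratumSpec,
    load_cohort,
    sample_control_scans,
    sample_patient_series,
    visit_months,
    write_cohort,
)
from ambarpet.phantom import PhantomSpec, build_phantom


class TestPhantom:
    def test_regions_are_single_connected_components(self, small_spec, small_phantom):
        atlas, _, _ = small_phantom
        assert len(set(np.unique(atlas.labels)) - {0}) == small_spec.n_regions
        struct = ndimage.generate_binary_structure(3, 3)
        for rid in atlas.region_ids:
            _, n = ndimage.label(atlas.labels == rid, structure=struct)
            assert n == 1, f"region {rid} split into {n} components"

    def test_determinism(self, small_spec):
        a1, u1, g1 = build_phantom(small_spec)
        a2, u2, g2 = build_phantom(small_spec)
        assert np.array_equal(a1.labels, a2.labels)
        assert np.array_equal(u1.data, u2.data)
        assert np.array_equal(g1.data, g2.data)

    def test_overlapping_region_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            PhantomSpec(cerebellum_region_ids=(1, 3), ad_region_ids=(3, 4))

    def test_too_many_regions_for_grid_rejected(self):
        spec = PhantomSpec(grid_shape=(6, 6, 6), n_regions=10**4)
        with pytest.raises(ValueError, match="exceeds"):
            build_phantom(spec)

    def test_gm_probability_bounds(self, small_phantom):
        _, uptake, gm = small_phantom
        brain = uptake.data > 0
        assert gm.data[brain].min() >= 0.5
        assert gm.data[brain].max() <= 1.0
        assert np.all(gm.data[~brain] == 0)

    def test_region_table_flags(self, small_spec, small_phantom):
        atlas, _, _ = small_phantom
        assert set(atlas.cerebellum_ids()) == set(small_spec.cerebellum_region_ids)
        assert set(atlas.ad_ids()) == set(small_spec.ad_region_ids)


def _noise_free(spec: PhantomSpec) -> PhantomSpec:
    from dataclasses import replace

    return replace(spec, noise_sd=0.0)


class TestPatientSeries:
    def test_seeded_decline_is_exact_without_noise(self, small_spec, small_phantom):
        cohort = CohortSpec(
            arms=(ArmSpec("placebo", 0.06, 2),),
            severity_strata={"mild": StratumSpec(1.0, 0.0)},
            atrophy_rate=0.0,
            seed=3,
        )
        records, atlas = sample_patient_series(_noise_free(small_spec), cohort, small_phantom)
        ad = atlas.region_mask(atlas.ad_ids())
        r = records[0]
        ratio = r.scans["M14"].data[ad].mean() / r.scans["M0"].data[ad].mean()
        assert ratio == pytest.approx(0.94, abs=1e-12)

    def test_null_arm_only_differs_by_noise(self, small_spec, small_phantom):
        cohort = CohortSpec(
            arms=(ArmSpec("placebo", 0.0, 2),),
            severity_strata={"mild": StratumSpec(1.0, 0.0)},
            atrophy_rate=0.0,
            seed=3,
        )
        records, _ = sample_patient_series(_noise_free(small_spec), cohort, small_phantom)
        r = records[0]
        assert np.array_equal(r.scans["M0"].data, r.scans["M14"].data)

    def test_ground_truth_monotone_decline(self, small_spec, small_phantom):
        cohort = CohortSpec(
            arms=(ArmSpec("placebo", 0.08, 2),),
            severity_strata={"mild": StratumSpec(1.0, 0.0)},
            atrophy_rate=0.0,
            seed=3,
        )
        records, atlas = sample_patient_series(_noise_free(small_spec), cohort, small_phantom)
        ad = atlas.region_mask(atlas.ad_ids())
        means = [records[0].scans[v].data[ad].mean() for v in cohort.visits]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_default_cohort_smoke(self, small_spec, small_phantom):
        cohort = CohortSpec(seed=11)
        records, _ = sample_patient_series(small_spec, cohort, small_phantom)
        assert len(records) == 64  # 4 arms x 16 subjects
        strata = {(r.arm, r.stratum) for r in records}
        assert len(strata) == 8  # both severity strata in every arm
        for r in records[:4]:
            assert set(r.scans) == set(cohort.visits)
            for v in cohort.visits:
                assert np.all(np.isfinite(r.scans[v].data))
            assert len(r.volumetry) == len(cohort.visits)

    def test_determinism_bit_identical(self, small_spec, small_phantom):
        cohort = CohortSpec(seed=21, arms=(ArmSpec("placebo", 0.05, 4),))
        r1, _ = sample_patient_series(small_spec, cohort, small_phantom)
        r2, _ = sample_patient_series(small_spec, cohort, small_phantom)
        for a, b in zip(r1, r2):
            assert np.array_equal(a.scans["M14"].data, b.scans["M14"].data)
            assert a.volumetry.equals(b.volumetry)

    def test_unknown_visit_label_rejected(self):
        with pytest.raises(ValueError, match="visit"):
            visit_months("baseline")
        with pytest.raises(ValueError):
            CohortSpec(visits=("M2", "M0"))

    def test_moderate_stratum_declines_faster(self, small_spec, small_phantom):
        cohort = CohortSpec(arms=(ArmSpec("placebo", 0.05, 4),), seed=2)
        records, atlas = sample_patient_series(_noise_free(small_spec), cohort, small_phantom)
        ad = atlas.region_mask(atlas.ad_ids())
        drops = {}
        for r in records:
            drop = 1.0 - r.scans["M14"].data[ad].mean() / r.scans["M0"].data[ad].mean()
            drops.setdefault(r.stratum, []).append(drop)
        assert np.mean(drops["moderate"]) > np.mean(drops["mild"])


def test_cohort_round_trip_through_disk(tmp_path, small_spec, small_phantom):
    cohort = CohortSpec(arms=(ArmSpec("placebo", 0.05, 2),),
                        severity_strata={"mild": StratumSpec(1.0, 0.1)}, seed=9)
    records, atlas = sample_patient_series(small_spec, cohort, small_phantom)
    controls = sample_control_scans(small_phantom[1], 2, 5.0, seed=4)
    write_cohort(records, atlas, controls, tmp_path / "cohort")
    back, atlas2, controls2 = load_cohort(tmp_path / "cohort")
    assert len(back) == len(records)
    assert np.array_equal(atlas2.labels, atlas.labels)
    assert len(controls2) == 2
    # float32 storage precision
    a = records[0].scans["M0"].data
    b = back[0].scans["M0"].data
    assert np.allclose(a, b, atol=1e-3)
    assert back[0].true_decline == records[0].true_decline
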