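import numpy as np
import pytest

from cytomap import probmaps, synthetic


def _vol(labels, subject="S0", voxel=1.0):
    return probmaps.LabelVolume(
        labels=np.asarray(labels, dtype=np.int16), voxel_size=voxel, subject=subject
    )


@pytest.fixture(scope="module")
def small_cohort_spec():
    templates = {
        1: synthetic.ellipsoid_template((24, 24, 24), (12, 8, 8), (5, 4, 4)),
        2: synthetic.ellipsoid_template((24, 24, 24), (12, 16, 16), (5, 4, 4)),
    }
    return synthetic.CohortSpec(
        area_templates=templates,
        grid_shape=(24, 24, 24),
        n_subjects=8,
        jitter_translation_sd=1.0,
        jitter_rotation_sd=2.0,
        seed=3,
    )


class TestBuildProbabilityMaps:
    def test_single_subject_indicator(self):
        labels = np.zeros((4, 4, 4), dtype=np.int16)
        labels[1:3, 1:3, 1:3] = 2
        pm = probmaps.build_probability_maps([_vol(labels)])
        np.testing.assert_array_equal(pm.maps[2], (labels == 2).astype(float))

    def test_overlap_fraction(self):
        vols = []
        for k in range(10):
            labels = np.zeros((3, 3, 3), dtype=np.int16)
            if k < 4:
                labels[1, 1, 1] = 1
            vols.append(_vol(labels, subject=f"S{k}"))
        pm = probmaps.build_probability_maps(vols)
        assert pm.maps[1][1, 1, 1] == pytest.approx(0.4)

    def test_grid_mismatch_rejected(self):
        a = _vol(np.zeros((3, 3, 3), dtype=np.int16))
        b = _vol(np.zeros((4, 4, 4), dtype=np.int16))
        with pytest.raises(ValueError, match="grid mismatch"):
            probmaps.build_probability_maps([a, b])

    def test_probability_conservation(self, small_cohort_spec):
        """Σ_a p_a(v)·n equals the number of subjects labeling v, exactly."""
        vols = synthetic.make_cohort_labels(small_cohort_spec)
        pm = probmaps.build_probability_maps(vols)
        total = sum(pm.maps.values()) * pm.n_subjects
        expected = sum((v.labels > 0).astype(int) for v in vols)
        np.testing.assert_allclose(total, expected, atol=1e-9)

    def test_jittered_cohort_peak_near_template_centroid(self):
        """The probability maximum, averaged over 20 cohort seeds, lies
        within one voxel of the template centroid (zero-mean jitter)."""
        template = synthetic.ellipsoid_template((20, 20, 20), (10, 10, 10), (5, 4, 4))
        centroid = np.argwhere(template).mean(axis=0)
        peaks = []
        for seed in range(20):
            spec = synthetic.CohortSpec(
                area_templates={1: template},
                grid_shape=(20, 20, 20),
                n_subjects=10,
                jitter_translation_sd=2.0,
                jitter_rotation_sd=0.0,
                seed=seed,
            )
            pm = probmaps.build_probability_maps(synthetic.make_cohort_labels(spec))
            peaks.append(np.argwhere(pm.maps[1] == pm.maps[1].max()).mean(axis=0))
        assert np.linalg.norm(np.mean(peaks, axis=0) - centroid) <= 1.0


class TestMPM:
    def test_argmax_assignment(self):
        vols = []
        for k in range(10):
            labels = np.zeros((1, 1, 3), dtype=np.int16)
            labels[0, 0, 0] = 1 if k < 6 else 2
            vols.append(_vol(labels, subject=f"S{k}"))
        mpm = probmaps.compute_mpm(probmaps.build_probability_maps(vols))
        assert mpm.labels[0, 0, 0] == 1

    def test_threshold_leaves_low_probability_unassigned(self):
        labels = np.zeros((2, 2, 2), dtype=np.int16)
        labels[0, 0, 0] = 1
        vols = [_vol(labels, "S0")] + [
            _vol(np.zeros((2, 2, 2), dtype=np.int16), f"S{k}") for k in range(1, 10)
        ]
        pm = probmaps.build_probability_maps(vols)
        mpm = probmaps.compute_mpm(pm, threshold=0.4)
        assert mpm.labels[0, 0, 0] == 0

    def test_single_subject_idempotence(self):
        rng = np.random.default_rng(0)
        labels = rng.integers(0, 4, size=(6, 6, 6)).astype(np.int16)
        mpm = probmaps.compute_mpm(
            probmaps.build_probability_maps([_vol(labels)]), threshold=0.0
        )
        np.testing.assert_array_equal(mpm.labels, labels)

    def test_subject_order_invariance(self, small_cohort_spec):
        vols = synthetic.make_cohort_labels(small_cohort_spec)
        pm_fwd = probmaps.build_probability_maps(vols)
        pm_rev = probmaps.build_probability_maps(vols[::-1])
        np.testing.assert_array_equal(
            probmaps.compute_mpm(pm_fwd).labels, probmaps.compute_mpm(pm_rev).labels
        )

    def test_tie_resolved_by_assigned_neighbors(self):
        """A 0.5/0.5 tie voxel surrounded by uniquely-A neighbors goes to A,
        even when A has the higher area id."""
        # two subjects; voxel (1,1,1) is A (id 2) in one and B (id 1) in the
        # other; all 6 neighbors are A in both subjects.
        shape = (3, 3, 3)
        a, b = np.zeros(shape, np.int16), np.zeros(shape, np.int16)
        for nb in [(0, 1, 1), (2, 1, 1), (1, 0, 1), (1, 2, 1), (1, 1, 0), (1, 1, 2)]:
            a[nb] = 2
            b[nb] = 2
        a[1, 1, 1] = 2
        b[1, 1, 1] = 1
        mpm = probmaps.compute_mpm(probmaps.build_probability_maps([_vol(a), _vol(b)]))
        assert mpm.labels[1, 1, 1] == 2

    def test_remaining_tie_breaks_to_lowest_id(self):
        a = np.full((1, 1, 1), 3, np.int16)
        b = np.full((1, 1, 1), 1, np.int16)
        mpm = probmaps.compute_mpm(probmaps.build_probability_maps([_vol(a), _vol(b)]))
        assert mpm.labels[0, 0, 0] == 1


class TestCentersOfGravity:
    def test_single_voxel_area(self):
        labels = np.zeros((4, 4, 4), np.int16)
        labels[2, 1, 3] = 1
        mpm = probmaps.MaximumProbabilityMap(labels=labels, voxel_size=2.0)
        np.testing.assert_allclose(probmaps.center_of_gravity(mpm, 1), [4.0, 2.0, 6.0])

    def test_cuboid_center(self):
        labels = np.zeros((6, 6, 6), np.int16)
        labels[1:4, 2:5, 0:6] = 1
        mpm = probmaps.MaximumProbabilityMap(labels=labels, voxel_size=1.0)
        np.testing.assert_allclose(probmaps.center_of_gravity(mpm, 1), [2.0, 3.0, 2.5])

    def test_empty_area_rejected(self):
        mpm = probmaps.MaximumProbabilityMap(labels=np.zeros((2, 2, 2), np.int16))
        with pytest.raises(ValueError, match="empty"):
            probmaps.center_of_gravity(mpm, 5)

    def test_zero_jitter_cohort_centroid_matches_template(self):
        template = synthetic.ellipsoid_template((16, 16, 16), (8, 8, 8), (4, 3, 3))
        spec = synthetic.CohortSpec(
            area_templates={1: template},
            grid_shape=(16, 16, 16),
            n_subjects=5,
            jitter_translation_sd=0.0,
            jitter_rotation_sd=0.0,
            seed=0,
        )
        vols = synthetic.make_cohort_labels(spec)
        mpm = probmaps.compute_mpm(probmaps.build_probability_maps(vols))
        expected = np.argwhere(template).mean(axis=0)
        np.testing.assert_allclose(probmaps.center_of_gravity(mpm, 1), expected)


class TestCohortGenerator:
    def test_zero_jitter_reproduces_template(self, small_cohort_spec):
        from dataclasses import replace

        spec = replace(
            small_cohort_spec, jitter_translation_sd=0.0, jitter_rotation_sd=0.0
        )
        template = synthetic.template_labels(spec)
        for vol in synthetic.make_cohort_labels(spec):
            np.testing.assert_array_equal(vol.labels, template)

    def test_determinism(self, small_cohort_spec):
        a = synthetic.make_cohort_labels(small_cohort_spec)
        b = synthetic.make_cohort_labels(small_cohort_spec)
        for va, vb in zip(a, b):
            np.testing.assert_array_equal(va.labels, vb.labels)

    def test_area_pushed_outside_raises(self):
        template = synthetic.ellipsoid_template((10, 10, 10), (1, 1, 1), (1, 1, 1))
        spec = synthetic.CohortSpec(
            area_templates={1: template},
            grid_shape=(10, 10, 10),
            n_subjects=3,
            jitter_translation_sd=50.0,
            jitter_rotation_sd=0.0,
            seed=1,
        )
        with pytest.raises(ValueError, match="area 1"):
            synthetic.make_cohort_labels(spec)

    def test_overlapping_templates_rejected(self):
        t = synthetic.ellipsoid_template((10, 10, 10), (5, 5, 5), (3, 3, 3))
        with pytest.raises(ValueError, match="disjoint"):
            synthetic.CohortSpec(
                area_templates={1: t, 2: t}, grid_shape=(10, 10, 10)
            )

    def test_nifti_roundtrip(self, tmp_path, small_cohort_spec):
        vol = synthetic.make_cohort_labels(small_cohort_spec)[0]
        p = tmp_path / "labels.nii"
        probmaps.save_nifti(vol.labels, vol.voxel_size, p)
        back = probmaps.load_label_volume(p)
        np.testing.assert_array_equal(back.labels, vol.labels)
        assert back.voxel_size == pytest.approx(vol.voxel_size)
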