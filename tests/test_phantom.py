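import numpy as np
import pytest

from rhizopore import phantom as ph


class TestSpecValidation:
    def test_trajectory_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError):
            ph.PhantomSpec(dynamics_plan=ph.DynamicsPlan(
                trajectory_fractions={"into_biopore": 0.5, "into_macropore": 0.5,
                                      "into_matrix": 0.5}))

    def test_gray_ordering_enforced(self):
        with pytest.raises(ValueError):
            ph.PhantomSpec(gray_model={"matrix": 50.0, "air": 90.0, "organic": 70.0,
                                       "earthworm_cast": 200.0,
                                       "mesofauna_cast_speckle": (90.0, 180.0)})

    def test_detectability_floor(self):
        with pytest.raises(ValueError):
            ph.PhantomSpec(biopore_plan=[(0.05, 1)])  # below 2 voxels at 0.04 mm

    def test_min_shape(self):
        spec = ph.compact_spec()
        spec.shape = (32, 32, 32)
        with pytest.raises(ValueError):
            ph.generate_core_pair(spec)

    def test_infeasible_plan(self):
        spec = ph.PhantomSpec(shape=(64, 64, 64), blob_porosity_target=0.5,
                              biopore_plan=[(2.0, 30)])
        with pytest.raises(ph.PlacementError):
            ph.generate_core_pair(spec)

    def test_yaml_roundtrip(self, tmp_path):
        spec = ph.compact_spec(seed=5)
        path = tmp_path / "spec.yaml"
        spec.to_yaml(path)
        back = ph.PhantomSpec.from_yaml(path)
        assert back == spec


class TestEmptyAndDeterminism:
    def test_empty_plan_pure_matrix(self):
        spec = ph.PhantomSpec(
            shape=(64, 64, 64), blob_porosity_target=0, biopore_plan=[], root_plan=[],
            dynamics_plan=ph.DynamicsPlan(destroyed_fraction=0, created_plan=[],
                                          new_root_plan=[]),
        )
        v1, v2, truth = ph.generate_core_pair(spec)
        assert (truth.labels_t1 == ph.L_MATRIX).all()
        assert truth.recount()["macroporosity_t1"] == 0.0

    def test_same_seed_bit_identical(self):
        a = ph.generate_core_pair(ph.compact_spec(seed=11))
        b = ph.generate_core_pair(ph.compact_spec(seed=11))
        assert np.array_equal(a[0].voxels, b[0].voxels)
        assert np.array_equal(a[1].voxels, b[1].voxels)
        assert np.array_equal(a[2].labels_t2, b[2].labels_t2)

    def test_different_seeds_differ(self):
        a = ph.generate_core_pair(ph.compact_spec(seed=11))
        b = ph.generate_core_pair(ph.compact_spec(seed=12))
        assert not np.array_equal(a[0].voxels, b[0].voxels)


class TestTruthConsistency:
    def test_recount_matches_planted_summaries(self, compact_pair):
        truth = compact_pair["truth"]
        recount = truth.recount()
        for key, val in recount.items():
            assert truth.planted_summaries[key] == pytest.approx(val, abs=1e-9)

    def test_every_structure_voxel_has_object_id(self, compact_pair):
        truth = compact_pair["truth"]
        structured = truth.labels_t1 != ph.L_MATRIX
        assert (truth.object_ids_t1[structured] > 0).all()
        assert (truth.object_ids_t1[~structured] == 0).all()

    def test_gray_support_without_noise(self):
        spec = ph.compact_spec(seed=0)
        spec.noise_sd = 0.0
        v1, v2, truth = ph.generate_core_pair(spec)
        g = spec.gray_model
        expected_t1 = {g["air"], g["organic"], g["matrix"]}
        assert set(np.unique(v1.voxels).tolist()) == expected_t1
        # t2 adds the cast grays (speckle uses organic/matrix values)
        assert set(np.unique(v2.voxels).tolist()) <= expected_t1 | {g["earthworm_cast"]}

    def test_blob_porosity_on_target(self):
        spec = ph.PhantomSpec(shape=(128, 128, 128), seed=4, biopore_plan=[],
                              root_plan=[],
                              dynamics_plan=ph.DynamicsPlan(destroyed_fraction=0,
                                                            created_plan=[],
                                                            new_root_plan=[]))
        _, _, truth = ph.generate_core_pair(spec)
        assert truth.recount()["blob_porosity_t1"] == pytest.approx(15.0, abs=2.0)


class TestDynamicsPlanting:
    def test_zero_dynamics_identity(self):
        spec = ph.compact_spec(seed=1, with_dynamics=False)
        _, _, truth = ph.generate_core_pair(spec)
        assert np.array_equal(truth.labels_t1, truth.labels_t2)

    def test_jitter_is_rigid_shift(self):
        spec = ph.compact_spec(seed=1, with_dynamics=False)
        spec.jitter_voxels = 1
        _, _, truth = ph.generate_core_pair(spec)
        shift = truth.geometry["jitter_shift"]
        assert sum(abs(s) for s in shift) == 1
        shifted = ph._shift_fill(truth.labels_t1, shift, ph.L_MATRIX)
        assert np.array_equal(truth.labels_t2, shifted)

    def test_destruction_fraction_and_even_agent_split(self):
        # no threading roots, so all biopores are available for destruction
        spec = ph.compact_spec(seed=2)
        spec.dynamics_plan.new_root_plan = []
        spec.dynamics_plan.destroyed_fraction = 0.5
        spec.dynamics_plan.agent_fractions = {"earthworm": 0.5, "mesofauna": 0.5,
                                              "unidentified": 0.0}
        _, _, truth = ph.generate_core_pair(spec)
        s = truth.planted_summaries
        assert s["destroyed_fraction_of_t1_bioporosity"] == pytest.approx(0.5, abs=0.02)
        ew = s["destroyed_by_earthworm_voxels"]
        meso = s["destroyed_by_mesofauna_voxels"]
        total = ew + meso + s["destroyed_by_unidentified_voxels"]
        assert ew / total == pytest.approx(0.5, abs=0.02)
        assert s["destroyed_by_unidentified_voxels"] <= 0.02 * total

    def test_trajectory_fractions_planted_by_construction(self, flagship):
        # at full study scale the generator must realise the planned
        # {0.15, 0.40, 0.45} split within two points per class
        traj = flagship["truth"].planted_summaries["trajectory_fractions"]
        assert traj["into_biopore"] == pytest.approx(0.15, abs=0.02)
        assert traj["into_macropore"] == pytest.approx(0.40, abs=0.02)
        assert traj["into_matrix"] == pytest.approx(0.45, abs=0.02)

    def test_over_destruction_rejected(self):
        spec = ph.compact_spec(seed=0)
        spec.dynamics_plan.destroyed_fraction = 5.0
        with pytest.raises((ph.PlacementError, ValueError)):
            ph.generate_core_pair(spec)


class TestPersistence:
    def test_save_phantom_writes_text_artifacts(self, tmp_path, compact_pair):
        out = ph.save_phantom(tmp_path / "core", compact_pair["v1"],
                              compact_pair["v2"], compact_pair["truth"])
        for name in ("gray_t1.tif", "labels_t1.tif", "objects.csv", "spec.yaml",
                     "planted_summaries.json"):
            assert (out / name).exists()
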