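"""Ground-truth fidelity of the synthetic cohort generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import ndimage

from adpn.synthetic import (GROUP_ADNP, GROUP_ADP, GROUP_HEC, EdgeEffect,
                            GroundTruth, RegionSpec, SimConfig, build_atlas,
                            build_region_specs, assign_ground_truth,
                            generate_cohort, sample_region_values,
                            simulate_roi_cohort, _scan_rng)


class TestTypes:
    def test_region_spec_invariants(self):
        with pytest.raises(ValueError):
            RegionSpec(region_id=0, name="x")
        with pytest.raises(ValueError):
            RegionSpec(region_id=1, name="x", base_sd=0.0)

    def test_edge_effect_invariants(self):
        with pytest.raises(ValueError):
            EdgeEffect(1, 1, GROUP_HEC, 0.5)
        with pytest.raises(ValueError):
            EdgeEffect(1, 2, GROUP_HEC, 0.99)
        with pytest.raises(ValueError):
            EdgeEffect(1, 2, "nope", 0.5)

    @pytest.mark.parametrize("bad", [
        dict(timepoints=(6, 0, 12)),
        dict(timepoints=(6, 12)),
        dict(effect_size_disease=-1.0),
        dict(n_subjects={GROUP_HEC: 0, GROUP_ADP: 2, GROUP_ADNP: 2}),
        dict(n_disease_regions=60, n_psychosis_regions=40),
    ])
    def test_sim_config_validation(self, bad):
        with pytest.raises(ValueError):
            SimConfig(**bad)


class TestAtlas:
    def test_regions_nonempty_contiguous_and_deterministic(self):
        a1 = build_atlas((24, 28, 24), 30, seed=7)
        a2 = build_atlas((24, 28, 24), 30, seed=7)
        assert np.array_equal(a1.labels, a2.labels)
        sizes = np.bincount(a1.labels.ravel(), minlength=31)[1:]
        assert (sizes > 0).all()
        assert sizes.min() >= 27
        for rid in range(1, 31):
            _, n_comp = ndimage.label(a1.labels == rid)
            assert n_comp == 1, f"region {rid} not contiguous"

    def test_different_seed_differs(self):
        a1 = build_atlas((24, 28, 24), 30, seed=7)
        a2 = build_atlas((24, 28, 24), 30, seed=8)
        assert not np.array_equal(a1.labels, a2.labels)

    def test_grid_too_small_raises_sizing_error(self):
        with pytest.raises(ValueError, match="too small"):
            build_atlas((8, 8, 8), 95, seed=1)

    def test_reference_regions_flagged(self):
        a = build_atlas((24, 28, 24), 30, seed=7)
        assert len(a.reference_ids) == 2
        flagged = set(a.regions.loc[a.regions["is_reference"], "region_id"])
        assert flagged == set(a.reference_ids)


@pytest.fixture(scope="module")
def setup():
    cfg = SimConfig(n_subjects={GROUP_HEC: 4, GROUP_ADP: 4, GROUP_ADNP: 4},
                    n_longitudinal={}, seed=5)
    atlas = build_atlas(cfg.grid_shape, cfg.n_regions, cfg.seed, cfg.voxel_size_mm)
    gt = assign_ground_truth(atlas, cfg)
    specs = build_region_specs(atlas, cfg, gt)
    return cfg, atlas, gt, specs


class TestRegionModel:
    """sample_region_values is the shared generative core for both paths."""

    def test_unknown_group_rejected(self, setup):
        cfg, atlas, gt, specs = setup
        with pytest.raises(ValueError, match="group"):
            sample_region_values(specs, cfg, gt, "ADX", 1.0, 0,
                                 np.random.default_rng(0))

    def test_null_configuration_groups_identical_in_mean(self):
        cfg = SimConfig(n_subjects={GROUP_HEC: 4, GROUP_ADP: 4, GROUP_ADNP: 4},
                        n_longitudinal={}, effect_size_disease=0.0,
                        effect_size_psychosis=0.0, progression_per_month=0.0, seed=6)
        atlas = build_atlas(cfg.grid_shape, cfg.n_regions, cfg.seed, cfg.voxel_size_mm)
        gt = assign_ground_truth(atlas, cfg)
        specs = build_region_specs(atlas, cfg, gt)
        rng = np.random.default_rng(1)
        means = {}
        for grp in (GROUP_HEC, GROUP_ADP):
            draws = [sample_region_values(specs, cfg, gt, grp, 1.0, 0, rng)
                     for _ in range(400)]
            means[grp] = np.mean(draws, axis=0)
        # Monte-Carlo error of a mean of 400 draws at sd 0.05 is ~0.0025
        assert np.abs(means[GROUP_HEC] - means[GROUP_ADP]).max() < 0.012

    def test_hec_scans_do_not_progress(self, setup):
        cfg, atlas, gt, specs = setup
        rng0 = np.random.default_rng(3)
        rng1 = np.random.default_rng(3)
        v0 = sample_region_values(specs, cfg, gt, GROUP_HEC, 0.0, 0, rng0)
        v24 = sample_region_values(specs, cfg, gt, GROUP_HEC, 0.0, 24, rng1)
        np.testing.assert_allclose(v0, v24)

    def test_progression_shifts_affected_regions_only(self, setup):
        cfg, atlas, gt, specs = setup
        rng0 = np.random.default_rng(3)
        rng1 = np.random.default_rng(3)
        v0 = sample_region_values(specs, cfg, gt, GROUP_ADNP, 1.0, 0, rng0)
        v24 = sample_region_values(specs, cfg, gt, GROUP_ADNP, 1.0, 24, rng1)
        ids = [s.region_id for s in specs]
        diff = pd.Series(v24 - v0, index=ids)
        expected = cfg.progression_per_month * 24
        for rid in gt.disease_region_ids:
            assert diff.loc[rid] == pytest.approx(expected, abs=1e-12)
        unaffected = set(ids) - set(gt.disease_region_ids)
        assert np.abs(diff.loc[sorted(unaffected)]).max() < 1e-12

    def test_psychosis_effect_size_recovered_from_sample(self):
        # configured 1.5 sd shift, averaged over n=200 scans per group
        cfg = SimConfig(n_subjects={GROUP_HEC: 200, GROUP_ADP: 200, GROUP_ADNP: 4},
                        n_longitudinal={}, effect_size_disease=0.0,
                        effect_size_psychosis=1.5, burden_sd=0.0, burden_floor=0.0,
                        seed=8)
        roi, man, gt, atlas, specs = simulate_roi_cohort(cfg)
        man = man.set_index("scan_id")
        hec = roi.loc[man.index[man["group"] == GROUP_HEC]]
        adp = roi.loc[man.index[man["group"] == GROUP_ADP]]
        d = (hec[gt.psychosis_region_ids].mean()
             - adp[gt.psychosis_region_ids].mean()) / cfg.base_sd
        assert d.mean() == pytest.approx(1.5, abs=0.1)


class TestEdgeCorrelations:
    def test_targets_converge_within_tolerance(self):
        cfg = SimConfig(n_subjects={GROUP_HEC: 1000, GROUP_ADP: 1000, GROUP_ADNP: 4},
                        n_longitudinal={}, seed=3)
        roi, man, gt, atlas, specs = simulate_roi_cohort(cfg)
        man = man.set_index("scan_id")
        checked = 0
        for grp in (GROUP_HEC, GROUP_ADP):
            sub = roi.loc[man.index[(man["group"] == grp) & (man["months"] == 0)]]
            for e in gt.altered_edges:
                if e.group != grp:
                    continue
                r = np.corrcoef(sub[e.node_a], sub[e.node_b])[0, 1]
                assert r == pytest.approx(e.target_r, abs=0.05), \
                    f"{grp} edge ({e.node_a},{e.node_b})"
                checked += 1
        assert checked >= 8

    def test_infeasible_target_raises(self):
        cfg = SimConfig(n_subjects={GROUP_HEC: 4, GROUP_ADP: 4, GROUP_ADNP: 4},
                        n_longitudinal={}, seed=5)
        atlas = build_atlas(cfg.grid_shape, cfg.n_regions, cfg.seed, cfg.voxel_size_mm)
        gt = assign_ground_truth(atlas, cfg)
        # three strong edges sharing one node exceed its unit variance budget
        n0, n1, n2, n3 = gt.psychosis_region_ids[:4]
        gt.altered_edges = [EdgeEffect(n0, n1, GROUP_HEC, 0.9),
                            EdgeEffect(n0, n2, GROUP_HEC, 0.9),
                            EdgeEffect(n0, n3, GROUP_HEC, 0.9)]
        specs = build_region_specs(atlas, cfg, gt)
        with pytest.raises(ValueError, match="budget"):
            sample_region_values(specs, cfg, gt, GROUP_HEC, 0.0, 0,
                                 np.random.default_rng(0))


class TestCohort:
    def test_clinical_null_coupling(self):
        cfg = SimConfig(n_subjects={GROUP_HEC: 4, GROUP_ADP: 200, GROUP_ADNP: 4},
                        n_longitudinal={}, cdrsb_slope=0.0, cdrsb_noise_sd=1.0,
                        seed=9)
        roi, man, gt, atlas, specs = simulate_roi_cohort(cfg)
        adp = man[man["group"] == GROUP_ADP]
        burden = np.array([gt.burdens[s] for s in adp["subject_id"]])
        r = np.corrcoef(burden, adp["cdrsb"])[0, 1]
        assert abs(r) < 0.1

    def test_clinical_coupling_matches_closed_form(self):
        # default couplings solve a*SD(burden)/SD(CDRSB) = 0.5
        cfg = SimConfig(n_subjects={GROUP_HEC: 4, GROUP_ADP: 500, GROUP_ADNP: 4},
                        n_longitudinal={}, seed=10)
        roi, man, gt, atlas, specs = simulate_roi_cohort(cfg)
        adp = man[man["group"] == GROUP_ADP]
        burden = np.array([gt.burdens[s] for s in adp["subject_id"]])
        assert np.corrcoef(burden, adp["cdrsb"])[0, 1] == pytest.approx(0.5, abs=0.1)
        assert np.corrcoef(burden, adp["mmse"])[0, 1] == pytest.approx(-0.5, abs=0.1)

    def test_manifest_deterministic_and_volumes_positive(self, tmp_path):
        cfg = SimConfig(grid_shape=(24, 28, 24), n_regions=20,
                        n_disease_regions=5, n_psychosis_regions=3,
                        n_subjects={GROUP_HEC: 3, GROUP_ADP: 3, GROUP_ADNP: 3},
                        n_longitudinal={GROUP_ADP: {6: 1}}, seed=4)
        m1, gt1, atlas, vols1 = generate_cohort(cfg)
        m2, gt2, _, vols2 = generate_cohort(cfg)
        pd.testing.assert_frame_equal(m1, m2)
        for sid, v in vols1.items():
            assert v.data.min() > 0
            np.testing.assert_array_equal(v.data, vols2[sid].data)
        # byte-identical manifest on disk
        out1, out2 = tmp_path / "a", tmp_path / "b"
        generate_cohort(cfg, out_dir=out1)
        generate_cohort(cfg, out_dir=out2)
        assert (out1 / "manifest.csv").read_bytes() == (out2 / "manifest.csv").read_bytes()

    def test_ground_truth_ids_exist_in_atlas(self, roi_cohort):
        gt, atlas = roi_cohort["gt"], roi_cohort["atlas"]
        ids = set(int(i) for i in atlas.region_ids)
        assert set(gt.disease_region_ids) <= ids
        assert set(gt.psychosis_region_ids) <= ids
        assert not (set(gt.disease_region_ids) & set(gt.psychosis_region_ids))

    def test_longitudinal_design_counts(self):
        cfg = SimConfig(grid_shape=(24, 28, 24), n_regions=20,
                        n_disease_regions=5, n_psychosis_regions=3,
                        n_subjects={GROUP_HEC: 6, GROUP_ADP: 5, GROUP_ADNP: 4},
                        n_longitudinal={GROUP_ADP: {6: 2, 12: 2, 24: 3},
                                        GROUP_HEC: {6: 4, 12: 4, 24: 4}},
                        seed=2)
        roi, man, gt, atlas, specs = simulate_roi_cohort(cfg)
        counts = man.groupby(["group", "months"]).size()
        assert counts[(GROUP_ADP, 0)] == 5
        assert counts[(GROUP_ADP, 6)] == 2
        assert counts[(GROUP_ADP, 24)] == 3
        assert counts[(GROUP_HEC, 12)] == 4
        assert (GROUP_ADNP, 6) not in counts

    def test_ground_truth_json_round_trip(self, tmp_path, roi_cohort):
        gt = roi_cohort["gt"]
        gt.to_json(tmp_path / "gt.json")
        back = GroundTruth.from_json(tmp_path / "gt.json")
        assert back.disease_region_ids == gt.disease_region_ids
        assert back.altered_edges == gt.altered_edges

    def test_scan_substreams_stable_under_cohort_size(self):
        cfg_small = SimConfig(n_subjects={GROUP_HEC: 2, GROUP_ADP: 2, GROUP_ADNP: 2},
                              n_longitudinal={}, seed=7)
        cfg_big = SimConfig(n_subjects={GROUP_HEC: 5, GROUP_ADP: 5, GROUP_ADNP: 5},
                            n_longitudinal={}, seed=7)
        r_small = _scan_rng(cfg_small, GROUP_ADP, 1, 0).normal(size=3)
        r_big = _scan_rng(cfg_big, GROUP_ADP, 1, 0).normal(size=3)
        np.testing.assert_array_equal(r_small, r_big)
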