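"""Class-activation mapping, expression scoring, region selection, and
composite scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adpn.classify import TrainConfig, TrainedClassifier
from adpn.explain import (ExplainMap, composite_score, gradcam,
                          group_mean_map, local_expression_scores,
                          select_regions)
from adpn.nnet import (CNN3D, Conv3d, GlobalAvgPool, Linear, NetworkSpec,
                       build_model)


def wrap(model, spec, pool=1):
    """TrainedClassifier shell with an identity input transform."""
    shape = spec.input_shape
    return TrainedClassifier(model=model, spec=spec,
                             config=TrainConfig(input_pool=pool),
                             input_mean=np.zeros(shape), input_sd=np.ones(shape))


class TestGradcam:
    def test_constant_score_model_gives_zero_map(self, rng):
        spec = NetworkSpec(input_shape=(8, 8, 8), base_channels=3)
        model = build_model(spec, seed=2)
        head = model.layers[-1]
        head.w[1, :] = 0.0       # class-1 logit identically zero
        head.b[1] = 0.0
        m = gradcam(wrap(model, spec), rng.normal(size=(8, 8, 8)), target_class=1)
        assert np.all(m.data == 0.0)

    def test_hand_built_single_channel_closed_form(self, rng):
        """conv(w=2) -> GAP -> linear(w=3): the analytic channel weight is
        3/V and the map is relu(3/V * A), A = 2x + b."""
        shape = (6, 6, 6)
        net_rng = np.random.default_rng(0)
        conv = Conv3d(1, 1, 1, net_rng)
        conv.w[...] = 2.0
        conv.b[...] = 0.5
        lin = Linear(1, 2, net_rng)
        lin.w[...] = np.array([[0.0], [3.0]])
        lin.b[...] = 0.0
        spec = NetworkSpec(input_shape=shape, base_channels=1, kernel=1, head="gap")
        model = CNN3D([conv, GlobalAvgPool(), lin], final_conv_index=0, spec=spec)
        x = rng.normal(size=shape)
        m = gradcam(wrap(model, spec), x, target_class=1)
        v = np.prod(shape)
        expected = np.maximum((3.0 / v) * (2.0 * x + 0.5), 0.0)
        np.testing.assert_allclose(m.data, expected, atol=1e-5)

    def test_channel_weights_match_finite_difference(self, rng):
        """Grad-CAM channel weights equal central finite differences of the
        class score under uniform per-channel activation perturbations."""
        spec = NetworkSpec(input_shape=(8, 8, 8), base_channels=4)
        model = build_model(spec, seed=7)
        x = rng.normal(size=(1, 1, 8, 8, 8))
        acts, grad = model.final_conv_activations_and_grad(x, target_class=1)
        weights = grad.mean(axis=(2, 3, 4))[0]
        tap = model.final_conv_index
        v = np.prod(acts.shape[2:])
        eps = 1e-5
        for k in range(acts.shape[1]):
            up, down = acts.copy(), acts.copy()
            up[:, k] += eps
            down[:, k] -= eps
            sp = model.forward_from(tap + 1, up)[0, 1]
            sm = model.forward_from(tap + 1, down)[0, 1]
            num = (sp - sm) / (2 * eps) / v
            assert weights[k] == pytest.approx(num, rel=1e-3, abs=1e-12)

    def test_map_nonnegative_and_at_scan_resolution(self, rng):
        spec = NetworkSpec(input_shape=(8, 8, 8), base_channels=3)
        model = build_model(spec, seed=2)
        m = gradcam(wrap(model, spec), rng.normal(size=(8, 8, 8)), target_class=1,
                    output_shape=(16, 16, 16))
        assert m.data.shape == (16, 16, 16)
        assert m.data.min() >= 0.0

    def test_batched_maps_equal_per_scan_maps(self, rng):
        from adpn.explain import gradcam_batch
        spec = NetworkSpec(input_shape=(8, 8, 8), base_channels=3)
        model = build_model(spec, seed=4)
        clf = wrap(model, spec)
        vols = [rng.normal(size=(8, 8, 8)) for _ in range(5)]
        batched = gradcam_batch(clf, vols, 1, [f"s{i}" for i in range(5)],
                                (8, 8, 8), batch_size=2)
        for i, v in enumerate(vols):
            single = gradcam(clf, v, 1)
            np.testing.assert_allclose(batched[i].data, single.data, atol=1e-12)

    def test_invariant_to_constant_shift_of_other_class_score(self, rng):
        spec = NetworkSpec(input_shape=(8, 8, 8), base_channels=3)
        model = build_model(spec, seed=2)
        x = rng.normal(size=(8, 8, 8))
        m1 = gradcam(wrap(model, spec), x, target_class=1)
        model.layers[-1].b[0] += 17.0   # shift the non-target logit
        m2 = gradcam(wrap(model, spec), x, target_class=1)
        np.testing.assert_array_equal(m1.data, m2.data)


class TestExpressionScores:
    def test_zero_map_gives_zero_row(self, tiny_atlas):
        m = ExplainMap(np.zeros(tiny_atlas.shape), "s0", 1)
        table = local_expression_scores([m], tiny_atlas)
        assert (table.loc["s0"] == 0).all()

    def test_region_indicator_map(self, tiny_atlas):
        rid = int(tiny_atlas.region_ids[2])
        data = (tiny_atlas.labels == rid).astype(float)
        table = local_expression_scores([ExplainMap(data, "s0", 1)], tiny_atlas)
        assert table.loc["s0", rid] == pytest.approx(1.0)
        others = [r for r in tiny_atlas.region_ids if r != rid]
        # neighbouring regions see exactly 0 (indicator map, no smoothing)
        assert table.loc["s0", others].max() == 0.0

    def test_random_map_matches_masked_mean_oracle(self, rng, tiny_atlas):
        data = rng.uniform(size=tiny_atlas.shape)
        table = local_expression_scores([ExplainMap(data, "s0", 1)], tiny_atlas)
        for rid in tiny_atlas.region_ids:
            oracle = data[tiny_atlas.labels == rid].mean()
            assert table.loc["s0", rid] == pytest.approx(oracle, rel=1e-12)

    def test_shape_mismatch_rejected(self, tiny_atlas):
        with pytest.raises(ValueError, match="shape"):
            local_expression_scores([ExplainMap(np.zeros((4, 4, 4)), "s0", 1)],
                                    tiny_atlas)

    def test_negative_map_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            ExplainMap(np.full((4, 4, 4), -1.0), "s0", 1)


def _null_expression(rng, n_per_group=50, n_regions=95):
    X = rng.normal(size=(2 * n_per_group, n_regions))
    expr = pd.DataFrame(X, index=[f"s{i}" for i in range(2 * n_per_group)],
                        columns=pd.RangeIndex(1, n_regions + 1, name="region_id"))
    groups = pd.Series(["A"] * n_per_group + ["B"] * n_per_group, index=expr.index)
    return expr, groups


class TestSelectRegions:
    def test_bonferroni_familywise_error_under_null(self):
        """Fraction of null datasets with any selected region stays below
        alpha + 2*SE (the Bonferroni guarantee), over 500 simulations."""
        rng = np.random.default_rng(0)
        hits = 0
        n_sims = 500
        for _ in range(n_sims):
            expr, groups = _null_expression(rng, n_per_group=25, n_regions=40)
            sel = select_regions(expr, groups, ("A", "B"), alpha=0.05)
            hits += bool(sel.selected_region_ids)
        se = np.sqrt(0.05 * 0.95 / n_sims)
        assert hits / n_sims <= 0.05 + 2 * se

    def test_single_shifted_region_is_exactly_recovered(self):
        rng = np.random.default_rng(1)
        expr, groups = _null_expression(rng, n_per_group=50)
        expr.loc[groups == "A", 17] += 5.0
        sel = select_regions(expr, groups, ("A", "B"), alpha=0.05)
        assert sel.selected_region_ids == [17]

    def test_direction_constraint(self):
        rng = np.random.default_rng(2)
        expr, groups = _null_expression(rng, n_per_group=50)
        expr.loc[groups == "A", 17] += 5.0
        sel = select_regions(expr, groups, ("A", "B"), direction="B", alpha=0.05)
        assert 17 not in sel.selected_region_ids

    def test_alpha_zero_selects_nothing(self):
        rng = np.random.default_rng(3)
        expr, groups = _null_expression(rng, n_per_group=20)
        expr.loc[groups == "A"] += 3.0
        sel = select_regions(expr, groups, ("A", "B"), alpha=0.0)
        assert sel.selected_region_ids == []

    def test_zero_variance_region_gets_p_one(self):
        rng = np.random.default_rng(4)
        expr, groups = _null_expression(rng, n_per_group=10, n_regions=5)
        expr[3] = 1.0
        with pytest.warns(UserWarning, match="zero within-group variance"):
            sel = select_regions(expr, groups, ("A", "B"), alpha=0.05)
        row = sel.table.set_index("region_id").loc[3]
        assert row["p_raw"] == 1.0

    def test_welch_vs_student_flag(self):
        rng = np.random.default_rng(5)
        expr, groups = _null_expression(rng, n_per_group=30, n_regions=10)
        welch = select_regions(expr, groups, ("A", "B"), equal_var=False)
        student = select_regions(expr, groups, ("A", "B"), equal_var=True)
        a = expr.loc[groups == "A", 1]
        b = expr.loc[groups == "B", 1]
        t_w = stats.ttest_ind(a, b, equal_var=False)
        t_s = stats.ttest_ind(a, b, equal_var=True)
        assert welch.table["t"].iloc[0] == pytest.approx(t_w.statistic)
        assert student.table["t"].iloc[0] == pytest.approx(t_s.statistic)


class TestCompositeScore:
    def test_reference_scores_standardized_exactly(self, rng):
        expr = pd.DataFrame(rng.normal(size=(30, 6)),
                            index=[f"s{i}" for i in range(30)],
                            columns=pd.RangeIndex(1, 7, name="region_id"))
        ref = [f"s{i}" for i in range(10)]
        table, stats_out = composite_score(expr, [1, 3, 5], ref)
        z_ref = table.loc[ref, "z"]
        assert z_ref.mean() == pytest.approx(0.0, abs=1e-10)
        assert z_ref.std(ddof=1) == pytest.approx(1.0, abs=1e-10)

    def test_identical_scans_share_z(self, rng):
        X = rng.normal(size=(12, 4))
        X[11] = X[0]
        expr = pd.DataFrame(X, index=[f"s{i}" for i in range(12)],
                            columns=pd.RangeIndex(1, 5, name="region_id"))
        table, _ = composite_score(expr, [1, 2], [f"s{i}" for i in range(8)])
        assert table.loc["s11", "z"] == pytest.approx(table.loc["s0", "z"])

    def test_empty_selection_is_an_error(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 3)),
                            index=[f"s{i}" for i in range(5)],
                            columns=pd.RangeIndex(1, 4, name="region_id"))
        with pytest.raises(ValueError, match="empty"):
            composite_score(expr, [], ["s0", "s1"])

    def test_too_few_reference_rows_rejected(self, rng):
        expr = pd.DataFrame(rng.normal(size=(5, 3)),
                            index=[f"s{i}" for i in range(5)],
                            columns=pd.RangeIndex(1, 4, name="region_id"))
        with pytest.raises(ValueError, match="reference"):
            composite_score(expr, [1], ["s0"])


class TestGroupMeanMap:
    def test_single_map_is_identity(self, rng):
        m = ExplainMap(rng.uniform(size=(4, 4, 4)), "a", 1)
        out = group_mean_map([m])
        np.testing.assert_array_equal(out.data, m.data)

    def test_duplicate_maps_average_to_themselves(self, rng):
        m = ExplainMap(rng.uniform(size=(4, 4, 4)), "a", 1)
        out = group_mean_map([m, ExplainMap(m.data.copy(), "b", 1)])
        np.testing.assert_allclose(out.data, m.data)

    def test_matches_voxel_loop_oracle(self, rng):
        maps = [ExplainMap(rng.uniform(size=(3, 3, 3)), f"s{i}", 1) for i in range(5)]
        out = group_mean_map(maps)
        for idx in np.ndindex(3, 3, 3):
            oracle = np.mean([m.data[idx] for m in maps])
            assert out.data[idx] == pytest.approx(oracle, rel=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="at least one"):
            group_mean_map([])
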