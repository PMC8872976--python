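"""Block-jackknife differences, IVW pooling and multiple-testing control."""

import numpy as np
import pytest

import phenocomb as pc
from phenocomb import compare as cmp
from phenocomb.phenogrid import component_pairs


def _mean_estimator(data, idx):
    return float(np.mean(np.asarray(data)[idx]))


class TestJackknifeDifference:
    def test_identical_data_gives_zero_delta_zero_se(self):
        x = np.random.default_rng(0).standard_normal(100)
        res = pc.jackknife_difference(_mean_estimator, x, x, axis_len=100,
                                      n_blocks=20, seed=1)
        assert res.delta == 0.0 and res.se == 0.0 and res.p == 1.0

    def test_delete_one_mean_difference_matches_paired_t_se(self):
        # n_blocks = n: the block jackknife of the mean difference reduces
        # to the delete-one jackknife, whose SE equals the closed-form
        # paired-t standard error s_d / sqrt(n)
        rng = np.random.default_rng(2)
        n = 60
        x = rng.standard_normal(n)
        y = x * 0.5 + rng.standard_normal(n)
        res = pc.jackknife_difference(_mean_estimator, x, y, axis_len=n,
                                      n_blocks=n, seed=3)
        d = y - x
        closed_form = d.std(ddof=1) / np.sqrt(n)
        assert res.delta == pytest.approx(float(d.mean()), abs=1e-12)
        assert res.se == pytest.approx(closed_form, abs=1e-9)

    def test_delta_equals_full_sample_difference(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal(200), rng.standard_normal(200)
        res = pc.jackknife_difference(_mean_estimator, x, y, axis_len=200,
                                      n_blocks=40, seed=5)
        assert res.delta == pytest.approx(float(y.mean() - x.mean()), abs=1e-12)

    def test_invalid_block_counts_rejected(self):
        x = np.zeros(10)
        with pytest.raises(cmp.ComparisonError):
            pc.jackknife_difference(_mean_estimator, x, x, axis_len=10, n_blocks=1)
        with pytest.raises(cmp.ComparisonError):
            pc.jackknife_difference(_mean_estimator, x, x, axis_len=10, n_blocks=11)


class TestIVW:
    def test_hand_computed_pool(self):
        s = pc.ivw_pool([0.10, 0.20], [0.01, 0.02])
        assert s.mean_delta == pytest.approx(0.12)
        assert s.se == pytest.approx(np.sqrt(1 / 12500), abs=1e-9)
        assert s.n_members == 2

    def test_closed_form_identity_machine_precision(self):
        rng = np.random.default_rng(6)
        d = rng.standard_normal(9)
        se = rng.uniform(0.01, 0.5, 9)
        s = pc.ivw_pool(d, se)
        w = 1 / se**2
        assert s.mean_delta == (w * d).sum() / w.sum()
        assert s.se == np.sqrt(1 / w.sum())

    def test_single_member_passthrough(self):
        s = pc.ivw_pool([0.3], [0.07])
        assert s.mean_delta == pytest.approx(0.3) and s.se == pytest.approx(0.07)

    def test_equal_variances_reduce_to_plain_mean(self):
        d = [0.1, 0.2, 0.6]
        s = pc.ivw_pool(d, [0.05] * 3)
        assert s.mean_delta == pytest.approx(np.mean(d))
        assert s.se == pytest.approx(0.05 / np.sqrt(3))

    def test_member_order_invariance(self):
        d, se = [0.1, -0.2, 0.4], [0.03, 0.05, 0.01]
        a = pc.ivw_pool(d, se)
        b = pc.ivw_pool(d[::-1], se[::-1])
        assert a.mean_delta == pytest.approx(b.mean_delta, abs=1e-15)

    def test_negative_se_rejected(self):
        with pytest.raises(cmp.ComparisonError):
            pc.ivw_pool([0.1, 0.2], [-0.01, 0.1])

    def test_zero_se_member_dominates(self):
        s = pc.ivw_pool([0.3, 0.1], [0.0, 0.1])
        assert s.mean_delta == pytest.approx(0.3) and s.se == 0.0


def _grid_estimates(value_fn, reps_fn, n_blocks=30):
    defs = pc.enumerate_phenotypes()
    return defs, [
        cmp.BlockEstimate(
            name=d.name, value=value_fn(d), replicates=reps_fn(d),
            enrichment=d.enrichment,
        )
        for d in defs
    ]


class TestTrendAndAttribution:
    def test_identical_phenotypes_give_zero_trend(self):
        reps = np.linspace(0.1, 0.2, 30)
        defs, ests = _grid_estimates(lambda d: 0.15, lambda d: reps.copy())
        trend = pc.enrichment_trend(ests, "Cardinal")
        assert len(trend) == 6  # reference level + 5 enrichment levels
        for g in trend[1:]:
            assert g.mean_delta == pytest.approx(0.0, abs=1e-12)

    def test_attribution_cells_and_overall(self):
        rng = np.random.default_rng(7)
        defs, ests = _grid_estimates(
            lambda d: 0.1 * len(d.components),
            lambda d: 0.1 * len(d.components) + 0.01 * rng.standard_normal(30),
        )
        pairs = component_pairs(defs)
        out = pc.component_attribution(ests, pairs)
        assert len(out["cells"]) == 25
        assert len(out["overall"]) == 5
        # every pair differs by exactly 0.1 in the point estimates
        for cell in out["cells"]:
            assert cell.mean_delta == pytest.approx(0.1, abs=1e-12)

    def test_single_member_cell_equals_its_pair(self):
        rng = np.random.default_rng(8)
        defs, ests = _grid_estimates(
            lambda d: float(len(d.components)),
            lambda d: len(d.components) + 0.05 * rng.standard_normal(30),
        )
        by_name = {e.name: e for e in ests}
        pairs = [p for p in component_pairs(defs)
                 if p.added_component == "duration" and p.base_enrichment == 5]
        assert len(pairs) == 1
        out = pc.component_attribution(ests, pairs)
        single = cmp.difference_from_replicates(
            by_name[pairs[0].base.name], by_name[pairs[0].enriched.name]
        )
        cell = out["cells"][0]
        assert cell.mean_delta == pytest.approx(single.delta)
        assert cell.se == pytest.approx(single.se)

    def test_pair_deltas_telescope_along_chains(self):
        # point-estimate deltas along any addition chain sum exactly to the
        # end-to-end difference
        rng = np.random.default_rng(9)
        values = {}
        defs, ests = _grid_estimates(
            lambda d: values.setdefault(d.name, float(rng.standard_normal())),
            lambda d: rng.standard_normal(30),
        )
        by_name = {e.name: e for e in ests}
        chain = [(), ("recurrence",), ("recurrence", "duration"),
                 ("recurrence", "symptoms5", "duration")]
        from phenocomb.phenogrid import PhenotypeDefinition
        names = [PhenotypeDefinition(components=c).name for c in chain]
        total = sum(
            by_name[b].value - by_name[a].value for a, b in zip(names, names[1:])
        )
        assert total == pytest.approx(by_name[names[-1]].value - by_name[names[0]].value,
                                      abs=1e-12)

    def test_missing_reference_rejected(self):
        defs, ests = _grid_estimates(lambda d: 0.1, lambda d: np.zeros(10))
        with pytest.raises(cmp.ComparisonError):
            pc.enrichment_trend(ests, "NoSuchPhenotype")

    def test_degenerate_members_reported_missing_not_zero(self):
        rng = np.random.default_rng(10)
        defs, ests = _grid_estimates(
            lambda d: 0.1, lambda d: 0.1 + 0.01 * rng.standard_normal(10)
        )
        for e in ests:
            if "Duration" in e.name:
                e.value = float("nan")
        pairs = component_pairs(defs)
        out = pc.component_attribution(ests, pairs)
        dur = [c for c in out["cells"] if c.group.startswith("duration@")]
        assert all(np.isnan(c.mean_delta) and c.n_members == 0 for c in dur)


class TestBonferroni:
    def test_paper_thresholds(self):
        assert pc.bonferroni(0.05, 32) == pytest.approx(0.0015625)
        assert pc.bonferroni(0.05, 25) == pytest.approx(0.002)

    def test_single_test_unchanged(self):
        assert pc.bonferroni(0.05, 1) == 0.05

    def test_invalid_inputs(self):
        with pytest.raises(cmp.ComparisonError):
            pc.bonferroni(1.5, 10)
        with pytest.raises(cmp.ComparisonError):
            pc.bonferroni(0.05, 0)
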