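"""Heritability estimator: GRM, region exclusion, residualization, the
liability conversion, and equivalence with the brute-force pair regression."""

import numpy as np
import pytest

import phenocomb as pc
from phenocomb import h2pcgc
from phenocomb.h2pcgc import EstimationError, _PairStats, he_regression
from phenocomb.phenogrid import PhenotypeDefinition
from phenocomb.simgen import GenotypePanel

from conftest import make_table


def _toy_panel(bp, chrom=None, n=4, seed=0):
    m = len(bp)
    rng = np.random.default_rng(seed)
    dos = rng.integers(0, 3, size=(n, m)).astype(np.int8)
    dos[0] = 0
    dos[1] = 2  # guarantee polymorphism
    return GenotypePanel(
        dosages=dos,
        snp_ids=np.array([f"s{i}" for i in range(m)]),
        chrom=np.asarray(chrom if chrom is not None else [6] * m),
        bp=np.asarray(bp),
        a1=np.full(m, "A"),
        a2=np.full(m, "G"),
        freq=np.full(m, 0.3),
    )


class TestExcludeRegion:
    def test_no_overlap_returns_panel_unchanged(self):
        panel = _toy_panel([100, 200, 300])
        out, removed = h2pcgc.exclude_region(panel, 6, 1000, 2000)
        assert removed == 0
        assert out is panel

    def test_closed_interval_counts(self):
        panel = _toy_panel(list(range(100, 1100, 100)))  # bp 100..1000
        out, removed = h2pcgc.exclude_region(panel, 6, 300, 700)
        assert removed == 5
        assert out.m == 5

    def test_boundary_snp_removed(self):
        panel = _toy_panel([300, 800])
        out, removed = h2pcgc.exclude_region(panel, 6, 300, 500)
        assert removed == 1 and out.bp.tolist() == [800]

    def test_other_chromosome_untouched(self):
        panel = _toy_panel([300, 400], chrom=[1, 6])
        _, removed = h2pcgc.exclude_region(panel, 6, 1, 1000)
        assert removed == 1


class TestGRM:
    def test_two_by_two_hand_computation(self):
        panel = _toy_panel([1, 2], n=2)
        panel.dosages = np.array([[0, 2], [2, 0]], dtype=np.int8)
        grm = pc.compute_grm(panel)
        assert np.allclose(grm.values, [[1, -1], [-1, 1]])

    def test_duplicated_individual_relatedness(self):
        panel = pc.simulate_genotypes(50, 200, seed=3)
        dup = panel.dosages.copy()
        dup[1] = dup[0]
        panel.dosages = dup
        g = pc.compute_grm(panel).values
        assert g[0, 1] == pytest.approx((g[0, 0] + g[1, 1]) / 2, abs=1e-10)

    def test_diagonal_and_offdiagonal_scale(self):
        panel = pc.simulate_genotypes(200, 2000, seed=4)
        g = pc.compute_grm(panel).values
        assert abs(np.diag(g).mean() - 1.0) < 0.1
        off = g[np.triu_indices_from(g, k=1)]
        assert abs(off.std() - 1 / np.sqrt(2000)) / (1 / np.sqrt(2000)) < 0.10
        # sample standardization makes the grand total exactly zero, so the
        # off-diagonal mean equals -trace / (n^2 - n): near zero at scale
        assert off.mean() == pytest.approx(-np.trace(g) / (200 * 199), abs=1e-10)
        assert abs(off.mean()) < 0.01

    def test_monomorphic_snp_rejected(self):
        panel = _toy_panel([1, 2], n=4)
        panel.dosages[:, 0] = 1
        with pytest.raises(Exception):
            pc.compute_grm(panel)


class TestResidualize:
    def test_no_covariates_demeans(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        assert np.allclose(pc.residualize(y), y - 3.0)

    def test_covariate_equal_to_y_zeroes_residuals(self):
        y = np.array([1.0, 2.0, 3.0, 6.0])
        assert np.allclose(pc.residualize(y, y), 0.0, atol=1e-12)

    def test_four_point_closed_form(self):
        x = np.array([0.0, 1.0, 2.0, 3.0])
        y = np.array([1.0, 3.0, 2.0, 5.0])
        slope, intercept = np.polyfit(x, y, 1)
        assert np.allclose(pc.residualize(y, x), y - (slope * x + intercept))

    def test_rank_deficiency_rejected(self):
        y = np.arange(4.0)
        C = np.column_stack([np.ones(4), np.ones(4)])
        with pytest.raises(EstimationError):
            pc.residualize(y, C)


class TestConversionFactor:
    def test_half_half_value(self):
        # K = P = 0.5: z = phi(0), factor = 0.25 / z^2 = pi/2
        assert pc.conversion_factor(0.5, 0.5) == pytest.approx(1.570796, abs=1e-6)

    def test_reduces_to_simple_form_when_p_equals_k(self):
        from scipy import stats
        for K in (0.05, 0.2, 0.45):
            z = stats.norm.pdf(stats.norm.isf(K))
            assert pc.conversion_factor(K, K) == pytest.approx(K * (1 - K) / z**2)

    def test_finite_and_continuous_over_grid(self):
        grid = np.linspace(0.01, 0.99, 197)
        vals = np.array([pc.conversion_factor(k, k) for k in grid])
        assert np.all(np.isfinite(vals)) and np.all(vals > 0)
        # continuity: refining the grid shrinks the largest step ~proportionally
        fine = np.linspace(0.01, 0.99, 2 * 197 - 1)
        vals_fine = np.array([pc.conversion_factor(k, k) for k in fine])
        assert np.max(np.abs(np.diff(vals_fine))) < 0.75 * np.max(np.abs(np.diff(vals)))
        # symmetric in K about one half
        assert vals == pytest.approx(vals[::-1])

    def test_boundary_rejected(self):
        with pytest.raises(EstimationError):
            pc.conversion_factor(0.0, 0.5)
        with pytest.raises(EstimationError):
            pc.conversion_factor(0.5, 1.0)


def _brute_force_slope(G, y, drop=()):
    keep = np.setdiff1d(np.arange(y.size), drop)
    gs, ys = [], []
    for a in range(keep.size):
        for b in range(a + 1, keep.size):
            i, j = keep[a], keep[b]
            gs.append(G[i, j])
            ys.append(y[i] * y[j])
    return np.polyfit(gs, ys, 1)[0]


class TestHERegression:
    def test_matches_brute_force_pairs(self):
        panel = pc.simulate_genotypes(50, 300, seed=11)
        G = pc.compute_grm(panel).values
        y = np.random.default_rng(0).standard_normal(50)
        assert he_regression(G, y) == pytest.approx(_brute_force_slope(G, y), abs=1e-9)

    def test_block_deletion_matches_brute_force(self):
        # the jackknife's O(|B|^2) update equals recomputation from scratch
        panel = pc.simulate_genotypes(40, 200, seed=12)
        G = pc.compute_grm(panel).values
        y = np.random.default_rng(1).standard_normal(40)
        ps = _PairStats(G, y)
        block = np.array([3, 7, 11, 30])
        assert ps.slope(block) == pytest.approx(
            _brute_force_slope(G, y, drop=block), abs=1e-9
        )


def _assignment_for(panel, arch, seed, components=()):
    table = pc.simulate_components(panel, arch, seed)
    return pc.assign_case_control(table, PhenotypeDefinition(components=components))


class TestPcgcH2:
    def test_permuted_phenotype_is_null(self):
        panel = pc.simulate_genotypes(600, 800, seed=21)
        arch = pc.default_architecture(exclusion_rate=0.0)
        asg = _assignment_for(panel, arch, 21)
        rng = np.random.default_rng(2)
        asg.status = rng.permutation(asg.status)
        grm = pc.compute_grm(panel)
        est = pc.pcgc_h2(asg, grm)
        assert abs(est.h2_liability) < 2 * est.se_liability

    def test_liability_se_scales_with_conversion(self):
        panel = pc.simulate_genotypes(300, 400, seed=22)
        arch = pc.default_architecture(exclusion_rate=0.0)
        asg = _assignment_for(panel, arch, 22)
        grm = pc.compute_grm(panel)
        est = pc.pcgc_h2(asg, grm)
        cf = pc.conversion_factor(est.K, est.P)
        assert est.h2_liability == pytest.approx(est.h2_observed * cf)
        assert est.se_liability == pytest.approx(est.se_observed * cf)
        assert est.K == pytest.approx(asg.sample_prevalence_pre_exclusion)

    def test_degenerate_phenotype_refused(self, toy_table):
        asg = pc.assign_case_control(
            toy_table, PhenotypeDefinition(components=("recurrence", "impairment"))
        )
        asg.n_cases = 0
        grm = h2pcgc.GRM(values=np.eye(6), n_snps_used=50)
        with pytest.raises(EstimationError):
            pc.pcgc_h2(asg, grm)

    def test_se_decreases_with_sample_size(self):
        arch = pc.default_architecture(exclusion_rate=0.0)
        ses = []
        for n in (400, 900, 1800):
            panel = pc.simulate_genotypes(n, 500, seed=23)
            asg = _assignment_for(panel, arch, 23)
            ses.append(pc.pcgc_h2(asg, pc.compute_grm(panel)).se_liability)
        assert ses[0] > ses[1] > ses[2]
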