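import numpy as np
import pandas as pd
import pytest

from methcanyon.core import Region, ReferenceUMR
from methcanyon.diffmeth import (
    LRT_DF,
    call_pan_cancer,
    conserved_controls,
    dm_value,
    fit_beta_mle,
    lrt_region,
    moment_estimates,
)

from conftest import make_methylome


class TestBetaFit:
    def test_moment_initialization_formula(self):
        # mean 0.5, variance 0.05 -> alpha = beta = 2
        v = np.array([0.5 + d for d in (-0.3, -0.1, 0.1, 0.3)])
        v = (v - v.mean()) * np.sqrt(0.05 / v.var()) + 0.5
        a, b = moment_estimates(v)
        assert a == pytest.approx(2.0, rel=1e-6)
        assert b == pytest.approx(2.0, rel=1e-6)

    def test_symmetric_sample_gives_symmetric_fit(self):
        rng = np.random.default_rng(3)
        v = rng.beta(5, 5, 2000)
        v = np.concatenate([v, 1 - v])  # enforce exact symmetry
        fit = fit_beta_mle(v)
        assert abs(fit.alpha - fit.beta) / fit.alpha < 0.01

    def test_mle_matches_grid_search_oracle(self):
        rng = np.random.default_rng(10)
        v = np.clip(rng.beta(2, 5, 1000), 1e-6, 1 - 1e-6)
        grid = np.linspace(0.1, 20, 400)
        A, B = np.meshgrid(grid, grid, indexing="ij")
        from scipy.special import betaln

        slx, sl1x = np.log(v).sum(), np.log1p(-v).sum()
        ll = (A - 1) * slx + (B - 1) * sl1x - len(v) * betaln(A, B)
        i, j = np.unravel_index(np.argmax(ll), ll.shape)
        fit = fit_beta_mle(v)
        assert abs(fit.alpha - grid[i]) <= 0.15
        assert abs(fit.beta - grid[j]) <= 0.15

    def test_too_few_values_errors(self):
        with pytest.raises(ValueError, match="insufficient"):
            fit_beta_mle([0.2, 0.3])

    def test_zero_variance_falls_back_with_cap(self):
        fit = fit_beta_mle([0.25] * 10)
        assert not fit.converged
        assert fit.alpha + fit.beta <= 1e4 + 1e-6
        assert fit.mean == pytest.approx(0.25, abs=1e-3)

    def test_boundary_values_are_clamped(self):
        fit = fit_beta_mle([0.0, 0.1, 0.5, 0.9, 1.0])
        assert np.isfinite(fit.loglik)
        assert fit.alpha > 0 and fit.beta > 0


class TestLrt:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(1)
        v = rng.beta(2, 8, 20)
        D, p, *_ = lrt_region(v, v)
        assert D == pytest.approx(0.0, abs=1e-4)
        assert p > 0.99

    def test_df_is_two(self):
        assert LRT_DF == 2

    def test_symmetric_in_group_labels(self):
        rng = np.random.default_rng(2)
        a, b = rng.beta(2, 8, 15), rng.beta(4, 4, 15)
        D1, p1, *_ = lrt_region(a, b)
        D2, p2, *_ = lrt_region(b, a)
        assert D1 == pytest.approx(D2, rel=1e-6)
        assert p1 == pytest.approx(p2, rel=1e-6)
        assert D1 >= 0

    def test_power_monotone_in_separation(self):
        """Median p decreases as the planted group-mean separation grows."""
        rng = np.random.default_rng(9)
        med_p = []
        for shift in (0.0, 0.1, 0.2, 0.4):
            ps = []
            for _ in range(60):
                a = rng.beta(2, 8, 15)  # mean 0.2
                mean_t = 0.2 + shift
                conc = 10.0
                b = rng.beta(mean_t * conc, (1 - mean_t) * conc, 15)
                ps.append(lrt_region(a, b)[1])
            med_p.append(np.median(ps))
        assert all(x >= y for x, y in zip(med_p, med_p[1:]))
        assert med_p[-1] < 1e-4

    def test_null_type1_error_far_tail(self):
        """Empirical FPR at unadjusted alpha = 0.001 within 3x nominal over
        10,000 null regions (the chi-squared reference is asymptotic)."""
        rng = np.random.default_rng(5)
        hits = 0
        n_rep = 10000
        for _ in range(n_rep):
            if lrt_region(rng.beta(2, 8, 15), rng.beta(2, 8, 15))[1] < 0.001:
                hits += 1
        assert hits / n_rep <= 3 * 0.001


class TestDmValue:
    def test_arithmetic(self):
        assert dm_value([0.05] * 3, [0.45] * 3) == pytest.approx(0.40)

    def test_identical_groups_zero(self):
        v = [0.1, 0.2, 0.3]
        assert dm_value(v, v) == 0.0

    def test_matches_brute_force(self):
        rng = np.random.default_rng(11)
        a, b = rng.random(20), rng.random(25)
        assert dm_value(a, b) == pytest.approx(abs(b.mean() - a.mean()))


def _cohort_for_regions(region_specs, n_normals=10, n_tumors=10, seed=0):
    """region_specs: list of (start, length, normal_mean, tumor_mean)."""
    rng = np.random.default_rng(seed)
    refs = []
    for start, length, _, _ in region_specs:
        refs.append(ReferenceUMR(Region("chr1", start, start + length), 10, 10, 1e-20, 1e-18))
    conc = 60.0

    def build(sample_id, group, idx):
        pos, ratio = [], []
        for (start, length, nm, tm) in region_specs:
            mu = nm if group == "normal" else tm
            for t in range(20):
                pos.append(start + t * (length // 20))
                ratio.append(float(rng.beta(mu * conc, (1 - mu) * conc)))
        return make_methylome(pos, ratio, sample_id=sample_id, group=group)

    normals = [build(f"N{i}", "normal", i) for i in range(n_normals)]
    tumors = [build(f"T{i}", "tumor", i) for i in range(n_tumors)]
    for i, t in enumerate(tumors):
        t.tumor_type = f"TT{i % 2}"
    return refs, normals, tumors


class TestCallPanCancer:
    def test_planted_hyper_canyon_categorized(self):
        refs, normals, tumors = _cohort_for_regions(
            [(0, 4000, 0.05, 0.50), (10000, 1000, 0.05, 0.05)]
        )
        results, per_type = call_pan_cancer(refs, normals, tumors)
        by_start = {r.region.start: r for r in results}
        assert by_start[0].category == "hyper-canyon"
        assert by_start[0].n_types_recurrent == 2
        assert by_start[10000].category == "none"

    def test_effect_filter_blocks_small_dm(self):
        # strong statistical separation but |dm| = 0.05 < 0.1: not significant
        refs, normals, tumors = _cohort_for_regions(
            [(0, 1000, 0.05, 0.10), (5000, 1000, 0.05, 0.05)],
            n_normals=40, n_tumors=40,
        )
        results, _ = call_pan_cancer(refs, normals, tumors)
        r0 = next(r for r in results if r.region.start == 0)
        assert r0.dm_value < 0.1
        assert not r0.significant and r0.category == "none"

    def test_small_group_skipped(self):
        refs, normals, tumors = _cohort_for_regions([(0, 1000, 0.05, 0.5)])
        results, _ = call_pan_cancer(refs, normals, tumors[:2])
        assert results == []


class TestConservedControls:
    def test_partition_matches_hand_tabulation(self):
        refs, normals, tumors = _cohort_for_regions(
            [(0, 4000, 0.05, 0.05), (10000, 4000, 0.05, 0.5), (20000, 1000, 0.05, 0.05)]
        )
        results, per_type = call_pan_cancer(refs, normals, tumors)
        canyons, cumrs = conserved_controls(results, per_type)
        assert [r.region.start for r in canyons] == [0]
        assert [r.region.start for r in cumrs] == [20000]

    def test_significant_in_one_type_excluded(self):
        per_type = pd.DataFrame(
            {"A": [True, False], "B": [False, False]},
            index=["chr1:0-4000", "chr1:9000-9100"],
        )
        refs, normals, tumors = _cohort_for_regions(
            [(0, 4000, 0.05, 0.05)]
        )
        results, _ = call_pan_cancer(refs, normals, tumors)
        canyons, cumrs = conserved_controls(results, per_type)
        assert canyons == [] and cumrs == []


def test_beta_mean_recovery_on_synthetic_cohort(pipeline_state):
    """Fitted per-group beta means track the generator's planted region
    means within 0.02 at the default group sizes."""
    state = pipeline_state
    planted = [pr for pr in state.cohort.truth.regions if pr.kind != "unstable"]
    errs = []
    for r in state.dm_results:
        hits = [pr for pr in planted if pr.region.overlaps(r.region)]
        if len(hits) != 1:
            continue
        pr = hits[0]
        errs.append(abs(r.fit_normal.mean - pr.normal_mean))
        errs.append(abs(r.fit_tumor.mean - pr.tumor_mean))
    assert len(errs) > 100
    assert np.mean(errs) < 0.02


def test_hyper_hypo_canyon_proportions_recovered(pipeline_state):
    """Called canyon category proportions match the planted 18%/5%
    hyper/hypo asymmetry within 3 percentage points."""
    state = pipeline_state
    canyons = [r for r in state.dm_results if r.umr_class == "canyon"]
    hyper = 100 * sum(r.category == "hyper-canyon" for r in canyons) / len(canyons)
    hypo = 100 * sum(r.category == "hypo-canyon" for r in canyons) / len(canyons)
    cfg = state.cohort.truth.config
    planted_hyper = 100 * round(cfg.frac_hyper_canyon * cfg.n_canyons) / cfg.n_canyons
    planted_hypo = 100 * round(cfg.frac_hypo_canyon * cfg.n_canyons) / cfg.n_canyons
    assert abs(hyper - planted_hyper) <= 3.0
    assert abs(hypo - planted_hypo) <= 3.0
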