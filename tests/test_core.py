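import numpy as np
import pytest

from cdep import (
    CdepConfig,
    SamplerConfig,
    ThresholdGrid,
    assemble_fdr_panel,
    build_universe,
    count_significant,
    expected_likelihood,
    false_positive_rate,
    minus_log_likelihood,
    permutation_fdr,
    run_cdep,
)
from cdep.core import FdrPanel, RATE_MIN, _bin_rates, _gene_contributions

from conftest import make_dataset, make_fit, make_rp_result

FAST_CDEP = CdepConfig(
    n_perm_rankprod=20,
    n_meta_perm=20,
    sampler=SamplerConfig(chains=2, iterations=400, burn_in=200),
    seed=20260922,
)


def make_panel(fdr_up, fdr_down=None, dataset_ids=None):
    fdr_up = np.asarray(fdr_up, dtype=float)
    fdr_down = np.asarray(fdr_down, dtype=float) if fdr_down is not None else fdr_up.copy()
    G, D = fdr_up.shape
    return FdrPanel(
        genes=[f"g{i}" for i in range(G)],
        dataset_ids=dataset_ids or [f"d{j}" for j in range(D)],
        fdr_up=fdr_up,
        fdr_down=fdr_down,
        imputed=np.zeros((G, D), dtype=bool),
    )


def brute_force_el(F_row, rates, grid):
    """Per-gene EL by looping bins and datasets, no shared precomputation."""
    total = 0.0
    for j, l in enumerate(grid.l_values):
        delta = (F_row < l).astype(float)
        q = minus_log_likelihood(delta, rates[:, j])
        total += q * grid.weights[j] * grid.bin_width
    return total


class TestThresholdGrid:
    def test_density_integrates_to_one(self):
        grid = ThresholdGrid.make(100)
        assert abs((grid.weights * grid.bin_width).sum() - 1.0) < 1e-6

    def test_points_strictly_increasing_inside_unit_interval(self):
        grid = ThresholdGrid.make(100)
        assert (np.diff(grid.l_values) > 0).all()
        assert grid.l_values[0] > 0 and grid.l_values[-1] < 1

    def test_density_decreasing_in_l(self):
        grid = ThresholdGrid.make(50)
        assert (np.diff(grid.weights) < 0).all()


class TestAssemblePanel:
    def test_median_imputation_for_absent_gene(self):
        r1 = make_rp_result("d1", ["a", "b", "c"], [0.1, 0.4, 0.9])
        r2 = make_rp_result("d2", ["a", "b"], [0.2, 0.6])
        uni = build_universe(
            [
                make_dataset(np.zeros((3, 2)) + [[1, 0]], [1, 0], "d1", ["a", "b", "c"]),
                make_dataset(np.zeros((2, 2)) + [[1, 0]], [1, 0], "d2", ["a", "b"]),
            ]
        )
        panel = assemble_fdr_panel([r1, r2], uni)
        assert panel.fdr_up[2, 1] == pytest.approx(0.4)  # median of (0.2, 0.6)
        assert panel.imputed[2, 1]
        assert not panel.imputed[:, 0].any()

    def test_no_flags_when_gene_everywhere(self):
        r1 = make_rp_result("d1", ["a", "b", "c"], [0.1, 0.4, 0.9])
        r2 = make_rp_result("d2", ["a", "b", "c"], [0.2, 0.6, 0.8])
        uni = build_universe(
            [
                make_dataset(np.zeros((3, 2)) + [[1, 0]], [1, 0], d, ["a", "b", "c"])
                for d in ("d1", "d2")
            ]
        )
        panel = assemble_fdr_panel([r1, r2], uni)
        assert not panel.imputed.any()

    def test_odd_count_median_is_middle_order_statistic(self):
        r1 = make_rp_result("d1", ["a", "b", "c"], [0.9, 0.1, 0.3])
        r2 = make_rp_result("d2", ["a", "b", "c", "d"], [0.1, 0.2, 0.3, 0.4])
        uni = build_universe(
            [
                make_dataset(np.zeros((3, 2)) + [[1, 0]], [1, 0], "d1", ["a", "b", "c"]),
                make_dataset(np.zeros((4, 2)) + [[1, 0]], [1, 0], "d2", ["a", "b", "c", "d"]),
            ]
        )
        panel = assemble_fdr_panel([r1, r2], uni)
        assert panel.fdr_up[3, 0] == pytest.approx(0.3)


class TestCountsAndRates:
    def test_count_is_strict(self):
        panel = make_panel(np.array([[0.01], [0.5], [0.9]]))
        assert count_significant(panel, 0.05, 0, "up") == 1
        assert count_significant(panel, 0.01, 0, "up") == 0
        panel2 = make_panel(np.array([[0.2], [1.0], [0.999]]))
        assert count_significant(panel2, 0.999, 0, "up") == 1

    def test_threshold_domain(self):
        panel = make_panel(np.array([[0.5]]))
        with pytest.raises(ValueError):
            count_significant(panel, 1.0, 0, "up")

    def test_rate_formula(self):
        assert false_positive_rate(100, 0.05, 9500) == pytest.approx(100 * 0.05 / 9500)

    def test_rate_clamped_at_zero_count(self):
        assert false_positive_rate(0, 0.05, 100) == RATE_MIN

    def test_rate_clamped_above(self):
        assert false_positive_rate(10_000, 0.9, 10) == 1.0 - RATE_MIN


class TestMinusLogLikelihood:
    def test_two_dataset_example(self):
        q = minus_log_likelihood([1, 1], [0.01, 0.02])
        assert q == pytest.approx(-(np.log(0.01) + np.log(0.02)), abs=1e-9)
        assert q == pytest.approx(8.517, abs=1e-3)

    def test_nonsignificant_pattern_near_zero(self):
        assert minus_log_likelihood([0, 0], [1e-6, 1e-6]) == pytest.approx(0.0, abs=1e-5)

    def test_high_threshold_limit_vanishes(self):
        # as l -> 1 every gene is declared significant and r -> 1, so Q -> 0
        q = minus_log_likelihood(np.ones(6), np.full(6, 1.0 - RATE_MIN))
        assert 0.0 <= q < 1e-6


class TestExpectedLikelihood:
    def test_constant_q_integrates_to_itself(self):
        grid = ThresholdGrid.make(100)
        rates = np.full((3, 100), 0.01)
        F = np.zeros((5, 3))  # delta = 1 at every bin -> Q constant in l
        el = _gene_contributions(F, grid, rates).sum(axis=1)
        expected = -3 * np.log(0.01)
        np.testing.assert_allclose(el, expected, atol=1e-10)

    def test_matches_brute_force_per_gene_loop(self, rng):
        G, D = 20, 4
        panel = make_panel(rng.random((G, D)))
        fits = [make_fit(G - 2, dataset_id=d) for d in panel.dataset_ids]
        grid = ThresholdGrid.make(100)
        el = expected_likelihood(panel, fits, grid, "up")
        rates = _bin_rates(panel, fits, grid, "up")
        for g in range(G):
            assert el[g] == pytest.approx(
                brute_force_el(panel.fdr_up[g], rates, grid), abs=1e-10
            )

    def test_consistent_gene_scores_above_single_dataset_gene(self):
        F = np.array(
            [[0.001] * 6, [0.001] + [0.9] * 5]
        )
        panel = make_panel(F)
        fits = [make_fit(1000, dataset_id=d) for d in panel.dataset_ids]
        grid = ThresholdGrid.make(100)
        el = expected_likelihood(panel, fits, grid, "up")
        assert el[0] > el[1]

    def test_uniformly_insignificant_gene_scores_near_zero(self):
        F = np.vstack([np.full(4, 0.99), np.full(4, 0.2)])
        panel = make_panel(F)
        fits = [make_fit(50, dataset_id=d) for d in panel.dataset_ids]
        el = expected_likelihood(panel, fits, ThresholdGrid.make(100), "up")
        assert el[0] < 0.2
        assert el[0] < el[1]

    def test_lowering_one_fdr_never_lowers_el(self, rng):
        grid = ThresholdGrid.make(100)
        G, D = 15, 3
        F = rng.random((G, D))
        rates = np.clip(rng.random((D, 100)) * 0.4, RATE_MIN, None)
        el = _gene_contributions(F, grid, rates).sum(axis=1)
        F2 = F.copy()
        F2[7, 1] *= 0.3
        el2 = _gene_contributions(F2, grid, rates).sum(axis=1)
        assert el2[7] >= el[7]
        np.testing.assert_allclose(np.delete(el2, 7), np.delete(el, 7))

    def test_el_nonnegative(self, rng):
        panel = make_panel(rng.random((30, 5)))
        fits = [make_fit(25, dataset_id=d) for d in panel.dataset_ids]
        el = expected_likelihood(panel, fits, ThresholdGrid.make(100), "up")
        assert (el >= 0).all()


class TestPermutationFdr:
    def test_matches_brute_force_double_loop(self, rng):
        G, D, B = 40, 3, 8
        panel = make_panel(rng.random((G, D)))
        fits = [make_fit(G, dataset_id=d) for d in panel.dataset_ids]
        grid = ThresholdGrid.make(100)
        el = expected_likelihood(panel, fits, grid, "up")
        fdr, null_el = permutation_fdr(
            panel, fits, grid, B, seed=3, direction="up", el_obs=el, return_null=True
        )
        for g in range(G):
            num = sum(
                (el[g] <= null_el[b]).sum() for b in range(B)
            ) / B
            den = (el[g] <= el).sum()
            assert fdr[g] == pytest.approx(min(num / den, 1.0))

    def test_all_identical_rows_give_fdr_one(self):
        panel = make_panel(np.full((10, 3), 0.4))
        fits = [make_fit(10, dataset_id=d) for d in panel.dataset_ids]
        fdr = permutation_fdr(panel, fits, ThresholdGrid.make(100), 5, 0, "up")
        np.testing.assert_allclose(fdr, 1.0)

    def test_dominant_gene_reaches_fdr_zero(self, rng):
        F = rng.random((50, 6)) * 0.5 + 0.5
        F[0] = 1e-6  # one gene overwhelmingly consistent
        panel = make_panel(F)
        fits = [make_fit(49, dataset_id=d) for d in panel.dataset_ids]
        fdr = permutation_fdr(panel, fits, ThresholdGrid.make(100), 20, 1, "up")
        assert fdr[0] == 0.0

    def test_null_panel_calibration(self, rng):
        """i.i.d. FDR columns: few genes reach meta-FDR <= 0.05."""
        G, D = 1000, 4
        panel = make_panel(rng.random((G, D)))
        fits = [make_fit(G - 50, dataset_id=d) for d in panel.dataset_ids]
        grid = ThresholdGrid.make(100)
        fdr = permutation_fdr(panel, fits, grid, 50, 7, "up")
        assert (fdr <= 0.05).mean() <= 0.05 + 0.02

    def test_requires_positive_B(self):
        panel = make_panel(np.full((4, 2), 0.5))
        fits = [make_fit(4, dataset_id=d) for d in panel.dataset_ids]
        with pytest.raises(ValueError):
            permutation_fdr(panel, fits, ThresholdGrid.make(10), 0, 0, "up")


class TestRunCdep:
    def test_single_dataset_rejected(self, rng):
        ds = make_dataset(rng.normal(size=(5, 4)), [1, 1, 0, 0])
        with pytest.raises(ValueError, match="2 datasets"):
            run_cdep([ds])

    def test_planted_consistent_gene_attains_max_el(self, rng):
        datasets = []
        for d in range(2):
            values = rng.normal(size=(40, 8))
            values[0, :4] += 4.0  # same gene up-regulated in both studies
            datasets.append(make_dataset(values, [1, 1, 1, 1, 0, 0, 0, 0], f"d{d}"))
        res = run_cdep(datasets, FAST_CDEP)
        assert np.argmax(res.EL_up) == 0
        assert res.call[0] == "up"

    def test_no_signal_no_calls(self, rng):
        datasets = [
            make_dataset(rng.normal(size=(60, 8)), [1, 1, 1, 1, 0, 0, 0, 0], f"d{d}")
            for d in range(3)
        ]
        res = run_cdep(datasets, FAST_CDEP)
        assert (res.call == "none").mean() > 0.98

    def test_direction_call_prefers_smaller_fdr(self, rng):
        datasets = []
        for d in range(2):
            values = rng.normal(size=(40, 8))
            values[1, :4] -= 4.0  # consistent down-regulation
            datasets.append(make_dataset(values, [1, 1, 1, 1, 0, 0, 0, 0], f"d{d}"))
        res = run_cdep(datasets, FAST_CDEP)
        assert res.call[1] == "down"

    def test_output_frame_schema(self, rng):
        datasets = [
            make_dataset(rng.normal(size=(10, 4)), [1, 1, 0, 0], f"d{d}") for d in range(2)
        ]
        res = run_cdep(datasets, FAST_CDEP)
        df = res.to_frame()
        assert list(df.columns) == ["gene", "EL_up", "EL_down", "FDR_g_up", "FDR_g_down", "call"]
        assert len(df) == 10
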