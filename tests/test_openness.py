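"""Accumulation curves, Heaps'-law fitting, openness categories and the
rank test."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from panbgc import (
    FitConfig,
    SyntheticGCFSpec,
    accumulation_curve,
    analyze_openness,
    build_presence_absence,
    categorize_openness,
    compare_gamma_distributions,
    fit_heaps,
    generate_gcf,
    generate_powerlaw_curve,
    select_best_fit,
)
from panbgc.exceptions import TooFewMembersError
from panbgc.openness import METRICS, HeapsFit

from conftest import make_family, matrix_from_rows


def brute_force_mean_curve(presence_sets, metric):
    """Independent enumeration of all n! sampling orders."""
    n = len(presence_sets)
    totals = np.zeros(n)
    count = 0
    for order in itertools.permutations(range(n)):
        seen_ogs: set = set()
        seen_combos: set = set()
        for step, i in enumerate(order):
            if metric in ("gene_repertoire", "novel_gene"):
                seen_ogs |= presence_sets[i]
                totals[step] += len(seen_ogs)
            else:
                seen_combos.add(presence_sets[i])
                totals[step] += len(seen_combos)
        count += 1
    return totals / count


def random_small_matrix(rng, n_bgcs, n_ogs):
    while True:
        counts = (rng.random((n_bgcs, n_ogs)) < 0.5).astype(int)
        if counts.sum(axis=1).all() and counts.sum(axis=0).all():
            return matrix_from_rows(
                [f"b{i}" for i in range(n_bgcs)],
                [f"og{j}" for j in range(n_ogs)],
                counts,
            )


class TestAccumulationCurve:
    def test_worked_example_gene_repertoire(self, worked_matrix):
        curve = accumulation_curve(worked_matrix, "gene_repertoire", n_permutations=6)
        assert curve.exhaustive
        assert np.allclose(curve.mean_y, [7 / 3, 3, 3])

    def test_worked_example_composition(self, worked_matrix):
        curve = accumulation_curve(worked_matrix, "composition", n_permutations=6)
        assert np.allclose(curve.mean_y, [1, 2, 3])

    def test_identical_members_composition_is_flat(self):
        matrix = matrix_from_rows(
            [f"b{i}" for i in range(4)], ["A", "B"], [[1, 1]] * 4
        )
        curve = accumulation_curve(matrix, "composition", n_permutations=24)
        assert (curve.per_permutation_y == 1).all()

    @pytest.mark.parametrize("metric", METRICS)
    @pytest.mark.parametrize("n_bgcs", [3, 4, 5, 6])
    def test_exhaustive_equals_bruteforce(self, metric, n_bgcs):
        rng = np.random.default_rng(n_bgcs)
        matrix = random_small_matrix(rng, n_bgcs, 6)
        curve = accumulation_curve(
            matrix, metric, n_permutations=math.factorial(n_bgcs)
        )
        assert curve.exhaustive
        expected = brute_force_mean_curve(matrix.presence_sets(), metric)
        assert np.allclose(curve.mean_y, expected)

    def test_monte_carlo_converges_to_exhaustive_mean(self):
        rng = np.random.default_rng(17)
        matrix = random_small_matrix(rng, 5, 8)
        exact = accumulation_curve(
            matrix, "gene_repertoire", n_permutations=120
        ).mean_y
        sampled = accumulation_curve(
            matrix, "gene_repertoire", n_permutations=100, seed=3
        )
        assert not sampled.exhaustive
        se = sampled.per_permutation_y.std(axis=0, ddof=1) / np.sqrt(100)
        assert (np.abs(sampled.mean_y - exact) <= 3 * se + 1e-12).all()

    @pytest.mark.parametrize("metric", METRICS)
    def test_rows_nondecreasing_and_bounded(self, metric):
        rng = np.random.default_rng(23)
        matrix = random_small_matrix(rng, 6, 7)
        curve = accumulation_curve(matrix, metric, n_permutations=50, seed=2)
        assert (np.diff(curve.per_permutation_y, axis=1) >= 0).all()
        assert (curve.per_permutation_y[:, 0] >= 1).all()
        if metric == "composition":
            assert (curve.per_permutation_y <= curve.x).all()
            distinct = len(set(matrix.presence_sets()))
            assert (curve.per_permutation_y[:, -1] == distinct).all()
        else:
            assert (curve.per_permutation_y <= matrix.n_ogs).all()
            if metric == "gene_repertoire":
                assert (curve.per_permutation_y[:, -1] == matrix.n_ogs).all()

    def test_novel_gene_copies_mode_counts_copies(self):
        matrix = matrix_from_rows(
            ["b0", "b1", "b2"], ["A", "B"], [[2, 0], [1, 1], [1, 1]]
        )
        # b0 first contributes 2 copies of A; whoever first brings B adds
        # its copy count at that step
        curve = accumulation_curve(
            matrix, "novel_gene", n_permutations=6, novel_mode="copies"
        )
        assert (curve.per_permutation_y[:, -1] >= 2).all()
        og_curve = accumulation_curve(matrix, "novel_gene", n_permutations=6)
        assert (curve.per_permutation_y >= og_curve.per_permutation_y).all()

    def test_too_few_members_rejected(self):
        matrix = matrix_from_rows(["b0", "b1"], ["A"], [[1], [1]])
        with pytest.raises(TooFewMembersError):
            accumulation_curve(matrix, "gene_repertoire")

    def test_determinism(self, worked_matrix):
        a = accumulation_curve(worked_matrix, "gene_repertoire", 30, seed=9)
        b = accumulation_curve(worked_matrix, "gene_repertoire", 30, seed=9)
        assert (a.per_permutation_y == b.per_permutation_y).all()


class TestFitHeaps:
    @pytest.mark.parametrize("method", ["loglog", "weighted", "nls"])
    def test_exact_power_law_recovered(self, method):
        y = generate_powerlaw_curve(2.0, 0.5, 10)
        fit = fit_heaps(y, method)
        assert fit.k == pytest.approx(2.0, abs=1e-9)
        assert fit.gamma == pytest.approx(0.5, abs=1e-9)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("method", ["loglog", "weighted", "nls"])
    @pytest.mark.parametrize("gamma", [0.1, 0.5, 0.9, 1.0])
    def test_noiseless_gamma_recovery(self, method, gamma):
        y = generate_powerlaw_curve(3.0, gamma, 30)
        assert fit_heaps(y, method).gamma == pytest.approx(gamma, abs=1e-6)

    def test_flat_curve_gives_gamma_zero(self):
        fit = fit_heaps(np.full(10, 5.0), "loglog")
        assert fit.gamma == pytest.approx(0.0, abs=1e-12)
        assert fit.k == pytest.approx(5.0)
        assert fit.r2 == 1.0

    def test_noisy_nls_matches_grid_oracle(self):
        """Profiled grid search (gamma grid, closed-form k per gamma)
        minimizing SSE agrees with the bounded non-linear fit."""
        x = np.arange(1, 31, dtype=float)
        gammas = np.arange(0.0, 2.0 + 1e-12, 1e-3)
        for seed in range(5):
            y = generate_powerlaw_curve(3.0, 0.4, 30, noise_sd=0.05, seed=seed)
            xg = x[None, :] ** gammas[:, None]
            ks = np.clip((xg * y).sum(axis=1) / (xg * xg).sum(axis=1), 1e-9, 10.0)
            sse = ((ks[:, None] * xg - y) ** 2).sum(axis=1)
            oracle_gamma = gammas[np.argmin(sse)]
            fit = fit_heaps(y, "nls")
            assert fit.gamma == pytest.approx(oracle_gamma, abs=1e-2)

    def test_noisy_nls_recovers_truth_across_seeds(self):
        for seed in range(20):
            y = generate_powerlaw_curve(3.0, 0.4, 30, noise_sd=0.05, seed=seed)
            assert fit_heaps(y, "nls").gamma == pytest.approx(0.4, abs=0.1)

    def test_nonpositive_values_rejected(self):
        with pytest.raises(ValueError):
            fit_heaps([1.0, 0.0, 2.0], "loglog")

    def test_too_few_points_rejected(self):
        with pytest.raises(TooFewMembersError):
            fit_heaps([1.0, 2.0], "nls")

    def test_weight_rules(self):
        y = generate_powerlaw_curve(2.0, 0.7, 12)
        for rule in ("x", "x2", "sqrt", lambda x: x + 1):
            fit = fit_heaps(y, "weighted", FitConfig(weight_rule=rule))
            assert fit.gamma == pytest.approx(0.7, abs=1e-9)
        with pytest.raises(ValueError):
            fit_heaps(y, "weighted", FitConfig(weight_rule="cubic"))


class TestSelectBestFit:
    def test_exact_tie_goes_to_loglog(self):
        y = generate_powerlaw_curve(2.0, 0.5, 10)
        fits = [fit_heaps(y, m) for m in ("nls", "weighted", "loglog")]
        assert all(f.r2 == 1.0 for f in fits)
        assert select_best_fit(fits).method == "loglog"

    def test_argmax_r2_wins(self):
        fits = [
            HeapsFit(k=1, gamma=0.2, r2=0.9, method="loglog"),
            HeapsFit(k=1, gamma=0.3, r2=0.8, method="weighted"),
            HeapsFit(k=1, gamma=0.4, r2=0.95, method="nls"),
        ]
        assert select_best_fit(fits).method == "nls"

    def test_early_outlier_curve_prefers_downweighting_methods(self):
        # a large first-point outlier hurts the unweighted log fit most
        y = generate_powerlaw_curve(2.0, 0.6, 20)
        y[0] *= 4.0
        fits = {m: fit_heaps(y, m) for m in ("loglog", "weighted", "nls")}
        best = select_best_fit(list(fits.values()))
        assert best.r2 == max(f.r2 for f in fits.values())
        assert best.method != "loglog"


class TestCategorize:
    @pytest.mark.parametrize(
        "gamma,expected",
        [
            (0.286, "closed"),
            (0.841, "open"),
            (0.3, "intermediate"),
            (0.6, "intermediate"),
            (0.0, "closed"),
            (1.5, "open"),
        ],
    )
    def test_thresholds(self, gamma, expected):
        assert categorize_openness(gamma) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            categorize_openness(float("nan"))


class TestAnalyzeOpenness:
    def test_identity_family_is_closed_with_gamma_zero(self):
        gcf = make_family("same", [["A", "B", "C"]] * 10)
        result = analyze_openness(build_presence_absence(gcf), seed=0)
        comp = result.metrics["composition"]
        assert comp.best.gamma == pytest.approx(0.0, abs=1e-9)
        assert comp.category == "closed"

    def test_two_fresh_ogs_per_member_is_exactly_linear_and_open(self):
        gcf = make_family(
            "fresh", [[f"og{i}a", f"og{i}b"] for i in range(6)]
        )
        result = analyze_openness(build_presence_absence(gcf), seed=0)
        rep = result.metrics["gene_repertoire"]
        assert np.allclose(rep.curve.mean_y, 2 * rep.curve.x)
        assert rep.best.gamma == pytest.approx(1.0, abs=1e-9)
        assert rep.category == "open"

    def test_reshuffling_family_composition_exceeds_repertoire(self):
        gcf = generate_gcf(
            SyntheticGCFSpec(n_bgcs=12, core_size=8, accessory_pool_size=4,
                             accessory_prob=0.5, unique_rate=0.0, seed=21)
        )
        result = analyze_openness(build_presence_absence(gcf), seed=21)
        rep = result.metrics["gene_repertoire"]
        comp = result.metrics["composition"]
        assert rep.category == "closed"
        assert comp.best.gamma > rep.best.gamma

    def test_per_permutation_fitting_summary(self, worked_matrix):
        result = analyze_openness(
            worked_matrix, n_permutations=6, seed=0, fit_per_permutation=True
        )
        per = result.metrics["gene_repertoire"].per_permutation_gamma
        assert set(per) == {"gamma_median", "gamma_iqr", "gamma_values"}
        assert len(per["gamma_values"]) == 6

    def test_small_family_rejected(self):
        gcf = make_family("pair", [["A"], ["A"]])
        with pytest.raises(TooFewMembersError):
            analyze_openness(build_presence_absence(gcf))

    def test_determinism_bit_identical(self, worked_matrix):
        a = analyze_openness(worked_matrix, seed=5)
        b = analyze_openness(worked_matrix, seed=5)
        for metric in METRICS:
            assert a.metrics[metric].best == b.metrics[metric].best
            assert (
                a.metrics[metric].curve.per_permutation_y
                == b.metrics[metric].curve.per_permutation_y
            ).all()


class TestCompareGammaDistributions:
    def test_hand_computed_example(self):
        result = compare_gamma_distributions([[1, 2, 3], [4, 5, 6]])
        assert result.H == pytest.approx(3.857, abs=1e-3)
        assert result.group_sizes == [3, 3]

    def test_identical_groups_give_zero(self):
        result = compare_gamma_distributions([[0.5] * 3, [0.5] * 3])
        assert result.H == 0.0
        assert result.p == 1.0

    def test_matches_scipy_on_untied_data(self):
        rng = np.random.default_rng(8)
        groups = [rng.normal(loc, 1, size=12) for loc in (0.0, 0.4, 1.0)]
        ours = compare_gamma_distributions(groups)
        ref = sps.kruskal(*groups)
        assert ours.H == pytest.approx(ref.statistic, rel=1e-12)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_tie_correction_matches_scipy(self):
        groups = [[1, 1, 2, 3], [2, 2, 3, 4], [4, 4, 5, 1]]
        ours = compare_gamma_distributions(groups)
        ref = sps.kruskal(*groups)
        assert ours.H == pytest.approx(ref.statistic, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            compare_gamma_distributions([[1, 2, 3]])
        with pytest.raises(ValueError):
            compare_gamma_distributions([[1, 2], []])
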