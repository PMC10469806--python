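import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_posterior
from oracles import brute_force_hpdi

from asvglmm import (
    TaxonomyTable,
    differential_abundance,
    hpdi,
    partition_variance,
    repeatability,
    summarize_shifts,
)
from asvglmm.model_spec import GAUSSIAN


class TestHpdi:
    def test_uniform_lattice_tie_breaks_low(self):
        iv = hpdi(np.arange(100.0), 0.95)
        assert (iv.lower, iv.upper) == (0.0, 94.0)

    def test_constant_draws(self):
        iv = hpdi(np.full(50, 3.2), 0.9)
        assert (iv.lower, iv.upper) == (3.2, 3.2)

    def test_outlier_excluded(self):
        draws = np.concatenate([np.zeros(99), [100.0]])
        iv = hpdi(draws, 0.95)
        assert (iv.lower, iv.upper) == (0.0, 0.0)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            hpdi(np.arange(9.0), 0.9)

    def test_contains_median_and_prob_monotone(self):
        rng = np.random.default_rng(0)
        draws = rng.gamma(2.0, size=500)
        iv95 = hpdi(draws, 0.95)
        iv50 = hpdi(draws, 0.50)
        assert iv95.contains(float(np.median(draws)))
        assert (iv50.upper - iv50.lower) <= (iv95.upper - iv95.lower)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        n=st.integers(10, 200),
        prob=st.floats(0.5, 0.99),
        dist=st.sampled_from(["normal", "lognormal", "uniform", "mixture"]),
    )
    def test_matches_brute_force_search(self, seed, n, prob, dist):
        rng = np.random.default_rng(seed)
        if dist == "normal":
            draws = rng.normal(size=n)
        elif dist == "lognormal":
            draws = rng.lognormal(sigma=1.2, size=n)
        elif dist == "uniform":
            draws = rng.integers(0, 8, size=n).astype(float)  # heavy ties
        else:
            draws = np.concatenate([rng.normal(size=n // 2),
                                    rng.normal(6.0, 0.3, size=n - n // 2)])
        iv = hpdi(draws, prob)
        lo, hi = brute_force_hpdi(draws, prob)
        assert np.isclose(iv.upper - iv.lower, hi - lo)


class TestPartitionVariance:
    def test_gaussian_constant_draws(self):
        n = 20
        ps = make_posterior(
            variances={"A": np.ones(n), "B": np.ones(n), "C": 2 * np.ones(n),
                       "residual": np.zeros(n) + 1e-300},
            family=GAUSSIAN,
        )
        part = partition_variance(ps)
        got = {t: float(p.mean()) for t, p in part.proportions.items()}
        assert got["A"] == pytest.approx(0.25)
        assert got["B"] == pytest.approx(0.25)
        assert got["C"] == pytest.approx(0.5)
        assert got["residual"] == pytest.approx(0.0, abs=1e-12)

    def test_poisson_single_zero_variance_term(self):
        # sigma2 = 0, beta0 = 0: lambda_bar = 1, omega = ln 2, all of the
        # variance is distribution-specific
        n = 20
        ps = make_posterior(
            variances={"asv": np.zeros(n)},
            fixed={"intercept": np.zeros(n)},
        )
        part = partition_variance(ps)
        np.testing.assert_allclose(part.proportions["distribution"], 1.0)
        np.testing.assert_allclose(part.lambda_bar, 1.0)

    def test_poisson_matches_direct_arithmetic(self):
        # fixed draws -> proportions equal an independently coded formula
        s2a = np.array([0.5, 0.45, 0.6, 0.5] * 5)
        s2b = np.array([0.3, 0.35, 0.25, 0.3] * 5)
        b0 = np.array([3.0, 2.9, 3.1, 3.0] * 5)
        ps = make_posterior(variances={"a": s2a, "b": s2b},
                            fixed={"intercept": b0})
        part = partition_variance(ps)
        lam = np.exp(b0 + 0.5 * (s2a + s2b))
        om = np.log(1 + 1 / lam)
        np.testing.assert_allclose(part.proportions["a"], s2a / (s2a + s2b + om))
        np.testing.assert_allclose(part.proportions["distribution"],
                                   om / (s2a + s2b + om))

    def test_proportions_sum_to_one_per_draw(self):
        rng = np.random.default_rng(1)
        ps = make_posterior(
            variances={t: rng.gamma(2, size=200) for t in "abcd"},
            fixed={"intercept": rng.normal(3, 0.1, 200)},
        )
        total = sum(p for p in partition_variance(ps).proportions.values())
        np.testing.assert_allclose(total, 1.0, atol=1e-12)

    def test_missing_intercept_rejected(self):
        ps = make_posterior(variances={"a": np.ones(20)})
        with pytest.raises(ValueError, match="intercept"):
            partition_variance(ps)


class TestRepeatability:
    def test_constant_draws_half(self):
        ps = make_posterior(variances={
            "asv:host": 2 * np.ones(20), "asv:group": np.ones(20),
            "asv:host:group": np.ones(20)},
            residual_name="asv:host:group")
        r = repeatability(ps)
        assert r.mean == pytest.approx(0.5)
        assert (r.interval.lower, r.interval.upper) == (0.5, 0.5)

    def test_zero_host_variance_gives_zero(self):
        ps = make_posterior(variances={
            "asv:host": np.zeros(20), "asv:group": np.ones(20),
            "asv:host:group": np.ones(20)},
            residual_name="asv:host:group")
        assert repeatability(ps).mean == 0.0

    def test_varying_draws_mean_equals_per_draw_average(self):
        rng = np.random.default_rng(2)
        h, g, r = (rng.gamma(2, size=100) for _ in range(3))
        ps = make_posterior(variances={
            "asv:host": h, "asv:group": g, "asv:host:group": r},
            residual_name="asv:host:group")
        assert repeatability(ps).mean == pytest.approx(float((h / (g + h + r)).mean()))

    def test_missing_term_named_in_error(self):
        ps = make_posterior(variances={"asv:host": np.ones(20)},
                            residual_name="asv:host:group")
        with pytest.raises(ValueError, match="asv:group"):
            repeatability(ps)


def _contrast_posterior(contrasts: dict[str, np.ndarray], n: int):
    """Posterior whose asv:group draws realize given per-taxon contrasts:
    u[taxon, G1] = 0, u[taxon, G2] = contrast draws."""
    taxa = sorted(contrasts)
    labels = [(t, g) for t in taxa for g in ("G1", "G2")]
    arr = np.zeros((1, n, len(labels)))
    for i, (t, g) in enumerate(labels):
        if g == "G2":
            arr[0, :, i] = contrasts[t]
    return make_posterior(
        variances={"asv:group": np.ones(n)},
        random={"asv:group": arr},
        term_labels={"asv:group": labels},
    )


class TestDifferentialAbundance:
    def test_constant_contrast_robust(self):
        ps = _contrast_posterior({"A1": np.ones(50)}, 50)
        da = differential_abundance(ps, level_a="G1", level_b="G2")
        row = da.table.iloc[0]
        assert row["mean_diff"] == pytest.approx(1.0)
        assert (row["hpdi_lo"], row["hpdi_hi"]) == (1.0, 1.0)
        assert bool(row["robust"])

    def test_symmetric_contrast_not_robust(self):
        sym = np.concatenate([np.linspace(-1, -0.1, 25), np.linspace(0.1, 1, 25)])
        ps = _contrast_posterior({"A1": sym}, 50)
        da = differential_abundance(ps)
        assert not bool(da.table.iloc[0]["robust"])

    def test_uniform_grid_contrast(self):
        grid = np.linspace(0.8, 1.2, 41)
        ps = _contrast_posterior({"A1": grid}, 41)
        da = differential_abundance(ps)
        row = da.table.iloc[0]
        assert row["mean_diff"] == pytest.approx(1.0)
        assert row["hpdi_lo"] > 0
        assert bool(row["robust"])

    def test_antisymmetric_in_levels(self):
        rng = np.random.default_rng(3)
        ps = _contrast_posterior({"A1": rng.normal(0.4, 1, 200),
                                  "A2": rng.normal(-1, 0.2, 200)}, 200)
        fwd = differential_abundance(ps, level_a="G1", level_b="G2").table
        rev = differential_abundance(ps, level_a="G2", level_b="G1").table
        np.testing.assert_allclose(fwd["mean_diff"], -rev["mean_diff"])
        np.testing.assert_allclose(fwd["hpdi_lo"], -rev["hpdi_hi"])
        np.testing.assert_allclose(fwd["hpdi_hi"], -rev["hpdi_lo"])
        np.testing.assert_array_equal(fwd["robust"], rev["robust"])

    def test_missing_level_flagged_not_dropped(self):
        labels = [("A1", "G1"), ("A1", "G2"), ("A2", "G1")]  # A2 lacks G2
        arr = np.zeros((1, 50, 3))
        ps = make_posterior(variances={"asv:group": np.ones(50)},
                            random={"asv:group": arr},
                            term_labels={"asv:group": labels})
        da = differential_abundance(ps)
        assert list(da.table["asv_id"]) == ["A1", "A2"]
        assert bool(da.table.set_index("asv_id").loc["A2", "missing"])

    def test_unknown_level_rejected(self):
        ps = _contrast_posterior({"A1": np.ones(50)}, 50)
        with pytest.raises(ValueError, match="autumn"):
            differential_abundance(ps, level_a="G1", level_b="autumn")


class TestSummarizeShifts:
    @staticmethod
    def _da(mean_diffs, robust, phyla):
        from asvglmm.inference import DifferentialAbundanceTable
        table = pd.DataFrame({
            "asv_id": [f"A{i}" for i in range(len(mean_diffs))],
            "mean_diff": mean_diffs,
            "hpdi_lo": [m - 0.1 if r else -1 for m, r in zip(mean_diffs, robust)],
            "hpdi_hi": [m + 0.1 if r else 1 for m, r in zip(mean_diffs, robust)],
            "robust": robust,
            "inv_var": 1.0,
            "missing": False,
            "Phylum": phyla,
        })
        return DifferentialAbundanceTable("asv:group", "G1", "G2", 0.95, table)

    def test_direction_composition(self):
        da = self._da([1.0, 2.0, -1.0, -2.0], [True] * 4, ["X", "X", "X", "Y"])
        s = summarize_shifts(da, "Phylum")
        assert s.n_robust == 4 and s.n_positive == 2 and s.n_negative == 2
        assert s.positive_by_rank == {"X": 100.0}
        assert s.negative_by_rank == {"X": 50.0, "Y": 50.0}

    def test_empty_robust_set(self):
        da = self._da([0.1, -0.1], [False, False], ["X", "Y"])
        s = summarize_shifts(da, "Phylum")
        assert s.n_robust == 0 and s.pct_robust == 0.0
        assert s.positive_by_rank == {} and s.negative_by_rank == {}

    def test_robust_fraction_rounding(self):
        # 683 robust of 2023 -> 33.76% to two decimals
        n = 2023
        robust = [True] * 683 + [False] * (n - 683)
        da = self._da([1.0] * n, robust, ["X"] * n)
        s = summarize_shifts(da, "Phylum")
        assert s.pct_robust == 33.76

    def test_missing_rank_rejected(self):
        da = self._da([1.0], [True], ["X"])
        with pytest.raises(ValueError, match="Genus"):
            summarize_shifts(da, "Genus")
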