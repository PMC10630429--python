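"""Realized growth, its delta-method uncertainty, within-site comparisons,
survival curve fits, and cross-over detection."""

import numpy as np
import pytest
from scipy import stats

import phytoclines as pc
from phytoclines.performance import letters_from_significance
from phytoclines.simulate import SimulationConfig, SiteSurvivalParams


def _cell(species="a", site="s", n_planted=100, n_survived=50,
          n_measured=25, m=10.0, s=2.0):
    return pc.PerformanceCell(
        species_id=species, site_id=site, n_planted=n_planted,
        n_survived=n_survived, n_measured=n_measured, trait_mean=m, trait_sd=s,
    )


class TestRealizedGrowth:
    def test_certain_survival_reduces_to_sem(self):
        g = pc.realized_growth(_cell(n_survived=100, n_measured=25))
        assert g.h_star == pytest.approx(10.0)
        assert g.se == pytest.approx(2.0 / np.sqrt(25))

    def test_zero_survival(self):
        g = pc.realized_growth(_cell(n_survived=0, n_measured=0, m=0.0, s=0.0))
        assert g.h_star == 0.0 and g.se == 0.0

    def test_hand_arithmetic_oracle(self):
        """p=0.5, n'=100, m=10, s=2, n=25:
        se^2 = (0.25 + 0.0025)*(4/25) + 100*0.0025 = 0.2904."""
        g = pc.realized_growth(_cell())
        assert g.h_star == pytest.approx(5.0)
        assert g.se == pytest.approx(np.sqrt(0.2904), rel=1e-12)

    def test_monte_carlo_se_oracle(self, rng):
        """The closed form equals the s.d. of p_hat * mean under binomial
        survival and a normal sampling distribution of the mean (the
        product-moment identity makes this exact; MC to 2%)."""
        p, nprime, m, s, n = 0.3, 150, 20.0, 5.0, 12
        reps = 400_000
        p_hat = rng.binomial(nprime, p, reps) / nprime
        mbar = rng.normal(m, s / np.sqrt(n), reps)
        mc = np.std(p_hat * mbar)
        g = pc.realized_growth(_cell(n_planted=nprime, n_survived=int(p * nprime),
                                     n_measured=n, m=m, s=s))
        assert g.se == pytest.approx(mc, rel=0.02)

    def test_single_measurement_se_undefined(self):
        g = pc.realized_growth(_cell(n_survived=10, n_measured=1, s=0.0))
        assert g.se is None

    def test_zero_planted_rejected(self):
        with pytest.raises(Exception):
            pc.realized_growth(_cell(n_planted=0, n_survived=0, n_measured=0))


class TestCompareRealized:
    def _growth(self, h_stars, ses, site="s"):
        return [
            pc.RealizedGrowth(species_id=f"sp{i}", site_id=site, h_star=h,
                              se=se, p_hat=0.5, trait_mean=2 * h)
            for i, (h, se) in enumerate(zip(h_stars, ses))
        ]

    def test_identical_cells_p_one(self):
        df, _ = pc.compare_realized(self._growth([5.0, 5.0], [1.0, 1.0]))
        assert df["p"].iloc[0] == pytest.approx(1.0)

    def test_z_oracle(self):
        """H*={10,5}, se={1,1}: z = 5/sqrt(2) = 3.536, p = 2*Phi(-z)."""
        df, _ = pc.compare_realized(self._growth([10.0, 5.0], [1.0, 1.0]))
        assert df["z"].iloc[0] == pytest.approx(3.5355, abs=1e-3)
        assert df["p"].iloc[0] == pytest.approx(2 * stats.norm.sf(3.53553), rel=1e-3)

    def test_letter_groups_one_distinct(self):
        df, letters = pc.compare_realized(
            self._growth([20.0, 5.0, 5.2], [0.5, 0.5, 0.5])
        )
        assert letters["sp0"] != letters["sp1"]
        assert letters["sp1"] == letters["sp2"]

    def test_symmetry_and_scale_invariance(self):
        a = self._growth([10.0, 6.0, 3.0], [1.0, 2.0, 0.5])
        b = self._growth([30.0, 18.0, 9.0], [3.0, 6.0, 1.5])
        pa, _ = pc.compare_realized(a)
        pb, _ = pc.compare_realized(b)
        assert np.allclose(pa["p"], pb["p"])

    def test_adjusted_at_least_raw(self):
        df, _ = pc.compare_realized(
            self._growth([10, 8, 6, 4], [1, 1, 1, 1])
        )
        assert np.all(df["p_adjusted"] >= df["p"] - 1e-12)

    def test_needs_two_with_se(self):
        g = self._growth([5.0], [1.0])
        with pytest.raises(ValueError):
            pc.compare_realized(g)


class TestLetterDisplay:
    def test_brute_force_three_groups(self):
        """One group significantly distinct from two indistinguishable ones
        must receive its own letter: {a, b, b}."""
        letters = letters_from_significance(
            ["x", "y", "z"], {("x", "y"), ("x", "z")}
        )
        assert letters["x"] != letters["y"]
        assert letters["y"] == letters["z"]

    def test_no_significance_single_letter(self):
        letters = letters_from_significance(["x", "y", "z"], set())
        assert len(set(letters.values())) == 1

    def test_chain_structure(self):
        # x != z but y indistinguishable from both: y shares with each
        letters = letters_from_significance(["x", "y", "z"], {("x", "z")})
        assert set(letters["x"]) & set(letters["y"])
        assert set(letters["y"]) & set(letters["z"])
        assert not set(letters["x"]) & set(letters["z"])


class TestCompareSurvival:
    def test_equal_counts_p_one(self):
        df = pc.compare_survival([_cell(species="a"), _cell(species="b")])
        assert df["p"].iloc[0] == pytest.approx(1.0)

    def test_yates_textbook_oracle(self):
        """90/100 vs 10/100: chi2_Yates = 200*(|90*90-10*10|-100)^2/100^4
        = 124.82."""
        a = _cell(species="a", n_survived=90, n_measured=10)
        b = _cell(species="b", n_survived=10, n_measured=10)
        df = pc.compare_survival([a, b])
        assert df["chi2"].iloc[0] == pytest.approx(124.82, abs=0.01)
        assert df["p"].iloc[0] < 1e-25

    def test_small_counts_bounds(self):
        a = pc.PerformanceCell("a", "s", 2, 1, 1, 1.0, 0.0)
        b = pc.PerformanceCell("b", "s", 2, 2, 2, 1.0, 0.0)
        df = pc.compare_survival([a, b])
        assert df["chi2"].iloc[0] >= 0
        assert 0 < df["p"].iloc[0] <= 1

    def test_zero_margin_warns_p_one(self):
        a = pc.PerformanceCell("a", "s", 10, 10, 0, 0.0, 0.0)
        b = pc.PerformanceCell("b", "s", 10, 10, 0, 0.0, 0.0)
        with pytest.warns(UserWarning, match="zero-margin"):
            df = pc.compare_survival([a, b])
        assert df["p"].iloc[0] == 1.0


class TestCompareMeansHSD:
    def test_identical_groups_single_letter(self):
        samples = {k: np.array([5.0, 5.1, 4.9]) for k in "abc"}
        _, letters = pc.compare_means_hsd(samples)
        assert len(set(letters.values())) == 1

    def test_separated_groups_distinct_letters(self, rng):
        samples = {
            "lo": rng.normal(0, 1, 20),
            "hi": rng.normal(10, 1, 20),
        }
        _, letters = pc.compare_means_hsd(samples)
        assert letters["lo"] != letters["hi"]

    def test_singleton_group_excluded(self, rng):
        samples = {"a": rng.normal(0, 1, 10), "b": rng.normal(0, 1, 10),
                   "c": np.array([1.0])}
        _, letters = pc.compare_means_hsd(samples)
        assert "c" not in letters

    def test_balanced_three_group_studentized_range_oracle(self, rng):
        """The HSD p-value for a pair equals the studentized-range tail
        probability at q = |diff| / sqrt(MSE/n)."""
        k, n = 3, 15
        data = {g: rng.normal(i, 1.0, n) for i, g in enumerate("abc")}
        df, _ = pc.compare_means_hsd(data)
        mse = np.mean([np.var(v, ddof=1) for v in data.values()])
        dfree = k * (n - 1)
        row = df[(df.species_a == "a") & (df.species_b == "b")].iloc[0]
        q = abs(np.mean(data["a"]) - np.mean(data["b"])) / np.sqrt(mse / n)
        expect = stats.studentized_range.sf(q, k, dfree)
        assert row.p == pytest.approx(expect, rel=1e-6)


class TestSigmoidFit:
    def test_recovery_from_noisy_sigmoid(self, rng):
        x = np.linspace(0.15, 1.0, 10)
        true = pc.SigmoidFit(0.9, -10.0, 0.5, 0, 0, 0, 0, 0, 0, True)
        y = true.predict(x) + rng.normal(0, 0.01, len(x))
        fit = pc.fit_survival_sigmoid(y, x)
        assert fit.converged
        assert fit.s_max == pytest.approx(0.9, abs=0.1)
        assert fit.beta == pytest.approx(-10.0, rel=0.5)
        assert fit.a == pytest.approx(0.5, abs=0.1)

    def test_exact_sigmoid_zero_rss(self):
        x = np.linspace(0.2, 1.0, 8)
        y = 0.8 / (1 + np.exp(5.0 * (0.6 - x)))
        fit = pc.fit_survival_sigmoid(y, x)
        assert fit.rss == pytest.approx(0.0, abs=1e-10)
        assert fit.sigmoid_preferred

    def test_constant_survival_prefers_linear(self):
        x = np.linspace(0.2, 1.0, 8)
        fit = pc.fit_survival_sigmoid(np.full(8, 0.5), x)
        assert not fit.sigmoid_preferred

    def test_needs_four_points(self):
        with pytest.raises(ValueError):
            pc.fit_survival_sigmoid([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])


class TestCounterfactualSurvival:
    def _site_cells(self, p_hats, species_pe):
        cells, info = [], []
        for i, (p, pe) in enumerate(zip(p_hats, species_pe)):
            n = 100
            surv = int(round(p * n))
            cells.append(pc.PerformanceCell(
                f"sp{i}", "s", n, surv, min(surv, 10), 10.0, 2.0))
            info.append(pc.SpeciesInfo(f"sp{i}", pe))
        return cells, info

    def test_linear_prediction_oracle(self):
        """Others lie on p = 0.9 - 0.5*pe; target at pe=0.6 -> p=0.6."""
        pe = [0.2, 0.4, 0.8, 1.0, 0.6]
        p = [0.9 - 0.5 * x for x in pe[:4]] + [0.95]
        cells, info = self._site_cells(p, pe)
        adj, growth = pc.counterfactual_survival(cells, info, "sp4")
        assert adj.p_hat == pytest.approx(0.6, abs=0.01)
        assert growth.h_star == pytest.approx(0.6 * 10.0, abs=0.1)

    def test_on_line_target_unchanged(self):
        pe = [0.2, 0.4, 0.8, 1.0, 0.6]
        p = [0.9 - 0.5 * x for x in pe]
        cells, info = self._site_cells(p, pe)
        adj, _ = pc.counterfactual_survival(cells, info, "sp4")
        assert adj.p_hat == pytest.approx(cells[4].p_hat, abs=0.01)

    def test_outlier_above_line_strictly_lowered(self):
        pe = [0.2, 0.4, 0.8, 1.0, 0.6]
        p = [0.9 - 0.5 * x for x in pe[:4]] + [0.99]
        cells, info = self._site_cells(p, pe)
        _, growth = pc.counterfactual_survival(cells, info, "sp4")
        before = pc.realized_growth(cells[4])
        assert growth.h_star < before.h_star

    def test_needs_three_others(self):
        cells, info = self._site_cells([0.5, 0.6, 0.7], [0.2, 0.5, 0.8])
        with pytest.raises(ValueError):
            pc.counterfactual_survival(cells, info, "sp0")


class TestDetectCrossover:
    def _growth_table(self, h_by_site_species, sites, species):
        out = []
        for site, hs in h_by_site_species.items():
            for sp, h in hs.items():
                out.append(pc.RealizedGrowth(
                    species_id=sp, site_id=site, h_star=h, se=0.1,
                    p_hat=0.5, trait_mean=2 * h))
        return out

    def test_planted_reversal_flagged(self):
        """Default generator expectations reverse ranks between the driest
        and wettest garden; the detector must fire on the truth table."""
        cfg = pc.default_config(seed=4, n_traits=1)
        _, truth = pc.simulate_performance(cfg)
        growth = [
            pc.RealizedGrowth(species_id=k.split("@")[0],
                              site_id=k.split("@")[1],
                              h_star=v["h_star"], se=0.01, p_hat=v["survival"],
                              trait_mean=v["height"])
            for k, v in truth.items()
        ]
        report = pc.detect_crossover(growth, cfg.sites(), cfg.species())
        assert report.crossover
        assert report.rho_driest < 0 < report.rho_wettest

    def test_parallel_norms_not_flagged(self):
        sites = [pc.SiteInfo("d", 0.2), pc.SiteInfo("w", 1.2)]
        species = [pc.SpeciesInfo(f"sp{i}", 0.2 + 0.2 * i) for i in range(4)]
        h = {"d": {s.species_id: 1 + i for i, s in enumerate(species)},
             "w": {s.species_id: 2 + i for i, s in enumerate(species)}}
        report = pc.detect_crossover(
            self._growth_table(h, sites, species), sites, species)
        assert not report.crossover

    def test_single_site_rejected(self):
        sites = [pc.SiteInfo("d", 0.2)]
        species = [pc.SpeciesInfo(f"sp{i}", 0.3 + 0.2 * i) for i in range(3)]
        h = {"d": {s.species_id: 1.0 for s in species}}
        with pytest.raises(ValueError, match="2 sites"):
            pc.detect_crossover(self._growth_table(h, sites, species),
                                sites, species)

    def test_ordering_invariant_for_nontarget_species(self):
        """Counterfactually replacing one species' survival must not change
        the H* ordering of the others."""
        pe = [0.2, 0.35, 0.5, 0.75, 1.0]
        p = [0.8, 0.7, 0.6, 0.5, 0.95]
        cells = [pc.PerformanceCell(f"sp{i}", "s", 100, int(100 * pi),
                                    10, 5.0 + i, 1.0)
                 for i, pi in enumerate(p)]
        info = [pc.SpeciesInfo(f"sp{i}", x) for i, x in enumerate(pe)]
        before = {c.species_id: pc.realized_growth(c).h_star for c in cells}
        adj, _ = pc.counterfactual_survival(cells, info, "sp4")
        after = {c.species_id: pc.realized_growth(c).h_star
                 for c in cells if c.species_id != "sp4"}
        order_b = sorted(after, key=before.get)
        order_a = sorted(after, key=after.get)
        assert order_a == order_b
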