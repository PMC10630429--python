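"""The phylogenetic mixed model: likelihood correctness against independent
oracles, model selection, FDR adjustment, and agreement tallies."""

import io

import numpy as np
import pytest
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests

import phytoclines as pc
from phytoclines import regression
from phytoclines.datamodel import TraitDefinition, Transform
from phytoclines.regression import (
    build_random_structures,
    fit_candidate,
    select_model,
    tally_agreement,
    ybh_adjust,
)
from phytoclines.simulate import SimulationConfig, TraitGenerator


def _study(seed, *, sigma2_phylo=0.09, sigma2_site=0.01, sigma2_e=0.04,
           b_site=1.5, b_species=2.0, n_traits=1, transform=Transform.NONE):
    traits = [
        TraitGenerator(
            trait_id=f"t{i}", a=0.3, b_site=b_site, b_species=b_species,
            sigma2_phylo=sigma2_phylo, sigma2_site=sigma2_site,
            sigma2_e=sigma2_e, transform=transform,
        )
        for i in range(n_traits)
    ]
    cfg = SimulationConfig(traits=traits, seed=seed)
    tree = pc.simulate_tree(cfg.n_species, 52.0, seed=seed, labels=cfg.species_ids)
    tt = pc.simulate_traits(cfg, tree)
    return cfg, tree, tt


def _design_from_study(cfg, tree, tt, trait="t0"):
    ser = tt.trait(trait)
    sp = [i[0] for i in ser.index]
    si = [i[1] for i in ser.index]
    sp_order = sorted(set(sp))
    si_order = sorted(set(si))
    sp_codes = np.array([sp_order.index(s) for s in sp])
    si_codes = np.array([si_order.index(s) for s in si])
    C = pc.brownian_covariance(tree, sp_order)
    structures = build_random_structures(sp_codes, si_codes, C)
    site_pe = dict(zip(cfg.site_ids, cfg.site_pe))
    sp_pe = dict(zip(cfg.species_ids, cfg.species_pe))
    X = np.column_stack([
        np.ones(len(ser)),
        np.log([site_pe[s] for s in si]),
        np.log([sp_pe[s] for s in sp]),
    ])
    return ser.to_numpy(float), X, structures, sp


class TestFitCandidate:
    def test_star_tree_equals_iid_lmm_oracle(self):
        """On a star phylogeny the Brownian matrix is diagonal, so the
        phylogenetic model is an ordinary random-intercept LMM grouped by
        species; the ML log-likelihoods must agree to 1e-6."""
        cfg, _, tt = _study(21)
        star = pc.read_newick(io.StringIO(
            "(" + ",".join(f"{s}:1" for s in cfg.species_ids) + "):0;"
        ))
        y, X, structures, sp = _design_from_study(cfg, star, tt)
        fit = fit_candidate(y, X, ["b0", "b1", "b2"], structures, ["species_phylo"])
        oracle = sm.MixedLM(y, X, groups=np.array(sp)).fit(reml=False)
        assert fit.loglik == pytest.approx(float(oracle.llf), abs=1e-6)

    def test_zero_variances_match_ols(self):
        """Data generated exactly on the fixed-effect plane (all variances
        zero): the GLS coefficients equal OLS regardless of the fitted
        covariance."""
        cfg, tree, tt = _study(3, sigma2_phylo=0.0, sigma2_site=0.0, sigma2_e=0.0)
        y, X, structures, _ = _design_from_study(cfg, tree, tt)
        fit = fit_candidate(y, X, ["b0", "b1", "b2"], structures)
        ols = np.linalg.lstsq(X, y, rcond=None)[0]
        assert np.allclose(fit.beta, ols, atol=1e-8)

    def test_zero_phylo_variance_matches_nonphylo_model(self):
        """Removing a component whose fitted variance is zero leaves the
        likelihood unchanged: the phylogenetic model nests the plain one."""
        cfg, tree, tt = _study(5, sigma2_phylo=0.0)
        y, X, structures, _ = _design_from_study(cfg, tree, tt)
        with_phylo = fit_candidate(
            y, X, ["b0", "b1", "b2"], structures, ["site", "species", "species_phylo"]
        )
        without = fit_candidate(y, X, ["b0", "b1", "b2"], structures, ["site", "species"])
        assert with_phylo.loglik >= without.loglik - 1e-7
        assert with_phylo.loglik == pytest.approx(without.loglik, abs=1e-4)

    def test_aic_counts_parameters(self):
        cfg, tree, tt = _study(8)
        y, X, structures, _ = _design_from_study(cfg, tree, tt)
        f1 = fit_candidate(y, X, ["b0", "b1", "b2"], structures, ["species"])
        assert f1.aic == pytest.approx(-2 * f1.loglik + 2 * (3 + 1 + 1))


class TestSelectModel:
    def test_exact_site_trait_r2_one_species_dropped(self):
        """A trait equal to ln(site P/E_p) exactly is explained perfectly;
        species-level random effects are eliminated."""
        cfg, tree, tt = _study(2, sigma2_phylo=0.0, sigma2_site=0.0, sigma2_e=0.0,
                               b_site=1.0, b_species=0.0)
        res = select_model("t0", tt, tree, cfg.sites(), cfg.species())
        assert res.r2_total == pytest.approx(1.0, abs=1e-6)
        assert "species" not in res.retained_effects
        assert "species_phylo" not in res.retained_effects

    @pytest.mark.parametrize("seed", range(12))
    def test_generative_form_selected(self, seed):
        """A trait generated additive on the log scale should be recovered
        as additive/log by the AIC + parsimony rule in most replicates."""
        cfg, tree, tt = _study(
            100 + seed, b_site=1.5, b_species=2.0, sigma2_e=0.01,
            sigma2_phylo=0.02, sigma2_site=0.005, transform=Transform.LOG,
        )
        res = select_model("t0", tt, tree, cfg.sites(), cfg.species())
        self._record = res
        assert res.form == "additive"

    def test_slope_recovery_single_dataset(self):
        cfg, tree, tt = _study(77)
        res = select_model("t0", tt, tree, cfg.sites(), cfg.species())
        c_site = res.coefficients["ln_site_pe"]
        c_sp = res.coefficients["ln_species_pe"]
        assert abs(c_site["estimate"] - 1.5) < 3 * c_site["se"]
        assert abs(c_sp["estimate"] - 2.0) < 3 * c_sp["se"]

    def test_relabeling_invariance(self):
        """Renaming species and sites must not change the fitted model."""
        cfg, tree, tt = _study(31)
        res1 = select_model("t0", tt, tree, cfg.sites(), cfg.species())
        # relabel: reverse the id strings (keeps uniqueness, changes sort order)
        sp_map = {s: f"x{s[::-1]}" for s in cfg.species_ids}
        si_map = {s: f"y{s[::-1]}" for s in cfg.site_ids}
        df = tt.data.copy()
        df.index = type(df.index).from_tuples(
            [(sp_map[a], si_map[b]) for a, b in df.index],
            names=["species_id", "site_id"],
        )
        tt2 = pc.TraitTable(data=df)
        for leaf in tree.tree.leaf_node_iter():
            leaf.taxon.label = sp_map[leaf.taxon.label]
        tree2 = pc.Phylogeny(tree.tree)
        sites2 = [pc.SiteInfo(si_map[s.site_id], s.site_pe) for s in cfg.sites()]
        species2 = [pc.SpeciesInfo(sp_map[s.species_id], s.species_pe)
                    for s in cfg.species()]
        res2 = select_model("t0", tt2, tree2, sites2, species2)
        for pred in ("ln_site_pe", "ln_species_pe"):
            assert res2.coefficients[pred]["estimate"] == pytest.approx(
                res1.coefficients[pred]["estimate"], abs=1e-5
            )
        assert res2.loglik == pytest.approx(res1.loglik, abs=1e-5)

    def test_too_few_cells_rejected(self):
        cfg, tree, tt = _study(1)
        tt.data.iloc[:35, 0] = np.nan
        with pytest.raises(ValueError, match="non-missing"):
            select_model("t0", tt, tree, cfg.sites(), cfg.species())


class TestYbhAdjust:
    def test_all_zero(self):
        assert np.allclose(ybh_adjust([0.0, 0.0, 0.0], m_total=3), 0.0)

    def test_single_p_m1(self):
        assert ybh_adjust([0.05], m_total=1)[0] == pytest.approx(0.05)

    def test_three_p_brute_force_oracle(self):
        """Step-up with c(3) = 1 + 1/2 + 1/3 = 11/6, computed by hand:
        adj_(k) = min_{j>=k} 3*(11/6)*p_(j)/j, clipped to 1."""
        p = [0.001, 0.02, 0.9]
        c3 = 11.0 / 6.0
        raw = [3 * c3 * 0.001 / 1, 3 * c3 * 0.02 / 2, 3 * c3 * 0.9 / 3]
        expect = [min(raw[0], raw[1], 1.0), min(raw[1], 1.0), min(raw[2], 1.0)]
        assert np.allclose(ybh_adjust(p, m_total=3), expect)

    def test_matches_statsmodels_when_family_complete(self, rng):
        p = rng.uniform(0, 1, 50)
        ours = ybh_adjust(p, m_total=50)
        theirs = multipletests(p, method="fdr_by")[1]
        assert np.allclose(ours, theirs, atol=1e-12)

    def test_dominates_plain_bh(self, rng):
        p = rng.uniform(0, 1, 40)
        by = ybh_adjust(p, m_total=40)
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.all(by >= bh - 1e-12)

    def test_adjusted_at_least_raw(self, rng):
        p = rng.uniform(0, 1, 30)
        assert np.all(ybh_adjust(p, m_total=106) >= p - 1e-12)

    def test_family_too_small_rejected(self):
        with pytest.raises(ValueError, match="m_total"):
            ybh_adjust([0.1, 0.2], m_total=1)

    def test_monotone_in_rank(self, rng):
        p = np.sort(rng.uniform(0, 1, 20))
        adj = ybh_adjust(p, m_total=106)
        assert np.all(np.diff(adj) >= -1e-12)


class TestTallyAgreement:
    def _results(self, signs_site, signs_species, p=1e-4):
        out = []
        for i, (a, b) in enumerate(zip(signs_site, signs_species)):
            out.append(
                regression.RegressionResult(
                    trait_id=f"t{i}", form="additive", transform=Transform.NONE,
                    coefficients={
                        "intercept": {"estimate": 0.0, "se": 1.0, "p": 1.0},
                        "ln_site_pe": {"estimate": float(a), "se": 0.1, "p": p},
                        "ln_species_pe": {"estimate": float(b), "se": 0.1, "p": p},
                    },
                    variance_components={}, retained_effects=[], aic=0.0,
                    loglik=0.0, n_obs=40, r2_total=0.5, partial_r2={},
                )
            )
        return out

    def _defs(self, n, direction=1):
        return [TraitDefinition(trait_id=f"t{i}", predicted_direction=direction)
                for i in range(n)]

    def test_all_agree_is_100(self):
        res = self._results([1] * 53, [1] * 53)
        report = tally_agreement(res, self._defs(53))
        assert report.pct_agree["ln_site_pe"] == pytest.approx(100.0)
        assert report.pct_agree["ln_species_pe"] == pytest.approx(100.0)

    def test_one_discounted_at_09_gives_998(self):
        """52 full agreements + one at 0.9 out of 53 -> 52.9/53 = 99.8%."""
        res = self._results([1] * 52 + [-1], [1] * 53)
        report = tally_agreement(
            res, self._defs(53), exceptions={("t52", "ln_site_pe"): ("species", 1)}
        )
        assert report.pct_agree["ln_site_pe"] == pytest.approx(100 * 52.9 / 53)

    def test_all_exception_weights_applied_exactly(self):
        res = self._results([-1, -1, -1, -1, 1], [1] * 5)
        exceptions = {
            ("t0", "ln_site_pe"): ("species", 1),
            ("t1", "ln_site_pe"): ("species", 2),
            ("t2", "ln_site_pe"): ("garden", 1),
            ("t3", "ln_site_pe"): ("garden", 2),
        }
        report = tally_agreement(res, self._defs(5), exceptions=exceptions)
        weights = dict(
            zip(report.rows[report.rows.predictor == "ln_site_pe"]["trait_id"],
                report.rows[report.rows.predictor == "ln_site_pe"]["weight"])
        )
        assert weights == {"t0": 0.9, "t1": 0.8, "t2": 0.75, "t3": 0.5, "t4": 1.0}
        assert report.pct_agree["ln_site_pe"] == pytest.approx(
            100 * (0.9 + 0.8 + 0.75 + 0.5 + 1.0) / 5
        )

    def test_disagreement_counts_zero(self):
        res = self._results([-1] * 4, [1] * 4)
        report = tally_agreement(res, self._defs(4))
        assert report.pct_agree["ln_site_pe"] == 0.0
        assert report.pct_agree["ln_species_pe"] == pytest.approx(100.0)

    def test_missing_prediction_excluded(self):
        res = self._results([1, 1], [1, 1])
        report = tally_agreement(res, self._defs(1))
        assert report.n_traits == 1

    def test_detected_species_exception(self):
        """A trait agreeing with the predicted direction except for the
        driest species: the refit-without-driest path assigns weight 0.9."""
        tg = TraitGenerator(trait_id="t0", a=0.0, b_site=1.0, b_species=1.5,
                            sigma2_phylo=0.0, sigma2_site=0.0, sigma2_e=1e-4)
        cfg = SimulationConfig(traits=[tg], seed=9)
        tree = pc.simulate_tree(cfg.n_species, 52.0, seed=9, labels=cfg.species_ids)
        tt = pc.simulate_traits(cfg, tree)
        # force the driest species far above the plane so the overall
        # species slope flips sign
        driest = cfg.species_ids[int(np.argmin(cfg.species_pe))]
        mask = tt.data.index.get_level_values("species_id") == driest
        tt.data.loc[mask, "t0"] += 8.0
        res = select_model("t0", tt, tree, cfg.sites(), cfg.species())
        assert res.coef_sign("ln_species_pe") == -1
        report = tally_agreement(
            [res], [tg.definition()], detect_exceptions=True,
            refit_context=(tt, tree, cfg.sites(), cfg.species()),
        )
        row = report.rows[
            (report.rows.trait_id == "t0")
            & (report.rows.predictor == "ln_species_pe")
        ].iloc[0]
        assert row.verdict == "agree-except-driest-species"
        assert row.weight == 0.9
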