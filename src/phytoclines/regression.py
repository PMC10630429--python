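"""Phylogenetically structured regression of traits on moisture supply.

For each trait the model is a Gaussian mixed model on the transformed
species-by-site means

    z = b0 + b_site ln(site P/E_p) + b_species ln(species P/E_p)
        [+ c ln(site)*ln(species)] + random effects + error,

with up to four variance components: garden (iid site effect), species
(iid, absorbing non-phylogenetic species differences), species-with-
phylogeny (covariance proportional to the Brownian matrix of the
time-calibrated tree), and phylogeny-nested-in-site ("phylogenetic
attraction": an independent Brownian draw within each garden).

Model choice follows the two-stage procedure of the analysis it
implements: the fixed form (additive vs. interaction) and trait transform
are chosen by AIC and parsimony on ordinary least squares, then the four
random effects are added and backward-eliminated with a generous
likelihood-ratio retention cutoff (p < 0.5), never removing the iid
species term while a phylogenetic term remains untested.  Estimation is
by maximum likelihood (profiled over the fixed effects and the residual
variance) so AIC comparisons across fixed-effect forms are valid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datamodel import (
    Phylogeny,
    SiteInfo,
    SpeciesInfo,
    TraitDefinition,
    TraitTable,
    Transform,
    apply_transform,
    brownian_covariance,
)

__all__ = [
    "RANDOM_EFFECTS",
    "MixedModelFit",
    "RegressionResult",
    "TallyReport",
    "build_random_structures",
    "fit_candidate",
    "select_model",
    "ybh_adjust",
    "tally_agreement",
]

RANDOM_EFFECTS = ("site", "species", "species_phylo", "phylo_in_site")

_SIGMA2_FLOOR = 1e-10  # residual-variance floor for exact-fit degenerate data


# ---------------------------------------------------------------------------
# Random-effect covariance structures over the observation grid
# ---------------------------------------------------------------------------

def build_random_structures(
    species_codes: np.ndarray,
    site_codes: np.ndarray,
    brownian: np.ndarray,
) -> dict[str, np.ndarray]:
    """Covariance kernels (unit-variance scale) for the four random effects
    over n observations indexed by species and site codes.

    ``brownian`` is the species-level Brownian matrix, normalized so its
    diagonal is 1 (tip-level variance) before being expanded to the grid.
    """
    h = float(np.max(np.diag(brownian)))
    C = brownian / h if h > 0 else brownian
    same_site = (site_codes[:, None] == site_codes[None, :]).astype(float)
    same_species = (species_codes[:, None] == species_codes[None, :]).astype(float)
    C_obs = C[np.ix_(species_codes, species_codes)]
    return {
        "site": same_site,
        "species": same_species,
        "species_phylo": C_obs,
        "phylo_in_site": C_obs * same_site,
    }


# ---------------------------------------------------------------------------
# Profile-ML fitting
# ---------------------------------------------------------------------------


@dataclass
class MixedModelFit:
    """One fitted Gaussian mixed model (ML)."""

    loglik: float
    aic: float
    beta: np.ndarray
    beta_se: np.ndarray
    beta_names: list[str]
    sigma2_e: float
    variance_components: dict[str, float]
    n_obs: int
    n_params: int
    converged: bool = True
    optimizer_trace: str = ""

    def wald_p(self) -> dict[str, float]:
        """Two-sided Wald p-values with a standard-normal reference."""
        out = {}
        for name, b, se in zip(self.beta_names, self.beta, self.beta_se):
            z = b / se if se > 0 else np.inf * np.sign(b)
            out[name] = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
        return out


def _profile_nll(theta, X, y, G_list, n, reml=False):
    """Negative profile log-likelihood over log variance ratios theta.

    With ``reml`` the restricted likelihood is used: the residual variance
    divides by n - p, and the criterion carries the log|X'V^-1 X| penalty.
    """
    V = np.eye(n)
    for th, G in zip(theta, G_list):
        V = V + np.exp(th) * G
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError:
        V = V + 1e-8 * np.trace(V) / n * np.eye(n)
        L = np.linalg.cholesky(V)
    logdet = 2.0 * np.sum(np.log(np.diag(L)))
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    r = yw - Xw @ beta
    if reml:
        p = X.shape[1]
        sigma2 = max(float(r @ r) / (n - p), _SIGMA2_FLOOR)
        sign, logdet_xvx = np.linalg.slogdet(Xw.T @ Xw)
        nll = 0.5 * (
            (n - p) * (np.log(2 * np.pi * sigma2) + 1.0) + logdet + logdet_xvx
        )
    else:
        sigma2 = max(float(r @ r) / n, _SIGMA2_FLOOR)
        nll = 0.5 * (n * (np.log(2 * np.pi * sigma2) + 1.0) + logdet)
    return nll, beta, sigma2, L, Xw


def fit_candidate(
    y: np.ndarray,
    X: np.ndarray,
    beta_names: Sequence[str],
    structures: dict[str, np.ndarray],
    random_effects: Sequence[str] = RANDOM_EFFECTS,
    *,
    n_starts: int = 3,
    loglik_offset: float = 0.0,
    reml: bool = False,
) -> MixedModelFit:
    """Fit one Gaussian mixed model by profiled (restricted) maximum
    likelihood.

    Variance components are parameterized as log ratios to the residual
    variance; the fixed effects and the residual variance are profiled
    out, leaving a bounded quasi-Newton search over at most four
    parameters with multiple deterministic starts to reduce the risk of
    local optima.  ``loglik_offset`` is added to the log-likelihood (and
    enters AIC): it carries the Jacobian of the response transform so that
    AIC values are comparable across transforms.  ML (the default) keeps
    AIC comparisons across fixed-effect forms valid; ``reml`` gives the
    less biased variance components appropriate for Wald inference on the
    final model.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n = len(y)
    G_list = [structures[name] for name in random_effects]
    k_re = len(G_list)
    trace: list[str] = []

    if k_re == 0:
        nll, beta, sigma2, L, Xw = _profile_nll((), X, y, [], n, reml)
        best_theta, best_nll = np.empty(0), nll
        converged = True
    else:
        starts = [np.full(k_re, v) for v in (-2.0, 0.0, -6.0)][:n_starts]
        best_theta, best_nll, converged = None, np.inf, False
        for s in starts:
            res = optimize.minimize(
                lambda th: _profile_nll(th, X, y, G_list, n, reml)[0],
                s,
                method="L-BFGS-B",
                bounds=[(-25.0, 15.0)] * k_re,
                options={"ftol": 1e-13, "gtol": 1e-9, "maxiter": 500},
            )
            trace.append(f"start={s[0]:.0f} nll={res.fun:.6f} success={res.success}")
            if res.fun < best_nll:
                best_nll, best_theta, converged = res.fun, res.x, bool(res.success)
        nll, beta, sigma2, L, Xw = _profile_nll(best_theta, X, y, G_list, n, reml)

    loglik = -nll + loglik_offset
    p = X.shape[1]
    n_params = p + 1 + k_re
    XtX = Xw.T @ Xw
    cov_beta = sigma2 * np.linalg.pinv(XtX)
    se = np.sqrt(np.clip(np.diag(cov_beta), 0, None))
    vcomps = {
        name: float(sigma2 * np.exp(th))
        for name, th in zip(random_effects, best_theta)
    }
    return MixedModelFit(
        loglik=float(loglik),
        aic=float(-2 * loglik + 2 * n_params),
        beta=beta,
        beta_se=se,
        beta_names=list(beta_names),
        sigma2_e=float(sigma2),
        variance_components=vcomps,
        n_obs=n,
        n_params=n_params,
        converged=converged,
        optimizer_trace="; ".join(trace),
    )


# ---------------------------------------------------------------------------
# Small-sample confidence intervals (REML + Satterthwaite)
# ---------------------------------------------------------------------------


def _reml_nll_unprofiled(w, X, y, G_list):
    """REML negative log-likelihood over w = log(sigma2_e, sigma2_1, ...),
    without profiling, up to an additive constant (for Hessian use)."""
    n = X.shape[0]
    V = np.exp(w[0]) * np.eye(n)
    for lw, G in zip(w[1:], G_list):
        V = V + np.exp(lw) * G
    L = np.linalg.cholesky(V)
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    r = yw - Xw @ beta
    _, ld_xvx = np.linalg.slogdet(Xw.T @ Xw)
    return 0.5 * (2.0 * np.sum(np.log(np.diag(L))) + ld_xvx + float(r @ r))


def satterthwaite_df(
    fit: MixedModelFit,
    y: np.ndarray,
    X: np.ndarray,
    structures: dict[str, np.ndarray],
    random_effects: Sequence[str],
    contrast: np.ndarray,
) -> float:
    """Satterthwaite denominator degrees of freedom for a fixed-effect
    contrast, from a REML fit.

    df = 2 (c' Sigma c)^2 / Var(c' Sigma c), with the variance of the
    estimated coefficient variance obtained by the delta method over the
    log variance components (numerical gradient and Hessian of the
    restricted likelihood).  With only 4 gardens this is ~2 for the
    site-level slope — far from the naive n - p, which is why a plain z
    (or residual-df t) interval undercovers.
    """
    G_list = [structures[name] for name in random_effects]
    w_hat = np.concatenate(
        [
            [np.log(max(fit.sigma2_e, 1e-12))],
            [np.log(max(fit.variance_components[nm], 1e-12))
             for nm in random_effects],
        ]
    )
    c = np.asarray(contrast, float)
    n = X.shape[0]

    def se2(w):
        V = np.exp(w[0]) * np.eye(n)
        for lw, G in zip(w[1:], G_list):
            V = V + np.exp(lw) * G
        L = np.linalg.cholesky(V)
        Xw = np.linalg.solve(L, X)
        # V carries sigma2_e itself, so this is c'(X'V^-1 X)^-1 c directly
        return float(c @ np.linalg.pinv(Xw.T @ Xw) @ c)

    k = len(w_hat)
    h = 1e-3
    grad = np.zeros(k)
    for i in range(k):
        e = np.zeros(k)
        e[i] = h
        grad[i] = (se2(w_hat + e) - se2(w_hat - e)) / (2 * h)
    H = np.zeros((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h
            ej = np.zeros(k); ej[j] = h
            H[i, j] = H[j, i] = (
                _reml_nll_unprofiled(w_hat + ei + ej, X, y, G_list)
                - _reml_nll_unprofiled(w_hat + ei - ej, X, y, G_list)
                - _reml_nll_unprofiled(w_hat - ei + ej, X, y, G_list)
                + _reml_nll_unprofiled(w_hat - ei - ej, X, y, G_list)
            ) / (4 * h * h)
    cov_w = np.linalg.pinv(H)
    v = se2(w_hat)
    denom = float(grad @ cov_w @ grad)
    if denom <= 0 or not np.isfinite(denom):
        return float(n - X.shape[1])
    return float(np.clip(2.0 * v * v / denom, 1.0, n - X.shape[1]))


def confidence_intervals(
    fit: MixedModelFit,
    y: np.ndarray,
    X: np.ndarray,
    structures: dict[str, np.ndarray],
    random_effects: Sequence[str],
    *,
    alpha: float = 0.05,
) -> dict[str, tuple[float, float, float]]:
    """Satterthwaite-t confidence intervals per coefficient:
    name -> (lower, upper, df).  Expects a REML fit."""
    out = {}
    for j, name in enumerate(fit.beta_names):
        c = np.zeros(X.shape[1])
        c[j] = 1.0
        df = satterthwaite_df(fit, y, X, structures, random_effects, c)
        q = stats.t.ppf(1 - alpha / 2, df)
        out[name] = (
            float(fit.beta[j] - q * fit.beta_se[j]),
            float(fit.beta[j] + q * fit.beta_se[j]),
            df,
        )
    return out


# ---------------------------------------------------------------------------
# Data assembly and transform/AIC bookkeeping
# ---------------------------------------------------------------------------


def _assemble(
    trait_id: str,
    tt: TraitTable,
    sites: Sequence[SiteInfo],
    species: Sequence[SpeciesInfo],
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray, list[str], list[str]]:
    """Extract the non-missing observations for one trait, with predictors."""
    site_pe = {s.site_id: s.site_pe for s in sites}
    sp_pe = {s.species_id: s.species_pe for s in species}
    ser = tt.trait(trait_id).dropna()
    sp_labels = [i[0] for i in ser.index]
    si_labels = [i[1] for i in ser.index]
    sp_order = sorted(set(sp_labels))
    si_order = sorted(set(si_labels))
    sp_codes = np.array([sp_order.index(s) for s in sp_labels])
    si_codes = np.array([si_order.index(s) for s in si_labels])
    ln_site = np.log([site_pe[s] for s in si_labels])
    ln_sp = np.log([sp_pe[s] for s in sp_labels])
    return ser.to_numpy(float), ln_site, ln_sp, sp_codes, si_codes, sp_order, si_order


def _design(ln_site, ln_sp, form: str):
    cols = [np.ones_like(ln_site), ln_site, ln_sp]
    names = ["intercept", "ln_site_pe", "ln_species_pe"]
    if form == "interaction":
        cols.append(ln_site * ln_sp)
        names.append("ln_site_pe:ln_species_pe")
    return np.column_stack(cols), names


def _transform_offset(y_raw: np.ndarray, transform: Transform) -> float:
    """log |d transform(y)/dy| summed over observations: makes likelihoods
    of transformed-response models comparable on the original data scale."""
    if transform == Transform.LOG:
        return float(-np.sum(np.log(y_raw)))
    if transform == Transform.SQRT:
        return float(-np.sum(np.log(2.0 * np.sqrt(y_raw))))
    return 0.0


def _candidate_transforms(y_raw: np.ndarray) -> list[Transform]:
    out = [Transform.NONE]
    if np.all(y_raw > 0):
        out += [Transform.LOG, Transform.SQRT]
    return out


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------


@dataclass
class RegressionResult:
    """Final fitted model and summaries for one trait."""

    trait_id: str
    form: str
    transform: Transform
    coefficients: dict[str, dict[str, float]]  # name -> {estimate, se, p}
    variance_components: dict[str, float]
    retained_effects: list[str]
    aic: float
    loglik: float
    n_obs: int
    r2_total: float
    partial_r2: dict[str, float]
    adjusted_p: dict[str, float] = field(default_factory=dict)
    verdicts: dict[str, str] = field(default_factory=dict)
    tally_weights: dict[str, float] = field(default_factory=dict)

    def coef_sign(self, predictor: str) -> int:
        est = self.coefficients[predictor]["estimate"]
        return int(np.sign(est)) if est != 0 else 0


def _r2_lik(loglik_full: float, loglik_null: float, n: int) -> float:
    """Likelihood-ratio R2: 1 - exp(-(2/n)(l_full - l_null)), clipped to [0, 1]."""
    return float(np.clip(1.0 - np.exp(-(2.0 / n) * (loglik_full - loglik_null)), 0.0, 1.0))


def select_model(
    trait_id: str,
    tt: TraitTable,
    tree: Phylogeny,
    sites: Sequence[SiteInfo],
    species: Sequence[SpeciesInfo],
    *,
    use_phylogeny: bool = True,
    lrt_cutoff: float = 0.5,
    aic_parsimony_window: float = 2.0,
    min_cells: int = 8,
) -> RegressionResult:
    """Full per-trait model selection.

    1. Choose fixed form (additive vs. interaction) and trait transform by
       OLS AIC, breaking near-ties (within ``aic_parsimony_window``) toward
       fewer parameters.  AICs include the transform Jacobian so they are
       comparable across transforms.
    2. Starting from all four random effects (or two, without phylogeny),
       backward-eliminate by likelihood-ratio test, dropping the component
       with the largest p while p >= ``lrt_cutoff``; the iid species term
       is retained (to absorb non-phylogenetic species differences) until
       both phylogenetic terms have been tested out of the model.
    3. Report Wald z p-values, ML variance components, and total/partial
       likelihood-ratio R2.
    """
    y_raw, ln_site, ln_sp, sp_codes, si_codes, sp_order, _ = _assemble(
        trait_id, tt, sites, species
    )
    if len(y_raw) < min_cells:
        raise ValueError(
            f"trait {trait_id!r}: only {len(y_raw)} non-missing cells (< {min_cells})"
        )
    C = brownian_covariance(tree, sp_order)
    structures = build_random_structures(sp_codes, si_codes, C)

    # -- stage 1: fixed form + transform by OLS AIC -------------------------
    candidates = []
    for transform in _candidate_transforms(y_raw):
        z = apply_transform(y_raw, transform)
        offset = _transform_offset(y_raw, transform)
        for form in ("additive", "interaction"):
            X, names = _design(ln_site, ln_sp, form)
            fit = fit_candidate(z, X, names, structures, (), loglik_offset=offset)
            candidates.append((fit.aic, fit.n_params, form, transform))
    best_aic = min(c[0] for c in candidates)
    in_window = [c for c in candidates if c[0] <= best_aic + aic_parsimony_window]
    in_window.sort(key=lambda c: (c[1], c[0]))
    _, _, form, transform = in_window[0]

    z = apply_transform(y_raw, transform)
    offset = _transform_offset(y_raw, transform)
    X, names = _design(ln_site, ln_sp, form)

    # -- stage 2: backward elimination of random effects --------------------
    active = list(RANDOM_EFFECTS) if use_phylogeny else ["site", "species"]
    full = fit_candidate(z, X, names, structures, active, loglik_offset=offset)
    while active:
        phylo_present = any(e in active for e in ("species_phylo", "phylo_in_site"))
        removable = [e for e in active if not (e == "species" and phylo_present)]
        drop_stats = []
        for eff in removable:
            reduced = fit_candidate(
                z, X, names, structures, [e for e in active if e != eff],
                loglik_offset=offset,
            )
            lr = max(0.0, 2.0 * (full.loglik - reduced.loglik))
            p = float(stats.chi2.sf(lr, df=1))
            drop_stats.append((p, eff, reduced))
        drop_stats.sort(key=lambda t: -t[0])
        if not drop_stats or drop_stats[0][0] < lrt_cutoff:
            break
        _, dropped, full = drop_stats[0][0:3]
        active = [e for e in active if e != dropped]

    final = full

    # -- stage 3: inference and R2 ------------------------------------------
    n = final.n_obs
    null_fit = fit_candidate(
        z, np.ones((n, 1)), ["intercept"], structures, (), loglik_offset=offset
    )
    r2_total = _r2_lik(final.loglik, null_fit.loglik, n)
    partial = {}
    for j, name in enumerate(names):
        if name == "intercept":
            continue
        X_red = np.delete(X, j, axis=1)
        red_names = [m for m in names if m != name]
        red = fit_candidate(z, X_red, red_names, structures, active, loglik_offset=offset)
        partial[name] = max(0.0, r2_total - _r2_lik(red.loglik, null_fit.loglik, n))

    pvals = final.wald_p()
    coeffs = {
        name: {
            "estimate": float(b),
            "se": float(se),
            "p": pvals[name],
        }
        for name, b, se in zip(final.beta_names, final.beta, final.beta_se)
    }
    return RegressionResult(
        trait_id=trait_id,
        form=form,
        transform=transform,
        coefficients=coeffs,
        variance_components=final.variance_components,
        retained_effects=list(active),
        aic=final.aic,
        loglik=final.loglik,
        n_obs=n,
        r2_total=r2_total,
        partial_r2=partial,
    )


# ---------------------------------------------------------------------------
# Multiple-testing correction
# ---------------------------------------------------------------------------


def ybh_adjust(pvals: Sequence[float], m_total: int = 106) -> np.ndarray:
    """Benjamini-Yekutieli step-up adjustment with a fixed family size.

    Valid under arbitrary or positive dependence via the harmonic-sum
    penalty c(m) = sum_{i=1..m} 1/i.  ``m_total`` is the conservative
    total number of comparisons in the family (default 2 x 53 = 106): when
    fewer p-values are supplied the remaining family members are treated
    as unobserved tests at p = 1 occupying the top ranks.
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    k = len(p)
    if m_total < k:
        raise ValueError(f"m_total ({m_total}) < number of p-values ({k})")
    c_m = float(np.sum(1.0 / np.arange(1, m_total + 1)))
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    scaled = m_total * c_m * ranked / np.arange(1, k + 1)
    # step-up: running minimum from the largest rank down
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(k)
    out[order] = adj
    return out


# ---------------------------------------------------------------------------
# Agreement tallies against the prediction table
# ---------------------------------------------------------------------------

PREDICTORS = ("ln_site_pe", "ln_species_pe")
_TIER_ALPHAS = ((0.001, "***"), (0.01, "**"), (0.05, "*"), (0.1, "o"))

# weights for responses that agree with prediction except for the driest
# species / gardens: one exception vs. two
EXCEPTION_WEIGHTS = {
    ("species", 1): 0.9,
    ("species", 2): 0.8,
    ("garden", 1): 0.75,
    ("garden", 2): 0.5,
}


def significance_tier(p_adj: float) -> str:
    for alpha, symbol in _TIER_ALPHAS:
        if p_adj < alpha:
            return symbol
    return ""


@dataclass
class TallyReport:
    """Per trait x predictor agreement with the prediction table, plus the
    weighted aggregate percentages."""

    rows: pd.DataFrame  # trait_id, predictor, direction, tier, verdict, weight
    pct_agree: dict[str, float]  # per predictor, weighted
    pct_significant_agree: dict[str, float]  # at alpha=0.05 after adjustment
    n_traits: int


def _exception_verdict(
    res: RegressionResult,
    predictor: str,
    predicted: int,
    tt: TraitTable,
    tree: Phylogeny,
    sites: Sequence[SiteInfo],
    species: Sequence[SpeciesInfo],
    max_exceptions: int,
) -> tuple[str, float] | None:
    """Refit with the 1..max_exceptions driest species (or gardens) removed;
    if the coefficient sign then matches the prediction, return the
    discounted verdict."""
    sp_sorted = sorted(species, key=lambda s: s.species_pe)
    si_sorted = sorted(sites, key=lambda s: s.site_pe)
    for kind, pool in (("species", sp_sorted), ("garden", si_sorted)):
        for k in (1, 2):
            if k > max_exceptions or k >= len(pool) - 1:
                continue
            drop = {p.species_id if kind == "species" else p.site_id for p in pool[:k]}
            level = "species_id" if kind == "species" else "site_id"
            keep = ~tt.data.index.get_level_values(level).isin(drop)
            sub = TraitTable(
                data=tt.data.loc[keep].copy(), definitions=tt.definitions
            )
            sub_species = [s for s in species if s.species_id not in drop] \
                if kind == "species" else list(species)
            sub_sites = [s for s in sites if s.site_id not in drop] \
                if kind == "garden" else list(sites)
            try:
                refit = select_model(res.trait_id, sub, tree, sub_sites, sub_species)
            except ValueError:
                continue
            if refit.coef_sign(predictor) == predicted:
                verdict = f"agree-except-driest-{kind}" + ("s" if k == 2 else "")
                return verdict, EXCEPTION_WEIGHTS[(kind, k)]
    return None


def tally_agreement(
    results: Sequence[RegressionResult],
    defs: Sequence[TraitDefinition] | dict[str, TraitDefinition],
    *,
    exceptions: dict[tuple[str, str], tuple[str, int]] | None = None,
    detect_exceptions: bool = False,
    refit_context: tuple | None = None,
    m_total: int = 106,
    alpha: float = 0.05,
) -> TallyReport:
    """Tally trait-by-predictor agreement with the predicted directions.

    A relationship whose coefficient sign matches the prediction counts
    1.  A relationship that agrees except for the one (two) driest species
    counts 0.9 (0.8); except for the one (two) driest gardens, 0.75 (0.5);
    a full disagreement counts 0.  Exceptions may be supplied explicitly
    via ``exceptions`` (keyed by (trait_id, predictor), value
    ("species"|"garden", 1|2)) or detected by refitting without the driest
    species/gardens when ``detect_exceptions`` is set (needs
    ``refit_context = (trait_table, tree, sites, species)``).

    Adjusted p-values (Benjamini-Yekutieli over the 2 x n_traits family)
    are written back onto each result.
    """
    if isinstance(defs, dict):
        dmap = dict(defs)
    else:
        dmap = {d.trait_id: d for d in defs}
    exceptions = exceptions or {}
    usable = [r for r in results if r.trait_id in dmap]
    flat_p = []
    for r in usable:
        for pred in PREDICTORS:
            flat_p.append(r.coefficients[pred]["p"])
    adj = ybh_adjust(flat_p, m_total=max(m_total, len(flat_p)))
    k = 0
    rows = []
    agree_w = {pred: 0.0 for pred in PREDICTORS}
    sig_agree_w = {pred: 0.0 for pred in PREDICTORS}
    for r in usable:
        predicted = dmap[r.trait_id].predicted_direction
        for pred in PREDICTORS:
            p_adj = float(adj[k]); k += 1
            r.adjusted_p[pred] = p_adj
            sign = r.coef_sign(pred)
            if sign == predicted:
                verdict, weight = "agree", 1.0
            else:
                key = (r.trait_id, pred)
                if key in exceptions:
                    kind, count = exceptions[key]
                    verdict = f"agree-except-driest-{kind}" + ("s" if count == 2 else "")
                    weight = EXCEPTION_WEIGHTS[(kind, count)]
                elif detect_exceptions and refit_context is not None:
                    found = _exception_verdict(
                        r, pred, predicted, *refit_context, max_exceptions=2
                    )
                    verdict, weight = found if found else ("disagree", 0.0)
                else:
                    verdict, weight = "disagree", 0.0
            r.verdicts[pred] = verdict
            r.tally_weights[pred] = weight
            agree_w[pred] += weight
            if p_adj < alpha and weight > 0:
                sig_agree_w[pred] += weight
            rows.append(
                {
                    "trait_id": r.trait_id,
                    "predictor": pred,
                    "direction": sign,
                    "tier": significance_tier(p_adj),
                    "p_adjusted": p_adj,
                    "verdict": verdict,
                    "weight": weight,
                }
            )
    n = len(usable)
    return TallyReport(
        rows=pd.DataFrame(rows),
        pct_agree={pred: 100.0 * agree_w[pred] / n for pred in PREDICTORS},
        pct_significant_agree={
            pred: 100.0 * sig_agree_w[pred] / n for pred in PREDICTORS
        },
        n_traits=n,
    )
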