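"""Realized-growth statistics and adaptive cross-over detection.

Realized height growth H* (and its mass analogue M*) is the product of
the survival fraction and the mean final height (mass) of survivors:
dead plants are effectively treated as having zero live height.  Its
standard error combines binomial uncertainty in survival with sampling
uncertainty in the trait mean via the delta method:

    se^2 = (p^2 + p(1-p)/n') * s^2/n + m^2 * p(1-p)/n'

where p is the survival fraction out of n' planted, and m, s are the
mean and s.d. of the trait over the n plants measured.

Species are compared within each garden by pairwise z-tests on H* (with
Benjamini-Hochberg correction within site), by Yates-corrected 2x2
chi-square tests on survival, and by Tukey HSD on raw means.  Adaptive
cross-over — each species outperforming the others under conditions like
those it dominates in nature — is flagged when the rank correlation
between species P/E_p and H* flips sign from the driest to the wettest
garden.
"""

from __future__ import annotations

import string
import warnings as _warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .datamodel import PerformanceCell, SiteInfo, SpeciesInfo

__all__ = [
    "RealizedGrowth",
    "SigmoidFit",
    "realized_growth",
    "compare_realized",
    "compare_survival",
    "compare_means_hsd",
    "fit_survival_sigmoid",
    "counterfactual_survival",
    "detect_crossover",
    "letters_from_significance",
]


@dataclass
class RealizedGrowth:
    """Survival x growth product for one species at one site."""

    species_id: str
    site_id: str
    h_star: float
    se: float | None  # None when n_measured < 2
    p_hat: float
    trait_mean: float
    letters: str = ""


def realized_growth(cell: PerformanceCell) -> RealizedGrowth:
    """H* (or M*) = survival fraction x trait mean, with delta-method s.e.

    With certain survival (p = 1) the s.e. reduces to the standard error
    of the mean, s/sqrt(n); with zero survival H* = 0 exactly (se = 0).
    """
    if cell.n_planted == 0:
        raise ValueError("n_planted must be >= 1")
    p = cell.p_hat
    if p == 0.0:
        return RealizedGrowth(
            species_id=cell.species_id, site_id=cell.site_id,
            h_star=0.0, se=0.0, p_hat=0.0, trait_mean=0.0,
        )
    m, s, n, nprime = cell.trait_mean, cell.trait_sd, cell.n_measured, cell.n_planted
    h_star = p * m
    if n >= 2:
        binom = p * (1.0 - p) / nprime
        se = float(np.sqrt((p**2 + binom) * s**2 / n + m**2 * binom))
    else:
        se = None
    return RealizedGrowth(
        species_id=cell.species_id, site_id=cell.site_id,
        h_star=float(h_star), se=se, p_hat=p, trait_mean=m,
    )


# ---------------------------------------------------------------------------
# Pairwise comparisons and compact letter displays
# ---------------------------------------------------------------------------


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Plain Benjamini-Hochberg step-up (within-site families)."""
    k = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * k / np.arange(1, k + 1)
    adj = np.minimum.accumulate(scaled[::-1])[::-1]
    out = np.empty(k)
    out[order] = np.clip(adj, 0, 1)
    return out


def letters_from_significance(
    names: Sequence[str], sig_pairs: set[tuple[str, str]]
) -> dict[str, str]:
    """Compact letter display by insert-and-absorb.

    Groups sharing a letter are not significantly different; every
    significantly different pair ends up with disjoint letter sets.
    """
    names = list(names)
    sig = {frozenset(p) for p in sig_pairs}
    # start with one group holding everyone, split on each significant pair
    groups: list[set[str]] = [set(names)]
    for pair in sig:
        a, b = tuple(pair)
        new_groups: list[set[str]] = []
        for g in groups:
            if a in g and b in g:
                new_groups.extend([g - {b}, g - {a}])
            else:
                new_groups.append(g)
        groups = new_groups
    # absorb: drop groups contained in another
    groups = [g for g in groups if not any(g < h for h in groups)]
    # deduplicate while keeping a stable, name-ordered arrangement
    uniq: list[set[str]] = []
    for g in groups:
        if g not in uniq:
            uniq.append(g)
    uniq.sort(key=lambda g: min(names.index(x) for x in g))
    letters = {n: "" for n in names}
    alphabet = string.ascii_lowercase
    for i, g in enumerate(uniq):
        lab = alphabet[i % 26] * (i // 26 + 1)
        for n in g:
            letters[n] += lab
    return letters


def compare_realized(
    growth: Sequence[RealizedGrowth], *, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Pairwise z-tests on H* within one site, BH-adjusted, plus letters.

    z = (H1 - H2) / sqrt(se1^2 + se2^2) with a two-sided normal p-value.
    Species without a defined s.e. are excluded from comparisons.
    """
    usable = [g for g in growth if g.se is not None]
    if len(usable) < 2:
        raise ValueError("need >= 2 species with defined s.e.")
    rows = []
    for i in range(len(usable)):
        for j in range(i + 1, len(usable)):
            a, b = usable[i], usable[j]
            var = a.se**2 + b.se**2
            if var == 0:
                if a.h_star == b.h_star:
                    p = 1.0
                else:
                    p = 0.0
                    _warnings.warn(
                        f"zero s.e. with unequal H* for {a.species_id}/{b.species_id}"
                    )
                z = np.inf if p == 0.0 else 0.0
            else:
                z = (a.h_star - b.h_star) / np.sqrt(var)
                p = float(2.0 * stats.norm.sf(abs(z)))
            rows.append(
                {"species_a": a.species_id, "species_b": b.species_id,
                 "z": float(z), "p": p}
            )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = _bh_adjust(df["p"].to_numpy())
    sig = {
        (r.species_a, r.species_b)
        for r in df.itertuples()
        if r.p_adjusted < alpha
    }
    order = [g.species_id for g in sorted(usable, key=lambda g: -g.h_star)]
    letters = letters_from_significance(order, sig)
    for g in usable:
        g.letters = letters[g.species_id]
    return df, letters


def compare_survival(
    cells: Sequence[PerformanceCell], *, alpha: float = 0.05
) -> pd.DataFrame:
    """Pairwise survival comparisons within a site: 2x2 chi-square with
    Yates' continuity correction, BH-adjusted."""
    if len(cells) < 2:
        raise ValueError("need >= 2 species")
    rows = []
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            a, b = cells[i], cells[j]
            table = np.array(
                [
                    [a.n_survived, a.n_planted - a.n_survived],
                    [b.n_survived, b.n_planted - b.n_survived],
                ]
            )
            if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
                _warnings.warn(
                    f"zero-margin survival table for {a.species_id}/{b.species_id}"
                )
                chi2, p = 0.0, 1.0
            else:
                chi2, p, _, _ = stats.chi2_contingency(table, correction=True)
            rows.append(
                {"species_a": a.species_id, "species_b": b.species_id,
                 "chi2": float(chi2), "p": float(p)}
            )
    df = pd.DataFrame(rows)
    df["p_adjusted"] = _bh_adjust(df["p"].to_numpy())
    return df


def compare_means_hsd(
    samples: dict[str, np.ndarray], *, alpha: float = 0.05
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Tukey HSD over raw per-plant values within one site, plus letters.

    Singleton groups are excluded (no letters): no comparison can be made
    from one observation.
    """
    usable = {k: np.asarray(v, float) for k, v in samples.items() if len(v) >= 2}
    if len(usable) < 2:
        raise ValueError("need >= 2 groups with >= 2 observations")
    names = list(usable)
    res = stats.tukey_hsd(*usable.values())
    rows = []
    sig = set()
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = float(res.pvalue[i, j])
            rows.append({"species_a": names[i], "species_b": names[j], "p": p})
            if p < alpha:
                sig.add((names[i], names[j]))
    order = sorted(names, key=lambda n: -float(np.mean(usable[n])))
    letters = letters_from_significance(order, sig)
    return pd.DataFrame(rows), letters


# ---------------------------------------------------------------------------
# Survival-vs-species-P/E_p curve fits
# ---------------------------------------------------------------------------


@dataclass
class SigmoidFit:
    """Least-squares sigmoid s = s_max / (1 + exp(beta (a - x))).

    ``beta`` may take either sign: positive for survival rising with
    P/E_p, negative for the sharp decline seen at dry sites.
    """

    s_max: float
    beta: float
    a: float
    rss: float
    aic: float
    linear_intercept: float
    linear_slope: float
    linear_rss: float
    linear_aic: float
    converged: bool

    @property
    def sigmoid_preferred(self) -> bool:
        return self.converged and self.aic < self.linear_aic

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.s_max / (1.0 + np.exp(self.beta * (self.a - np.asarray(x))))


def _gaussian_aic(rss: float, n: int, k: int) -> float:
    rss = max(rss, 1e-300)
    return n * np.log(rss / n) + 2 * k


def fit_survival_sigmoid(
    survival: Sequence[float], species_pe: Sequence[float]
) -> SigmoidFit:
    """Fit the sigmoid and a linear alternative to survival vs species P/E_p
    and report which has the lower AIC.  On non-convergence the linear fit
    is reported as preferred."""
    y = np.asarray(survival, float)
    x = np.asarray(species_pe, float)
    if len(y) < 4:
        raise ValueError("need >= 4 points")
    lin_slope, lin_int = np.polyfit(x, y, 1)
    lin_rss = float(np.sum((y - (lin_int + lin_slope * x)) ** 2))
    lin_aic = _gaussian_aic(lin_rss, len(y), 3)

    def f(x, s_max, beta, a):
        return s_max / (1.0 + np.exp(np.clip(beta * (a - x), -500, 500)))

    beta0 = 5.0 if lin_slope >= 0 else -5.0
    converged = True
    try:
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore")
            popt, _ = optimize.curve_fit(
                f, x, y,
                p0=[min(max(y.max(), 0.05), 1.0), beta0, float(np.median(x))],
                bounds=([1e-6, -200.0, x.min() - 2.0], [1.0, 200.0, x.max() + 2.0]),
                maxfev=20000,
            )
        rss = float(np.sum((y - f(x, *popt)) ** 2))
    except (RuntimeError, ValueError):
        converged = False
        popt = (float(np.clip(y.max(), 1e-6, 1.0)), 0.0, float(np.median(x)))
        rss = float(np.sum((y - np.mean(y)) ** 2))
    return SigmoidFit(
        s_max=float(popt[0]), beta=float(popt[1]), a=float(popt[2]),
        rss=rss, aic=_gaussian_aic(rss, len(y), 4),
        linear_intercept=float(lin_int), linear_slope=float(lin_slope),
        linear_rss=lin_rss, linear_aic=lin_aic, converged=converged,
    )


# ---------------------------------------------------------------------------
# Counterfactual survival replacement
# ---------------------------------------------------------------------------


def counterfactual_survival(
    cells: Sequence[PerformanceCell],
    species: Sequence[SpeciesInfo],
    target_species: str,
    *,
    form: str = "linear",
) -> tuple[PerformanceCell, RealizedGrowth]:
    """Replace one species' observed survival with the value expected from
    the survival-vs-species-P/E_p regression over the other species at the
    same site, then recompute H* and its s.e.

    Used when a species' survival is anomalous relative to the within-site
    trend (e.g., a transient window of unusually favourable conditions):
    the counterfactual H* shows what its realized growth would have been
    had it followed the same relationship as its neighbours.
    """
    sp_pe = {s.species_id: s.species_pe for s in species}
    target = next(c for c in cells if c.species_id == target_species)
    others = [c for c in cells if c.species_id != target_species]
    if len(others) < 3:
        raise ValueError("need >= 3 other species at the site")
    x = np.array([sp_pe[c.species_id] for c in others])
    y = np.array([c.p_hat for c in others])
    if form == "sigmoid":
        fit = fit_survival_sigmoid(y, x)
        pred = float(fit.predict(np.array([sp_pe[target_species]]))[0])
    else:
        slope, intercept = np.polyfit(x, y, 1)
        pred = float(intercept + slope * sp_pe[target_species])
    if pred < 0:
        _warnings.warn("predicted survival < 0; clipped to 0")
    pred = float(np.clip(pred, 0.0, 1.0))
    n_surv = int(round(pred * target.n_planted))
    adj = PerformanceCell(
        species_id=target.species_id,
        site_id=target.site_id,
        n_planted=target.n_planted,
        n_survived=n_surv,
        n_measured=min(target.n_measured, n_surv),
        trait_mean=target.trait_mean if n_surv > 0 else 0.0,
        trait_sd=target.trait_sd if n_surv > 0 else 0.0,
    )
    return adj, realized_growth(adj)


# ---------------------------------------------------------------------------
# Adaptive cross-over detection
# ---------------------------------------------------------------------------


@dataclass
class CrossoverReport:
    crossover: bool
    rho_driest: float
    rho_wettest: float
    driest_site: str
    wettest_site: str
    per_site: pd.DataFrame  # ranked species with significance letters
    top_species_local: dict[str, bool]  # top species' pe closer to site pe than median
    skipped_sites: list[str] = field(default_factory=list)


def detect_crossover(
    growth: Sequence[RealizedGrowth],
    sites: Sequence[SiteInfo],
    species: Sequence[SpeciesInfo],
) -> CrossoverReport:
    """Flag adaptive cross-over in realized growth.

    Operational rule: compute the Spearman correlation between species
    P/E_p and H* at the driest and the wettest garden; cross-over is
    flagged when the sign flips (dry-adapted species lead where it is dry,
    wet-adapted where it is wet).  Per site, the report also ranks species
    by H* and checks whether the top species' native P/E_p is closer to
    the site's P/E_p than the median competitor's.
    """
    site_pe = {s.site_id: s.site_pe for s in sites}
    sp_pe = {s.species_id: s.species_pe for s in species}
    df = pd.DataFrame(
        [
            {"species_id": g.species_id, "site_id": g.site_id,
             "h_star": g.h_star, "letters": g.letters}
            for g in growth
        ]
    )
    present = [s for s in sites if s.site_id in set(df["site_id"])]
    if len(present) < 2:
        raise ValueError("need H* at >= 2 sites to assess cross-over")
    skipped = []
    rows = []
    top_local: dict[str, bool] = {}
    for s in present:
        sub = df[df["site_id"] == s.site_id].sort_values(
            "h_star", ascending=False, kind="stable"
        )
        if len(sub) < 2:
            skipped.append(s.site_id)
            continue
        sub = sub.assign(rank=np.arange(1, len(sub) + 1))
        rows.append(sub)
        top = sub.iloc[0]["species_id"]
        d_top = abs(sp_pe[top] - s.site_pe)
        d_others = [
            abs(sp_pe[sp] - s.site_pe) for sp in sub["species_id"].iloc[1:]
        ]
        top_local[s.site_id] = bool(d_top < np.median(d_others))
    ordered = sorted(present, key=lambda s: s.site_pe)
    driest, wettest = ordered[0], ordered[-1]

    def _rho(site_id: str) -> float:
        sub = df[df["site_id"] == site_id]
        if sub["h_star"].nunique() < 2:
            return 0.0
        rho, _ = stats.spearmanr(
            [sp_pe[s] for s in sub["species_id"]], sub["h_star"]
        )
        return float(rho) if np.isfinite(rho) else 0.0

    rho_dry, rho_wet = _rho(driest.site_id), _rho(wettest.site_id)
    return CrossoverReport(
        crossover=bool(rho_dry < 0 < rho_wet),
        rho_driest=rho_dry,
        rho_wettest=rho_wet,
        driest_site=driest.site_id,
        wettest_site=wettest.site_id,
        per_site=pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(),
        top_species_local=top_local,
        skipped_sites=skipped,
    )
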