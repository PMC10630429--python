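"""Multivariate trait summary: standardized PCA, gradient projection,
sector classification, and PC-score reaction norms.

The species-by-site trait matrix is centered and standardized and
decomposed by (phylogenetically unstructured) PCA.  The two moisture
gradients — site P/E_p (what a plant experiences now) and species P/E_p
(its lineage's climatic history) — are projected into the PC1-PC2 plane
as supplementary variables; each trait's loading vector is then
classified into one of eight descriptive sectors according to whether it
aligns with the site gradient (adaptive plasticity), the species
gradient (adaptive fixed differences), both, or their opposites
(nominally maladaptive responses).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .datamodel import SiteInfo, SpeciesInfo, TraitTable

__all__ = [
    "OrdinationResult",
    "run_pca",
    "project_gradients",
    "classify_sectors",
    "pc_reaction_norms",
    "SECTOR_LABELS",
]

# labels for the 8 half-axes, in order: +site, +both, +species, site-opposed
# mix, -site, -both, -species, species-opposed mix.  "adaptive" means the
# trait vector aligns with the gradient's predicted direction.
SECTOR_LABELS = [
    "adaptive-to-site",
    "adaptive-to-both",
    "adaptive-to-species",
    "adaptive-species-maladaptive-site",
    "maladaptive-plastic",  # opposite the site gradient
    "maladaptive-to-both",
    "maladaptive-fixed",  # opposite the species gradient
    "adaptive-site-maladaptive-species",
]


@dataclass
class OrdinationResult:
    loadings: pd.DataFrame  # trait x axis, orthonormal columns
    scores: pd.DataFrame  # (species, site) x axis
    variance_fraction: np.ndarray  # per axis, sums to 1
    site_vector: np.ndarray | None = None  # unit vectors in the PC1-PC2 plane
    species_vector: np.ndarray | None = None
    gradient_angle_deg: float | None = None
    sectors: pd.Series | None = None
    n_imputed_cells: int = 0


def _standardize(tt: TraitTable) -> tuple[pd.DataFrame, int]:
    """Complete-case preparation: drop excluded rows (already absent from the
    table), mean-impute sporadic missing cells, z-score each trait column."""
    df = tt.data.copy()
    n_imputed = int(df.isna().sum().sum())
    if n_imputed:
        df = df.fillna(df.mean())
    sd = df.std(ddof=1)
    constant = sd[sd == 0].index.tolist()
    if constant:
        raise ValueError(f"constant trait column(s): {constant}")
    return (df - df.mean()) / sd, n_imputed


def run_pca(tt: TraitTable) -> OrdinationResult:
    """Standardized (correlation-matrix) PCA of the trait table.

    Deterministic up to sign; signs are fixed downstream so the projected
    site-gradient vector has positive PC1-PC2 coordinates (see
    :func:`project_gradients`).
    """
    Z, n_imputed = _standardize(tt)
    U, s, Vt = np.linalg.svd(Z.to_numpy(), full_matrices=False)
    keep = s > s[0] * 1e-12 if s[0] > 0 else np.zeros_like(s, bool)
    U, s, Vt = U[:, keep], s[keep], Vt[keep]
    axes = [f"PC{i+1}" for i in range(len(s))]
    scores = pd.DataFrame(U * s, index=Z.index, columns=axes)
    loadings = pd.DataFrame(Vt.T, index=Z.columns, columns=axes)
    var = s**2
    return OrdinationResult(
        loadings=loadings,
        scores=scores,
        variance_fraction=var / var.sum(),
        n_imputed_cells=n_imputed,
    )


def project_gradients(
    ordn: OrdinationResult,
    sites: Sequence[SiteInfo],
    species: Sequence[SpeciesInfo],
) -> OrdinationResult:
    """Project ln(site P/E_p) and ln(species P/E_p) into the PC1-PC2 plane.

    Each gradient's direction is its supplementary-variable projection:
    the vector of correlations with the PC1 and PC2 scores (equivalently,
    the coefficients of the regression of the log gradient on the
    unit-variance scores), scaled to unit length.  Unlike raw regression
    coefficients, this weighting preserves the angle between gradients
    that lie in the PC1-PC2 plane.  PC signs are then fixed so the site
    vector has positive coordinates.  Mutates and returns ``ordn``.
    """
    site_pe = {s.site_id: s.site_pe for s in sites}
    sp_pe = {s.species_id: s.species_pe for s in species}
    idx = ordn.scores.index
    g_site = np.log([site_pe[i[1]] for i in idx])
    g_sp = np.log([sp_pe[i[0]] for i in idx])
    S = ordn.scores[["PC1", "PC2"]].to_numpy()

    def _vec(g: np.ndarray) -> np.ndarray:
        if np.std(g) == 0:
            raise ValueError("degenerate (zero-variance) gradient")
        Sz = (S - S.mean(axis=0)) / S.std(axis=0, ddof=1)
        X = np.column_stack([np.ones(len(g)), Sz])
        coef, *_ = np.linalg.lstsq(X, g, rcond=None)
        v = coef[1:3]
        nrm = np.linalg.norm(v)
        if nrm == 0:
            raise ValueError("gradient has no projection in the PC1-PC2 plane")
        return v / nrm

    v_site = _vec(g_site)
    # fix signs: flip each of PC1/PC2 so the site vector points positive
    for k, axis in enumerate(("PC1", "PC2")):
        if v_site[k] < 0:
            ordn.scores[axis] *= -1
            ordn.loadings[axis] *= -1
            S[:, k] *= -1
            v_site[k] *= -1
    v_sp = _vec(g_sp)
    ordn.site_vector = v_site
    ordn.species_vector = v_sp
    cosang = float(np.clip(np.dot(v_site, v_sp), -1.0, 1.0))
    ordn.gradient_angle_deg = float(np.degrees(np.arccos(cosang)))
    return ordn


def classify_sectors(ordn: OrdinationResult) -> pd.Series:
    """Assign each trait's PC1-PC2 loading vector to one of eight sectors.

    The eight half-axes are the two (prediction-signed) gradient
    directions, their opposites, and the four bisectors; each trait goes
    to the angularly nearest half-axis.  When the gradients are exactly
    perpendicular this reduces to +/-22.5-degree bands about each
    half-axis; nearest-axis assignment keeps the classification exhaustive
    and exclusive when they are not.  Zero-length loading vectors are
    labelled "unclassified".
    """
    if ordn.site_vector is None or ordn.species_vector is None:
        raise ValueError("project gradients before classifying sectors")
    th_site = np.arctan2(*ordn.site_vector[::-1])
    th_sp = np.arctan2(*ordn.species_vector[::-1])

    def bisector(a: float, b: float) -> float:
        return np.angle(np.exp(1j * a) + np.exp(1j * b))

    half_axes = [
        th_site,
        bisector(th_site, th_sp),
        th_sp,
        bisector(th_sp, th_site + np.pi),
        th_site + np.pi,
        bisector(th_site + np.pi, th_sp + np.pi),
        th_sp + np.pi,
        bisector(th_sp + np.pi, th_site),
    ]
    labels = {}
    L = ordn.loadings[["PC1", "PC2"]].to_numpy()
    for trait, (x, y) in zip(ordn.loadings.index, L):
        r = np.hypot(x, y)
        if r < 1e-12:
            labels[trait] = "unclassified"
            continue
        th = np.arctan2(y, x)
        dists = [abs(np.angle(np.exp(1j * (th - h)))) for h in half_axes]
        labels[trait] = SECTOR_LABELS[int(np.argmin(dists))]
    out = pd.Series(labels, name="sector")
    ordn.sectors = out
    return out


@dataclass
class ReactionNormSummary:
    per_site_slopes: pd.Series  # PC1 ~ species_pe within each garden
    per_species_slopes: pd.Series  # PC1 ~ site_pe within each species
    species_slope_mean: float
    species_slope_sd: float
    site_slope_mean: float
    site_slope_sd: float
    slope_ratio: float  # mean plastic slope / mean fixed slope
    per_species_ratio_mean: float
    common_slope_p: dict[str, float]  # ANCOVA interaction F-test p, per grouping
    skipped: list[str]


def pc_reaction_norms(
    ordn: OrdinationResult,
    sites: Sequence[SiteInfo],
    species: Sequence[SpeciesInfo],
    axis: str = "PC1",
) -> ReactionNormSummary:
    """Reaction-norm slopes of a PC score on the two gradients.

    Within each garden, the OLS slope of the score against species P/E_p
    measures multivariate fixed differences; within each species, the
    slope against site P/E_p measures multivariate plasticity.  The ratio
    of mean slopes compares plasticity with fixed differences; parallelism
    is tested by the ANCOVA interaction F-test.
    """
    site_pe = {s.site_id: s.site_pe for s in sites}
    sp_pe = {s.species_id: s.species_pe for s in species}
    df = pd.DataFrame(
        {
            "score": ordn.scores[axis],
            "species_id": [i[0] for i in ordn.scores.index],
            "site_id": [i[1] for i in ordn.scores.index],
        }
    ).reset_index(drop=True)
    df["site_pe"] = df["site_id"].map(site_pe)
    df["species_pe"] = df["species_id"].map(sp_pe)

    skipped: list[str] = []

    def _slopes(by: str, x: str) -> pd.Series:
        out = {}
        for key, sub in df.groupby(by, sort=True):
            if sub[x].nunique() < 2:
                skipped.append(f"{by}={key}")
                continue
            out[key] = float(np.polyfit(sub[x], sub["score"], 1)[0])
        return pd.Series(out)

    per_site = _slopes("site_id", "species_pe")
    per_species = _slopes("species_id", "site_pe")
    if per_site.empty or per_species.empty:
        raise ValueError("need >= 2 species and >= 2 sites")

    def _ancova_p(x: str, group: str) -> float:
        m_int = smf.ols(f"score ~ {x} * C({group})", data=df).fit()
        m_add = smf.ols(f"score ~ {x} + C({group})", data=df).fit()
        table = sm.stats.anova_lm(m_add, m_int)
        return float(table["Pr(>F)"].iloc[1])

    mean_fixed = float(per_site.mean())
    mean_plastic = float(per_species.mean())
    # per-species ratio averaging: each species' plastic slope against the
    # mean fixed slope (alternative summary of relative plasticity)
    per_species_ratio = float((per_species / mean_fixed).mean()) if mean_fixed else np.nan
    return ReactionNormSummary(
        per_site_slopes=per_site,
        per_species_slopes=per_species,
        species_slope_mean=mean_fixed,
        species_slope_sd=float(per_site.std(ddof=1)) if len(per_site) > 1 else 0.0,
        site_slope_mean=mean_plastic,
        site_slope_sd=float(per_species.std(ddof=1)) if len(per_species) > 1 else 0.0,
        slope_ratio=mean_plastic / mean_fixed if mean_fixed else np.nan,
        per_species_ratio_mean=per_species_ratio,
        common_slope_p={
            "species_pe_by_site": _ancova_p("species_pe", "site_id"),
            "site_pe_by_species": _ancova_p("site_pe", "species_id"),
        },
        skipped=skipped,
    )
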