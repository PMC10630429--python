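"""Synthetic common-garden studies with the statistical structure the
analysis assumes.

The default configuration mirrors the study design the pipeline targets:
ten tree species planted in four common gardens spanning an eightfold
moisture-supply gradient (site P/E_p 0.16-1.25), species range-mean
P/E_p spanning 0.19-0.98, 81-254 individuals planted per species per
garden, and a 52-My ultrametric phylogeny.  Traits respond log-linearly
to log site and species P/E_p with Brownian phylogenetic random effects;
survival follows per-site sigmoids that decline with species P/E_p at
dry sites and rise at wet sites; heights of survivors increase with
species P/E_p, more steeply at wetter sites.  Together these produce an
adaptive cross-over in realized height growth (survival x height) by
construction.
"""

from __future__ import annotations

import json
import random as _random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim

from .datamodel import (
    PerformanceCell,
    Phylogeny,
    SiteInfo,
    SpeciesInfo,
    TraitDefinition,
    TraitTable,
    Transform,
    brownian_covariance,
)

__all__ = [
    "TraitGenerator",
    "SiteSurvivalParams",
    "SimulationConfig",
    "default_config",
    "simulate_tree",
    "simulate_traits",
    "simulate_performance",
    "simulate_raw_streams",
    "write_study",
]

# Study-design constants (defaults; all overridable through SimulationConfig)
SITE_PE_DEFAULT = (0.16, 0.39, 1.03, 1.25)
SPECIES_PE_RANGE = (0.19, 0.98)
N_PLANTED_RANGE = (81, 254)
TREE_HEIGHT_MY = 52.0


def _child_rng(seed: int, stream: int) -> np.random.Generator:
    """Counter-derived child generator so stages can be rerun independently."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


@dataclass(frozen=True)
class TraitGenerator:
    """Generative coefficients for one trait on its transformed scale.

    transformed value = a + b_site*ln(site_pe) + b_species*ln(species_pe)
                        + c*ln(site_pe)*ln(species_pe)
                        + u_phylo(species) + u_site(site) + eps
    """

    trait_id: str
    a: float = 0.0
    b_site: float = 1.5
    b_species: float = 2.0
    c: float = 0.0
    sigma2_phylo: float = 0.09
    sigma2_site: float = 0.01
    sigma2_e: float = 0.04
    transform: Transform = Transform.NONE
    predicted_direction: int = 1

    def definition(self) -> TraitDefinition:
        return TraitDefinition(
            trait_id=self.trait_id,
            transform=self.transform,
            predicted_direction=self.predicted_direction,
        )


@dataclass(frozen=True)
class SiteSurvivalParams:
    """Sigmoid survival parameters for one garden.

    s(species_pe) = s_max / (1 + exp(beta * (a - species_pe)));
    beta > 0 makes survival rise with species P/E_p, beta < 0 fall.
    """

    s_max: float
    beta: float
    a: float


@dataclass
class SimulationConfig:
    n_species: int = 10
    n_sites: int = 4
    site_pe: tuple[float, ...] = SITE_PE_DEFAULT
    species_pe: tuple[float, ...] | None = None  # None: even spacing over range
    species_pe_range: tuple[float, float] = SPECIES_PE_RANGE
    traits: list[TraitGenerator] = field(default_factory=list)
    sigma2_phylo_site: float = 0.0  # per-site phylogenetic ("attraction") draw
    tree_height: float = TREE_HEIGHT_MY
    survival: list[SiteSurvivalParams] = field(default_factory=list)
    # log-height model for survivors: ln h ~ Normal(h0 + h1*species_pe, s);
    # one (h0, h1) pair per site, ordered as site_pe.
    height_intercepts: tuple[float, ...] = (2.0, 2.3, 2.6, 2.8)
    height_slopes: tuple[float, ...] = (0.3, 0.8, 1.6, 2.2)
    height_sdlog: float = 0.35
    n_planted_range: tuple[int, int] = N_PLANTED_RANGE
    seed: int = 0

    def __post_init__(self) -> None:
        if self.species_pe is None:
            lo, hi = self.species_pe_range
            self.species_pe = tuple(
                float(x) for x in np.linspace(lo, hi, self.n_species)
            )
        if len(self.site_pe) != self.n_sites:
            raise ValueError("site_pe length must equal n_sites")
        if len(self.species_pe) != self.n_species:
            raise ValueError("species_pe length must equal n_species")
        if any(p <= 0 for p in self.site_pe + tuple(self.species_pe)):
            raise ValueError("P/E_p values must be > 0")
        if not self.survival:
            self.survival = default_survival_params(self.site_pe)
        for tg in self.traits:
            for v in (tg.sigma2_phylo, tg.sigma2_site, tg.sigma2_e):
                if v < 0 or not np.isfinite(v):
                    raise ValueError(f"invalid variance for trait {tg.trait_id}")
            for v in (tg.a, tg.b_site, tg.b_species, tg.c):
                if not np.isfinite(v):
                    raise ValueError(f"non-finite coefficient for trait {tg.trait_id}")

    @property
    def site_ids(self) -> list[str]:
        return [f"site{i+1:02d}" for i in range(self.n_sites)]

    @property
    def species_ids(self) -> list[str]:
        return [f"sp{i+1:02d}" for i in range(self.n_species)]

    def sites(self) -> list[SiteInfo]:
        return [
            SiteInfo(site_id=s, site_pe=pe)
            for s, pe in zip(self.site_ids, self.site_pe)
        ]

    def species(self) -> list[SpeciesInfo]:
        return [
            SpeciesInfo(species_id=s, species_pe=pe)
            for s, pe in zip(self.species_ids, self.species_pe)
        ]


def default_survival_params(site_pe: Sequence[float]) -> list[SiteSurvivalParams]:
    """Survival sigmoids emulating the study pattern: steep decline with
    species P/E_p at the driest garden, shallower decline, slight rise, and
    steep rise at progressively moister gardens."""
    n = len(site_pe)
    order = np.argsort(site_pe)
    betas = np.linspace(-10.0, 8.0, n)
    s_maxes = np.linspace(0.75, 0.95, n)
    mids = np.linspace(0.45, 0.6, n)
    out: list[SiteSurvivalParams] = [None] * n  # type: ignore[list-item]
    for rank, idx in enumerate(order):
        out[idx] = SiteSurvivalParams(
            s_max=float(s_maxes[rank]), beta=float(betas[rank]), a=float(mids[rank])
        )
    return out


def default_traits(
    n_traits: int = 53,
    *,
    seed: int = 12345,
    predicted_directions: Sequence[int] | None = None,
) -> list[TraitGenerator]:
    """A default trait panel emulating the heterogeneity of real trait
    responses: traits span a continuum from strongly plastic (site-
    dominated response, like gas-exchange traits) to strongly fixed
    (species-dominated, like wood anatomy), with directions following the
    prediction table (every generated trait responds in its predicted
    direction unless overridden)."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_traits):
        d = 1 if predicted_directions is None else int(predicted_directions[i])
        plasticity_share = rng.uniform(0.15, 0.85)
        total_mag = rng.uniform(1.5, 3.5)
        mag_site = total_mag * plasticity_share
        mag_species = total_mag * (1.0 - plasticity_share)
        out.append(
            TraitGenerator(
                trait_id=f"trait{i+1:02d}",
                a=float(rng.uniform(-1, 1)),
                b_site=d * float(mag_site),
                b_species=d * float(mag_species),
                c=0.0,
                sigma2_phylo=0.09,
                sigma2_site=0.01,
                sigma2_e=0.04,
                transform=Transform.NONE,
                predicted_direction=d,
            )
        )
    return out


def default_config(seed: int = 0, n_traits: int = 53) -> SimulationConfig:
    return SimulationConfig(traits=default_traits(n_traits), seed=seed)


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------

def simulate_tree(
    n_species: int, total_height: float = TREE_HEIGHT_MY, seed: int = 0,
    labels: Sequence[str] | None = None,
) -> Phylogeny:
    """Pure-birth (Yule) ultrametric tree scaled to the stated root height."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if labels is None:
        labels = [f"sp{i+1:02d}" for i in range(n_species)]
    taxa = dendropy.TaxonNamespace(list(labels))
    tree = treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        taxon_namespace=taxa,
        rng=_random.Random(seed),
    )
    # drop any stem edge above the root, then scale every edge so the
    # root-to-tip distance equals total_height
    tree.seed_node.edge.length = None

    def depth(leaf) -> float:
        d, node = 0.0, leaf
        while node is not tree.seed_node:
            d += node.edge.length or 0.0
            node = node.parent_node
        return d

    height = max(depth(leaf) for leaf in tree.leaf_node_iter())
    if height == 0.0:
        # the process stopped at the first split (n=2): place it at the root
        for node in tree.seed_node.child_nodes():
            node.edge.length = 1.0
        height = 1.0
    factor = total_height / height
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is not None:
            edge.length *= factor
    return Phylogeny(tree, ultrametric_rtol=1e-9)


# ---------------------------------------------------------------------------
# Trait simulation
# ---------------------------------------------------------------------------

def simulate_traits(
    cfg: SimulationConfig, tree: Phylogeny, seed: int | None = None
) -> TraitTable:
    """Simulate species-by-site trait means under the generative mixed model.

    The phylogenetic effect is one multivariate-normal draw per trait with
    covariance sigma2_phylo * C where C is the Brownian matrix normalized
    by tree height (so sigma2_phylo is the tip-level variance).  An
    optional per-site phylogenetic draw (``sigma2_phylo_site``) exercises
    the "phylogenetic attraction" component.
    """
    if not cfg.traits:
        raise ValueError("config has no traits")
    seed = cfg.seed if seed is None else seed
    rng = _child_rng(seed, 1)
    sp_ids, si_ids = cfg.species_ids, cfg.site_ids
    if set(sp_ids) - set(tree.tips):
        raise ValueError("config species not all present as tree tips")
    C = brownian_covariance(tree, sp_ids)
    if tree.height > 0:
        C = C / tree.height
    Lc = np.linalg.cholesky(C + 1e-12 * np.eye(len(sp_ids)))
    ln_site = np.log(np.asarray(cfg.site_pe))
    ln_sp = np.log(np.asarray(cfg.species_pe))
    idx = pd.MultiIndex.from_product(
        [sp_ids, si_ids], names=["species_id", "site_id"]
    )
    i_sp = np.repeat(np.arange(cfg.n_species), cfg.n_sites)
    i_si = np.tile(np.arange(cfg.n_sites), cfg.n_species)
    cols = {}
    for tg in cfg.traits:
        fixed = (
            tg.a
            + tg.b_site * ln_site[i_si]
            + tg.b_species * ln_sp[i_sp]
            + tg.c * ln_site[i_si] * ln_sp[i_sp]
        )
        u_phylo = np.sqrt(tg.sigma2_phylo) * (Lc @ rng.standard_normal(cfg.n_species))
        u_site = np.sqrt(tg.sigma2_site) * rng.standard_normal(cfg.n_sites)
        y = fixed + u_phylo[i_sp] + u_site[i_si]
        if cfg.sigma2_phylo_site > 0:
            for s in range(cfg.n_sites):
                draw = np.sqrt(cfg.sigma2_phylo_site) * (
                    Lc @ rng.standard_normal(cfg.n_species)
                )
                y[i_si == s] += draw[i_sp[i_si == s]]
        y = y + np.sqrt(tg.sigma2_e) * rng.standard_normal(len(y))
        if tg.transform == Transform.LOG:
            y = np.exp(y)
        elif tg.transform == Transform.SQRT:
            y = np.square(y)
        cols[tg.trait_id] = y
    df = pd.DataFrame(cols, index=idx)
    return TraitTable(
        data=df, definitions={tg.trait_id: tg.definition() for tg in cfg.traits}
    )


# ---------------------------------------------------------------------------
# Performance (survival + height) simulation
# ---------------------------------------------------------------------------

def sigmoid_survival(species_pe: float, p: SiteSurvivalParams) -> float:
    s = p.s_max / (1.0 + np.exp(np.clip(p.beta * (p.a - species_pe), -500, 500)))
    return float(np.clip(s, 0.0, 1.0))


def expected_log_height(cfg: SimulationConfig, i_site: int, species_pe: float) -> float:
    return cfg.height_intercepts[i_site] + cfg.height_slopes[i_site] * species_pe


def simulate_performance(
    cfg: SimulationConfig, seed: int | None = None
) -> tuple[list[PerformanceCell], dict]:
    """Simulate per-cell planting outcomes.

    Returns the cells plus a truth record holding each cell's expected
    survival fraction and expected height, from which planted rank
    reversals can be verified downstream.
    """
    seed = cfg.seed if seed is None else seed
    rng = _child_rng(seed, 2)
    cells: list[PerformanceCell] = []
    truth: dict[str, dict] = {}
    for i_site, (site_id, spar) in enumerate(zip(cfg.site_ids, cfg.survival)):
        for sp_id, sp_pe in zip(cfg.species_ids, cfg.species_pe):
            n_planted = int(rng.integers(cfg.n_planted_range[0], cfg.n_planted_range[1] + 1))
            s_true = sigmoid_survival(sp_pe, spar)
            n_surv = int(rng.binomial(n_planted, s_true))
            mu = expected_log_height(cfg, i_site, sp_pe)
            if n_surv > 0:
                heights = rng.lognormal(mean=mu, sigma=cfg.height_sdlog, size=n_surv)
                m, s = float(np.mean(heights)), float(np.std(heights, ddof=1)) if n_surv > 1 else 0.0
                n_meas = n_surv
            else:
                m, s, n_meas = float("nan"), 0.0, 0
            cells.append(
                PerformanceCell(
                    species_id=sp_id,
                    site_id=site_id,
                    n_planted=n_planted,
                    n_survived=n_surv,
                    n_measured=n_meas,
                    trait_mean=m,
                    trait_sd=float(s),
                )
            )
            truth[f"{sp_id}@{site_id}"] = {
                "survival": s_true,
                # expected height of a lognormal survivor
                "height": float(np.exp(mu + cfg.height_sdlog**2 / 2)),
                "h_star": s_true * float(np.exp(mu + cfg.height_sdlog**2 / 2)),
            }
    return cells, truth


# ---------------------------------------------------------------------------
# Raw measurement streams (fixtures for the derived-trait calculators)
# ---------------------------------------------------------------------------

def simulate_raw_streams(
    cfg: SimulationConfig | None = None, seed: int = 0, noise: float = 0.0
) -> dict:
    """Generate raw measurement streams with known ground-truth derived
    values recorded alongside.

    Returns a dict of DataFrames (drying, flow_pressure, vessels, roots,
    growth) plus a ``truth`` dict of the generative values each derived
    trait should recover (exactly at ``noise=0``).
    """
    rng = _child_rng(seed, 3)
    out: dict = {"truth": {}}

    # -- leaf drying series: fast decline then quasi-linear phase ---------
    t = np.arange(0.0, 30.0, 2.0)  # hours
    leaf_area = 10e-4  # m^2 (10 cm^2)
    fast = 5e-3 * np.exp(-t / 2.0)  # g, stomatal-closure transient
    lin_slope = 1.08e-3  # g h^-1 quasi-linear mass loss
    mass = 0.5 + fast - lin_slope * t
    mass = mass + noise * 1e-5 * rng.standard_normal(len(t))
    fvfm = np.full(len(t), np.nan)
    fvfm[::2] = 0.8
    out["drying"] = pd.DataFrame(
        {
            "time_h": t,
            "leaf_mass_g": mass,
            "fvfm": fvfm,
            "rh": 0.5,
            "temp_c": 20.0,
            "pressure_kpa": 101.3,
            "leaf_area_m2": leaf_area,
        }
    )
    from .derived import tetens_svp, MOLAR_MASS_WATER

    vpd = tetens_svp(20.0) * (1 - 0.5)
    g_truth = (lin_slope / 3600.0 / MOLAR_MASS_WATER / leaf_area) / (vpd / 101.3)
    out["truth"]["g_min"] = float(g_truth)

    # -- stem flow-pressure pairs ------------------------------------------
    k = 0.01  # g s^-1 per MPa mm^-1
    grads = np.repeat(np.array([0.5e-3, 1.0e-3, 1.5e-3]), 3)  # MPa mm^-1
    flow = k * grads + noise * 1e-7 * rng.standard_normal(len(grads))
    out["flow_pressure"] = pd.DataFrame(
        {
            "flow_g_s": flow,
            "pressure_gradient_mpa_mm": grads,
            "temp_c": 20.0,
            "xylem_area_mm2": 1.0,
        }
    )
    out["truth"]["k_stem"] = k  # per mm^2 at 20 °C

    # -- vessel diameters ---------------------------------------------------
    d = rng.lognormal(mean=np.log(30.0), sigma=0.3, size=40)  # µm
    out["vessels"] = pd.DataFrame({"diameter_um": d, "counted_area_mm2": 1.0})
    out["truth"]["d_h"] = float(np.mean(d**4) ** 0.25)

    # -- root segments with one broken tip ---------------------------------
    alpha, beta_allo = -2.0, 2.4  # ln(mass) = alpha + beta*ln(diameter)
    diam = np.array([0.5, 0.8, 1.2, 1.8, 2.5, 3.5])
    masses = np.exp(alpha + beta_allo * np.log(diam))
    roots = pd.DataFrame(
        {
            "proximal_diameter_mm": diam,
            "distal_diameter_mm": diam * 0.6,
            "dry_mass_g": masses,
        }
    )
    # break the second-smallest segment: mass lost, diameter still measured
    broken_mass = float(roots.loc[1, "dry_mass_g"])
    roots.loc[1, "dry_mass_g"] = np.nan
    out["roots"] = roots
    out["truth"]["root_total_mass"] = float(masses.sum())
    out["truth"]["root_broken_mass"] = broken_mass

    # -- growth series: exact exponential growth ---------------------------
    r = 0.01  # day^-1
    days = np.array([0.0, 100.0, 200.0])
    out["growth"] = pd.DataFrame(
        {"day": days, "geometric_mean_mass_g": np.exp(r * days)}
    )
    out["truth"]["rgr_mass"] = r * 1000.0  # mg g^-1 day^-1
    return out


# ---------------------------------------------------------------------------
# Full-study writer (CLI `simulate`)
# ---------------------------------------------------------------------------

def write_study(cfg: SimulationConfig, outdir: str | Path) -> dict:
    """Emit the complete synthetic input bundle: trait table, tree, site and
    species info, prediction table, performance CSV, raw streams, and a
    truth.json of generative parameters.  Returns the paths written."""
    from .datamodel import write_trait_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = simulate_tree(cfg.n_species, cfg.tree_height, seed=cfg.seed,
                         labels=cfg.species_ids)
    tt = simulate_traits(cfg, tree)
    cells, perf_truth = simulate_performance(cfg)
    streams = simulate_raw_streams(cfg, seed=cfg.seed)

    paths = {}
    paths["tree"] = outdir / "tree.nwk"
    paths["tree"].write_text(tree.as_newick() + "\n")
    paths["traits"] = outdir / "trait_table.csv"
    write_trait_table(tt, paths["traits"])
    paths["sites"] = outdir / "sites.csv"
    pd.DataFrame(
        {"site_id": cfg.site_ids, "site_pe": cfg.site_pe}
    ).to_csv(paths["sites"], index=False)
    paths["species"] = outdir / "species.csv"
    pd.DataFrame(
        {"species_id": cfg.species_ids, "species_pe": cfg.species_pe}
    ).to_csv(paths["species"], index=False)
    paths["predictions"] = outdir / "predictions.csv"
    pd.DataFrame(
        {
            "trait_id": [tg.trait_id for tg in cfg.traits],
            "transform": [tg.transform.value for tg in cfg.traits],
            "predicted_direction": [tg.predicted_direction for tg in cfg.traits],
        }
    ).to_csv(paths["predictions"], index=False)
    paths["performance"] = outdir / "performance.csv"
    pd.DataFrame([asdict(c) for c in cells]).to_csv(paths["performance"], index=False)
    for name in ("drying", "flow_pressure", "vessels", "roots", "growth"):
        paths[name] = outdir / f"raw_{name}.csv"
        streams[name].to_csv(paths[name], index=False)
    truth = {
        "seed": cfg.seed,
        "traits": {
            tg.trait_id: {
                "a": tg.a, "b_site": tg.b_site, "b_species": tg.b_species,
                "c": tg.c, "sigma2_phylo": tg.sigma2_phylo,
                "sigma2_site": tg.sigma2_site, "sigma2_e": tg.sigma2_e,
                "transform": tg.transform.value,
                "predicted_direction": tg.predicted_direction,
            }
            for tg in cfg.traits
        },
        "survival": [asdict(s) for s in cfg.survival],
        "performance": perf_truth,
        "raw_streams": streams["truth"],
    }
    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(json.dumps(truth, indent=1, sort_keys=True))
    return {k: str(v) for k, v in paths.items()}
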