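"""Domain types, file readers/writers, and validation shared by all stages.

The analysis operates on species-by-site trait means from a reciprocal
transplant experiment: each of ``n_species`` taxa is grown in each of
``n_sites`` common gardens along a climatic moisture-supply gradient
measured by P/E_p (mean annual precipitation over pan evaporation,
mm/mm).  Species relatedness enters through a time-calibrated phylogeny
whose shared branch lengths define a Brownian-motion covariance among
species effects.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "SiteInfo",
    "SpeciesInfo",
    "Phylogeny",
    "Transform",
    "TraitDefinition",
    "TraitTable",
    "PerformanceCell",
    "read_trait_table",
    "write_trait_table",
    "read_newick",
    "read_site_info",
    "read_species_info",
    "read_trait_definitions",
    "brownian_covariance",
    "apply_transform",
    "invert_transform",
]

MISSING_TOKENS = {"", "NA", "NaN", "nan"}


class ValidationError(ValueError):
    """Raised when an input file or in-memory object violates an invariant."""


@dataclass(frozen=True)
class SiteInfo:
    """One common garden: identifier and its moisture-supply index."""

    site_id: str
    site_pe: float
    mat_c: float | None = None  # mean annual temperature, °C
    map_mm: float | None = None  # mean annual precipitation, mm

    def __post_init__(self) -> None:
        if not self.site_pe > 0:
            raise ValidationError(f"site_pe must be > 0 (site {self.site_id!r})")


@dataclass(frozen=True)
class SpeciesInfo:
    """One study species: identifier and range-mean moisture supply."""

    species_id: str
    species_pe: float
    species_pe_sd: float = 0.0
    subgenus: str = ""

    def __post_init__(self) -> None:
        if not self.species_pe > 0:
            raise ValidationError(
                f"species_pe must be > 0 (species {self.species_id!r})"
            )


class Transform(str, Enum):
    """Response transform used to normalise a trait before regression."""

    NONE = "none"
    LOG = "log"
    SQRT = "sqrt"


def apply_transform(x: np.ndarray, transform: Transform) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if transform == Transform.LOG:
        return np.log(x)
    if transform == Transform.SQRT:
        return np.sqrt(x)
    return x


def invert_transform(z: np.ndarray, transform: Transform) -> np.ndarray:
    z = np.asarray(z, dtype=float)
    if transform == Transform.LOG:
        return np.exp(z)
    if transform == Transform.SQRT:
        return np.square(z)
    return z


@dataclass(frozen=True)
class TraitDefinition:
    """Metadata for one trait column.

    ``predicted_direction`` is the theoretically expected sign of the
    trait's response to moisture supply (+1: increases with P/E_p,
    -1: decreases).
    """

    trait_id: str
    units: str = ""
    transform: Transform = Transform.NONE
    predicted_direction: int = 1

    def __post_init__(self) -> None:
        if self.predicted_direction not in (-1, 1):
            raise ValidationError(
                f"predicted_direction must be -1 or +1 (trait {self.trait_id!r})"
            )


class Phylogeny:
    """Ultrametric, time-calibrated tree (branch lengths in My).

    Thin wrapper over a :class:`dendropy.Tree` that enforces unique tip
    labels, non-negative branch lengths, and ultrametricity.
    """

    def __init__(self, tree: dendropy.Tree, *, ultrametric_rtol: float = 1e-6):
        self._tree = tree
        tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(tips)) != len(tips):
            raise ValidationError("tip labels are not unique")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is tree.seed_node:
                continue
            if edge.length is None:
                raise ValidationError("tree has an edge with no branch length")
            if edge.length < 0:
                raise ValidationError("tree has a negative branch length")
        self.tips: list[str] = tips
        depths = self._tip_depths()
        height = max(depths.values())
        if height > 0:
            spread = max(depths.values()) - min(depths.values())
            if spread > ultrametric_rtol * height:
                raise ValidationError(
                    f"tree is not ultrametric: tip depth spread {spread:g} "
                    f"exceeds tolerance for height {height:g}"
                )
        self.height: float = height

    @property
    def tree(self) -> dendropy.Tree:
        return self._tree

    def _tip_depths(self) -> dict[str, float]:
        depths: dict[str, float] = {}
        for leaf in self._tree.leaf_node_iter():
            d = 0.0
            node = leaf
            while node is not self._tree.seed_node:
                d += node.edge.length or 0.0
                node = node.parent_node
            depths[leaf.taxon.label] = d
        return depths

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick").strip()


def read_newick(path: str | Path | _io.StringIO) -> Phylogeny:
    """Read a single-tree Newick file into a validated :class:`Phylogeny`."""
    if isinstance(path, _io.StringIO):
        data = path.getvalue()
    else:
        data = Path(path).read_text()
    try:
        tree = dendropy.Tree.get(
            data=data, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise ValidationError(f"could not parse Newick: {exc}") from exc
    return Phylogeny(tree)


def brownian_covariance(
    tree: Phylogeny, tips_order: Sequence[str]
) -> np.ndarray:
    """Brownian-motion covariance matrix over the requested tips.

    Under a Brownian model of trait evolution the covariance between two
    tips is the length of their shared root-to-MRCA path; the variance of
    each tip is its root-to-tip distance (the tree height for an
    ultrametric tree).
    """
    known = set(tree.tips)
    for t in tips_order:
        if t not in known:
            raise ValidationError(f"tip {t!r} not present in tree")
    t = tree.tree
    # depth of every node from the root
    depth: dict[int, float] = {id(t.seed_node): 0.0}
    for node in t.preorder_node_iter():
        if node is t.seed_node:
            continue
        depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    leaves = {leaf.taxon.label: leaf for leaf in t.leaf_node_iter()}

    def ancestors(node) -> list:
        out = []
        while node is not None:
            out.append(node)
            node = node.parent_node
        return out

    anc = {lab: ancestors(leaves[lab]) for lab in tips_order}
    anc_sets = {lab: {id(n) for n in anc[lab]} for lab in tips_order}
    n = len(tips_order)
    cov = np.zeros((n, n))
    for i, a in enumerate(tips_order):
        cov[i, i] = depth[id(leaves[a])]
        for j in range(i + 1, n):
            b = tips_order[j]
            # deepest shared ancestor = MRCA
            mrca_depth = 0.0
            for node in anc[a]:
                if id(node) in anc_sets[b]:
                    mrca_depth = depth[id(node)]
                    break
            cov[i, j] = cov[j, i] = mrca_depth
    return cov


@dataclass
class TraitTable:
    """Species-by-site trait means.

    ``data`` is indexed by a (species_id, site_id) MultiIndex; columns are
    trait ids.  Missing cells are NaN.  Combinations dropped because of
    very low or zero survival are recorded in ``excluded`` rather than
    silently absent.
    """

    data: pd.DataFrame
    definitions: dict[str, TraitDefinition] = field(default_factory=dict)
    excluded: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        idx = self.data.index
        if idx.nlevels != 2:
            raise ValidationError("TraitTable index must be (species_id, site_id)")
        if idx.has_duplicates:
            dups = idx[idx.duplicated()].tolist()
            raise ValidationError(f"duplicate (species, site) keys: {dups}")
        self.data.index = idx.set_names(["species_id", "site_id"])

    @property
    def species_ids(self) -> list[str]:
        return sorted(self.data.index.get_level_values("species_id").unique())

    @property
    def site_ids(self) -> list[str]:
        return sorted(self.data.index.get_level_values("site_id").unique())

    @property
    def trait_ids(self) -> list[str]:
        return list(self.data.columns)

    def trait(self, trait_id: str) -> pd.Series:
        return self.data[trait_id]

    def validate_against(
        self, species: Iterable[SpeciesInfo], sites: Iterable[SiteInfo]
    ) -> None:
        sp = {s.species_id for s in species}
        si = {s.site_id for s in sites}
        for a, b in self.data.index:
            if a not in sp:
                raise ValidationError(f"unknown species {a!r} in trait table")
            if b not in si:
                raise ValidationError(f"unknown site {b!r} in trait table")


@dataclass(frozen=True)
class PerformanceCell:
    """Survival and growth summary for one species at one site.

    ``p_hat`` is the fraction surviving out of ``n_planted``;
    ``trait_mean``/``trait_sd`` summarise final height (cm) or shoot mass
    (g) over the ``n_measured`` plants actually measured.
    """

    species_id: str
    site_id: str
    n_planted: int
    n_survived: int
    n_measured: int
    trait_mean: float
    trait_sd: float

    def __post_init__(self) -> None:
        if not (0 <= self.n_survived <= self.n_planted):
            raise ValidationError("need 0 <= n_survived <= n_planted")
        if self.n_measured > self.n_survived:
            raise ValidationError("n_measured cannot exceed n_survived")
        if self.n_measured > 0 and self.trait_sd < 0:
            raise ValidationError("trait_sd must be >= 0")

    @property
    def p_hat(self) -> float:
        return self.n_survived / self.n_planted


# ---------------------------------------------------------------------------
# CSV readers / writers.  One dialect throughout: comma separated, UTF-8,
# "." decimal, empty or "NA" = missing.
# ---------------------------------------------------------------------------

def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, na_values=sorted(MISSING_TOKENS), keep_default_na=False)


def read_trait_table(
    path, defs: Sequence[TraitDefinition] | None = None
) -> TraitTable:
    """Read a species-by-site trait-mean CSV.

    The file must carry ``species_id`` and ``site_id`` key columns; every
    other column is a trait.  An optional boolean ``excluded`` column flags
    combinations dropped for very low or zero survival.
    """
    df = _read_csv(path)
    for col in ("species_id", "site_id"):
        if col not in df.columns:
            raise ValidationError(f"missing key column {col!r}")
    keys = list(zip(df["species_id"], df["site_id"]))
    seen: set = set()
    for k in keys:
        if k in seen:
            raise ValidationError(f"duplicate (species, site) key {k}")
        seen.add(k)
    excluded: list[tuple[str, str]] = []
    if "excluded" in df.columns:
        flag = df["excluded"].fillna(False).astype(bool)
        excluded = [
            (str(a), str(b))
            for a, b in zip(df.loc[flag, "species_id"], df.loc[flag, "site_id"])
        ]
        df = df.loc[~flag].drop(columns=["excluded"])
    df = df.set_index(["species_id", "site_id"])
    bad_cells: list[str] = []
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        newly_bad = coerced.isna() & df[col].notna()
        bad_cells.extend(f"{col}@{idx}" for idx in df.index[newly_bad])
        df[col] = coerced
    if bad_cells:
        raise ValidationError(f"non-numeric trait cells: {bad_cells}")
    dmap = {d.trait_id: d for d in defs} if defs else {}
    return TraitTable(data=df, definitions=dmap, excluded=excluded)


def write_trait_table(tt: TraitTable, path) -> None:
    df = tt.data.reset_index()
    if tt.excluded:
        extra = pd.DataFrame(
            tt.excluded, columns=["species_id", "site_id"]
        ).reindex(columns=df.columns)
        extra["excluded"] = True
        df = df.assign(excluded=False)
        df = pd.concat([df, extra], ignore_index=True)
    df.to_csv(path, index=False, na_rep="NA")


def read_site_info(path) -> list[SiteInfo]:
    df = _read_csv(path)
    out = [
        SiteInfo(
            site_id=str(r.site_id),
            site_pe=float(r.site_pe),
            mat_c=float(r.mat_c) if "mat_c" in df.columns and pd.notna(r.mat_c) else None,
            map_mm=float(r.map_mm) if "map_mm" in df.columns and pd.notna(r.map_mm) else None,
        )
        for r in df.itertuples()
    ]
    ids = [s.site_id for s in out]
    if len(set(ids)) != len(ids):
        raise ValidationError("site_ids are not unique")
    return out


def read_species_info(path) -> list[SpeciesInfo]:
    df = _read_csv(path)
    out = [
        SpeciesInfo(
            species_id=str(r.species_id),
            species_pe=float(r.species_pe),
            species_pe_sd=float(getattr(r, "species_pe_sd", 0.0) or 0.0),
            subgenus=str(getattr(r, "subgenus", "") or ""),
        )
        for r in df.itertuples()
    ]
    ids = [s.species_id for s in out]
    if len(set(ids)) != len(ids):
        raise ValidationError("species_ids are not unique")
    return out


def read_trait_definitions(path) -> list[TraitDefinition]:
    df = _read_csv(path)
    return [
        TraitDefinition(
            trait_id=str(r.trait_id),
            units=str(getattr(r, "units", "") or ""),
            transform=Transform(str(getattr(r, "transform", "none") or "none")),
            predicted_direction=int(r.predicted_direction),
        )
        for r in df.itertuples()
    ]
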