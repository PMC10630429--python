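"""Physiological, hydraulic, and allocational traits derived from raw
measurement streams.

Each calculator takes one measurement series and returns the derived
trait on the scale the downstream regression expects, flagging (rather
than silently dropping) measurements that fail their quality criteria:

* ``compute_gmin`` — minimum leaf conductance from a bench drying curve.
* ``compute_kleaf`` — leaf hydraulic conductance from paired bagged /
  unbagged water potentials and transpiration.
* ``compute_kstem`` — stem hydraulic conductivity from steady-state
  flow-pressure pairs, standardized to 20 °C and xylem area.
* ``hydraulic_diameter`` / ``theoretical_conductivity`` — hydraulically
  weighted vessel diameter and the Poiseuille no-embolism conductivity.
* ``relative_growth_rate`` — slope of log size against time.
* ``impute_root_mass`` — allometric completion of broken root systems.
* ``standardized_ratio`` — common-slope allometric intercepts, removing
  size confounding from trait ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DryingSeries",
    "KleafMeasurement",
    "FlowPressureSeries",
    "VesselSample",
    "RootSegmentTable",
    "GrowthSeries",
    "DerivedValue",
    "tetens_svp",
    "water_viscosity_ratio",
    "compute_gmin",
    "compute_kleaf",
    "compute_kstem",
    "hydraulic_diameter",
    "theoretical_conductivity",
    "relative_growth_rate",
    "impute_root_mass",
    "standardized_ratio",
]

# Physical constants.  Water properties at 20 °C.
MOLAR_MASS_WATER = 18.015  # g mol^-1
WATER_DENSITY_20C = 998.2  # kg m^-3
WATER_VISCOSITY_20C = 1.002e-3  # Pa s


def tetens_svp(temp_c: float) -> float:
    """Saturation vapor pressure over liquid water (kPa), Tetens equation."""
    return 0.61078 * np.exp(17.27 * temp_c / (temp_c + 237.3))


def water_viscosity_ratio(temp_c: float) -> float:
    """eta(T)/eta(20 °C) for liquid water (Kestin-type correlation, 0-100 °C)."""
    expo = (20.0 - temp_c) * (1.3272 - 0.001053 * (temp_c - 20.0)) / (temp_c + 105.0)
    return 10.0**expo


@dataclass
class DerivedValue:
    """A derived trait value plus its QC status."""

    value: float | None
    ok: bool = True
    reason: str = ""
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# g_min: minimum leaf conductance from a drying curve
# ---------------------------------------------------------------------------


@dataclass
class DryingSeries:
    time_h: np.ndarray  # strictly increasing
    leaf_mass_g: np.ndarray
    fvfm: np.ndarray  # NaN where not measured (every other weighing)
    rh: float  # chamber relative humidity, fraction
    temp_c: float
    pressure_kpa: float
    leaf_area_m2: float

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, dtype=float)
        self.leaf_mass_g = np.asarray(self.leaf_mass_g, dtype=float)
        self.fvfm = np.asarray(self.fvfm, dtype=float)
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.leaf_mass_g <= 0):
            raise ValueError("leaf masses must be > 0")
        good = self.fvfm[np.isfinite(self.fvfm)]
        if np.any((good < 0) | (good > 1)):
            raise ValueError("F_v/F_m must lie in [0, 1]")


def _interval_conductance(s: DryingSeries) -> np.ndarray:
    """Per-interval conductance (mol m^-2 s^-1) from successive weighings."""
    dm = -np.diff(s.leaf_mass_g)  # g lost per interval
    dt = np.diff(s.time_h) * 3600.0  # s
    flux = dm / dt / MOLAR_MASS_WATER / s.leaf_area_m2  # mol m^-2 s^-1
    vpd = tetens_svp(s.temp_c) * (1.0 - s.rh)  # kPa
    return flux / (vpd / s.pressure_kpa)


def _bracketing_fvfm_ok(s: DryingSeries, i: int, threshold: float) -> bool:
    """F_v/F_m is read every other weighing; an interval passes when the
    nearest measured values before its start and after its end both exceed
    the threshold."""
    before = s.fvfm[: i + 1]
    after = s.fvfm[i + 1 :]
    before = before[np.isfinite(before)]
    after = after[np.isfinite(after)]
    lo = before[-1] if before.size else np.nan
    hi = after[0] if after.size else np.nan
    if np.isnan(lo) and np.isnan(hi):
        return False
    vals = [v for v in (lo, hi) if not np.isnan(v)]
    return all(v > threshold for v in vals)


def compute_gmin(
    s: DryingSeries,
    *,
    fvfm_threshold: float = 0.7,
    quasilinear_tol: float = 0.2,
) -> DerivedValue:
    """Minimum leaf conductance (mol m^-2 s^-1) from a bench drying curve.

    Per-interval conductance is the molar water flux per leaf area divided
    by the mole-fraction vapor pressure deficit.  The quasi-linear phase is
    the longest suffix of valid intervals whose conductance stays within
    ``quasilinear_tol`` of its median; the reported value is the mean of
    the lowest-conductance sequential pair inside that phase, restricted
    to intervals whose bracketing F_v/F_m readings exceed the viability
    threshold.
    """
    if len(s.time_h) < 4:
        return DerivedValue(None, ok=False, reason="fewer than 4 weighings")
    g = _interval_conductance(s)
    warnings: list[str] = []
    valid = np.ones(len(g), dtype=bool)
    gains = g < 0  # mass gained over the interval
    if gains.any():
        valid &= ~gains
        warnings.append(f"{int(gains.sum())} interval(s) excluded for mass gain")
    fv_ok = np.array(
        [_bracketing_fvfm_ok(s, i, fvfm_threshold) for i in range(len(g))]
    )
    if (valid & fv_ok).sum() < 2:
        return DerivedValue(
            None, ok=False, reason="fewer than 2 intervals with viable F_v/F_m",
            warnings=warnings,
        )
    # longest suffix of valid intervals within tolerance of its median
    idx_valid = np.flatnonzero(valid)
    phase: np.ndarray = idx_valid[-2:]
    for start in range(len(idx_valid) - 1):
        cand = idx_valid[start:]
        med = np.median(g[cand])
        scale = abs(med) if med != 0 else 1.0
        if np.all(np.abs(g[cand] - med) <= quasilinear_tol * scale):
            phase = cand
            break
    usable = [i for i in phase if fv_ok[i]]
    # lowest sequential (consecutive-interval) pair
    best = None
    for a, b in zip(usable, usable[1:]):
        if b == a + 1:
            pair_mean = 0.5 * (g[a] + g[b])
            if best is None or pair_mean < best:
                best = pair_mean
    if best is None:
        return DerivedValue(
            None, ok=False,
            reason="no sequential interval pair with viable F_v/F_m in quasi-linear phase",
            warnings=warnings,
        )
    return DerivedValue(float(best), warnings=warnings)


# ---------------------------------------------------------------------------
# k_leaf
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class KleafMeasurement:
    transpiration: float  # mmol m^-2 s^-1
    psi_stem: float  # MPa, bagged leaf
    psi_leaf: float  # MPa, unbagged leaf

    def __post_init__(self) -> None:
        if self.psi_stem > 0 or self.psi_leaf > 0:
            raise ValueError("water potentials must be <= 0 MPa")
        if self.transpiration < 0:
            raise ValueError("transpiration must be >= 0")


def compute_kleaf(
    m: KleafMeasurement, *, min_gradient_mpa: float = 0.3
) -> DerivedValue:
    """Leaf hydraulic conductance k_leaf = T / (psi_stem - psi_leaf),
    mmol m^-2 s^-1 MPa^-1.

    Measurements with a small driving gradient (< ~0.3 MPa) are excluded:
    such gradients likely reflect continued transpiration by the bagged
    leaf or a low unbagged transpiration rate.
    """
    dpsi = m.psi_stem - m.psi_leaf
    if dpsi <= 0:
        return DerivedValue(None, ok=False, reason="non-positive gradient")
    if dpsi < min_gradient_mpa:
        return DerivedValue(
            None, ok=False,
            reason=f"pressure difference {dpsi:.3g} MPa below {min_gradient_mpa} MPa",
        )
    return DerivedValue(m.transpiration / dpsi)


# ---------------------------------------------------------------------------
# K_stem
# ---------------------------------------------------------------------------


@dataclass
class FlowPressureSeries:
    flow_g_s: np.ndarray
    pressure_gradient_mpa_mm: np.ndarray
    temp_c: float = 20.0
    xylem_area_mm2: float = 1.0
    leaf_area_m2: float | None = None
    site_id: str = ""

    def __post_init__(self) -> None:
        self.flow_g_s = np.asarray(self.flow_g_s, dtype=float)
        self.pressure_gradient_mpa_mm = np.asarray(
            self.pressure_gradient_mpa_mm, dtype=float
        )
        if len(self.flow_g_s) < 3:
            raise ValueError("need at least three steady-state flow points")
        if len(np.unique(self.pressure_gradient_mpa_mm)) < 2:
            raise ValueError("need at least two distinct pressures")


def compute_kstem(
    series: FlowPressureSeries, *, per_leaf_area: bool = False
) -> DerivedValue:
    """Stem hydraulic conductivity: OLS slope of flow (g s^-1) against
    pressure gradient (MPa mm^-1), standardized to 20 °C by the water
    dynamic-viscosity ratio, divided by xylem area (mm^2) or leaf area.
    """
    x = series.pressure_gradient_mpa_mm
    y = series.flow_g_s
    slope = float(np.polyfit(x, y, 1)[0])
    if slope < 0:
        return DerivedValue(None, ok=False, reason="negative flow-pressure slope")
    if slope == 0:
        return DerivedValue(None, ok=False, reason="zero flow-pressure slope")
    k20 = slope * water_viscosity_ratio(series.temp_c)
    if per_leaf_area:
        if not series.leaf_area_m2 or series.leaf_area_m2 <= 0:
            return DerivedValue(None, ok=False, reason="no leaf area recorded")
        return DerivedValue(k20 / series.leaf_area_m2)
    return DerivedValue(k20 / series.xylem_area_mm2)


def rescale_to_median_area(
    kstem_per_area: Sequence[float],
    xylem_area_mm2: Sequence[float],
    site_ids: Sequence[str],
    *,
    median_area: float | None = None,
) -> np.ndarray:
    """Rescale per-area K_stem values to the median xylem area using the
    per-species regression ln(K/XA) ~ ln(XA) + site.

    Per-area conductivity is not fully standardized by xylem area, so
    residual area variation can bias species comparisons; this removes the
    fitted allometric dependence, evaluating every measurement at the
    (per-species by default) median area.
    """
    k = np.asarray(kstem_per_area, dtype=float)
    xa = np.asarray(xylem_area_mm2, dtype=float)
    if np.any(k <= 0) or np.any(xa <= 0):
        raise ValueError("K_stem and xylem areas must be > 0")
    sites = pd.Categorical(list(site_ids))
    X = np.column_stack(
        [np.log(xa)]
        + [(sites.codes == c).astype(float) for c in range(len(sites.categories))]
    )
    coef, *_ = np.linalg.lstsq(X, np.log(k), rcond=None)
    b = coef[0]
    xa_med = float(np.median(xa)) if median_area is None else float(median_area)
    return np.exp(np.log(k) - b * (np.log(xa) - np.log(xa_med)))


# ---------------------------------------------------------------------------
# Xylem anatomy
# ---------------------------------------------------------------------------


@dataclass
class VesselSample:
    diameters_um: np.ndarray
    counted_area_mm2: float = 1.0

    def __post_init__(self) -> None:
        self.diameters_um = np.asarray(self.diameters_um, dtype=float)
        if self.diameters_um.size == 0:
            raise ValueError("empty vessel sample")
        if np.any(self.diameters_um <= 0):
            raise ValueError("vessel diameters must be > 0")


def hydraulic_diameter(v: VesselSample) -> float:
    """Hydraulically weighted vessel diameter D_h = ((1/n) sum D_i^4)^(1/4), µm."""
    return float(np.mean(v.diameters_um**4) ** 0.25)


def theoretical_conductivity(v: VesselSample) -> float:
    """Theoretical stem conductivity from Poiseuille's law assuming no
    embolism: (pi rho_w / (128 eta_20)) * sum(D_i^4) / counted area.

    Returned in g s^-1 mm^-1 MPa^-1 per mm^2 of counted xylem (numerically
    equal to the SI value in kg s^-1 m^-1 Pa^-1 m^-2).
    """
    if v.counted_area_mm2 <= 0:
        raise ValueError("counted area must be > 0")
    d_m = v.diameters_um * 1e-6
    area_m2 = v.counted_area_mm2 * 1e-6
    return float(
        np.pi * WATER_DENSITY_20C / (128.0 * WATER_VISCOSITY_20C)
        * np.sum(d_m**4) / area_m2
    )


# ---------------------------------------------------------------------------
# Relative growth rate
# ---------------------------------------------------------------------------


@dataclass
class GrowthSeries:
    day: np.ndarray
    value: np.ndarray  # geometric-mean biomass (g) or height (cm)
    mass_units: bool = True  # True: report in mg g^-1 day^-1 (x1000)

    def __post_init__(self) -> None:
        self.day = np.asarray(self.day, dtype=float)
        self.value = np.asarray(self.value, dtype=float)
        if len(self.day) < 2:
            raise ValueError("need at least two time points")
        if np.any(self.value <= 0):
            raise ValueError("growth values must be > 0")


def relative_growth_rate(g: GrowthSeries) -> float:
    """RGR: OLS slope of ln(size) against days since planting.

    Returned in mg g^-1 day^-1 for mass series (slope x 1000), or the raw
    per-day log slope for height series.
    """
    slope = float(np.polyfit(g.day, np.log(g.value), 1)[0])
    return slope * 1000.0 if g.mass_units else slope


# ---------------------------------------------------------------------------
# Root-mass imputation
# ---------------------------------------------------------------------------


@dataclass
class RootSegmentTable:
    """Excavated root segments: proximal/distal diameters (mm) and dry mass
    (g; NaN where the segment broke and its mass was lost)."""

    table: pd.DataFrame  # columns: proximal_diameter_mm, distal_diameter_mm, dry_mass_g

    def __post_init__(self) -> None:
        req = {"proximal_diameter_mm", "distal_diameter_mm", "dry_mass_g"}
        if not req.issubset(self.table.columns):
            raise ValueError(f"root table needs columns {sorted(req)}")
        d = self.table[["proximal_diameter_mm", "distal_diameter_mm"]].to_numpy()
        if np.any(d <= 0):
            raise ValueError("root diameters must be > 0")
        m = self.table["dry_mass_g"]
        if np.any(m.dropna() < 0):
            raise ValueError("root masses must be >= 0 when present")


def impute_root_mass(t: RootSegmentTable) -> tuple[pd.DataFrame, dict]:
    """Complete a root-segment table by allometric imputation.

    Fits ln(mass) ~ ln(proximal diameter) on complete segments, then
    predicts missing masses working from the smallest to the largest
    proximal diameter, refitting as newly completed segments accumulate.
    Masses of complete segments are never altered.

    Returns the completed table plus a summary with the total mass and the
    imputed fraction.
    """
    df = t.table.copy().reset_index(drop=True)
    complete = df["dry_mass_g"].notna()
    if complete.sum() < 3:
        raise ValueError("need >= 3 complete segments to fit the allometry")

    def _fit(sub: pd.DataFrame) -> tuple[float, float]:
        x = np.log(sub["proximal_diameter_mm"].to_numpy())
        y = np.log(sub["dry_mass_g"].to_numpy())
        b, a = np.polyfit(x, y, 1)
        return a, b

    missing_idx = df.index[~complete].tolist()
    missing_idx.sort(key=lambda i: df.loc[i, "proximal_diameter_mm"])
    imputed_total = 0.0
    for i in missing_idx:
        a, b = _fit(df[df["dry_mass_g"].notna()])
        pred = float(np.exp(a + b * np.log(df.loc[i, "proximal_diameter_mm"])))
        df.loc[i, "dry_mass_g"] = pred
        imputed_total += pred
    total = float(df["dry_mass_g"].sum())
    summary = {
        "total_mass_g": total,
        "imputed_mass_g": imputed_total,
        "imputed_fraction": imputed_total / total if total > 0 else 0.0,
        "n_imputed": len(missing_idx),
    }
    return df, summary


# ---------------------------------------------------------------------------
# Standardized (common-slope allometric) ratios
# ---------------------------------------------------------------------------


def standardized_ratio(
    t1: Sequence[float], t2: Sequence[float], groups: Sequence
) -> tuple[np.ndarray, float]:
    """Size-standardized trait ratio via a common allometric slope.

    Fits ln(T1) = a_group + beta * ln(T2) with one intercept per
    (species, site) group and a single shared slope; returns the
    per-observation standardized ratio ln(T1) - beta*ln(T2) and beta.
    Unlike the raw ratio T1/T2, this does not confound the trait contrast
    with plant size when T1 scales allometrically with T2.
    """
    y = np.log(np.asarray(t1, dtype=float))
    x = np.log(np.asarray(t2, dtype=float))
    if np.any(~np.isfinite(y)) or np.any(~np.isfinite(x)):
        raise ValueError("T1 and T2 must be positive and finite")
    cats = pd.Categorical(list(groups))
    n_groups = len(cats.categories)
    if len(y) < n_groups + 1:
        raise ValueError("common slope unidentifiable: too few observations")
    X = np.column_stack(
        [x] + [(cats.codes == c).astype(float) for c in range(n_groups)]
    )
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    beta = float(coef[0])
    return y - beta * x, beta
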