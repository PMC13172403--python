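"""Carbon stocks to 1 m equivalent depth and organic-matter depth trends.

Organic carbon is modeled from loss-on-ignition with the quadratic Craft
conversion OC = 0.40*LOI + 0.0025*LOI^2 (both in percent of dry mass), carbon
density as its product with dry bulk density, and the core stock as the
mass-depth-weighted mean carbon density scaled to a 1 m column.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import CoreValidationError, SoilCore

__all__ = [
    "StockResult",
    "TrendResult",
    "loi_to_oc",
    "carbon_density",
    "stock_to_1m",
    "om_depth_trend",
    "summarize_stocks",
    "IPCC_STOCK_1M_KGC_M2",
    "IPCC_CAR_GC_M2_YR",
]

# IPCC Tier I reference constants, for report annotation only (never used in
# any computation): default 1 m stock emission factor and removal factor.
IPCC_STOCK_1M_KGC_M2 = 25.5
IPCC_CAR_GC_M2_YR = 91.0

# Craft quadratic LOI -> OC coefficients (percent scale)
_CRAFT_LINEAR = 0.40
_CRAFT_QUAD = 0.0025


@dataclass(frozen=True)
class StockResult:
    core_id: str
    stock_1m: float  # kgC m-2, scaled to a 1 m column
    profile_depth: float  # cm actually measured (capped at 100)
    n_increments: int
    mean_loi: float  # fraction
    extrapolated: bool  # True when profile_depth < 100 cm


@dataclass(frozen=True)
class TrendResult:
    core_id: str
    slope: float  # LOI-percent per cm
    intercept: float  # LOI-percent at the surface
    p_value: float
    classification: str  # {"decrease", "increase", "none"}


def loi_to_oc(loi_percent):
    """Convert loss-on-ignition (percent) to organic carbon (percent).

    Uses the quadratic conversion for wetland soils,
    ``OC = 0.40 LOI + 0.0025 LOI**2``; monotone increasing on [0, 100].
    """
    loi_percent = np.asarray(loi_percent, dtype=float)
    if np.any((loi_percent < 0) | (loi_percent > 100)):
        raise ValueError("loi_percent must be within [0, 100]")
    out = _CRAFT_LINEAR * loi_percent + _CRAFT_QUAD * loi_percent**2
    return float(out) if out.ndim == 0 else out


def carbon_density(dbd, oc_percent):
    """Carbon density (gC cm-3) as dry bulk density x organic carbon fraction."""
    dbd = np.asarray(dbd, dtype=float)
    oc_percent = np.asarray(oc_percent, dtype=float)
    if np.any(dbd < 0) or np.any(oc_percent < 0):
        raise ValueError("dry bulk density and organic carbon must be non-negative")
    out = dbd * oc_percent / 100.0
    return float(out) if out.ndim == 0 else out


def core_carbon_density(core: SoilCore) -> np.ndarray:
    """Per-increment carbon density (gC cm-3) for a core (NaN where inputs missing)."""
    loi = core.data["loi"].to_numpy(dtype=float)
    dbd = core.data["dry_bulk_density"].to_numpy(dtype=float)
    rho_c = np.full(len(loi), np.nan)
    ok = ~np.isnan(loi) & ~np.isnan(dbd)
    rho_c[ok] = carbon_density(dbd[ok], loi_to_oc(np.clip(loi[ok], 0, 1) * 100.0))
    return rho_c


def stock_to_1m(core: SoilCore, min_depth: float = 90.0) -> StockResult:
    """Carbon stock scaled to a 1 m column, kgC m-2.

    The stock is the thickness-weighted mean carbon density over increments
    within the top 1 m (a straddling increment is clipped at 100 cm), scaled
    to a 100 cm column: ``(sum rho_i dz_i / sum dz_i) * 100`` gC cm-2, then
    x10 to kgC m-2.  Cores shallower than ``min_depth`` cm are ineligible;
    cores between ``min_depth`` and 100 cm are scaled by their mean density
    and flagged ``extrapolated``.
    """
    dmin = core.data["depth_min"].to_numpy(dtype=float)
    dmax = core.data["depth_max"].to_numpy(dtype=float)
    profile_depth = float(dmax.max()) if len(dmax) else 0.0
    if profile_depth < min_depth:
        raise CoreValidationError(
            f"core {core.core_id}: profile depth {profile_depth:.1f} cm < required {min_depth:.0f} cm"
        )
    rho_c = core_carbon_density(core)

    top = np.minimum(dmax, 100.0)
    dz = np.clip(top - dmin, 0.0, None)  # clipped thickness within the top meter
    use = dz > 0
    if np.isnan(rho_c[use]).any():
        bad = dmin[use][np.isnan(rho_c[use])]
        raise CoreValidationError(
            f"core {core.core_id}: missing carbon density in the top meter at depths {bad.tolist()} "
            "(interpolate gaps first)"
        )
    mean_rho = float(np.sum(rho_c[use] * dz[use]) / np.sum(dz[use]))  # gC cm-3
    stock = mean_rho * 100.0 * 10.0  # gC cm-2 over 1 m column -> kgC m-2
    loi = core.data["loi"].to_numpy(dtype=float)
    return StockResult(
        core_id=core.core_id,
        stock_1m=stock,
        profile_depth=min(profile_depth, 100.0),
        n_increments=int(use.sum()),
        mean_loi=float(np.nanmean(loi[use])),
        extrapolated=profile_depth < 100.0,
    )


def om_depth_trend(core: SoilCore, alpha: float = 0.05) -> TrendResult:
    """Classify the organic-matter depth trend of a core by OLS.

    Regresses LOI (percent) on increment midpoint depth (cm) and applies a
    two-sided t-test on the slope; classification is "decrease"/"increase"
    by slope sign when p < alpha, else "none".
    """
    loi = core.data["loi"].to_numpy(dtype=float) * 100.0
    mids = core.midpoints
    ok = ~np.isnan(loi)
    if ok.sum() < 3:
        raise CoreValidationError(f"core {core.core_id}: need >=3 LOI values for a depth trend")
    res = stats.linregress(mids[ok], loi[ok])
    p = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
    if p < alpha and res.slope < 0:
        cls = "decrease"
    elif p < alpha and res.slope > 0:
        cls = "increase"
    else:
        cls = "none"
    return TrendResult(
        core_id=core.core_id,
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=p,
        classification=cls,
    )


def summarize_stocks(results: list[StockResult], group_by: str = "dataset",
                     site_ids: dict[str, str] | None = None) -> pd.DataFrame:
    """Mean/median/min/max/n of 1 m stocks at core, site or dataset grouping.

    The dataset mean is the unweighted mean over cores.  ``site_ids`` maps
    core_id -> site_id (required for ``group_by="site"``).
    """
    if not results:
        raise ValueError("no stock results to summarize")
    df = pd.DataFrame(
        {
            "core_id": [r.core_id for r in results],
            "stock_1m": [r.stock_1m for r in results],
        }
    )
    if group_by == "core":
        grouped = df.set_index("core_id")[["stock_1m"]]
        out = grouped.rename(columns={"stock_1m": "mean"})
        out["median"] = out["mean"]
        out["min"] = out["mean"]
        out["max"] = out["mean"]
        out["n"] = 1
        return out.reset_index().rename(columns={"core_id": "group"})
    if group_by == "site":
        if site_ids is None:
            raise ValueError("site_ids mapping required for site grouping")
        df["group"] = df["core_id"].map(site_ids)
    elif group_by == "dataset":
        df["group"] = "dataset"
    else:
        raise ValueError(f"unknown grouping {group_by!r}")
    agg = df.groupby("group")["stock_1m"].agg(mean="mean", median="median", min="min", max="max", n="count")
    return agg.reset_index()
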