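"""Reading, writing, validation and cleaning of soil-core depth-series tables.

Tables follow the Coastal Carbon Network style template: a *depthseries* CSV
with one row per depth increment of a core, and a *cores* CSV with one row of
positional/descriptive metadata per core.  Internally everything is held in
canonical units: activities in Bq kg-1, dry bulk density in g cm-3, and
loss-on-ignition (LOI) as a mass fraction in [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DepthIncrement",
    "SoilCore",
    "ValidationReport",
    "SchemaError",
    "ParseError",
    "CoreValidationError",
    "read_depthseries",
    "write_depthseries",
    "join_core_metadata",
    "interpolate_gaps",
    "filter_loi_outliers",
    "validate_core",
]

#: factor converting dpm g-1 to Bq kg-1 (1 dpm = 1/60 Bq; 1 g = 1e-3 kg)
DPM_G_TO_BQ_KG = 1000.0 / 60.0

HABITAT_ZONES = ("high", "high-mid", "mid", "low", "unspecified")

# canonical internal column names, in order
_CANON_COLS = [
    "depth_min",
    "depth_max",
    "dry_bulk_density",
    "loi",
    "cs137",
    "cs137_sd",
    "pb210_total",
    "pb210_total_sd",
    "ra226",
    "ra226_sd",
    "c14_age",
    "c14_sd",
    "c14_material",
]

_ACTIVITY_COLS = ["cs137", "cs137_sd", "pb210_total", "pb210_total_sd", "ra226", "ra226_sd"]

# default mapping from the external CSV dialect to canonical names
DEFAULT_ALIASES = {
    "core_id": "core_id",
    "depth_min": "depth_min",
    "depth_max": "depth_max",
    "dry_bulk_density": "dry_bulk_density",
    "fraction_organic_matter": "loi",
    "cs137_activity": "cs137",
    "cs137_activity_se": "cs137_sd",
    "total_pb210_activity": "pb210_total",
    "total_pb210_activity_se": "pb210_total_sd",
    "ra226_activity": "ra226",
    "ra226_activity_se": "ra226_sd",
    "c14_age": "c14_age",
    "c14_age_se": "c14_sd",
    "c14_material": "c14_material",
}

_CORES_ALIASES = {
    "core_id": "core_id",
    "site_id": "site_id",
    "latitude": "latitude",
    "longitude": "longitude",
    "year": "collection_year",
    "habitat": "habitat_zone",
    "vegetation": "dominant_species",
}


class SchemaError(ValueError):
    """A required column is missing or the file layout is wrong."""


class ParseError(ValueError):
    """A cell could not be parsed as the expected type."""


class CoreValidationError(ValueError):
    """A core violates a structural precondition of an operation."""


@dataclass(frozen=True)
class DepthIncrement:
    """One depth slice of a core; depths are cm below surface, [min, max)."""

    depth_min: float
    depth_max: float
    dry_bulk_density: float | None = None  # g cm-3
    loi: float | None = None  # fraction of dry mass, 0-1
    cs137: float | None = None  # Bq kg-1
    cs137_sd: float | None = None
    pb210_total: float | None = None  # Bq kg-1
    pb210_total_sd: float | None = None
    ra226: float | None = None  # Bq kg-1
    ra226_sd: float | None = None
    c14_age: float | None = None  # 14C yr BP
    c14_sd: float | None = None
    c14_material: str = "none"

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.depth_min + self.depth_max)

    @property
    def thickness(self) -> float:
        return self.depth_max - self.depth_min


@dataclass
class SoilCore:
    """An ordered stack of depth increments plus core-level metadata.

    ``data`` is a DataFrame with the canonical columns; rows are sorted by
    ``depth_min``.  Missing measurements are NaN, never zero.
    """

    core_id: str
    data: pd.DataFrame
    site_id: str | None = None
    latitude: float | None = None
    longitude: float | None = None
    collection_year: int | None = None
    habitat_zone: str = "unspecified"
    dominant_species: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        df = self.data.copy()
        for col in _CANON_COLS:
            if col not in df.columns:
                df[col] = "none" if col == "c14_material" else np.nan
        for col in ("dbd_interpolated", "loi_interpolated"):
            if col not in df.columns:
                df[col] = False
        df = df.sort_values("depth_min", kind="stable").reset_index(drop=True)
        self.data = df

    def __len__(self) -> int:
        return len(self.data)

    @property
    def midpoints(self) -> np.ndarray:
        return 0.5 * (self.data["depth_min"].to_numpy() + self.data["depth_max"].to_numpy())

    @property
    def max_depth(self) -> float:
        return float(self.data["depth_max"].max()) if len(self.data) else 0.0

    @property
    def contiguous(self) -> bool:
        dmin = self.data["depth_min"].to_numpy()
        dmax = self.data["depth_max"].to_numpy()
        return bool(np.allclose(dmax[:-1], dmin[1:])) if len(dmin) > 1 else True

    def increments(self) -> Iterator[DepthIncrement]:
        for row in self.data.itertuples(index=False):
            yield DepthIncrement(
                depth_min=row.depth_min,
                depth_max=row.depth_max,
                dry_bulk_density=_nan_to_none(row.dry_bulk_density),
                loi=_nan_to_none(row.loi),
                cs137=_nan_to_none(row.cs137),
                cs137_sd=_nan_to_none(row.cs137_sd),
                pb210_total=_nan_to_none(row.pb210_total),
                pb210_total_sd=_nan_to_none(row.pb210_total_sd),
                ra226=_nan_to_none(row.ra226),
                ra226_sd=_nan_to_none(row.ra226_sd),
                c14_age=_nan_to_none(row.c14_age),
                c14_sd=_nan_to_none(row.c14_sd),
                c14_material=row.c14_material if isinstance(row.c14_material, str) else "none",
            )

    def copy(self) -> "SoilCore":
        return replace(self, data=self.data.copy(), dominant_species=list(self.dominant_species))


@dataclass
class ValidationReport:
    """Structural check results for one core; empty entries means a clean core."""

    core_id: str
    entries: list[tuple[str, str, str, list[float]]] = field(default_factory=list)
    # each entry: (rule_id, severity in {"error", "warning"}, message, affected depth_mins)

    def add(self, rule_id: str, severity: str, message: str, depths: Sequence[float] = ()) -> None:
        self.entries.append((rule_id, severity, message, list(depths)))

    @property
    def passed(self) -> bool:
        return not self.entries

    @property
    def has_errors(self) -> bool:
        return any(sev == "error" for _, sev, _, _ in self.entries)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "core_id": self.core_id,
                    "rule_id": rid,
                    "severity": sev,
                    "message": msg,
                    "depths": ";".join(f"{d:g}" for d in depths),
                }
                for rid, sev, msg, depths in self.entries
            ],
            columns=["core_id", "rule_id", "severity", "message", "depths"],
        )


def _nan_to_none(x):
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return None
    return x


def _resolve_aliases(alias_map: dict | None) -> dict:
    aliases = dict(DEFAULT_ALIASES)
    if alias_map:
        # user map: external column name -> canonical name
        aliases.update(alias_map)
    return aliases


def read_depthseries(
    path,
    unit_dialect: str = "Bq/kg",
    alias_map: dict | None = None,
) -> list[SoilCore]:
    """Read a depthseries CSV into one :class:`SoilCore` per distinct core_id.

    Parameters
    ----------
    path
        CSV file with a header row; required columns ``core_id``,
        ``depth_min``, ``depth_max`` (possibly under aliases).
    unit_dialect
        ``"Bq/kg"`` (canonical) or ``"dpm/g"``; dpm g-1 activities are
        converted to Bq kg-1 by x(1000/60).
    alias_map
        Optional mapping of external column names to canonical names,
        merged over the template defaults.

    Only increment-level measurements are populated; core metadata is joined
    later with :func:`join_core_metadata`.
    """
    if unit_dialect not in ("Bq/kg", "dpm/g"):
        raise ValueError(f"unknown unit dialect {unit_dialect!r}")
    aliases = _resolve_aliases(alias_map)
    raw = pd.read_csv(path, dtype=str, keep_default_na=True)
    raw = raw.rename(columns={k: v for k, v in aliases.items() if k in raw.columns})
    for required in ("core_id", "depth_min", "depth_max"):
        if required not in raw.columns:
            raise SchemaError(f"depthseries file is missing required column {required!r}")

    numeric_cols = [c for c in _CANON_COLS if c != "c14_material" and c in raw.columns]
    df = raw.copy()
    for col in numeric_cols:
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna() & (df[col].str.strip() != "")
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # header is line 1
            raise ParseError(f"non-numeric value {df[col][bad].iloc[0]!r} in column {col!r} at line {row}")
        df[col] = parsed

    if (df["depth_min"] >= df["depth_max"]).any():
        bad = df[df["depth_min"] >= df["depth_max"]].iloc[0]
        raise CoreValidationError(
            f"core {bad['core_id']}: depth_min {bad['depth_min']} >= depth_max {bad['depth_max']}"
        )

    if unit_dialect == "dpm/g":
        for col in _ACTIVITY_COLS:
            if col in df.columns:
                df[col] = df[col] * DPM_G_TO_BQ_KG

    cores = []
    for core_id, group in df.groupby("core_id", sort=False):
        cores.append(SoilCore(core_id=str(core_id), data=group.drop(columns=["core_id"])))
    return cores


def write_depthseries(cores: Sequence[SoilCore], path, alias_map: dict | None = None) -> None:
    """Write cores back to the external depthseries CSV dialect."""
    aliases = _resolve_aliases(alias_map)
    inverse = {v: k for k, v in aliases.items()}
    frames = []
    for core in cores:
        df = core.data[_CANON_COLS].copy()
        df.insert(0, "core_id", core.core_id)
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out = out.rename(columns={c: inverse.get(c, c) for c in out.columns})
    out.to_csv(path, index=False, float_format="%.6g")


def join_core_metadata(cores: Sequence[SoilCore], path, alias_map: dict | None = None) -> list[SoilCore]:
    """Attach positional/descriptive metadata from a cores CSV, joined on core_id."""
    aliases = dict(_CORES_ALIASES)
    if alias_map:
        aliases.update(alias_map)
    meta = pd.read_csv(path)
    meta = meta.rename(columns={k: v for k, v in aliases.items() if k in meta.columns})
    for required in ("core_id", "latitude", "longitude", "collection_year"):
        if required not in meta.columns:
            raise SchemaError(f"cores file is missing required column {required!r}")
    dup = meta["core_id"][meta["core_id"].duplicated()]
    if len(dup):
        raise SchemaError(f"duplicate core_id rows in cores file: {sorted(set(dup))}")
    meta = meta.set_index(meta["core_id"].astype(str))

    joined = []
    for core in cores:
        core = core.copy()
        if core.core_id in meta.index:
            row = meta.loc[core.core_id]
            core.site_id = str(row["site_id"]) if "site_id" in row and pd.notna(row.get("site_id")) else core.site_id
            core.latitude = float(row["latitude"])
            core.longitude = float(row["longitude"])
            core.collection_year = int(row["collection_year"])
            hz = row.get("habitat_zone")
            if isinstance(hz, str) and hz in HABITAT_ZONES:
                core.habitat_zone = hz
            veg = row.get("dominant_species")
            if isinstance(veg, str) and veg:
                core.dominant_species = [s.strip() for s in veg.split(";") if s.strip()]
        else:
            warnings.warn(f"core {core.core_id}: no metadata row found; metadata left unset")
        joined.append(core)
    return joined


def interpolate_gaps(core: SoilCore) -> SoilCore:
    """Fill missing dry bulk density and LOI from neighboring values.

    Interior gaps are linearly interpolated against increment midpoint depth;
    leading/trailing gaps are filled by nearest-value extension.  Filled cells
    are flagged in ``dbd_interpolated`` / ``loi_interpolated``.  Raises
    :class:`CoreValidationError` if a field is entirely missing.
    """
    core = core.copy()
    mids = core.midpoints
    for col, flag in (("dry_bulk_density", "dbd_interpolated"), ("loi", "loi_interpolated")):
        vals = core.data[col].to_numpy(dtype=float)
        present = ~np.isnan(vals)
        if not present.any():
            raise CoreValidationError(f"core {core.core_id}: all {col} values missing; cannot interpolate")
        if present.all():
            continue
        filled = np.interp(mids, mids[present], vals[present])  # np.interp extends edges by nearest
        core.data[col] = np.where(present, vals, filled)
        core.data[flag] = core.data[flag].to_numpy() | ~present
    return core


def filter_loi_outliers(core: SoilCore, iqr_factor: float = 1.5) -> tuple[SoilCore, list[float]]:
    """Set LOI values outside [Q1 - f*IQR, Q3 + f*IQR] (per core) to missing.

    Quartiles use linear interpolation between order statistics.  Returns the
    filtered core and the depth_min of each removed increment.  Fewer than 4
    non-missing values is a no-op with a warning.
    """
    core = core.copy()
    vals = core.data["loi"].to_numpy(dtype=float)
    present = ~np.isnan(vals)
    if present.sum() < 4:
        warnings.warn(f"core {core.core_id}: fewer than 4 LOI values; outlier filter skipped")
        return core, []
    q1, q3 = np.quantile(vals[present], [0.25, 0.75])
    iqr = q3 - q1
    lo, hi = q1 - iqr_factor * iqr, q3 + iqr_factor * iqr
    out = present & ((vals < lo) | (vals > hi))
    removed = [float(d) for d in core.data.loc[out, "depth_min"]]
    core.data.loc[out, "loi"] = np.nan
    return core, removed


def validate_core(core: SoilCore) -> ValidationReport:
    """Structural checks: depth ordering/contiguity, value ranges, sd positivity.

    Severity ``error`` blocks downstream dating; ``warning`` does not.
    """
    report = ValidationReport(core.core_id)
    df = core.data
    dmin = df["depth_min"].to_numpy(dtype=float)
    dmax = df["depth_max"].to_numpy(dtype=float)

    bad_depth = (dmin < 0) | (dmin >= dmax)
    if bad_depth.any():
        report.add("depth_order", "error", "depth_min must satisfy 0 <= depth_min < depth_max", dmin[bad_depth])
    if len(dmin) > 1:
        overlap = dmax[:-1] > dmin[1:] + 1e-9
        if overlap.any():
            report.add("depth_overlap", "error", "overlapping increments", dmin[1:][overlap])
        gap = dmax[:-1] < dmin[1:] - 1e-9
        if gap.any():
            report.add("non_contiguous", "warning", "gap between consecutive increments", dmin[1:][gap])

    dbd = df["dry_bulk_density"].to_numpy(dtype=float)
    bad = ~np.isnan(dbd) & (dbd <= 0)
    if bad.any():
        report.add("dbd_range", "error", "dry bulk density must be > 0", dmin[bad])

    loi = df["loi"].to_numpy(dtype=float)
    bad = ~np.isnan(loi) & ((loi < 0) | (loi > 1))
    if bad.any():
        report.add("loi_range", "error", "loi out of range [0, 1]", dmin[bad])

    for val_col, sd_col in (
        ("cs137", "cs137_sd"),
        ("pb210_total", "pb210_total_sd"),
        ("ra226", "ra226_sd"),
        ("c14_age", "c14_sd"),
    ):
        val = df[val_col].to_numpy(dtype=float)
        sd = df[sd_col].to_numpy(dtype=float)
        bad = ~np.isnan(val) & (np.isnan(sd) | (sd <= 0))
        if bad.any():
            report.add(f"{sd_col}_positive", "error", f"{sd_col} must be > 0 where {val_col} is present", dmin[bad])

    import datetime

    this_year = datetime.date.today().year
    if core.collection_year is not None and not (1900 <= core.collection_year <= this_year):
        report.add("collection_year", "error", f"collection_year {core.collection_year} outside [1900, {this_year}]")
    return report
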