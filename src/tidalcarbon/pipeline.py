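"""End-to-end orchestration: validate -> clean -> stocks -> Cs QC -> Pb
screening -> Bayesian age-depth MCMC -> carbon accumulation rates.

All tunable constants live in :class:`RunConfig`; the defaults are the
analysis settings every downstream stage reads (nothing is re-hard-coded in
the stages).  Stage errors are logged per core and the pipeline continues;
the run fails only if every core fails.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import car as car_mod
from . import core_io, cs_dating, pb_dating, stocks
from .pb_dating import PlumPriors

__all__ = ["RunConfig", "run_pipeline", "report_summary", "load_fallout_points"]

log = logging.getLogger("tidalcarbon")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run; serializable to/from YAML."""

    depthseries_path: str = ""
    cores_path: str = ""
    outdir: str = "tidalcarbon_run"
    unit_dialect: str = "Bq/kg"
    fallout_points_path: str | None = None  # None -> bundled synthetic fixture
    override_path: str | None = None  # manual 210Pb screening decisions

    # quality control
    background_quantile: float = 0.975
    max_overlap: float = 0.05
    iqr_factor: float = 1.5
    trend_alpha: float = 0.05
    min_depth: float = 90.0  # cm, stock inclusion rule

    # age-depth model
    priors: PlumPriors = field(default_factory=PlumPriors)
    n_burn: int = 2000
    n_store: int = 10000
    seed: int = 1
    horizon: float = 100.0  # yr
    use_kriged_phi: bool = True
    make_plots: bool = True

    def to_yaml(self, path) -> None:
        d = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "priors" in d and isinstance(d["priors"], dict):
            d["priors"] = PlumPriors(**d["priors"])
        return cls(**d)

    def config_hash(self) -> str:
        d = asdict(self)
        d.pop("outdir", None)
        d.pop("make_plots", None)
        return hashlib.sha256(json.dumps(d, sort_keys=True, default=str).encode()).hexdigest()[:12]


def load_fallout_points(path=None) -> list[tuple[float, float, float]]:
    """Load (lat, lon, log fallout) points; default is the bundled synthetic
    stand-in for a global fallout synthesis."""
    if path is None:
        ref = resources.files("tidalcarbon.data") / "fallout_points_synthetic.csv"
        with resources.as_file(ref) as p:
            df = pd.read_csv(p)
    else:
        df = pd.read_csv(path)
    return [
        (float(r.lat), float(r.lon), float(np.log(r.fallout_bq_m2_yr)))
        for r in df.itertuples(index=False)
    ]


def _load_overrides(path) -> dict[str, str]:
    if path is None:
        return {}
    df = pd.read_csv(path)
    return {str(r.core_id): str(r.decision) for r in df.itertuples(index=False)}


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage on every core; returns the artifact dict and writes
    derivative CSVs, a JSON manifest, and per-core diagnostic plots."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for p in (config.depthseries_path, config.cores_path):
        if not Path(p).exists():
            raise FileNotFoundError(f"input path {p!r} does not exist")

    cores = core_io.read_depthseries(config.depthseries_path, unit_dialect=config.unit_dialect)
    cores = core_io.join_core_metadata(cores, config.cores_path)
    overrides = _load_overrides(config.override_path)
    fallout_points = load_fallout_points(config.fallout_points_path)

    artifacts: dict = {
        "config": config,
        "validation": [],
        "stocks": [],
        "trends": [],
        "cs": [],
        "screen": [],
        "ensembles": {},
        "car": [],
        "errors": [],
        "n_cores": len(cores),
    }

    for core in cores:
        cid = core.core_id
        report = core_io.validate_core(core)
        artifacts["validation"].append(report)
        if report.has_errors:
            log.warning("%s: validation errors, skipping (%s)", cid,
                        "; ".join(m for _, s, m, _ in report.entries if s == "error"))
            artifacts["errors"].append((cid, "validation"))
            continue
        try:
            core = core_io.interpolate_gaps(core)
            core, removed = core_io.filter_loi_outliers(core, iqr_factor=config.iqr_factor)
            if removed:
                log.info("%s: LOI outliers removed at depths %s", cid, removed)
                core = core_io.interpolate_gaps(core)
        except core_io.CoreValidationError as exc:
            log.warning("%s: cleaning failed: %s", cid, exc)
            artifacts["errors"].append((cid, "cleaning"))
            continue

        # carbon stocks and organic-matter trend
        try:
            artifacts["stocks"].append(stocks.stock_to_1m(core, min_depth=config.min_depth))
        except core_io.CoreValidationError as exc:
            log.info("%s: no stock (%s)", cid, exc)
        try:
            artifacts["trends"].append(stocks.om_depth_trend(core, alpha=config.trend_alpha))
        except core_io.CoreValidationError:
            pass

        # radiocesium peak QC
        peak = cs_dating.detect_peak(
            core, background_quantile=config.background_quantile, max_overlap=config.max_overlap
        )
        if peak is not None:
            artifacts["cs"].append(peak)
            log.info("%s: Cs peak at %.0f-%.0f cm accepted=%s (bg=%s above=%s below=%s)",
                     cid, peak.peak_depth_min, peak.peak_depth_max, peak.accepted,
                     peak.pass_background, peak.pass_above, peak.pass_below)

        # lead-210 dating
        mode = config.priors.supported_mode
        try:
            unsup, unsup_sd = pb_dating.unsupported_pb210(core, mode=mode)
        except core_io.CoreValidationError as exc:
            if mode == "variable_radon" and "226Ra" in str(exc):
                mode = "tail_background"
                try:
                    unsup, unsup_sd = pb_dating.unsupported_pb210(core, mode=mode)
                except core_io.CoreValidationError as exc2:
                    log.info("%s: no 210Pb dating (%s)", cid, exc2)
                    continue
            else:
                log.info("%s: no 210Pb dating (%s)", cid, exc)
                continue
        screen = pb_dating.screen_profile(core, unsup, unsup_sd,
                                          manual_override=overrides.get(cid, "none"))
        artifacts["screen"].append(screen)
        if not screen.usable:
            log.info("%s: 210Pb profile screened out (low_activity=%s step=%s override=%s)",
                     cid, screen.flag_low_activity, screen.flag_step_shape, screen.manual_override)
            continue

        priors = config.priors
        if config.use_kriged_phi and core.latitude is not None:
            try:
                est = pb_dating.krige_fallout(fallout_points, (core.latitude, core.longitude))
                phi_mean, phi_shape = pb_dating.phi_prior(est)
                priors = PlumPriors(**{**asdict(config.priors),
                                       "phi_mean": phi_mean, "phi_shape": phi_shape,
                                       "supported_mode": mode})
            except ValueError as exc:
                log.info("%s: kriging failed (%s); using configured phi prior", cid, exc)
        elif mode != priors.supported_mode:
            priors = PlumPriors(**{**asdict(config.priors), "supported_mode": mode})

        accepted_anchor = peak if (peak is not None and peak.accepted) else None
        core_seed = int.from_bytes(
            hashlib.sha256(f"{config.seed}:{cid}".encode()).digest()[:4], "little"
        ) % (2**31)
        try:
            ens = pb_dating.plum_mcmc(core, priors, cs_anchor=accepted_anchor,
                                      n_burn=config.n_burn, n_store=config.n_store,
                                      seed=core_seed)
        except (core_io.CoreValidationError, RuntimeError) as exc:
            log.warning("%s: MCMC failed: %s", cid, exc)
            artifacts["errors"].append((cid, "mcmc"))
            continue
        artifacts["ensembles"][cid] = ens

        try:
            artifacts["car"].append(car_mod.car_from_ensemble(core, ens, horizon=config.horizon))
        except core_io.CoreValidationError as exc:
            log.warning("%s: CAR failed: %s", cid, exc)
            artifacts["errors"].append((cid, "car"))
            continue

        if config.make_plots:
            sup = float(np.mean(ens.supported_draws))
            from .plots import plot_core_panels

            plot_core_panels(core, ensemble=ens, supported_level=sup,
                             path=outdir / f"profile_{cid}.png")

    if artifacts["errors"] and len({c for c, _ in artifacts["errors"]}) == len(cores):
        raise RuntimeError("all cores failed; see log for per-core errors")

    _write_outputs(artifacts, outdir)
    return artifacts


def _write_outputs(artifacts: dict, outdir: Path) -> None:
    config: RunConfig = artifacts["config"]
    val = pd.concat([r.to_frame() for r in artifacts["validation"]], ignore_index=True) \
        if artifacts["validation"] else pd.DataFrame()
    val.to_csv(outdir / "validation_report.csv", index=False)

    stock_rows = {r.core_id: r for r in artifacts["stocks"]}
    trend_rows = {r.core_id: r for r in artifacts["trends"]}
    car_rows = {r.core_id: r for r in artifacts["car"]}
    all_ids = sorted(set(stock_rows) | set(trend_rows) | set(car_rows))
    deriv = pd.DataFrame(
        [
            {
                "core_id": cid,
                "stock_1m_kgC_m2": getattr(stock_rows.get(cid), "stock_1m", np.nan),
                "profile_depth_cm": getattr(stock_rows.get(cid), "profile_depth", np.nan),
                "extrapolated": getattr(stock_rows.get(cid), "extrapolated", None),
                "om_slope_pct_per_cm": getattr(trend_rows.get(cid), "slope", np.nan),
                "om_trend_p": getattr(trend_rows.get(cid), "p_value", np.nan),
                "om_trend_class": getattr(trend_rows.get(cid), "classification", None),
                "car_mean_gC_m2_yr": getattr(car_rows.get(cid), "car_mean", np.nan),
                "car_sd": getattr(car_rows.get(cid), "car_sd", np.nan),
                "car_ci_low": getattr(car_rows.get(cid), "ci_low", np.nan),
                "car_ci_high": getattr(car_rows.get(cid), "ci_high", np.nan),
                "accretion_mean_mm_yr": getattr(car_rows.get(cid), "accretion_mean_mm_yr", np.nan),
                "accretion_cv_percent": getattr(car_rows.get(cid), "accretion_cv_percent", np.nan),
                "n_draws": config.n_store if cid in car_rows else 0,
                "horizon_yr": config.horizon if cid in car_rows else np.nan,
            }
            for cid in all_ids
        ]
    )
    deriv.to_csv(outdir / "derivative_values.csv", index=False, float_format="%.6g")

    if artifacts["cs"]:
        pd.DataFrame(
            [
                {
                    "core_id": p.core_id,
                    "peak_depth_min": p.peak_depth_min,
                    "peak_depth_max": p.peak_depth_max,
                    "peak_activity": p.peak_activity,
                    "z_score": p.z_score,
                    "overlap_above": p.overlap_above,
                    "overlap_below": p.overlap_below,
                    "pass_background": p.pass_background,
                    "pass_above": p.pass_above,
                    "pass_below": p.pass_below,
                    "accepted": p.accepted,
                    "depth_mu": p.depth_mu,
                    "depth_sd": p.depth_sd,
                }
                for p in artifacts["cs"]
            ]
        ).to_csv(outdir / "cs_qc.csv", index=False, float_format="%.6g")

    if artifacts["screen"]:
        pd.DataFrame(
            [
                {
                    "core_id": s.core_id,
                    "flag_low_activity": s.flag_low_activity,
                    "flag_step_shape": s.flag_step_shape,
                    "manual_override": s.manual_override,
                    "usable": s.usable,
                }
                for s in artifacts["screen"]
            ]
        ).to_csv(outdir / "pb_screen.csv", index=False)

    for cid, ens in artifacts["ensembles"].items():
        ens.params_frame().to_csv(outdir / f"ensemble_params_{cid}.csv", index=False,
                                  float_format="%.6g")

    import tidalcarbon

    manifest = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "version": tidalcarbon.__version__,
        "n_cores": artifacts["n_cores"],
        "n_stocks": len(artifacts["stocks"]),
        "n_cs_accepted": sum(p.accepted for p in artifacts["cs"]),
        "n_dated": len(artifacts["car"]),
        "errors": artifacts["errors"],
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)


def report_summary(artifacts: dict) -> str:
    """Human-readable run summary: counts per measurement type, stock and CAR
    summaries, Cs acceptance counts."""
    lines = [f"cores read: {artifacts['n_cores']}"]
    if artifacts["stocks"]:
        s = stocks.summarize_stocks(artifacts["stocks"], group_by="dataset")
        lines.append(
            f"carbon stocks (1 m): n={int(s['n'].iloc[0])} mean={s['mean'].iloc[0]:.1f} "
            f"kgC m-2 (range {s['min'].iloc[0]:.1f}-{s['max'].iloc[0]:.1f})"
        )
    else:
        lines.append("carbon stocks (1 m): 0 eligible cores")
    if artifacts["trends"]:
        n = len(artifacts["trends"])
        dec = sum(t.classification == "decrease" for t in artifacts["trends"])
        inc = sum(t.classification == "increase" for t in artifacts["trends"])
        lines.append(f"OM depth trends: {dec}/{n} decrease, {inc}/{n} increase, "
                     f"{n - dec - inc}/{n} none")
    n_cs = len(artifacts["cs"])
    n_acc = sum(p.accepted for p in artifacts["cs"])
    lines.append(f"137Cs peaks: {n_acc}/{n_cs} accepted by all three QC criteria")
    n_usable = sum(s.usable for s in artifacts["screen"])
    lines.append(f"210Pb screening: {n_usable}/{len(artifacts['screen'])} profiles usable")
    if artifacts["car"]:
        summary = car_mod.summarize_dataset(
            artifacts["car"],
            reference_values={"ipcc_removal_factor": stocks.IPCC_CAR_GC_M2_YR},
        )
        lines.append(
            f"CAR: {summary['n_cores']} dated cores, mean {summary['dataset_mean']:.1f} "
            f"gC m-2 yr-1 (range {summary['dataset_min']:.1f}-{summary['dataset_max']:.1f}); "
            f"mean accretion {summary['mean_accretion_mm_yr']:.2f} mm yr-1, "
            f"mean accretion CV {summary['mean_accretion_cv_percent']:.1f}%"
        )
        lines.append(
            "cores whose 95% CrI overlaps the IPCC removal factor: "
            f"{summary['reference_overlap_counts']['ipcc_removal_factor']}/{summary['n_cores']}"
        )
    else:
        lines.append("CAR: 0 dated cores")
    return "\n".join(lines)
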