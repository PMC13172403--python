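"""Forward simulation of tidal-wetland soil cores with known ground truth.

A simulated core mirrors the structure of real depth-series data: organic
matter declining asymptotically with depth, dry bulk density anti-correlated
with organic matter through an ideal organic/mineral mixing model
(1/DBD = LOI/k1 + (1-LOI)/k2), unsupported 210Pb decaying over a supported
background according to constant-rate-of-supply physics with true supply
phi, and a 137Cs deposition pulse (onset 1954, peak 1963) mapped to depth
through the true age-depth relation.  Counting noise is multiplicative
normal with the sd recorded as the reported counting error, so every
downstream stage can be tested against the recorded truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core_io import SoilCore, write_depthseries
from .pb_dating import PB210_LAMBDA, expected_unsupported

__all__ = ["SimScenario", "simulate_accretion", "simulate_core", "make_dataset"]


@dataclass
class SimScenario:
    """Parameters of a simulated coring campaign (defaults: a typical
    California tidal marsh)."""

    seed: int = 0
    n_cores: int = 3
    collection_year: int = 2015
    depth: float = 100.0  # cm
    accretion_model: str = "constant"  # or "gamma_ar"
    acc_mean: float = 2.86  # yr cm-1 (slowness)
    acc_shape: float = 4.0
    acc_memory: float = 0.9
    phi_true: float = 150.0  # Bq m-2 yr-1
    supported_true: float = 15.0  # Bq kg-1
    om_surface: float = 0.195  # fraction
    om_depth_decay: float = 0.03  # per cm
    om_asymptote: float = 0.081  # fraction
    om_noise_sd: float = 0.01  # additive, truncated to keep LOI in (0,1)
    dbd_noise_cv: float = 0.03
    k1: float = 0.085  # organic self-packing density, g cm-3
    k2: float = 1.99  # mineral self-packing density, g cm-3
    counting_cv: float = 0.05
    cs_peak_year: int = 1963
    cs_onset_year: int = 1954
    cs_amplitude: float = 20.0  # Bq kg-1 at the 1963 peak
    cs_background: float = 1.0  # Bq kg-1 noise floor
    cs_tail_efold: float = 10.0  # yr, post-peak deposition decline
    sd_floor: float = 0.3  # Bq kg-1 minimum reported counting sd
    sample_every: float = 2.0  # cm between radionuclide samples
    sample_max_depth: float = 40.0  # cm, deepest radionuclide sample

    def __post_init__(self) -> None:
        if not (0 < self.om_asymptote < self.om_surface < 1):
            raise ValueError("require 0 < om_asymptote < om_surface < 1")
        for name in ("acc_mean", "phi_true", "supported_true", "counting_cv", "depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.accretion_model not in ("constant", "gamma_ar"):
            raise ValueError(f"unknown accretion model {self.accretion_model!r}")


def simulate_accretion(scenario: SimScenario, rng: np.random.Generator | None = None) -> np.ndarray:
    """True cumulative ages (yr) at 1 cm section boundaries, surface = 0.

    ``constant``: all sections at ``acc_mean`` yr/cm.  ``gamma_ar``: the same
    gamma-autoregressive process the Bayesian model uses as its prior
    (memory w, innovations Gamma(acc_shape, mean acc_mean)).
    """
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    n = int(np.ceil(scenario.depth))
    if scenario.accretion_model == "constant":
        alpha = np.full(n, scenario.acc_mean)
    else:
        w = scenario.acc_memory
        eps = rng.gamma(scenario.acc_shape, scenario.acc_mean / scenario.acc_shape, size=n)
        alpha = np.empty(n)
        alpha[0] = eps[0]
        for j in range(1, n):
            alpha[j] = w * alpha[j - 1] + (1.0 - w) * eps[j]
    return np.concatenate([[0.0], np.cumsum(alpha)])


def _mixing_dbd(loi: np.ndarray, k1: float, k2: float) -> np.ndarray:
    return 1.0 / (loi / k1 + (1.0 - loi) / k2)


def _cs_pulse(year: np.ndarray, onset: float, peak: float, efold: float) -> np.ndarray:
    """Relative 137Cs deposition by calendar year, normalized to 1 at the peak."""
    year = np.asarray(year, dtype=float)
    rise = np.clip((year - onset) / (peak - onset), 0.0, None)
    out = np.where(year <= peak, np.where(year < onset, 0.0, rise), np.exp(-(year - peak) / efold))
    return out


def simulate_core(
    scenario: SimScenario,
    truth_ages: np.ndarray,
    core_id: str = "SIM-01",
    rng: np.random.Generator | None = None,
) -> tuple[SoilCore, dict]:
    """Simulate one core given its true boundary ages; returns the core and a
    truth record (ages, phi, LOI/DBD truth, true 1 m stock and 100-yr CAR)."""
    if rng is None:
        rng = np.random.default_rng(scenario.seed)
    n = int(np.ceil(scenario.depth))
    if len(truth_ages) < n + 1:
        raise ValueError("truth ages shorter than the core depth")
    if np.any(np.diff(truth_ages) <= 0):
        raise ValueError("truth ages must be strictly increasing")
    dmin = np.arange(n, dtype=float)
    dmax = dmin + 1.0
    mids = dmin + 0.5

    loi_truth = scenario.om_asymptote + (scenario.om_surface - scenario.om_asymptote) * np.exp(
        -scenario.om_depth_decay * mids
    )
    loi = loi_truth + rng.normal(0.0, scenario.om_noise_sd, size=n)
    clipped = (loi <= 1e-3) | (loi >= 1 - 1e-3)
    loi = np.clip(loi, 1e-3, 1 - 1e-3)
    dbd_truth = _mixing_dbd(loi_truth, scenario.k1, scenario.k2)
    dbd = _mixing_dbd(loi, scenario.k1, scenario.k2) * np.exp(
        rng.normal(0.0, scenario.dbd_noise_cv, size=n)
    )

    t_top = truth_ages[:n]
    t_bot = truth_ages[1 : n + 1]
    mass = dbd_truth * 1.0 * 10.0  # kg m-2 per 1 cm slice
    pb_truth = expected_unsupported(scenario.phi_true, t_top, t_bot, mass) + scenario.supported_true

    year_mid = scenario.collection_year - 0.5 * (t_top + t_bot)
    cs_truth = scenario.cs_amplitude * _cs_pulse(
        year_mid, scenario.cs_onset_year, scenario.cs_peak_year, scenario.cs_tail_efold
    )

    sampled = np.zeros(n, dtype=bool)
    step = max(int(round(scenario.sample_every)), 1)
    sampled[0 : min(int(scenario.sample_max_depth), n) : step] = True

    def _measure(truth_vals):
        sd = np.maximum(scenario.counting_cv * np.abs(truth_vals), scenario.sd_floor)
        meas = truth_vals + rng.normal(0.0, sd)
        return np.clip(meas, 0.0, None), sd

    cs_meas, cs_sd = _measure(cs_truth + scenario.cs_background)
    pb_meas, pb_sd = _measure(pb_truth)
    ra_meas, ra_sd = _measure(np.full(n, scenario.supported_true))

    data = pd.DataFrame(
        {
            "depth_min": dmin,
            "depth_max": dmax,
            "dry_bulk_density": dbd,
            "loi": loi,
            "cs137": np.where(sampled, cs_meas, np.nan),
            "cs137_sd": np.where(sampled, cs_sd, np.nan),
            "pb210_total": np.where(sampled, pb_meas, np.nan),
            "pb210_total_sd": np.where(sampled, pb_sd, np.nan),
            "ra226": np.where(sampled, ra_meas, np.nan),
            "ra226_sd": np.where(sampled, ra_sd, np.nan),
        }
    )
    core = SoilCore(core_id=core_id, data=data, collection_year=scenario.collection_year)

    # truth derivatives: 1 m stock and the 100-yr CAR from noise-free fields
    loi_pct = loi_truth * 100.0
    oc_pct = 0.40 * loi_pct + 0.0025 * loi_pct**2
    rho_c = dbd_truth * oc_pct / 100.0  # gC cm-3
    stock_1m = float(rho_c[: min(n, 100)].mean() * 100.0 * 10.0)  # kgC m-2
    horizon = 100.0
    depth_100 = float(np.interp(horizon, truth_ages, np.arange(n + 1, dtype=float)))
    full = int(np.floor(depth_100))
    stock_100yr = float(rho_c[:full].sum() + (depth_100 - full) * (rho_c[full] if full < n else 0.0))
    truth = {
        "core_id": core_id,
        "phi": scenario.phi_true,
        "supported": scenario.supported_true,
        "ages": truth_ages[: n + 1],
        "alpha": np.diff(truth_ages[: n + 1]),
        "loi_truth": loi_truth,
        "dbd_truth": dbd_truth,
        "stock_1m": stock_1m,
        "depth_at_100yr": depth_100,
        "car_100yr": stock_100yr * 1e4 / horizon,  # gC m-2 yr-1
        "cs_peak_depth": float(np.interp(scenario.collection_year - scenario.cs_peak_year,
                                         truth_ages, np.arange(n + 1, dtype=float))),
        "n_clipped_loi": int(clipped.sum()),
    }
    return core, truth


def make_dataset(scenario: SimScenario, outdir, overwrite: bool = False) -> tuple[Path, Path, Path]:
    """Write a simulated campaign as depthseries/cores/truth CSVs.

    Files use the exact dialect :mod:`tidalcarbon.core_io` reads; the truth
    CSV holds per-core phi, true 1 m stock, true 100-yr CAR and the true
    1963 peak depth.  Byte-identical across runs with the same scenario.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = tuple(outdir / f for f in ("depthseries.csv", "cores.csv", "truth.csv"))
    for p in paths:
        if p.exists() and not overwrite:
            raise FileExistsError(f"{p} exists (pass overwrite=True)")

    master = np.random.default_rng(scenario.seed)
    cores, truths, meta_rows = [], [], []
    for i in range(scenario.n_cores):
        rng = np.random.default_rng([scenario.seed, i])
        core_id = f"SIM-{i + 1:02d}"
        ages = simulate_accretion(scenario, rng)
        core, truth = simulate_core(scenario, ages, core_id=core_id, rng=rng)
        cores.append(core)
        truths.append(truth)
        meta_rows.append(
            {
                "core_id": core_id,
                "site_id": f"SITE-{i // 3 + 1}",
                "latitude": round(34.0 + 7.0 * (i / max(scenario.n_cores - 1, 1)), 4),
                "longitude": round(-123.5 + 3.0 * (i / max(scenario.n_cores - 1, 1)), 4),
                "year": scenario.collection_year,
                "habitat": "mid",
                "vegetation": "Salicornia pacifica",
            }
        )
    del master

    write_depthseries(cores, paths[0])
    pd.DataFrame(meta_rows).to_csv(paths[1], index=False)
    truth_df = pd.DataFrame(
        [
            {
                "core_id": t["core_id"],
                "phi": t["phi"],
                "supported": t["supported"],
                "stock_1m_kgC_m2": t["stock_1m"],
                "car_100yr_gC_m2_yr": t["car_100yr"],
                "depth_at_100yr_cm": t["depth_at_100yr"],
                "cs_peak_depth_cm": t["cs_peak_depth"],
                "age_30cm_yr": float(np.interp(30.0, np.arange(len(t["ages"]), dtype=float), t["ages"])),
            }
            for t in truths
        ]
    )
    truth_df.to_csv(paths[2], index=False, float_format="%.8g")
    return paths
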