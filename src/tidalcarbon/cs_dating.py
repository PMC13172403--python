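"""Detection and quality control of the 1963 radiocesium fallout peak.

Atmospheric nuclear weapons testing peaked just before the 1963 test-ban
treaty, so the depth of maximum 137Cs activity in an undisturbed core marks
the 1963 CE horizon.  A candidate peak is accepted only if it passes three
automated statistical checks:

1. *background*: the peak activity is in the upper tail (default 97.5%
   quantile) of a normal fit to the core's activity distribution;
2/3. *adjacent separation*: the peak is greater than each of its nearest
   measured shallower and deeper neighbors, with the two normal counting
   distributions sharing less than 5% proportional overlapping area.

Positional/age uncertainty of the dated horizon is the moment-matched
uniform distribution over the peak increment (mean and sd of U[a, b]).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import integrate, stats

from .core_io import SoilCore

__all__ = [
    "CsPeakResult",
    "background_test",
    "normal_overlap",
    "adjacent_separation_test",
    "detect_peak",
    "moment_match",
    "CS_PEAK_YEAR",
]

CS_PEAK_YEAR = 1963


@dataclass(frozen=True)
class CsPeakResult:
    """Candidate 137Cs peak with its three QC flags and dating moments."""

    core_id: str
    peak_depth_min: float
    peak_depth_max: float
    peak_activity: float  # Bq kg-1
    peak_sd: float
    pass_background: bool
    pass_above: bool  # separation from the nearest shallower sample
    pass_below: bool  # separation from the nearest deeper sample
    date_year: int = CS_PEAK_YEAR
    depth_mu: float = float("nan")  # cm, moment-matched over the peak increment
    depth_sd: float = float("nan")
    age_mu: float = float("nan")  # yr before collection
    age_sd: float = float("nan")
    z_score: float = float("nan")
    overlap_above: float = float("nan")
    overlap_below: float = float("nan")

    @property
    def accepted(self) -> bool:
        return self.pass_background and self.pass_above and self.pass_below


def moment_match(a_min: float, a_max: float) -> tuple[float, float]:
    """Mean and sd of the uniform distribution on [a_min, a_max].

    mu = (a_max + a_min)/2;  sd = sqrt((a_max - a_min)^2 / 12).
    """
    if a_min > a_max:
        raise ValueError(f"a_min {a_min} > a_max {a_max}")
    mu = 0.5 * (a_max + a_min)
    sd = np.sqrt((a_max - a_min) ** 2 / 12.0)
    return float(mu), float(sd)


def background_test(activities, peak_activity: float, threshold: float = 0.975) -> bool:
    """Is the peak in the upper tail of the reference activity distribution?

    True iff ``Phi((peak - mean)/sd) >= threshold`` where mean/sd are of the
    reference ``activities`` (the peak itself included).  With zero spread
    the test degenerates to ``peak > mean``.
    """
    activities = np.asarray(activities, dtype=float)
    activities = activities[~np.isnan(activities)]
    if len(activities) < 3:
        raise ValueError("background test needs >=3 reference activities")
    mean = activities.mean()
    sd = activities.std(ddof=1)
    if sd == 0:
        warnings.warn("degenerate background distribution (zero sd); comparing peak to mean")
        return bool(peak_activity > mean)
    return bool(stats.norm.cdf((peak_activity - mean) / sd) >= threshold)


def normal_overlap(mu1: float, sd1: float, mu2: float, sd2: float) -> float:
    """Proportional overlapping area of two normal densities, in [0, 1].

    Computes ``integral of min(phi1, phi2)``; symmetric in its arguments.
    For equal sds this equals ``2*Phi(-|mu1-mu2|/(2*sd))``.
    """
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("normal_overlap requires positive standard deviations")
    if mu1 == mu2 and sd1 == sd2:
        return 1.0
    lo = min(mu1 - 9 * sd1, mu2 - 9 * sd2)
    hi = max(mu1 + 9 * sd1, mu2 + 9 * sd2)
    val, _ = integrate.quad(
        lambda x: np.minimum(stats.norm.pdf(x, mu1, sd1), stats.norm.pdf(x, mu2, sd2)),
        lo,
        hi,
        epsabs=1e-9,
        limit=200,
        points=[mu1, mu2],
    )
    return float(min(max(val, 0.0), 1.0))


def adjacent_separation_test(
    peak: tuple[float, float],
    neighbor: tuple[float, float] | None,
    max_overlap: float = 0.05,
) -> tuple[bool, float]:
    """Is the peak significantly greater than an adjacent sample?

    ``peak`` and ``neighbor`` are (activity, counting sd).  Passes iff the
    peak mean exceeds the neighbor mean and their counting distributions
    share less than ``max_overlap`` proportional area.  A missing neighbor
    (peak at the profile end) fails: a peak shape cannot be confirmed there.
    Returns (pass, overlap).
    """
    if neighbor is None:
        warnings.warn("peak at profile end: no adjacent sample to compare against")
        return False, float("nan")
    (pa, psd), (na, nsd) = peak, neighbor
    if psd <= 0 or nsd <= 0:
        raise ValueError("adjacent separation test requires positive sds")
    ov = normal_overlap(pa, psd, na, nsd)
    return bool(pa > na and ov < max_overlap), ov


def detect_peak(
    core: SoilCore,
    background_quantile: float = 0.975,
    max_overlap: float = 0.05,
    reference_activities=None,
) -> CsPeakResult | None:
    """Find and QC the 137Cs peak of a core.

    The candidate is the maximum-activity increment (ties break to the
    shallowest).  ``reference_activities`` overrides the background
    reference distribution (e.g. to pool all cores of a site); by default
    the core's own activities are used.  Returns None when fewer than three
    increments carry 137Cs measurements.
    """
    df = core.data
    act = df["cs137"].to_numpy(dtype=float)
    sd = df["cs137_sd"].to_numpy(dtype=float)
    measured = np.flatnonzero(~np.isnan(act))
    if len(measured) < 3:
        return None

    peak_pos = measured[int(np.argmax(act[measured]))]  # argmax takes the first (shallowest) tie
    peak_act = float(act[peak_pos])
    peak_sd = float(sd[peak_pos]) if not np.isnan(sd[peak_pos]) else 0.0

    ref = act[measured] if reference_activities is None else np.asarray(reference_activities, float)
    pass_bg = background_test(ref, peak_act, threshold=background_quantile)
    mean, ref_sd = ref[~np.isnan(ref)].mean(), np.nanstd(ref, ddof=1)
    z = (peak_act - mean) / ref_sd if ref_sd > 0 else float("inf")

    idx = int(np.flatnonzero(measured == peak_pos)[0])
    shallower = measured[idx - 1] if idx > 0 else None
    deeper = measured[idx + 1] if idx + 1 < len(measured) else None

    def _pair(i):
        if i is None or np.isnan(sd[i]) or sd[i] <= 0:
            return None
        return (float(act[i]), float(sd[i]))

    if peak_sd <= 0:
        pass_above, ov_above = False, float("nan")
        pass_below, ov_below = False, float("nan")
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            pass_above, ov_above = adjacent_separation_test((peak_act, peak_sd), _pair(shallower), max_overlap)
            pass_below, ov_below = adjacent_separation_test((peak_act, peak_sd), _pair(deeper), max_overlap)

    d0, d1 = float(df["depth_min"].iloc[peak_pos]), float(df["depth_max"].iloc[peak_pos])
    depth_mu, depth_sd = moment_match(d0, d1)
    # age before collection: fixed 1963 calendar year; uncertainty is the
    # uniform half-width of one calendar year, moment matched
    age_mu = float((core.collection_year or CS_PEAK_YEAR) - CS_PEAK_YEAR)
    _, age_sd = moment_match(-0.5, 0.5)
    return CsPeakResult(
        core_id=core.core_id,
        peak_depth_min=d0,
        peak_depth_max=d1,
        peak_activity=peak_act,
        peak_sd=peak_sd,
        pass_background=pass_bg,
        pass_above=pass_above,
        pass_below=pass_below,
        depth_mu=depth_mu,
        depth_sd=depth_sd,
        age_mu=age_mu,
        age_sd=age_sd,
        z_score=float(z),
        overlap_above=ov_above,
        overlap_below=ov_below,
    )
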