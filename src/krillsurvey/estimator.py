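"""Weighted Jolly-Hampton design-based survey estimator.

Transects are the sampling units. Each transect's effective length is its
coverage weight (0.5 on the survey boundary, else 1.0) times the sum of its
interval weights; interval weights downweight stretches where the vessel
deviated from the planned track. Sampling weights are effective length over
mean effective length, the survey mean density is the weight-weighted mean
of transect densities, and the variance is the ratio-estimator form with an
N/(N-1) finite-sample correction:

    w_j   = L_j / mean(L)
    rho^  = sum(w_j rho_j) / sum(w_j)
    Var   = N/(N-1) * sum(w_j^2 (rho_j - rho^)^2) / (sum w_j)^2
    CV    = sqrt(Var) / rho^

Biomass is mean density times survey area (1 g m^-2 = 1 t km^-2) with
normal-theory 95% bounds biomass * (1 -/+ 1.96 CV), floored at zero.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import GM2_PER_TONNE_KM2, SurveyEstimate, ValidationError

logger = logging.getLogger(__name__)

#: raw interval weights at or above this are treated as "on track" (weight 1)
DEVIATION_THRESHOLD = 0.9

#: normal-theory multiplier for 95% confidence bounds
Z_95 = 1.96


def interval_weight(delta_planned, delta_made_good) -> np.ndarray | float:
    """Track-deviation weight for an integration interval.

    ``delta_planned`` is the planned change in latitude over the interval
    (degrees), ``delta_made_good`` the change actually surveyed. The raw
    weight is (|dL| - |dL - dL^|) / |dL|; deviations under 10% are forgiven
    and the weight snaps to 1.
    """
    dp = np.asarray(delta_planned, dtype=float)
    dm = np.asarray(delta_made_good, dtype=float)
    if np.any(dp == 0):
        raise ValidationError("planned latitude change of zero: interval weight undefined")
    raw = (np.abs(dp) - np.abs(dp - dm)) / np.abs(dp)
    out = np.where(raw >= DEVIATION_THRESHOLD, 1.0, raw)
    return float(out) if out.ndim == 0 else out


def effective_length(intervals: pd.DataFrame, coverage_weight: float = 1.0) -> float:
    """Effective transect length: coverage weight x sum of interval weights.

    With every interval weight 1 (no deviation) this is just the interval
    count (one nautical mile each) times the coverage weight.
    """
    if len(intervals) == 0:
        raise ValidationError("effective length of an empty transect is undefined")
    if "interval_weight" in intervals.columns:
        total = float(intervals["interval_weight"].sum())
    else:
        total = float(len(intervals))
    return coverage_weight * total


def jolly_hampton(densities, lengths, transect_ids=None, coverage_weights=None) -> SurveyEstimate:
    """Weighted mean density, variance and CV over transects.

    Parameters
    ----------
    densities
        Per-transect mean areal density, g m^-2 (must be >= 0).
    lengths
        Per-transect *effective* lengths, nautical miles (> 0).
    """
    rho = np.asarray(densities, dtype=float)
    length = np.asarray(lengths, dtype=float)
    n = len(rho)
    if n < 2:
        raise ValidationError("variance needs >= 2 transects")
    if len(length) != n:
        raise ValidationError("densities and lengths differ in length")
    if np.any(length <= 0):
        raise ValidationError("effective lengths must be positive")
    if np.any(rho < 0):
        raise ValidationError("negative transect density")
    w = length / length.mean()
    mean = float(np.sum(w * rho) / np.sum(w))
    dev = (rho - mean) ** 2
    var = float(n / (n - 1) * np.sum(w**2 * dev) / np.sum(w) ** 2)
    cv = float(np.sqrt(var) / mean) if mean > 0 else np.inf
    if transect_ids is None:
        transect_ids = list(range(1, n + 1))
    if coverage_weights is None:
        coverage_weights = np.ones(n)
    return SurveyEstimate(
        transect_ids=list(transect_ids),
        effective_lengths=length,
        coverage_weights=np.asarray(coverage_weights, float),
        transect_densities=rho,
        transect_weights=w,
        weighted_densities=w * rho,
        deviations=dev,
        mean_density=mean,
        variance=var,
        cv=cv,
        n_transects=n,
    )


def biomass(estimate: SurveyEstimate, area_km2: float) -> SurveyEstimate:
    """Scale mean density to total biomass (tonnes) with normal 95% bounds."""
    if area_km2 <= 0:
        raise ValidationError("survey area must be positive")
    b = estimate.mean_density * GM2_PER_TONNE_KM2 * area_km2
    half = Z_95 * estimate.cv
    estimate.area_km2 = float(area_km2)
    estimate.biomass = float(b)
    estimate.bounds = (float(max(0.0, b * (1 - half))), float(b * (1 + half)))
    return estimate


def transect_density(intervals: pd.DataFrame) -> float:
    """Interval-weight-weighted mean density of one transect's intervals."""
    d = intervals["density"].to_numpy(float)
    if "interval_weight" in intervals.columns:
        w = intervals["interval_weight"].to_numpy(float)
    else:
        w = np.ones_like(d)
    return float(np.sum(w * d) / np.sum(w))


def estimate_survey(
    intervals: pd.DataFrame,
    area_km2: float | None = None,
    coverage_weights: dict | None = None,
    day_only: bool = False,
) -> SurveyEstimate:
    """End-to-end design-based estimate from labelled, density-bearing intervals.

    ``intervals`` must carry ``transect_id`` and ``density`` (plus optional
    ``interval_weight``, ``in_division`` and ``day`` columns). Out-of-division
    intervals are excluded; with ``day_only`` night intervals are too (the
    day-only recalculation when diel migration biases night densities low).
    Transects left with no intervals are dropped with a warning and N is
    decremented.
    """
    df = intervals
    if "in_division" in df.columns:
        df = df[df["in_division"]]
    if day_only:
        if "day" not in df.columns:
            raise ValidationError("day_only requested but intervals carry no 'day' column")
        df = df[df["day"]]
    ids, densities, lengths, covs = [], [], [], []
    for tid, group in df.groupby("transect_id", sort=True):
        if len(group) == 0:
            continue
        cov = 1.0 if coverage_weights is None else float(coverage_weights.get(tid, 1.0))
        ids.append(tid)
        densities.append(transect_density(group))
        lengths.append(effective_length(group, cov))
        covs.append(cov)
    dropped = set(intervals["transect_id"].unique()) - set(ids)
    if dropped:
        logger.warning("transects dropped (no usable intervals): %s", sorted(dropped))
    est = jolly_hampton(densities, lengths, transect_ids=ids, coverage_weights=covs)
    if area_km2 is not None:
        est = biomass(est, area_km2)
    return est
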