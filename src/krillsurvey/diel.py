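"""Day-night comparisons: density tests, swarm depths, encounter rates.

Krill migrate toward the surface at night; swarms rising above the
echosounder's ~15-20 m surface exclusion zone vanish from the record, so
night-time areal densities read low. These comparisons quantify that:
a two-sample KS test on interval densities, a Welch t-test with a CI on
the day-night mean difference, per-period swarm encounter rates, a
density-weighted LOESS through swarm depth, and day/night depth histograms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .model import ValidationError


@dataclass
class EncounterRate:
    """Swarms per nautical mile for one diel period, with across-transect CV."""

    rate: float
    cv: float
    n_swarms: int
    n_miles: float


@dataclass
class DielComparison:
    ks_d: float
    ks_p: float
    t_stat: float
    t_p: float
    mean_diff_ci: tuple[float, float]
    encounter_day: EncounterRate | None = None
    encounter_night: EncounterRate | None = None


def ks_two_sample(x, y) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov statistic and asymptotic p-value.

    D is the exact sup over pooled points of |ECDF_x - ECDF_y|; the p-value
    uses the asymptotic Kolmogorov distribution with effective sample size
    n_x n_y / (n_x + n_y), appropriate at the hundreds-to-thousands of
    intervals seen in survey data.
    """
    x = np.sort(np.asarray(x, dtype=float))
    y = np.sort(np.asarray(y, dtype=float))
    nx, ny = len(x), len(y)
    if nx == 0 or ny == 0:
        raise ValidationError("KS test needs two nonempty samples")
    pooled = np.concatenate([x, y])
    cdf_x = np.searchsorted(x, pooled, side="right") / nx
    cdf_y = np.searchsorted(y, pooled, side="right") / ny
    d = float(np.max(np.abs(cdf_x - cdf_y)))
    en = nx * ny / (nx + ny)
    p = float(special.kolmogorov(np.sqrt(en) * d))
    return d, min(1.0, p)


def welch_t(x, y, conf: float = 0.95) -> tuple[float, float, tuple[float, float]]:
    """Welch's unequal-variance t-test with a CI on mean(x) - mean(y).

    Returns (t, two-sided p, (lower, upper)). Satterthwaite degrees of
    freedom; raises if both samples are degenerate (zero variance).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValidationError("Welch t-test needs >= 2 observations per sample")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        if np.mean(x) == np.mean(y):
            raise ValidationError("degenerate zero-variance samples with equal means")
        raise ValidationError("zero-variance samples: t statistic undefined")
    res = stats.ttest_ind(x, y, equal_var=False)
    ci = res.confidence_interval(confidence_level=conf)
    return float(res.statistic), float(res.pvalue), (float(ci.low), float(ci.high))


def compare_daynight_density(intervals: pd.DataFrame) -> DielComparison:
    """KS and Welch comparisons of day vs night interval densities."""
    if "day" not in intervals.columns:
        raise ValidationError("intervals need a 'day' column (see solar.label_intervals)")
    day = intervals.loc[intervals["day"], "density"].to_numpy(float)
    night = intervals.loc[~intervals["day"], "density"].to_numpy(float)
    d, ks_p = ks_two_sample(day, night)
    t, t_p, ci = welch_t(day, night)
    return DielComparison(ks_d=d, ks_p=ks_p, t_stat=t, t_p=t_p, mean_diff_ci=ci)


def encounter_rate(intervals: pd.DataFrame) -> dict[str, EncounterRate]:
    """Day and night swarm encounter rates (swarms per nautical mile).

    The rate is total swarms over total distance per period; the CV is the
    sd/mean of per-transect rates, the transect being the design's sampling
    unit. Intervals must carry ``day`` and ``swarm_count`` columns; each
    interval is one nautical mile.
    """
    if "swarm_count" not in intervals.columns:
        raise ValidationError("intervals need a 'swarm_count' column")
    out = {}
    for label, sub in (("day", intervals[intervals["day"]]), ("night", intervals[~intervals["day"]])):
        if len(sub) == 0:
            raise ValidationError(f"no surveyed distance in period '{label}'")
        per_transect = sub.groupby("transect_id")["swarm_count"].agg(["sum", "size"])
        rates = per_transect["sum"] / per_transect["size"]
        cv = float(rates.std(ddof=1) / rates.mean()) if len(rates) > 1 and rates.mean() > 0 else 0.0
        out[label] = EncounterRate(
            rate=float(sub["swarm_count"].sum() / len(sub)),
            cv=cv,
            n_swarms=int(sub["swarm_count"].sum()),
            n_miles=float(len(sub)),
        )
    return out


def weighted_loess(x, y, weights=None, span: float = 0.4) -> np.ndarray:
    """Locally weighted linear regression (tricube kernel) with case weights.

    For each point, the ``ceil(span * n)`` nearest neighbours get tricube
    distance weights multiplied by the supplied case weights (here swarm
    volumetric density: denser swarms pull the depth curve harder), and a
    weighted straight line is fitted and evaluated at that point. Exact on
    globally linear data; invariant to rescaling all case weights.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n < 10:
        raise ValidationError("weighted LOESS needs >= 10 points")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    k = max(2, int(np.ceil(span * n)))
    order = np.argsort(x)
    xs, ys, ws = x[order], y[order], w[order]
    fitted_sorted = np.empty(n)
    for i in range(n):
        dist = np.abs(xs - xs[i])
        idx = np.argpartition(dist, k - 1)[:k]
        h = dist[idx].max()
        if h == 0:
            fitted_sorted[i] = np.average(ys[idx], weights=ws[idx])
            continue
        tric = (1 - (dist[idx] / h) ** 3) ** 3
        wi = tric * ws[idx]
        if wi.sum() == 0:
            wi = tric
        xi, yi = xs[idx], ys[idx]
        xm = np.average(xi, weights=wi)
        ym = np.average(yi, weights=wi)
        sxx = np.sum(wi * (xi - xm) ** 2)
        slope = np.sum(wi * (xi - xm) * (yi - ym)) / sxx if sxx > 0 else 0.0
        fitted_sorted[i] = ym + slope * (xs[i] - xm)
    fitted = np.empty(n)
    fitted[order] = fitted_sorted
    return fitted


def depth_distribution(swarms: pd.DataFrame, bin_width: float = 10.0) -> dict:
    """Day/night histograms of swarm depth with the modal bin per period.

    Returns ``{"day": {...}, "night": {...}}`` where each entry carries bin
    edges, counts and the (lower, upper) edges of the modal bin.
    """
    depths = swarms["depth"].to_numpy(float)
    lo = np.floor(depths.min() / bin_width) * bin_width
    hi = np.ceil(depths.max() / bin_width) * bin_width
    if hi <= lo:
        hi = lo + bin_width
    edges = np.arange(lo, hi + bin_width / 2, bin_width)
    out = {}
    for label, sub in (("day", swarms[swarms["day"]]), ("night", swarms[~swarms["day"]])):
        counts, _ = np.histogram(sub["depth"].to_numpy(float), bins=edges)
        mode_i = int(np.argmax(counts)) if counts.sum() else 0
        out[label] = {
            "edges": edges,
            "counts": counts,
            "modal_bin": (float(edges[mode_i]), float(edges[mode_i + 1])),
            "n": int(counts.sum()),
        }
    return out
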