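"""Length-to-wetmass power law with trawl-level bootstrap uncertainty.

The allometric model is ``WW = a * TL**b`` (wetmass in g, total length in
mm), fitted by nonlinear least squares on the untransformed scale — not by
log-linear regression, which would minimise a different criterion under
multiplicative noise. Parameter uncertainty is quantified by a
non-parametric bootstrap that resamples whole trawls (the natural cluster:
krill within a trawl share a swarm and are not independent).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .model import MIN_LENGTH_MM, ValidationError


@dataclass
class PowerLawFit:
    """Fitted allometry ``WW = a * TL**b``.

    ``a`` has units g mm^-b, ``b`` is dimensionless. ``cv_a``/``cv_b`` are
    bootstrap coefficients of variation (sd of replicates / point estimate),
    present only after :func:`bootstrap_fit` has run.
    """

    a: float
    b: float
    n_obs: int
    converged: bool = True
    cv_a: float | None = None
    cv_b: float | None = None
    bootstrap_reps: int | None = None
    seed: int | None = None

    def predict(self, lengths) -> np.ndarray:
        return predict_wetmass(self, lengths)


def _power(tl, a, b):
    return a * np.power(tl, b)


def _extract(records: pd.DataFrame, min_length_mm: float):
    sub = records.dropna(subset=["wetmass_g"])
    sub = sub[(sub["total_length_mm"] >= min_length_mm) & (sub["wetmass_g"] > 0)]
    return sub["total_length_mm"].to_numpy(float), sub["wetmass_g"].to_numpy(float), sub


def fit_power_law(
    records: pd.DataFrame, min_length_mm: float = MIN_LENGTH_MM
) -> PowerLawFit:
    """Fit ``WW = a * TL**b`` by untransformed nonlinear least squares.

    ``records`` needs ``total_length_mm`` and ``wetmass_g`` columns; rows
    with missing wetmass or length below ``min_length_mm`` are dropped.
    Starting values come from log-log OLS, which is within a few percent of
    the optimum and makes convergence essentially certain.

    Raises
    ------
    ValidationError
        Fewer than 3 usable records, or the optimiser fails to converge.
    """
    tl, ww, _ = _extract(records, min_length_mm)
    if len(tl) < 3:
        raise ValidationError(f"power-law fit needs >= 3 records, got {len(tl)}")
    # log-log OLS start values
    slope, intercept = np.polyfit(np.log(tl), np.log(ww), 1)
    p0 = (float(np.exp(intercept)), float(slope))
    try:
        popt, _ = curve_fit(_power, tl, ww, p0=p0, maxfev=10_000, xtol=1e-12, ftol=1e-12)
    except RuntimeError as exc:  # pragma: no cover - pathological data
        raise ValidationError(f"power-law fit did not converge: {exc}") from exc
    a, b = map(float, popt)
    if not (a > 0 and np.isfinite(a) and np.isfinite(b)):
        raise ValidationError(f"power-law fit produced invalid parameters a={a}, b={b}")
    return PowerLawFit(a=a, b=b, n_obs=len(tl))


def bootstrap_fit(
    records: pd.DataFrame,
    n_reps: int = 999,
    seed: int | None = None,
    min_length_mm: float = MIN_LENGTH_MM,
) -> PowerLawFit:
    """Trawl-level (cluster) bootstrap of the power-law parameters.

    Trawls are resampled with replacement ``n_reps`` times; the model is
    refitted per replicate and the CV of each parameter is sd(replicates)
    divided by the full-data point estimate. Reproducible given ``seed``.
    """
    fit = fit_power_law(records, min_length_mm)
    _, _, sub = _extract(records, min_length_mm)
    trawl_ids = sub["trawl_id"].unique()
    if len(trawl_ids) < 2:
        raise ValidationError("cluster bootstrap needs >= 2 distinct trawls")
    groups = {t: g for t, g in sub.groupby("trawl_id")}
    rng = np.random.default_rng(seed)
    reps_a = np.empty(n_reps)
    reps_b = np.empty(n_reps)
    kept = 0
    for r in range(n_reps):
        chosen = rng.choice(trawl_ids, size=len(trawl_ids), replace=True)
        boot = pd.concat([groups[t] for t in chosen], ignore_index=True)
        try:
            f = fit_power_law(boot, min_length_mm)
        except ValidationError:
            continue  # degenerate resample; skipped, not fabricated
        reps_a[kept] = f.a
        reps_b[kept] = f.b
        kept += 1
    if kept < 2:
        raise ValidationError("bootstrap produced fewer than 2 successful refits")
    fit.cv_a = float(np.std(reps_a[:kept], ddof=1) / fit.a)
    fit.cv_b = float(np.std(reps_b[:kept], ddof=1) / fit.b)
    fit.bootstrap_reps = kept
    fit.seed = seed
    return fit


def predict_wetmass(fit: PowerLawFit, lengths) -> np.ndarray:
    """Evaluate ``a * TL**b`` elementwise; lengths must be positive (mm)."""
    tl = np.asarray(lengths, dtype=float)
    if np.any(tl <= 0):
        raise ValidationError("lengths must be positive")
    return fit.a * np.power(tl, fit.b)
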