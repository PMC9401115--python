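"""NASC-to-areal-density conversion via length frequency and target strength.

An interval's areal biomass density (g m^-2) is its NASC (m^2 n.mile^-2)
times a survey-wide conversion factor

    C = [sum_i f_i * WW(l_i)] / [sum_i f_i * sigma_sp(l_i)] / 1852**2

where f_i is the count of krill in the 1-mm length class l_i, WW the fitted
length-wetmass allometry, sigma_sp = 4*pi*10**(TS/10) the spherical
scattering cross-section (m^2) from the 120 kHz TS-at-length table, and
1/1852**2 converts per-square-nautical-mile to per-square-metre. A single
survey-wide C is used: the combined all-trawl length frequency drives it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .length_weight import PowerLawFit, predict_wetmass
from .model import METRES_PER_NMILE, MIN_LENGTH_MM, TSTable, ValidationError


@dataclass
class LengthFrequency:
    """Krill length classes (mm) with counts, at the TS table's resolution."""

    lengths: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if np.any(self.counts < 0) or self.counts.sum() <= 0:
            raise ValidationError("length frequency needs non-negative counts with a positive sum")
        if np.any(self.lengths < MIN_LENGTH_MM):
            raise ValidationError(f"length classes below {MIN_LENGTH_MM} mm are excluded")


@dataclass
class ConversionFactor:
    """NASC -> density factor ``c`` with its two physical components."""

    c: float  # g m^-2 per (m^2 n.mile^-2)
    mean_wetmass_g: float
    mean_sigma_sp_m2: float


def length_frequency(records: pd.DataFrame, bin_mm: float = 1.0) -> LengthFrequency:
    """Bin trawl length records into ``bin_mm``-wide classes (class centres).

    Every record with a valid length participates, weighed or not — the
    length-frequency distribution pools all measured krill.
    """
    tl = records["total_length_mm"].to_numpy(float)
    tl = tl[tl >= MIN_LENGTH_MM]
    if len(tl) == 0:
        raise ValidationError("no length records at or above the minimum length")
    centres = np.round(tl / bin_mm) * bin_mm
    values, counts = np.unique(centres, return_counts=True)
    return LengthFrequency(lengths=values, counts=counts.astype(float))


def sigma_sp(ts) -> np.ndarray | float:
    """Spherical scattering cross-section (m^2) from TS (dB re 1 m^2)."""
    return 4.0 * np.pi * np.power(10.0, np.asarray(ts, dtype=float) / 10.0)


def ts_at_length(table: TSTable, length) -> np.ndarray | float:
    """TS at ``length`` mm: exact at grid points, linear in dB between them.

    Raises for lengths outside the table's range (extrapolating TS would be
    silent physics invention). A one-row table only supports its own length.
    """
    length = np.asarray(length, dtype=float)
    lo, hi = table.lengths[0], table.lengths[-1]
    if np.any(length < lo) or np.any(length > hi):
        bad = length[(length < lo) | (length > hi)]
        raise ValidationError(
            f"length {np.atleast_1d(bad)[0]:g} mm outside TS table range [{lo:g}, {hi:g}]"
        )
    out = np.interp(length, table.lengths, table.ts)
    return float(out) if out.ndim == 0 else out


def conversion_factor(
    lf: LengthFrequency, fit: PowerLawFit, table: TSTable
) -> ConversionFactor:
    """Compute the survey-wide NASC-to-density conversion factor.

    The numerator is the frequency-weighted mean wetmass, the denominator
    the frequency-weighted mean sigma_sp; their ratio, scaled by 1/1852^2,
    converts NASC to g m^-2. Invariant to rescaling all counts.
    """
    ww = predict_wetmass(fit, lf.lengths)
    sp = sigma_sp(ts_at_length(table, lf.lengths))
    total = lf.counts.sum()
    mean_ww = float(np.dot(lf.counts, ww) / total)
    mean_sp = float(np.dot(lf.counts, sp) / total)
    c = mean_ww / mean_sp / METRES_PER_NMILE**2
    return ConversionFactor(c=c, mean_wetmass_g=mean_ww, mean_sigma_sp_m2=mean_sp)


def apply_conversion(intervals: pd.DataFrame, c: ConversionFactor | float) -> pd.DataFrame:
    """Add/overwrite a ``density`` column: NASC times the conversion factor."""
    factor = c.c if isinstance(c, ConversionFactor) else float(c)
    out = intervals.copy()
    out["density"] = out["nasc"].to_numpy(float) * factor
    return out
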