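"""Domain types and unit conventions shared by every pipeline stage.

Conventions
-----------
* Coordinates are decimal degrees, south-negative latitude, east-positive
  longitude; all timestamps are ISO-8601 UTC.
* Echo-integration intervals are one nautical mile along-track by 250 m deep
  and arrive pre-binned; the pipeline never touches raw pings.
* NASC (nautical area scattering coefficient, ``s_A``) is in m^2 n.mile^-2;
  areal biomass density in g m^-2 (numerically equal to t km^-2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: metres per nautical mile; fixes the n.mile^-2 -> m^-2 unit conversion
METRES_PER_NMILE = 1852.0

#: g m^-2 and t km^-2 are the same number: 1 g/m^2 = 1e-6 t / 1e-6 km^2
GM2_PER_TONNE_KM2 = 1.0

INTERVAL_COLUMNS = ["transect_id", "interval_index", "timestamp", "lat", "lon", "nasc"]
TRAWL_COLUMNS = ["trawl_id", "trawl_type", "timestamp", "lat", "lon", "total_length_mm"]

#: krill below this total length are excluded from all analyses
MIN_LENGTH_MM = 10.0


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class ValidationError(ValueError):
    """An input value violates a domain invariant."""


@dataclass
class TSTable:
    """Length-specific target strength lookup at 120 kHz.

    ``lengths`` (mm) must be strictly increasing; ``ts`` values are in
    dB re 1 m^2 and are negative for krill-sized scatterers.
    """

    lengths: np.ndarray
    ts: np.ndarray

    def __post_init__(self) -> None:
        self.lengths = np.asarray(self.lengths, dtype=float)
        self.ts = np.asarray(self.ts, dtype=float)
        if self.lengths.ndim != 1 or self.lengths.shape != self.ts.shape:
            raise ValidationError("TS table lengths and ts must be 1-D and equal length")
        if len(self.lengths) == 0:
            raise ValidationError("TS table is empty")
        if len(self.lengths) > 1 and not np.all(np.diff(self.lengths) > 0):
            raise ValidationError("TS table lengths must be strictly increasing")
        if not np.all(np.isfinite(self.ts)):
            raise ValidationError("TS table contains non-finite TS values")

    def __len__(self) -> int:
        return len(self.lengths)


@dataclass
class Transect:
    """Ordered intervals of one transect plus its design metadata.

    ``coverage_weight`` is 0.5 for transects lying on the survey-area
    boundary (half the effective coverage falls outside) and 1.0 otherwise.
    """

    transect_id: str
    coverage_weight: float = 1.0
    intervals: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def effective_length(self) -> float:
        """Coverage-weighted sum of interval weights, in nautical miles."""
        if len(self.intervals) == 0:
            raise ValidationError(f"transect {self.transect_id} has no intervals")
        w = self.intervals.get("interval_weight")
        total = float(len(self.intervals)) if w is None else float(np.sum(w))
        return self.coverage_weight * total


@dataclass
class SurveyEstimate:
    """Weighted Jolly-Hampton survey result.

    Densities are g m^-2; ``biomass`` and ``bounds`` are in tonnes.
    ``transect_weights`` are the per-transect sampling weights
    (effective length / mean effective length); ``deviations`` are the
    squared departures of transect density from the survey mean.
    """

    transect_ids: list
    effective_lengths: np.ndarray
    coverage_weights: np.ndarray
    transect_densities: np.ndarray
    transect_weights: np.ndarray
    weighted_densities: np.ndarray
    deviations: np.ndarray
    mean_density: float
    variance: float
    cv: float
    n_transects: int
    area_km2: float | None = None
    biomass: float | None = None
    bounds: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        d = {
            "transect_ids": list(self.transect_ids),
            "effective_lengths": list(map(float, self.effective_lengths)),
            "coverage_weights": list(map(float, self.coverage_weights)),
            "transect_densities": list(map(float, self.transect_densities)),
            "transect_weights": list(map(float, self.transect_weights)),
            "weighted_densities": list(map(float, self.weighted_densities)),
            "deviations": list(map(float, self.deviations)),
            "mean_density": float(self.mean_density),
            "variance": float(self.variance),
            "cv": float(self.cv),
            "n_transects": int(self.n_transects),
        }
        if self.area_km2 is not None:
            d["area_km2"] = float(self.area_km2)
            d["biomass_tonnes"] = float(self.biomass)
            d["bounds_tonnes"] = [float(self.bounds[0]), float(self.bounds[1])]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SurveyEstimate":
        bounds = d.get("bounds_tonnes")
        return cls(
            transect_ids=list(d["transect_ids"]),
            effective_lengths=np.asarray(d["effective_lengths"], float),
            coverage_weights=np.asarray(d["coverage_weights"], float),
            transect_densities=np.asarray(d["transect_densities"], float),
            transect_weights=np.asarray(d["transect_weights"], float),
            weighted_densities=np.asarray(d["weighted_densities"], float),
            deviations=np.asarray(d["deviations"], float),
            mean_density=float(d["mean_density"]),
            variance=float(d["variance"]),
            cv=float(d["cv"]),
            n_transects=int(d["n_transects"]),
            area_km2=d.get("area_km2"),
            biomass=d.get("biomass_tonnes"),
            bounds=None if bounds is None else (bounds[0], bounds[1]),
        )
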