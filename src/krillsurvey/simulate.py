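"""Synthetic acoustic-trawl surveys with fully known truth.

Generates everything the pipeline consumes — echo-integration intervals,
swarm records, trawl length/wetmass records and a TS-at-length table —
from a :class:`SurveyScenario` whose defaults emulate a six-transect
meridional krill survey: zero-inflated, right-skewed (lognormal) interval
densities around 6 g m^-2, a day>night mean difference of a few g m^-2,
night swarms shoaling to a 15-30 m depth mode, day/night swarm encounter
rates near 3.7 and 1 per nautical mile, trawl lengths spanning ~10-60 mm,
and a power-law length-wetmass relation with multiplicative lognormal
noise.

Interval day/night labels are not drawn: the generator lays out real
timestamps and positions (vessel at 7.3 knots, one-nautical-mile
intervals) and runs the package's own civil-twilight classifier, so the
day fraction emerges from geometry exactly as it does at sea.

NASC is back-computed from true density through the scenario's own
conversion factor (true allometry + generated length frequency + TS
table), so a noiseless scenario round-trips through the pipeline exactly.
``truth.json`` records every generating parameter plus derived truths
(true C, day/night means, the emergent day fraction).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import conversion, solar
from .bands import DEFAULT_BAND_HEIGHT, BandPartition
from .length_weight import PowerLawFit
from .model import MIN_LENGTH_MM, TSTable, ValidationError

_NMILE_DEG = 1.0 / 60.0  # one nautical mile northward, in degrees latitude
_KNOTS = 7.3  # survey speed: minutes per nautical mile = 60/7.3


@dataclass
class LengthMixture:
    """Gaussian mixture of krill total lengths (mm), truncated at 10 mm."""

    means: tuple = (36.0, 49.0)
    sds: tuple = (5.0, 3.0)
    weights: tuple = (0.55, 0.45)


@dataclass
class SurveyScenario:
    """Generating parameters for one synthetic survey.

    Defaults reflect a late-summer East Antarctic krill survey: six
    north-south transects (the two boundary ones coverage-weighted 0.5),
    ~200 one-nautical-mile intervals each, an unconditional mean areal
    density near 6 g m^-2 split into a presence layer and a lognormal
    conditional layer, and a day-minus-night mean difference of 4.8 g m^-2
    (krill above the transducer at night go unseen).
    """

    n_transects: int = 6
    n_intervals: int = 200
    lat_start: float = -67.1  # transects run northward from here
    lon_west: float = 57.0
    lon_east: float = 77.0
    start_date: str = "2021-02-13T12:00:00Z"
    intertransect_gap_h: float = 14.0
    true_mean_density: float = 6.2  # g m^-2, unconditional, survey-wide
    day_night_diff: float = 4.8  # g m^-2, day mean minus night mean
    presence_prob: float = 0.5  # chance an interval contains krill
    sdlog: float = 1.0  # lognormal shape of conditional densities
    band_density_scale: dict = field(default_factory=dict)  # band label -> scale
    band_presence: dict = field(default_factory=dict)  # band label -> presence
    # reference small-box survey (latitudinal height = one band)
    box_centre_lat: float = -66.28
    box_centre_lon: float = 63.35
    box_height: float = DEFAULT_BAND_HEIGHT
    box_n_intervals: int = 120
    n_bands: int = 4
    # swarms
    swarm_rate_day: float = 3.7  # swarms per nautical mile
    swarm_rate_night: float = 1.0
    day_depth_mean: float = 120.0
    day_depth_sd: float = 60.0
    night_depth_mode: float = 25.0
    night_depth_sd: float = 8.0
    # trawls
    n_trawls: int = 34
    n_lengths: int = 3247
    n_weighed: int = 502
    length_mixture: LengthMixture = field(default_factory=LengthMixture)
    trawl_shift_sd: float = 1.5  # mm, between-trawl shift of mixture means
    lw_a: float = 1.71e-6
    lw_b: float = 3.41
    lw_noise_sdlog: float = 0.2
    # TS table stand-in: TS(l) = ts_a0 + ts_slope * log10(l)
    ts_a0: float = -127.45
    ts_slope: float = 34.85
    seed: int = 0

    @property
    def coverage_weights(self) -> dict:
        """Boundary transects (first and last) carry half coverage."""
        ids = [f"T{i + 1}" for i in range(self.n_transects)]
        w = {tid: 1.0 for tid in ids}
        w[ids[0]] = 0.5
        w[ids[-1]] = 0.5
        return w

    @property
    def box_south(self) -> float:
        return self.box_centre_lat - self.box_height / 2

    @property
    def box_north(self) -> float:
        return self.box_centre_lat + self.box_height / 2


def generate_ts_table(a0: float = -127.45, slope: float = 34.85,
                      lmin: float = 10.0, lmax: float = 65.0) -> TSTable:
    """Synthetic TS-at-length table: TS = a0 + slope*log10(length).

    A smooth stand-in with realistic magnitude (about -71.6 dB at 40 mm),
    monotone in length for positive slope, on a 1-mm grid.
    """
    lengths = np.arange(lmin, lmax + 0.5, 1.0)
    return TSTable(lengths=lengths, ts=a0 + slope * np.log10(lengths))


def generate_lengths(mixture: LengthMixture, n: int, rng) -> np.ndarray:
    """Draw ``n`` total lengths (mm) from the mixture, truncated below 10 mm."""
    weights = np.asarray(mixture.weights, float)
    if not np.isclose(weights.sum(), 1.0):
        raise ValidationError("mixture weights must sum to 1")
    out = np.empty(n)
    filled = 0
    while filled < n:
        comp = rng.choice(len(weights), size=n - filled, p=weights)
        draw = rng.normal(np.asarray(mixture.means)[comp], np.asarray(mixture.sds)[comp])
        draw = draw[draw >= MIN_LENGTH_MM]
        out[filled:filled + len(draw)] = draw
        filled += len(draw)
    return out


def _truncnorm(rng, mean, sd, lo, hi, n):
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sd, size=max(n - filled, 8))
        draw = draw[(draw > lo) & (draw < hi)]
        take = min(len(draw), n - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def _layout_intervals(sc: SurveyScenario) -> pd.DataFrame:
    """Transect geometry and timing: positions, UTC timestamps, day flags."""
    start = pd.Timestamp(sc.start_date)
    mins_per_interval = 60.0 / _KNOTS
    lons = np.linspace(sc.lon_west, sc.lon_east, sc.n_transects)
    frames = []
    t0 = start
    for j in range(sc.n_transects):
        idx = np.arange(sc.n_intervals)
        lat = sc.lat_start + idx * _NMILE_DEG
        if j % 2 == 1:  # alternate direction like a real lawnmower survey
            lat = lat[::-1]
        times = t0 + pd.to_timedelta(idx * mins_per_interval, unit="m")
        frames.append(pd.DataFrame({
            "transect_id": f"T{j + 1}",
            "interval_index": idx,
            "timestamp": times,
            "lat": lat,
            "lon": lons[j],
        }))
        t0 = times[-1] + pd.Timedelta(hours=sc.intertransect_gap_h)
    df = pd.concat(frames, ignore_index=True)
    df["day"] = solar.classify_daynight(df["lat"].to_numpy(), df["lon"].to_numpy(), df["timestamp"])
    return df


def _band_label(sc: SurveyScenario, lat: np.ndarray) -> np.ndarray:
    part = BandPartition(sc.box_south, sc.box_north, n_bands=sc.n_bands)
    idx = np.searchsorted(part.edges, lat, side="right") - 1
    labels = np.array(part.labels, dtype=object)
    out = np.where((idx >= 0) & (idx < sc.n_bands), labels[np.clip(idx, 0, sc.n_bands - 1)], None)
    return out


def _draw_densities(sc: SurveyScenario, df: pd.DataFrame, day_frac: float, rng) -> np.ndarray:
    """Zero-inflated lognormal densities with diel and latitudinal structure."""
    mu_day = sc.true_mean_density + (1 - day_frac) * sc.day_night_diff
    mu_night = sc.true_mean_density - day_frac * sc.day_night_diff
    if mu_night <= 0:
        raise ValidationError("infeasible scenario: night mean density would be non-positive")
    band = _band_label(sc, df["lat"].to_numpy())
    presence = np.array([
        sc.band_presence.get(b, sc.presence_prob) if b is not None else sc.presence_prob
        for b in band
    ])
    scale = np.array([
        sc.band_density_scale.get(b, 1.0) if b is not None else 1.0 for b in band
    ])
    mu = np.where(df["day"].to_numpy(bool), mu_day, mu_night) * scale
    cond_mean = mu / presence
    meanlog = np.log(cond_mean) - sc.sdlog**2 / 2
    present = rng.random(len(df)) < presence
    dens = np.where(present, rng.lognormal(meanlog, sc.sdlog), 0.0)
    return dens


def _generate_trawls(sc: SurveyScenario, rng) -> pd.DataFrame:
    n_per = rng.multinomial(sc.n_lengths, np.full(sc.n_trawls, 1 / sc.n_trawls))
    n_per = np.maximum(n_per, 2)
    rows = []
    start = pd.Timestamp(sc.start_date)
    for t in range(sc.n_trawls):
        shift = rng.normal(0, sc.trawl_shift_sd)
        mix = LengthMixture(
            means=tuple(m + shift for m in sc.length_mixture.means),
            sds=sc.length_mixture.sds,
            weights=sc.length_mixture.weights,
        )
        tl = generate_lengths(mix, int(n_per[t]), rng)
        rows.append(pd.DataFrame({
            "trawl_id": f"TR{t + 1:02d}",
            "trawl_type": "R" if t % 3 else "T",
            "timestamp": start + pd.Timedelta(hours=16 * t),
            "lat": sc.lat_start + rng.uniform(0, sc.n_intervals * _NMILE_DEG),
            "lon": rng.uniform(sc.lon_west, sc.lon_east),
            "total_length_mm": tl,
        }))
    trawls = pd.concat(rows, ignore_index=True)
    ww = sc.lw_a * trawls["total_length_mm"].to_numpy() ** sc.lw_b
    if sc.lw_noise_sdlog > 0:
        ww = ww * rng.lognormal(0.0, sc.lw_noise_sdlog, size=len(ww))
    weighed = rng.choice(len(trawls), size=min(sc.n_weighed, len(trawls)), replace=False)
    col = np.full(len(trawls), np.nan)
    col[weighed] = ww[weighed]
    trawls["wetmass_g"] = col
    return trawls


def _generate_swarms(sc: SurveyScenario, intervals: pd.DataFrame, rng):
    day = intervals["day"].to_numpy(bool)
    rate = np.where(day, sc.swarm_rate_day, sc.swarm_rate_night)
    counts = rng.poisson(rate)
    rows = []
    for (i, row), c in zip(intervals.iterrows(), counts):
        if c == 0:
            continue
        if row["day"]:
            depth = _truncnorm(rng, sc.day_depth_mean, sc.day_depth_sd, 15.1, 249.9, c)
        else:
            depth = _truncnorm(rng, sc.night_depth_mode, sc.night_depth_sd, 15.1, 249.9, c)
        rows.append(pd.DataFrame({
            "transect_id": row["transect_id"],
            "timestamp": row["timestamp"],
            "lat": row["lat"],
            "lon": row["lon"],
            "depth": depth,
            "volumetric_density": rng.lognormal(np.log(20.0), 0.8, size=c),
            "day": row["day"],
        }))
    swarms = (pd.concat(rows, ignore_index=True) if rows else
              pd.DataFrame(columns=["transect_id", "timestamp", "lat", "lon",
                                    "depth", "volumetric_density", "day"]))
    return swarms, counts


def generate_survey(scenario: SurveyScenario | None = None, out_dir=None) -> dict:
    """Generate a complete synthetic survey; optionally write its CSVs.

    Returns a dict with keys ``intervals``, ``box_intervals``, ``swarms``,
    ``trawls`` (DataFrames), ``ts_table`` (:class:`TSTable`) and ``truth``
    (every generating parameter plus derived truths). With ``out_dir`` the
    tables are written as ``intervals.csv``, ``box_intervals.csv``,
    ``swarms.csv``, ``trawls.csv``, ``ts.csv`` and ``truth.json``.
    """
    sc = scenario or SurveyScenario()
    lat_top = sc.lat_start + sc.n_intervals * _NMILE_DEG
    if not (sc.lat_start <= sc.box_south and sc.box_north <= lat_top):
        raise ValidationError("infeasible scenario: reference box outside the survey's latitude span")
    rng = np.random.default_rng(sc.seed)

    intervals = _layout_intervals(sc)
    day_frac = float(intervals["day"].mean())
    density = _draw_densities(sc, intervals, day_frac, rng)

    # trawls, allometry truth and the scenario's own conversion factor
    trawls = _generate_trawls(sc, rng)
    ts_table = generate_ts_table(sc.ts_a0, sc.ts_slope)
    lf = conversion.length_frequency(trawls)
    true_fit = PowerLawFit(a=sc.lw_a, b=sc.lw_b, n_obs=len(trawls))
    c_true = conversion.conversion_factor(lf, true_fit, ts_table)

    intervals["density_true"] = density
    intervals["nasc"] = density / c_true.c
    intervals["delta_lat_planned"] = _NMILE_DEG * np.where(
        intervals["transect_id"].map(lambda t: int(t[1:]) % 2 == 0), -1.0, 1.0
    )
    intervals["delta_lat_made_good"] = intervals["delta_lat_planned"]

    swarms, counts = _generate_swarms(sc, intervals, rng)
    intervals["swarm_count"] = counts

    # reference small-box survey: generated like its own band of the main survey
    part = BandPartition(sc.box_south, sc.box_north, n_bands=sc.n_bands)
    box = pd.DataFrame({
        "transect_id": "BOX",
        "interval_index": np.arange(sc.box_n_intervals),
        # the box survey runs over ~3 days; spacing its intervals evenly
        # in time gives it the same diel composition as the main survey
        "timestamp": pd.Timestamp(sc.start_date) + pd.Timedelta(days=10)
        + pd.to_timedelta(np.linspace(0, 72.0, sc.box_n_intervals), unit="h"),
        "lat": rng.uniform(sc.box_south, sc.box_north, sc.box_n_intervals),
        "lon": sc.box_centre_lon + rng.uniform(-0.3, 0.3, sc.box_n_intervals),
    })
    box["day"] = solar.classify_daynight(box["lat"].to_numpy(), box["lon"].to_numpy(), box["timestamp"])
    box["density_true"] = _draw_densities(sc, box, day_frac, rng)
    box["nasc"] = box["density_true"] / c_true.c

    truth = {k: v for k, v in dataclasses.asdict(sc).items()}
    truth.update(
        conversion_factor=c_true.c,
        day_fraction=day_frac,
        mean_density_day=sc.true_mean_density + (1 - day_frac) * sc.day_night_diff,
        mean_density_night=sc.true_mean_density - day_frac * sc.day_night_diff,
        coverage_weights=sc.coverage_weights,
        box_band=part.box_band,
    )

    result = {
        "intervals": intervals,
        "box_intervals": box,
        "swarms": swarms,
        "trawls": trawls,
        "ts_table": ts_table,
        "truth": truth,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        intervals.drop(columns=["density_true"]).to_csv(out / "intervals.csv", index=False, float_format="%.17g")
        box.drop(columns=["density_true"]).to_csv(out / "box_intervals.csv", index=False, float_format="%.17g")
        swarms.to_csv(out / "swarms.csv", index=False, float_format="%.17g")
        trawls.to_csv(out / "trawls.csv", index=False, float_format="%.17g")
        pd.DataFrame({"length_mm": ts_table.lengths, "ts_120_db": ts_table.ts}).to_csv(
            out / "ts.csv", index=False, float_format="%.17g"
        )
        (out / "truth.json").write_text(json.dumps(truth, indent=1, default=str))
    return result
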