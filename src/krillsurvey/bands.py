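"""Latitudinal-band representativeness tests for a small-box survey.

The large survey's intervals are split into contiguous equal-height
latitudinal bands, one of which coincides exactly with the small reference
box's latitudinal extent (the box band; remaining bands tile northward).
Per band we report the presence fraction (percent of intervals containing
krill) and the conditional densities rho[rho > 0]; representativeness is
assessed by a Kruskal-Wallis test across bands plus per-band KS and Welch
tests of conditional densities against the box.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .diel import ks_two_sample, welch_t
from .model import ValidationError

#: default band height in degrees latitude (the reference box's extent)
DEFAULT_BAND_HEIGHT = 0.63


@dataclass
class BandPartition:
    """Contiguous equal-height latitude bands anchored on a reference box.

    ``edges`` run south to north; band i spans ``[edges[i], edges[i+1])``
    (half-open, so an interval on an interior edge belongs to the band whose
    southern edge it sits on). Labels run A (northernmost) to the box band
    at the southern end, matching the convention of lettering away from the
    box.
    """

    box_south: float
    box_north: float
    n_bands: int = 4
    labels: list[str] = field(init=False)
    edges: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        height = self.box_north - self.box_south
        if height <= 0:
            raise ValidationError("box_north must exceed box_south")
        if self.n_bands < 1:
            raise ValidationError("need at least one band")
        self.edges = self.box_south + height * np.arange(self.n_bands + 1)
        self.labels = list(string.ascii_uppercase[: self.n_bands][::-1])

    @property
    def band_height(self) -> float:
        return self.box_north - self.box_south

    @property
    def box_band(self) -> str:
        """Label of the band that coincides with the reference box."""
        return self.labels[0]


def assign_bands(intervals: pd.DataFrame, partition: BandPartition) -> pd.DataFrame:
    """Label each interval with its latitude band; flag out-of-range ones.

    Adds a ``band`` column (NA outside the partition). Conservation holds:
    band counts plus excluded count equals the input count.
    """
    out = intervals.copy()
    lat = out["lat"].to_numpy(float)
    idx = np.searchsorted(partition.edges, lat, side="right") - 1
    in_range = (idx >= 0) & (idx < partition.n_bands)
    labels = np.array(partition.labels + [""], dtype=object)
    band = np.where(in_range, labels[np.clip(idx, 0, partition.n_bands - 1)], None)
    out["band"] = band
    out.attrs["n_excluded"] = int((~in_range).sum())
    return out


def presence_fraction(band_intervals: pd.DataFrame) -> float:
    """Percent of a band's intervals with krill present (density > 0)."""
    if len(band_intervals) == 0:
        raise ValidationError("presence fraction of an empty band is undefined")
    d = band_intervals["density"].to_numpy(float)
    return float(100.0 * np.mean(d > 0))


def conditional_densities(band_intervals: pd.DataFrame) -> np.ndarray:
    """The nonzero densities rho[rho > 0] of a band."""
    d = band_intervals["density"].to_numpy(float)
    return d[d > 0]


def band_summaries(labelled: pd.DataFrame) -> pd.DataFrame:
    """Per-band interval count, presence fraction and conditional-mean density."""
    rows = []
    for band, sub in labelled.dropna(subset=["band"]).groupby("band", sort=True):
        cond = conditional_densities(sub)
        rows.append(
            {
                "band": band,
                "n_intervals": len(sub),
                "presence_pct": presence_fraction(sub),
                "mean_conditional_density": float(cond.mean()) if len(cond) else np.nan,
            }
        )
    return pd.DataFrame(rows)


def kruskal_wallis(groups) -> tuple[float, float]:
    """Kruskal-Wallis H (midranks, tie-corrected) and chi-square p-value.

    All-identical data across groups is a valid no-signal outcome
    (H = 0, p = 1), not an error.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if sum(len(g) > 0 for g in groups) < 2:
        raise ValidationError("Kruskal-Wallis needs >= 2 nonempty groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def _holm(pvals: np.ndarray) -> np.ndarray:
    order = np.argsort(pvals)
    adj = np.empty_like(pvals)
    running = 0.0
    m = len(pvals)
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * pvals[i])
        adj[i] = min(1.0, running)
    return adj


def compare_box_to_bands(labelled: pd.DataFrame, box_intervals: pd.DataFrame) -> pd.DataFrame:
    """Per-band KS and Welch tests of conditional densities against the box.

    Returns one row per band with the KS D and p, Welch t and p, and
    Holm-adjusted columns alongside the raw p-values. Bands with fewer than
    two conditional densities are reported as untestable (NaN statistics),
    never silently dropped.
    """
    box = conditional_densities(box_intervals)
    if len(box) < 2:
        raise ValidationError("reference box needs >= 2 conditional densities")
    rows = []
    for band, sub in labelled.dropna(subset=["band"]).groupby("band", sort=True):
        cond = conditional_densities(sub)
        if len(cond) < 2:
            rows.append({"band": band, "n": len(cond), "ks_d": np.nan, "ks_p": np.nan,
                         "t_stat": np.nan, "t_p": np.nan, "testable": False})
            continue
        d, ks_p = ks_two_sample(cond, box)
        t, t_p, _ = welch_t(cond, box)
        rows.append({"band": band, "n": len(cond), "ks_d": d, "ks_p": ks_p,
                     "t_stat": t, "t_p": t_p, "testable": True})
    out = pd.DataFrame(rows)
    for col in ("ks_p", "t_p"):
        adj = np.full(len(out), np.nan)
        mask = out["testable"].to_numpy(bool)
        if mask.any():
            adj[mask] = _holm(out.loc[mask, col].to_numpy(float))
        out[col + "_holm"] = adj
    return out
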