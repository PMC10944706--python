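"""Camera-trap relative abundance and Jacobs' prey-preference index.

Prey availability is estimated from camera-trap records: a detection burst
of the same species at the same station collapses to one independent
record unless successive (retained) photographs are more than 30 minutes
apart, and RAI = independent records / trap-days is computed per survey
sector and then averaged (unweighted) over the sectors of an area.
Preference contrasts the proportion r of a prey species in the diet with
its proportional availability p through Jacobs' index

    D = (r - p) / (r + p - 2 r p),

which runs from -1 (maximum avoidance) to +1 (maximum preference), with
D = 0 when use matches availability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from scatcomp.errors import ValidationError


@dataclass
class PreferenceResult:
    predator: str
    stratum: str
    species: str
    r: float
    p_avail: float
    D: float  # NaN when the species has no availability estimate
    availability_source: str


def independent_records(
    records: pd.DataFrame, window_min: float = 30.0, chained: bool = True
) -> pd.DataFrame:
    """Collapse photo bursts to independent detections per station/species.

    Sorted by time within each (station, species), a record is retained iff
    it is the first, or it falls strictly more than ``window_min`` minutes
    after the previously *retained* record (``chained=True``, the usual
    camera-trap convention) or after the previous raw photograph
    (``chained=False``).  Different species at the same station never
    suppress each other.  Multi-animal frames count once.
    """
    if len(records) == 0:
        return records.copy()
    window = pd.Timedelta(minutes=window_min)
    keep_mask = np.zeros(len(records), dtype=bool)
    pos = {idx: i for i, idx in enumerate(records.index)}
    for _, grp in records.groupby(["station_id", "species"], sort=False):
        grp = grp.sort_values("timestamp", kind="mergesort")
        last_kept = None
        prev_time = None
        for idx, t in zip(grp.index, grp["timestamp"]):
            ref = last_kept if chained else prev_time
            if ref is None or t - ref > window:
                keep_mask[pos[idx]] = True
                last_kept = t
            prev_time = t
    return records[keep_mask].copy()


def _station_meta(records: pd.DataFrame, effort: pd.DataFrame) -> pd.DataFrame:
    """Station -> (sector, area), from effort columns if present else records."""
    if {"sector", "area"} <= set(effort.columns):
        return effort[["station_id", "sector", "area"]].drop_duplicates("station_id")
    meta = records[["station_id", "sector", "area"]].drop_duplicates("station_id")
    unknown = set(effort["station_id"]) - set(meta["station_id"])
    if unknown:
        raise ValidationError(
            "effort stations without sector/area metadata and no camera records: "
            f"{sorted(unknown)}"
        )
    return meta


def rai(
    records: pd.DataFrame,
    effort: pd.DataFrame,
    level: str = "area",
    window_min: float = 30.0,
    prefiltered: bool = False,
) -> pd.DataFrame:
    """Relative abundance index per species at sector or area level.

    Sector RAI = independent records of the species at the sector's
    stations / the sector's total trap-days.  Area RAI = unweighted mean
    of the area's sector RAIs.  Species detected nowhere in a sector get
    RAI 0 there (and thus enter area means as 0).

    Returns a long DataFrame with columns ``species``, ``sector``/``area``
    and ``rai``.
    """
    if level not in ("sector", "area"):
        raise ValueError(f"unknown level {level!r}")
    no_effort = set(records["station_id"]) - set(effort["station_id"])
    if no_effort:
        raise ValidationError(
            f"camera stations without an effort record: {sorted(no_effort)}"
        )
    indep = records if prefiltered else independent_records(records, window_min)
    meta = _station_meta(records, effort)
    eff = effort.merge(meta, on="station_id", how="left", suffixes=("", "_meta"))
    sector_days = eff.groupby("sector")["trap_days"].sum()
    species = sorted(indep["species"].unique())
    counts = (
        indep.groupby(["sector", "species"]).size().rename("n_records").reset_index()
    )
    grid = pd.MultiIndex.from_product(
        [sector_days.index, species], names=["sector", "species"]
    ).to_frame(index=False)
    sector_rai = grid.merge(counts, on=["sector", "species"], how="left").fillna(
        {"n_records": 0}
    )
    sector_rai["rai"] = sector_rai["n_records"] / sector_rai["sector"].map(sector_days)
    if level == "sector":
        return sector_rai[["species", "sector", "rai"]]
    sec_area = eff[["sector", "area"]].drop_duplicates("sector").set_index("sector")["area"]
    sector_rai["area"] = sector_rai["sector"].map(sec_area)
    area_rai = (
        sector_rai.groupby(["species", "area"])["rai"].mean().rename("rai").reset_index()
    )
    return area_rai[["species", "area", "rai"]]


def jacobs_index(r: float, p_avail: float) -> float:
    """Jacobs' selectivity D = (r - p) / (r + p - 2 r p) in [-1, 1].

    r is the proportion of the prey in the diet, p its proportional
    availability.  Undefined at r = p = 0; returns 0 at r = p = 1 by
    continuity (the index -> 0 along r = p).
    """
    if not (0 <= r <= 1 and 0 <= p_avail <= 1):
        raise ValidationError("r and p must be proportions in [0, 1]")
    if r == 0 and p_avail == 0:
        raise ValidationError("Jacobs' index undefined at r = p = 0")
    denom = r + p_avail - 2 * r * p_avail
    if denom == 0:  # only at r = p = 1
        return 0.0
    return (r - p_avail) / denom


def preference_table(
    diet_fo: dict[tuple[str, str], dict[str, float]],
    availability: pd.DataFrame,
    source: str = "rai",
    stratum_col: str = "area",
    value_col: str | None = None,
) -> pd.DataFrame:
    """Jacobs' preference for every predator x stratum x prey species.

    Parameters
    ----------
    diet_fo : dict
        ``{(predator, stratum): {species: diet proportion}}`` maps, e.g.
        frequency-of-occurrence output per analysis cell.
    availability : pandas.DataFrame
        Long table with ``species``, a stratum column (default ``area``)
        and an abundance column (``rai`` or ``density_per_km2``; chosen
        automatically from ``source`` unless ``value_col`` is given).
    source : {"rai", "density"}
        Recorded on every output row.

    Diet and availability are restricted to their shared species within
    each stratum and both renormalised over that subset, so r and p are
    comparable proportions.  Diet species absent from the availability
    table are reported with ``D`` = NaN and a warning rather than dropped.
    """
    if value_col is None:
        value_col = {"rai": "rai", "density": "density_per_km2"}.get(source)
        if value_col is None:
            raise ValueError(f"unknown availability source {source!r}")
    rows: list[PreferenceResult] = []
    for (predator, stratum), fo in diet_fo.items():
        avail = availability[availability[stratum_col] == stratum]
        if len(avail) == 0:
            raise ValidationError(f"no availability data for stratum {stratum!r}")
        avail_map = dict(zip(avail["species"], avail[value_col]))
        shared = sorted(set(fo) & set(avail_map))
        uncovered = sorted(set(fo) - set(avail_map))
        if uncovered:
            warnings.warn(
                f"{predator}/{stratum}: no availability for {uncovered}; "
                "reported with D undefined",
                stacklevel=2,
            )
        r_tot = sum(fo[sp] for sp in shared)
        p_tot = sum(avail_map[sp] for sp in shared)
        if r_tot == 0 or p_tot == 0:
            raise ValidationError(
                f"{predator}/{stratum}: diet and availability share no used species"
            )
        for sp in shared:
            r = fo[sp] / r_tot
            p = avail_map[sp] / p_tot
            D = jacobs_index(r, p) if (r > 0 or p > 0) else math.nan
            rows.append(PreferenceResult(predator, stratum, sp, r, p, D, source))
        for sp in uncovered:
            rows.append(
                PreferenceResult(predator, stratum, sp, fo[sp], math.nan, math.nan, source)
            )
    return pd.DataFrame([vars(x) for x in rows])
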