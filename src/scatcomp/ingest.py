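"""Reading and cleaning of scat, prey-trait, camera and effort tables.

The cleaning rules implemented here are the standard guards of scat-based
diet studies:

- **Pseudo-replication filters.** Several scats deposited by the same
  individual (or the same social unit) within a short window are not
  independent diet samples.  For solitary/territorial predators (lion,
  spotted hyaena) only one sample per 24 h per location is kept, where two
  locations count as "the same" when they lie within 1 km of each other.
  For African wild dogs, which travel as a pack, one sample per 24 h per
  pack is kept regardless of location.  No rule is defined for cheetah and
  leopard scats, which pass through unchanged.
- **Season assignment.**  Two alternative seasonal partitions of the year:
  a weather scheme (wet-early dry: November-June; late dry: July-October)
  and a wild-dog behavioural scheme (nomadic: September-April; breeding,
  i.e. denning: May-August).
- **Prey size classes.**  Mean adult female mass cut into XS/S/M/L/XL.
- **Minimum-sample rule.**  Analysis cells (predator x stratum) with fewer
  than 21 scats are excluded from statistical comparisons.
"""

from __future__ import annotations

import datetime as _dt
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from scatcomp.errors import SchemaError, ValidationError

#: The five-predator guild under study.
PREDATORS = frozenset({"wild_dog", "cheetah", "leopard", "lion", "hyaena"})

#: Study areas (park sectors with contrasting waterhole density).
AREAS = frozenset({"NE", "NW", "SW"})

#: Prey size classes, half-open mass intervals in kg: [low, high).
SIZE_CLASS_BOUNDS = {
    "XS": (0.0, 5.0),
    "S": (5.0, 25.0),
    "M": (25.0, 100.0),
    "L": (100.0, 350.0),
    "XL": (350.0, float("inf")),
}

WATER_DEPENDENCY_LEVELS = frozenset({"high", "medium", "low"})
FEEDING_GUILDS = frozenset(
    {
        "mixed_feeder",
        "browser",
        "grassland_grazer",
        "woodland_grazer",
        "omnivore",
        "carnivore",
        "other",
    }
)

_SCAT_COLUMNS = ["scat_id", "predator", "date", "x_m", "y_m", "area", "pack_id", "prey_species"]
_TRAIT_COLUMNS = ["species", "mean_female_mass_kg", "water_dependency", "feeding_guild"]
_CAMERA_COLUMNS = ["station_id", "sector", "area", "species", "timestamp", "n_individuals"]
_EFFORT_COLUMNS = ["station_id", "trap_days"]


def _require_columns(df: pd.DataFrame, required: Iterable[str], table: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{table}: missing required column(s): {', '.join(missing)}")


def read_scat_table(path) -> pd.DataFrame:
    """Read a long-format scat table (one row per prey item found in a scat).

    Parameters
    ----------
    path : str or file-like
        CSV with columns ``scat_id, predator, date, x_m, y_m, area,
        pack_id, prey_species``.  Scat-level fields are repeated on every
        prey-item row of the same scat.  ``pack_id`` must be present for
        wild dog scats and empty otherwise.

    Returns
    -------
    pandas.DataFrame
        The validated long table with ``date`` parsed to datetime and a
        derived ``year`` column.  An optional ``denning`` boolean column is
        passed through when present (used to exclude non-denning packs from
        breeding-season analyses).

    Raises
    ------
    SchemaError
        If a required column is absent.
    ValidationError
        On unknown predator or area labels, unparseable dates, or pack_id
        inconsistent with the predator.
    """
    df = pd.read_csv(path, dtype={"scat_id": str, "pack_id": str})
    _require_columns(df, _SCAT_COLUMNS, "scats")
    if len(df) == 0:
        out = df.copy()
        out["date"] = pd.to_datetime(out["date"])
        out["year"] = pd.Series([], dtype=int)
        return out

    bad_pred = sorted(set(df["predator"]) - PREDATORS)
    if bad_pred:
        rows = df.index[df["predator"].isin(bad_pred)].tolist()
        raise ValidationError(
            f"scats: unknown predator label(s) {bad_pred} in rows {rows}"
        )
    bad_area = sorted(set(df["area"]) - AREAS)
    if bad_area:
        rows = df.index[df["area"].isin(bad_area)].tolist()
        raise ValidationError(f"scats: unknown area label(s) {bad_area} in rows {rows}")

    try:
        df["date"] = pd.to_datetime(df["date"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"scats: unparseable date: {exc}") from exc

    pack_missing = df["pack_id"].isna() | (df["pack_id"].astype(str).str.strip() == "")
    wd = df["predator"] == "wild_dog"
    if (wd & pack_missing).any():
        rows = df.index[wd & pack_missing].tolist()
        raise ValidationError(f"scats: wild_dog rows missing pack_id: {rows}")
    if (~wd & ~pack_missing).any():
        rows = df.index[~wd & ~pack_missing].tolist()
        raise ValidationError(f"scats: non-wild_dog rows carry a pack_id: {rows}")

    # one scat = one set of scat-level fields; check they do not contradict
    scat_level = df[["scat_id", "predator", "date", "x_m", "y_m", "area", "pack_id"]]
    nuniq = scat_level.groupby("scat_id", dropna=False).nunique(dropna=False)
    inconsistent = nuniq.index[(nuniq > 1).any(axis=1)].tolist()
    if inconsistent:
        raise ValidationError(
            f"scats: scat-level fields differ between rows of scat_id(s) {inconsistent}"
        )

    df["year"] = df["date"].dt.year
    if "denning" in df.columns:
        df["denning"] = df["denning"].astype(bool)
    return df


def read_trait_table(path) -> pd.DataFrame:
    """Read the prey-trait table and derive the size class from mass.

    Expects columns ``species, mean_female_mass_kg, water_dependency,
    feeding_guild``.  Adds a ``size_class`` column via
    :func:`assign_size_class`.
    """
    df = pd.read_csv(path)
    _require_columns(df, _TRAIT_COLUMNS, "prey_traits")
    if (df["mean_female_mass_kg"] <= 0).any():
        bad = df.loc[df["mean_female_mass_kg"] <= 0, "species"].tolist()
        raise ValidationError(f"prey_traits: non-positive mass for {bad}")
    bad_wd = sorted(set(df["water_dependency"]) - WATER_DEPENDENCY_LEVELS)
    if bad_wd:
        raise ValidationError(f"prey_traits: unknown water_dependency level(s) {bad_wd}")
    bad_fg = sorted(set(df["feeding_guild"]) - FEEDING_GUILDS)
    if bad_fg:
        raise ValidationError(f"prey_traits: unknown feeding_guild label(s) {bad_fg}")
    if df["species"].duplicated().any():
        dup = df.loc[df["species"].duplicated(), "species"].tolist()
        raise ValidationError(f"prey_traits: duplicated species {dup}")
    df = df.copy()
    df["size_class"] = [assign_size_class(m) for m in df["mean_female_mass_kg"]]
    return df


def read_camera_table(path) -> pd.DataFrame:
    """Read camera-trap photo records (station, sector, area, species, timestamp)."""
    df = pd.read_csv(path, dtype={"station_id": str})
    _require_columns(df, _CAMERA_COLUMNS, "cameras")
    try:
        df["timestamp"] = pd.to_datetime(df["timestamp"], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"cameras: unparseable timestamp: {exc}") from exc
    if len(df) and (df["n_individuals"] < 1).any():
        raise ValidationError("cameras: n_individuals must be >= 1")
    return df


def read_effort_table(path) -> pd.DataFrame:
    """Read per-station trap-day effort. Optional sector/area columns pass through."""
    df = pd.read_csv(path, dtype={"station_id": str})
    _require_columns(df, _EFFORT_COLUMNS, "effort")
    if len(df) and (df["trap_days"] <= 0).any():
        raise ValidationError("effort: trap_days must be > 0")
    return df


def scat_level(items: pd.DataFrame) -> pd.DataFrame:
    """Collapse a long prey-item table to one row per scat."""
    cols = [c for c in items.columns if c != "prey_species"]
    return items[cols].drop_duplicates(subset="scat_id").reset_index(drop=True)


def _conflict_matrix_times(dates: pd.Series) -> np.ndarray:
    """|t_i - t_j| strictly below 24 h, as a boolean matrix."""
    t = dates.to_numpy(dtype="datetime64[s]").astype("int64")
    dt = np.abs(t[:, None] - t[None, :])
    return dt < 24 * 3600


def filter_pseudoreplicates(scats: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop scats that likely replicate an already-sampled defecation cluster.

    Rules, applied per predator with earliest-first greedy retention
    (a scat is kept iff it conflicts with no already-retained scat):

    - lion, hyaena: conflict = same predator, < 24 h apart AND <= 1 km
      (Euclidean on projected coordinates) from a retained scat;
    - wild_dog: conflict = same pack, < 24 h apart, any distance;
    - cheetah, leopard: never dropped.

    Date-only records (midnight timestamps) therefore conflict exactly when
    they fall on the same calendar day.

    Parameters
    ----------
    scats : pandas.DataFrame
        Scat-level table (one row per scat; pass items through
        :func:`scat_level` first if needed).

    Returns
    -------
    (retained, log) : tuple of DataFrame
        ``retained`` preserves scat-level columns; ``log`` lists dropped
        scat_ids with the rule applied and the retained scat that
        triggered the drop.
    """
    if scats["scat_id"].duplicated().any():
        raise ValidationError("filter_pseudoreplicates expects one row per scat")
    wd = scats["predator"] == "wild_dog"
    pack_missing = scats["pack_id"].isna() | (scats["pack_id"].astype(str) == "")
    if (wd & pack_missing).any():
        rows = scats.loc[wd & pack_missing, "scat_id"].tolist()
        raise ValidationError(f"wild_dog scats missing pack_id: {rows}")

    keep_ids: list = []
    log_rows: list[dict] = []
    for predator, grp in scats.groupby("predator", sort=False):
        grp = grp.sort_values(["date", "scat_id"], kind="mergesort")
        if predator in ("cheetah", "leopard"):
            keep_ids.extend(grp["scat_id"])
            continue
        close_time = _conflict_matrix_times(grp["date"])
        if predator == "wild_dog":
            pk = grp["pack_id"].to_numpy()
            conflict = close_time & (pk[:, None] == pk[None, :])
            rule = "24h_same_pack"
        else:
            xy = grp[["x_m", "y_m"]].to_numpy(dtype=float)
            d2 = ((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2)
            conflict = close_time & (d2 <= 1000.0**2)
            rule = "24h_within_1km"
        retained_idx: list[int] = []
        ids = grp["scat_id"].to_numpy()
        for i in range(len(grp)):
            hit = next((j for j in retained_idx if conflict[i, j]), None)
            if hit is None:
                retained_idx.append(i)
                keep_ids.append(ids[i])
            else:
                log_rows.append(
                    {
                        "scat_id": ids[i],
                        "predator": predator,
                        "rule": rule,
                        "conflicts_with": ids[hit],
                    }
                )
    retained = scats[scats["scat_id"].isin(keep_ids)].reset_index(drop=True)
    log = pd.DataFrame(log_rows, columns=["scat_id", "predator", "rule", "conflicts_with"])
    return retained, log


_WEATHER = {m: "wet_early_dry" for m in (11, 12, 1, 2, 3, 4, 5, 6)}
_WEATHER.update({m: "late_dry" for m in (7, 8, 9, 10)})
_BEHAVIOURAL = {m: "nomadic" for m in (9, 10, 11, 12, 1, 2, 3, 4)}
_BEHAVIOURAL.update({m: "breeding" for m in (5, 6, 7, 8)})


def assign_season(date, scheme: str) -> str:
    """Map a date to its season label under the given scheme.

    ``weather``: wet_early_dry (Nov-Jun) vs late_dry (Jul-Oct).
    ``behavioural``: nomadic (Sep-Apr) vs breeding (May-Aug).
    """
    if isinstance(date, str):
        date = pd.Timestamp(date)
    month = date.month
    if scheme == "weather":
        return _WEATHER[month]
    if scheme == "behavioural":
        return _BEHAVIOURAL[month]
    raise ValueError(f"unknown season scheme {scheme!r}")


def assign_size_class(mass_kg: float) -> str:
    """Prey size class from mean adult female mass (kg).

    Half-open intervals: XS [0,5), S [5,25), M [25,100), L [100,350),
    XL [350, inf) — so every positive mass gets exactly one class.
    """
    if not mass_kg > 0:
        raise ValidationError(f"mass must be positive, got {mass_kg}")
    for label, (lo, hi) in SIZE_CLASS_BOUNDS.items():
        if lo <= mass_kg < hi:
            return label
    raise AssertionError("unreachable: size classes partition (0, inf)")


def enforce_min_samples(
    groups: Mapping, threshold: int = 21
) -> tuple[dict, pd.DataFrame]:
    """Flag analysis cells with fewer than ``threshold`` scats for exclusion.

    Returns ``(flags, log)`` where ``flags[cell]`` is True iff the cell's
    scat count is at or above the threshold, and ``log`` records each
    excluded cell with its count and the rule applied.
    """
    flags: dict = {}
    rows: list[dict] = []
    for cell, count in groups.items():
        if count < 0:
            raise ValidationError(f"negative scat count for cell {cell!r}")
        ok = count >= threshold
        flags[cell] = bool(ok)
        if not ok:
            rows.append(
                {"cell": str(cell), "n_scats": int(count),
                 "reason": f"fewer than {threshold} scats"}
            )
    return flags, pd.DataFrame(rows, columns=["cell", "n_scats", "reason"])
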