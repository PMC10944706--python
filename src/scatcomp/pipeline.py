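"""End-to-end orchestration: ingest -> composition -> overlap/breadth ->
PERMANOVA -> preference -> accumulation, from a single run configuration.

Analysis cells are predator x stratum combinations, where strata are
"All", the three areas, and the two season schemes.  Seasonal cells use
only scats from the northern areas (NE, NW), since wild dog sampling in
the south does not cover both seasons; breeding-season cells drop
non-denning packs when the scat table carries a ``denning`` flag.  Cells
below the minimum-sample threshold are excluded from every statistical
comparison and logged with the rule that removed them.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from scatcomp import ingest, composition
from scatcomp.accumulation import species_accumulation
from scatcomp.dissimilarity import scat_distance_matrix, permanova
from scatcomp.errors import ScatcompError
from scatcomp.ingest import scat_level
from scatcomp.overlap import utilization_matrix, overlap_null_test, levins_breadth
from scatcomp.preference import rai, preference_table

logger = logging.getLogger("scatcomp")

NORTHERN_AREAS = ("NE", "NW")


@dataclass
class RunConfig:
    scats: str
    traits: str
    cameras: str | None = None
    effort: str | None = None
    densities: str | None = None
    out_dir: str = "scatcomp_out"
    min_scats: int = 21
    n_perm_permanova: int = 1000
    n_iter_overlap: int = 10000
    n_perm_accumulation: int = 100
    seed: int = 0
    window_min: float = 30.0
    season_schemes: tuple = ("weather", "behavioural")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _strata_frames(items: pd.DataFrame, schemes) -> dict[str, pd.DataFrame]:
    """Split the item table into the analysis strata."""
    out: dict[str, pd.DataFrame] = {"All": items}
    for area in sorted(items["area"].unique()):
        out[area] = items[items["area"] == area]
    north = items[items["area"].isin(NORTHERN_AREAS)]
    for scheme in schemes:
        labels = north["date"].map(lambda d: ingest.assign_season(d, scheme))
        for season in sorted(labels.unique()):
            sub = north[labels == season]
            if scheme == "behavioural" and season == "breeding" and "denning" in sub.columns:
                drop = (sub["predator"] == "wild_dog") & (~sub["denning"])
                sub = sub[~drop]
            out[season] = sub
    return out


def run_all(config: RunConfig, stage_errors: str = "raise") -> dict:
    """Run the full analysis and write all output tables.

    Returns a dict of DataFrames (``composition``, ``overlap``,
    ``breadth``, ``permanova``, ``preference``, ``accumulation``,
    ``filter_log``, ``exclusion_log``).  Deterministic for fixed seeds.
    Any stage failure is re-raised annotated with the stage and cell;
    ``stage_errors="log"`` records it and continues instead.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def note(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    items = ingest.read_scat_table(config.scats)
    traits = ingest.read_trait_table(config.traits)
    scats = scat_level(items)
    retained, filter_log = ingest.filter_pseudoreplicates(scats)
    note(
        f"pseudo-replication filter: {len(scats) - len(retained)} of "
        f"{len(scats)} scats dropped"
    )
    items = items[items["scat_id"].isin(retained["scat_id"])]

    strata = _strata_frames(items, config.season_schemes)

    # cell inclusion by the minimum-sample rule
    cell_counts = {
        (pred, name): int(sub.loc[sub["predator"] == pred, "scat_id"].nunique())
        for name, sub in strata.items()
        for pred in sorted(sub["predator"].unique())
    }
    flags, exclusion_log = ingest.enforce_min_samples(cell_counts, config.min_scats)
    for _, row in exclusion_log.iterrows():
        note(f"excluded cell {row['cell']}: {row['reason']} (n={row['n_scats']})")
    included = [cell for cell, ok in flags.items() if ok]

    def guarded(stage: str, cell, fn):
        try:
            return fn()
        except ScatcompError as exc:
            msg = f"stage {stage}, cell {cell}: {exc}"
            if stage_errors == "log":
                note(f"ERROR {msg}")
                return None
            raise type(exc)(msg) from exc

    # --- composition ---
    comp_rows = []
    diets = {}
    for pred, stratum in included:
        sub = strata[stratum]
        diet = composition.diet_counts(sub, pred, stratum)
        diets[(pred, stratum)] = diet
        fo_items = composition.frequency_of_occurrence(diet, "items")
        fo_scats = composition.frequency_of_occurrence(diet, "scats")
        biomass = guarded(
            "composition", (pred, stratum),
            lambda: composition.relative_biomass(diet, traits),
        ) or {}
        for sp in diet.species:
            comp_rows.append(
                {
                    "predator": pred,
                    "stratum": stratum,
                    "species": sp,
                    "n_items": diet.counts[sp],
                    "fo_items": fo_items[sp],
                    "fo_scats": fo_scats[sp],
                    "biomass_prop": biomass.get(sp),
                }
            )
    comp = pd.DataFrame(
        comp_rows,
        columns=["predator", "stratum", "species", "n_items", "fo_items", "fo_scats",
                 "biomass_prop"],
    )

    # --- overlap and breadth per stratum ---
    overlap_rows, breadth_rows = [], []
    for stratum in dict.fromkeys(s for _, s in included):
        preds = [p for p, s in included if s == stratum]
        fo = {
            p: composition.frequency_of_occurrence(diets[(p, stratum)], "items")
            for p in preds
        }
        if len(fo) >= 2:
            U = utilization_matrix(fo)
            results = guarded(
                "overlap", stratum,
                lambda: overlap_null_test(U, config.n_iter_overlap, config.seed),
            )
            for res in results or []:
                overlap_rows.append(
                    {
                        "stratum": stratum,
                        "predator_j": res.pair[0],
                        "predator_k": res.pair[1],
                        "O": res.O_jk,
                        "null_mean": res.null_mean,
                        "null_sd": res.null_sd,
                        "p_value": res.p_value,
                        "n_iter": res.n_iter,
                    }
                )
            for p in preds:
                br = levins_breadth(U.row(p), n=len(U.prey))
                breadth_rows.append(
                    {"stratum": stratum, "predator": p, "B": br.B, "Bs": br.Bs,
                     "n_prey": br.n}
                )
        else:
            note(f"overlap skipped for stratum {stratum}: fewer than 2 predators")
    overlap = pd.DataFrame(
        overlap_rows,
        columns=["stratum", "predator_j", "predator_k", "O", "null_mean", "null_sd",
                 "p_value", "n_iter"],
    )
    breadth = pd.DataFrame(
        breadth_rows, columns=["stratum", "predator", "B", "Bs", "n_prey"]
    )

    # --- PERMANOVA: predator-vs-predator within areas, area-vs-area within
    # predators; Jaccard on per-scat species presence, stratified by year ---
    perm_rows = []

    def run_permanova(sub: pd.DataFrame, factor: str, comparison: str):
        sl = scat_level(sub)
        if sl[factor].nunique() < 2 or (sl.groupby(factor).size() < 2).any():
            return
        res = guarded(
            "permanova", comparison,
            lambda: permanova(
                scat_distance_matrix(sub, "species_presence"),
                groups=sl[factor].to_numpy(),
                strata=sl["year"].to_numpy(),
                n_perm=config.n_perm_permanova,
                seed=config.seed,
            ),
        )
        if res is not None:
            perm_rows.append(
                {
                    "comparison": comparison,
                    "pseudo_F": res.pseudo_F,
                    "df_between": res.df_between,
                    "df_within": res.df_within,
                    "r2": res.r2,
                    "p_value": res.p_value,
                    "n_perm": res.n_perm,
                }
            )

    area_cells = {(p, s) for p, s in included if s in ("NE", "NW", "SW")}
    for pred in sorted({p for p, _ in area_cells}):
        areas = sorted(s for q, s in area_cells if q == pred)
        for i, a1 in enumerate(areas):
            for a2 in areas[i + 1:]:
                sub = items[(items["predator"] == pred) & items["area"].isin([a1, a2])]
                run_permanova(sub, "area", f"{pred}: {a1} vs {a2}")
    for area in sorted({s for _, s in area_cells}):
        preds = sorted(p for p, s in area_cells if s == area)
        if "wild_dog" in preds:
            for other in preds:
                if other == "wild_dog":
                    continue
                sub = items[
                    (items["area"] == area)
                    & items["predator"].isin(["wild_dog", other])
                ]
                run_permanova(sub, "predator", f"{area}: wild_dog vs {other}")
    perm = pd.DataFrame(
        perm_rows,
        columns=["comparison", "pseudo_F", "df_between", "df_within", "r2", "p_value",
                 "n_perm"],
    )

    # --- preference (Jacobs with RAI and/or density availability) ---
    pref_frames = []
    area_fo = {
        (p, s): composition.frequency_of_occurrence(diets[(p, s)], "items")
        for p, s in included
        if s in ("NE", "NW", "SW")
    }
    if config.cameras and config.effort and area_fo:
        cams = ingest.read_camera_table(config.cameras)
        eff = ingest.read_effort_table(config.effort)
        rai_tbl = rai(cams, eff, level="area", window_min=config.window_min)
        pref_frames.append(preference_table(area_fo, rai_tbl, source="rai"))
    if config.densities and area_fo:
        dens = pd.read_csv(config.densities)
        pref_frames.append(preference_table(area_fo, dens, source="density"))
    pref = (
        pd.concat(pref_frames, ignore_index=True)
        if pref_frames
        else pd.DataFrame(
            columns=["predator", "stratum", "species", "r", "p_avail", "D",
                     "availability_source"]
        )
    )

    # --- species accumulation per included cell ---
    accum_rows = []
    for pred, stratum in included:
        sub = strata[stratum]
        curve = species_accumulation(
            sub[sub["predator"] == pred],
            n_perm=config.n_perm_accumulation,
            seed=config.seed,
        )
        frame = curve.to_frame()
        frame.insert(0, "stratum", stratum)
        frame.insert(0, "predator", pred)
        accum_rows.append(frame)
    accum = (
        pd.concat(accum_rows, ignore_index=True)
        if accum_rows
        else pd.DataFrame(
            columns=["predator", "stratum", "n_scats", "mean_richness", "sd_richness"]
        )
    )

    outputs = {
        "composition": comp,
        "overlap": overlap,
        "breadth": breadth,
        "permanova": perm,
        "preference": pref,
        "accumulation": accum,
        "filter_log": filter_log,
        "exclusion_log": exclusion_log,
    }
    for name, df in outputs.items():
        df.to_csv(out_dir / f"{name}.csv", index=False)
    (out_dir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    with open(out_dir / "run_meta.json", "w") as fh:
        json.dump(
            {
                "seed": config.seed,
                "min_scats": config.min_scats,
                "n_perm_permanova": config.n_perm_permanova,
                "n_iter_overlap": config.n_iter_overlap,
                "included_cells": [f"{p}/{s}" for p, s in included],
            },
            fh,
            indent=1,
        )
    return outputs
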