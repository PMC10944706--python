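"""Synthetic scat-and-camera studies with known ground truth.

Emulates the data-collection design of a multi-predator dietary
competition study in a large savanna park: opportunistic scat collection
for five predators across three areas over a four-year window (with pack
structure for wild dogs), a prey-trait table, and a grid camera-trap
survey (three sectors per area) whose detection rates are proportional to
configured true prey densities.  Every generating parameter — true diet
proportion vectors, densities, sample sizes — is recorded in a truth
object so pipeline estimates can be scored against it.

Default scale is roughly one quarter of the motivating field study
(~340 scats across five predators, a 24-species prey pool, ~110 camera
stations), which keeps a full pipeline run in the seconds range while
leaving every analysis cell above, and a deliberate few below, the
21-scat minimum-sample rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from scatcomp.errors import ValidationError
from scatcomp.overlap import pianka_overlap, levins_breadth

# species, mean female mass (kg), water dependency, feeding guild
_DEFAULT_PREY_POOL = [
    ("impala", 40, "high", "mixed_feeder"),
    ("kudu", 170, "medium", "browser"),
    ("duiker", 18, "low", "browser"),
    ("bushbuck", 30, "low", "browser"),
    ("steenbok", 11, "low", "browser"),
    ("scrub_hare", 2.5, "low", "other"),
    ("warthog", 70, "high", "grassland_grazer"),
    ("buffalo", 520, "high", "grassland_grazer"),
    ("sable", 220, "high", "woodland_grazer"),
    ("eland", 450, "low", "mixed_feeder"),
    ("elephant", 2700, "high", "mixed_feeder"),
    ("zebra", 300, "high", "grassland_grazer"),
    ("wildebeest", 180, "high", "grassland_grazer"),
    ("waterbuck", 180, "high", "grassland_grazer"),
    ("giraffe", 800, "low", "browser"),
    ("reedbuck", 50, "high", "grassland_grazer"),
    ("gemsbok", 200, "low", "mixed_feeder"),
    ("bushpig", 65, "medium", "omnivore"),
    ("baboon", 15, "medium", "omnivore"),
    ("porcupine", 15, "low", "other"),
    ("springhare", 3, "low", "other"),
    ("genet", 1.8, "low", "carnivore"),
    ("civet", 10, "low", "carnivore"),
    ("jackal", 8, "low", "carnivore"),
]

# characteristic diets per predator and area: main prey shift with
# waterhole density (NE maximum, NW high, SW low), mirroring the pattern
# of interest — the SW (low density) diets of the large predators converge
# on duiker/steenbok/kudu.
_DEFAULT_DIETS = {
    "wild_dog": {
        "NE": {"kudu": 0.28, "bushbuck": 0.18, "waterbuck": 0.12, "impala": 0.30,
               "duiker": 0.08, "steenbok": 0.04},
        "NW": {"impala": 0.34, "kudu": 0.30, "bushpig": 0.10, "bushbuck": 0.12,
               "duiker": 0.10, "steenbok": 0.04},
        "SW": {"duiker": 0.28, "steenbok": 0.20, "kudu": 0.16, "impala": 0.10,
               "sable": 0.08, "reedbuck": 0.07, "gemsbok": 0.06, "baboon": 0.05},
    },
    "cheetah": {
        "NW": {"bushbuck": 0.24, "duiker": 0.22, "scrub_hare": 0.20,
               "impala": 0.18, "steenbok": 0.10, "baboon": 0.06},
    },
    "leopard": {
        "NE": {"impala": 0.35, "duiker": 0.25, "bushbuck": 0.20, "steenbok": 0.20},
        "NW": {"impala": 0.30, "kudu": 0.18, "duiker": 0.18, "bushbuck": 0.14,
               "steenbok": 0.08, "scrub_hare": 0.06, "porcupine": 0.06},
        "SW": {"duiker": 0.26, "bushbuck": 0.20, "steenbok": 0.18, "kudu": 0.12,
               "scrub_hare": 0.08, "porcupine": 0.06, "jackal": 0.05, "genet": 0.05},
    },
    "lion": {
        "NE": {"impala": 0.26, "buffalo": 0.20, "sable": 0.14, "kudu": 0.12,
               "zebra": 0.10, "wildebeest": 0.08, "warthog": 0.06, "elephant": 0.04},
        "NW": {"buffalo": 0.24, "bushpig": 0.14, "impala": 0.16, "kudu": 0.14,
               "zebra": 0.12, "eland": 0.08, "warthog": 0.07, "wildebeest": 0.05},
        "SW": {"kudu": 0.28, "duiker": 0.20, "gemsbok": 0.12, "eland": 0.10,
               "steenbok": 0.08, "reedbuck": 0.08, "sable": 0.08, "impala": 0.06},
    },
    "hyaena": {
        "NE": {"impala": 0.26, "sable": 0.18, "kudu": 0.14, "wildebeest": 0.12,
               "buffalo": 0.10, "waterbuck": 0.08, "warthog": 0.07, "zebra": 0.05},
        "NW": {"kudu": 0.24, "impala": 0.22, "wildebeest": 0.14, "buffalo": 0.12,
               "bushpig": 0.10, "warthog": 0.08, "zebra": 0.10},
        "SW": {"duiker": 0.26, "steenbok": 0.18, "kudu": 0.18, "impala": 0.10,
               "reedbuck": 0.10, "gemsbok": 0.08, "sable": 0.06, "eland": 0.04},
    },
}

_DEFAULT_N_SCATS = {
    "wild_dog": {"NE": 24, "NW": 30, "SW": 22},
    "cheetah": {"NW": 26},
    "leopard": {"NE": 8, "NW": 26, "SW": 25},  # NE deliberately below 21
    "lion": {"NE": 30, "NW": 28, "SW": 28},
    "hyaena": {"NE": 28, "NW": 26, "SW": 26},
}

# prey densities per km^2 (NW reference values); area multipliers model the
# abundance gradient (lowest in SW)
_DEFAULT_DENSITIES = {
    "impala": 6.0, "kudu": 2.5, "duiker": 4.0, "bushbuck": 1.5, "steenbok": 2.0,
    "scrub_hare": 3.0, "warthog": 1.2, "buffalo": 1.5, "sable": 0.8, "eland": 0.5,
    "elephant": 1.5, "zebra": 1.2, "wildebeest": 0.9, "waterbuck": 0.5,
    "giraffe": 0.5, "reedbuck": 0.4, "gemsbok": 0.3, "bushpig": 0.7,
    "baboon": 2.0, "porcupine": 0.5, "springhare": 0.8, "genet": 0.2,
    "civet": 0.2, "jackal": 0.4,
}
_DEFAULT_AREA_DENSITY_FACTOR = {"NE": 1.2, "NW": 1.0, "SW": 0.5}

# planar coordinate boxes (metres) per area; boxes are disjoint
_AREA_BOXES = {
    "NE": ((60_000.0, 120_000.0), (60_000.0, 120_000.0)),
    "NW": ((0.0, 60_000.0), (60_000.0, 120_000.0)),
    "SW": ((0.0, 60_000.0), (0.0, 60_000.0)),
}


@dataclass
class SyntheticConfig:
    """All generating parameters of a synthetic study.

    ``diets[predator][area]`` are true diet proportion vectors (each must
    sum to 1); ``n_scats[predator][area]`` the scat sample sizes.  Scat
    prey items are drawn multinomially from the area diet, with
    ``1 + Poisson(items_per_scat_lambda)`` distinct species per scat.
    ``duplicate_rate`` injects pseudo-replicate scats (same pack and day
    for wild dogs; same day within 500 m for lions/hyaenas) at the given
    per-scat probability, to exercise the cleaning filters.  Camera
    detections per station and species are Poisson with mean
    ``density * detection_rate * trap_days``; ``burst_rate`` is the
    probability that a detection spawns extra photographs within the
    30-minute independence window.
    """

    seed: int = 0
    prey_pool: list = field(default_factory=lambda: [list(r) for r in _DEFAULT_PREY_POOL])
    diets: dict = field(default_factory=lambda: json.loads(json.dumps(_DEFAULT_DIETS)))
    n_scats: dict = field(default_factory=lambda: json.loads(json.dumps(_DEFAULT_N_SCATS)))
    items_per_scat_lambda: float = 0.1
    packs_per_area: int = 2
    duplicate_rate: float = 0.0
    study_start: str = "2012-01-01"
    study_end: str = "2015-12-31"
    densities: dict = field(default_factory=lambda: dict(_DEFAULT_DENSITIES))
    area_density_factor: dict = field(
        default_factory=lambda: dict(_DEFAULT_AREA_DENSITY_FACTOR)
    )
    stations_per_sector: int = 12
    trap_days_per_station: float = 47.0
    detection_rate: float = 0.02  # records per trap-day per unit density
    burst_rate: float = 0.3

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def validate(self) -> None:
        pool = {row[0] for row in self.prey_pool}
        for pred, by_area in self.diets.items():
            for area, diet in by_area.items():
                unknown = sorted(set(diet) - pool)
                if unknown:
                    raise ValidationError(
                        f"diet of {pred}/{area} uses species not in prey pool: {unknown}"
                    )
                if abs(sum(diet.values()) - 1.0) > 1e-9:
                    raise ValidationError(f"diet of {pred}/{area} does not sum to 1")
        unknown = sorted(set(self.densities) - pool)
        if unknown:
            raise ValidationError(f"densities for species not in prey pool: {unknown}")
        for pred, by_area in self.n_scats.items():
            if pred not in self.diets:
                raise ValidationError(f"n_scats given for {pred} but no diet configured")
            for area, n in by_area.items():
                if area not in self.diets[pred]:
                    raise ValidationError(f"n_scats for {pred}/{area} but no diet")
                if n <= 0:
                    raise ValidationError("scat counts must be positive")


def _draw_scat_items(rng, diet: dict, lam: float) -> list[str]:
    species = list(diet)
    probs = np.array([diet[s] for s in species])
    k = 1 + rng.poisson(lam)
    k = min(k, len(species))
    return list(rng.choice(species, size=k, replace=False, p=probs / probs.sum()))


def _true_overall_diet(config: SyntheticConfig, predator: str) -> dict[str, float]:
    """Scat-count-weighted mixture of the predator's area diets."""
    total = sum(config.n_scats[predator].values())
    out: dict[str, float] = {}
    for area, n in config.n_scats[predator].items():
        for sp, p in config.diets[predator][area].items():
            out[sp] = out.get(sp, 0.0) + p * n / total
    return out


def _truth_indices(config: SyntheticConfig) -> dict:
    """True Pianka overlaps and Levins breadths implied by the config."""
    strata: dict[str, dict[str, dict[str, float]]] = {
        "All": {p: _true_overall_diet(config, p) for p in config.n_scats}
    }
    areas = sorted({a for by in config.n_scats.values() for a in by})
    for area in areas:
        strata[area] = {
            p: config.diets[p][area]
            for p in config.n_scats
            if area in config.n_scats[p]
        }
    pianka: dict[str, dict[str, float]] = {}
    bs: dict[str, dict[str, float]] = {}
    for stratum, diets in strata.items():
        prey = sorted({sp for d in diets.values() for sp in d})
        vecs = {
            p: np.array([d.get(sp, 0.0) for sp in prey]) for p, d in diets.items()
        }
        preds = sorted(vecs)
        pianka[stratum] = {
            f"{a}|{b}": pianka_overlap(vecs[a], vecs[b])
            for i, a in enumerate(preds)
            for b in preds[i + 1:]
        }
        if len(prey) >= 2:
            bs[stratum] = {p: levins_breadth(v, n=len(prey)).Bs for p, v in vecs.items()}
    return {"pianka": pianka, "levins_bs": bs}


def generate_study(config: SyntheticConfig | None = None, out_dir=None) -> dict:
    """Generate a complete synthetic study.

    Returns a dict with DataFrames ``scats`` (long prey-item table),
    ``traits``, ``cameras``, ``effort`` and the ``truth`` dict holding
    every generating parameter plus the implied true overlap/breadth
    values.  With ``out_dir``, also writes ``scats.csv``,
    ``prey_traits.csv``, ``cameras.csv``, ``effort.csv`` and
    ``truth.json``.  Output is byte-identical for a fixed config.
    """
    config = config or SyntheticConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    traits = pd.DataFrame(
        config.prey_pool,
        columns=["species", "mean_female_mass_kg", "water_dependency", "feeding_guild"],
    )

    start = pd.Timestamp(config.study_start)
    end = pd.Timestamp(config.study_end)
    n_days = (end - start).days + 1

    scat_rows: list[dict] = []
    n_duplicates = 0

    def add_scat(scat_id, predator, day, x, y, area, pack_id, items):
        for sp in items:
            scat_rows.append(
                {
                    "scat_id": scat_id,
                    "predator": predator,
                    "date": (start + pd.Timedelta(days=int(day))).date().isoformat(),
                    "x_m": round(float(x), 1),
                    "y_m": round(float(y), 1),
                    "area": area,
                    "pack_id": pack_id,
                    "prey_species": sp,
                }
            )

    for predator in sorted(config.n_scats):
        for area in sorted(config.n_scats[predator]):
            n = config.n_scats[predator][area]
            diet = config.diets[predator][area]
            (x0, x1), (y0, y1) = _AREA_BOXES[area]
            if predator == "wild_dog":
                packs = [f"{area}_pack{i + 1}" for i in range(config.packs_per_area)]
                assignment = rng.choice(len(packs), size=n)
                # distinct collection days within each pack: the base study
                # carries no pseudo-replicates unless duplicate_rate > 0
                days = np.empty(n, dtype=int)
                for pi in range(len(packs)):
                    members = np.flatnonzero(assignment == pi)
                    days[members] = rng.choice(n_days, size=len(members), replace=False)
            elif predator in ("lion", "hyaena"):
                packs = None
                days = rng.choice(n_days, size=n, replace=False)
            else:
                packs = None
                days = rng.integers(0, n_days, size=n)
            xs = rng.uniform(x0, x1, size=n)
            ys = rng.uniform(y0, y1, size=n)
            for i in range(n):
                pack_id = packs[assignment[i]] if packs else ""
                scat_id = f"{predator}_{area}_{i + 1:04d}"
                items = _draw_scat_items(rng, diet, config.items_per_scat_lambda)
                add_scat(scat_id, predator, days[i], xs[i], ys[i], area, pack_id, items)
                if config.duplicate_rate > 0 and predator in ("wild_dog", "lion", "hyaena"):
                    if rng.random() < config.duplicate_rate:
                        n_duplicates += 1
                        dup_items = _draw_scat_items(rng, diet, config.items_per_scat_lambda)
                        if predator == "wild_dog":
                            dx, dy = rng.uniform(-5000, 5000, size=2)
                        else:
                            r, th = rng.uniform(0, 500), rng.uniform(0, 2 * np.pi)
                            dx, dy = r * np.cos(th), r * np.sin(th)
                        add_scat(
                            f"{scat_id}_dup", predator, days[i],
                            np.clip(xs[i] + dx, x0, x1), np.clip(ys[i] + dy, y0, y1),
                            area, pack_id, dup_items,
                        )

    scats = pd.DataFrame(scat_rows)
    scats["date"] = pd.to_datetime(scats["date"])
    scats["year"] = scats["date"].dt.year

    # camera survey: grid stations per sector, Poisson detections
    cam_rows: list[dict] = []
    effort_rows: list[dict] = []
    for area in sorted(_AREA_BOXES):
        factor = config.area_density_factor.get(area, 1.0)
        for s in range(3):
            sector = f"{area}_s{s + 1}"
            for st in range(config.stations_per_sector):
                station = f"{sector}_st{st + 1:02d}"
                effort_rows.append(
                    {
                        "station_id": station,
                        "trap_days": config.trap_days_per_station,
                        "sector": sector,
                        "area": area,
                    }
                )
                for sp in sorted(config.densities):
                    lam = (
                        config.densities[sp]
                        * factor
                        * config.detection_rate
                        * config.trap_days_per_station
                    )
                    k = rng.poisson(lam)
                    if k == 0:
                        continue
                    secs = np.sort(
                        rng.integers(0, n_days * 86400, size=k)
                    )
                    for t0 in secs:
                        cam_rows.append(
                            {
                                "station_id": station,
                                "sector": sector,
                                "area": area,
                                "species": sp,
                                "timestamp": (
                                    start + pd.Timedelta(seconds=int(t0))
                                ).isoformat(),
                                "n_individuals": int(1 + rng.poisson(0.5)),
                            }
                        )
                        if rng.random() < config.burst_rate:
                            for _ in range(int(1 + rng.integers(0, 2))):
                                dt = int(rng.integers(30, 29 * 60))
                                cam_rows.append(
                                    {
                                        "station_id": station,
                                        "sector": sector,
                                        "area": area,
                                        "species": sp,
                                        "timestamp": (
                                            start + pd.Timedelta(seconds=int(t0) + dt)
                                        ).isoformat(),
                                        "n_individuals": 1,
                                    }
                                )

    cameras = pd.DataFrame(
        cam_rows,
        columns=["station_id", "sector", "area", "species", "timestamp", "n_individuals"],
    )
    if len(cameras):
        cameras["timestamp"] = pd.to_datetime(cameras["timestamp"])
    effort = pd.DataFrame(effort_rows)

    truth = {
        "seed": config.seed,
        "config": asdict(config),
        "n_duplicates": n_duplicates,
        "diets": {
            p: {**config.diets[p], "All": _true_overall_diet(config, p)}
            for p in config.n_scats
        },
        "expected_rai": {
            area: {
                sp: config.densities[sp]
                * config.area_density_factor.get(area, 1.0)
                * config.detection_rate
                for sp in sorted(config.densities)
            }
            for area in sorted(_AREA_BOXES)
        },
        **_truth_indices(config),
    }

    study = {
        "scats": scats,
        "traits": traits,
        "cameras": cameras,
        "effort": effort,
        "truth": truth,
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        w = scats.copy()
        w["date"] = w["date"].dt.date.astype(str)
        w.drop(columns="year").to_csv(out / "scats.csv", index=False)
        traits.to_csv(out / "prey_traits.csv", index=False)
        c = cameras.copy()
        if len(c):
            c["timestamp"] = c["timestamp"].astype(str)
        c.to_csv(out / "cameras.csv", index=False)
        effort.to_csv(out / "effort.csv", index=False)
        with open(out / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
    return study


def recovery_report(truth: dict, estimates: dict) -> pd.DataFrame:
    """Score pipeline estimates against the generating truth.

    ``estimates`` may hold any of:

    - ``"diet"``: ``{(predator, stratum): {species: proportion}}``
    - ``"pianka"``: ``{(predator_j, predator_k, stratum): O}``
    - ``"levins_bs"``: ``{(predator, stratum): Bs}``
    - ``"seed"``: the seed of the run being scored (must match truth)

    Returns a long table (quantity, predator, stratum, species, true,
    estimated, abs_error).  With fewer than two predators in the truth the
    overlap section is a single "n/a" row.
    """
    if "seed" in estimates and estimates["seed"] != truth["seed"]:
        raise ValidationError(
            f"estimate seed {estimates['seed']} does not match truth seed {truth['seed']}"
        )
    rows: list[dict] = []

    def add(quantity, predator, stratum, species, true, est):
        rows.append(
            {
                "quantity": quantity,
                "predator": predator,
                "stratum": stratum,
                "species": species,
                "true": true,
                "estimated": est,
                "abs_error": abs(true - est) if est == est else float("nan"),
            }
        )

    for (pred, stratum), fo in estimates.get("diet", {}).items():
        true_diet = truth["diets"][pred][stratum]
        for sp in sorted(set(true_diet) | set(fo)):
            add("diet_proportion", pred, stratum, sp,
                true_diet.get(sp, 0.0), fo.get(sp, 0.0))

    if len(truth["diets"]) < 2 and "pianka" in estimates:
        rows.append(
            {
                "quantity": "pianka",
                "predator": "n/a (single predator configured)",
                "stratum": "",
                "species": "",
                "true": float("nan"),
                "estimated": float("nan"),
                "abs_error": float("nan"),
            }
        )
    else:
        for (pj, pk, stratum), o in estimates.get("pianka", {}).items():
            a, b = sorted((pj, pk))
            true_o = truth["pianka"][stratum][f"{a}|{b}"]
            add("pianka", f"{pj}|{pk}", stratum, "", true_o, o)

    for (pred, stratum), bs in estimates.get("levins_bs", {}).items():
        add("levins_bs", pred, stratum, "", truth["levins_bs"][stratum][pred], bs)

    return pd.DataFrame(
        rows,
        columns=["quantity", "predator", "stratum", "species", "true", "estimated", "abs_error"],
    )
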