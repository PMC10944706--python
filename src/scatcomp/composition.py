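"""Diet composition: frequency of occurrence, biomass correction, aggregation.

Scat counts over-represent small prey (more scats per kg ingested), so raw
frequencies are complemented by a biomass correction: a linear model of
prey mass ingested per collectable scat as a function of the prey species'
mean adult female mass, capped at the predator's stomach capacity.  Wild
dog diets use the wolf-derived model (0.439 + 0.008 * mass); the other
predators use the puma-derived model (1.980 + 0.035 * mass) with caps of
10 kg (leopard), 24 kg (hyaena) and 50 kg (lion).  Wild dog and cheetah
per-scat masses never approach stomach capacity, so they carry no cap.
The resulting proportions are indicative of relative, not absolute,
biomass intake.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from scatcomp.errors import ValidationError


@dataclass(frozen=True)
class BiomassModel:
    """Linear prey-mass-per-scat model with an optional stomach-capacity cap."""

    predator: str
    intercept: float  # kg per scat
    slope: float  # kg per scat per kg female mass
    cap: float | None = None  # kg, maximum stomach capacity

    def __post_init__(self):
        if self.intercept <= 0 or self.slope < 0:
            raise ValidationError("biomass model needs intercept > 0 and slope >= 0")
        if self.cap is not None and self.cap <= self.intercept:
            raise ValidationError("cap must exceed the intercept")


_WEAVER = dict(intercept=0.439, slope=0.008)  # grey wolf model
_ACKERMAN = dict(intercept=1.980, slope=0.035)  # puma model

#: Default biomass models per predator.
BIOMASS_MODELS: dict[str, BiomassModel] = {
    "wild_dog": BiomassModel("wild_dog", **_WEAVER),
    "cheetah": BiomassModel("cheetah", **_ACKERMAN),
    "leopard": BiomassModel("leopard", **_ACKERMAN, cap=10.0),
    "hyaena": BiomassModel("hyaena", **_ACKERMAN, cap=24.0),
    "lion": BiomassModel("lion", **_ACKERMAN, cap=50.0),
}


@dataclass
class DietCounts:
    """Prey occurrence counts for one predator in one analysis stratum.

    ``counts`` holds item occurrences (a species found in k scats of the
    stratum contributes k); ``scat_counts`` holds the number of distinct
    scats containing each species (identical to ``counts`` unless a species
    occurs twice in one scat, which the one-item-per-species-per-scat
    convention precludes — kept separate because n_items > n_scats when
    scats contain multiple species).
    """

    predator: str
    stratum: str
    counts: dict[str, int]
    n_scats: int
    scat_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if not self.scat_counts:
            self.scat_counts = dict(self.counts)
        if any(v < 0 for v in self.counts.values()):
            raise ValidationError("negative prey count")

    @property
    def n_items(self) -> int:
        return int(sum(self.counts.values()))

    @property
    def species(self) -> list[str]:
        return sorted(self.counts)


def diet_counts(items: pd.DataFrame, predator: str, stratum: str = "All") -> DietCounts:
    """Build :class:`DietCounts` from a long prey-item table for one predator.

    ``items`` must already be restricted to the stratum of interest; the
    ``stratum`` argument is a label recorded on the result.
    """
    sub = items[items["predator"] == predator]
    if len(sub) == 0:
        raise ValidationError(f"no prey items for predator {predator!r}")
    counts = sub.groupby("prey_species").size().to_dict()
    scat_counts = (
        sub.drop_duplicates(["scat_id", "prey_species"])
        .groupby("prey_species")
        .size()
        .to_dict()
    )
    return DietCounts(
        predator=predator,
        stratum=stratum,
        counts={k: int(v) for k, v in counts.items()},
        n_scats=int(sub["scat_id"].nunique()),
        scat_counts={k: int(v) for k, v in scat_counts.items()},
    )


def frequency_of_occurrence(diet: DietCounts, convention: str = "items") -> dict[str, float]:
    """Frequency of occurrence of each prey species in a diet.

    ``items`` (the default): count_i / total items — proportions summing
    to 1, the convention feeding overlap and breadth indices.
    ``scats``: scats containing the species / total scats — may exceed 1
    in sum when scats hold several species; exposed for sensitivity checks.
    """
    if diet.n_items == 0:
        raise ValidationError("empty diet")
    if convention == "items":
        total = diet.n_items
        return {sp: c / total for sp, c in diet.counts.items()}
    if convention == "scats":
        return {sp: c / diet.n_scats for sp, c in diet.scat_counts.items()}
    raise ValueError(f"unknown FO convention {convention!r}")


def biomass_per_scat(model: BiomassModel | str, mass_kg: float) -> float:
    """Prey mass (kg) represented by one scat, capped at stomach capacity.

    ``min(intercept + slope * mass, cap)``; mass 0 is allowed so the
    analytic intercept can be read off directly.
    """
    if isinstance(model, str):
        try:
            model = BIOMASS_MODELS[model]
        except KeyError:
            raise ValidationError(f"unknown predator {model!r}") from None
    if mass_kg < 0:
        raise ValidationError("mass must be non-negative")
    raw = model.intercept + model.slope * mass_kg
    return min(raw, model.cap) if model.cap is not None else raw


def relative_biomass(
    diet: DietCounts,
    traits: pd.DataFrame,
    model: BiomassModel | str | None = None,
) -> dict[str, float]:
    """Biomass-corrected diet proportions.

    proportion_i = count_i * mass_per_scat_i / sum_j count_j * mass_per_scat_j

    ``model`` defaults to the predator's entry in :data:`BIOMASS_MODELS`.
    """
    if model is None:
        model = diet.predator
    masses = traits.set_index("species")["mean_female_mass_kg"]
    missing = sorted(set(diet.counts) - set(masses.index))
    if missing:
        raise ValidationError(f"species missing from trait table: {missing}")
    weights = {
        sp: c * biomass_per_scat(model, float(masses[sp])) for sp, c in diet.counts.items()
    }
    total = sum(weights.values())
    return {sp: w / total for sp, w in weights.items()}


def aggregate_by_category(
    diet: DietCounts, traits: pd.DataFrame, category: str
) -> dict[str, int]:
    """Sum diet item counts over prey sharing a trait level.

    ``category`` is one of ``water_dependency``, ``feeding_guild``,
    ``size_class``.  Levels with zero count are omitted; totals are
    conserved.
    """
    if category not in ("water_dependency", "feeding_guild", "size_class"):
        raise ValueError(f"unknown category {category!r}")
    levels = traits.set_index("species")[category]
    missing = sorted(
        set(diet.counts) - set(levels.dropna().index)
    )
    if missing:
        raise ValidationError(f"species missing {category}: {missing}")
    out: dict[str, int] = {}
    for sp, c in diet.counts.items():
        if c == 0:
            continue
        lvl = levels[sp]
        out[lvl] = out.get(lvl, 0) + int(c)
    return out
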