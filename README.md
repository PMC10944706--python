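# scatcomp

Dietary competition analysis for sympatric large-carnivore guilds from
scat contents and camera-trap surveys.

`scatcomp` is aimed at community ecologists quantifying trophic niche
partitioning among predators — the motivating system is a five-species
African guild (African wild dog, cheetah, leopard, lion, spotted hyaena)
sampled by opportunistic scat collection across park areas with
contrasting waterhole density — but every component works on any
scat + trait + camera dataset in the documented CSV schemas.

## What it computes

**Diet composition.** Frequency of occurrence of each prey species
(item convention: `FO_i = n_i / Σ n`, and the per-scat variant), and
biomass-corrected proportions using linear prey-mass-per-scat models:
`m(w) = 0.439 + 0.008 w` (wolf-derived, applied to wild dogs) and
`m(w) = 1.980 + 0.035 w` (puma-derived, other predators), with `w` the
prey's mean adult female mass (kg), capped at stomach capacity
(leopard 10 kg, hyaena 24 kg, lion 50 kg). Counts aggregate by prey
water dependency, feeding guild, or size class (XS < 5 kg through
XL ≥ 350 kg).

**Dissimilarity and PERMANOVA.** Scat-level Jaccard distances
`(A + B − 2J)/(A + B − J)` on prey-species presence, Bray–Curtis
`Σ|x_i − y_i| / Σ(x_i + y_i)` on prey-category counts, and a
from-scratch one-factor PERMANOVA

```
F = [SS_among/(a−1)] / [SS_within/(N−a)],   p = (1 + #{F* ≥ F}) / (n_perm + 1)
```

with group-label permutations restricted to calendar-year strata.

**Overlap and breadth.** Pianka's index
`O_jk = Σ p_ij p_ik / √(Σ p_ij² Σ p_ik²)` on the predators' shared
resource axis, tested against a richness-preserving null (each row's
non-zero utilization values relocated to random columns, 10 000
iterations by default), and standardised Levins breadth
`B = 1/Σp²`, `Bs = (B−1)/(n−1)`.

**Prey preference.** Camera-trap relative abundance
`RAI = independent records / trap-days` (30-minute chained independence
filter, sector-level RAI averaged per area) feeding Jacobs' index
`D = (r − p)/(r + p − 2rp)` ∈ [−1 (avoidance), +1 (preference)].

**Cleaning rules** mirror field practice: one scat per 24 h per
location (≤ 1 km) for lions/hyaenas, one per 24 h per pack for wild
dogs; cells under 21 scats excluded from statistics; species
accumulation curves for sampling sufficiency.

A synthetic-study generator (`scatcomp.synthetic`) produces complete
datasets with known true diets, overlaps and densities so the whole
pipeline can be validated without any field data.

## Worked example

```python
import scatcomp as sc

study = sc.generate_study(sc.SyntheticConfig(seed=1))   # synthetic guild study
items = study["scats"]

fo = {p: sc.frequency_of_occurrence(sc.diet_counts(items, p, "All"))
      for p in ("wild_dog", "lion", "hyaena")}
U = sc.utilization_matrix(fo)
print(round(sc.pianka_overlap(U.row("wild_dog"), U.row("hyaena")), 3))
print(round(sc.pianka_overlap(U.row("wild_dog"), U.row("lion")), 3))
print(round(sc.levins_breadth(U.row("wild_dog"), n=len(U.prey)).Bs, 3))
```

prints

```
0.82
0.616
0.267
```

— the wild dog's diet overlaps the hyaena's far more than the lion's
(Pianka 0.82 vs 0.62 on this draw), while its standardised niche
breadth (0.27 on the three-predator resource axis) marks it as the
specialist of the trio. (These numbers are estimates from one simulated
327-scat study; the generating truth stored in `study["truth"]` holds
Pianka 0.86 and 0.75 for the two pairs.)

The same analyses run from the shell:

```sh
scatcomp simulate --seed 1 --out fixtures/
scatcomp run --config run.yaml          # full pipeline
scatcomp overlap --scats fixtures/scats.csv --niter 10000 --seed 7 --out overlap.csv
```

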