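# Methods

This note documents the statistical procedures implemented in
`scatcomp`, the choices made where the underlying field methodology
leaves room, and what the synthetic validation does and does not
demonstrate.

## Data model and cleaning

A *scat* is one faecal sample of one predator with a date, projected
planar coordinates (metres), a study-area label (NE/NW/SW) and — for
wild dogs — a pack identifier. A scat contains one or more *prey
items*, each a prey species identified from undigested remains. The
long CSV schema (one row per item, scat-level fields repeated) is the
only input format; all readers validate labels against closed sets and
fail loudly with the offending rows.

**Pseudo-replication.** Repeated defecations by the same individual or
social unit within a short window are not independent samples of the
diet. Retention is greedy and earliest-first (sort by timestamp, then
scat id; keep a scat iff it conflicts with no already-kept scat), which
is deterministic and idempotent. Conflicts: lion/hyaena — strictly less
than 24 h apart *and* within 1 km (inclusive, Euclidean); wild dog —
strictly less than 24 h apart in the same pack, any distance; cheetah
and leopard — never (no rule is defined for them, so they pass
through). Date-only records are treated as midnight timestamps, making
"within 24 h" equivalent to "same calendar day"; records exactly one
day apart do not conflict.

**Seasons.** Two partitions of the calendar: weather (wet–early dry,
November–June; late dry, July–October) and wild-dog behaviour (nomadic,
September–April; breeding/denning, May–August). Both partition all 12
months exactly once.

**Size classes.** Mean adult female mass cut at 5, 25, 100 and 350 kg
into XS/S/M/L/XL. The published class bounds leave the gaps 5–6, 24–25,
99–100 and 349–350 kg unassigned; we close them with half-open
intervals ([5, 25) kg is S, and so on) so that every positive mass has
exactly one class.

**Minimum sample.** Analysis cells (predator × stratum) with fewer than
21 scats are excluded from all statistical comparisons and logged. The
threshold is configurable (`min_scats`).

## Diet composition

Two frequency-of-occurrence conventions exist in the scat literature;
we make the *item* convention primary (count of a species across items
÷ total items), because it yields proportions that sum to 1 — the form
required by the overlap and breadth indices — and expose the per-scat
variant (scats containing the species ÷ scats) for sensitivity
analysis.

Biomass correction uses linear prey-mass-per-scat regressions: a
wolf-derived model (0.439 + 0.008·mass kg) for wild dogs and a
puma-derived model (1.980 + 0.035·mass kg) for the felids and the
hyaena, the per-scat value capped at stomach capacity (10/24/50 kg for
leopard/hyaena/lion; wild dog and cheetah per-scat masses cannot reach
capacity, so no cap). Because these models come from other species, the
resulting proportions are *indicative* of relative biomass intake, not
absolute estimates. The cap applies to the per-scat mass, not the
aggregate, since the correction is defined on the per-scat quantity.
Carnivore prey remains in all computations.

## Dissimilarity and PERMANOVA

Species-composition comparisons use Jaccard distances on per-scat
presence/absence; prey-category comparisons use Bray–Curtis on per-scat
category counts (a scat can contribute several items to one category).
Matrices are built with `scipy.spatial.distance.pdist`; the pairwise
formula functions exist independently and the tests assert the matrix
equals their element-wise application.

The one-factor PERMANOVA partitions the squared distances:
`SS_total = (1/N) Σ_{i<j} d²`, `SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²`,
`F = (SS_among/(a−1))/(SS_within/(N−a))`. Significance comes from
permuting group labels *within calendar-year strata* (uniformly, via a
seeded `numpy` Generator), with the standard `(b+1)/(m+1)` p-value so p
is never 0. With every observation its own stratum nothing can move and
p = 1, the expected degenerate behaviour. A zero within-group sum of
squares yields an infinite F, still reported with its permutation p.
Only the single-factor design is implemented: every comparison of
interest (predator vs predator within an area, area vs area within a
predator, season vs season) is one factor with year as stratum, which
is also why sequential-vs-marginal sums of squares never arise.

## Overlap null model and breadth

The utilization matrix holds each predator's item-convention diet
proportions over the *union* of prey consumed by all predators in the
stratum, so rows share one resource axis. Pianka's index is tested
against a null that conserves each predator's diet *richness*: every
iteration relocates each row's non-zero utilization values to a
uniformly random column subset of the same size (values untouched, rows
independent) — implemented as a random permutation of the full row,
which is the same distribution. The alternative null that resamples the
values themselves is rejected because richness is the quantity the
procedure is meant to conserve. Significance is one-tailed
(observed ≥ null), matching the scientific claim that overlaps are
high; a two-sided option is exposed. Pianka's denominator is invariant
under the reshuffle, so the null is computed vectorised from the
numerators alone.

Per-pair null streams are derived from the master seed and the pair's
species names (CRC32-keyed `SeedSequence`), so adding a predator to the
matrix never perturbs existing pairs' results.

Levins breadth uses `B = 1/Σp²` standardised by `Bs = (B−1)/(n−1)` with
`n` the number of columns of the stratum's utilization matrix (the
per-stratum union, not the global prey list). Adding a prey column
consumed by no one therefore lowers every `Bs` while leaving every
Pianka overlap unchanged — both asserted in tests.

Plug-in estimation of Pianka from finite scat samples is biased
downward (sampling noise inflates the `Σp²` terms in the denominator);
at the default quarter-scale study the per-pair error is typically
0.03–0.10 and largest for the 26-scat cheetah cells. The acceptance
script reports both the mean and the max recovery error.

## Preference

Camera records collapse to independent detections per station ×
species: a record is kept iff it falls strictly more than 30 minutes
after the previously *kept* record (chained, the common camera-trap
convention; the gap-from-last-raw-photo variant is an option).
Multi-animal frames count once — RAI is records per trap-day, not
animals per trap-day. Sector RAI divides a sector's independent records
by its total trap-days; area RAI is the unweighted mean over the area's
three sectors (no effort weighting, following the "averaged per area"
design).

Jacobs' index `D = (r − p)/(r + p − 2rp)` compares the diet proportion
`r` with proportional availability `p`. Both are renormalised over the
prey species shared by the diet and availability tables within each
stratum, so they are comparable proportions; diet species with no
availability estimate are reported with `D` undefined (NaN) and a
warning rather than dropped. `D` is antisymmetric in (r, p), increasing
in r, and set to 0 at r = p = 1 by continuity. Availability can come
from RAI or from a user-supplied density table (density estimation
itself is out of scope; densities are accepted as input).

## Species accumulation

The random-permutation estimator averages cumulative richness over
random scat orderings; the closed form
`E[S(n)] = Σ_s (1 − C(N−m_s, n)/C(N, n))` (computed via log-gamma)
provides an analytic cross-check, and the two agree in expectation.
Curves are used qualitatively (sampling sufficiency); no plateau
statistic is computed.

## Synthetic studies

The generator emulates the field design: five predators across three
areas over a 2012–2015 window, per-area true diet vectors, wild-dog
pack structure, a prey-trait table of 24 savanna species, and a
three-sector-per-area camera grid whose per-station detection counts
are Poisson with mean density × detection rate × trap-days, plus photo
bursts inside the 30-minute window. Items per scat are
1 + Poisson(0.1), matching the ~1.03–1.21 items/scat ratios of real
scat datasets. Default sample sizes are roughly one quarter of the
motivating study (wild dog 76, cheetah 26, leopard 59, lion 86, hyaena
80 scats), keeping the full pipeline in the seconds range; the
leopard/NE cell is deliberately below the 21-scat rule so the exclusion
path is always exercised. Collection days are drawn without replacement
within each conflict group (pack, or predator × area), so the base
study contains no pseudo-replicates; `duplicate_rate` injects
rule-violating duplicates on demand.

What passing tests show: the estimators are unbiased/consistent where
they should be, the permutation tests are calibrated, and every
filtering rule fires exactly on its defining edge cases. What they do
not show: robustness to prey misidentification, non-multinomial item
dependence within packs, spatial autocorrelation of camera detections,
or detection probabilities varying by species or habitat — none of
which the generator models.

## Numerical and design choices

- Permutation p-values use `(b+1)/(m+1)`; all randomness flows through
  seeded `numpy.random.Generator` instances.
- Distances are validated to be symmetric, zero-diagonal and in [0, 1].
- Jaccard of two empty sets, Bray–Curtis of two zero vectors, Pianka
  with a zero row and Jacobs at r = p = 0 are errors, not silent zeros.
- The pipeline's seasonal cells use northern-area (NE, NW) scats only,
  because southern sampling does not cover both seasons; breeding-season
  cells drop non-denning wild-dog packs when a `denning` column is
  present.
- Area labels are taken from the input table, never recomputed from
  coordinates (sector polygons are not part of the data model).

## Known limitations

- PERMANOVA is single-factor; no multi-factor partitioning, post-hoc
  corrections or dispersion (PERMDISP) tests.
- Biomass proportions depend on borrowed regression coefficients and
  should be read comparatively.
- The overlap null conserves richness but not prey identity structure
  (e.g. phylogenetic similarity of prey is ignored).
- RAI assumes equal detectability across species and stations.
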