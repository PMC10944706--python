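"""Scat-level dissimilarity matrices and stratified one-factor PERMANOVA.

Diet comparisons operate on a scat-by-scat distance matrix: Jaccard on the
presence/absence of prey species in each scat, or Bray-Curtis on per-scat
counts of prey categories (water dependency, feeding guild, size class).
Group differences (predator vs predator, area vs area, season vs season)
are tested with a permutational ANOVA on the distance matrix, with the
permutations of group labels restricted to calendar-year strata so that
between-year composition shifts cannot masquerade as group effects.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from scatcomp.errors import ValidationError


@dataclass
class DistanceMatrix:
    """Symmetric pairwise scat dissimilarities in [0, 1]."""

    labels: list
    d: np.ndarray
    metric: str

    def __post_init__(self):
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("distance matrix must be symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValidationError("distance matrix diagonal must be zero")
        if self.d.min() < -1e-12 or self.d.max() > 1 + 1e-12:
            raise ValidationError("distances must lie in [0, 1]")


@dataclass
class PermanovaResult:
    pseudo_F: float
    df_between: int
    df_within: int
    r2: float
    p_value: float
    n_perm: int
    seed: int
    ss_among: float = float("nan")
    ss_within: float = float("nan")
    ss_total: float = float("nan")


def jaccard_distance(species_set_a, species_set_b) -> float:
    """Jaccard dissimilarity between two species sets.

    (A + B - 2J) / (A + B - J) with A, B the set sizes and J the number of
    shared species: 0 for identical sets, 1 for disjoint ones.
    """
    a, b = set(species_set_a), set(species_set_b)
    if not a and not b:
        raise ValidationError("Jaccard undefined for two empty sets")
    A, B, J = len(a), len(b), len(a & b)
    return (A + B - 2 * J) / (A + B - J)


def bray_curtis(x: Sequence[float], y: Sequence[float]) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) between count vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("vectors must share the category index")
    denom = float(np.sum(x + y))
    if denom == 0:
        raise ValidationError("Bray-Curtis undefined for two all-zero vectors")
    return float(np.sum(np.abs(x - y)) / denom)


def scat_distance_matrix(
    items: pd.DataFrame,
    mode: str = "species_presence",
    category: str | None = None,
    traits: pd.DataFrame | None = None,
) -> DistanceMatrix:
    """Pairwise dissimilarities between scats.

    Parameters
    ----------
    items : pandas.DataFrame
        Long prey-item table (``scat_id``, ``prey_species``, ...).
    mode : {"species_presence", "category_counts"}
        ``species_presence``: Jaccard on the set of prey species per scat.
        ``category_counts``: Bray-Curtis on per-scat counts of prey
        category levels (requires ``category`` and ``traits``).
    category : str, optional
        Trait column (``water_dependency``, ``feeding_guild``,
        ``size_class``) for ``category_counts`` mode.
    traits : pandas.DataFrame, optional
        Prey-trait table mapping species to category levels.
    """
    ids = items["scat_id"].drop_duplicates().tolist()
    if len(ids) < 2:
        raise ValidationError("need at least 2 scats")
    if mode == "species_presence":
        incidence = (
            pd.crosstab(items["scat_id"], items["prey_species"]).reindex(ids) > 0
        )
        dv = pdist(incidence.to_numpy(bool), metric="jaccard")
        return DistanceMatrix(ids, squareform(dv), "jaccard")
    if mode == "category_counts":
        if category is None or traits is None:
            raise ValidationError("category_counts mode needs category and traits")
        levels = traits.set_index("species")[category]
        missing = sorted(set(items["prey_species"]) - set(levels.index))
        if missing:
            raise ValidationError(f"species missing from trait table: {missing}")
        cat = items["prey_species"].map(levels)
        counts = pd.crosstab(items["scat_id"], cat).reindex(ids)
        dv = pdist(counts.to_numpy(float), metric="braycurtis")
        return DistanceMatrix(ids, squareform(dv), "bray_curtis")
    raise ValueError(f"unknown mode {mode!r}")


def _ss_within(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    ss = 0.0
    for g in range(n_groups):
        mask = codes == g
        ng = mask.sum()
        ss += d2[np.ix_(mask, mask)].sum() / (2.0 * ng)
    return ss


def permanova(
    d: DistanceMatrix | np.ndarray,
    groups: Sequence,
    strata: Sequence | None = None,
    n_perm: int = 1000,
    seed: int = 0,
) -> PermanovaResult:
    """One-factor PERMANOVA with permutations stratified by year.

    The total sum of squares of a distance matrix, SS_total =
    (1/N) sum_{i<j} d_ij^2, is split into among- and within-group parts
    (SS_within = sum over groups of the group's squared distances divided
    by its size).  The pseudo-F statistic

        F = (SS_among / (a - 1)) / (SS_within / (N - a))

    is compared against its permutation distribution: group labels are
    shuffled uniformly, but only within each stratum (here, calendar
    year), and p = (1 + #{F_perm >= F_obs}) / (n_perm + 1).

    A within-group sum of squares of exactly zero (all groups internally
    homogeneous) yields an infinite F; the permutation p-value is still
    reported.
    """
    dm = d.d if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    groups = np.asarray(groups)
    N = dm.shape[0]
    if len(groups) != N:
        raise ValidationError("one group label per observation required")
    labels, codes = np.unique(groups, return_inverse=True)
    a = len(labels)
    if a < 2:
        raise ValidationError("need at least 2 groups")
    group_sizes = np.bincount(codes)
    if (group_sizes < 2).any():
        small = labels[group_sizes < 2].tolist()
        raise ValidationError(f"groups with fewer than 2 members: {small}")
    if strata is None:
        strata = np.zeros(N, dtype=int)
    strata = np.asarray(strata)
    if len(strata) != N:
        raise ValidationError("strata labels must cover all observations")

    d2 = dm**2
    ss_total = d2.sum() / (2.0 * N)
    ss_within = _ss_within(d2, codes, a)
    ss_among = ss_total - ss_within
    df_b, df_w = a - 1, N - a
    if ss_within > 0:
        f_obs = (ss_among / df_b) / (ss_within / df_w)
    else:
        f_obs = float("inf")

    rng = np.random.default_rng(seed)
    strata_idx = [np.flatnonzero(strata == s) for s in np.unique(strata)]
    count_ge = 0
    for _ in range(n_perm):
        perm = codes.copy()
        for idx in strata_idx:
            perm[idx] = perm[rng.permutation(idx)]
        ssw = _ss_within(d2, perm, a)
        f_perm = (ss_total - ssw) / df_b / (ssw / df_w) if ssw > 0 else float("inf")
        if f_perm >= f_obs:
            count_ge += 1
    p = (1 + count_ge) / (n_perm + 1)

    return PermanovaResult(
        pseudo_F=float(f_obs),
        df_between=df_b,
        df_within=df_w,
        r2=float(ss_among / ss_total),
        p_value=float(p),
        n_perm=n_perm,
        seed=seed,
        ss_among=float(ss_among),
        ss_within=float(ss_within),
        ss_total=float(ss_total),
    )
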