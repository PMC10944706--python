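"""Pianka diet overlap with a richness-preserving null, and Levins breadth.

The utilization matrix holds, for each predator (row), the proportion of
its diet contributed by each prey species (column); columns span the union
of all prey consumed by any predator in the stratum, so rows share one
resource axis.  Pianka's index is the cosine similarity of two rows;
significance is judged against a null model in which each row's non-zero
utilization values are relocated, values untouched, to a uniformly random
set of columns of the same size — diet breadth (richness) is conserved
while the identity of the prey is randomized.  Levins breadth is the
inverse Simpson concentration of a row, standardised to [0, 1].
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from scatcomp.errors import ValidationError


@dataclass
class UtilizationMatrix:
    """Predator x prey matrix of diet proportions; each row sums to 1."""

    predators: list[str]
    prey: list[str]
    p: np.ndarray

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (len(self.predators), len(self.prey)):
            raise ValidationError("matrix shape does not match labels")
        if (self.p < 0).any():
            raise ValidationError("utilization proportions must be non-negative")
        if not np.allclose(self.p.sum(axis=1), 1.0, atol=1e-12):
            raise ValidationError("each utilization row must sum to 1")

    def row(self, predator: str) -> np.ndarray:
        return self.p[self.predators.index(predator)]


@dataclass
class OverlapResult:
    pair: tuple[str, str]
    O_jk: float
    null_mean: float
    null_sd: float
    p_value: float
    n_iter: int
    seed: int


@dataclass
class BreadthResult:
    predator: str
    B: float
    Bs: float
    n: int


def pianka_overlap(p_j: Sequence[float], p_k: Sequence[float]) -> float:
    """Pianka's niche overlap: sum(p_j p_k) / sqrt(sum p_j^2 * sum p_k^2).

    0 = disjoint diets, 1 = identical utilization (Cauchy-Schwarz bound).
    """
    pj = np.asarray(p_j, dtype=float)
    pk = np.asarray(p_k, dtype=float)
    if pj.shape != pk.shape:
        raise ValidationError("vectors must share the prey index")
    den = np.sqrt((pj**2).sum() * (pk**2).sum())
    if den == 0:
        raise ValidationError("Pianka undefined for a zero utilization vector")
    return float((pj * pk).sum() / den)


def levins_breadth(p_j: Sequence[float], n: int | None = None) -> BreadthResult:
    """Levins niche breadth B = 1/sum(p^2), standardised Bs = (B-1)/(n-1).

    ``n`` is the total number of prey columns on the shared resource axis
    (defaults to the vector length); Bs is 0 for a single-prey diet and 1
    for perfectly even use of all n prey.
    """
    pj = np.asarray(p_j, dtype=float)
    if n is None:
        n = pj.size
    if n < 2:
        raise ValidationError("need at least 2 prey columns for Bs")
    s = float((pj**2).sum())
    if s == 0:
        raise ValidationError("zero utilization vector")
    B = 1.0 / s
    return BreadthResult(predator="", B=B, Bs=(B - 1.0) / (n - 1.0), n=int(n))


def utilization_matrix(fo_by_predator: dict[str, dict[str, float]]) -> UtilizationMatrix:
    """Assemble a utilization matrix from per-predator diet proportion maps.

    Columns are the sorted union of all prey consumed by any predator, so
    every row is expressed on the same resource axis.
    """
    if not fo_by_predator:
        raise ValidationError("no predators supplied")
    prey = sorted({sp for fo in fo_by_predator.values() for sp in fo})
    predators = list(fo_by_predator)
    p = np.zeros((len(predators), len(prey)))
    col = {sp: i for i, sp in enumerate(prey)}
    for r, pred in enumerate(predators):
        for sp, v in fo_by_predator[pred].items():
            p[r, col[sp]] = v
    return UtilizationMatrix(predators=predators, prey=prey, p=p)


def _pair_seed(master_seed: int, name_j: str, name_k: str) -> np.random.SeedSequence:
    # stable per-pair stream: adding predators never perturbs existing pairs
    a, b = sorted((name_j, name_k))
    return np.random.SeedSequence(
        [int(master_seed), zlib.crc32(a.encode()), zlib.crc32(b.encode())]
    )


def _null_overlaps(
    pj: np.ndarray, pk: np.ndarray, n_iter: int, rng: np.random.Generator
) -> np.ndarray:
    """Vectorised richness-preserving null for one predator pair.

    Each iteration independently permutes each row across all columns
    (equivalently: relocates its non-zero values to a uniform random
    column subset of the same size, in random order).  The Pianka
    denominator is permutation-invariant, so only numerators vary.
    """
    n = pj.size
    den = np.sqrt((pj**2).sum() * (pk**2).sum())
    idx_j = np.argsort(rng.random((n_iter, n)), axis=1)
    idx_k = np.argsort(rng.random((n_iter, n)), axis=1)
    return (pj[idx_j] * pk[idx_k]).sum(axis=1) / den


def overlap_null_test(
    U: UtilizationMatrix,
    n_iter: int = 10000,
    seed: int = 0,
    alternative: str = "greater",
) -> list[OverlapResult]:
    """Test each pairwise Pianka overlap against the richness-preserving null.

    For every predator pair, ``n_iter`` null matrices are drawn by
    reshuffling each row's utilization values to random columns (richness
    and values preserved) and the overlap recomputed.  The one-tailed
    p-value is (1 + #{null O >= observed O}) / (n_iter + 1); pass
    ``alternative="two-sided"`` to double the smaller tail.

    The observed matrix is never mutated.  Null streams are derived per
    pair from the master seed, so results for a pair do not change when
    predators are added to the matrix.
    """
    if len(U.predators) < 2:
        raise ValidationError("need at least 2 predators")
    if len(U.prey) < 2:
        raise ValidationError("null model degenerate with a single prey column")
    if alternative not in ("greater", "two-sided"):
        raise ValueError(f"unknown alternative {alternative!r}")
    results = []
    for j in range(len(U.predators)):
        for k in range(j + 1, len(U.predators)):
            name_j, name_k = U.predators[j], U.predators[k]
            obs = pianka_overlap(U.p[j], U.p[k])
            rng = np.random.default_rng(_pair_seed(seed, name_j, name_k))
            null = _null_overlaps(U.p[j].copy(), U.p[k].copy(), n_iter, rng)
            n_ge = int((null >= obs - 1e-12).sum())
            p_hi = (1 + n_ge) / (n_iter + 1)
            if alternative == "greater":
                p = p_hi
            else:
                n_le = int((null <= obs + 1e-12).sum())
                p = min(1.0, 2 * min(p_hi, (1 + n_le) / (n_iter + 1)))
            results.append(
                OverlapResult(
                    pair=(name_j, name_k),
                    O_jk=obs,
                    null_mean=float(null.mean()),
                    null_sd=float(null.std(ddof=1)),
                    p_value=float(p),
                    n_iter=n_iter,
                    seed=seed,
                )
            )
    return results
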