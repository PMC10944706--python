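"""Jaccard/Bray-Curtis dissimilarities and the stratified PERMANOVA."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from scatcomp import (
    jaccard_distance,
    bray_curtis,
    scat_distance_matrix,
    permanova,
)
from scatcomp.errors import ValidationError


class TestJaccard:
    def test_identical_sets_zero(self):
        assert jaccard_distance({"a", "b"}, {"a", "b"}) == 0

    def test_disjoint_sets_one(self):
        assert jaccard_distance({"a"}, {"b", "c"}) == 1

    def test_worked_example(self):
        assert jaccard_distance(
            {"kudu", "impala"}, {"kudu", "duiker", "steenbok"}
        ) == pytest.approx(0.75)

    def test_both_empty_rejected(self):
        with pytest.raises(ValidationError):
            jaccard_distance(set(), set())

    @given(
        st.sets(st.integers(0, 8)), st.sets(st.integers(0, 8)), st.sets(st.integers(0, 8))
    )
    def test_metric_axioms(self, a, b, c):
        sets = [s for s in (a, b, c)]
        if not all(sets):
            return
        dab = jaccard_distance(a, b)
        assert 0 <= dab <= 1
        assert dab == jaccard_distance(b, a)
        assert jaccard_distance(a, a) == 0
        # triangle inequality (Jaccard distance is a true metric)
        assert dab <= jaccard_distance(a, c) + jaccard_distance(c, b) + 1e-12


class TestBrayCurtis:
    def test_identity(self):
        assert bray_curtis([3, 1, 2], [3, 1, 2]) == 0

    def test_no_shared_abundance(self):
        assert bray_curtis([1, 0], [0, 1]) == 1

    def test_worked_example(self):
        assert bray_curtis([2, 1], [1, 1]) == pytest.approx(0.2)

    def test_both_zero_rejected(self):
        with pytest.raises(ValidationError):
            bray_curtis([0, 0], [0, 0])

    @given(
        st.lists(st.integers(0, 20), min_size=3, max_size=3),
        st.lists(st.integers(0, 20), min_size=3, max_size=3),
    )
    def test_bounds_and_symmetry(self, x, y):
        if sum(x) + sum(y) == 0:
            return
        d = bray_curtis(x, y)
        assert 0 <= d <= 1
        assert d == pytest.approx(bray_curtis(y, x))


def items_frame(scat_species: dict[str, list[str]]) -> pd.DataFrame:
    rows = [
        {"scat_id": sid, "prey_species": sp}
        for sid, species in scat_species.items()
        for sp in species
    ]
    return pd.DataFrame(rows)


class TestScatDistanceMatrix:
    def test_identical_single_species_scats(self):
        dm = scat_distance_matrix(items_frame({"s1": ["kudu"], "s2": ["kudu"]}))
        assert dm.d[0, 1] == 0

    def test_pairwise_disjoint(self):
        dm = scat_distance_matrix(
            items_frame({"s1": ["a"], "s2": ["b"], "s3": ["c"]})
        )
        off = dm.d[np.triu_indices(3, 1)]
        assert (off == 1).all()

    def test_matches_pairwise_formula(self):
        # compositionality: the matrix equals element-wise pairwise calls
        sets = {
            "s1": ["kudu", "impala"],
            "s2": ["kudu", "duiker", "steenbok"],
            "s3": ["impala"],
            "s4": ["kudu", "impala", "duiker"],
        }
        dm = scat_distance_matrix(items_frame(sets))
        for i, j in itertools.combinations(range(4), 2):
            si, sj = dm.labels[i], dm.labels[j]
            assert dm.d[i, j] == pytest.approx(
                jaccard_distance(set(sets[si]), set(sets[sj]))
            )

    def test_category_counts_matches_bray_curtis(self, toy_traits):
        sets = {
            "s1": ["kudu", "impala"],   # medium 1, high 1
            "s2": ["duiker", "steenbok"],  # low 2
            "s3": ["impala", "buffalo"],  # high 2
        }
        dm = scat_distance_matrix(
            items_frame(sets), "category_counts", "water_dependency", toy_traits
        )
        assert dm.metric == "bray_curtis"
        # s1 (h1,m1) vs s3 (h2): sum|x-y| = 1+1+... -> (1+1)/(2+2) wait:
        # s1 = {high:1, medium:1}, s3 = {high:2}: |1-2|+|1-0| = 2, total 4
        i1, i3 = dm.labels.index("s1"), dm.labels.index("s3")
        assert dm.d[i1, i3] == pytest.approx(bray_curtis([1, 1], [2, 0]))

    def test_single_scat_rejected(self):
        with pytest.raises(ValidationError):
            scat_distance_matrix(items_frame({"s1": ["a"]}))


def random_distance_matrix(rng, n):
    """Random Euclidean-embeddable distance matrix scaled into [0, 1]."""
    pts = rng.random((n, 4))
    d = np.sqrt(((pts[:, None] - pts[None, :]) ** 2).sum(-1))
    return d / (d.max() + 1e-9)


class TestPermanova:
    def test_ss_decomposition_identity(self):
        rng = np.random.default_rng(0)
        d = random_distance_matrix(rng, 12)
        groups = ["a"] * 6 + ["b"] * 6
        res = permanova(d, groups, n_perm=99, seed=1)
        assert res.ss_among + res.ss_within == pytest.approx(res.ss_total, abs=1e-9)
        assert res.r2 == pytest.approx(res.ss_among / res.ss_total)

    def test_matches_exhaustive_enumeration(self):
        # N = 6, two groups of 3, one stratum: compare the sampled
        # permutation p with the exact p over all 20 label assignments
        rng = np.random.default_rng(7)
        d = random_distance_matrix(rng, 6)
        groups = np.array(["a", "a", "a", "b", "b", "b"])

        def pseudo_f(codes):
            d2 = d**2
            ss_tot = d2.sum() / 12.0
            ssw = 0.0
            for g in ("a", "b"):
                m = codes == g
                ssw += d2[np.ix_(m, m)].sum() / 6.0
            return (ss_tot - ssw) / 1.0 / (ssw / 4.0)

        f_obs = pseudo_f(groups)
        exact = [
            pseudo_f(np.array(p)) for p in set(itertools.permutations(groups))
        ]
        assert len(exact) == 20
        p_exact = sum(f >= f_obs - 1e-12 for f in exact) / 20
        res = permanova(d, groups, n_perm=4000, seed=3)
        assert res.pseudo_F == pytest.approx(f_obs)
        assert res.p_value == pytest.approx(p_exact, abs=0.05)

    def test_pseudo_f_matches_scikit_bio(self):
        from skbio.stats.distance import DistanceMatrix as SkbioDM
        from skbio.stats.distance import permanova as skbio_permanova

        rng = np.random.default_rng(11)
        d = random_distance_matrix(rng, 14)
        d = (d + d.T) / 2
        np.fill_diagonal(d, 0)
        groups = list("aaaaabbbbbcccc")
        ours = permanova(d, groups, n_perm=99, seed=0)
        theirs = skbio_permanova(SkbioDM(d), groups, permutations=99)
        assert ours.pseudo_F == pytest.approx(theirs["test statistic"], rel=1e-9)

    def test_disjoint_groups_minimal_p(self):
        # groups use disjoint species pools but vary internally, so the
        # observed F is the unique maximum over label assignments; the
        # unbalanced design (9 vs 11 scats) means not even a group-label
        # swap can recreate the observed partition, so a random
        # permutation essentially never ties and p attains its floor
        # 1/(n_perm + 1)
        rng = np.random.default_rng(6)
        pool1 = [f"a{i}" for i in range(6)]
        pool2 = [f"b{i}" for i in range(6)]
        items = items_frame(
            {
                f"g1_{i}": sorted(
                    rng.choice(pool1, size=rng.integers(2, 5), replace=False)
                )
                for i in range(9)
            }
            | {
                f"g2_{i}": sorted(
                    rng.choice(pool2, size=rng.integers(2, 5), replace=False)
                )
                for i in range(11)
            }
        )
        dm = scat_distance_matrix(items)
        groups = [lab.split("_")[0] for lab in dm.labels]
        res = permanova(dm, groups, n_perm=199, seed=0)
        assert res.p_value == pytest.approx(1 / 200)

    def test_own_stratum_per_scat_gives_p_one(self):
        rng = np.random.default_rng(2)
        d = random_distance_matrix(rng, 8)
        res = permanova(d, ["a"] * 4 + ["b"] * 4, strata=np.arange(8), n_perm=99, seed=0)
        assert res.p_value == 1.0

    def test_invariant_to_observation_order(self):
        rng = np.random.default_rng(4)
        d = random_distance_matrix(rng, 10)
        groups = np.array(["a"] * 5 + ["b"] * 5)
        perm = rng.permutation(10)
        r1 = permanova(d, groups, n_perm=0, seed=0)
        r2 = permanova(d[np.ix_(perm, perm)], groups[perm], n_perm=0, seed=0)
        assert r1.pseudo_F == pytest.approx(r2.pseudo_F)
        assert r1.r2 == pytest.approx(r2.r2)

    def test_stratified_permutations_stay_within_strata(self):
        # every stratum is single-label, so within-stratum shuffles can
        # never move a label between groups: F_perm == F_obs always, p = 1
        rng = np.random.default_rng(5)
        d = random_distance_matrix(rng, 8)
        groups = ["a", "a", "b", "b", "a", "a", "b", "b"]
        strata = [1, 1, 2, 2, 3, 3, 4, 4]
        res = permanova(d, groups, strata=strata, n_perm=199, seed=0)
        assert res.p_value == 1.0

    def test_type_one_error_calibrated(self):
        # identically distributed groups: p should be uniform; at
        # n_perm = 99 the rejection rate at alpha = .05 is exactly 5%
        # in expectation
        rng = np.random.default_rng(9)
        reject = 0
        n_rep = 200
        for _ in range(n_rep):
            d = random_distance_matrix(rng, 12)
            res = permanova(
                d, ["a"] * 6 + ["b"] * 6, n_perm=99, seed=int(rng.integers(2**31))
            )
            reject += res.p_value <= 0.05
        rate = reject / n_rep
        # 3 sigma binomial band around 0.05
        assert 0.05 - 3 * np.sqrt(0.05 * 0.95 / n_rep) <= rate \
            <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_rep)

    def test_group_size_guard(self):
        rng = np.random.default_rng(1)
        d = random_distance_matrix(rng, 5)
        with pytest.raises(ValidationError):
            permanova(d, ["a", "a", "a", "a", "b"], n_perm=9, seed=0)
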