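"""Distance engine against brute-force and algebraic oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import cryptistat as cs
from cryptistat.io_formats import ValidationError


def _table(values: np.ndarray, chars, cs_col=None, species=None):
    n = len(values)
    values = np.asarray(values, dtype=float)
    if values.min() < 0:  # shift preserves correlations and distances
        values = values - values.min() + 0.1
    df = pd.DataFrame(values, columns=list(chars))
    df.insert(0, "cs", cs_col if cs_col is not None else np.ones(n))
    df.insert(0, "locality_id", "loc")
    df.insert(0, "species", species if species is not None else ["A"] * n)
    df.insert(0, "nest_id", [f"n{i}" for i in range(n)])
    return cs.NestTable(df, tuple(chars))


class TestNormalizeByCS:
    def test_divides_by_row_cs(self):
        t = _table(np.array([[1000.0, 250.0]]), ("CL", "ML"),
                   cs_col=np.array([500.0]))
        out = cs.normalize_by_cs(t)
        assert out.data["CL"].iloc[0] == pytest.approx(2.0)
        assert out.data["ML"].iloc[0] == pytest.approx(0.5)

    def test_characters_equal_to_cs_become_one(self):
        vals = np.full((4, 3), 7.0)
        t = _table(vals, ("a", "b", "c"), cs_col=np.full(4, 7.0))
        np.testing.assert_allclose(cs.normalize_by_cs(t).matrix, 1.0)

    def test_complementary_head_characters_anticorrelate(self, tiny_dataset):
        """CS = (CL + CW)/2, so the normalised pair is strongly negatively
        correlated across nests — the collinearity the pruning must find."""
        norm = cs.normalize_by_cs(tiny_dataset.workers)
        nests = cs.nest_means(norm)
        r = np.corrcoef(nests.data["CL"], nests.data["CW"])[0, 1]
        assert r < -0.8


class TestNestMeans:
    def test_single_worker_nest_is_identity(self):
        t = _table(np.array([[2.0, 3.0]]), ("a", "b"))
        out = cs.nest_means(t)
        np.testing.assert_allclose(out.matrix, [[2.0, 3.0]])

    def test_two_workers_average(self):
        df = pd.DataFrame({
            "nest_id": ["n0", "n0"], "worker_id": ["w1", "w2"],
            "species": ["A", "A"], "locality_id": ["l", "l"],
            "cs": [1.0, 1.0], "a": [2.0, 4.0]})
        out = cs.nest_means(cs.NestTable(df, ("a",)))
        assert out.data["a"].iloc[0] == pytest.approx(3.0)

    def test_matches_per_nest_loop_oracle(self, tiny_dataset):
        workers = tiny_dataset.workers
        out = cs.nest_means(workers)
        for _, row in out.data.iterrows():
            grp = workers.data[workers.data["nest_id"] == row["nest_id"]]
            for c in workers.characters:
                assert row[c] == pytest.approx(grp[c].mean(), rel=1e-12)


class TestPrune:
    def test_duplicate_column_drops_one(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=10)
        t = _table(np.column_stack([x, x, rng.normal(size=10)]),
                   ("a", "b", "c"))
        retained, report = cs.prune_correlated_characters(t, 0.8, seed=1)
        assert len(retained) == 2 and "c" in retained
        assert len(report) == 1

    def test_uncorrelated_characters_untouched(self):
        rng = np.random.default_rng(1)
        t = _table(rng.normal(size=(200, 5)), tuple("abcde"))
        retained, report = cs.prune_correlated_characters(t, 0.8, seed=0)
        assert retained == tuple("abcde") and report == []

    def test_default_simulator_drops_exactly_two(self):
        """At realistic nest counts only the two engineered pairs
        (CL~CW via CS, SPST~MPSP) trip the 0.8 threshold, leaving 29."""
        sc = cs.SimScenario(n_species=10, n_nests_per_species=20,
                            n_workers_per_nest=2, seed=12)
        ds = cs.simulate_dataset(sc)
        nests = cs.nest_means(cs.normalize_by_cs(ds.workers))
        retained, report = cs.prune_correlated_characters(nests, 0.8, seed=12)
        assert len(retained) == 29
        dropped_pairs = {frozenset((d, k)) for d, k, _, _ in report}
        assert dropped_pairs == {frozenset(("CL", "CW")),
                                 frozenset(("SPST", "MPSP"))}

    def test_bad_threshold(self, tiny_dataset):
        nests = cs.nest_means(tiny_dataset.workers)
        with pytest.raises(ValidationError):
            cs.prune_correlated_characters(nests, 1.5)


class TestPCAReduce:
    def test_single_varying_variable(self):
        X = np.column_stack([np.arange(10.0), np.full(10, 3.0)])
        red = cs.pca_reduce(X, 0.8, "covariance")
        assert red.n_retained == 1
        assert red.explained_fractions[0] == pytest.approx(1.0)

    def test_two_independent_standardised_variables_need_two(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(500, 2))
        red = cs.pca_reduce(X, 0.8, "correlation")
        assert red.n_retained == 2

    def test_variance_conservation(self, rng):
        X = rng.normal(size=(50, 10)) @ rng.normal(size=(10, 10))
        red = cs.pca_reduce(X, 1.0, "covariance")
        total = np.var(X - X.mean(axis=0), axis=0, ddof=1).sum()
        comp = np.var(red.component_scores, axis=0, ddof=1).sum()
        assert comp == pytest.approx(total, abs=1e-8 * total)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValidationError):
            cs.pca_reduce(np.ones((5, 3)), 0.8, "covariance")

    def test_full_variance_pca_preserves_euclidean_distances(self, rng):
        """Rotation invariance: at threshold 1.0 under covariance scaling
        the component-space distances equal plain Euclidean distances."""
        X = rng.normal(size=(20, 6))
        red = cs.pca_reduce(X, 1.0, "covariance")
        d_pca = cs.euclidean_distance(red.component_scores).values
        d_raw = cs.euclidean_distance(X - X.mean(axis=0)).values
        np.testing.assert_allclose(d_pca, d_raw, atol=1e-8)

    def test_duplicated_variables_invariant_under_correlation_scaling(self, rng):
        """Duplicating every variable k times rescales correlation-PCA
        distances by sqrt(k) but preserves their relative structure."""
        X = rng.normal(size=(30, 4))
        base = cs.pca_reduce(X, 0.999, "correlation").component_scores
        dup = cs.pca_reduce(np.hstack([X, X, X]), 0.999,
                            "correlation").component_scores
        d0 = cs.euclidean_distance(base).upper_triangle()
        d1 = cs.euclidean_distance(dup).upper_triangle()
        np.testing.assert_allclose(d1, np.sqrt(3.0) * d0, atol=1e-8)


class TestEuclidean:
    def test_three_four_five(self):
        d = cs.euclidean_distance(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert d.values[0, 1] == pytest.approx(5.0)

    def test_identical_rows_zero(self):
        d = cs.euclidean_distance(np.ones((3, 4)))
        np.testing.assert_allclose(d.values, 0.0)

    def test_matches_double_loop_oracle(self, rng):
        X = rng.normal(size=(20, 5))
        d = cs.euclidean_distance(X).values
        for i in range(20):
            for j in range(20):
                brute = np.sqrt(((X[i] - X[j]) ** 2).sum())
                assert d[i, j] == pytest.approx(brute, abs=1e-10)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(arrays(float, (6, 3), elements=st.floats(-100, 100)))
    def test_triangle_inequality(self, X):
        d = cs.euclidean_distance(X).values
        for i, j, k in itertools.permutations(range(6), 3):
            assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


class TestSingleCharacter:
    def test_absolute_difference(self):
        t = _table(np.array([[1.0], [3.5]]), ("a",))
        d = cs.single_character_distance(t, "a")
        assert d.values[0, 1] == pytest.approx(2.5)

    def test_constant_character_all_zero(self):
        t = _table(np.full((4, 1), 2.0), ("a",))
        np.testing.assert_allclose(
            cs.single_character_distance(t, "a").values, 0.0)

    def test_equals_euclidean_on_single_column(self, tiny_dataset):
        nests = cs.nest_means(cs.normalize_by_cs(tiny_dataset.workers))
        char = nests.characters[0]
        d1 = cs.single_character_distance(nests, char)
        d2 = cs.euclidean_distance(
            nests.data[char].to_numpy()[:, None],
            labels=nests.data["nest_id"])
        np.testing.assert_allclose(d1.values, d2.values, atol=1e-12)

    def test_unknown_character(self, tiny_dataset):
        with pytest.raises(ValidationError):
            cs.single_character_distance(tiny_dataset.workers, "nope")


class TestSpeciesMeans:
    def test_worked_example(self):
        vals = np.array([[0.0, 2.0, 3.0], [2.0, 0.0, 5.0], [3.0, 5.0, 0.0]])
        d = cs.DistanceMatrix(("A1", "A2", "B1"), vals)
        summ = cs.species_mean_distances(d, {"A1": "A", "A2": "A", "B1": "B"})
        ia, ib = summ.species.index("A"), summ.species.index("B")
        assert summ.intra[ia] == pytest.approx(2.0)
        assert summ.inter[ia, ib] == pytest.approx(4.0)
        assert np.isnan(summ.intra[ib])  # singleton species

    def test_single_species(self, rng):
        from conftest import random_distance_matrix

        d = random_distance_matrix(rng, 5)
        summ = cs.species_mean_distances(d, {l: "X" for l in d.labels})
        assert summ.species == ("X",)
        assert summ.intra[0] == pytest.approx(d.upper_triangle().mean())

    def test_matches_pair_enumeration_oracle(self, rng):
        from conftest import random_distance_matrix

        d = random_distance_matrix(rng, 12)
        species_of = {l: f"S{i % 3}" for i, l in enumerate(d.labels)}
        summ = cs.species_mean_distances(d, species_of)
        for a, sa in enumerate(summ.species):
            for b, sb in enumerate(summ.species):
                pairs = [d.values[i, j]
                         for i, li in enumerate(d.labels)
                         for j, lj in enumerate(d.labels)
                         if i < j and {species_of[li], species_of[lj]}
                         == ({sa, sb} if sa != sb else {sa})]
                expect = np.mean(pairs)
                got = summ.intra[a] if a == b else summ.inter[a, b]
                assert got == pytest.approx(expect, rel=1e-12)

    def test_invariant_under_entity_permutation(self, rng):
        from conftest import random_distance_matrix

        d = random_distance_matrix(rng, 10)
        species_of = {l: f"S{i % 2}" for i, l in enumerate(d.labels)}
        perm = rng.permutation(10)
        d2 = cs.DistanceMatrix(tuple(d.labels[i] for i in perm),
                               d.values[np.ix_(perm, perm)])
        s1 = cs.species_mean_distances(d, species_of)
        s2 = cs.species_mean_distances(d2, species_of)
        for sp in s1.species:
            i1, i2 = s1.species.index(sp), s2.species.index(sp)
            assert s1.intra[i1] == pytest.approx(s2.intra[i2], rel=1e-12)
            for sq in s1.species:
                assert (s1.inter[i1, s1.species.index(sq)]
                        == pytest.approx(s2.inter[i2, s2.species.index(sq)],
                                         rel=1e-12))


class TestAssembledFamilies:
    def test_disjoint_band_profiles(self):
        vals = np.array([[1, 1, 1, 0, 0, 0]] * 3 + [[0, 0, 0, 1, 1, 1]] * 3)
        aflp = cs.AFLPMatrix(tuple(f"i{k}" for k in range(6)),
                             ("a",) * 3 + ("b",) * 3,
                             tuple(f"L{j}" for j in range(6)), vals)
        summ, _ = cs.phylogenetic_distance(aflp, cs.PipelineConfig())
        ia, ib = summ.species.index("a"), summ.species.index("b")
        assert summ.inter[ia, ib] > 0
        assert summ.intra[ia] == pytest.approx(0.0, abs=1e-9)

    def test_identical_individuals_zero_distances(self):
        vals = np.tile(np.array([1, 0, 1, 1, 0]), (4, 1))
        aflp = cs.AFLPMatrix(tuple(f"i{k}" for k in range(4)),
                             ("a", "a", "b", "b"),
                             tuple(f"L{j}" for j in range(5)), vals)
        summ, _ = cs.phylogenetic_distance(aflp, cs.PipelineConfig())
        assert np.nanmax(np.abs(summ.inter)) == pytest.approx(0.0, abs=1e-12)

    def test_phylo_distance_recovers_tree(self):
        """Species-level AFLP distances rank-correlate with the true
        patristic distances in essentially every replicate."""
        from scipy.stats import spearmanr

        hits = 0
        for s in range(40):
            tree = cs.simulate_species_tree(8, seed=s)
            sc = cs.SimScenario(n_species=8, n_loci=200,
                                n_aflp_individuals_per_species=6, seed=s)
            aflp = cs.simulate_aflp(tree, sc)
            summ, _ = cs.phylogenetic_distance(aflp, cs.PipelineConfig())
            order = [list(tree.labels).index(s2) for s2 in summ.species]
            P = tree.patristic()[np.ix_(order, order)]
            iu = np.triu_indices(len(order), k=1)
            hits += spearmanr(P[iu], summ.inter[iu]).statistic > 0
        assert hits / 40 > 0.95
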