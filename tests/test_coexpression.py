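import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import integrate, special

from teaheterosis import (
    assign_modules,
    co_module_candidates,
    correlation_matrix,
    correlation_p,
    train_som,
    zscore_profiles,
)


def planted_prototype_data(n_per: int = 30, noise: float = 0.05, seed: int = 0):
    """8 well-separated 4-d prototypes with Gaussian jitter."""
    rng = np.random.default_rng(seed)
    protos = np.vstack([np.eye(4), -np.eye(4)])
    x = np.vstack([p + rng.normal(0, noise, (n_per, 4)) for p in protos])
    ids = [f"g{i}" for i in range(len(x))]
    labels = np.repeat(np.arange(8), n_per)
    return pd.DataFrame(x, index=ids), labels


# ---------------------------------------------------------------------------
# SOM training
# ---------------------------------------------------------------------------

class TestTrainSom:
    def test_single_unit_codebook_is_mean_profile(self):
        df = pd.DataFrame([[0.0, 1.0], [2.0, 3.0], [4.0, 5.0]], index=list("abc"))
        model = train_som(df, rows=1, cols=1, epochs=5, seed=0)
        assert model.codebook.shape == (1, 2)
        np.testing.assert_allclose(model.codebook[0], [2.0, 3.0])
        a = assign_modules(model, df)
        assert set(a.unit_of.values()) == {0}

    def test_two_clusters_match_exhaustive_two_means(self):
        """On a 1x2 grid the SOM partition equals the optimal 2-means split."""
        rng = np.random.default_rng(3)
        pts = np.vstack(
            [rng.normal(0, 0.1, (5, 3)), rng.normal(4, 0.1, (5, 3))]
        )
        df = pd.DataFrame(pts, index=[f"g{i}" for i in range(10)])
        model = train_som(df, rows=1, cols=2, epochs=20, seed=0)
        got = assign_modules(model, df)
        # exhaustive 2-means: best within-cluster SS over all 2-partitions
        best, best_ss = None, np.inf
        for mask in itertools.product([0, 1], repeat=10):
            mask = np.array(mask)
            if mask.sum() in (0, 10):
                continue
            ss = sum(
                ((pts[mask == k] - pts[mask == k].mean(axis=0)) ** 2).sum()
                for k in (0, 1)
            )
            if ss < best_ss:
                best, best_ss = mask, ss
        units = np.array([got.unit_of[f"g{i}"] for i in range(10)])
        same = (units == best).all() or (units == 1 - best).all()
        assert same

    def test_quantization_error_improves_over_training(self):
        df, _ = planted_prototype_data()
        model = train_som(df, rows=2, cols=4, epochs=30, seed=1)
        assert model.quantization_errors[-1] <= model.quantization_errors[0]

    def test_deterministic_given_seed(self):
        df, _ = planted_prototype_data()
        m1 = train_som(df, rows=2, cols=4, epochs=10, seed=7)
        m2 = train_som(df, rows=2, cols=4, epochs=10, seed=7)
        np.testing.assert_array_equal(m1.codebook, m2.codebook)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="no input genes"):
            train_som(pd.DataFrame(columns=[0, 1]), rows=1, cols=2)

    def test_non_finite_profile_names_gene(self):
        df = pd.DataFrame([[0.0, 1.0], [np.nan, 2.0]], index=["ok", "bad"])
        with pytest.raises(ValueError, match="bad"):
            train_som(df, rows=1, cols=2)


class TestAssignModules:
    def test_gene_equal_to_codebook_vector_maps_there(self):
        df, _ = planted_prototype_data()
        model = train_som(df, rows=2, cols=4, epochs=20, seed=0)
        probe = pd.DataFrame(model.codebook[5:6], index=["probe"])
        assert assign_modules(model, probe).unit_of["probe"] == 5

    def test_equidistant_tie_broken_to_lowest_unit(self):
        from teaheterosis.coexpression import SomModel

        model = SomModel(
            rows=1, cols=2,
            codebook=np.array([[1.0, 0.0], [-1.0, 0.0]]),
            epochs=1, seed=0,
        )
        probe = pd.DataFrame([[0.0, 5.0]], index=["mid"])
        assert assign_modules(model, probe).unit_of["mid"] == 0

    def test_dimension_mismatch_rejected(self):
        df, _ = planted_prototype_data()
        model = train_som(df, rows=1, cols=2, epochs=2, seed=0)
        with pytest.raises(ValueError, match="dimension"):
            assign_modules(model, pd.DataFrame([[1.0, 2.0]], index=["g"]))

    def test_planted_prototypes_recovered_with_high_purity(self):
        df, labels = planted_prototype_data()
        model = train_som(df, rows=2, cols=4, epochs=30, seed=0)
        a = assign_modules(model, df)
        units = np.array([a.unit_of[g] for g in df.index])
        majority = sum(
            np.bincount(labels[units == u]).max() for u in set(units)
        )
        assert majority / len(labels) >= 0.9


class TestCoModuleCandidates:
    def test_anchor_alone_yields_empty_set(self):
        from teaheterosis.coexpression import ModuleAssignment

        a = ModuleAssignment(rows=1, cols=2, unit_of={"anchor": 0, "tf1": 1})
        assert co_module_candidates(a, {"anchor"}, {"tf1"}) == {"anchor": set()}

    def test_colocated_tfs_returned(self):
        from teaheterosis.coexpression import ModuleAssignment

        unit_of = {"anchor": 3, "tf1": 3, "tf2": 3, "tf3": 3, "tf4": 1, "g": 3}
        a = ModuleAssignment(rows=2, cols=4, unit_of=unit_of)
        out = co_module_candidates(a, {"anchor"}, {"tf1", "tf2", "tf3", "tf4"})
        assert out == {"anchor": {"tf1", "tf2", "tf3"}}

    def test_unknown_anchor_rejected(self):
        from teaheterosis.coexpression import ModuleAssignment

        a = ModuleAssignment(rows=1, cols=1, unit_of={"g": 0})
        with pytest.raises(KeyError, match="ghost"):
            co_module_candidates(a, {"ghost"}, set())


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

class TestCorrelationP:
    def test_published_example(self):
        """r = 0.978 over the four genotype means -> p = 0.022."""
        assert round(correlation_p(0.978, 4), 3) == 0.022

    def test_zero_correlation_p_one(self):
        assert correlation_p(0.0, 10) == pytest.approx(1.0)

    def test_perfect_correlation_p_zero(self):
        assert correlation_p(1.0, 5) == 0.0
        assert correlation_p(-1.0, 5) == 0.0

    def test_too_few_observations_rejected(self):
        with pytest.raises(ValueError):
            correlation_p(0.5, 2)

    def test_matches_t_density_quadrature(self):
        """Cross-check against numerical integration of the t density."""
        r, n = 0.5, 12
        df = n - 2
        t = r * np.sqrt(df) / np.sqrt(1 - r * r)

        def density(x):
            c = special.gamma((df + 1) / 2) / (
                np.sqrt(df * np.pi) * special.gamma(df / 2)
            )
            return c * (1 + x * x / df) ** (-(df + 1) / 2)

        tail, _ = integrate.quad(density, t, np.inf)
        assert correlation_p(r, n) == pytest.approx(2 * tail, rel=1e-6)

    def test_monotone_in_r_and_n(self):
        ps_r = [correlation_p(r, 6) for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert ps_r == sorted(ps_r, reverse=True)
        ps_n = [correlation_p(0.5, n) for n in (4, 8, 16, 32)]
        assert ps_n == sorted(ps_n, reverse=True)


class TestCorrelationMatrix:
    def test_self_and_anti_correlation(self):
        x = [1.0, 2.0, 3.0, 4.0]
        cm = correlation_matrix({"a": x, "b": [-v for v in x]})
        assert cm.r[0, 0] == pytest.approx(1.0)
        assert cm.p[0, 0] == 0.0
        assert cm.r[0, 1] == pytest.approx(-1.0)

    def test_hand_computed_four_point_vectors(self):
        """Pearson r by the covariance formula on hand-listed vectors."""
        vecs = {
            "u": [1.0, 2.0, 4.0, 3.0],
            "v": [2.0, 1.0, 5.0, 4.0],
            "w": [10.0, 8.0, 2.0, 4.0],
        }

        def pearson(a, b):
            a, b = np.asarray(a), np.asarray(b)
            ca, cb = a - a.mean(), b - b.mean()
            return (ca * cb).sum() / np.sqrt((ca**2).sum() * (cb**2).sum())

        cm = correlation_matrix(vecs)
        for (i, ki), (j, kj) in itertools.combinations(enumerate(vecs), 2):
            assert cm.r[i, j] == pytest.approx(pearson(vecs[ki], vecs[kj]))
            assert cm.r[i, j] == cm.r[j, i]

    def test_long_format_export(self):
        cm = correlation_matrix({"a": [1, 2, 3], "b": [3, 2, 1], "c": [1, 3, 2]})
        long = cm.to_long()
        assert len(long) == 3
        assert set(long.columns) == {"a", "b", "r", "p", "n"}


def test_zscore_profiles_flat_rows_become_zero():
    df = pd.DataFrame([[1.0, 1.0, 1.0], [1.0, 2.0, 3.0]], index=["flat", "var"])
    z = zscore_profiles(df)
    np.testing.assert_allclose(z.loc["flat"], 0.0)
    assert z.loc["var"].mean() == pytest.approx(0.0)
    # z-scoring removes additive offsets: assignment is shift-invariant
    z_shifted = zscore_profiles(df + 100.0)
    np.testing.assert_allclose(z.to_numpy(), z_shifted.to_numpy())
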