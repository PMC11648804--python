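"""GGE decomposition and the three biplot views against geometric oracles."""

import numpy as np
import pandas as pd
import pytest

from metstab import (
    cell_means,
    discriminativeness_representativeness,
    gge_decompose,
    gge_views,
    mean_vs_stability,
    random_spec,
    simulate_trial,
    which_won_where,
)
from metstab.ammi import BiplotDecomposition
from metstab.gge import DegenerateConfigurationError, average_environment_axis
from test_ammi import means_from_array


def dec_from_scores(gen: np.ndarray, env: np.ndarray) -> BiplotDecomposition:
    """Wrap explicit 2-D coordinates as a decomposition (λ = 1 ⇒ scores
    equal the supplied coordinates under any SVP exponent)."""
    g, e = len(gen), len(env)
    return BiplotDecomposition(
        model="GGE",
        singular_values=np.array([1.0, 1.0]),
        genotype_basis=pd.DataFrame(
            gen, index=[f"G{i + 1}" for i in range(g)], columns=["PC1", "PC2"]
        ),
        environment_basis=pd.DataFrame(
            env, index=[f"C{j + 1}" for j in range(e)], columns=["PC1", "PC2"]
        ),
        svp_exponent=0.5,
        centering="synthetic coordinates",
    )


class TestDecomposition:
    def test_identical_genotypes_give_zero_matrix(self):
        Y = np.tile(np.array([5.0, 6.0, 7.0, 4.0]), (4, 1))
        dec = gge_decompose(means_from_array(Y))
        assert np.allclose(dec.singular_values, 0.0, atol=1e-10)

    def test_variance_proportions_match_oracle_svd(self):
        spec = random_spec(seed=21, noise_sd=0.0, rep_effect_sd=0.0, grand_mean=50.0)
        table = simulate_trial(spec)
        m = cell_means(table, spec.trait_name)
        dec = gge_decompose(m)
        Y = m.values.to_numpy()
        oracle = np.linalg.svd(Y - Y.mean(axis=0, keepdims=True), compute_uv=False)
        oracle_vp = 100.0 * oracle**2 / np.sum(oracle**2)
        assert np.allclose(dec.variance_proportion, oracle_vp[: dec.n_components],
                           atol=1e-8)
        assert dec.variance_proportion.sum() == pytest.approx(100.0)

    def test_svp_conventions(self, study_table):
        m = cell_means(study_table, "Y")
        gen = gge_decompose(m, svp="genotype")
        env = gge_decompose(m, svp="environment")
        sym = gge_decompose(m, svp="symmetric")
        lam = gen.singular_values
        # genotype-focused: genotype scores carry the full singular value
        assert np.allclose(
            gen.genotype_scores.to_numpy(),
            gen.genotype_basis.to_numpy() * lam,
        )
        assert np.allclose(env.environment_scores.to_numpy(),
                           env.environment_basis.to_numpy() * lam)
        assert np.allclose(sym.genotype_scores.to_numpy(),
                           sym.genotype_basis.to_numpy() * np.sqrt(lam))
        with pytest.raises(ValueError):
            gge_decompose(m, svp="weird")


class TestDiscRep:
    def test_lengths_and_angles_match_trig_oracle(self, rng):
        env = rng.normal(size=(6, 2))
        gen = rng.normal(size=(8, 2))
        dec = dec_from_scores(gen, env)
        out = discriminativeness_representativeness(dec)
        aea = env.mean(axis=0) / np.linalg.norm(env.mean(axis=0))
        for j, label in enumerate(out.index):
            v = env[j]
            assert out.loc[label, "vector_length"] == pytest.approx(np.hypot(*v))
            expected = np.degrees(
                np.arccos(np.clip(v @ aea / np.linalg.norm(v), -1, 1))
            )
            assert out.loc[label, "angle_to_AEA_deg"] == pytest.approx(expected)

    def test_zero_vector_is_type_one(self):
        env = np.array([[0.0, 0.0], [2.0, 0.0], [1.8, 0.3]])
        gen = np.array([[1.0, 0.0], [0.0, 1.0], [-1.0, -1.0]])
        out = discriminativeness_representativeness(dec_from_scores(gen, env))
        assert out.loc["C1", "env_type"] == "I"
        assert out.loc["C1", "vector_length"] == 0.0

    def test_coincident_long_vectors_angle_zero(self):
        env = np.array([[2.0, 0.0], [2.0, 0.0]])
        gen = np.eye(2)
        dec = dec_from_scores(gen, env)
        out = discriminativeness_representativeness(dec)
        assert np.allclose(average_environment_axis(dec), [1.0, 0.0])
        assert np.allclose(out["angle_to_AEA_deg"], 0.0)
        assert (out["env_type"] == "II").all()

    def test_degenerate_aea_raises(self):
        env = np.array([[1.0, 0.0], [-1.0, 0.0]])
        gen = np.eye(2)
        with pytest.raises(DegenerateConfigurationError):
            discriminativeness_representativeness(dec_from_scores(gen, env))


class TestMeanVsStability:
    def test_projection_distance_geometry(self):
        env = np.array([[2.0, 0.0], [1.0, 0.0]])  # AEA = (1, 0)
        gen = np.array([[3.0, 4.0], [0.0, 0.0], [-1.0, 2.0]])
        out = mean_vs_stability(dec_from_scores(gen, env))
        assert out.loc["G1", "mean_projection"] == pytest.approx(3.0)
        assert out.loc["G1", "stability_distance"] == pytest.approx(4.0)
        assert out.loc["G2", "mean_projection"] == 0.0
        assert out.loc["G2", "stability_distance"] == 0.0
        assert bool(out.loc["G1", "above_average"]) is True
        assert bool(out.loc["G3", "above_average"]) is False

    def test_additive_limit_ranking_matches_genotype_means(self):
        """Without GEI the AEA projection orders genotypes exactly like
        their raw means."""
        spec = random_spec(seed=31, gei_rank=0, noise_sd=0.0, rep_effect_sd=0.0,
                           grand_mean=50.0)
        table = simulate_trial(spec)
        m = cell_means(table, spec.trait_name)
        out = mean_vs_stability(gge_decompose(m, svp="genotype"))
        proj_order = out["mean_projection"].sort_values().index.tolist()
        mean_order = m.genotype_means().sort_values().index.tolist()
        assert proj_order == mean_order
        assert np.allclose(out["stability_distance"], 0.0, atol=1e-8)


class TestWhichWonWhere:
    def test_symmetric_triangle(self):
        gen = np.array([[1.0, 0.0], [-0.5, 0.866], [-0.5, -0.866]])
        env = np.array([[1.0, 0.1]])
        sectors, assignments = which_won_where(dec_from_scores(gen, env))
        assert len(sectors) == 3
        assert assignments.loc[0, "winner"] == "G1"
        assert sectors["n_environments"].sum() == 1

    def test_winner_matches_projection_oracle_100_configs(self):
        """Sector winners equal the argmax-projection genotype for ≥ 99%
        of environments over 100 random configurations."""
        rng = np.random.default_rng(77)
        agree = total = 0
        for _ in range(100):
            g = int(rng.integers(4, 12))
            e = int(rng.integers(3, 9))
            gen = rng.normal(size=(g, 2))
            env = rng.normal(size=(e, 2))
            dec = dec_from_scores(gen, env)
            _, assignments = which_won_where(dec)
            for _, row in assignments.iterrows():
                j = int(row["environment"][1:]) - 1
                oracle = f"G{int(np.argmax(gen @ env[j])) + 1}"
                agree += oracle == row["winner"]
                total += 1
        assert agree / total >= 0.99

    def test_rotation_invariance_of_membership(self):
        rng = np.random.default_rng(5)
        gen = rng.normal(size=(7, 2))
        env = rng.normal(size=(5, 2))
        _, base = which_won_where(dec_from_scores(gen, env))
        theta = np.radians(73.0)
        R = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        _, rotated = which_won_where(dec_from_scores(gen @ R.T, env @ R.T))
        assert base["winner"].tolist() == rotated["winner"].tolist()

    def test_every_environment_in_exactly_one_sector(self, study_table):
        m = cell_means(study_table, "Y")
        views = gge_views(m)
        listed = [
            e for envs in views.sectors["environments"] if envs for e in envs.split(";")
        ]
        assert sorted(listed) == [e.label for e in m.environments]
        assert len(views.assignments) == 6

    def test_collinear_scores_degenerate(self):
        gen = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0], [3.0, 3.0]])
        env = np.array([[1.0, 0.0]])
        with pytest.raises(DegenerateConfigurationError):
            which_won_where(dec_from_scores(gen, env))

    def test_vertices_are_hull_vertices(self, study_table):
        from scipy.spatial import ConvexHull

        m = cell_means(study_table, "Y")
        views = gge_views(m)
        pts = views.decomposition.genotype_scores[["PC1", "PC2"]]
        hull = ConvexHull(pts.to_numpy())
        hull_names = {pts.index[i] for i in hull.vertices}
        assert set(views.sectors["vertex_genotype"]) == hull_names
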