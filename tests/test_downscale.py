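import numpy as np
import pytest
from scipy.stats import spearmanr

from drwr import (
    EnvTable,
    GridSpec,
    OccurrenceMatrix,
    RangeMapSet,
    ValidationError,
    direct_downscale,
    fit_downscale_model,
    generate_landscape,
    monotone_signal_config,
    predict_fine,
    rasterize_ranges,
    rwr,
    varimax,
    vrfa_select,
)

# varimax of this loading matrix computed independently with R's
# stats::varimax (normalize=TRUE, eps=1e-12)
VARIMAX_INPUT = np.array(
    [[0.8, 0.1], [0.7, 0.2], [0.6, 0.1], [0.1, 0.9], [0.2, 0.8], [0.1, 0.7]]
)
VARIMAX_R_REFERENCE = np.array(
    [
        [0.8010643059, 0.09108225861],
        [0.7021844525, 0.19218999619],
        [0.6010767149, 0.09331014283],
        [0.1100192744, 0.89883021714],
        [0.2088991278, 0.79772247956],
        [0.1077913902, 0.69884262620],
    ]
)


class TestVarimax:
    def test_matches_independent_reference_rotation(self):
        rotated, _ = varimax(VARIMAX_INPUT)
        assert np.allclose(rotated, VARIMAX_R_REFERENCE, atol=1e-4)

    def test_rotation_preserves_communalities(self):
        rng = np.random.default_rng(0)
        L = rng.normal(size=(12, 3))
        rotated, T = varimax(L)
        assert np.allclose((rotated**2).sum(1), (L**2).sum(1), atol=1e-8)
        assert np.allclose(T @ T.T, np.eye(3), atol=1e-8)


def _block_env(seed=14, n_sites=60):
    """Two independent blocks of 3 near-perfectly correlated variables."""
    rng = np.random.default_rng(seed)
    f1, f2 = rng.normal(size=(2, n_sites))
    cols = [f1, f1 * 1.01 + 1e-3 * rng.normal(size=n_sites), f1 * 0.99,
            f2, f2 * 1.02 + 1e-3 * rng.normal(size=n_sites), f2 * 0.98]
    return EnvTable(
        [f"s{i}" for i in range(n_sites)],
        [f"v{j}" for j in range(6)],
        np.column_stack(cols),
    )


class TestVrfaSelect:
    def test_two_blocks_two_factors_one_pick_each(self):
        model = vrfa_select(_block_env())
        assert model.n_factors == 2
        assert len(model.selected_unique) == 2
        picks = {model.selected_unique[0][:2], model.selected_unique[1][:2]}
        # one pick from {v0,v1,v2}, one from {v3,v4,v5}
        blocks = [{"v0", "v1", "v2"}, {"v3", "v4", "v5"}]
        assert all(any(p in b for b in blocks) for p in model.selected_unique)
        assert not any(
            set(model.selected_unique) <= b for b in blocks
        ), "both picks came from the same correlated block"

    def test_orthogonal_variables_fail_kaiser_criterion(self):
        # centered, exactly orthogonal columns -> correlation = I -> no
        # eigenvalue exceeds 1
        rng = np.random.default_rng(1)
        X = rng.normal(size=(40, 5))
        Q, _ = np.linalg.qr(X - X.mean(axis=0))
        env = EnvTable([f"s{i}" for i in range(40)], [f"v{j}" for j in range(5)], Q)
        with pytest.raises(ValidationError, match="Kaiser criterion"):
            vrfa_select(env)

    def test_constant_variables_dropped_with_warning(self):
        env = _block_env()
        with_const = EnvTable(
            env.sites,
            env.variables + ["flat"],
            np.column_stack([env.values, np.ones(env.n_sites)]),
        )
        with pytest.warns(UserWarning, match="constant"):
            model = vrfa_select(with_const)
        assert "flat" in model.dropped_constant

    def test_too_few_variables_rejected(self):
        env = EnvTable(["a", "b", "c"], ["v0", "v1"], np.random.default_rng(0).normal(size=(3, 2)))
        with pytest.raises(ValidationError, match=">= 3 non-constant"):
            vrfa_select(env)


def _constant_rwr_data(n_sites=20):
    sites = [f"s{i}" for i in range(n_sites)]
    # every site hosts the same two species -> identical RWR everywhere
    occ = OccurrenceMatrix(sites, ["sp1", "sp2"], np.ones((n_sites, 2)))
    rng = np.random.default_rng(0)
    env = EnvTable(sites, ["v0", "v1"], rng.normal(size=(n_sites, 2)))
    return occ, env


class TestFitDownscaleModel:
    def test_constant_response_predicts_constant_zero_importance(self):
        occ, env = _constant_rwr_data()
        with pytest.warns(UserWarning, match="n_trees"):
            model = fit_downscale_model(occ, env, ["v0", "v1"], n_trees=30, seed=0)
        const = rwr(occ).scores[0]
        assert np.allclose(model.predict(env.values), const)
        assert np.allclose(model.importances.to_numpy(), 0.0, atol=1e-12)

    def test_seed_determinism(self, default_landscape):
        ls = default_landscape
        kwargs = dict(n_trees=200, seed=7)
        m1 = fit_downscale_model(ls.occ_coarse, ls.env_coarse, ["env00", "env01"], **kwargs)
        m2 = fit_downscale_model(ls.occ_coarse, ls.env_coarse, ["env00", "env01"], **kwargs)
        assert m1.importances.equals(m2.importances)
        assert np.array_equal(
            predict_fine(m1, ls.env_fine).scores, predict_fine(m2, ls.env_fine).scores
        )
        assert m1.oob_mse == m2.oob_mse

    def test_missing_sites_dropped_and_recorded(self, default_landscape):
        ls = default_landscape
        vals = ls.env_coarse.values.copy()
        vals[3, 0] = np.nan
        env = EnvTable(ls.env_coarse.sites, ls.env_coarse.variables, vals)
        model = fit_downscale_model(ls.occ_coarse, env, ["env00"], n_trees=200, seed=0)
        assert model.dropped_sites == [ls.env_coarse.sites[3]]

    def test_refuses_too_few_sites(self):
        occ, env = _constant_rwr_data(n_sites=8)
        with pytest.raises(ValidationError, match="refusing"):
            fit_downscale_model(occ, env, ["v0"], n_trees=200, seed=0)

    def test_unknown_predictor_rejected(self, default_landscape):
        ls = default_landscape
        with pytest.raises(ValidationError, match="not in environmental table"):
            fit_downscale_model(ls.occ_coarse, ls.env_coarse, ["nope"], seed=0)

    def test_manifest_round_trip(self, tmp_path, default_landscape):
        ls = default_landscape
        model = fit_downscale_model(
            ls.occ_coarse, ls.env_coarse, ["env00", "env01"], n_trees=200, seed=1
        )
        model.write_manifest(tmp_path / "m")
        text = (tmp_path / "m" / "model_manifest.txt").read_text()
        assert "n_trees=200" in text and "predictors=env00,env01" in text
        assert (tmp_path / "m" / "importances.csv").exists()


class TestPredictFine:
    def test_in_sample_identity(self, default_landscape):
        ls = default_landscape
        model = fit_downscale_model(
            ls.occ_coarse, ls.env_coarse, ["env00", "env01"], n_trees=200, seed=2
        )
        vec = predict_fine(model, ls.env_coarse)  # "fine" table = training table
        assert np.allclose(vec.scores, model.fitted_values())

    def test_constant_model_constant_predictions(self):
        occ, env = _constant_rwr_data()
        model = fit_downscale_model(occ, env, ["v0", "v1"], n_trees=200, seed=0)
        vec = predict_fine(model, env)
        assert np.allclose(vec.scores, vec.scores[0])

    def test_missing_predictor_column_rejected(self, default_landscape):
        ls = default_landscape
        model = fit_downscale_model(
            ls.occ_coarse, ls.env_coarse, ["env00"], n_trees=200, seed=0
        )
        bare = EnvTable(ls.env_fine.sites, ["env01"], ls.env_fine.values[:, [2]])
        with pytest.raises(ValidationError, match="lacks predictor"):
            predict_fine(model, bare)

    def test_signal_recovery_on_monotone_landscape(self):
        # occupancy driven by a single gradient: the model should rank fine
        # cells like the true fine RWR and put that gradient first
        ls = generate_landscape(monotone_signal_config(seed=15))
        model = fit_downscale_model(
            ls.occ_coarse, ls.env_coarse,
            ["env00", "env01", "env02", "env03"], n_trees=500, seed=15,
        )
        assert model.oob_r2 > 0.7
        assert model.importances.idxmax() == "env00"
        pred = predict_fine(model, ls.env_fine)
        true = rwr(ls.occ_fine)
        rho = spearmanr(pred.scores, true.scores).statistic
        assert rho >= 0.8


class TestDirectDownscale:
    def test_one_species_everywhere_scores_inverse_cell_count(self):
        grid = GridSpec(4, 4, 2)
        ranges = RangeMapSet(["sp1"], {"sp1": np.arange(16)})
        vec = direct_downscale(ranges, grid)
        assert np.allclose(vec.scores, 1 / 16)
        assert vec.method_tag == "DDC_r"

    def test_single_cell_species_scores_one(self):
        grid = GridSpec(4, 4, 2)
        ranges = RangeMapSet(["sp1"], {"sp1": np.array([6])})
        vec = direct_downscale(ranges, grid)
        assert vec.scores[6] == 1.0 and vec.scores.sum() == 1.0

    def test_equals_rasterize_then_rwr_composition(self):
        grid = GridSpec(25, 25, 5)
        rng = np.random.default_rng(16)
        masks = {}
        for j in range(15):
            r0, c0 = rng.integers(0, 20, 2)
            h, w = rng.integers(1, 6, 2)
            masks[f"sp{j:02d}"] = np.array(
                [r * 25 + c for r in range(r0, r0 + h) for c in range(c0, c0 + w)]
            )
        ranges = RangeMapSet(sorted(masks), masks)
        vec = direct_downscale(ranges, grid)
        oracle = rwr(rasterize_ranges(ranges, grid, "fine"))
        assert vec.sites == oracle.sites
        assert np.allclose(vec.scores, oracle.scores)

    def test_total_mass_is_species_with_nonempty_masks(self, default_landscape):
        ls = default_landscape
        vec = direct_downscale(ls.ranges, ls.grid)
        assert vec.scores.sum() == pytest.approx(len(ls.ranges.nonempty_species()))
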