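import numpy as np
import pandas as pd
import pytest
from matplotlib.path import Path as MplPath

from rollcompact import pls
from rollcompact.design_space import map_targets, project_material, refine_model
from rollcompact.pls import PLSError, fit_pls
from rollcompact.synthetic import make_lvm_fixture


@pytest.fixture(scope="module")
def fixture_model():
    X, Y, _ = make_lvm_fixture(60, noise=0.2, seed=3)
    model = fit_pls(X, Y, 4)
    refined, kept = refine_model(model, X, Y, seed=0)
    return X, Y, model, refined, kept


class TestRefine:
    def test_all_vip_below_cutoff_errors(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(size=(40, 5)), columns=list("abcde"))
        Y = pd.DataFrame(rng.normal(size=(40, 2)), columns=["TS", "SF"])
        model = fit_pls(X, Y, 2)
        with pytest.raises(PLSError):
            refine_model(model, X, Y, vip_cutoff=1e9)

    def test_refined_keeps_informative_columns(self, fixture_model):
        X, Y, model, refined, kept = fixture_model
        assert "P" in kept and len(kept) >= 2
        assert refined.x_columns == kept

    def test_refined_q2_close_to_full(self, fixture_model):
        # discarded variables are noise, so predictivity is preserved
        X, Y, model, refined, _ = fixture_model
        q2_full, _ = pls.cross_validate(X, Y, model.n_components, seed=0)
        assert refined.q2y_cum >= q2_full[-1] - 0.05


class TestMapTargets:
    def test_masks_and_region_consistent(self, fixture_model):
        *_, refined, _ = fixture_model
        dsmap = map_targets(refined, n_grid=101)
        assert np.array_equal(dsmap.region,
                              dsmap.ts_ok & dsmap.sf_ok & dsmap.inside_limit)
        assert 0.0 <= dsmap.area_fraction <= 1.0

    def test_region_points_satisfy_direct_predictions(self, fixture_model):
        """Every grid point inside the region re-checks against a direct
        2-LV prediction of both constraints (exact self-consistency)."""
        *_, refined, _ = fixture_model
        dsmap = map_targets(refined, n_grid=101)
        ii, jj = np.where(dsmap.region)
        t = np.column_stack([dsmap.t1[jj], dsmap.t2[ii]])
        y = refined.predict_from_scores(t, 2)
        ts = y[:, refined.y_columns.index("TS")]
        sf = y[:, refined.y_columns.index("SF")]
        assert (ts >= 1.0).all()
        assert ((sf >= 0.6) & (sf <= 0.8)).all()
        assert (np.linalg.norm(t, axis=1) <= dsmap.radius).all()

    def test_analytical_boundary_agrees_with_grid(self, fixture_model):
        *_, refined, _ = fixture_model
        dsmap = map_targets(refined, n_grid=201)
        if not dsmap.boundary:
            pytest.skip("empty region for this fixture")
        poly = MplPath(np.asarray(dsmap.boundary))
        cell = dsmap.t1[1] - dsmap.t1[0]
        G1, G2 = np.meshgrid(dsmap.t1, dsmap.t2)
        pts = np.column_stack([G1.ravel(), G2.ravel()])
        inside_poly = poly.contains_points(pts).reshape(G1.shape)
        near_edge = poly.contains_points(pts, radius=2.5 * cell).reshape(G1.shape) \
            != poly.contains_points(pts, radius=-2.5 * cell).reshape(G1.shape)
        disagree = (inside_poly != dsmap.region) & ~near_edge
        assert not disagree.any()

    def test_unreachable_target_gives_empty_region(self, fixture_model):
        *_, refined, _ = fixture_model
        dsmap = map_targets(refined, ts_min=1e9, n_grid=51)
        assert not dsmap.region.any()
        assert dsmap.boundary == []
        assert dsmap.area_fraction == 0.0


class TestProjection:
    def test_training_rows_project_to_training_scores(self, fixture_model):
        X, Y, model, refined, _ = fixture_model
        dsmap = map_targets(refined, n_grid=51)
        proj = project_material(refined, X[refined.x_columns], dsmap)
        assert np.allclose(proj[["t1", "t2"]].to_numpy(),
                           refined.T[:, :2], atol=1e-10)

    def test_membership_ignores_discarded_columns(self, fixture_model):
        X, Y, model, refined, _ = fixture_model
        dsmap = map_targets(refined, n_grid=51)
        a = project_material(refined, X, dsmap)           # full column set
        extra = X.copy()
        extra["unrelated"] = 123.0
        b = project_material(refined, extra, dsmap)
        assert a["in_design_space"].equals(b["in_design_space"])

    def test_missing_column_named(self, fixture_model):
        X, Y, model, refined, _ = fixture_model
        dsmap = map_targets(refined, n_grid=51)
        with pytest.raises(PLSError, match="P"):
            project_material(refined, X.drop(columns=["P"]), dsmap)


@pytest.fixture(scope="module")
def library_run(tmp_path_factory):
    from rollcompact import pipeline

    cfg = pipeline.PipelineConfig(
        out_dir=str(tmp_path_factory.mktemp("ds")), seed=0,
        sigma_ts=0.0, sigma_sf=0.0)
    return pipeline.run_pipeline(cfg)


class TestLibraryDesignSpace:

    def test_most_category_i_materials_reach_design_space(self, library_run):
        """On the noiseless library, at least 90% of Category I materials
        have one pressure point projecting inside the design space."""
        b = library_run
        mem = b["membership"].merge(b["truth"][["material_id", "category"]],
                                    on="material_id")
        cat1 = mem[mem.category.str.startswith("I") & ~mem.category.str.startswith("II")]
        frac = cat1.groupby("material_id").in_design_space.any().mean()
        assert frac >= 0.90

    def test_weak_material_projects_outside_everywhere(self, library_run):
        """An extreme Category-III-like observation (no cohesion, minimal
        ribbonability, high strength-porosity slope) stays outside the
        design space at every pressure."""
        b = library_run
        X, refined, dsmap = b["X"], b["refined"], b["dsmap"]
        ext = X.iloc[:5].copy()
        for c in X.columns:
            ext[c] = X[c].median()
        ext["Icd"] = 0.0
        ext["d"] = X["d"].min()
        ext["TS0"] = X["TS0"].min()
        ext["kb"] = X["kb"].quantile(0.9)
        ext["g"] = X["g"].quantile(0.9)
        ext["P"] = [30.0, 50.0, 70.0, 90.0, 110.0]
        proj = project_material(refined, ext, dsmap)
        assert not proj["in_design_space"].any()
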