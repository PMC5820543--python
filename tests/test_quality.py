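import numpy as np
import pytest

from bloomcount.quality import (CellLabel, CountErrorModel, GroundPlane,
                                compute_pcc, expected_miss, filter_plots,
                                fit_ground_mlesac, mlesac_score, pcc_report,
                                rasterize, split_canopy)
from bloomcount.scene_io import PlotBoundary, PointCloud

PLOT = PlotBoundary("p", np.array([[0, 0, 0], [1, 0, 0],
                                   [1, 1, 0], [0, 1, 0]], float))


def _grid_cloud(x0, x1, step=0.01, z=0.5, rng=None):
    xs = np.arange(x0 + step / 2, x1, step)
    ys = np.arange(0 + step / 2, 1, step)
    xx, yy = np.meshgrid(xs, ys)
    pts = np.column_stack([xx.ravel(), yy.ravel(), np.full(xx.size, float(z))])
    return PointCloud(pts)


# ------------------------------------------------------------- rasterize

def test_uniform_cloud_leaves_no_empty_cells():
    grid = rasterize(_grid_cloud(0, 1, step=0.005), PLOT, cell_size=0.013)
    assert not np.isnan(grid.elevation[grid.inside]).any()


def test_half_coverage_gives_half_empty():
    grid = rasterize(_grid_cloud(0, 0.5, step=0.005), PLOT, cell_size=0.013)
    empty_frac = np.isnan(grid.elevation[grid.inside]).mean()
    assert empty_frac == pytest.approx(0.5, abs=0.03)


def test_single_point_fills_one_cell_with_its_elevation():
    grid = rasterize(PointCloud([[0.5, 0.5, 0.7]]), PLOT, cell_size=0.013)
    filled = np.isfinite(grid.elevation[grid.inside])
    assert filled.sum() == 1
    assert np.nanmax(grid.elevation) == pytest.approx(0.7)


def test_cell_keeps_maximum_elevation():
    cloud = PointCloud([[0.5, 0.5, 0.2], [0.5005, 0.5005, 0.9]])
    grid = rasterize(cloud, PLOT, cell_size=0.013)
    assert np.nanmax(grid.elevation) == pytest.approx(0.9)


def test_rasterize_permutation_invariant():
    rng = np.random.default_rng(0)
    pts = rng.uniform(0, 1, (500, 3))
    a = rasterize(PointCloud(pts), PLOT, 0.05)
    b = rasterize(PointCloud(pts[rng.permutation(500)]), PLOT, 0.05)
    assert np.array_equal(a.elevation, b.elevation, equal_nan=True)


def test_empty_plot_is_all_empty_not_error():
    grid = rasterize(PointCloud(np.empty((0, 3))), PLOT, 0.013)
    assert np.isnan(grid.elevation[grid.inside]).all()


# ---------------------------------------------------------------- MLESAC

def _plane_with_outliers(rng, n=400, frac=0.3, z0=0.3, noise=0.004):
    pts = np.column_stack([rng.uniform(0, 2, n), rng.uniform(0, 2, n),
                           z0 + rng.normal(0, noise, n)])
    out = rng.random(n) < frac
    pts[out, 2] += 1.0  # canopy a meter above the ground
    return pts


def test_exact_plane_recovered():
    rng = np.random.default_rng(0)
    pts = np.column_stack([rng.uniform(0, 1, (200, 2)), np.zeros(200)])
    plane = fit_ground_mlesac(pts, iterations=100, seed=1)
    assert np.abs(plane.normal - [0, 0, 1]).max() < 1e-6
    assert abs(plane.offset) < 1e-9


def test_plane_recovered_under_30pct_outliers():
    rng = np.random.default_rng(3)
    plane = fit_ground_mlesac(_plane_with_outliers(rng), iterations=200, seed=7)
    assert abs(plane.height_at(1.0, 1.0) - 0.3) < 0.01
    assert plane.inlier_fraction > 0.6


def test_true_plane_scores_no_worse_than_tilted_plane():
    rng = np.random.default_rng(1)
    pts = _plane_with_outliers(rng)
    span = pts[:, 2].max() - pts[:, 2].min()
    d_true = pts[:, 2] - 0.3
    tilt = np.array([np.sin(np.radians(10)), 0, np.cos(np.radians(10))])
    d_tilt = pts @ tilt - np.median(pts @ tilt)
    assert mlesac_score(d_true, 0.02, span) <= mlesac_score(d_tilt, 0.02, span)


def test_mlesac_deterministic_and_degenerate_cases():
    rng = np.random.default_rng(2)
    pts = _plane_with_outliers(rng)
    a = fit_ground_mlesac(pts, iterations=100, seed=5)
    b = fit_ground_mlesac(pts, iterations=100, seed=5)
    assert np.array_equal(a.normal, b.normal) and a.offset == b.offset
    collinear = np.outer(np.arange(10.0), [1, 1, 0])
    with pytest.raises(ValueError):
        fit_ground_mlesac(collinear, iterations=20, seed=0)
    with pytest.raises(ValueError):
        fit_ground_mlesac(np.zeros((2, 3)))


# ------------------------------------------------------------- split / PCC

FLAT = GroundPlane(normal=np.array([0.0, 0.0, 1.0]), offset=0.0,
                   inlier_fraction=1.0)


def _uniform_grid(z):
    cloud = _grid_cloud(0, 1, step=0.005, z=z)
    return rasterize(cloud, PLOT, cell_size=0.013)


def test_split_canopy_rules():
    labels = split_canopy(_uniform_grid(0.5), FLAT)
    assert (labels[labels != CellLabel.OUTSIDE] == CellLabel.CANOPY).all()
    labels = split_canopy(_uniform_grid(0.0), FLAT)
    assert (labels[labels != CellLabel.OUTSIDE] == CellLabel.GROUND).all()
    # exactly at the threshold stays ground (strict inequality)
    labels = split_canopy(_uniform_grid(0.1), FLAT)
    assert (labels[labels != CellLabel.OUTSIDE] == CellLabel.GROUND).all()


def _labels(n_canopy, n_empty, n_ground=0):
    return np.array([CellLabel.CANOPY] * n_canopy + [CellLabel.EMPTY] * n_empty
                    + [CellLabel.GROUND] * n_ground, dtype=np.int8)


def test_pcc_definition():
    assert compute_pcc(_labels(90, 10)) == pytest.approx(0.9)
    assert compute_pcc(_labels(50, 0, 50)) == 1.0
    assert compute_pcc(_labels(0, 10)) == 0.0
    assert compute_pcc(_labels(0, 0, 20)) == 0.0  # degenerate, defined 0


def test_pcc_monotone_as_empty_cells_fill():
    labels = _labels(40, 30, 10)
    prev = compute_pcc(labels)
    empty_idx = np.flatnonzero(labels == CellLabel.EMPTY)
    for i in empty_idx:
        labels[i] = CellLabel.CANOPY
        now = compute_pcc(labels)
        assert now >= prev
        prev = now
    assert prev == 1.0


# ------------------------------------------------------------ plot filter

def test_filter_plots_strict_threshold():
    import pandas as pd
    table = pd.DataFrame({"plot_id": ["a", "b", "c"],
                          "pcc": [0.79, 0.80, 1.0]})
    retained, report = filter_plots(table, threshold=0.8)
    assert retained == ["b", "c"]
    assert list(report.plot_id) == ["a"]
    retained, report = filter_plots(pd.DataFrame({"plot_id": [], "pcc": []}))
    assert retained == [] and len(report) == 0


def test_pcc_report_columns():
    grid = _uniform_grid(0.5)
    report = pcc_report([(grid, split_canopy(grid, FLAT))])
    assert list(report.columns) == ["plot_id", "n_canopy", "n_ground",
                                    "n_empty", "pcc", "retained"]
    assert report.iloc[0].pcc == 1.0 and bool(report.iloc[0].retained)


# --------------------------------------------------------- binomial model

def test_expected_miss_formulas():
    out = expected_miss(CountErrorModel(n=10, p=0.9))
    assert out["mean_missed"] == pytest.approx(1.0)
    assert out["relative_error"] == pytest.approx(0.1)
    full = expected_miss(CountErrorModel(n=5, p=1.0))
    assert full["distribution"][0] == pytest.approx(1.0)
    assert full["mean_missed"] == 0.0


def test_expected_miss_pmf_moments():
    rng = np.random.default_rng(0)
    for _ in range(20):
        n = int(rng.integers(1, 60))
        p = float(rng.uniform())
        out = expected_miss(CountErrorModel(n=n, p=p))
        pmf = out["distribution"]
        k = np.arange(n + 1)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-9)
        assert (pmf * k).sum() == pytest.approx(n * (1 - p), abs=1e-9)


def test_model_validation():
    with pytest.raises(ValueError):
        CountErrorModel(n=5, p=1.2)
    with pytest.raises(ValueError):
        CountErrorModel(n=-1, p=0.5)
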