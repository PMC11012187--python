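"""Response surfaces, factor grids, Pareto dominance and compromise picks."""

import numpy as np
import pandas as pd
import pytest

import mae_lipidomics as ml
from mae_lipidomics.design import model_matrix
from mae_lipidomics.pareto_opt import (
    ParetoResult,
    SurfaceModel,
    build_grid,
    evaluate_surfaces,
    hypervolume_2d,
    pareto_front,
    select_compromise,
)


def _scores_df(design, c1, c2):
    X = model_matrix(design)
    return pd.DataFrame(
        {"PC1": X @ np.asarray(c1, float), "PC2": X @ np.asarray(c2, float)},
        index=list(design.run_ids),
    )


def test_surfaces_recover_known_coefficients(design):
    rng = np.random.default_rng(0)
    c1, c2 = rng.normal(size=8), rng.normal(size=8)
    s1, s2 = ml.fit_pc_surfaces(design, _scores_df(design, c1, c2))
    assert np.allclose(s1.coef, c1, atol=1e-10)
    assert np.allclose(s2.coef, c2, atol=1e-10)
    assert s1.r2 == pytest.approx(1.0)
    # interpolation: predictions reproduce the scores at the design points
    assert np.allclose(s1.predict(design.coded), model_matrix(design) @ c1)


def test_constant_scores_give_flat_surface(design):
    scores = _scores_df(design, [3.0] + [0] * 7, [0.0] * 8)
    s1, s2 = ml.fit_pc_surfaces(design, scores)
    assert np.allclose(s1.coef[1:], 0.0, atol=1e-12)
    assert s1.coef[0] == pytest.approx(3.0)
    # intercept equals the prediction at coded (0,0,0)
    assert s1.predict([[0, 0, 0]])[0] == pytest.approx(3.0)


def test_misaligned_score_index_rejected(design):
    scores = _scores_df(design, np.ones(8), np.ones(8))
    scores.index = [f"X{i}" for i in range(11)]
    with pytest.raises(ValueError):
        ml.fit_pc_surfaces(design, scores)


@pytest.mark.parametrize("n_levels,expected", [(40, 64000), (2, 8), (5, 125)])
def test_grid_point_counts(design, n_levels, expected):
    grid = build_grid(design.factors, n_levels)
    assert grid.n_points == expected


def test_grid_levels_cover_range_uniformly(design):
    grid = build_grid(design.factors, 7)
    for j, f in enumerate(grid.factors):
        levels = np.unique(grid.real[:, j])
        assert levels[0] == f.low and levels[-1] == f.high
        assert np.allclose(np.diff(levels), np.diff(levels)[0], atol=1e-12)
    assert np.all(grid.coded >= -1 - 1e-12) and np.all(grid.coded <= 1 + 1e-12)


def test_two_level_grid_is_the_corner_set(design):
    grid = build_grid(design.factors, 2)
    assert {tuple(r) for r in grid.coded} == {
        tuple(c) for c in np.array(np.meshgrid(*[[-1, 1]] * 3)).T.reshape(-1, 3)
    }
    with pytest.raises(ValueError):
        build_grid(design.factors, 1)


def test_evaluation_matches_symbolic_expansion(design):
    rng = np.random.default_rng(1)
    c1, c2 = rng.normal(size=8), rng.normal(size=8)
    s1, s2 = SurfaceModel("PC1", c1, 1.0), SurfaceModel("PC2", c2, 1.0)
    grid = build_grid(design.factors, 4)
    pts = evaluate_surfaces(grid, (s1, s2))
    idx = rng.choice(grid.n_points, 10, replace=False)
    for i in idx:
        x1, x2, x3 = grid.coded[i]
        expect = (
            c1[0] + c1[1] * x1 + c1[2] * x2 + c1[3] * x3
            + c1[4] * x1 * x2 + c1[5] * x1 * x3 + c1[6] * x2 * x3
            + c1[7] * x1 * x2 * x3
        )
        assert pts["PC1"].iloc[i] == pytest.approx(expect)


def test_flat_surfaces_collapse_and_linearity_midpoint(design):
    flat = SurfaceModel("PC1", np.array([2.0] + [0] * 7), 1.0)
    grid = build_grid(design.factors, 3)
    pts = evaluate_surfaces(grid, (flat, flat))
    assert pts["PC1"].nunique() == 1
    lin = SurfaceModel("PC1", np.array([0, 1.0, 2.0, -1.0, 0, 0, 0, 0]), 1.0)
    lo = lin.predict([[-1, 0, 0]])[0]
    hi = lin.predict([[1, 0, 0]])[0]
    assert lin.predict([[0, 0, 0]])[0] == pytest.approx((lo + hi) / 2)


# ---------------------------------------------------------------------------
# Pareto dominance
# ---------------------------------------------------------------------------


def _brute_force_front(pts, directions):
    v = pts.copy().astype(float)
    for j, d in enumerate(directions):
        if d == "min":
            v[:, j] = -v[:, j]
    keep = []
    for i in range(len(v)):
        dominated = False
        for j in range(len(v)):
            if i == j:
                continue
            if np.all(v[j] >= v[i]) and np.any(v[j] > v[i]):
                dominated = True
                break
        if not dominated:
            keep.append(i)
    return np.array(keep)


@pytest.mark.parametrize("directions", [("max", "max"), ("max", "min"), ("min", "min")])
def test_front_equals_bruteforce_oracle(directions):
    rng = np.random.default_rng(2)
    pts = rng.normal(size=(500, 2))
    got = pareto_front(pts, directions)
    assert np.array_equal(got, np.sort(_brute_force_front(pts, directions)))


def test_front_trivia():
    assert list(pareto_front(np.array([[3.0, 4.0]]))) == [0]
    line = np.column_stack([np.arange(10.0), np.arange(10.0)])
    assert list(pareto_front(line, ("max", "max"))) == [9]
    with pytest.raises(ValueError):
        pareto_front(np.empty((0, 2)))


def test_exact_duplicate_optima_all_retained():
    pts = np.array([[1.0, 1.0], [1.0, 1.0], [0.0, 0.5], [1.0, 0.5]])
    got = set(pareto_front(pts, ("max", "max")))
    assert got == {0, 1}


def test_front_invariant_under_positive_scaling():
    rng = np.random.default_rng(3)
    pts = rng.normal(size=(400, 2))
    base = pareto_front(pts, ("max", "min"))
    scaled = pts * np.array([3.7, 0.02])
    assert np.array_equal(base, pareto_front(scaled, ("max", "min")))


def test_monotone_surfaces_yield_single_corner_front(design):
    s1 = SurfaceModel("PC1", np.array([0, 1.0, 0.5, 0.25, 0, 0, 0, 0]), 1.0)
    s2 = SurfaceModel("PC2", np.array([0, 0.3, 1.0, 0.6, 0, 0, 0, 0]), 1.0)
    grid = build_grid(design.factors, 6)
    pts = evaluate_surfaces(grid, (s1, s2))
    front = pareto_front(pts[["PC1", "PC2"]].to_numpy(), ("max", "max"))
    assert len(front) == 1
    assert np.allclose(grid.coded[front[0]], [1, 1, 1])


# ---------------------------------------------------------------------------
# compromise and hypervolume
# ---------------------------------------------------------------------------


def _result(points, directions=("max", "max")):
    df = pd.DataFrame(points, columns=["PC1", "PC2"])
    front = pareto_front(points, directions)
    return ParetoResult(df, ("PC1", "PC2"), directions, front)


def test_compromise_on_symmetric_front_is_the_middle():
    pts = np.array([[0, 1], [0.25, 0.75], [0.5, 0.5], [0.75, 0.25], [1, 0]], float)
    # bow the middle outward so every point is non-dominated yet the knee is central
    pts[1:4] += 0.05
    res = select_compromise(_result(pts))
    assert res.compromise_index == 2


def test_single_point_front_returned_directly():
    res = select_compromise(_result(np.array([[2.0, 3.0]])))
    assert res.compromise_index == 0
    assert res.compromise_distance == 0.0


def test_compromise_handles_flat_objective():
    pts = np.array([[0.0, 1.0], [1.0, 1.0], [0.5, 1.0]])
    res = select_compromise(_result(pts))
    assert res.compromise_index == 1  # best in the only varying objective


def test_hypervolume_reference_rectangle():
    front = np.array([[1.0, 1.0]])
    assert hypervolume_2d(front, [0.0, 0.0]) == pytest.approx(1.0)
    stairs = np.array([[1.0, 2.0], [2.0, 1.0]])
    # union of 1x2 and 2x1 rectangles anchored at the origin
    assert hypervolume_2d(stairs, [0.0, 0.0]) == pytest.approx(3.0)


def test_hypervolume_nondecreasing_under_grid_refinement(design):
    rng = np.random.default_rng(4)
    s1 = SurfaceModel("PC1", rng.normal(size=8), 1.0)
    s2 = SurfaceModel("PC2", rng.normal(size=8), 1.0)
    big = evaluate_surfaces(build_grid(design.factors, 17), (s1, s2))
    ref = big[["PC1", "PC2"]].to_numpy().min(axis=0) - 1.0
    hvs = []
    for n in (3, 5, 9, 17):  # nested level sets
        pts = evaluate_surfaces(build_grid(design.factors, n), (s1, s2))[["PC1", "PC2"]].to_numpy()
        hvs.append(hypervolume_2d(pts[pareto_front(pts)], ref))
    assert all(a <= b + 1e-12 for a, b in zip(hvs, hvs[1:]))


# ---------------------------------------------------------------------------
# orientation helpers
# ---------------------------------------------------------------------------


def test_directions_from_loadings():
    loadings = pd.DataFrame(
        {"PC1": [0.8, -0.6], "PC2": [-0.1, 0.9]}, index=["LPI", "PC"]
    )
    assert ml.directions_from_loadings(loadings, ("LPI", "PC")) == ("max", "max")
    assert ml.directions_from_loadings(loadings, ("PC", "LPI")) == ("min", "min")
    with pytest.raises(KeyError):
        ml.directions_from_loadings(loadings, ("nope", "PC"))


def test_split_and_group_surfaces(design, zero_noise_responses):
    fits = [
        ml.fit_ffd(design, zero_noise_responses.data[c], c)
        for c in ("LPC", "LPE", "PC", "PE", "PI")
    ]
    pos, neg = ml.split_by_effect_sign(fits, "b1")
    assert set(pos) == {"LPC", "LPE"}
    assert set(neg) == {"PC", "PE", "PI"}
    ga, gb = ml.group_recovery_surfaces(fits, pos, neg)
    by = {f.response_name: f.coef for f in fits}
    assert np.allclose(ga.coef, (by["LPC"] + by["LPE"]) / 2)
    assert np.allclose(gb.coef, (by["PC"] + by["PE"] + by["PI"]) / 3)
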