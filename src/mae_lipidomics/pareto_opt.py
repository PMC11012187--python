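"""Multi-objective optimization of extraction settings on PC response surfaces.

After the per-subclass factorial fits, the retained responses are projected
onto their first two principal components; a linear-with-interactions model
(the same 8-term coded basis as the factorial fits) is fitted to the PC1 and
PC2 scores over the three factors.  The two surfaces are evaluated on a
dense factor grid (default 40 equally spaced levels per factor — 64,000
points for three factors), the non-dominated (Pareto) set is extracted under
configurable objective senses, and a compromise setting is picked as the
front point nearest to the utopia point in min-max-normalized objective
space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import DesignTable, FactorSpec, model_matrix, real_to_coded

__all__ = [
    "SurfaceModel",
    "FactorGrid",
    "ParetoResult",
    "fit_pc_surfaces",
    "build_grid",
    "evaluate_surfaces",
    "pareto_front",
    "select_compromise",
    "directions_from_loadings",
    "split_by_effect_sign",
    "group_recovery_surfaces",
    "hypervolume_2d",
]


@dataclass(frozen=True)
class SurfaceModel:
    """An 8-term response surface for one PC score over the coded factors."""

    response_name: str
    coef: np.ndarray  # length 8, basis order of design.MODEL_TERMS
    r2: float

    def predict(self, coded) -> np.ndarray:
        return model_matrix(np.asarray(coded, float)) @ self.coef


def fit_pc_surfaces(design: DesignTable, pc_scores) -> tuple[SurfaceModel, SurfaceModel]:
    """OLS surfaces for PC1 and PC2 scores over the design factors.

    ``pc_scores`` is a DataFrame with columns PC1 and PC2 whose index aligns
    with the design run ids (checked).
    """
    scores = pc_scores if isinstance(pc_scores, pd.DataFrame) else pd.DataFrame(pc_scores)
    ids = tuple(str(i) for i in scores.index)
    if ids != design.run_ids:
        raise ValueError(f"PC score rows {ids} do not align with design runs {design.run_ids}")
    X = model_matrix(design)
    out = []
    for name in ("PC1", "PC2"):
        y = scores[name].to_numpy(float)
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        tss = np.sum((y - y.mean()) ** 2)
        r2 = 1.0 - np.sum(resid**2) / tss if tss > 0 else 1.0
        out.append(SurfaceModel(name, beta, float(r2)))
    return out[0], out[1]


@dataclass(frozen=True)
class FactorGrid:
    """Cartesian grid of equally spaced factor levels, endpoints inclusive."""

    factors: tuple[FactorSpec, ...]
    n_levels: int
    real: np.ndarray  # (n_points, k)
    coded: np.ndarray  # (n_points, k)

    @property
    def n_points(self) -> int:
        return self.real.shape[0]


def build_grid(factors, n_levels: int = 40) -> FactorGrid:
    """Equally spaced ``n_levels`` per factor; full cartesian product."""
    factors = tuple(factors)
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    axes = [np.linspace(f.low, f.high, n_levels) for f in factors]
    real = np.array(list(itertools.product(*axes)))
    coded = np.column_stack(
        [real_to_coded(real[:, j], f) for j, f in enumerate(factors)]
    )
    return FactorGrid(factors=factors, n_levels=n_levels, real=real, coded=coded)


def evaluate_surfaces(grid: FactorGrid, surfaces) -> pd.DataFrame:
    """Evaluate both PC surfaces at every grid point (in coded units).

    Returns a DataFrame with one row per grid point: the factor settings in
    real units plus the predicted PC1 and PC2 coordinates.
    """
    s1, s2 = surfaces
    X = model_matrix(grid.coded)
    df = pd.DataFrame(grid.real, columns=[f.name for f in grid.factors])
    df[s1.response_name] = X @ s1.coef
    df[s2.response_name] = X @ s2.coef
    return df


def _orient(values: np.ndarray, directions) -> np.ndarray:
    """Flip minimized objectives so every column is maximized."""
    out = values.astype(float).copy()
    for j, d in enumerate(directions):
        if d not in ("max", "min"):
            raise ValueError(f"direction must be 'max' or 'min', got {d!r}")
        if d == "min":
            out[:, j] = -out[:, j]
    return out


def directions_from_loadings(loadings: pd.DataFrame, favor) -> tuple[str, ...]:
    """Objective senses that make each PC objective favor a named response.

    Which end of a principal component corresponds to which lipid group is a
    property of the data (and of the sign convention), so the objective
    senses cannot be fixed a priori.  ``favor`` names one response per
    component (e.g. a lyso-lipid for PC1 and a ceramide for PC2 when those
    groups pull in opposite directions); each component is then maximized if
    the named response loads positively on it and minimized otherwise, so
    that improving the objective improves that group's recovery.
    """
    dirs = []
    for comp, response in zip(loadings.columns, favor):
        if response not in loadings.index:
            raise KeyError(f"response {response!r} not among the loadings")
        dirs.append("max" if loadings.loc[response, comp] >= 0 else "min")
    return tuple(dirs)


def split_by_effect_sign(fits, term: str = "b1") -> tuple[list[str], list[str]]:
    """Partition responses by the sign of a significant model term.

    Returns the response names with a significant positive coefficient on
    ``term`` and those with a significant negative one (responses where the
    term is not significant belong to neither group).  With the default
    ``b1`` this recovers the antagonistic solvent-to-solid groups — the
    lyso-lipids whose extraction improves with more solvent versus the
    phospholipids and ceramides that behave oppositely.
    """
    pos, neg = [], []
    for fit in fits:
        c = fit.coefficient(term)
        if c.tier == "ns":
            continue
        (pos if c.value > 0 else neg).append(fit.response_name)
    return pos, neg


def group_recovery_surfaces(fits, group_a, group_b) -> tuple[SurfaceModel, SurfaceModel]:
    """Mean-recovery surfaces for two antagonistic subclass groups.

    Because every per-subclass fit shares the 8-term coded basis, the mean
    scaled recovery of a group of subclasses is itself an 8-term surface
    with the averaged coefficients.  Maximizing both group surfaces is the
    signed, group-aligned form of the two-objective optimization: the front
    exposes the solvent-to-solid trade-off between the groups directly,
    independent of the sign convention of the principal components.
    """
    by_name = {f.response_name: f for f in fits}
    surfaces = []
    for label, group in (("group_a", list(group_a)), ("group_b", list(group_b))):
        if not group:
            raise ValueError(f"{label} is empty")
        missing = [g for g in group if g not in by_name]
        if missing:
            raise KeyError(f"no fit for responses {missing}")
        coef = np.mean([by_name[g].coef for g in group], axis=0)
        surfaces.append(SurfaceModel(label, coef, float("nan")))
    return surfaces[0], surfaces[1]


def pareto_front(points, directions=("max", "max")) -> np.ndarray:
    """Indices of the non-dominated points (two objectives).

    Point p dominates q iff p is at least as good in both oriented
    objectives and strictly better in at least one.  Exact ties on both
    coordinates are all retained.  O(n log n) sort-and-scan; returns indices
    sorted ascending.
    """
    pts = np.asarray(points, float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if pts.shape[0] == 0:
        raise ValueError("empty point set")
    v = _orient(pts, directions)
    order = np.lexsort((-v[:, 1], -v[:, 0]))  # f1 desc, then f2 desc
    best_f2 = -np.inf
    kept: set[tuple[float, float]] = set()
    front = []
    for i in order:
        f1, f2 = v[i]
        if f2 > best_f2 or (f1, f2) in kept:
            front.append(i)
            kept.add((f1, f2))
            best_f2 = max(best_f2, f2)
    return np.sort(np.asarray(front))


@dataclass(frozen=True)
class ParetoResult:
    """Evaluated grid, its non-dominated subset, and the compromise pick."""

    points: pd.DataFrame  # evaluate_surfaces output
    objective_names: tuple[str, str]
    directions: tuple[str, str]
    front: np.ndarray  # indices into points
    compromise_index: int | None = None
    compromise_distance: float | None = None

    @property
    def front_points(self) -> pd.DataFrame:
        return self.points.iloc[self.front]

    @property
    def compromise(self) -> pd.Series | None:
        if self.compromise_index is None:
            return None
        return self.points.iloc[self.compromise_index]


def select_compromise(result: ParetoResult) -> ParetoResult:
    """Pick the front point nearest the utopia point.

    Objectives are min-max normalized over the front; the utopia point is
    (1, 1) in oriented normalized space.  A single-point front is returned
    directly.  The rule is a standard "knee" heuristic: it balances the two
    objectives without weighting either.
    """
    if len(result.front) == 0:
        raise ValueError("empty front")
    obj = result.front_points[list(result.objective_names)].to_numpy(float)
    if len(result.front) == 1:
        idx = int(result.front[0])
        return ParetoResult(
            result.points, result.objective_names, result.directions, result.front,
            compromise_index=idx, compromise_distance=0.0,
        )
    v = _orient(obj, result.directions)
    span = v.max(axis=0) - v.min(axis=0)
    span[span == 0] = 1.0  # flat objective: every front point is equally good in it
    z = (v - v.min(axis=0)) / span
    d = np.sqrt(np.sum((z - 1.0) ** 2, axis=1))
    best = int(np.argmin(d))
    return ParetoResult(
        result.points, result.objective_names, result.directions, result.front,
        compromise_index=int(result.front[best]),
        compromise_distance=float(d[best]),
    )


def hypervolume_2d(front_points, reference, directions=("max", "max")) -> float:
    """Dominated hypervolume of a two-objective front w.r.t. a reference point.

    The reference (nadir) point is given on the original objective scale and
    oriented internally; points not dominating the reference contribute 0.
    """
    pts = _orient(np.asarray(front_points, float), directions)
    ref = _orient(np.asarray(reference, float)[None, :], directions)[0]
    pts = pts[(pts[:, 0] > ref[0]) & (pts[:, 1] > ref[1])]
    if len(pts) == 0:
        return 0.0
    # reduce to the non-dominated staircase: f1 descending, keep rising f2
    pts = pts[np.lexsort((-pts[:, 1], -pts[:, 0]))]
    hv = 0.0
    best_f2 = ref[1]
    for f1, f2 in pts:
        if f2 > best_f2:
            hv += (f1 - ref[0]) * (f2 - best_f2)
            best_f2 = f2
    return float(hv)
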