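"""End-to-end workflows: screening, optimization, annotation.

Three orchestrated chains behind one surface (and the CLI):

* ``run_screening`` — labeled solvent-screening table → PCA + UPGMA
  dendrogram + PLS-DA (double cross-validation and bootstrap), emitting the
  score/loading tables, Newick dendrogram, cluster assignments and the
  per-class diagnostic report.
* ``run_optimization`` — design + per-subclass responses → 8-term factorial
  fits → significance table → PCA restricted to the responsive subclasses →
  PC1/PC2 response surfaces → dense factor grid → Pareto front → compromise
  setting.
* ``run_annotation`` — identification export → parsed inventory summary,
  optional method comparison and QC gate.

Every workflow writes its tables as delimited text under an output
directory, together with a JSON run manifest (config snapshot, input
digests, seed, package version, per-stage outputs) from which the numeric
outputs are reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chemometrics import hca_average_linkage, pca, plsda_bootstrap, plsda_double_cv
from .design import DesignTable
from .ffd_model import ResponseTable, fit_ffd, range_scale_responses, significance_table
from .lipid_annotation import (
    compare_methods,
    qc_check,
    read_identification_table,
    summarize_inventory,
)
from .pareto_opt import (
    ParetoResult,
    build_grid,
    directions_from_loadings,
    evaluate_surfaces,
    fit_pc_surfaces,
    group_recovery_surfaces,
    pareto_front,
    select_compromise,
    split_by_effect_sign,
)

__all__ = ["RunManifest", "PipelineError", "run_screening", "run_optimization", "run_annotation"]


class PipelineError(RuntimeError):
    pass


@dataclass
class RunManifest:
    workflow: str
    seed: int | None
    config: dict
    input_digests: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    version: str = __version__

    def add_input(self, name: str, obj) -> None:
        if isinstance(obj, (str, Path)) and Path(obj).exists():
            digest = hashlib.sha256(Path(obj).read_bytes()).hexdigest()
        else:
            digest = hashlib.sha256(
                pd.util.hash_pandas_object(pd.DataFrame(obj)).values.tobytes()
            ).hexdigest()
        self.input_digests[name] = digest

    def write(self, path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "workflow": self.workflow,
                    "seed": self.seed,
                    "config": self.config,
                    "input_digests": self.input_digests,
                    "outputs": self.outputs,
                    "version": self.version,
                },
                indent=2,
                sort_keys=True,
            )
        )


def _outdir(path) -> Path:
    out = Path(path)
    out.mkdir(parents=True, exist_ok=True)
    return out


@dataclass(frozen=True)
class ScreeningBundle:
    pca_model: object
    tree: object
    clusters: pd.DataFrame
    report: pd.DataFrame  # stats × (class, mode)
    manifest: RunManifest


def run_screening(
    screening: pd.DataFrame,
    outdir,
    *,
    seed: int = 0,
    outer_folds: int = 6,
    inner_folds: int = 5,
    max_components: int = 5,
    bootstrap_B: int = 1000,
    cut_height: float = 4.0,
    pca_scale: bool = True,
) -> ScreeningBundle:
    """Solvent-screening diagnostics on a labeled abundance table.

    ``screening`` needs a ``sample_id`` column, a ``solvent`` class label
    column and one column per subclass.  ``cut_height`` is on the linkage
    (squared Euclidean) scale.
    """
    out = _outdir(outdir)
    if "solvent" not in screening.columns:
        raise PipelineError("screening table needs a 'solvent' label column")
    y = screening["solvent"].to_numpy()
    classes = sorted(set(y.tolist()))
    if len(classes) < 3:
        raise PipelineError(f"need >= 3 solvent classes, got {classes}")
    X = screening.drop(columns=[c for c in ("sample_id", "solvent") if c in screening]).astype(float)
    X.index = screening["sample_id"] if "sample_id" in screening else X.index
    if len(X) != len(y):
        raise PipelineError("labels misaligned with abundance rows")

    model = pca(X, center=True, scale=pca_scale)
    model.scores.to_csv(out / "pca_scores.csv")
    model.loadings.to_csv(out / "pca_loadings.csv")
    pd.Series(
        model.explained_variance_pct,
        index=model.scores.columns,
        name="explained_variance_pct",
    ).to_csv(out / "pca_explained_variance.csv")

    scaled = range_scale_responses(X).data
    tree = hca_average_linkage(scaled, labels=X.index.astype(str))
    (out / "dendrogram.nwk").write_text(tree.to_newick() + "\n")
    clusters = pd.DataFrame(
        {"sample_id": X.index, "solvent": y, "cluster": tree.cut(cut_height)}
    )
    clusters.to_csv(out / "clusters.csv", index=False)

    dcv = plsda_double_cv(
        X, y, outer_folds=outer_folds, inner_folds=inner_folds,
        max_components=max_components, seed=seed,
    )
    boot = plsda_bootstrap(X, y, B=bootstrap_B, seed=seed, max_components=max_components)
    report = pd.concat(
        {"double_cv": dcv.stats, "bootstrap": boot.stats}, axis=1
    )  # columns: (mode, class)
    report.to_csv(out / "plsda_report.csv")

    manifest = RunManifest(
        workflow="screening",
        seed=seed,
        config={
            "outer_folds": outer_folds, "inner_folds": inner_folds,
            "max_components": max_components, "bootstrap_B": bootstrap_B,
            "cut_height": cut_height, "pca_scale": pca_scale,
        },
    )
    manifest.add_input("screening", screening)
    manifest.outputs = {
        "pca_scores": "pca_scores.csv", "pca_loadings": "pca_loadings.csv",
        "dendrogram": "dendrogram.nwk", "clusters": "clusters.csv",
        "plsda_report": "plsda_report.csv",
    }
    manifest.write(out / "manifest.json")
    return ScreeningBundle(model, tree, clusters, report, manifest)


@dataclass(frozen=True)
class OptimizationBundle:
    fits: tuple
    significance: object
    pca_model: object
    surfaces: tuple
    result: ParetoResult
    manifest: RunManifest

    @property
    def compromise(self) -> pd.Series:
        return self.result.compromise


def run_optimization(
    design: DesignTable,
    responses: ResponseTable | pd.DataFrame,
    outdir,
    *,
    keep_if_model_p: float = 0.05,
    grid_levels: int = 40,
    objectives: str = "pc",
    directions: tuple[str, str] = ("max", "max"),
    favor: tuple[str, str] | None = None,
    pca_scale: bool = True,
) -> OptimizationBundle:
    """Factorial fits → responsive-subclass PCA → response surfaces → Pareto front.

    Raw responses are [0, 1] range-scaled before fitting; a
    :class:`ResponseTable` with the ``scaled`` flag set is used as-is.

    ``objectives`` selects what the two optimization objectives are:

    * ``"pc"`` — the PC1/PC2 score surfaces.  Which end of each PC favors
      which lipid group depends on the data, so the objective senses are
      configuration: pass ``directions`` explicitly, or name one subclass
      per component in ``favor`` to orient each PC objective toward that
      subclass's recovery (see
      :func:`~mae_lipidomics.pareto_opt.directions_from_loadings`); the
      loadings are persisted so the orientation can be audited.
    * ``"groups"`` — mean-recovery surfaces of the two antagonistic
      subclass groups (positive vs negative significant solvent-to-solid
      effect), both maximized.  This signed, group-aligned objective pair
      exposes the trade-off between the groups directly and is how the
      "extract everything at once" compromise is meant to be read.
    """
    out = _outdir(outdir)
    table = responses if isinstance(responses, ResponseTable) else ResponseTable(responses)
    table.check_alignment(design)
    if not table.scaled:
        table = range_scale_responses(table)

    fits = tuple(
        fit_ffd(design, table.data[col], response_name=col) for col in table.data.columns
    )
    sig = significance_table(fits, keep_if_model_p=keep_if_model_p)
    sig.to_csv(out / "significance_wide.csv", out / "significance_long.csv")
    if not sig.retained:
        raise PipelineError(
            "no subclass shows a significant dependence on the factors; "
            "nothing to optimize"
        )

    responsive = table.data[list(sig.retained)]
    model = pca(responsive, center=True, scale=pca_scale, n_components=2)
    model.scores.to_csv(out / "pc_scores.csv")
    model.loadings.to_csv(out / "pc_loadings.csv")

    s1, s2 = fit_pc_surfaces(design, model.scores[["PC1", "PC2"]])
    if objectives == "pc":
        if favor is not None:
            directions = directions_from_loadings(model.loadings, favor)
        obj_surfaces = (s1, s2)
    elif objectives == "groups":
        retained_fits = [f for f in fits if f.response_name in sig.retained]
        pos, neg = split_by_effect_sign(retained_fits, term="b1")
        if not pos or not neg:
            raise PipelineError(
                "group objectives need responses with significant solvent-to-solid "
                f"effects of both signs (positive: {pos}, negative: {neg})"
            )
        obj_surfaces = group_recovery_surfaces(retained_fits, pos, neg)
        directions = ("max", "max")
    else:
        raise ValueError(f"objectives must be 'pc' or 'groups', got {objectives!r}")

    grid = build_grid(design.factors, n_levels=grid_levels)
    points = evaluate_surfaces(grid, obj_surfaces)
    obj_names = (obj_surfaces[0].response_name, obj_surfaces[1].response_name)
    front_idx = pareto_front(points[list(obj_names)].to_numpy(), directions=directions)
    result = select_compromise(
        ParetoResult(points, obj_names, tuple(directions), front_idx)
    )
    points.iloc[front_idx].to_csv(out / "pareto_front.csv", index=False)
    result.compromise.to_frame("value").to_csv(out / "compromise.csv")

    manifest = RunManifest(
        workflow="optimization",
        seed=None,
        config={
            "keep_if_model_p": keep_if_model_p,
            "grid_levels": grid_levels,
            "n_grid_points": int(grid.n_points),
            "objectives": objectives,
            "objective_names": list(obj_names),
            "directions": list(directions),
            "pca_scale": pca_scale,
            "retained": list(sig.retained),
            "excluded": list(sig.excluded),
        },
    )
    manifest.add_input("responses", table.data)
    manifest.outputs = {
        "significance_wide": "significance_wide.csv",
        "significance_long": "significance_long.csv",
        "pc_scores": "pc_scores.csv", "pc_loadings": "pc_loadings.csv",
        "pareto_front": "pareto_front.csv", "compromise": "compromise.csv",
    }
    manifest.write(out / "manifest.json")
    return OptimizationBundle(fits, sig, model, (s1, s2), result, manifest)


@dataclass(frozen=True)
class AnnotationBundle:
    summary: object
    comparison: pd.DataFrame | None
    qc: object
    manifest: RunManifest


def _summary_frames(summary) -> dict[str, pd.DataFrame]:
    counts = pd.DataFrame(
        sorted(summary.counts.items()), columns=["subclass", "count"]
    )
    pos_rows = []
    for fam, positions in summary.positional.items():
        for pos, tallies in positions.items():
            for taxonomy in ("saturation", "chain_length"):
                for cat, n in sorted(tallies[taxonomy].items()):
                    pos_rows.append(
                        {"family": fam, "sn_position": pos, "taxonomy": taxonomy,
                         "category": cat, "count": n}
                    )
            for fa, n in tallies["top_fa"]:
                pos_rows.append(
                    {"family": fam, "sn_position": pos, "taxonomy": "top_fa",
                     "category": fa, "count": n}
                )
    return {"counts": counts, "positional": pd.DataFrame(pos_rows)}


def run_annotation(
    identification,
    outdir,
    *,
    compare_with=None,
    qc_areas=None,
    rsd_threshold: float = 20.0,
    max_unparseable: float = 0.05,
) -> AnnotationBundle:
    """Inventory summary (+ optional method comparison and QC gate)."""
    out = _outdir(outdir)
    species = read_identification_table(identification, max_unparseable=max_unparseable)
    summary = summarize_inventory(species)
    frames = _summary_frames(summary)
    frames["counts"].to_csv(out / "subclass_counts.csv", index=False)
    frames["positional"].to_csv(out / "positional_tallies.csv", index=False)

    comparison = None
    if compare_with is not None:
        other = read_identification_table(compare_with, max_unparseable=max_unparseable)
        comparison = compare_methods(species, other, names=("a", "b"))
        comparison.to_csv(out / "method_comparison.csv", index=False)

    qc = None
    if qc_areas is not None:
        qc = qc_check(qc_areas, threshold_pct=rsd_threshold)
        qc.table.to_csv(out / "qc_report.csv")

    manifest = RunManifest(
        workflow="annotation",
        seed=None,
        config={"rsd_threshold": rsd_threshold, "max_unparseable": max_unparseable,
                "n_species": summary.n_species, "n_subclasses": summary.n_subclasses},
    )
    manifest.add_input("identification", identification)
    manifest.outputs = {
        "subclass_counts": "subclass_counts.csv",
        "positional_tallies": "positional_tallies.csv",
    }
    if comparison is not None:
        manifest.outputs["method_comparison"] = "method_comparison.csv"
    if qc is not None:
        manifest.outputs["qc_report"] = "qc_report.csv"
    manifest.write(out / "manifest.json")
    return AnnotationBundle(summary, comparison, qc, manifest)
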