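"""End-to-end analysis runs: input CSV to report files.

`analyze` ties the stages together per item and per radius: matched-set
construction, weighted contingency table, full association matrix,
optional category collapse with merge-criteria reports, and optional
permutation nulls for the same-category statistics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .association import association_matrix, permutation_null
from .collapse import DEFAULT_TAU, CollapseSpec, collapse_table, evaluate_collapse
from .contingency import CategoryScheme, build_table, table_long_format
from .dataset import RatingDataset, read_ratings_csv
from .errors import InvalidInputError
from .geometry import NeighborConfig, find_nearest_neighbors
from .report import render_from_long, results_long

__all__ = ["RunConfig", "analyze"]

log = logging.getLogger("cokappa")


@dataclass(frozen=True)
class RunConfig:
    """Settings for one analysis run."""

    input_path: Path
    out_dir: Path
    items: tuple | None = None  # None = all item columns in the file
    radii: tuple = (500.0,)
    distance_metric: str = "planar-euclidean"
    collapse: str | CollapseSpec | None = None
    n_permutations: int = 0
    seed: int = 0
    tau: float = DEFAULT_TAU

    def __post_init__(self) -> None:
        object.__setattr__(self, "input_path", Path(self.input_path))
        object.__setattr__(self, "out_dir", Path(self.out_dir))
        radii = tuple(float(r) for r in self.radii)
        if not radii or any(r <= 0 for r in radii):
            raise InvalidInputError("radius list must be non-empty with positive values")
        object.__setattr__(self, "radii", radii)
        if self.items is not None:
            object.__setattr__(self, "items", tuple(str(i) for i in self.items))
        if self.n_permutations < 0:
            raise InvalidInputError("n_permutations must be >= 0")

    def collapse_spec(self) -> CollapseSpec | None:
        if self.collapse is None:
            return None
        if isinstance(self.collapse, CollapseSpec):
            return self.collapse
        return CollapseSpec.parse(self.collapse)


def _radius_tag(radius: float) -> str:
    return f"r{radius:g}".replace(".", "_")


def _analyze_item(
    data: RatingDataset,
    search,
    item: str,
    cfg: RunConfig,
    out_dir: Path,
    tag: str,
    summary: dict,
) -> None:
    scheme = CategoryScheme(codes=data.codes_used(item))
    table = build_table(search.sets, data, item, scheme)
    matrix = association_matrix(table)
    long_df = results_long(matrix, item=item)

    if cfg.n_permutations > 0:
        perm_sd = {}
        perm_p = {}
        for code in scheme.codes:
            null = permutation_null(
                data, search.sets, item, code, code, cfg.n_permutations, cfg.seed
            )
            observed = matrix.get(code, code).kappa_exact
            perm_sd[code] = null.kappa_sd
            exceed = (abs(null.kappa) >= abs(observed)).mean()
            perm_p[code] = float(min(1.0, (exceed * cfg.n_permutations + 1) / (cfg.n_permutations + 1)))
        long_df["perm_sd"] = [
            perm_sd.get(r.index_cat) if r.index_cat == r.neighbor_cat else None
            for r in long_df.itertuples()
        ]
        long_df["perm_p"] = [
            perm_p.get(r.index_cat) if r.index_cat == r.neighbor_cat else None
            for r in long_df.itertuples()
        ]

    base = out_dir / f"{item}_{tag}"
    long_df.to_csv(f"{base}_results.csv", index=False)
    table_long_format(table, item).to_csv(f"{base}_contingency.csv", index=False)
    with open(f"{base}_table.txt", "w") as fh:
        fh.write(render_from_long(long_df))

    item_summary = {"max_clq_asymmetry": matrix.max_asymmetry}
    log.info("item %s %s: CLQ symmetry diagnostic %.3g", item, tag, matrix.max_asymmetry)

    spec = cfg.collapse_spec()
    if spec is not None:
        spec.validate_against(scheme)
        collapsed = collapse_table(table, spec)
        cmatrix = association_matrix(collapsed)
        clong = results_long(cmatrix, item=f"{item}_collapsed")
        clong.to_csv(f"{base}_collapsed_results.csv", index=False)
        with open(f"{base}_collapsed_table.txt", "w") as fh:
            fh.write(render_from_long(clong))
        reports = []
        for _, codes in spec.groups:
            for i, a in enumerate(codes):
                for b in codes[i + 1 :]:
                    reports.append(evaluate_collapse(table, a, b, tau=cfg.tau))
        with open(f"{base}_collapse_reports.txt", "w") as fh:
            for rep in reports:
                fh.write(rep.summary() + "\n")
        item_summary["collapse_verdicts"] = {
            f"{rep.a}+{rep.b}": rep.verdict for rep in reports
        }
    summary["items"][item] = item_summary


def analyze(cfg: RunConfig) -> dict:
    """Run the full analysis; returns the summary written to summary.json."""
    data = read_ratings_csv(cfg.input_path, items=list(cfg.items) if cfg.items else None)
    items = cfg.items or data.items
    cfg.out_dir.mkdir(parents=True, exist_ok=True)

    run_summary: dict = {"input": str(cfg.input_path), "radii": {}}
    for radius in cfg.radii:
        ncfg = NeighborConfig(max_radius=radius, distance_metric=cfg.distance_metric)
        search = find_nearest_neighbors(data, ncfg)
        if search.n_sets == 0:
            raise InvalidInputError(f"no matched sets within radius {radius} m")
        tag = _radius_tag(radius)
        summary = dict(search.summary())
        summary["items"] = {}
        log.info(
            "radius %g m: %d matched sets, %d raters excluded (median NN distance %.1f m)",
            radius,
            search.n_sets,
            search.n_excluded,
            summary["median_distance_m"],
        )
        for item in items:
            _analyze_item(data, search, item, cfg, cfg.out_dir, tag, summary)
        run_summary["radii"][tag] = summary

    with open(cfg.out_dir / "summary.json", "w") as fh:
        json.dump(run_summary, fh, indent=2)
    return run_summary
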