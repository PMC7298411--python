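"""End-to-end orchestration: dataset → alignment → fields → PLS → reports.

:func:`run_qsar` runs the full 3D-QSAR analysis from a single
:class:`RunConfig` and writes the statistics table, the experimental-vs-
predicted table, contour cube files and a manifest carrying the
serialized config and its hash. :func:`run_cdft` runs the reactivity-
descriptor analysis over a set of orbital files. Both are importable
functions; the ``qsar3d`` command-line tool is a thin wrapper.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np

from . import __version__
from .align import mcs_align_series
from .cdft import descriptor_table, fukui_table, parse_orbital_file
from .fields import assemble_descriptor_matrix, build_grid, stack_blocks
from .io import read_activity_table, read_structures, split_train_test
from .pls import (
    PLSQsarRegressor,
    contour_maps,
    export_contour_cubes,
    model_stats,
    predict_table,
    prediction_report,
    stats_report,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All knobs of one analysis run (serialized into every manifest)."""

    structures: str = ""
    activity: str = ""
    orbitals: Tuple[str, ...] = ()
    methods: Tuple[str, ...] = ("comfa", "comsia")
    template_id: Optional[str] = None
    grid_spacing: float = 0.6
    grid_margin: float = 4.0
    comsia_alpha: float = 0.3
    min_sigma: float = 2.0
    # CoMSIA similarity indices are dimensionless and far smaller than CoMFA
    # probe energies, so the column filter needs its own threshold
    comsia_min_sigma: float = 0.05
    max_components: int = 10
    test_ids: Tuple[str, ...] = ()
    contour_percentiles: Tuple[float, float] = (80.0, 20.0)
    out_dir: str = "qsar3d_out"
    seed: int = 0

    def to_dict(self) -> Dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def parse_config_file(path: Union[str, Path]) -> Dict[str, str]:
    """Flat ``key = value`` config format; '#' starts a comment."""
    out: Dict[str, str] = {}
    for raw in Path(path).read_text().splitlines():
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line: {raw!r}")
        key, val = (s.strip() for s in line.split("=", 1))
        out[key] = val
    return out


def config_from_mapping(mapping: Dict[str, str]) -> RunConfig:
    kwargs: Dict = {}
    for f in dataclasses.fields(RunConfig):
        if f.name not in mapping:
            continue
        raw = mapping[f.name]
        if f.name in ("methods", "test_ids", "orbitals"):
            kwargs[f.name] = tuple(s.strip() for s in str(raw).split(",") if s.strip())
        elif f.name == "contour_percentiles":
            a, b = (float(s) for s in str(raw).split(","))
            kwargs[f.name] = (a, b)
        elif f.type in ("float",):
            kwargs[f.name] = float(raw)
        elif f.type in ("int",):
            kwargs[f.name] = int(raw)
        else:
            kwargs[f.name] = raw
    return RunConfig(**kwargs)


def _write_manifest(out_dir: Path, config: RunConfig, extra: Optional[Dict] = None) -> None:
    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "package_version": __version__,
    }
    if extra:
        manifest.update(extra)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def _stage(name: str, start: float, shape_note: str = "") -> None:
    logger.info("[%s] %.2fs %s", name, time.perf_counter() - start, shape_note)


def run_qsar(config: RunConfig) -> Dict:
    """Full analysis; returns a bundle of in-memory results and writes reports.

    Output files: ``stats.csv`` (model statistics, one column per
    method), ``predictions.csv`` (experimental vs predicted pIC50 with
    residuals), ``contours/<method>/<field>_{favored,disfavored}.cube``
    and ``manifest.json``.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()

    molecules = read_structures(config.structures)
    records = read_activity_table(config.activity)
    by_id = {m.name: m for m in molecules}
    records = [r for r in records if r.compound_id in by_id]
    if not records:
        raise ValueError("no overlap between structures and activity table")
    if config.test_ids:
        split_train_test(records, list(config.test_ids))
    _stage("load", t0, f"{len(molecules)} structures, {len(records)} records")

    if config.template_id is not None:
        template = by_id[str(config.template_id)]
    else:
        template = by_id[max(records, key=lambda r: r.pic50).compound_id]
    t0 = time.perf_counter()
    ordered = [by_id[r.compound_id] for r in records]
    aligned, align_report = mcs_align_series(ordered, template)
    align_report.to_csv(out_dir / "alignment.csv", index=False)
    kept = set(align_report.loc[align_report.status == "aligned", "compound_id"])
    records = [r for r in records if r.compound_id in kept]
    _stage("align", t0, f"{len(aligned)} aligned")

    t0 = time.perf_counter()
    grid = build_grid(aligned, margin=config.grid_margin, spacing=config.grid_spacing)
    train_idx = np.array([r.subset == "train" for r in records])
    y = np.array([r.pic50 for r in records])
    stats_by_method, tables_by_method, results = {}, {}, {}
    for method in config.methods:
        blocks = assemble_descriptor_matrix(
            aligned, grid, method=method, alpha=config.comsia_alpha
        )
        X, block_index = stack_blocks(blocks)
        min_sigma = config.min_sigma if method == "comfa" else config.comsia_min_sigma
        model = PLSQsarRegressor(
            max_components=config.max_components, min_sigma=min_sigma
        )
        model.fit(X[train_idx], y[train_idx], block_index=block_index)
        field_names = [b.field_kind for b in blocks]
        stats_by_method[method] = model_stats(model, field_names)
        tables_by_method[method] = predict_table(model, records, X)
        maps = contour_maps(
            model, grid, blocks,
            favored_pct=config.contour_percentiles[0],
            disfavored_pct=config.contour_percentiles[1],
        )
        export_contour_cubes(out_dir / "contours" / method, maps, template)
        results[method] = {"model": model, "blocks": blocks, "maps": maps}
        logger.info(
            "[%s] onc=%d q2=%.3f r2=%.3f", method,
            model.n_components_, model.q2_, model.r2_,
        )
    _stage("model", t0, f"grid {grid.dims}")

    stats_df = stats_report(stats_by_method)
    stats_df.to_csv(out_dir / "stats.csv", index=False)
    pred_df = prediction_report(tables_by_method)
    pred_df.to_csv(out_dir / "predictions.csv", index=False)
    _write_manifest(out_dir, config, {"n_compounds": len(records),
                                      "grid_dims": list(grid.dims)})
    return {
        "stats": stats_by_method,
        "stats_table": stats_df,
        "predictions": pred_df,
        "per_method": results,
        "grid": grid,
        "records": records,
    }


def run_cdft(config: RunConfig) -> Dict:
    """Reactivity-descriptor run over the configured orbital files.

    Writes ``descriptors.csv`` (μ, η, S, ω per compound, 4 d.p.) and a
    per-atom Fukui CSV for every input carrying N±1 populations.
    """
    if not config.orbitals:
        raise ValueError("no orbital input files configured")
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = []
    for path in config.orbitals:
        fmt = "qm-log" if str(path).endswith((".log", ".out")) else "native-json"
        data.append(parse_orbital_file(path, format=fmt))
    table = descriptor_table(data)
    table.to_csv(out_dir / "descriptors.csv", index=False)
    fukui_written = []
    for d in data:
        if d.has_fukui_data:
            fpath = out_dir / f"fukui_{d.compound_id}.csv"
            fukui_table(d).to_csv(fpath, index=False)
            fukui_written.append(fpath.name)
    _write_manifest(out_dir, config, {"n_compounds": len(data),
                                      "fukui_reports": fukui_written})
    return {"descriptors": table, "orbital_data": data}
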