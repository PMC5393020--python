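"""Case-table parsing, run configuration and pipeline orchestration.

The pipeline per case: generate synthetic geometry -> assemble the
multibody model -> surgical release of the fused levels -> side-bending
flexibility calibration -> for each screw pattern: instrument, run
segmental translation, measure corrected indices and bone-screw forces.
Outputs are CSV/JSON files plus a manifest that records the configuration
hash and seeds, so any run can be reproduced exactly.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import calibration as cal
from . import instrumentation as ins
from . import metrics
from . import model as md
from . import report as rpt
from . import synthetic
from .indices import ClinicalIndices, SCHEMA_COLUMNS

__all__ = ["RunConfig", "read_case_table", "run_pipeline",
           "packaged_case_table", "load_packaged_cases"]

log = logging.getLogger("spinesim")

_NUMERIC = {"age", "height", "weight", "pt_cobb", "mt_cobb", "tll_cobb",
            "pt_bend_left", "pt_bend_right", "mt_bend_left",
            "mt_bend_right", "tll_bend_left", "tll_bend_right",
            "mt_avr", "tll_avr", "kyphosis", "lordosis"}


def packaged_case_table() -> Path:
    """Path of the shipped 10-case clinical-index table."""
    return Path(__file__).parent / "data" / "ais_cohort.csv"


def read_case_table(path) -> list:
    """Parse a case-table CSV into validated :class:`ClinicalIndices`.

    Errors name the offending row and column.  An empty file yields an
    empty list with a logged warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype=str)
    except pd.errors.EmptyDataError:
        log.warning("case table %s is empty", path)
        return []
    missing = [c for c in SCHEMA_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"case table {path}: missing column(s) "
                         f"{', '.join(missing)}")
    if df.empty:
        log.warning("case table %s has no rows", path)
        return []
    out = []
    optional = {c: df[c] for c in ("mt_convexity", "tll_inf_end")
                if c in df.columns}
    for i, row in df.iterrows():
        kw = {}
        for c in SCHEMA_COLUMNS:
            val = row[c]
            if c in _NUMERIC:
                try:
                    val = float(val)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"case table row {i} column {c!r}: "
                        f"non-numeric angle/value {val!r}") from None
            kw[c] = val
        for c, colvals in optional.items():
            if pd.notna(colvals.iloc[i]):
                kw[c] = colvals.iloc[i]
        try:
            out.append(ClinicalIndices(**kw).validate())
        except ValueError as e:
            raise ValueError(f"case table row {i}: {e}") from e
    return out


def load_packaged_cases() -> list:
    return read_case_table(packaged_case_table())


@dataclass
class RunConfig:
    """Everything a full cohort run needs; round-trips through YAML."""

    case_table: str = ""                     # empty -> packaged table
    output_dir: str = "spinesim_out"
    seed: int = 1
    pattern_ids: tuple = (1, 2, 3, 4, 5)
    schedule_steps: int = 20
    connector_k_N_mm: float = ins.CONNECTOR_K_N_MM
    standoff_mm: float = ins.HEAD_STANDOFF_MM
    convex_contour_deg: float = ins.CONVEX_ROD_CONTOUR_DEG
    concave_contour_deg: float = ins.CONCAVE_ROD_CONTOUR_DEG
    rod_node_spacing_mm: float = ins.ROD_NODE_SPACING_MM
    rigid_rods: bool = False
    force_tol_N: float = 0.5
    torque_tol_Nmm: float = 50.0
    bend_t1_moment_Nmm: float = cal.BEND_MOMENT_T1_NMM
    bend_distributed_Nmm: float = cal.BEND_MOMENT_DISTRIBUTED_NMM
    allow_liv_dropout: bool = True
    write_plots: bool = False
    verbosity: str = "info"

    def validate(self):
        if self.case_table and not Path(self.case_table).exists():
            raise ValueError(f"case table not found: {self.case_table}")
        if self.force_tol_N <= 0 or self.torque_tol_Nmm <= 0:
            raise ValueError("solver tolerances must be > 0")
        if self.schedule_steps < 1:
            raise ValueError("schedule_steps must be >= 1")
        return self

    def to_yaml(self, path=None) -> str:
        doc = asdict(self)
        doc["pattern_ids"] = list(self.pattern_ids)
        text = yaml.safe_dump(doc, sort_keys=True)
        if path:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text()) or {}
        if "pattern_ids" in doc:
            doc["pattern_ids"] = tuple(doc["pattern_ids"])
        return cls(**doc).validate()

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str)
            .encode()).hexdigest()[:16]


def prepare_case(indices: ClinicalIndices, params, config: RunConfig,
                 seed=None):
    """Generate geometry, assemble, release and calibrate one case.

    Returns (geometry, corrective-scaled released model, calibration).
    """
    seed = config.seed if seed is None else seed
    geom = synthetic.generate_spine(indices, synthetic._row_seed(
        indices, seed))
    model = md.assemble_model(geom, params)
    load = {"t1_moment": config.bend_t1_moment_Nmm,
            "distributed": config.bend_distributed_Nmm}
    calib = cal.calibrate_patient(model, indices, load=load)
    released = md.apply_surgical_release(model, indices.fused_levels[:-1])
    scaled = released.scaled(cal.corrective_factors(calib, indices))
    return geom, scaled, calib


def run_pipeline(config: RunConfig):
    """Run the whole cohort; returns (CohortSummary, comparisons DataFrame).

    Per-case failures are isolated and recorded in the manifest; the
    remaining cases continue.
    """
    config.validate()
    t_start = time.time()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    cases = (read_case_table(config.case_table) if config.case_table
             else load_packaged_cases())

    params = cal.calibrate_release_partition(
        md.default_stiffness_params(), cal.default_fsu_targets())

    results, preop_reports, patterns, failures = {}, {}, {}, []
    calibs = {}
    import spinesim.solver as solver
    opts = solver.SolverOptions(force_tol=config.force_tol_N,
                                torque_tol=config.torque_tol_Nmm)
    for indices in cases:
        cid = indices.case_id
        try:
            geom, scaled, calib = prepare_case(indices, params, config)
            calibs[cid] = calib
            preop_reports[cid] = metrics.index_report(geom, indices)
            patterns[cid] = ins.patterns_for_case(
                indices, geom, config.pattern_ids,
                allow_liv_dropout=config.allow_liv_dropout)
            rods = ins.default_rods(
                geom, indices, convex_contour=config.convex_contour_deg,
                concave_contour=config.concave_contour_deg,
                node_spacing=config.rod_node_spacing_mm,
                rigid=config.rigid_rods)
            for pid, pat in patterns[cid].items():
                try:
                    res = ins.simulate_segmental_translation(
                        scaled, pat, rods, indices,
                        schedule_steps=config.schedule_steps,
                        connector_k=config.connector_k_N_mm,
                        standoff=config.standoff_mm, options=opts)
                    results[(cid, pid)] = res
                    log.info("case %s pattern %s: MT %.1f deg, mean force "
                             "%.0f N", cid, pid,
                             res.report.mt_cobb if res.report else -1,
                             float(np.mean(res.force_magnitudes()))
                             if res.screw_forces else 0.0)
                except Exception as e:       # isolate per-simulation failure
                    failures.append({"case": cid, "pattern": pid,
                                     "error": f"{type(e).__name__}: {e}"})
                    log.error("case %s pattern %s failed: %s", cid, pid, e)
        except Exception as e:               # isolate per-case failure
            failures.append({"case": cid, "pattern": None,
                             "error": f"{type(e).__name__}: {e}"})
            log.error("case %s failed: %s", cid, e)

    summary = rpt.summarize_cohort(results, preop_reports, patterns)
    comparisons = rpt.compare_patterns(summary)

    summary.indices.to_csv(out / "indices.csv", index=False)
    summary.forces.to_csv(out / "screw_forces.csv", index=False)
    summary.force_stats.to_csv(out / "forces.csv", index=False)
    summary.reductions.to_csv(out / "reductions.csv", index=False)
    comparisons.to_csv(out / "comparisons.csv", index=False)
    for cid, calib in calibs.items():
        calib.to_json(out / f"calibration_case{cid}.json")
    if config.write_plots:
        rpt.plot_force_summary(summary, out / "forces.png")

    from . import __version__
    manifest = {
        "package_version": __version__,
        "config": json.loads(json.dumps(asdict(config), default=str)),
        "config_digest": config.digest(),
        "root_seed": config.seed,
        "n_cases": len(cases),
        "n_simulations": len(results),
        "failures": failures,
        "elapsed_s": round(time.time() - t_start, 1),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return summary, comparisons
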