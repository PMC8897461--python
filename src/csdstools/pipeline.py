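"""End-to-end orchestration: simulate -> classify -> motor -> spines -> glia
-> proteome -> report.

Every stage reads its inputs from the run directory (written by an earlier
stage), so stages can be re-run individually; a missing upstream table is a
dependency error.  All outputs are plain CSV/TSV/TIFF plus a JSON report
carrying row counts, exclusion logs and a provenance block (seed, config
hash, package version).  Given (config, seed) a run is byte-identical.
"""

from __future__ import annotations

import json
import os
import tempfile
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
import tifffile

from . import __version__
from .behavior import CutoffSet, classify_cohort, cohort_phenotype_summary
from .config import RunConfig, config_hash
from .glia import colocalization_fraction, microglia_cell_metrics, threshold_image
from .motor import fit_learning_curve, learning_speed, max_time, reaching_success_rate
from .proteomics import run_all_comparisons
from .spines import (
    SessionSchedule,
    apply_roi_inclusion,
    density_timecourse,
    group_aggregate,
    interval_turnover,
    survival_fraction,
)
from . import synthetic

__all__ = ["run_pipeline", "validate_inputs", "DependencyError"]


class DependencyError(RuntimeError):
    """An enabled stage is missing an upstream output."""


def _atomic_write(path: Path, writer: Callable[[Path], None]) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    os.close(fd)
    try:
        writer(Path(tmp))
        os.replace(tmp, path)
    finally:
        if os.path.exists(tmp):
            os.unlink(tmp)


def _write_table(df: pd.DataFrame, path: Path) -> None:
    sep = "\t" if path.suffix == ".tsv" else ","
    _atomic_write(path, lambda p: df.to_csv(p, sep=sep, index=False))


def _need(path: Path, stage: str) -> Path:
    if not path.exists():
        raise DependencyError(f"stage {stage!r} requires missing input {path.name}")
    return path


def _stage_simulate(cfg: RunConfig, out: Path, report: dict) -> None:
    sim = cfg.sim
    behavior, truth = synthetic.gen_behavior(sim)
    _write_table(behavior, out / "behavior.csv")
    _write_table(truth, out / "behavior_groundtruth.csv")
    rot = synthetic.gen_rotarod(sim, truth)
    _write_table(rot, out / "rotarod.csv")
    reach = synthetic.gen_reaching(sim, truth)
    _write_table(reach, out / "reaching.csv")
    spines, spine_truth = synthetic.gen_spine_timeline(sim, truth)
    _write_table(spines, out / "spines.csv")
    _write_table(spine_truth, out / "spines_groundtruth.csv")
    field = synthetic.gen_microglia_image(sim)
    _atomic_write(out / "microglia.tif", lambda p: tifffile.imwrite(p, field.image))
    stack = np.stack([m.astype(np.uint8) * 255 for m in field.cell_masks])
    _atomic_write(out / "microglia_cells.tif", lambda p: tifffile.imwrite(p, stack, photometric="minisblack"))
    _write_table(field.ground_truth, out / "microglia_groundtruth.csv")
    coloc = synthetic.gen_coloc_image(sim)
    rgb = np.zeros((*coloc.mask_green.shape, 3), np.uint8)
    rgb[..., 0] = coloc.mask_red * 255
    rgb[..., 1] = coloc.mask_green * 255
    _atomic_write(out / "coloc.tif", lambda p: tifffile.imwrite(p, rgb, photometric="rgb"))
    roi_stack = np.stack([r.astype(np.uint8) * 255 for r in coloc.segment_rois])
    _atomic_write(out / "coloc_rois.tif", lambda p: tifffile.imwrite(p, roi_stack, photometric="minisblack"))
    _write_table(coloc.ground_truth, out / "coloc_groundtruth.csv")
    matrix, design, ptruth = synthetic.gen_proteome(sim)
    _atomic_write(out / "proteome.tsv",
                  lambda p: matrix.to_csv(p, sep="\t", index_label="protein"))
    _write_table(design.rename("group").rename_axis("sample").reset_index(),
                 out / "proteome_design.tsv")
    _atomic_write(out / "proteome_groundtruth.tsv",
                  lambda p: ptruth.to_csv(p, sep="\t"))
    report["stages"]["simulate"] = {
        "n_animals": int(len(behavior)),
        "n_spine_rows": int(len(spines)),
        "n_cells": len(field.cell_masks),
        "n_proteins": int(len(matrix)),
    }


def _stage_classify(cfg: RunConfig, out: Path, report: dict) -> None:
    behavior = pd.read_csv(_need(out / "behavior.csv", "classify"))
    cutoffs = CutoffSet(interaction_inclusive=cfg.interaction_cutoff_inclusive)
    labeled = classify_cohort(behavior, cutoffs)
    _write_table(labeled, out / "classification.tsv")
    summary = cohort_phenotype_summary(labeled)
    report["stages"]["classify"] = {
        "counts": summary["counts"],
        "pct_susceptible": summary["pct_susceptible"],
        "pct_excluded_control": summary["pct_excluded_control"],
        "n_excluded": summary["counts"]["excluded_control"],
    }


def _stage_motor(cfg: RunConfig, out: Path, report: dict) -> None:
    rot = pd.read_csv(_need(out / "rotarod.csv", "motor"))
    rows = []
    for aid, sub in rot.groupby("animal_id"):
        times = sub.sort_values("trial")["time_s"].to_numpy()
        fit = fit_learning_curve(times)
        rec = dict(animal_id=aid, t0=fit.t0, tmax=fit.tmax,
                   ls50_param=fit.ls50, h=fit.h, rss=fit.rss,
                   converged=fit.converged, flat=fit.flat,
                   tmax_at_bound=fit.tmax_at_bound,
                   **{k: v for k, v in max_time(times, fit).items()
                      if k == "empirical_max_s"})
        if fit.converged and not fit.flat:
            ls = learning_speed(fit)
            rec["ls50_literal"] = ls.trials
            rec["starts_above_half_max"] = ls.starts_above_half_max
        else:
            rec["ls50_literal"] = np.nan
            rec["starts_above_half_max"] = False
        rows.append(rec)
    _write_table(pd.DataFrame(rows), out / "rotarod_fits.tsv")
    reach = pd.read_csv(_need(out / "reaching.csv", "motor"))
    srows = [
        dict(animal_id=aid, day=day,
             success_pct=reaching_success_rate(sub.sort_values("pellet")["success"]))
        for (aid, day), sub in reach.groupby(["animal_id", "day"])
    ]
    _write_table(pd.DataFrame(srows), out / "reaching_success.tsv")
    report["stages"]["motor"] = {
        "n_fits": len(rows),
        "n_nonconverged": int(sum(not r["converged"] for r in rows)),
    }


def _stage_spines(cfg: RunConfig, out: Path, report: dict) -> None:
    df = pd.read_csv(_need(out / "spines.csv", "spines"))
    schedule = SessionSchedule(tuple(cfg.sim.session_days))
    included, exclusion_log = apply_roi_inclusion(df, schedule)
    _write_table(exclusion_log, out / "spine_exclusions.tsv")
    dens = density_timecourse(included, schedule)
    animal_map = included.drop_duplicates("roi_id").set_index("roi_id")["animal_id"]
    dens["animal_id"] = dens["roi_id"].map(animal_map)
    _write_table(dens, out / "spine_density.tsv")
    days = schedule.session_days
    turn = []
    for a, b in zip(days, days[1:]):
        t = interval_turnover(included, a, b, cfg.turnover_denominator,
                              baseline_day=schedule.baseline_day)
        t.insert(1, "interval", f"{a}->{b}")
        turn.append(t)
    turnover = pd.concat(turn, ignore_index=True)
    turnover["animal_id"] = turnover["roi_id"].map(animal_map)
    _write_table(turnover, out / "spine_turnover.tsv")
    surv_rows = []
    for birth, assess in ((5, [11, 17]), (11, [17])):
        if birth in days:
            rec = survival_fraction(included, birth, assess, schedule)
            for day, frac in rec.survival_fraction.items():
                surv_rows.append(dict(birth_day=birth, assess_day=day,
                                      cohort_size=rec.cohort_size,
                                      surviving=rec.surviving[day],
                                      survival_fraction=frac))
    _write_table(pd.DataFrame(surv_rows), out / "spine_survival.tsv")
    truth = pd.read_csv(out / "behavior_groundtruth.csv") if (out / "behavior_groundtruth.csv").exists() else None
    if truth is not None:
        labels = truth.set_index("animal_id")["planted_phenotype"]
        agg = group_aggregate(dens.dropna(subset=["norm_density_pct"]), labels,
                              ["norm_density_pct", "density_per_um"])
        _write_table(agg, out / "spine_density_groups.tsv")
    report["stages"]["spines"] = {
        "n_rois_in": int(df["roi_id"].nunique()),
        "n_rois_included": int(included["roi_id"].nunique()),
        "n_rois_excluded": int(len(exclusion_log)),
    }


def _stage_glia(cfg: RunConfig, out: Path, report: dict) -> None:
    img = tifffile.imread(_need(out / "microglia.tif", "glia"))
    cells = tifffile.imread(_need(out / "microglia_cells.tif", "glia")) > 0
    mask, thr = threshold_image(img)
    px = cfg.sim.images.pixel_size_um
    rows = []
    for i, cell in enumerate(cells):
        seg = mask & cell  # thresholded pixels of this cell
        m = microglia_cell_metrics(seg, px) if seg.any() else None
        if m is None:
            continue
        rows.append(dict(cell_id=i, ramification_index=m.ramification_index,
                         tree_length_um=m.tree_length_um,
                         spanned_area_um2=m.spanned_area_um2,
                         total_area_um2=m.total_area_um2))
    _write_table(pd.DataFrame(rows), out / "microglia_metrics.tsv")
    rgb = tifffile.imread(_need(out / "coloc.tif", "glia"))
    rois = tifffile.imread(_need(out / "coloc_rois.tif", "glia")) > 0
    red, green = rgb[..., 0] > 0, rgb[..., 1] > 0
    crow = []
    for i, roi in enumerate(rois):
        res = colocalization_fraction(red, green, roi,
                                      roi_length_um=None)
        crow.append(dict(segment_id=i, fraction=res.fraction,
                         n_yellow=res.n_yellow, n_green_only=res.n_green_only,
                         undefined=res.undefined))
    _write_table(pd.DataFrame(crow), out / "coloc_metrics.tsv")
    report["stages"]["glia"] = {
        "threshold": int(thr),
        "n_cells": len(rows),
        "n_segments": len(crow),
        "iba1_coverage": float(mask.mean()),
    }


def _stage_proteome(cfg: RunConfig, out: Path, report: dict) -> None:
    matrix = pd.read_csv(_need(out / "proteome.tsv", "proteome"), sep="\t",
                         index_col="protein")
    design = pd.read_csv(_need(out / "proteome_design.tsv", "proteome"),
                         sep="\t").set_index("sample")["group"]
    res = run_all_comparisons(matrix, design, scope=cfg.min_valid_scope)
    for tag, comp in res["comparisons"].items():
        fname = f"comparison_{tag.replace('/', '_vs_')}.tsv"
        _atomic_write(out / fname,
                      lambda p, t=comp.table: t.to_csv(p, sep="\t", index_label="protein"))
    report["stages"]["proteome"] = res["summary"]


def _stage_report(cfg: RunConfig, out: Path, report: dict) -> None:
    report["provenance"] = {
        "seed": int(cfg.sim.seed),
        "config_hash": config_hash(cfg),
        "csdstools_version": __version__,
    }
    _atomic_write(out / "report.json",
                  lambda p: p.write_text(json.dumps(report, indent=2, sort_keys=True)))


_STAGES = {
    "simulate": _stage_simulate,
    "classify": _stage_classify,
    "motor": _stage_motor,
    "spines": _stage_spines,
    "glia": _stage_glia,
    "proteome": _stage_proteome,
    "report": _stage_report,
}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the enabled stages in canonical order; returns the report."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": {}}
    for name in _STAGES:
        if name in cfg.stages:
            try:
                _STAGES[name](cfg, out, report)
            except DependencyError:
                raise
            except Exception as exc:
                raise RuntimeError(f"stage {name!r} failed: {exc}") from exc
    return report


# ---------------------------------------------------------------------------
# input validation

_SEVERITY_GRID = (1.0, 1.5, 2.0, 2.5, 3.0)


def validate_inputs(paths: dict) -> list[str]:
    """Schema/range checks for input tables; returns violation messages.

    ``paths`` maps kind -> file path for any of: behavior, defeats, rotarod,
    spines.  Checks are line-level and fail-fast per file.
    """
    violations: list[str] = []

    def check(kind, path, columns, row_check):
        try:
            df = pd.read_csv(path)
        except Exception as exc:
            violations.append(f"{kind}: unreadable ({exc})")
            return
        missing = set(columns) - set(df.columns)
        if missing:
            violations.append(f"{kind}: missing columns {sorted(missing)}")
            return
        for i, row in df.iterrows():
            msg = row_check(row)
            if msg:
                violations.append(f"{kind} line {i + 2}: {msg}")

    if "behavior" in paths:
        def _b(row):
            if not 0 <= row["sucrose_preference_pct"] <= 100:
                return f"sucrose preference {row['sucrose_preference_pct']} outside [0, 100] %"
            if not 0 <= row["nestlet_score"] <= 5:
                return f"nestlet score {row['nestlet_score']} outside [0, 5]"
            if row["interaction_time_s"] < 0:
                return f"negative interaction time {row['interaction_time_s']}"
            if row["group"] not in ("control", "stressed"):
                return f"unknown group {row['group']!r}"
            return None
        check("behavior", paths["behavior"],
              ["animal_id", "group", "sucrose_preference_pct", "nestlet_score",
               "interaction_time_s"], _b)
    if "defeats" in paths:
        def _d(row):
            if row["severity"] not in _SEVERITY_GRID:
                return f"severity {row['severity']} off the 0.5-step grid"
            if not 1 <= row["day"] <= 10:
                return f"day {row['day']} outside 1..10"
            return None
        check("defeats", paths["defeats"], ["animal_id", "day", "severity"], _d)
    if "rotarod" in paths:
        def _r(row):
            if not 0 <= row["time_s"] <= 90:
                return f"trial time {row['time_s']} outside [0, 90] s"
            return None
        check("rotarod", paths["rotarod"], ["animal_id", "trial", "time_s"], _r)
    if "spines" in paths:
        def _s(row):
            if row["state"] not in ("present", "absent", "not_imaged"):
                return f"unknown state {row['state']!r}"
            if row["dendrite_length_um"] <= 0:
                return f"non-positive dendrite length {row['dendrite_length_um']}"
            return None
        check("spines", paths["spines"],
              ["roi_id", "animal_id", "spine_id", "session_day", "state",
               "dendrite_length_um"], _s)
    return violations
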