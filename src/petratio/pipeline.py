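"""End-to-end orchestration: simulate → fit → outcomes → reliability → structure.

Each stage reads the previous stage's files, so stages can also be run
standalone (see :mod:`petratio.cli`). All randomness flows from the single
cohort seed; a run manifest records the configuration and library versions.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .kinetics import FitOptions, fit_roi, fit_whole_brain
from .outcomes import build_outcome_table, suv_table
from .reliability import build_reliability_report
from .structure import (
    association_r2,
    interregional_correlation,
    pca_variance_explained,
    region_matrix,
    zscore_within_genotype,
)
from .synthetic import WHOLE_BRAIN, CohortSpec, PlasmaModel, generate_cohort, read_cohort, write_cohort

__all__ = [
    "RunConfig",
    "run_all",
    "summarize",
    "fit_scans",
    "outcomes_from_files",
    "structure_reports",
    "load_config",
    "save_config",
]

log = logging.getLogger("petratio")

BUNDLE_FILES = ("fits.tsv", "outcomes.tsv", "table1.tsv", "table2.tsv",
                "pca.tsv", "correlations.tsv", "manifest.yaml")

FIT_COLUMNS = ("subject", "scan", "roi", "K1", "k2", "k3", "k4", "vB",
               "delay", "vt", "wrss", "converged")


@dataclass
class RunConfig:
    """Everything a full reproducible run needs."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    fit_options: FitOptions = field(default_factory=FitOptions)
    target_roi: str = "frontal_cortex"
    denominators: tuple[str, ...] = ("whole_brain", "cerebellum")
    suv_window: tuple[float, float] = (40.0, 60.0)
    log_level: str = "INFO"

    def __post_init__(self):
        if self.target_roi not in self.cohort.roi_names:
            raise ValueError(f"target ROI {self.target_roi!r} not in cohort ROIs "
                             f"{self.cohort.roi_names}")
        for den in self.denominators:
            if den not in self.cohort.roi_names:
                raise ValueError(f"denominator ROI {den!r} not in cohort ROIs")
        span = max(s + d for s, d in self.cohort.frame_schedule)
        if self.suv_window[1] > span + 1e-9 or self.suv_window[0] < 0:
            raise ValueError(f"SUV window {self.suv_window} outside frame span [0, {span}]")


def fit_scans(scans, options: FitOptions | None = None) -> pd.DataFrame:
    """Two-stage fitting of every scan.

    ``scans`` is a list of (meta, tacs, input_function). The whole-brain
    curve is fitted first with vB and delay free; ROI curves are then
    fitted with those fixed. Returns the long fits table.
    """
    options = options or FitOptions()
    rows = []
    for meta, tacs, inp in scans:
        if WHOLE_BRAIN not in tacs:
            raise ValueError(f"scan {meta.scan_id}: whole-brain TAC required "
                             "for the stage-one fit")
        wb = fit_whole_brain(tacs[WHOLE_BRAIN], inp, options)
        log.info("fit %s whole_brain: vB=%.4f delay=%.3f min vt=%.3f",
                 meta.scan_id, wb.params.vB, wb.params.delay, wb.vt)
        # every ROI — the whole brain included — gets a stage-two fit with
        # the scan-level vB and delay held at the stage-one estimates
        results = {}
        for roi, tac in tacs.items():
            results[roi] = fit_roi(tac, inp, wb.params.vB, wb.params.delay, options)
        for roi, res in results.items():
            p = res.params
            rows.append({"subject": meta.subject_id, "scan": meta.scan_index,
                         "roi": roi, "K1": p.K1, "k2": p.k2, "k3": p.k3,
                         "k4": p.k4, "vB": p.vB, "delay": p.delay, "vt": res.vt,
                         "wrss": res.wrss, "converged": res.converged})
    return pd.DataFrame(rows, columns=list(FIT_COLUMNS))


def outcomes_from_files(fits_path: str | Path, data_dir: str | Path,
                        target_roi: str = "frontal_cortex",
                        window: tuple[float, float] = (40.0, 60.0)) -> pd.DataFrame:
    fits = pd.read_csv(fits_path, sep="\t", comment="#")
    scans = read_cohort(data_dir)
    tacs_by_scan = {m.scan_id: t for m, t, _ in scans}
    metas = [m for m, _, _ in scans]
    return build_outcome_table(fits, tacs_by_scan, metas,
                               target_rois=(target_roi,), window=window)


def structure_reports(fits: pd.DataFrame, scans, target_roi: str,
                      window=(40.0, 60.0)):
    """Correlation matrices, PCA fractions and V_T-association R² tables."""
    metas = [m for m, _, _ in scans]
    tacs_by_scan = {m.scan_id: t for m, t, _ in scans}
    geno = {m.subject_id: m.genotype for m in metas}
    vt_long = fits.copy()
    vt_long["genotype"] = vt_long["subject"].map(geno)

    mat_vt = region_matrix(vt_long, "vt")
    suvs = suv_table(tacs_by_scan, metas, window)
    mat_suv = region_matrix(suvs, "SUV")

    corr_frames = []
    for name, mat in (("VT", mat_vt), ("SUV", mat_suv)):
        c = interregional_correlation(mat).reset_index(names="roi")
        c.insert(0, "measure", name)
        corr_frames.append(c)
    correlations = pd.concat(corr_frames, ignore_index=True)

    z = zscore_within_genotype(mat_vt)
    pca_rows = []
    for scan_idx in sorted(set(mat_vt.scan_index)):
        frac = pca_variance_explained(z, scan_index=scan_idx)
        for comp, f in enumerate(frac, start=1):
            pca_rows.append({"scan_index": scan_idx, "component": comp,
                             "fraction": float(f)})
    pca = pd.DataFrame(pca_rows)

    # associations of each outcome with target-region V_T, per genotype
    tgt_vt = vt_long[vt_long["roi"] == target_roi].set_index(["subject", "scan"])
    out_tbl = build_outcome_table(fits, tacs_by_scan, metas,
                                  target_rois=(target_roi,), window=window)
    assoc_rows = []
    for measure in ("SUV", "DVR_CBL", "DVR_WB", "SUVR_CBL", "SUVR_WB"):
        sub = out_tbl[out_tbl["measure"] == measure].set_index(["subject", "scan"])
        joined = sub.join(tgt_vt["vt"], how="inner")
        r2 = association_r2(joined["value"].to_numpy(), joined["vt"].to_numpy(),
                            joined["genotype"].to_numpy())
        for group, value in sorted(r2.items()):
            assoc_rows.append({"measure": measure, "genotype": group, "r2": value})
    table2 = pd.DataFrame(assoc_rows)
    return correlations, pca, table2


def _write(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", lineterminator="\n")


def run_all(config: RunConfig, out_dir: str | Path) -> dict:
    """Run every stage; returns {name: path} for the report bundle."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    log.info("stage simulate: %d subjects, seed %d",
             config.cohort.n_hab + config.cohort.n_mab, config.cohort.seed)
    cohort = generate_cohort(config.cohort)
    data_dir = out_dir / "data"
    write_cohort(cohort, data_dir)
    scans = [(s.meta, s.tacs, s.input_function) for s in cohort.scans]

    log.info("stage fit: %d scans", len(scans))
    fits = fit_scans(scans, config.fit_options)
    _write(fits, out_dir / "fits.tsv")

    log.info("stage outcomes: target %s", config.target_roi)
    tacs_by_scan = {m.scan_id: t for m, t, _ in scans}
    metas = [m for m, _, _ in scans]
    outcome_tbl = build_outcome_table(fits, tacs_by_scan, metas,
                                      target_rois=(config.target_roi,),
                                      window=config.suv_window)
    _write(outcome_tbl, out_dir / "outcomes.tsv")

    log.info("stage reliability")
    table1 = build_reliability_report(outcome_tbl)
    _write(table1, out_dir / "table1.tsv")

    log.info("stage structure")
    correlations, pca, table2 = structure_reports(fits, scans, config.target_roi,
                                                  config.suv_window)
    _write(correlations, out_dir / "correlations.tsv")
    _write(pca, out_dir / "pca.tsv")
    _write(table2, out_dir / "table2.tsv")

    manifest = {
        "config": config_to_dict(config),
        "seed": config.cohort.seed,
        "versions": _versions(),
        "files": {p.name: str(p) for p in
                  [out_dir / f for f in BUNDLE_FILES if f != "manifest.yaml"]},
    }
    with open(out_dir / "manifest.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return {f: str(out_dir / f) for f in BUNDLE_FILES}


def summarize(bundle_dir: str | Path) -> str:
    """Human-readable headline summary of a run bundle; no recomputation."""
    bundle_dir = Path(bundle_dir)
    for name in BUNDLE_FILES:
        if not (bundle_dir / name).exists():
            raise FileNotFoundError(f"bundle is missing {name}")
    table1 = pd.read_csv(bundle_dir / "table1.tsv", sep="\t")
    table2 = pd.read_csv(bundle_dir / "table2.tsv", sep="\t")
    pca = pd.read_csv(bundle_dir / "pca.tsv", sep="\t")
    lines = ["Test-retest reliability (mean / COV% / ICC / VAR% / SEM%):"]
    for r in table1.itertuples():
        label = r.measure if r.denominator == "-" else f"{r.measure}_{r.denominator}"
        lines.append(f"  {label:10s} {r.genotype:4s} n={r.n:2d}  "
                     f"{r.mean:7.3f} {r.cov_pct:6.1f} {r.icc:6.2f} "
                     f"{r.var_pct:6.1f} {r.sem_pct:6.1f}")
    lines.append("First principal component of within-genotype z-scored V_T:")
    for scan_idx, grp in pca.groupby("scan_index"):
        f1 = grp.sort_values("component").iloc[0]["fraction"]
        lines.append(f"  scan {scan_idx}: {100 * f1:.1f}% of variance")
    lines.append("Association with target-region V_T (R², per genotype):")
    for r in table2.itertuples():
        lines.append(f"  {r.measure:10s} {r.genotype:4s} R²={r.r2:.2f}")
    return "\n".join(lines)


# ---------------------------------------------------------------------------
# Config round-trip (YAML)


def _sanitize(obj):
    """Make a config tree YAML-safe (tuples → lists, numpy → python)."""
    if isinstance(obj, dict):
        return {k: _sanitize(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_sanitize(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [float(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def config_to_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["cohort"]["blood_times"] = [float(t) for t in config.cohort.blood_times]
    d["cohort"]["frame_schedule"] = [[float(s), float(du)] for s, du in
                                     config.cohort.frame_schedule]
    d["cohort"]["plasma_model"] = {
        "amplitudes": list(config.cohort.plasma_model.amplitudes),
        "decay_rates": list(config.cohort.plasma_model.decay_rates),
        "peak_time": config.cohort.plasma_model.peak_time,
    }
    return _sanitize(d)


def config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    cohort_d = dict(d.get("cohort", {}))
    if "plasma_model" in cohort_d:
        pm = cohort_d["plasma_model"]
        cohort_d["plasma_model"] = PlasmaModel(
            amplitudes=tuple(pm["amplitudes"]),
            decay_rates=tuple(pm["decay_rates"]),
            peak_time=pm["peak_time"])
    if "blood_times" in cohort_d:
        cohort_d["blood_times"] = np.asarray(cohort_d["blood_times"], float)
    if "frame_schedule" in cohort_d:
        cohort_d["frame_schedule"] = [tuple(f) for f in cohort_d["frame_schedule"]]
    if "roi_names" in cohort_d:
        cohort_d["roi_names"] = tuple(cohort_d["roi_names"])
    if "vb_range" in cohort_d:
        cohort_d["vb_range"] = tuple(cohort_d["vb_range"])
    fit_d = dict(d.get("fit_options", {}))
    for key in ("bounds_K1", "bounds_k", "bounds_vB", "x0"):
        if key in fit_d:
            fit_d[key] = tuple(fit_d[key])
    kwargs = {k: v for k, v in d.items() if k not in ("cohort", "fit_options")}
    if "denominators" in kwargs:
        kwargs["denominators"] = tuple(kwargs["denominators"])
    if "suv_window" in kwargs:
        kwargs["suv_window"] = tuple(kwargs["suv_window"])
    return RunConfig(cohort=CohortSpec(**cohort_d), fit_options=FitOptions(**fit_d),
                     **kwargs)


def load_config(path: str | Path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def _versions() -> dict:
    import scipy

    from . import __version__
    return {"petratio": __version__, "numpy": np.__version__,
            "scipy": scipy.__version__, "pandas": pd.__version__}
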