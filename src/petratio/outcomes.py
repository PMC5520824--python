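"""Ratio-based and uptake outcome measures: SUV, SUVR and DVR.

SUV is the standardised uptake value over a late time window (default
40–60 min): the time-weighted mean activity concentration divided by
injected dose per body weight. With activity in kBq/mL, dose in MBq and
weight in kg the quotient is numerically dose[kBq]/weight[g], so SUV comes
out in g/mL. SUVR and DVR divide the target region's SUV or V_T by a
denominator region (whole brain or cerebellum).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .tac_io import ScanMeta, TimeActivityCurve

__all__ = ["suv", "ratio", "build_outcome_table", "suv_table", "MEASURES"]

MEASURES = ("VT", "SUV", "SUVR_WB", "SUVR_CBL", "DVR_WB", "DVR_CBL")

_DENOMINATOR_ROI = {"WB": "whole_brain", "CBL": "cerebellum"}


def suv(tac: TimeActivityCurve, meta: ScanMeta,
        window: tuple[float, float] = (40.0, 60.0)) -> float:
    """Standardised uptake value over ``window`` minutes (g/mL).

    Frames partially overlapping the window contribute by overlap fraction
    (time-weighted mean), so the value is independent of the frame schedule.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("window must have positive width")
    overlap = np.minimum(tac.frame_end, hi) - np.maximum(tac.frame_start, lo)
    overlap = np.maximum(overlap, 0.0)
    total = overlap.sum()
    if total <= 0:
        raise ValueError(f"no frames overlap the SUV window [{lo}, {hi}) min")
    mean_activity = float(np.dot(overlap, tac.activity) / total)  # kBq/mL
    dose_per_weight = meta.injected_dose_MBq * 1e3 / (meta.body_weight_kg * 1e3)  # kBq/g
    return mean_activity / dose_per_weight


def ratio(numerator: float, denominator: float) -> float:
    """Plain quotient; SUV pairs give SUVR, V_T pairs give DVR."""
    if denominator <= 0:
        raise ValueError(f"denominator must be positive, got {denominator}")
    return numerator / denominator


def suv_table(tacs_by_scan: dict[str, dict[str, TimeActivityCurve]],
              metas: list[ScanMeta],
              window: tuple[float, float] = (40.0, 60.0)) -> pd.DataFrame:
    """Per scan × ROI SUV values (long format)."""
    rows = []
    for meta in metas:
        for roi, tac in tacs_by_scan[meta.scan_id].items():
            rows.append({"subject": meta.subject_id, "scan": meta.scan_index,
                         "genotype": meta.genotype, "roi": roi,
                         "SUV": suv(tac, meta, window)})
    return pd.DataFrame(rows)


def build_outcome_table(fits: pd.DataFrame,
                        tacs_by_scan: dict[str, dict[str, TimeActivityCurve]],
                        metas: list[ScanMeta],
                        target_rois: tuple[str, ...] = ("frontal_cortex",),
                        window: tuple[float, float] = (40.0, 60.0)) -> pd.DataFrame:
    """Assemble the six outcome measures per target ROI per scan.

    ``fits`` is a long table with columns subject, scan, roi, vt (the fits
    TSV of the kinetic stage). Returns rows (subject, scan, genotype, roi,
    measure, value) in deterministic (subject, scan, roi, measure) order.
    """
    vt = {(r.subject, int(r.scan), r.roi): float(r.vt) for r in fits.itertuples()}
    rows = []
    for meta in sorted(metas, key=lambda m: (m.subject_id, m.scan_index)):
        scan_tacs = tacs_by_scan[meta.scan_id]
        for roi in sorted(target_rois):
            values = {}
            key = (meta.subject_id, meta.scan_index, roi)
            if key not in vt:
                raise KeyError(f"missing V_T fit for ROI {roi!r} of scan {meta.scan_id}")
            values["VT"] = vt[key]
            if roi not in scan_tacs:
                raise KeyError(f"missing TAC for ROI {roi!r} of scan {meta.scan_id}")
            values["SUV"] = suv(scan_tacs[roi], meta, window)
            for short, den_roi in _DENOMINATOR_ROI.items():
                den_key = (meta.subject_id, meta.scan_index, den_roi)
                if den_key not in vt:
                    raise KeyError(
                        f"missing denominator fit {den_roi!r} for DVR_{short} "
                        f"of scan {meta.scan_id}")
                if den_roi not in scan_tacs:
                    raise KeyError(
                        f"missing denominator TAC {den_roi!r} for SUVR_{short} "
                        f"of scan {meta.scan_id}")
                values[f"DVR_{short}"] = ratio(values["VT"], vt[den_key])
                values[f"SUVR_{short}"] = ratio(
                    values["SUV"], suv(scan_tacs[den_roi], meta, window))
            for measure in MEASURES:
                rows.append({"subject": meta.subject_id, "scan": meta.scan_index,
                             "genotype": meta.genotype, "roi": roi,
                             "measure": measure, "value": values[measure]})
    return pd.DataFrame(rows)
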