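"""Shared fixtures: fitted cohorts are expensive, so they are session-scoped
and reused by the unit suites and the acceptance suite alike."""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import pytest

import petratio as pr
from petratio.outcomes import build_outcome_table
from petratio.pipeline import fit_scans, structure_reports
from petratio.reliability import build_reliability_report


def cohort_scans(cohort):
    return [(s.meta, s.tacs, s.input_function) for s in cohort.scans]


@pytest.fixture(scope="session")
def noise_free_cohort():
    """12-subject cohort with noise_scale = 0 (exact forward-model TACs)."""
    return pr.generate_cohort(pr.CohortSpec(seed=11, noise_scale=0.0))


@pytest.fixture(scope="session")
def noise_free_fits(noise_free_cohort):
    """Two-stage fits of every scan of the noise-free cohort."""
    return fit_scans(cohort_scans(noise_free_cohort))


@pytest.fixture(scope="session")
def noisy_recovery():
    """Frontal-cortex and whole-brain V_T recovery under default noise.

    100 scans (50 subjects x 2); returns (true_vt, fitted_vt) frames for the
    frontal cortex plus whole-brain stage-one relative errors.
    """
    spec = pr.CohortSpec(n_hab=25, n_mab=25, seed=21)
    cohort = pr.generate_cohort(spec)
    rows = []
    for scan in cohort.scans:
        wb = pr.fit_whole_brain(scan.tacs["whole_brain"], scan.input_function)
        fc = pr.fit_roi(scan.tacs["frontal_cortex"], scan.input_function,
                        wb.params.vB, wb.params.delay)
        rows.append({
            "scan_id": scan.meta.scan_id,
            "true_fc": scan.state.true_vt("frontal_cortex"),
            "fit_fc": fc.vt,
            "true_wb": scan.state.true_vt("whole_brain"),
            "fit_wb": wb.vt,
            "true_vB": scan.state.vB,
            "fit_vB": wb.params.vB,
        })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def multi_seed_reports():
    """Full pipeline tables for default cohorts at seeds 0..4.

    Returns a list of dicts with fits, outcomes, reliability table and the
    structure reports for each seed; used for the ordering and calibration
    checks that need sampling noise averaged out.
    """
    reports = []
    for seed in range(5):
        cohort = pr.generate_cohort(pr.CohortSpec(seed=seed))
        scans = cohort_scans(cohort)
        fits = fit_scans(scans)
        tacs_by_scan = {m.scan_id: t for m, t, _ in scans}
        metas = [m for m, _, _ in scans]
        outcomes = build_outcome_table(fits, tacs_by_scan, metas)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            table1 = build_reliability_report(outcomes)
            correlations, pca, table2 = structure_reports(fits, scans, "frontal_cortex")
        geno = {m.subject_id: m.genotype for m in metas}
        reports.append({"seed": seed, "cohort": cohort, "fits": fits,
                        "outcomes": outcomes, "table1": table1,
                        "correlations": correlations, "pca": pca,
                        "table2": table2, "genotype": geno})
    return reports


def reliability_value(table1: pd.DataFrame, measure: str, genotype: str, col: str) -> float:
    den = "CBL" if measure.endswith("CBL") else "WB" if measure.endswith("WB") else "-"
    base = measure.split("_")[0] if den != "-" else measure
    row = table1[(table1.measure == base) & (table1.denominator == den)
                 & (table1.genotype == genotype)]
    assert len(row) == 1, f"no unique row for {measure}/{genotype}"
    return float(row[col].iloc[0])
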