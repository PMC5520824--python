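"""Test-retest reliability statistics for two-scan designs.

For n subjects measured twice (k = 2), the one-way ANOVA decomposes
variance into between-subject MS_B = 2·Σ(m_i − m)²/(n−1) and within-subject
MS_W = Σ(test_i − retest_i)²/(2n), from which

    ICC  = (MS_B − MS_W) / (MS_B + (k−1)·MS_W)           (one-way, fixed)
    SEM% = 100·√MS_W / grand mean                        (within-subject COV)

COV pools all 2n measurements (100·SD/mean, sample SD) and VAR is the mean
symmetric absolute percentage difference 200·|test−retest|/(test+retest).
The error-variance fraction is 100·(1 − ICC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "PairedMeasurements",
    "anova_oneway",
    "icc_oneway",
    "error_variance_pct",
    "cov_pct",
    "var_pct",
    "sem_pct",
    "build_reliability_report",
]


@dataclass
class PairedMeasurements:
    """Test and retest values, one pair per subject, same order."""

    subjects: list[str]
    test: np.ndarray
    retest: np.ndarray

    def __post_init__(self):
        self.test = np.asarray(self.test, dtype=float)
        self.retest = np.asarray(self.retest, dtype=float)
        n = len(self.subjects)
        if len(self.test) != n or len(self.retest) != n:
            raise ValueError("subjects, test and retest must have equal length")
        if n < 2:
            raise ValueError("need at least 2 subjects")
        if len(set(self.subjects)) != n:
            raise ValueError("one pair per subject required")
        if not (np.all(np.isfinite(self.test)) and np.all(np.isfinite(self.retest))):
            raise ValueError("values must be finite")

    @property
    def n(self) -> int:
        return len(self.subjects)

    @property
    def pooled(self) -> np.ndarray:
        return np.concatenate([self.test, self.retest])


def anova_oneway(pairs: PairedMeasurements) -> tuple[float, float]:
    """Between- and within-subject mean squares (MS_B, MS_W) for k = 2."""
    means = 0.5 * (pairs.test + pairs.retest)
    grand = means.mean()
    ms_b = 2.0 * np.sum((means - grand) ** 2) / (pairs.n - 1)
    ms_w = np.sum((pairs.test - pairs.retest) ** 2 / 2.0) / pairs.n
    return float(ms_b), float(ms_w)


def icc_oneway(pairs: PairedMeasurements) -> float:
    """One-way ANOVA fixed-effects ICC, (MS_B−MS_W)/(MS_B+(k−1)MS_W), k=2.

    May be negative. If all values are identical (MS_B = MS_W = 0) the
    limiting value 1.0 is returned with a warning.
    """
    ms_b, ms_w = anova_oneway(pairs)
    denom = ms_b + ms_w
    if denom == 0.0:
        warnings.warn("all measurements identical; ICC defined as 1.0 by convention")
        return 1.0
    return float((ms_b - ms_w) / denom)


def error_variance_pct(icc: float) -> float:
    """Percent of variance attributable to error: 100·(1 − ICC)."""
    if icc > 1:
        raise ValueError("ICC cannot exceed 1")
    return 100.0 * (1.0 - icc)


def cov_pct(values: np.ndarray) -> float:
    """Coefficient of variation (%) of all pooled measurements (sample SD)."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values")
    mean = values.mean()
    if mean == 0:
        raise ValueError("mean is zero; COV undefined")
    return float(100.0 * values.std(ddof=1) / mean)


def var_pct(pairs: PairedMeasurements) -> float:
    """Absolute percentage variability: mean of 200·|d|/(test+retest)."""
    s = pairs.test + pairs.retest
    if np.any(s <= 0):
        raise ValueError("pair sums must be positive")
    return float(np.mean(200.0 * np.abs(pairs.test - pairs.retest) / s))


def sem_pct(pairs: PairedMeasurements) -> float:
    """Standard error of measurement as percent of the grand mean (within COV)."""
    _, ms_w = anova_oneway(pairs)
    grand = pairs.pooled.mean()
    if grand == 0:
        raise ValueError("grand mean is zero; SEM% undefined")
    return float(100.0 * np.sqrt(ms_w) / grand)


# ---------------------------------------------------------------------------
# Report assembly (machine twin of a mean/COV/ICC/VAR/SEM outcome table)

_MEASURE_LAYOUT = [
    # (measure, denominator label, groupings)
    ("VT", "-", ("HAB", "MAB")),
    ("DVR_CBL", "CBL", ("All", "HAB", "MAB")),
    ("DVR_WB", "WB", ("All", "HAB", "MAB")),
    ("SUV", "-", ("HAB", "MAB")),
    ("SUVR_CBL", "CBL", ("All", "HAB", "MAB")),
    ("SUVR_WB", "WB", ("All", "HAB", "MAB")),
]


def _pairs_from(df: pd.DataFrame) -> PairedMeasurements | None:
    """Build paired measurements from long rows, dropping incomplete subjects."""
    wide = df.pivot_table(index="subject", columns="scan", values="value")
    complete = wide.dropna()
    dropped = set(wide.index) - set(complete.index)
    for subject in sorted(dropped):
        warnings.warn(f"subject {subject} lacks a complete scan pair; "
                      "excluded from test-retest analysis")
    if len(complete) < 2:
        return None
    return PairedMeasurements(subjects=list(complete.index),
                              test=complete[1].to_numpy(),
                              retest=complete[2].to_numpy())


def build_reliability_report(outcomes: pd.DataFrame,
                             layout=_MEASURE_LAYOUT) -> pd.DataFrame:
    """Mean/COV/ICC/VAR/SEM per outcome measure and genotype grouping.

    ``outcomes`` is the long outcome table (subject, scan, genotype, roi,
    measure, value). V_T and SUV are reported per genotype only (their
    genotype effect dominates); ratio outcomes also pooled ("All") since
    the genotype effect largely cancels in the quotient.
    """
    rows = []
    for measure, denom, groupings in layout:
        sub = outcomes[outcomes["measure"] == measure]
        if sub.empty:
            continue
        for group in groupings:
            grp = sub if group == "All" else sub[sub["genotype"] == group]
            pairs = _pairs_from(grp)
            if pairs is None:
                raise ValueError(f"no complete test-retest pairs for {measure}/{group}")
            icc = icc_oneway(pairs)
            rows.append({
                "measure": measure.split("_")[0] if denom != "-" else measure,
                "genotype": group,
                "denominator": denom,
                "n": pairs.n,
                "mean": float(pairs.pooled.mean()),
                "cov_pct": cov_pct(pairs.pooled),
                "icc": icc,
                "var_pct": var_pct(pairs),
                "sem_pct": sem_pct(pairs),
            })
    if not rows:
        raise ValueError("outcome table contains none of the expected measures")
    return pd.DataFrame(rows)
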