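"""Tabular I/O for time-activity curves, arterial blood data and scan metadata.

All times are minutes post-injection; activity concentrations are kBq/mL.
Frames are half-open intervals ``[start, start + duration)``.

File dialects (UTF-8, tab-separated, ``#``-prefixed comment lines carry units):

* TAC TSV: columns ``frame_start_min``, ``frame_dur_min``, then one column
  per ROI.
* Blood TSV: columns ``time_min``, ``whole_blood_kBq_mL``,
  ``plasma_parent_kBq_mL``.
* Metadata TSV: ``subject_id``, ``scan_index``, ``genotype``,
  ``injected_dose_MBq``, ``body_weight_kg``, ``tac_file``, ``blood_file``.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TimeActivityCurve",
    "InputFunction",
    "ScanMeta",
    "ValidationError",
    "read_tacs",
    "write_tacs",
    "read_blood",
    "write_blood",
    "read_metadata",
    "write_metadata",
    "interpolate_input",
]

TAC_TIME_COLUMNS = ("frame_start_min", "frame_dur_min")
BLOOD_COLUMNS = ("time_min", "whole_blood_kBq_mL", "plasma_parent_kBq_mL")
META_COLUMNS = (
    "subject_id",
    "scan_index",
    "genotype",
    "injected_dose_MBq",
    "body_weight_kg",
    "tac_file",
    "blood_file",
)


class ValidationError(ValueError):
    """A file or in-memory table violated a format invariant.

    Carries row/column coordinates of the offending value where known.
    """

    def __init__(self, message: str, *, row: int | None = None, column: str | None = None):
        loc = []
        if row is not None:
            loc.append(f"row {row}")
        if column is not None:
            loc.append(f"column {column!r}")
        if loc:
            message = f"{message} ({', '.join(loc)})"
        super().__init__(message)
        self.row = row
        self.column = column


@dataclass
class TimeActivityCurve:
    """Framed activity concentrations for one ROI of one scan."""

    frame_start: np.ndarray  # min
    frame_duration: np.ndarray  # min
    activity: np.ndarray  # kBq/mL
    roi: str
    scan_id: str = ""

    def __post_init__(self):
        self.frame_start = np.asarray(self.frame_start, dtype=float)
        self.frame_duration = np.asarray(self.frame_duration, dtype=float)
        self.activity = np.asarray(self.activity, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.frame_start)
        if len(self.frame_duration) != n or len(self.activity) != n:
            raise ValidationError(
                f"TAC arrays for ROI {self.roi!r} have unequal lengths "
                f"({n}, {len(self.frame_duration)}, {len(self.activity)})"
            )
        if n == 0:
            raise ValidationError(f"TAC for ROI {self.roi!r} is empty")
        if np.any(self.frame_duration <= 0):
            i = int(np.argmax(self.frame_duration <= 0))
            raise ValidationError("non-positive frame duration", row=i, column="frame_dur_min")
        ends = self.frame_start + self.frame_duration
        for i in range(1, n):
            if self.frame_start[i] < ends[i - 1] - 1e-9:
                raise ValidationError(
                    f"frame starting at {self.frame_start[i]:g} min overlaps previous "
                    f"frame ending at {ends[i - 1]:g} min",
                    row=i,
                    column="frame_start_min",
                )
        if not np.all(np.isfinite(self.activity)):
            i = int(np.argmax(~np.isfinite(self.activity)))
            raise ValidationError("non-finite activity value", row=i, column=self.roi)

    @property
    def frame_end(self) -> np.ndarray:
        return self.frame_start + self.frame_duration

    @property
    def frame_mid(self) -> np.ndarray:
        return self.frame_start + 0.5 * self.frame_duration


@dataclass
class InputFunction:
    """Arterial whole-blood and metabolite-corrected plasma curves for one scan."""

    time: np.ndarray  # min, strictly ascending
    whole_blood: np.ndarray  # kBq/mL
    plasma_parent: np.ndarray  # kBq/mL, metabolite-corrected

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.whole_blood = np.asarray(self.whole_blood, dtype=float)
        self.plasma_parent = np.asarray(self.plasma_parent, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.time)
        if n < 2:
            raise ValidationError("input function needs at least 2 samples")
        if len(self.whole_blood) != n or len(self.plasma_parent) != n:
            raise ValidationError("input-function arrays have unequal lengths")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            i = int(np.argmax(dt <= 0)) + 1
            raise ValidationError("time not strictly ascending", row=i, column="time_min")
        for name, arr in (("whole_blood_kBq_mL", self.whole_blood),
                          ("plasma_parent_kBq_mL", self.plasma_parent)):
            if not np.all(np.isfinite(arr)):
                i = int(np.argmax(~np.isfinite(arr)))
                raise ValidationError("non-finite activity", row=i, column=name)
            if np.any(arr < 0):
                i = int(np.argmax(arr < 0))
                raise ValidationError("negative activity", row=i, column=name)


@dataclass
class ScanMeta:
    subject_id: str
    scan_index: int  # 1 or 2
    genotype: str  # "HAB" | "MAB"
    injected_dose_MBq: float
    body_weight_kg: float
    tac_file: str = ""
    blood_file: str = ""

    def __post_init__(self):
        if self.scan_index not in (1, 2):
            raise ValidationError(f"scan_index must be 1 or 2, got {self.scan_index}")
        if self.genotype not in ("HAB", "MAB"):
            raise ValidationError(f"genotype must be HAB or MAB, got {self.genotype!r}")
        if self.injected_dose_MBq <= 0:
            raise ValidationError("injected dose must be positive")
        if self.body_weight_kg <= 0:
            raise ValidationError("body weight must be positive")

    @property
    def scan_id(self) -> str:
        return f"{self.subject_id}_scan{self.scan_index}"


def _read_tsv(path: str | Path, required: tuple[str, ...], what: str) -> pd.DataFrame:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    comments = [ln for ln in text.splitlines() if ln.startswith("#")]
    if what in ("TAC", "blood"):  # activity units carried in comments; kBq/mL required
        for ln in comments:
            if "Bq" in ln and "kBq/mL" not in ln:
                raise ValidationError(f"{what} file {path.name} declares units other "
                                      f"than kBq/mL: {ln.strip()!r}")
    body = "\n".join(ln for ln in text.splitlines() if not ln.startswith("#"))
    if not body.strip():
        raise ValidationError(f"{what} file {path.name} has no data section")
    first = body.splitlines()[0]
    if "\t" not in first and ("," in first or ";" in first):
        raise ValidationError(f"{what} file {path.name} is not tab-separated")
    try:
        df = pd.read_csv(_io.StringIO(body), sep="\t")
    except Exception as exc:  # malformed header/body
        raise ValidationError(f"{what} file {path.name} is malformed: {exc}") from exc
    if df.empty:
        raise ValidationError(f"{what} file {path.name} has a header but no data rows")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{what} file {path.name} missing columns {missing}")
    return df


def read_tacs(path: str | Path, scan_id: str = "") -> dict[str, TimeActivityCurve]:
    """Read a TAC TSV into one :class:`TimeActivityCurve` per ROI column."""
    df = _read_tsv(path, TAC_TIME_COLUMNS, "TAC")
    rois = [c for c in df.columns if c not in TAC_TIME_COLUMNS]
    if not rois:
        raise ValidationError(f"TAC file {Path(path).name} has no ROI columns")
    start = df["frame_start_min"].to_numpy(float)
    dur = df["frame_dur_min"].to_numpy(float)
    return {
        roi: TimeActivityCurve(start, dur, df[roi].to_numpy(float), roi=roi, scan_id=scan_id)
        for roi in rois
    }


def write_tacs(tacs: dict[str, TimeActivityCurve], path: str | Path) -> None:
    first = next(iter(tacs.values()))
    cols = {"frame_start_min": first.frame_start, "frame_dur_min": first.frame_duration}
    for roi, tac in tacs.items():
        if not np.array_equal(tac.frame_start, first.frame_start):
            raise ValidationError(f"ROI {roi!r} has a different frame schedule")
        cols[roi] = tac.activity
    _write_tsv(pd.DataFrame(cols), path, "# time-activity curves; times min, activity kBq/mL")


def read_blood(path: str | Path) -> InputFunction:
    df = _read_tsv(path, BLOOD_COLUMNS, "blood")
    return InputFunction(
        time=df["time_min"].to_numpy(float),
        whole_blood=df["whole_blood_kBq_mL"].to_numpy(float),
        plasma_parent=df["plasma_parent_kBq_mL"].to_numpy(float),
    )


def write_blood(inp: InputFunction, path: str | Path) -> None:
    df = pd.DataFrame(
        {"time_min": inp.time, "whole_blood_kBq_mL": inp.whole_blood,
         "plasma_parent_kBq_mL": inp.plasma_parent}
    )
    _write_tsv(df, path, "# arterial blood; time min, activity kBq/mL (plasma metabolite-corrected)")


def read_metadata(path: str | Path) -> list[ScanMeta]:
    df = _read_tsv(path, META_COLUMNS[:5], "metadata")
    metas = []
    for _, row in df.iterrows():
        metas.append(
            ScanMeta(
                subject_id=str(row["subject_id"]),
                scan_index=int(row["scan_index"]),
                genotype=str(row["genotype"]),
                injected_dose_MBq=float(row["injected_dose_MBq"]),
                body_weight_kg=float(row["body_weight_kg"]),
                tac_file=str(row.get("tac_file", "")),
                blood_file=str(row.get("blood_file", "")),
            )
        )
    return metas


def write_metadata(metas: list[ScanMeta], path: str | Path) -> None:
    df = pd.DataFrame([{c: getattr(m, c) for c in META_COLUMNS} for m in metas],
                      columns=list(META_COLUMNS))
    _write_tsv(df, path, "# scan metadata; dose MBq, weight kg")


def _write_tsv(df: pd.DataFrame, path: str | Path, header_comment: str) -> None:
    path = Path(path)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(header_comment + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def interpolate_input(inp: InputFunction, dt: float) -> InputFunction:
    """Resample an input function onto a uniform grid by linear interpolation.

    The grid runs from 0 to the last sample time in steps of ``dt`` minutes;
    values before the first sample are linearly continued from (0, 0) if the
    first sample is after t=0, i.e. extrapolation before the data is zero at
    t=0 and linear up to the first sample. Values at original sample times on
    the grid are reproduced exactly.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    span = inp.time[-1]
    if dt > span:
        raise ValueError(f"dt={dt} exceeds the input-function span {span} min")
    n = int(np.floor(span / dt + 1e-9)) + 1
    t = np.arange(n) * dt
    t0, v0w, v0p = inp.time, inp.whole_blood, inp.plasma_parent
    if t0[0] > 0:  # anchor at (0, 0): curves are zero before injection
        t0 = np.concatenate([[0.0], t0])
        v0w = np.concatenate([[0.0], v0w])
        v0p = np.concatenate([[0.0], v0p])
    return InputFunction(
        time=t,
        whole_blood=np.interp(t, t0, v0w),
        plasma_parent=np.interp(t, t0, v0p),
    )
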