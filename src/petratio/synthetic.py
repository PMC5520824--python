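"""Synthetic test-retest TSPO PET cohorts with a controlled latent structure.

The generator emulates the measurement situation of a two-scan arterial-input
TSPO PET study: a small cohort split into high-affinity (HAB) and
mixed-affinity (MAB) binders, six brain regions whose binding is driven by
one dominant shared latent factor, and frame-level counting noise. Regional
binding for scan *s* of subject *i* is

    k3(i, s, r) = k3_base(genotype) · S_i · G_is · (1 + ε_isr)

where S (between-subject) and G (within-subject, scan-level) are lognormal
with mean 1 and the configured CVs, and ε is a small region-specific
Gaussian perturbation. K1, k2 and k4 are held at their defaults, so
V_T = K1/k2·(1+k3/k4) is analytically controlled: group mean V_T converges
exactly to the configured genotype targets.

The arterial input is a piecewise-linear rise to a peak followed by a
tri-exponential decay; plasma is emitted already metabolite-corrected with a
constant plasma-to-whole-blood ratio. The whole-brain curve is the
activity-weighted mean of the five tissue regions (it *contains* the target
region — the overlap at the heart of ratio-outcome behaviour) plus its own
noise draw.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .kinetics import KineticParams, twotcm_forward
from .tac_io import (
    InputFunction,
    ScanMeta,
    TimeActivityCurve,
    write_blood,
    write_metadata,
    write_tacs,
    read_blood,
    read_metadata,
    read_tacs,
)

__all__ = [
    "PlasmaModel",
    "CohortSpec",
    "TrueScanState",
    "SyntheticScan",
    "SyntheticCohort",
    "generate_plasma_input",
    "generate_true_cohort",
    "generate_cohort",
    "synthesize_tac",
    "write_cohort",
    "read_cohort",
    "default_frame_schedule",
    "default_blood_times",
]

#: constant metabolite-corrected plasma to whole-blood activity ratio
PLASMA_TO_BLOOD = 0.8

TISSUE_ROIS = ("frontal_cortex", "cerebellum", "temporal_cortex", "striatum", "thalamus")
WHOLE_BRAIN = "whole_brain"


def default_frame_schedule() -> list[tuple[float, float]]:
    """Framing 6×10 s, 3×20 s, 3×60 s, 5×180 s, 8×300 s (0–60 min)."""
    frames = []
    t = 0.0
    for n, dur_s in ((6, 10), (3, 20), (3, 60), (5, 180), (8, 300)):
        for _ in range(n):
            frames.append((t, dur_s / 60.0))
            t += dur_s / 60.0
    return frames


def default_blood_times() -> np.ndarray:
    """Arterial sampling grid: 5-s spacing to 3 min, 15 s to 10 min, 2.5 min to 60."""
    return np.unique(np.concatenate([
        np.arange(0.0, 3.0 + 1e-9, 1.0 / 12.0),
        np.arange(3.0, 10.0 + 1e-9, 0.25),
        np.arange(10.0, 60.0 + 1e-9, 2.5),
    ]))


@dataclass(frozen=True)
class PlasmaModel:
    """Parametric metabolite-corrected plasma curve.

    Piecewise-linear rise from 0 at injection to the peak, then
    tri-exponential decay Σ amplitudes_i·exp(−decay_rates_i·(t−peak_time)).
    """

    amplitudes: tuple[float, float, float]  # kBq/mL
    decay_rates: tuple[float, float, float]  # 1/min
    peak_time: float  # min

    def __post_init__(self):
        if any(r <= 0 for r in self.decay_rates):
            raise ValueError("decay rates must be positive")
        if len(set(self.decay_rates)) != 3:
            raise ValueError("decay rates must be distinct")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be non-negative")
        if self.peak_time <= 0:
            raise ValueError("peak_time must be positive")

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        peak = float(sum(self.amplitudes))
        rise = peak * t / self.peak_time
        tail = sum(a * np.exp(-r * (t - self.peak_time))
                   for a, r in zip(self.amplitudes, self.decay_rates))
        return np.where(t <= 0, 0.0, np.where(t < self.peak_time, rise, tail))


DEFAULT_PLASMA = PlasmaModel(amplitudes=(60.0, 12.0, 4.0),
                             decay_rates=(3.0, 0.35, 0.010), peak_time=1.5)


def generate_plasma_input(model: PlasmaModel, times: np.ndarray) -> InputFunction:
    """Sample paired whole-blood and metabolite-corrected plasma curves.

    Plasma is the model curve; whole blood is plasma / plasma-to-blood
    ratio (0.8), so plasma ≤ whole blood everywhere.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly ascending")
    if times[0] < 0:
        raise ValueError("times must be non-negative")
    plasma = model(times)
    return InputFunction(time=times, whole_blood=plasma / PLASMA_TO_BLOOD,
                         plasma_parent=plasma)


@dataclass
class CohortSpec:
    """Study conditions for the synthetic cohort.

    Defaults describe a 12-subject (6 HAB / 6 MAB) two-scan study with
    genotype frontal-cortex V_T targets 3.9 (HAB) and 3.9/ratio (MAB),
    between-subject latent CV 0.30, scan-level latent CV 0.10 and
    region-specific CV 0.02.
    """

    n_hab: int = 6
    n_mab: int = 6
    roi_names: tuple[str, ...] = (WHOLE_BRAIN,) + TISSUE_ROIS
    hab_vt_target: float = 3.9
    genotype_vt_ratio: float = 3.9 / 2.2  # HAB/MAB binding multiplier
    between_subject_cv: float = 0.30
    within_subject_cv: float = 0.10
    region_noise_cv: float = 0.02
    vb_range: tuple[float, float] = (0.027, 0.064)
    frame_schedule: list[tuple[float, float]] = field(default_factory=default_frame_schedule)
    noise_scale: float = 0.025
    seed: int = 0
    # fixed kinetic defaults; genotype and latent factors act on k3 only
    K1: float = 0.12  # mL·cm⁻³·min⁻¹
    k2: float = 0.08  # 1/min
    k4: float = 0.05  # 1/min
    delay_bound: float = 1.0 / 3.0  # true delay ~ U(−20 s, +20 s)
    injected_dose_MBq: float = 400.0
    dose_cv: float = 0.10
    body_weight_kg: float = 70.0
    weight_cv: float = 0.10
    plasma_scale_cv: float = 0.05
    plasma_model: PlasmaModel = DEFAULT_PLASMA
    blood_times: np.ndarray = field(default_factory=default_blood_times)

    def __post_init__(self):
        if self.n_hab + self.n_mab < 2:
            raise ValueError("cohort needs at least 2 subjects")
        for name in ("between_subject_cv", "within_subject_cv", "region_noise_cv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        lo, hi = self.vb_range
        if not (0 < lo <= hi < 0.15):
            raise ValueError("vb_range must lie within (0, 0.15)")
        starts = np.array([s for s, _ in self.frame_schedule])
        durs = np.array([d for _, d in self.frame_schedule])
        if starts[0] != 0:
            raise ValueError("first frame must start at 0")
        if np.any(np.diff(starts) <= 0) or np.any(starts[1:] < (starts + durs)[:-1] - 1e-9):
            raise ValueError("frames must be ascending and non-overlapping")
        for required in (WHOLE_BRAIN, "cerebellum", "frontal_cortex"):
            if required not in self.roi_names:
                raise ValueError(f"roi_names must include {required!r}")

    @property
    def mab_vt_target(self) -> float:
        return self.hab_vt_target / self.genotype_vt_ratio

    def k3_base(self, genotype: str) -> float:
        """k3 giving the genotype's target V_T at the default K1, k2, k4."""
        target = self.hab_vt_target if genotype == "HAB" else self.mab_vt_target
        bp = target * self.k2 / self.K1 - 1.0  # k3/k4 at target
        if bp <= 0:
            raise ValueError("V_T target below the non-displaceable volume K1/k2")
        return bp * self.k4

    @property
    def tissue_rois(self) -> tuple[str, ...]:
        return tuple(r for r in self.roi_names if r != WHOLE_BRAIN)


@dataclass
class TrueScanState:
    """Ground truth for one scan: latent factors and per-ROI kinetics."""

    subject_id: str
    scan_index: int
    genotype: str
    latent_factor: float  # subject-level, lognormal mean 1
    scan_factor: float  # scan-level, lognormal mean 1
    params: dict[str, KineticParams]  # tissue ROIs only
    vB: float
    delay: float
    injected_dose_MBq: float
    body_weight_kg: float
    plasma_scale: float

    def __post_init__(self):
        if self.latent_factor <= 0 or self.scan_factor <= 0:
            raise ValueError("latent factors must be positive")

    def true_vt(self, roi: str) -> float:
        """Ground-truth V_T; the whole brain is the equal-weight ROI mean."""
        if roi == WHOLE_BRAIN:
            return float(np.mean([p.vt for p in self.params.values()]))
        return self.params[roi].vt


def _lognormal(rng: np.random.Generator, cv: float, size=None):
    """Lognormal draw with mean exactly 1 and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size) if size is not None else 1.0
    s2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-0.5 * s2, sigma=np.sqrt(s2), size=size)


def generate_true_cohort(spec: CohortSpec) -> list[TrueScanState]:
    """Draw per-scan ground truth (latent factors, kinetics, dose/weight)."""
    rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 0]))
    states: list[TrueScanState] = []
    genotypes = ["HAB"] * spec.n_hab + ["MAB"] * spec.n_mab
    for i, genotype in enumerate(genotypes):
        subject_id = f"sub{i + 1:03d}"
        S = float(_lognormal(rng, spec.between_subject_cv))
        weight = spec.body_weight_kg * float(_lognormal(rng, spec.weight_cv))
        k3_base = spec.k3_base(genotype)
        for scan_index in (1, 2):
            G = float(_lognormal(rng, spec.within_subject_cv))
            eps = rng.normal(0.0, spec.region_noise_cv, size=len(spec.tissue_rois))
            vB = float(rng.uniform(*spec.vb_range))
            delay = float(rng.uniform(-spec.delay_bound, spec.delay_bound))
            dose = spec.injected_dose_MBq * float(_lognormal(rng, spec.dose_cv))
            # activity concentrations scale with injected dose per body size
            # (dilution) times an individual clearance/delivery factor
            dilution = (dose / spec.injected_dose_MBq) / (weight / spec.body_weight_kg)
            plasma_scale = float(_lognormal(rng, spec.plasma_scale_cv)) * dilution
            params = {}
            for roi, e in zip(spec.tissue_rois, eps):
                k3 = max(k3_base * S * G * (1.0 + e), 1e-6)
                params[roi] = KineticParams(K1=spec.K1, k2=spec.k2, k3=k3,
                                            k4=spec.k4, vB=vB, delay=delay)
            states.append(TrueScanState(
                subject_id=subject_id, scan_index=scan_index, genotype=genotype,
                latent_factor=S, scan_factor=G, params=params, vB=vB, delay=delay,
                injected_dose_MBq=dose, body_weight_kg=weight,
                plasma_scale=plasma_scale,
            ))
    return states


def synthesize_tac(state: TrueScanState, roi: str, inp: InputFunction,
                   frames: list[tuple[float, float]], noise_scale: float,
                   rng: np.random.Generator) -> TimeActivityCurve:
    """Forward-model one ROI's TAC and add frame-level Gaussian noise.

    Noise SD per frame is ``noise_scale·sqrt(model / duration)`` — the
    counting-statistics scaling in which long frames and low activity are
    less and more noisy respectively. ``noise_scale = 0`` returns the exact
    noise-free forward model.
    """
    start = np.array([s for s, _ in frames])
    dur = np.array([d for _, d in frames])
    if roi == WHOLE_BRAIN:
        curves = [twotcm_forward(p, inp, start, dur) for p in state.params.values()]
        clean = np.mean(curves, axis=0)
    elif roi in state.params:
        clean = twotcm_forward(state.params[roi], inp, start, dur)
    else:
        raise KeyError(f"ROI {roi!r} not in scan state for {state.subject_id}")
    sd = noise_scale * np.sqrt(np.maximum(clean, 0.0) / dur)
    noisy = clean + rng.normal(0.0, 1.0, size=clean.size) * sd
    return TimeActivityCurve(start, dur, noisy, roi=roi,
                             scan_id=f"{state.subject_id}_scan{state.scan_index}")


@dataclass
class SyntheticScan:
    meta: ScanMeta
    state: TrueScanState
    input_function: InputFunction
    tacs: dict[str, TimeActivityCurve]


@dataclass
class SyntheticCohort:
    spec: CohortSpec
    scans: list[SyntheticScan]


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Full generation pipeline: ground truth → input functions → noisy TACs."""
    states = generate_true_cohort(spec)
    scans = []
    for k, state in enumerate(states):
        model = PlasmaModel(
            amplitudes=tuple(a * state.plasma_scale for a in spec.plasma_model.amplitudes),
            decay_rates=spec.plasma_model.decay_rates,
            peak_time=spec.plasma_model.peak_time,
        )
        inp = generate_plasma_input(model, spec.blood_times)
        rng = np.random.default_rng(np.random.SeedSequence([int(spec.seed), 1, k]))
        tacs = {
            roi: synthesize_tac(state, roi, inp, spec.frame_schedule,
                                spec.noise_scale, rng)
            for roi in spec.roi_names
        }
        meta = ScanMeta(
            subject_id=state.subject_id, scan_index=state.scan_index,
            genotype=state.genotype, injected_dose_MBq=state.injected_dose_MBq,
            body_weight_kg=state.body_weight_kg,
            tac_file=f"{state.subject_id}_scan{state.scan_index}_tacs.tsv",
            blood_file=f"{state.subject_id}_scan{state.scan_index}_blood.tsv",
        )
        scans.append(SyntheticScan(meta=meta, state=state, input_function=inp, tacs=tacs))
    return SyntheticCohort(spec=spec, scans=scans)


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict:
    """Write per-scan TAC and blood TSVs plus one metadata TSV.

    Returns a manifest: metadata path and the per-scan file paths.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {"metadata": str(directory / "metadata.tsv"), "scans": []}
    metas = []
    for scan in cohort.scans:
        tac_path = directory / scan.meta.tac_file
        blood_path = directory / scan.meta.blood_file
        write_tacs(scan.tacs, tac_path)
        write_blood(scan.input_function, blood_path)
        metas.append(scan.meta)
        manifest["scans"].append({"tac": str(tac_path), "blood": str(blood_path)})
    write_metadata(metas, directory / "metadata.tsv")
    return manifest


def read_cohort(directory: str | Path):
    """Read back a written cohort: list of (meta, tacs, input_function)."""
    directory = Path(directory)
    out = []
    for meta in read_metadata(directory / "metadata.tsv"):
        tacs = read_tacs(directory / meta.tac_file, scan_id=meta.scan_id)
        inp = read_blood(directory / meta.blood_file)
        out.append((meta, tacs, inp))
    return out
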