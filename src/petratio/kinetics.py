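"""Two-tissue compartment model (2TCM): forward model and two-stage fitting.

The 2TCM describes tracer exchange between arterial plasma and two tissue
compartments (free/non-specific and specifically bound) with rate constants
K1 (mL·cm⁻³·min⁻¹) and k2, k3, k4 (min⁻¹). Its tissue impulse response is

    IRF(t) = K1/(θ1−θ2) · [(θ1−k3−k4)·e^(−θ1·t) + (k3+k4−θ2)·e^(−θ2·t)]

with macro rates θ1 ≥ θ2 the eigenvalue magnitudes of the compartment system
(θ1+θ2 = k2+k3+k4, θ1·θ2 = k2·k4). The measured concentration additionally
contains a fractional blood volume vB and a blood-to-tissue delay:

    C(t) = (1−vB)·(IRF ⊛ Cp)(t−delay) + vB·Cb(t−delay)

frame-averaged over each half-open frame interval. The total distribution
volume is V_T = ∫₀^∞ IRF dt = K1/k2·(1+k3/k4).

Fitting follows a two-stage protocol: vB and the delay are estimated once
from the whole-brain curve (all six parameters free), then held fixed for
the per-ROI fits (K1, k2, k3, k4 free). This reflects that delay and blood
volume are scan-level, not region-level, quantities.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares
from scipy.signal import lfilter

from .tac_io import InputFunction, TimeActivityCurve

__all__ = [
    "KineticParams",
    "FitResult",
    "FitOptions",
    "macro_rates",
    "vt_from_params",
    "twotcm_irf",
    "twotcm_forward",
    "fit_whole_brain",
    "fit_roi",
]

#: uniform convolution grid step, minutes (0.5 s)
FINE_DT = 1.0 / 120.0


@dataclass(frozen=True)
class KineticParams:
    """2TCM rate constants plus scan-level nuisance parameters."""

    K1: float  # mL·cm⁻³·min⁻¹
    k2: float  # min⁻¹
    k3: float  # min⁻¹
    k4: float  # min⁻¹
    vB: float = 0.0  # fractional blood volume
    delay: float = 0.0  # min, blood-to-tissue time shift

    def __post_init__(self):
        if self.K1 < 0:
            raise ValueError("K1 must be non-negative")
        if self.k2 <= 0 or self.k4 <= 0:
            raise ValueError("k2 and k4 must be positive")
        if self.k3 < 0:
            raise ValueError("k3 must be non-negative")
        if not 0 <= self.vB < 0.15:
            raise ValueError("vB must lie in [0, 0.15)")
        if abs(self.delay) > 1.0:
            raise ValueError("|delay| must be at most 1 min")

    @property
    def vt(self) -> float:
        return vt_from_params(self)


@dataclass
class FitResult:
    params: KineticParams
    vt: float
    wrss: float
    converged: bool
    residuals: np.ndarray

    def __post_init__(self):
        assert np.isfinite(self.wrss)


def macro_rates(k2: float, k3: float, k4: float) -> tuple[float, float]:
    """Macro rate constants (θ1, θ2) of the 2TCM, θ1 ≥ θ2 > 0.

    These are the eigenvalue magnitudes of the 2×2 compartment rate matrix;
    θ1+θ2 = k2+k3+k4 and θ1·θ2 = k2·k4.
    """
    if k2 <= 0 or k4 <= 0:
        raise ValueError("k2 and k4 must be positive")
    if k3 < 0:
        raise ValueError("k3 must be non-negative")
    s = k2 + k3 + k4
    disc = np.sqrt(max(s * s - 4.0 * k2 * k4, 0.0))
    return 0.5 * (s + disc), 0.5 * (s - disc)


def vt_from_params(params: KineticParams) -> float:
    """Total distribution volume V_T = K1/k2 · (1 + k3/k4)."""
    if params.k2 == 0 or params.k4 == 0:
        raise ValueError("k2 and k4 must be non-zero")
    return params.K1 / params.k2 * (1.0 + params.k3 / params.k4)


def twotcm_irf(params: KineticParams, t: np.ndarray) -> np.ndarray:
    """Tissue impulse response of the 2TCM evaluated at times ``t``."""
    th1, th2 = macro_rates(params.k2, params.k3, params.k4)
    t = np.asarray(t, dtype=float)
    if th1 - th2 < 1e-9:  # degenerate repeated root; nudge apart
        th1 += 5e-10
        th2 -= 5e-10
    a1 = (th1 - params.k3 - params.k4) / (th1 - th2)
    a2 = (params.k3 + params.k4 - th2) / (th1 - th2)
    return params.K1 * (a1 * np.exp(-th1 * t) + a2 * np.exp(-th2 * t))


def _exp_conv(theta: float, x: np.ndarray, dt: float) -> np.ndarray:
    """Trapezoid-corrected discrete convolution of e^(−θt) with ``x``.

    Recursion y[n] = a·y[n−1] + dt/2·(x[n] + a·x[n−1]) with a = e^(−θ·dt),
    evaluated as an IIR filter.
    """
    a = np.exp(-theta * dt)
    return lfilter([dt / 2.0, a * dt / 2.0], [1.0, -a], x)


class _ConvProblem:
    """Precomputed fine-grid quantities for repeated forward evaluations.

    The fine grid spans [0, t_end + margin]; the input curves are linearly
    interpolated onto it once, delay shifts are cached per delay value.
    """

    def __init__(self, inp: InputFunction, frame_start: np.ndarray,
                 frame_duration: np.ndarray, dt: float = FINE_DT, margin: float = 0.6):
        self.dt = dt
        frame_start = np.asarray(frame_start, float)
        frame_duration = np.asarray(frame_duration, float)
        t_end = float(frame_start[-1] + frame_duration[-1])
        if t_end > inp.time[-1] + 0.5 + 1e-9:
            raise ValueError(
                f"frames extend to {t_end:g} min but the input function ends "
                f"at {inp.time[-1]:g} min"
            )
        n = int(round((t_end + margin) / dt)) + 1
        self.t = np.arange(n) * dt
        src_t, src_p, src_b = inp.time, inp.plasma_parent, inp.whole_blood
        if src_t[0] > 0:
            src_t = np.concatenate([[0.0], src_t])
            src_p = np.concatenate([[0.0], src_p])
            src_b = np.concatenate([[0.0], src_b])
        self._src = (src_t, src_p, src_b)
        self.cp = np.interp(self.t, src_t, src_p)
        self.cb = np.interp(self.t, src_t, src_b)
        # frame boundaries as fine-grid indices; round half up so that
        # sub-grid frames still span at least one grid interval
        self.i0 = np.floor(frame_start / dt + 0.5).astype(int)
        self.i1 = np.floor((frame_start + frame_duration) / dt + 0.5).astype(int)
        self.i1 = np.maximum(self.i1, self.i0 + 1)
        self._shift_cache: dict[float, tuple[np.ndarray, np.ndarray]] = {}

    def shifted(self, delay: float) -> tuple[np.ndarray, np.ndarray]:
        """Input curves evaluated at t − delay (zero before injection)."""
        key = round(delay, 9)
        if key not in self._shift_cache:
            if key == 0.0:
                self._shift_cache[key] = (self.cp, self.cb)
            else:
                src_t, src_p, src_b = self._src
                tq = self.t - delay
                self._shift_cache[key] = (
                    np.interp(tq, src_t, src_p, left=0.0),
                    np.interp(tq, src_t, src_b, left=0.0),
                )
        return self._shift_cache[key]

    def frame_average(self, fine: np.ndarray) -> np.ndarray:
        """Trapezoid mean of a fine-grid curve over each frame."""
        cum = np.concatenate([[0.0], np.cumsum(0.5 * (fine[1:] + fine[:-1]))])
        return (cum[self.i1] - cum[self.i0]) / (self.i1 - self.i0)

    def model(self, K1, k2, k3, k4, vB, delay) -> np.ndarray:
        cp, cb = self.shifted(delay)
        th1, th2 = macro_rates(k2, k3, k4)
        if th1 - th2 < 1e-9:
            th1 += 5e-10
            th2 -= 5e-10
        a1 = (th1 - k3 - k4) / (th1 - th2)
        a2 = (k3 + k4 - th2) / (th1 - th2)
        tissue = K1 * (a1 * _exp_conv(th1, cp, self.dt) + a2 * _exp_conv(th2, cp, self.dt))
        return self.frame_average((1.0 - vB) * tissue + vB * cb)


def twotcm_forward(params: KineticParams, inp: InputFunction,
                   frame_start: np.ndarray, frame_duration: np.ndarray,
                   dt: float = FINE_DT) -> np.ndarray:
    """Noise-free frame-averaged 2TCM model curve (kBq/mL).

    ``dt`` is the uniform convolution grid step (minutes); the 0.5-s default
    matches the fitting stage.
    """
    prob = _ConvProblem(inp, np.asarray(frame_start, float),
                        np.asarray(frame_duration, float), dt=dt)
    return prob.model(params.K1, params.k2, params.k3, params.k4, params.vB, params.delay)


# ---------------------------------------------------------------------------
# Fitting


@dataclass
class FitOptions:
    """Configuration of the nonlinear least-squares protocol.

    weights: "uniform" (default) or "duration" (w ∝ frame duration).
    n_starts: multi-starts from jittered default initials; best WRSS wins,
        ties broken by first start.
    delay search: coarse grid over ±delay_bound in delay_step increments,
        then golden-section refinement to delay_tol (whole-brain stage only).
    fix_k3: force k3 = 0 (degenerate one-tissue fit).
    """

    weights: str = "uniform"
    n_starts: int = 5
    start_seed: int = 7  # fixed jitter stream → deterministic fits
    delay_bound: float = 0.5  # min
    delay_step: float = 1.0 / 12.0  # 5 s coarse grid
    delay_tol: float = 1.0 / 240.0  # 0.25 s refinement tolerance
    fit_window: float = 63.0  # use frames starting before this time (min)
    fix_k3: bool = False
    bounds_K1: tuple[float, float] = (0.0, 1.0)
    bounds_k: tuple[float, float] = (1e-4, 0.5)
    bounds_vB: tuple[float, float] = (0.0, 0.15)
    x0: tuple[float, float, float, float] = (0.1, 0.07, 0.05, 0.04)  # K1,k2,k3,k4
    x0_vB: float = 0.04


def _weights(opts: FitOptions, dur: np.ndarray) -> np.ndarray:
    if opts.weights == "uniform":
        w = np.ones_like(dur)
    elif opts.weights == "duration":
        w = dur / dur.mean()
    else:
        raise ValueError(f"unknown weighting {opts.weights!r}")
    return np.sqrt(w)


def _starts(opts: FitOptions, base: np.ndarray, lo: np.ndarray, hi: np.ndarray) -> list[np.ndarray]:
    rng = np.random.default_rng(opts.start_seed)
    starts = [base.copy()]
    for _ in range(opts.n_starts - 1):
        jitter = np.exp(rng.normal(0.0, 0.45, size=base.size))
        starts.append(np.clip(base * jitter, lo + 1e-9, hi - 1e-9))
    return starts


def _nls(prob: _ConvProblem, y: np.ndarray, sw: np.ndarray, opts: FitOptions,
         delay: float, vB_fixed: float | None, x0_list: list[np.ndarray]):
    """Bounded NLS over (K1,k2,k3,k4[,vB]) at a fixed delay. Returns best solution."""
    klo, khi = opts.bounds_k
    lo = [opts.bounds_K1[0], klo, klo, klo]
    hi = [opts.bounds_K1[1], khi, khi, khi]
    if vB_fixed is None:
        lo.append(opts.bounds_vB[0])
        hi.append(opts.bounds_vB[1])
    lo, hi = np.array(lo), np.array(hi)

    def resid(x):
        K1, k2, k3, k4 = x[:4]
        if opts.fix_k3:
            k3 = 0.0
        vB = vB_fixed if vB_fixed is not None else x[4]
        return sw * (prob.model(K1, k2, k3, k4, vB, delay) - y)

    best = None
    for x0 in x0_list:
        x0 = np.clip(x0, lo + 1e-12, hi - 1e-12)
        sol = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                            x_scale=np.maximum(np.abs(x0), 1e-3),
                            ftol=1e-10, xtol=1e-10, gtol=1e-10)
        if best is None or sol.cost < best.cost * (1 - 1e-12):
            best = sol
    return best


def _result_from(sol, opts: FitOptions, vB: float, delay: float) -> FitResult:
    K1, k2, k3, k4 = sol.x[:4]
    if opts.fix_k3:
        k3 = 0.0
    params = KineticParams(K1=float(K1), k2=float(k2), k3=float(k3), k4=float(k4),
                           vB=float(vB), delay=float(delay))
    return FitResult(params=params, vt=vt_from_params(params),
                     wrss=float(2.0 * sol.cost), converged=bool(sol.success),
                     residuals=sol.fun.copy())


def _restrict(tac: TimeActivityCurve, opts: FitOptions):
    keep = tac.frame_start < opts.fit_window
    return tac.frame_start[keep], tac.frame_duration[keep], tac.activity[keep]


def fit_whole_brain(tac: TimeActivityCurve, inp: InputFunction,
                    options: FitOptions | None = None) -> FitResult:
    """Stage-one fit: all of K1, k2, k3, k4, vB and the delay are free.

    The delay is handled by a coarse grid search wrapped around the smooth
    NLS over the remaining parameters, followed by golden-section
    refinement; the final parameters come from a multi-start NLS at the
    selected delay.
    """
    opts = options or FitOptions()
    start, dur, y = _restrict(tac, opts)
    n_free = 6 if not opts.fix_k3 else 5
    if len(y) < n_free:
        raise ValueError(f"only {len(y)} frames for {n_free} free parameters")
    prob = _ConvProblem(inp, start, dur)
    sw = _weights(opts, dur)
    base = np.array(list(opts.x0) + [opts.x0_vB])

    warm = [base]

    def objective(delay: float):
        sol = _nls(prob, y, sw, opts, delay, None, [warm[0]])
        warm[0] = sol.x.copy()
        return sol

    # coarse grid
    grid = np.arange(-opts.delay_bound, opts.delay_bound + 1e-12, opts.delay_step)
    sols = {}
    for d in grid:
        sols[d] = objective(d)
    d_best = min(sols, key=lambda d: sols[d].cost)

    # golden-section refinement around the best grid point
    gr = (np.sqrt(5.0) - 1.0) / 2.0
    a = max(d_best - opts.delay_step, -opts.delay_bound)
    b = min(d_best + opts.delay_step, opts.delay_bound)
    c, d = b - gr * (b - a), a + gr * (b - a)
    fc, fd = objective(c), objective(d)
    while b - a > opts.delay_tol:
        if fc.cost < fd.cost:
            b, d, fd = d, c, fc
            c = b - gr * (b - a)
            fc = objective(c)
        else:
            a, c, fc = c, d, fd
            d = a + gr * (b - a)
            fd = objective(d)
    cands = {c: fc, d: fd, d_best: sols[d_best]}
    d_final = min(cands, key=lambda k: cands[k].cost)

    # multi-start polish at the selected delay
    lo = np.array([opts.bounds_K1[0], *(opts.bounds_k[0],) * 3, opts.bounds_vB[0]])
    hi = np.array([opts.bounds_K1[1], *(opts.bounds_k[1],) * 3, opts.bounds_vB[1]])
    starts = [cands[d_final].x] + _starts(opts, base, lo, hi)[1:]
    sol = _nls(prob, y, sw, opts, d_final, None, starts)
    return _result_from(sol, opts, vB=sol.x[4], delay=d_final)


def fit_roi(tac: TimeActivityCurve, inp: InputFunction, fixed_vB: float,
            fixed_delay: float, options: FitOptions | None = None) -> FitResult:
    """Stage-two fit: K1, k2, k3, k4 free; vB and delay fixed from stage one."""
    opts = options or FitOptions()
    start, dur, y = _restrict(tac, opts)
    n_free = 4 if not opts.fix_k3 else 3
    if len(y) < n_free:
        raise ValueError(f"only {len(y)} frames for {n_free} free parameters")
    prob = _ConvProblem(inp, start, dur)
    sw = _weights(opts, dur)
    base = np.array(opts.x0)
    lo = np.array([opts.bounds_K1[0], *(opts.bounds_k[0],) * 3])
    hi = np.array([opts.bounds_K1[1], *(opts.bounds_k[1],) * 3])
    sol = _nls(prob, y, sw, opts, fixed_delay, fixed_vB, _starts(opts, base, lo, hi))
    return _result_from(sol, opts, vB=fixed_vB, delay=fixed_delay)
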