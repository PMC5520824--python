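"""Independent oracles used to cross-check the analytic implementations.

Each oracle deliberately takes a different computational route from the code
it checks: stiff ODE integration instead of analytic convolution, quadrature
instead of closed forms, first-principles sums instead of the packaged
statistics.
"""

from __future__ import annotations

import numpy as np
from scipy.integrate import quad, solve_ivp

from petratio.kinetics import KineticParams
from petratio.tac_io import InputFunction


def ode_model_at(params: KineticParams, inp: InputFunction, times: np.ndarray) -> np.ndarray:
    """Measured-concentration model via stiff integration of the 2TCM ODEs.

    dC1/dt = K1·Cp − (k2+k3)·C1 + k4·C2 ; dC2/dt = k3·C1 − k4·C2 ;
    C(t) = (1−vB)(C1+C2)(t) + vB·Cb(t−delay), with Cp evaluated at t−delay.
    """
    src_t = np.concatenate([[min(0.0, inp.time[0] - 1.0)], inp.time])
    src_p = np.concatenate([[0.0], inp.plasma_parent])
    src_b = np.concatenate([[0.0], inp.whole_blood])

    def cp(t):
        return np.interp(t - params.delay, src_t, src_p, left=0.0)

    def cb(t):
        return np.interp(t - params.delay, src_t, src_b, left=0.0)

    def rhs(t, y):
        c1, c2 = y
        return [params.K1 * cp(t) - (params.k2 + params.k3) * c1 + params.k4 * c2,
                params.k3 * c1 - params.k4 * c2]

    sol = solve_ivp(rhs, (0.0, float(times[-1])), [0.0, 0.0], method="Radau",
                    t_eval=times, rtol=1e-8, atol=1e-10, max_step=0.25)
    tissue = sol.y.sum(axis=0)
    return (1.0 - params.vB) * tissue + params.vB * cb(times)


def irf_integral(params: KineticParams) -> float:
    """Quadrature of the tissue impulse response over [0, ∞)."""
    from petratio.kinetics import twotcm_irf

    val, _ = quad(lambda t: float(twotcm_irf(params, t)), 0.0, np.inf, limit=200)
    return val


def anova_first_principles(test: np.ndarray, retest: np.ndarray) -> tuple[float, float]:
    """Textbook one-way ANOVA over all 2n observations, subjects as groups."""
    data = np.stack([test, retest], axis=1)  # n × k
    n, k = data.shape
    grand = data.mean()
    group_means = data.mean(axis=1)
    ss_between = k * np.sum((group_means - grand) ** 2)
    ss_within = np.sum((data - group_means[:, None]) ** 2)
    return ss_between / (n - 1), ss_within / (n * (k - 1))


def pearson_from_scratch(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson r via explicit covariance and SDs (sample, n−1)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    cov = np.sum(xc * yc) / (len(x) - 1)
    sx = np.sqrt(np.sum(xc ** 2) / (len(x) - 1))
    sy = np.sqrt(np.sum(yc ** 2) / (len(y) - 1))
    return cov / (sx * sy)


def random_params(rng: np.random.Generator, with_nuisance: bool = True) -> KineticParams:
    """Physiologically plausible random 2TCM parameter draw."""
    return KineticParams(
        K1=float(rng.uniform(0.05, 0.3)),
        k2=float(rng.uniform(0.02, 0.2)),
        k3=float(rng.uniform(0.005, 0.15)),
        k4=float(rng.uniform(0.02, 0.15)),
        vB=float(rng.uniform(0.02, 0.08)) if with_nuisance else 0.0,
        delay=float(rng.uniform(-0.3, 0.3)) if with_nuisance else 0.0,
    )
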