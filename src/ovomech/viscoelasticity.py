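"""Viscous dissipation from indentation cycles and stress-relaxation fitting.

Dissipated viscous energy is the area enclosed between the approach and
retraction force-indentation branches, restricted to the positive-force
region; on a whole cycle it measures the energy lost to viscous flow during
one compression. It is reported in fJ (1 nN·µm = 1 fJ).

Stress relaxation under constant compression is described by a generalized
Maxwell model with two elements::

    F(t) = a0 + a1 exp(-(t - t0)/tau1) + a2 exp(-(t - t0)/tau2)

with tau1 < tau2 by convention. Each Maxwell element obeys tau = eta / E, so
a relaxation time times a modulus gives a viscosity. The faster time is
assigned to the zona pellucida (stiffer, less viscous) and the slower to the
ooplasm.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .curveio import CurveValidationError, IndentationCurve, RelaxationTrace

__all__ = [
    "DissipationResult",
    "MaxwellFit",
    "CompartmentAssignment",
    "dissipated_energy",
    "fit_maxwell2",
    "viscosity_from",
    "assign_compartments",
]


@dataclass
class DissipationResult:
    energy: float  # fJ
    positive_force_span: float  # µm of indentation with F > 0
    n_points_used: int
    flagged_negative: bool = False


def dissipated_energy(ind: IndentationCurve, noise_sd: float = 0.0) -> DissipationResult:
    """Area between approach and retraction in the positive-force region.

    The retract branch is linearly interpolated onto the approach indentation
    grid over the overlapping range; both branches are clipped at F > 0 and
    the difference is integrated by the trapezoidal rule. A negative result
    beyond 3x the supplied noise bound is flagged (it indicates a corrupted
    cycle, not negative dissipation).
    """
    d_app, f_app = ind.seg("approach")
    d_ret, f_ret = ind.seg("retract")
    if len(d_ret) == 0:
        raise CurveValidationError("missing retract segment")
    order = np.argsort(d_ret)
    d_ret, f_ret = d_ret[order], f_ret[order]
    lo = max(d_app.min(), d_ret.min())
    hi = min(d_app.max(), d_ret.max())
    if hi <= lo:
        raise CurveValidationError("approach and retract indentation ranges do not overlap")
    m = (d_app >= lo) & (d_app <= hi)
    grid = d_app[m]
    order = np.argsort(grid)
    grid = grid[order]
    fa = f_app[m][order]
    fr = np.interp(grid, d_ret, f_ret)
    diff = np.clip(fa, 0.0, None) - np.clip(fr, 0.0, None)
    energy = float(np.trapezoid(diff, grid))  # nN * µm == fJ
    pos = grid[np.clip(fa, 0.0, None) > 0]
    span = float(pos.max() - pos.min()) if len(pos) > 1 else 0.0
    flagged = energy < -3.0 * noise_sd * max(span, 0.0)
    return DissipationResult(
        energy=energy,
        positive_force_span=span,
        n_points_used=int(len(grid)),
        flagged_negative=bool(flagged and energy < 0),
    )


@dataclass
class MaxwellFit:
    """Two-element generalized Maxwell fit of a hold trace (tau1 < tau2)."""

    a0: float  # nN
    a1: float  # nN
    a2: float  # nN
    t0: float  # s
    tau1: float  # s
    tau2: float  # s
    rss: float  # nN^2
    converged: bool
    n_elements: int = 2  # 1 when the single-exponential fallback was used


@dataclass(frozen=True)
class MaxwellConfig:
    tail_fraction: float = 0.4  # window for the tau2 peel-off
    head_fraction: float = 0.2
    min_tau_ratio: float = 1.5  # below this two exponentials are unresolvable
    amp_noise_mult: float = 3.0  # amplitude below this x residual SD -> fallback


def _peel_init(t: np.ndarray, f: np.ndarray):
    """Two-stage log-linear peel-off initializer (tail tau2, then head tau1)."""
    a0 = float(np.mean(f[-max(len(f) // 20, 2):]))
    y = f - a0
    n_tail = max(int(len(t) * 0.4), 4)
    tt, yt = t[-n_tail:], y[-n_tail:]
    pos = yt > 0
    tau2, a2 = None, None
    if pos.sum() >= 4:
        slope, icpt = np.polyfit(tt[pos], np.log(yt[pos]), 1)
        if slope < 0:
            tau2 = -1.0 / slope
            a2 = float(np.exp(icpt))
    if tau2 is None:
        tau2 = max((t[-1] - t[0]) / 3.0, 1.0)
        a2 = max(float(y[len(y) // 2]), 1e-3)
    y1 = y - a2 * np.exp(-t / tau2)
    n_head = max(int(len(t) * 0.2), 4)
    th, yh = t[:n_head], y1[:n_head]
    pos = yh > max(float(np.max(yh)), 0.0) * 0.02
    tau1, a1 = None, None
    if pos.sum() >= 4:
        slope, icpt = np.polyfit(th[pos], np.log(yh[pos]), 1)
        if slope < 0:
            tau1 = -1.0 / slope
            a1 = float(np.exp(icpt))
    if tau1 is None:
        tau1 = tau2 / 10.0
        a1 = max(float(y[0] - a2), 1e-3)
    return a0, a1, a2, tau1, tau2


def _fit_single_exp(t, f):
    a0 = float(np.mean(f[-max(len(f) // 20, 2):]))
    a1 = max(float(f[0] - a0), 1e-6)
    tau = max(float(t[np.argmin(np.abs((f - a0) - a1 / np.e))]), 1e-2)

    def resid(x):
        return x[0] + x[1] * np.exp(-t / x[2]) - f

    res = least_squares(resid, x0=[a0, a1, tau], bounds=([-np.inf, 0, 1e-3], [np.inf, np.inf, np.inf]))
    return res


def fit_maxwell2(trace: RelaxationTrace, cfg: MaxwellConfig = MaxwellConfig()) -> MaxwellFit:
    """Least-squares fit of the two-element generalized Maxwell model.

    The initializer is a two-stage exponential peel (tail window for the slow
    element, head window for the fast one). When the two time constants are
    not resolvable (ratio < ``min_tau_ratio``) or one amplitude drowns in the
    residual noise, the fit falls back to a single element and flags it.
    """
    hold = trace.t >= trace.t0
    t = trace.t[hold] - trace.t0
    f = trace.force[hold]
    if len(t) < 50:
        raise CurveValidationError(f"hold has {len(t)} samples, need >= 50")

    a0, a1, a2, tau1, tau2 = _peel_init(t, f)
    if tau1 > tau2:
        tau1, tau2, a1, a2 = tau2, tau1, a2, a1

    def resid(x):
        return x[0] + x[1] * np.exp(-t / x[3]) + x[2] * np.exp(-t / x[4]) - f

    res = least_squares(
        resid,
        x0=[a0, max(a1, 1e-6), max(a2, 1e-6), max(tau1, 1e-3), max(tau2, 2e-3)],
        bounds=([-np.inf, 0, 0, 1e-3, 1e-3], [np.inf, np.inf, np.inf, np.inf, np.inf]),
        x_scale="jac",
    )
    a0, a1, a2, tau1, tau2 = res.x
    if tau1 > tau2:
        tau1, tau2, a1, a2 = tau2, tau1, a2, a1
    rss = float(2.0 * res.cost)
    sd_res = float(np.sqrt(rss / max(len(t) - 5, 1)))

    unresolvable = (tau2 / max(tau1, 1e-12)) < cfg.min_tau_ratio
    weak = min(a1, a2) < cfg.amp_noise_mult * sd_res
    if unresolvable or weak:
        res1 = _fit_single_exp(t, f)
        rss1 = float(2.0 * res1.cost)
        return MaxwellFit(
            a0=float(res1.x[0]), a1=float(res1.x[1]), a2=0.0,
            t0=trace.t0, tau1=float(res1.x[2]), tau2=float("nan"),
            rss=rss1, converged=bool(res1.success), n_elements=1,
        )
    return MaxwellFit(
        a0=float(a0), a1=float(a1), a2=float(a2), t0=trace.t0,
        tau1=float(tau1), tau2=float(tau2), rss=rss,
        converged=bool(res.success and np.isfinite(rss)), n_elements=2,
    )


def viscosity_from(tau: float, E: float) -> float:
    """Viscosity eta = tau * E (Pa·s) from the Maxwell relation tau = eta/E."""
    if not (tau > 0 and E > 0):
        raise ValueError("tau and E must be > 0")
    return tau * E


@dataclass(frozen=True)
class CompartmentAssignment:
    """Relaxation times mapped onto oocyte compartments (ZP fast, ooplasm slow)."""

    zp_tau: float  # s
    ooplasm_tau: float  # s
    zp_eta: float | None = None  # Pa·s, filled when a ZP modulus is supplied


def assign_compartments(fit: MaxwellFit, zp_E: float | None = None) -> CompartmentAssignment:
    """Assign the faster relaxation time to the ZP and the slower to the ooplasm."""
    if fit.n_elements < 2 or not np.isfinite(fit.tau2):
        raise ValueError(
            "single-element fallback fit: compartments cannot be assigned "
            "(two resolvable relaxation times are required)"
        )
    zp_tau = min(fit.tau1, fit.tau2)
    oo_tau = max(fit.tau1, fit.tau2)
    eta = viscosity_from(zp_tau, zp_E) if zp_E is not None else None
    return CompartmentAssignment(zp_tau=zp_tau, ooplasm_tau=oo_tau, zp_eta=eta)
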