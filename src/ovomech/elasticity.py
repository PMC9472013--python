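"""Contact-point detection and single/two-layer Hertz fitting of approach curves.

The zona pellucida of a mouse oocyte indents as two mechanically distinct
regimes: a soft, irregular outer glycoprotein layer (modulus E1) and a
stiffer, more homogeneous inner layer (modulus E2). Force-indentation curves
therefore show two slopes, modelled here as the *sum of two contributions*::

    F(delta) = H(delta; E1) + [delta > dc2] * H(delta - dc2; E2c)

where ``H`` is the spherical Hertz form
``H(d; E) = (4/3) * E / (1 - nu^2) * sqrt(R) * d^(3/2)`` and ``dc2`` is the
indentation depth at which the second contribution engages (the second
contact point).

Reported-modulus convention: the headline ``E2`` is the modulus a
*single-layer* Hertz fit restricted to the post-``dc2`` regime would report
on the combined response — i.e. the slope of the second regime, which is what
is quoted for oocytes. The additive component ``E2c`` is preserved alongside.
Both conventions meet in :func:`second_regime_modulus`; swap that function to
change the interpretation.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .curveio import (
    DEFLECTION_TO_FORCE_NN,
    CurveValidationError,
    ForceCurve,
    IndentationCurve,
)

__all__ = [
    "HertzParams",
    "HertzFit",
    "TwoLayerFit",
    "GridSummary",
    "FitConfig",
    "NoContactError",
    "hertz_force",
    "two_layer_force",
    "second_regime_modulus",
    "detect_contact",
    "fit_single_hertz",
    "fit_two_layer",
    "summarize_grid",
]

#: nN per (Pa * sqrt(µm) * µm^1.5): (4/3)E' sqrt(R) d^1.5 with R, d in µm
#: gives 1e-12 N, i.e. 1e-3 nN.
_HERTZ_UNIT_NN = 1.0e-3


class NoContactError(RuntimeError):
    """No sustained force rise found on the approach segment."""


@dataclass(frozen=True)
class HertzParams:
    """Single-layer Hertz parameters (E in Pa, lengths in µm)."""

    E: float
    nu: float = 0.5
    R: float = 2.25
    contact_z: float = 0.0

    def __post_init__(self) -> None:
        if not self.E > 0:
            raise ValueError("E must be > 0")
        if not 0.0 <= self.nu <= 0.5 + 1e-9:
            raise ValueError("nu must be in [0, 0.5]")
        if not self.R > 0:
            raise ValueError("R must be > 0")


def _hertz_prefactor(E: float | np.ndarray, nu: float, R: float):
    return (4.0 / 3.0) * (E / (1.0 - nu**2)) * np.sqrt(R) * _HERTZ_UNIT_NN


def hertz_force(delta, p: HertzParams):
    """Spherical Hertz force (nN) at indentation ``delta`` (µm), F(0) = 0."""
    delta = np.asarray(delta, dtype=float)
    if np.any(delta < 0):
        raise ValueError("negative indentation passed to hertz_force")
    return _hertz_prefactor(p.E, p.nu, p.R) * delta**1.5


def two_layer_force(delta, E1: float, E2c: float, dc2: float, nu: float = 0.5, R: float = 2.25):
    """Additive two-regime force (nN); ``E2c`` is the *component* modulus."""
    delta = np.asarray(delta, dtype=float)
    out = _hertz_prefactor(E1, nu, R) * np.clip(delta, 0.0, None) ** 1.5
    out += _hertz_prefactor(E2c, nu, R) * np.clip(delta - dc2, 0.0, None) ** 1.5
    return out


def second_regime_modulus(
    delta: np.ndarray, E1: float, E2c: float, dc2: float, nu: float = 0.5, R: float = 2.25
) -> float:
    """Reported E2: single-layer modulus of the post-``dc2`` combined regime.

    Least-squares projection of the noise-free two-regime model onto the
    single-layer basis ``(delta - dc2)^(3/2)`` over the supplied post-contact
    samples. Affine in (E1, E2c), so exactly invertible by the generator.
    """
    d = np.asarray(delta, dtype=float)
    d = d[d > dc2]
    if len(d) < 2:
        raise ValueError("need at least 2 samples beyond the second contact")
    b = (d - dc2) ** 1.5
    f = E1 * d**1.5 + E2c * b  # common prefactor cancels in the ratio
    return float(np.dot(f, b) / np.dot(b, b))


# ---------------------------------------------------------------------------
# Contact detection
# ---------------------------------------------------------------------------


def detect_contact(
    curve: ForceCurve,
    threshold: float = 3.0,
    min_run: int = 5,
    baseline_fraction: float = 0.3,
) -> float:
    """Detect the first contact point on a baseline-corrected approach.

    Returns the piezo height ``z`` (µm) of the first sample after which the
    force exceeds ``threshold`` × baseline noise SD for at least ``min_run``
    consecutive samples. The ZP surface is rough, so a sustained-crossing
    rule is used instead of a single-sample threshold.
    """
    app = curve.mask("approach")
    z = curve.z[app]
    f = curve.meta.spring_constant * curve.d[app] * DEFLECTION_TO_FORCE_NN
    n_win = int(np.floor(baseline_fraction * len(z)))
    if n_win < 16:
        raise CurveValidationError("need >= 16 non-contact samples for detection")
    sd = float(np.std(f[:n_win]))
    sd = max(sd, 1e-9)  # noise-free synthetic curves: fall back to a tiny floor
    above = f > threshold * sd
    # first index where `min_run` consecutive samples are all above threshold
    run = np.convolve(above.astype(int), np.ones(min_run, dtype=int), mode="valid")
    hits = np.flatnonzero(run == min_run)
    if len(hits) == 0:
        raise NoContactError(
            f"no sustained force rise above {threshold} x noise SD ({sd:.3g} nN)"
        )
    return float(z[hits[0]])


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitConfig:
    """Knobs for the Hertz fits; defaults are the package's declared choices."""

    nu: float = 0.5
    E_bounds: tuple[float, float] = (1.0, 1.0e6)
    baseline_cut: float = -1.0  # µm of pre-contact data kept to anchor the offset
    n_multistart: int = 5
    min_single_points: int = 20
    min_two_layer_points: int = 40
    # two-layer specifics; the threshold detector fires late by
    # (threshold*sd/E1)^(2/3)-ish, ~0.4 µm on a 50 Pa outer layer, so the
    # first-contact search must extend well before the detected point
    n_contact1_candidates: int = 9
    contact1_before: float = 0.6  # µm searched before min(0, single-layer offset)
    contact1_after: float = 0.2  # µm searched after max(0, single-layer offset)
    max_contact2_candidates: int = 60
    min_rss_improvement: float = 0.05  # second layer supported if rss drops >5%


@dataclass
class HertzFit:
    """Single-layer fit result.

    ``delta0`` and ``force_offset`` are nuisance parameters: the threshold
    contact detector fires late on soft samples (by construction the force at
    the detected point equals the detection threshold), so both the contact
    position and a constant force offset must be co-fitted.
    """

    E: float  # Pa
    delta0: float  # µm, refinement of the contact point on the delta axis
    force_offset: float  # nN, constant baseline offset co-fitted with E
    nu: float
    R: float
    rss: float  # nN^2
    n_points: int
    converged: bool


@dataclass
class TwoLayerFit:
    """Two-contact-point fit result (E1/E2 in Pa, depths in µm)."""

    E1: float
    E2: float  # reported convention: second-regime slope modulus
    E2_component: float  # additive component modulus E2c
    contact1_z: float  # µm in the original z axis (nan if unknown)
    contact1_delta: float  # µm refinement on the delta axis
    contact2_delta: float  # µm beyond the first contact; nan if unsupported
    force_offset: float  # nN, constant baseline offset co-fitted with the moduli
    nu: float
    R: float
    rss: float  # nN^2
    n_points: int
    converged: bool
    second_layer_supported: bool


def _curve_seed(arr: np.ndarray) -> int:
    return zlib.crc32(np.ascontiguousarray(arr).tobytes()) & 0x7FFFFFFF


def _fit_arrays(ind: IndentationCurve, cfg: FitConfig, delta_max: float | None):
    delta, force = ind.seg("approach")
    keep = delta >= cfg.baseline_cut
    if delta_max is not None:
        keep &= delta <= delta_max
    return delta[keep], force[keep]


def fit_single_hertz(
    ind: IndentationCurve,
    p0: HertzParams | None = None,
    cfg: FitConfig = FitConfig(),
    delta_max: float | None = None,
) -> HertzFit:
    """Nonlinear least squares of the single-layer Hertz model.

    Free parameters are the modulus ``E`` and a contact-offset refinement
    ``delta0`` (the threshold detector fires late on soft samples, so the
    offset must be fitted). Five deterministic multistarts over ``delta0``
    guard against the shallow-contact local minimum; non-convergence is
    flagged on the result rather than raised.
    """
    delta, force = _fit_arrays(ind, cfg, delta_max)
    n_contact = int((delta > 0).sum())
    if n_contact < cfg.min_single_points:
        raise CurveValidationError(
            f"{n_contact} in-contact samples, need >= {cfg.min_single_points}"
        )
    R = ind.meta.bead_radius if p0 is None else p0.R
    nu = cfg.nu if p0 is None else p0.nu
    pref = _hertz_prefactor(1.0, nu, R)
    dmax = float(delta.max())

    def resid(x):
        E, d0, f0 = x
        return pref * E * np.clip(delta - d0, 0.0, None) ** 1.5 + f0 - force

    rng = np.random.default_rng(_curve_seed(delta))
    starts = np.array([0.0, -0.1, 0.1, -0.25, 0.25])[: cfg.n_multistart] * max(dmax, 0.5)
    starts = starts + rng.normal(0.0, 0.01, size=len(starts))
    lo_d0, hi_d0 = max(float(delta.min()), -2.0), 0.8 * dmax
    f_span = float(force.max() - force.min())
    best = None
    for d0 in np.clip(starts, lo_d0 + 1e-6, hi_d0 - 1e-6):
        span = max(dmax - d0, 0.1)
        e0 = float(np.clip(force.max() / (pref * span**1.5), *cfg.E_bounds))
        if p0 is not None:
            e0 = float(np.clip(p0.E, *cfg.E_bounds))
        res = least_squares(
            resid,
            x0=[e0, d0, 0.0],
            bounds=(
                [cfg.E_bounds[0], lo_d0, -0.5 * f_span],
                [cfg.E_bounds[1], hi_d0, 0.5 * f_span],
            ),
            x_scale="jac",
        )
        if best is None or res.cost < best.cost:
            best = res
    rss = float(2.0 * best.cost)
    return HertzFit(
        E=float(best.x[0]),
        delta0=float(best.x[1]),
        force_offset=float(best.x[2]),
        nu=nu,
        R=R,
        rss=rss,
        n_points=len(delta),
        converged=bool(best.success and np.isfinite(rss)),
    )


def _nnls2(b1: np.ndarray, b2: np.ndarray, f: np.ndarray):
    """Nonnegative least squares for two basis columns, closed form."""
    a11, a12, a22 = b1 @ b1, b1 @ b2, b2 @ b2
    y1, y2 = b1 @ f, b2 @ f
    ff = f @ f
    det = a11 * a22 - a12 * a12
    if det > 0:
        x1 = (a22 * y1 - a12 * y2) / det
        x2 = (a11 * y2 - a12 * y1) / det
        if x1 >= 0 and x2 >= 0:
            rss = ff - x1 * y1 - x2 * y2
            return x1, x2, max(rss, 0.0)
    # boundary: one component only
    x1 = max(y1 / a11, 0.0) if a11 > 0 else 0.0
    x2 = max(y2 / a22, 0.0) if a22 > 0 else 0.0
    rss1 = ff - 2 * x1 * y1 + x1 * x1 * a11
    rss2 = ff - 2 * x2 * y2 + x2 * x2 * a22
    return (x1, 0.0, max(rss1, 0.0)) if rss1 <= rss2 else (0.0, x2, max(rss2, 0.0))


def fit_two_layer(ind: IndentationCurve, cfg: FitConfig = FitConfig()) -> TwoLayerFit:
    """Fit the additive two-regime model with two contact points.

    Strategy: a single-layer fit first (reference for the nested-model
    support test), then a grid over candidate first-contact refinements and
    second-contact depths with a closed-form nonnegative least squares for
    (E1, E2c) at each node, then a bounded 4-parameter polish. For inputs
    that are genuinely single-layer the improvement criterion fails and the
    second contribution is flagged unsupported (E2 then equals the
    single-layer modulus and ``contact2_delta`` is NaN).
    """
    delta, force = _fit_arrays(ind, cfg, None)
    n_contact = int((delta > 0).sum())
    if n_contact < cfg.min_two_layer_points:
        raise CurveValidationError(
            f"{n_contact} in-contact samples, need >= {cfg.min_two_layer_points}"
        )
    single = fit_single_hertz(ind, cfg=cfg)
    nu, R = cfg.nu, ind.meta.bead_radius
    pref = _hertz_prefactor(1.0, nu, R)

    # candidate first-contact refinements span both the detected contact (0)
    # and the single-layer offset, either of which may be closer to truth
    c1_lo = min(0.0, single.delta0) - cfg.contact1_before
    c1_hi = max(0.0, single.delta0) + cfg.contact1_after
    c1_grid = np.linspace(c1_lo, c1_hi, cfg.n_contact1_candidates)
    f_mean = float(force.mean())
    fc = force - f_mean
    best = None  # (rss, E1, E2c, c1, c2)
    for c1 in c1_grid:
        dr = delta - c1
        in_contact = np.sort(dr[dr > 0])
        if len(in_contact) < cfg.min_two_layer_points:
            continue
        # candidate engagement depths: interior quantiles at sample resolution
        lo = int(0.05 * len(in_contact))
        hi = int(0.90 * len(in_contact))
        cands = in_contact[lo:hi]
        if len(cands) > cfg.max_contact2_candidates:
            idx = np.linspace(0, len(cands) - 1, cfg.max_contact2_candidates).astype(int)
            cands = cands[idx]
        b1 = pref * np.clip(dr, 0.0, None) ** 1.5
        b1c = b1 - b1.mean()
        for c2 in cands:
            b2 = pref * np.clip(dr - c2, 0.0, None) ** 1.5
            # free constant offset projected out by mean-centering; the
            # nonnegativity case analysis in _nnls2 remains exact
            e1, e2c, rss = _nnls2(b1c, b2 - b2.mean(), fc)
            if best is None or rss < best[0]:
                best = (rss, e1, e2c, c1, c2)

    if best is None:
        raise CurveValidationError("no valid second-contact candidates")
    _, e1, e2c, c1, c2 = best

    dr_max = float((delta - c1).max())
    f_span = float(force.max() - force.min())

    def resid(x):
        E1, E2c, cc1, cc2, f0 = x
        return two_layer_force(delta - cc1, E1, E2c, cc2, nu, R) + f0 - force

    res = least_squares(
        resid,
        x0=[max(e1, 1.0), max(e2c, 0.0), c1, c2, 0.0],
        bounds=(
            [cfg.E_bounds[0], 0.0, c1_lo - 0.05, 0.02, -0.5 * f_span],
            [cfg.E_bounds[1], cfg.E_bounds[1], c1_hi + 0.05, 0.95 * dr_max, 0.5 * f_span],
        ),
        x_scale="jac",
    )
    E1, E2c, c1, c2, f0 = (float(v) for v in res.x)
    rss_two = float(2.0 * res.cost)

    improvement = 1.0 - rss_two / single.rss if single.rss > 0 else 0.0
    dr = delta - c1
    interior = 0.05 * dr_max < c2 < 0.90 * dr_max
    supported = improvement > cfg.min_rss_improvement and interior and E2c > 0
    converged = bool(res.success and np.isfinite(rss_two))

    contact1_z = ind.contact_z + c1 if np.isfinite(ind.contact_z) else float("nan")
    if supported:
        e2_reported = second_regime_modulus(dr, E1, E2c, c2, nu, R)
        return TwoLayerFit(
            E1=E1, E2=e2_reported, E2_component=E2c,
            contact1_z=contact1_z, contact1_delta=c1, contact2_delta=c2,
            force_offset=f0,
            nu=nu, R=R, rss=rss_two, n_points=len(delta),
            converged=converged, second_layer_supported=True,
        )
    return TwoLayerFit(
        E1=single.E, E2=single.E, E2_component=0.0,
        contact1_z=(ind.contact_z + single.delta0 if np.isfinite(ind.contact_z) else float("nan")),
        contact1_delta=single.delta0, contact2_delta=float("nan"),
        force_offset=single.force_offset,
        nu=nu, R=R, rss=single.rss, n_points=single.n_points,
        converged=single.converged, second_layer_supported=False,
    )


# ---------------------------------------------------------------------------
# Grid aggregation
# ---------------------------------------------------------------------------


@dataclass
class GridSummary:
    """Per-oocyte summary of a grid of two-layer fits."""

    table: pd.DataFrame  # one row per fit: position, replicate, E1, E2, converged
    mean_E1: float
    sd_E1: float
    mean_E2: float
    sd_E2: float
    n_curves: int
    per_position: pd.DataFrame = field(default=None)  # type: ignore[assignment]


def summarize_grid(
    fits: list[TwoLayerFit],
    layout: tuple[int, int, int] = (3, 3, 3),
    positions: list[tuple[int, int, int]] | None = None,
) -> GridSummary:
    """Aggregate grid fits: means/SDs over converged fits, per-position means.

    ``layout`` is (rows, cols, replicates); the standard protocol is a
    3 µm × 3 µm grid of 3×3 positions with 3 curves each, 27 curves per
    oocyte. Incomplete grids are summarized as-is.
    """
    rows, cols, reps = layout
    if positions is None:
        positions = [
            (r, c, k)
            for r in range(rows)
            for c in range(cols)
            for k in range(reps)
        ][: len(fits)]
    recs = [
        {
            "row": p[0], "col": p[1], "replicate": p[2],
            "E1_Pa": f.E1, "E2_Pa": f.E2,
            "contact2_delta_um": f.contact2_delta,
            "rss": f.rss, "converged": f.converged,
        }
        for f, p in zip(fits, positions)
    ]
    table = pd.DataFrame(recs)
    conv = table[table["converged"]]
    if len(conv) == 0:
        raise CurveValidationError("zero converged fits in grid")
    per_position = (
        conv.groupby(["row", "col"])[["E1_Pa", "E2_Pa"]].mean().reset_index()
    )
    return GridSummary(
        table=table,
        mean_E1=float(conv["E1_Pa"].mean()),
        sd_E1=float(conv["E1_Pa"].std(ddof=1)) if len(conv) > 1 else 0.0,
        mean_E2=float(conv["E2_Pa"].mean()),
        sd_E2=float(conv["E2_Pa"].std(ddof=1)) if len(conv) > 1 else 0.0,
        n_curves=len(fits),
        per_position=per_position,
    )
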