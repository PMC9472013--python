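"""Ground-truth generators for every input the analysis pipeline consumes.

The generators encode the study conditions the analysis assumes: spherical
1-nN indentations of a two-layer zona pellucida acquired at 5 µm/s on a
3×3×3 grid, 30-s stress-relaxation holds after a 20 µm compression at
2 µm/s, ring-shaped perivitelline fluorescence with photobleaching, and
hourly aging cohorts in which stiffness doubles and dissipation halves one
hour before visual degradation, anticipated ~2 h earlier by the
cortical-granule fluorescence rise.

Every generator is a pure function of (config, seed) and logs its truths so
downstream estimators can be scored without re-reading the config.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .aging import OocyteTimeline
from .curveio import DEFLECTION_TO_FORCE_NN, ForceCurve, ProbeMeta, RelaxationTrace
from .elasticity import hertz_force, HertzParams, second_regime_modulus, two_layer_force

__all__ = [
    "SynthConfig",
    "gen_force_curve",
    "gen_grid",
    "gen_relaxation",
    "gen_cohort",
    "gen_fluor_stack",
]


@dataclass(frozen=True)
class SynthConfig:
    """Study-condition defaults for all generators.

    Mechanical truths default to the thawed-oocyte means (E1 = 50 Pa,
    E2 = 160 Pa); the probe is the 0.32 N/m cantilever with a 4.5 µm bead at
    a 1 nN setpoint and 5 µm/s. Aging multipliers mirror the observed
    doubling of the elastic modulus and halving of dissipation one hour
    before degradation, with the fluorescence onset leading by 2 h; the
    photobleaching control loses 20% of intensity over 90 min.
    """

    seed: int = 0
    probe: ProbeMeta = field(default_factory=lambda: ProbeMeta(spring_constant=0.32))
    # indentation truths
    e1: float = 50.0  # Pa, outer ZP layer
    e2: float | None = 160.0  # Pa, reported second-regime modulus; None -> single layer
    contact2_delta: float = 0.8  # µm
    nu: float = 0.5
    noise_sd_force: float = 0.01  # nN, 1% of the 1 nN setpoint
    hysteresis_level: float = 0.5  # unitless viscosity index
    baseline_tilt: float = 0.0  # µm deflection drift per µm of z
    n_samples: int = 600  # approach samples
    pre_contact: float = 2.0  # µm of free travel before contact
    # relaxation truths
    a0: float = 0.5  # nN
    a1: float = 1.0  # nN
    a2: float = 0.5  # nN
    tau1: float = 1.0  # s
    tau2: float = 10.0  # s
    relax_noise_frac: float = 0.01  # of the initial hold force
    relax_speed: float = 2.0  # µm/s
    applied_displacement: float = 20.0  # µm
    hold_duration: float = 30.0  # s
    relax_dt: float = 0.05  # s
    # grid heterogeneity (within-cell scatter of the outer layer dominates)
    e1_grid_cv: float = 0.40
    e2_grid_cv: float = 0.07
    # cohort
    n_healthy: int = 15
    n_degraded: int = 20
    degradation_lo: float = 4.0  # h, uniform bounds for degradation time
    degradation_hi: float = 7.0
    aging_e2_mult: float = 2.0  # E2 multiplier at t_rel = -1 h
    post_peak_mult: float = 0.7  # softening factor applied to the peak at 0 h
    aging_diss_mult: float = 0.5  # dissipation multiplier from -1 h
    cg_onset_lead: float = 2.0  # h before degradation at which CG signal rises
    cg_rise_per_h: float = 1.5  # fractional CG rise per hour past onset
    baseline_dissipation: float = 0.30  # fJ
    baseline_cg: float = 100.0  # ADU·µm
    value_noise_cv: float = 0.03  # measurement noise on timeline values
    # fluorescence imaging
    bleach_fraction: float = 0.2  # intensity lost over bleach_span_min
    bleach_span_min: float = 90.0
    pixel_size: float = 0.65  # µm
    image_size: int = 128  # px
    ooplasm_radius_px: float = 26.0
    ring_radius_px: float = 31.0
    ring_sigma_px: float = 1.5
    ring_amplitude: float = 3000.0  # ADU above local base
    read_noise_sd: float = 3.0  # ADU


def _rng(cfg: SynthConfig, seed: int | None) -> np.random.Generator:
    return np.random.default_rng(cfg.seed if seed is None else seed)


# ---------------------------------------------------------------------------
# Force curves
# ---------------------------------------------------------------------------


def _forward_force(delta, e1, e2c, dc2, nu, R):
    if e2c is None:
        return hertz_force(np.clip(delta, 0.0, None), HertzParams(E=e1, nu=nu, R=R))
    return two_layer_force(delta, e1, e2c, dc2, nu, R)


def _delta_at_setpoint(e1, e2c, dc2, nu, R, setpoint):
    return brentq(
        lambda d: float(_forward_force(d, e1, e2c, dc2, nu, R)) - setpoint, 1e-9, 100.0
    )


def _component_from_reported(cfg: SynthConfig) -> tuple[float | None, float]:
    """Invert the reported-E2 convention: find the additive component modulus
    whose combined second regime fits the target E2 at the setpoint depth."""
    if cfg.e2 is None:
        return None, _delta_at_setpoint(
            cfg.e1, None, 0.0, cfg.nu, cfg.probe.bead_radius, cfg.probe.setpoint_force
        )
    e2c = max(cfg.e2 - cfg.e1, 1.0)
    dmax = 1.0
    for _ in range(20):
        dmax = _delta_at_setpoint(
            cfg.e1, e2c, cfg.contact2_delta, cfg.nu, cfg.probe.bead_radius,
            cfg.probe.setpoint_force,
        )
        ds = np.linspace(cfg.contact2_delta, dmax, 400)[1:]
        b = (ds - cfg.contact2_delta) ** 1.5
        alpha = float(np.dot(ds**1.5, b) / np.dot(b, b))
        new = max(cfg.e2 - alpha * cfg.e1, 0.5)
        if abs(new - e2c) < 1e-8 * max(e2c, 1.0):
            e2c = new
            break
        e2c = new
    return e2c, dmax


def gen_force_curve(cfg: SynthConfig, seed: int | None = None) -> ForceCurve:
    """One synthetic approach/retract force curve at the configured truths.

    The approach follows the additive two-regime Hertz model (or single-layer
    when ``cfg.e2`` is None); the retract is the approach minus a
    rate-and-viscosity-scaled fractional offset, producing a hysteresis loop
    whose area grows monotonically with ``hysteresis_level``. Gaussian force
    noise is mapped back to deflection. Truths (including the noise-free
    force backbone) are logged in ``curve.extra['truth']``.
    """
    rng = _rng(cfg, seed)
    k = cfg.probe.spring_constant
    R = cfg.probe.bead_radius
    e2c, dmax = _component_from_reported(cfg)
    zc = cfg.pre_contact
    d_at_max = cfg.probe.setpoint_force / (k * DEFLECTION_TO_FORCE_NN)
    z_end = zc + dmax + d_at_max

    # invert z(delta) = zc + delta + F(delta)/k on a fine grid
    fine = np.linspace(0.0, dmax, 4000)
    f_fine = _forward_force(fine, cfg.e1, e2c, cfg.contact2_delta, cfg.nu, R)
    z_of_delta = zc + fine + f_fine / (k * DEFLECTION_TO_FORCE_NN)

    z = np.linspace(0.0, z_end, cfg.n_samples)
    delta_true = np.where(z <= zc, z - zc, np.interp(z, z_of_delta, fine))
    f_app = np.where(
        z <= zc, 0.0, _forward_force(np.clip(delta_true, 0.0, None), cfg.e1, e2c,
                                     cfg.contact2_delta, cfg.nu, R)
    )
    hyst = min(0.25 * cfg.hysteresis_level * (cfg.probe.approach_speed / 5.0), 0.9)
    f_ret = (1.0 - hyst) * f_app

    sd_d = cfg.noise_sd_force / (k * DEFLECTION_TO_FORCE_NN)
    d_app = f_app / (k * DEFLECTION_TO_FORCE_NN) + rng.normal(0.0, sd_d, len(z))
    # retract deflection solved from the retract force law on the same z grid
    z_ret_of_delta = zc + fine + (1.0 - hyst) * f_fine / (k * DEFLECTION_TO_FORCE_NN)
    delta_ret = np.where(z <= zc, z - zc, np.interp(z, z_ret_of_delta, fine))
    f_ret_true = np.where(
        z <= zc, 0.0,
        (1.0 - hyst) * _forward_force(np.clip(delta_ret, 0.0, None), cfg.e1, e2c,
                                      cfg.contact2_delta, cfg.nu, R),
    )
    d_ret = f_ret_true / (k * DEFLECTION_TO_FORCE_NN) + rng.normal(0.0, sd_d, len(z))

    if cfg.baseline_tilt != 0.0:
        d_app = d_app + cfg.baseline_tilt * z
        d_ret = d_ret + cfg.baseline_tilt * z

    z_all = np.concatenate([z, z[::-1]])
    d_all = np.concatenate([d_app, d_ret[::-1]])
    seg = np.array(["approach"] * len(z) + ["retract"] * len(z), dtype=object)
    dt = np.abs(np.diff(z_all, prepend=z_all[0])) / cfg.probe.approach_speed
    t_all = np.cumsum(dt)

    energy_truth = hyst * float(np.trapezoid(f_fine, fine))
    truth = {
        "E1_Pa": cfg.e1,
        "E2_Pa": cfg.e2 if cfg.e2 is not None else cfg.e1,
        "E2_component_Pa": e2c,
        "contact2_delta_um": cfg.contact2_delta if cfg.e2 is not None else None,
        "contact_z_um": zc,
        "delta_max_um": dmax,
        "dissipated_energy_fJ": energy_truth,
        "hysteresis_fraction": hyst,
        "force_app_nN": f_app,
        "force_ret_nN": f_ret_true,
        "delta_app_um": delta_true,
    }
    curve = ForceCurve(
        z=z_all, d=d_all, t=t_all, segment=seg, meta=cfg.probe,
        extra={"truth": truth},
    )
    return curve


def gen_grid(cfg: SynthConfig, seed: int | None = None) -> list[ForceCurve]:
    """A 3×3 grid × 3 replicates (27 curves) with per-position modulus jitter.

    The outer layer is irregular (E1 jitter CV 40%) while the inner layer is
    homogeneous (E2 jitter CV 7%), reproducing the observed within-cell
    heterogeneity contrast. Replicates at a position share its truths and
    differ only in noise.
    """
    base = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(base)
    pos_rng = np.random.default_rng(ss.spawn(1)[0])
    curve_seeds = ss.generate_state(27) % (2**31)
    sig1 = np.sqrt(np.log(1 + cfg.e1_grid_cv**2))
    sig2 = np.sqrt(np.log(1 + cfg.e2_grid_cv**2))
    curves: list[ForceCurve] = []
    i = 0
    for r in range(3):
        for c in range(3):
            e1_p = cfg.e1 * float(pos_rng.lognormal(-sig1**2 / 2, sig1))
            e2_p = (
                cfg.e2 * float(pos_rng.lognormal(-sig2**2 / 2, sig2))
                if cfg.e2 is not None
                else None
            )
            if e2_p is not None:
                e2_p = max(e2_p, 1.5 * e1_p)  # the inner layer is the stiffer one
            pos_cfg = replace(cfg, e1=e1_p, e2=e2_p)
            for rep in range(3):
                curve = gen_force_curve(pos_cfg, seed=int(curve_seeds[i]))
                curve.position = (r, c, rep)
                curves.append(curve)
                i += 1
    return curves


# ---------------------------------------------------------------------------
# Stress relaxation
# ---------------------------------------------------------------------------


def gen_relaxation(cfg: SynthConfig, seed: int | None = None) -> RelaxationTrace:
    """A loading ramp plus 30-s hold following the two-element Maxwell law."""
    rng = _rng(cfg, seed)
    t_ramp = cfg.applied_displacement / cfg.relax_speed
    t = np.arange(0.0, t_ramp + cfg.hold_duration + cfg.relax_dt / 2, cfg.relax_dt)
    f0 = cfg.a0 + cfg.a1 + cfg.a2
    f = np.where(
        t < t_ramp,
        f0 * (t / t_ramp),
        cfg.a0
        + cfg.a1 * np.exp(-(t - t_ramp) / cfg.tau1)
        + cfg.a2 * np.exp(-(t - t_ramp) / cfg.tau2),
    )
    noisy = f + rng.normal(0.0, cfg.relax_noise_frac * f0, len(t))
    truth = {
        "a0_nN": cfg.a0, "a1_nN": cfg.a1, "a2_nN": cfg.a2,
        "tau1_s": cfg.tau1, "tau2_s": cfg.tau2, "t0_s": t_ramp,
        "force_nN": f,
    }
    return RelaxationTrace(
        t=t, force=noisy, t0=t_ramp,
        applied_displacement=cfg.applied_displacement,
        meta=replace(cfg.probe, approach_speed=cfg.relax_speed),
        extra={"truth": truth},
    )


# ---------------------------------------------------------------------------
# Fluorescence stacks
# ---------------------------------------------------------------------------


def gen_fluor_stack(
    cfg: SynthConfig,
    seed: int | None = None,
    n_frames: int = 19,
    schedule: np.ndarray | None = None,
    bleach: bool = True,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Synthetic fluorescence stack: ooplasm disk + annular PVS ring + noise.

    ``schedule`` holds the pre-bleach ring amplitude per frame (default: a
    constant control series). Exponential photobleaching scales the *whole*
    image so that ``bleach_fraction`` of the intensity is lost over
    ``bleach_span_min``. Returns (uint16 stack, times in minutes, truths).
    """
    rng = _rng(cfg, seed)
    n = cfg.image_size
    times = np.linspace(0.0, cfg.bleach_span_min, n_frames)
    if schedule is None:
        schedule = np.full(n_frames, cfg.ring_amplitude)
    schedule = np.asarray(schedule, dtype=float)
    if len(schedule) != n_frames:
        raise ValueError("schedule length must equal n_frames")
    center = ((n - 1) / 2.0 + rng.uniform(-2, 2), (n - 1) / 2.0 + rng.uniform(-2, 2))
    rr, cc = np.mgrid[0:n, 0:n]
    r = np.hypot(rr - center[0], cc - center[1])
    base = 40.0 + 60.0 * (r < cfg.ooplasm_radius_px)
    ring_shape = np.exp(-((r - cfg.ring_radius_px) ** 2) / (2 * cfg.ring_sigma_px**2))
    lam = -np.log(1.0 - cfg.bleach_fraction) / cfg.bleach_span_min if bleach else 0.0
    frames = []
    for i, t_min in enumerate(times):
        f = np.exp(-lam * t_min)
        img = f * (base + schedule[i] * ring_shape)
        img = rng.poisson(img).astype(float) + rng.normal(0.0, cfg.read_noise_sd, img.shape)
        frames.append(np.clip(img, 0.0, 65535.0))
    stack = np.stack(frames).astype(np.uint16)
    truth = {
        "center_px": center,
        "ring_radius_um": cfg.ring_radius_px * cfg.pixel_size,
        "schedule": schedule,
        "bleach_lambda_per_min": lam,
        "expected_end_over_start": (
            float(np.exp(-lam * times[-1]) * schedule[-1] / schedule[0])
            if schedule[0] > 0
            else float("nan")
        ),
        "pixel_size_um": cfg.pixel_size,
    }
    return stack, times, truth


# ---------------------------------------------------------------------------
# Aging cohorts
# ---------------------------------------------------------------------------


def _degraded_multipliers(t_rel: float, cfg: SynthConfig) -> tuple[float, float, float]:
    """(E2, dissipation, CG) multipliers at aligned hour ``t_rel`` (<= 0)."""
    if t_rel <= -2:
        m_e2 = 1.0
    elif t_rel == -1:
        m_e2 = cfg.aging_e2_mult
    else:  # t_rel == 0: post-peak softening
        m_e2 = cfg.aging_e2_mult * cfg.post_peak_mult
    m_diss = cfg.aging_diss_mult if t_rel >= -1 else 1.0
    # the CG signal is already elevated at the onset observation and keeps
    # ramping, so the fluorescence rise leads the stiffness jump by the lead
    m_cg = (
        1.0 + cfg.cg_rise_per_h * (t_rel + cfg.cg_onset_lead + 1.0)
        if t_rel >= -cfg.cg_onset_lead
        else 1.0
    )
    return m_e2, m_diss, m_cg


def gen_cohort(
    cfg: SynthConfig,
    seed: int | None = None,
    detail: str = "values",
) -> tuple[list[OocyteTimeline], dict]:
    """Hourly aging cohort of healthy and degrading oocytes.

    Healthy oocytes hold flat baselines over hours 0–6. Degrading oocytes
    draw a degradation time U(4, 7) h; their E2 doubles at −1 h and softens
    to 0.7× the peak at 0 h, dissipation halves from −1 h, and the CG signal
    ramps up from −2 h. Morphology turns (and stays) degraded at the first
    observation at/after the degradation time.

    ``detail="values"`` emits timelines only; ``detail="curves"`` also
    returns one synthetic force curve per oocyte-hour at the hour's E2 truth
    (in the second element of the returned truths under ``"curves"``).
    """
    if detail not in ("values", "curves"):
        raise ValueError("detail must be 'values' or 'curves'")
    base = cfg.seed if seed is None else seed
    ss = np.random.SeedSequence(base)
    rng = np.random.default_rng(ss.spawn(1)[0])
    curve_seed_iter = iter(ss.generate_state(2000) % (2**31))

    timelines: list[OocyteTimeline] = []
    truths: dict = {"oocytes": {}, "config": cfg, "curves": {}}

    def noisy(x):
        return float(x * (1.0 + rng.normal(0.0, cfg.value_noise_cv)))

    for i in range(cfg.n_healthy + cfg.n_degraded):
        oid = f"oo{i:03d}"
        is_deg = i >= cfg.n_healthy
        e2_base = cfg.e2 * float(rng.lognormal(-0.00125, 0.05))
        diss_base = cfg.baseline_dissipation * float(rng.lognormal(-0.00125, 0.05))
        cg_base = cfg.baseline_cg * float(rng.lognormal(-0.00125, 0.05))
        if is_deg:
            t_deg = float(rng.uniform(cfg.degradation_lo, cfg.degradation_hi))
            h_deg = int(np.ceil(t_deg))
            hours = np.arange(0, h_deg + 1)
        else:
            t_deg = None
            hours = np.arange(0, 7)
        rows = []
        for h in hours:
            if is_deg:
                m_e2, m_diss, m_cg = _degraded_multipliers(h - h_deg, cfg)
                morph = "degraded" if h >= t_deg else "healthy"
            else:
                m_e2 = m_diss = m_cg = 1.0
                morph = "healthy"
            e2_h = noisy(e2_base * m_e2)
            rows.append(
                {
                    "t_hours": float(h),
                    "E2_Pa": e2_h,
                    "dissipation_fJ": noisy(diss_base * m_diss),
                    "cg_area": noisy(cg_base * m_cg),
                    "morphology": morph,
                }
            )
            if detail == "curves":
                ccfg = replace(cfg, e2=max(e2_h, 1.5 * cfg.e1))
                truths["curves"][(oid, int(h))] = gen_force_curve(
                    ccfg, seed=int(next(curve_seed_iter))
                )
        timelines.append(
            OocyteTimeline(oocyte_id=oid, source="thawed", data=pd.DataFrame(rows))
        )
        truths["oocytes"][oid] = {
            "degradation_time_h": t_deg,
            "E2_baseline_Pa": e2_base,
            "dissipation_baseline_fJ": diss_base,
            "cg_baseline": cg_base,
        }
    return timelines, truths
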