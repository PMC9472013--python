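"""Force-curve data model, TSV readers/writers, and physical preprocessing.

Conventions
-----------
* piezo height ``z`` increases toward the sample (extension);
* deflection ``d`` is positive when the cantilever is pushed up, so force is
  positive in compression;
* indentation ``delta`` is positive into the sample.

Arrays are stored in µm / nN / s; the only unit conversion in this module is
spring constant (N/m) × deflection (µm) → µN, times 1e3 to express force in nN.
"""

from __future__ import annotations

import io
import json
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ProbeMeta",
    "ForceCurve",
    "IndentationCurve",
    "RelaxationTrace",
    "CurveFormatError",
    "CurveValidationError",
    "read_curve",
    "write_curve",
    "baseline_correct",
    "to_indentation",
    "DEFLECTION_TO_FORCE_NN",
]

#: nN of force per (N/m of stiffness × µm of deflection)
DEFLECTION_TO_FORCE_NN = 1.0e3

SEGMENTS = ("approach", "hold", "retract")

MIN_CURVE_SAMPLES = 16


class CurveFormatError(ValueError):
    """A curve file does not conform to the TSV dialect."""


class CurveValidationError(ValueError):
    """Curve data violate a physical or structural invariant."""


@dataclass(frozen=True)
class ProbeMeta:
    """Probe and acquisition metadata.

    Parameters
    ----------
    spring_constant : float
        Cantilever stiffness in N/m (nominal 0.32 N/m for the bead probes).
    bead_radius : float
        Spherical indenter radius in µm (default 2.25 µm, i.e. a 4.5 µm bead).
    approach_speed : float
        Piezo speed in µm/s.
    setpoint_force : float
        Maximum force load in nN.
    deflection_sensitivity : float or None
        Optical-lever sensitivity in nm/V, ``None`` when the deflection
        channel is already expressed in length units.
    """

    spring_constant: float
    bead_radius: float = 2.25
    approach_speed: float = 5.0
    setpoint_force: float = 1.0
    deflection_sensitivity: float | None = None

    def __post_init__(self) -> None:
        if not self.spring_constant > 0:
            raise CurveValidationError("spring_constant must be > 0")
        if not self.bead_radius > 0:
            raise CurveValidationError("bead_radius must be > 0")
        if not self.approach_speed > 0:
            raise CurveValidationError("approach_speed must be > 0")


def _monotone(x: np.ndarray, increasing: bool, tol: float = 1e-12) -> int:
    """Return -1 if monotone (given direction), else first offending index."""
    dx = np.diff(x)
    bad = dx < -tol if increasing else dx > tol
    if bad.any():
        return int(np.argmax(bad)) + 1
    return -1


@dataclass
class ForceCurve:
    """Raw piezo-height / deflection / time record with segment labels."""

    z: np.ndarray  # µm
    d: np.ndarray  # µm
    t: np.ndarray  # s
    segment: np.ndarray  # str labels from SEGMENTS
    meta: ProbeMeta
    position: tuple[int, int, int] | None = None  # (row, col, replicate)
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        self.segment = np.asarray(self.segment, dtype=object)
        n = len(self.z)
        if not (len(self.d) == len(self.t) == len(self.segment) == n):
            raise CurveValidationError("z, d, t, segment must have equal length")
        if n < MIN_CURVE_SAMPLES:
            raise CurveValidationError(
                f"curve has {n} samples, need >= {MIN_CURVE_SAMPLES}"
            )
        unknown = set(np.unique(self.segment)) - set(SEGMENTS)
        if unknown:
            raise CurveValidationError(f"unknown segment labels: {sorted(unknown)}")
        app = self.segment == "approach"
        ret = self.segment == "retract"
        if app.any():
            i = _monotone(self.z[app], increasing=True)
            if i >= 0:
                raise CurveValidationError(
                    f"approach z is not monotone non-decreasing (first offending sample {i})"
                )
        if ret.any():
            i = _monotone(self.z[ret], increasing=False)
            if i >= 0:
                raise CurveValidationError(
                    f"retract z is not monotone non-increasing (first offending sample {i})"
                )
        if not ret.any():
            warnings.warn("curve has no retract segment", stacklevel=2)

    def mask(self, name: str) -> np.ndarray:
        return self.segment == name

    @property
    def approach(self) -> "ForceCurve":
        m = self.mask("approach")
        return replace(self, z=self.z[m], d=self.d[m], t=self.t[m], segment=self.segment[m])


@dataclass
class IndentationCurve:
    """Force vs indentation per segment, derived from a ForceCurve.

    ``delta`` is zero at the supplied contact point by construction; samples
    acquired before contact keep their negative delta for diagnostics.
    """

    delta: np.ndarray  # µm
    force: np.ndarray  # nN
    segment: np.ndarray
    meta: ProbeMeta
    contact_z: float = float("nan")  # µm, in the original z axis
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.delta = np.asarray(self.delta, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        self.segment = np.asarray(self.segment, dtype=object)
        if not (len(self.delta) == len(self.force) == len(self.segment)):
            raise CurveValidationError("delta, force, segment must have equal length")

    def seg(self, name: str) -> tuple[np.ndarray, np.ndarray]:
        m = self.segment == name
        return self.delta[m], self.force[m]


@dataclass
class RelaxationTrace:
    """Force-vs-time record of a constant-compression hold."""

    t: np.ndarray  # s
    force: np.ndarray  # nN
    t0: float  # s, start of the hold (end of the loading ramp)
    applied_displacement: float  # µm
    meta: ProbeMeta
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.force = np.asarray(self.force, dtype=float)
        if len(self.t) != len(self.force):
            raise CurveValidationError("t and force must have equal length")
        hold = self.t >= self.t0
        if hold.sum() < 2 or (self.t[hold][-1] - self.t0) < 10.0:
            raise CurveValidationError("hold window must last at least 10 s")


# ---------------------------------------------------------------------------
# TSV dialect
# ---------------------------------------------------------------------------
# UTF-8 TSV; '#'-prefixed `key: value` header lines with units in the key
# names; fixed column header `t_s  z_um  d_um  segment`; one curve per file.

_COLUMNS = ("t_s", "z_um", "d_um", "segment")

_META_KEYS = {
    "spring_constant_N_per_m": "spring_constant",
    "bead_radius_um": "bead_radius",
    "approach_speed_um_per_s": "approach_speed",
    "setpoint_force_nN": "setpoint_force",
    "deflection_sensitivity_nm_per_V": "deflection_sensitivity",
}


def read_curve(path, dialect: dict | None = None) -> ForceCurve:
    """Read a force curve from the TSV dialect.

    ``dialect`` may override ``sep`` (default tab) and ``comment`` (default
    ``#``). Unknown header keys are preserved in ``curve.extra``.
    """
    sep = (dialect or {}).get("sep", "\t")
    comment = (dialect or {}).get("comment", "#")
    header: dict[str, str] = {}
    body_lines: list[str] = []
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            if line.startswith(comment):
                stripped = line.lstrip(comment).strip()
                if ":" in stripped:
                    key, _, val = stripped.partition(":")
                    header[key.strip()] = val.strip()
            else:
                body_lines.append(line)
    if not body_lines:
        raise CurveFormatError(f"{path}: no data rows")
    df = pd.read_csv(io.StringIO("".join(body_lines)), sep=sep)
    for col in _COLUMNS:
        if col not in df.columns:
            raise CurveFormatError(f"{path}: missing mandatory column '{col}'")

    meta_kwargs: dict[str, float] = {}
    extra: dict = {}
    position = [None, None, None]
    for key, val in header.items():
        if key in _META_KEYS:
            meta_kwargs[_META_KEYS[key]] = float(val)
        elif key == "position_row":
            position[0] = int(val)
        elif key == "position_col":
            position[1] = int(val)
        elif key == "replicate":
            position[2] = int(val)
        else:
            extra[key] = val
    if "spring_constant" not in meta_kwargs:
        raise CurveFormatError(
            f"{path}: missing mandatory header key 'spring_constant_N_per_m'"
        )
    meta = ProbeMeta(**meta_kwargs)
    pos = tuple(p if p is not None else 0 for p in position) if any(
        p is not None for p in position
    ) else None
    return ForceCurve(
        z=df["z_um"].to_numpy(),
        d=df["d_um"].to_numpy(),
        t=df["t_s"].to_numpy(),
        segment=df["segment"].to_numpy(),
        meta=meta,
        position=pos,
        extra=extra,
    )


def write_curve(curve: ForceCurve, path) -> None:
    """Write a curve in the TSV dialect (lossless to float round-trip)."""
    inv = {v: k for k, v in _META_KEYS.items()}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# ovomech force curve v1\n")
        for attr, key in ((a, inv[a]) for a in inv):
            val = getattr(curve.meta, attr)
            if val is not None:
                fh.write(f"# {key}: {val!r}\n")
        if curve.position is not None:
            fh.write(f"# position_row: {curve.position[0]}\n")
            fh.write(f"# position_col: {curve.position[1]}\n")
            fh.write(f"# replicate: {curve.position[2]}\n")
        for key, val in curve.extra.items():
            if isinstance(val, (str, int, float)):
                fh.write(f"# {key}: {val}\n")
        fh.write("\t".join(_COLUMNS) + "\n")
        for ti, zi, di, si in zip(curve.t, curve.z, curve.d, curve.segment):
            fh.write(f"{float(ti)!r}\t{float(zi)!r}\t{float(di)!r}\t{si}\n")


def metadata_json(curve: ForceCurve) -> str:
    """JSON export of parsed metadata (probe, position, free header keys)."""
    payload = {
        "spring_constant_N_per_m": curve.meta.spring_constant,
        "bead_radius_um": curve.meta.bead_radius,
        "approach_speed_um_per_s": curve.meta.approach_speed,
        "setpoint_force_nN": curve.meta.setpoint_force,
        "deflection_sensitivity_nm_per_V": curve.meta.deflection_sensitivity,
        "position": curve.position,
        "extra": {k: v for k, v in curve.extra.items() if isinstance(v, (str, int, float))},
    }
    return json.dumps(payload, indent=2)


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------


def baseline_correct(curve: ForceCurve, fraction: float = 0.3) -> ForceCurve:
    """Subtract a linear baseline fitted on the first ``fraction`` of approach.

    The first ``fraction`` of approach samples (in acquisition order) are
    assumed non-contact; a line in ``z`` fitted there is subtracted from the
    deflection over *all* segments, so the corrected non-contact deflection
    has ~zero mean and slope.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    app = curve.mask("approach")
    n_win = int(np.floor(fraction * app.sum()))
    if n_win < 8:
        raise CurveValidationError(
            f"baseline window has {n_win} samples, need >= 8"
        )
    zw = curve.z[app][:n_win]
    dw = curve.d[app][:n_win]
    slope, intercept = np.polyfit(zw, dw, 1)
    d_corr = curve.d - (slope * curve.z + intercept)
    out = replace(curve, d=d_corr)
    out.extra = dict(curve.extra)
    out.extra["baseline_fraction"] = fraction
    out.extra["baseline_noise_sd_um"] = float(np.std(d_corr[app][:n_win]))
    return out


def to_indentation(curve: ForceCurve, contact_z: float) -> IndentationCurve:
    """Convert a baseline-corrected curve to force vs indentation.

    ``delta = (z - contact_z) - (d - d(contact_z))``: the cantilever bending
    is subtracted from the piezo travel past contact. Force is
    ``k * (d - d(contact_z))`` expressed in nN.
    """
    app = curve.mask("approach")
    z_app, d_app = curve.z[app], curve.d[app]
    if not (z_app.min() <= contact_z <= z_app.max()):
        raise CurveValidationError(
            f"contact_z={contact_z:g} outside approach z range "
            f"[{z_app.min():g}, {z_app.max():g}]"
        )
    d_c = float(np.interp(contact_z, z_app, d_app))
    delta = (curve.z - contact_z) - (curve.d - d_c)
    force = curve.meta.spring_constant * (curve.d - d_c) * DEFLECTION_TO_FORCE_NN
    return IndentationCurve(
        delta=delta,
        force=force,
        segment=curve.segment.copy(),
        meta=curve.meta,
        contact_z=contact_z,
        extra=dict(curve.extra),
    )
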