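"""End-to-end helpers chaining preprocessing, fitting, and dissipation."""

from __future__ import annotations

from .curveio import ForceCurve, IndentationCurve, baseline_correct, to_indentation
from .elasticity import (
    FitConfig,
    HertzFit,
    TwoLayerFit,
    detect_contact,
    fit_single_hertz,
    fit_two_layer,
)
from .viscoelasticity import DissipationResult, dissipated_energy

__all__ = ["prepare_indentation", "analyze_curve", "single_layer_modulus"]


def prepare_indentation(
    curve: ForceCurve, baseline_fraction: float = 0.3, threshold: float = 3.0
) -> IndentationCurve:
    """Baseline-correct, detect the first contact point, convert to indentation."""
    corr = baseline_correct(curve, fraction=baseline_fraction)
    contact_z = detect_contact(corr, threshold=threshold, baseline_fraction=baseline_fraction)
    return to_indentation(corr, contact_z)


def analyze_curve(
    curve: ForceCurve, cfg: FitConfig = FitConfig()
) -> tuple[TwoLayerFit, DissipationResult]:
    """Two-layer fit plus dissipated energy for one approach/retract cycle."""
    ind = prepare_indentation(curve)
    fit = fit_two_layer(ind, cfg=cfg)
    diss = dissipated_energy(ind)
    return fit, diss


def single_layer_modulus(curve: ForceCurve, cfg: FitConfig = FitConfig()) -> HertzFit:
    """Single-layer Hertz modulus of a prepared curve (e.g. ZP-removed ooplasm)."""
    ind = prepare_indentation(curve)
    return fit_single_hertz(ind, cfg=cfg)
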