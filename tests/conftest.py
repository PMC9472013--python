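import numpy as np
import pytest

from ovomech import ProbeMeta, SynthConfig
from ovomech.curveio import ForceCurve


@pytest.fixture
def probe() -> ProbeMeta:
    return ProbeMeta(spring_constant=0.32)


@pytest.fixture
def default_cfg() -> SynthConfig:
    return SynthConfig(seed=0)


def make_toy_curve(
    probe: ProbeMeta,
    n: int = 64,
    contact_z: float = 1.0,
    z_end: float = 2.0,
    deflection_fn=None,
    with_retract: bool = True,
) -> ForceCurve:
    """Hand-built curve: zero deflection before contact, caller-supplied after."""
    z = np.linspace(0.0, z_end, n)
    if deflection_fn is None:
        deflection_fn = lambda zz: np.zeros_like(zz)  # noqa: E731
    d = np.where(z > contact_z, deflection_fn(z), 0.0)
    if with_retract:
        z_all = np.concatenate([z, z[::-1]])
        d_all = np.concatenate([d, d[::-1]])
        seg = np.array(["approach"] * n + ["retract"] * n, dtype=object)
    else:
        z_all, d_all = z, d
        seg = np.array(["approach"] * n, dtype=object)
    t = np.arange(len(z_all)) * 0.001
    return ForceCurve(z=z_all, d=d_all, t=t, segment=seg, meta=probe)
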