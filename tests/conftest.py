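import numpy as np
import pytest

from dcemaxent.kinetics import KineticParams
from dcemaxent.synthetic_data import AIFShape, TimeGrid, generate_aif_curve


@pytest.fixture
def default_aif_curve():
    """Weibull-shaped AIF sampled on the 46-frame / 11.9 s protocol grid."""
    return generate_aif_curve(AIFShape(), TimeGrid())


@pytest.fixture
def fine_biexp_curve():
    """Biexponential AIF on a dense grid (dt = 0.01 min) for convolution oracles."""
    shape = AIFShape(family="biexponential", amplitude=0.1)
    return generate_aif_curve(shape, TimeGrid(0.0, 0.6, 901)), shape


def biexp_tissue_closed_form(times_min, shape: AIFShape, k: KineticParams):
    """Closed-form convolution of a biexponential with the exponential kernel.

    For Cp = sum_i a_i exp(-m_i t): Ctis = K1 sum_i a_i (e^{-m_i t} - e^{-K2 t})/(K2 - m_i).
    Independent oracle for the piecewise-linear convolution recursion.
    """
    t = np.asarray(times_min, dtype=float)
    out = np.zeros_like(t)
    for a, m in ((shape.a1, shape.m1), (shape.a2, shape.m2)):
        out += shape.amplitude * k.k1 * a * (np.exp(-m * t) - np.exp(-k.k2 * t)) / (k.k2 - m)
    return out
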