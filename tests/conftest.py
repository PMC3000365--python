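import numpy as np
import pytest

from repeatdyn import Trace, TraceRenderConfig
from repeatdyn.peakfit import GaussianPeak, _model


@pytest.fixture
def make_trace():
    """Noiseless trace built from a list of (mean_bp, sigma_bp, amplitude)."""

    def _make(peaks, pad=40.0, step=0.5):
        comps = [GaussianPeak(*p) for p in peaks]
        lo = min(c.mean_bp for c in comps) - pad
        hi = max(c.mean_bp for c in comps) + pad
        x = np.arange(lo, hi, step)
        return Trace(x, _model(x, comps)), comps

    return _make


@pytest.fixture
def quiet_render():
    """Render config without amplification attenuation (analysis default)."""
    return TraceRenderConfig(attenuation=1.0)
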