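import matplotlib
import pytest

matplotlib.use("Agg")

from leafphys.synth import CurveDesign, generate_synthetic_curve  # noqa: E402


@pytest.fixture
def make_curve():
    """Factory for synthetic curves: make_curve(kind, noise_sd=0, seed=1, ...)."""

    def _make(kind, noise_sd=0.0, seed=1, **kwargs):
        return generate_synthetic_curve(
            CurveDesign(kind=kind, noise_sd=noise_sd, seed=seed, **kwargs))

    return _make
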