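import numpy as np
import pytest

from ssse.mlp import SoftLabelMLP
from ssse.phantom import PhantomSpec
from ssse.pipeline import PipelineConfig, run_phantom_case


def make_logistic_model(w: float, b: float = 0.0) -> SoftLabelMLP:
    """A 1-D two-class model realising p(1|x) = sigmoid(w*x + b) almost exactly.

    The hidden tanh is driven in its linear regime (|eps*x| << 1) and the
    output layer rescales, so for |x| <= ~3 the posterior matches the
    logistic to ~1e-8 relative accuracy.
    """
    eps = 1e-4
    model = SoftLabelMLP(hidden_units=1)
    model.coef_hidden_ = np.array([[eps]])
    model.intercept_hidden_ = np.array([0.0])
    model.coef_output_ = np.array([[w / (2 * eps)], [-w / (2 * eps)]])
    model.intercept_output_ = np.array([b / 2, -b / 2])
    model.classes_ = np.array([1, 2])
    model.n_features_in_ = 1
    return model


@pytest.fixture(scope="session")
def default_case():
    """One default phantom (10x10, 692 points, SNR 10) run in both modes."""
    return run_phantom_case(
        PhantomSpec(seed=1, snr=10.0), PipelineConfig(mode="both", seed=1)
    )


@pytest.fixture(scope="session")
def noiseless_case():
    """A noiseless default phantom run in both modes."""
    return run_phantom_case(
        PhantomSpec(seed=3, snr=np.inf), PipelineConfig(mode="both", seed=3)
    )


@pytest.fixture(scope="session")
def toy_classifier():
    """A small MLP trained on well-separated 2-class spectra."""
    rng = np.random.default_rng(42)
    d = 30
    centers = np.zeros((2, d))
    centers[0, 5] = 2.0
    centers[1, 20] = 2.0
    X = np.vstack([c + rng.normal(0, 0.05, (15, d)) for c in centers])
    y = np.repeat([1, 2], 15)
    model = SoftLabelMLP(random_state=0, max_epochs=2000).fit(X, y)
    return model, X, y
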