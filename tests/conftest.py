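import numpy as np
import pytest

from awarekit import grt, simulate


@pytest.fixture(scope="session")
def small_cohort():
    """Six simulated participants, all three blocks, default generative model."""
    spec = simulate.DesignSpec(n_participants=6, seed=11)
    return simulate.simulate_experiment(spec, simulate.GenerativeParams())


@pytest.fixture(scope="session")
def null_cohort():
    """Cohort where absent and present classes coincide and no RT effect."""
    spec = simulate.DesignSpec(n_participants=6, seed=13)
    return simulate.simulate_experiment(spec, simulate.null_params())


def make_grt_spec(
    flags=grt.MOST_CONSTRAINED,
    n=8,
    means=None,
    sds=None,
    rhos=None,
    cuts=(0.8, 1.6, 2.4),
    bounds=0.1,
    slopes=0.0,
    kappa=1.0,
    rng=None,
):
    """Convenience constructor for GRT model specs in tests."""
    means = means or {
        "square": (0.7, 0.9),
        "diamond": (-0.3, 0.9),
        "absent": (0.0, 0.0),
    }
    sds = sds or {lbl: (1.0, 1.0) for lbl in grt.STIMULI}
    rhos = rhos or {lbl: 0.0 for lbl in grt.STIMULI}
    return grt.GRTModelSpec(
        flags=flags,
        means=means,
        sds=sds,
        rhos=rhos,
        kappa=np.full(n, float(kappa)),
        bounds=np.full(n, float(bounds)) if np.isscalar(bounds) else np.asarray(bounds),
        cuts=np.tile(np.asarray(cuts, float), (n, 1)),
        slopes=np.full(n, float(slopes)) if np.isscalar(slopes) else np.asarray(slopes),
    )
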