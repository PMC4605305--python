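import pytest

import raslquant as rq
from raslquant import synthetic_data as sd


@pytest.fixture(scope="session")
def reference_events():
    """The packaged 39-event PSF-dependence table (condition means)."""
    return rq.psf_dependent_events()


@pytest.fixture(scope="session")
def small_experiment():
    """A 20-event, 3-condition x 3-replicate simulated experiment with
    counts drawn at moderate depth (Poisson totals)."""
    library = rq.make_probe_library(20, seed=11)
    samples = rq.make_samples(sd.default_conditions(), replicates=3, seed=11)
    conditions = sorted({s.condition for s in samples})
    true_psi = rq.random_true_psi(
        20, conditions, seed=11, event_ids=[e.event_id for e in library]
    )
    config = rq.SimulationConfig(
        true_psi=true_psi, mean_depth=300, dispersion=float("inf"), seed=11
    )
    counts = rq.simulate_counts(config, samples)
    return {
        "library": library,
        "samples": samples,
        "true_psi": true_psi,
        "config": config,
        "counts": counts,
    }
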