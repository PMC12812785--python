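import numpy as np
import pytest

import twinlag as tl


def random_psd(rng, scale=0.3):
    a = rng.standard_normal((2, 2)) * scale
    return a @ a.T + 0.05 * np.eye(2)


def random_process(rng, component):
    """Random stable-ish component process with PSD covariances."""
    return tl.ComponentProcess(
        component,
        sigma1=random_psd(rng),
        B12=rng.uniform(-0.4, 0.6, size=(2, 2)),
        B23=rng.uniform(-0.4, 0.6, size=(2, 2)),
        psi2=random_psd(rng),
        psi3=random_psd(rng),
    )


@pytest.fixture
def random_spec():
    rng = np.random.default_rng(42)
    procs = {x: random_process(rng, x) for x in ("A", "C", "E")}
    return tl.GenSpec(processes=procs, n_pairs=100, seed=1)


@pytest.fixture
def small_cohort():
    """Complete-data cohort from a generic spec, small enough for fast tests."""
    spec = tl.flat_ace_spec((0.5, 0.2, 0.3), (0.2, 0.3, 0.5), trait_r=0.3,
                            n_pairs=800, prop_mz=0.4, seed=11)
    return tl.simulate_cohort(spec), spec
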