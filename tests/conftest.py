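import numpy as np
import pytest

from ifpwv.synthetic_data import CohortSpec, CycleSpec, generate_cycle, generate_cohort


@pytest.fixture(scope="session")
def clean_cycle():
    """Noise-free, dip-free beat straight from the two-frequency model."""
    return generate_cycle(CycleSpec(notch_dip=0.0, noise_sd=0.0))


@pytest.fixture(scope="session")
def noisy_cycle():
    """Default beat (with notch dip) plus 2% additive noise."""
    return generate_cycle(CycleSpec(noise_sd=0.02, seed=42))


@pytest.fixture(scope="session")
def small_cohort():
    """Small synthetic cohort shared by model-layer tests."""
    return generate_cohort(CohortSpec(n=120, seed=7))


@pytest.fixture(scope="session")
def random_cycles():
    """Ten randomized, well-conditioned noisy beats for solver checks."""
    rng = np.random.default_rng(2024)
    cycles = []
    while len(cycles) < 10:
        T = float(rng.uniform(0.7, 1.1))
        frac = float(rng.uniform(0.3, 0.5))
        omega2 = float(rng.uniform(3.4, 5.0))
        if abs(np.sin(omega2 * T * (1 - frac))) < 0.4:
            continue  # keep the continuity/periodicity system well-posed
        spec = CycleSpec(
            omega1=float(rng.uniform(9.0, 16.0)),
            omega2=omega2,
            T=T,
            T0=frac * T,
            noise_sd=0.02,
            notch_dip=0.0,
            seed=int(rng.integers(2**31)),
        )
        cycles.append(generate_cycle(spec))
    return cycles
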