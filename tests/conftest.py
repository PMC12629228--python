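import numpy as np
import pytest

from sigconnect import (
    PlantedSignal,
    Signature,
    SimulationSpec,
    simulate_query,
    simulate_repository,
)


@pytest.fixture
def ref4() -> Signature:
    """Tiny 4-gene reference used by the hand-computed running-sum cases."""
    return Signature("ref4", ("g1", "g2", "g3", "g4"), [2.0, 1.0, -1.0, -2.0])


@pytest.fixture
def ref6() -> Signature:
    """6-gene reference with distinct |z| (signed ranks +5,+3,+1,-2,-4,-6)."""
    return Signature(
        "ref6",
        ("g1", "g2", "g3", "g4", "g5", "g6"),
        [3.0, 2.0, 1.0, -1.5, -2.5, -3.5],
    )


@pytest.fixture(scope="session")
def planted_screen_inputs():
    """Query + repository with one planted reversal (alpha=1, noise_sd=0.3)."""
    query = simulate_query(1000, seed=101)
    spec = SimulationSpec(
        n_genes=1000,
        n_signatures=201,
        planted=(PlantedSignal("reversal", alpha=1.0, noise_sd=0.3),),
        seed=202,
    )
    repo, truth = simulate_repository(spec, query)
    return query, repo, truth


def random_signature(rng: np.random.Generator, n: int, sig_id: str = "r") -> Signature:
    """A random continuous-z signature (ties have measure zero)."""
    genes = tuple(f"g{i:03d}" for i in range(n))
    return Signature(sig_id, genes, rng.normal(size=n) * rng.uniform(0.5, 2.0))
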