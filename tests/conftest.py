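import math

import numpy as np
import pytest

from ygeneflow.demography import (
    DemographicModel,
    NeEpoch,
    Population,
    Pulse,
    Split,
)


def single_pop_model(ne: float = 10_000.0) -> DemographicModel:
    return DemographicModel(
        populations=(Population("A", (NeEpoch(0.0, math.inf, ne),)),),
        splits=(),
        pulses=(),
    )


def two_pop_model(
    split_gen: float = 100_000.0, ne: float = 10_000.0, pulses=()
) -> DemographicModel:
    pops = tuple(
        Population(n, (NeEpoch(0.0, math.inf, ne),)) for n in ("A", "B", "anc")
    )
    return DemographicModel(
        populations=pops,
        splits=(Split(split_gen, "A", "anc"), Split(split_gen, "B", "anc")),
        pulses=tuple(pulses),
    )


def three_taxon_model(
    t_inner: float = 10_000.0,
    t_outer: float = 30_000.0,
    ne: float = 10_000.0,
) -> DemographicModel:
    """((A,B),C) with an internal branch of length t_outer - t_inner."""
    pops = tuple(
        Population(n, (NeEpoch(0.0, math.inf, ne),))
        for n in ("A", "B", "C", "ab", "root")
    )
    return DemographicModel(
        populations=pops,
        splits=(
            Split(t_inner, "A", "ab"),
            Split(t_inner, "B", "ab"),
            Split(t_outer, "ab", "root"),
            Split(t_outer, "C", "root"),
        ),
        pulses=(),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
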