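import numpy as np
import pytest

from gazemem import (
    MemSpec,
    MultilevelEntropyMap,
    SynthConfig,
    build_mem,
    extract_em_series,
    simulate_cohort,
)

#: Conditions for the end-to-end detection check: 5 participants x 2
#: sessions x 10 stimulus positions, default latency and saccade
#: distributions.  Shared session-wide because the 100 entropy maps are
#: the expensive part of the suite.
PIPELINE_CONFIG = SynthConfig(
    n_participants=5, n_sessions=2, n_points=10, seed=7
)


@pytest.fixture(scope="session")
def pipeline_cohort():
    return simulate_cohort(PIPELINE_CONFIG)


@pytest.fixture(scope="session")
def pipeline_maps(pipeline_cohort):
    return [
        build_mem(series)
        for rec, _ in pipeline_cohort
        for series in extract_em_series(rec)
    ]


@pytest.fixture(scope="session")
def small_cohort():
    """Two participants, one session, three trials each: fast I/O tests."""
    return simulate_cohort(
        SynthConfig(n_participants=2, n_sessions=1, n_points=3, seed=11)
    )


def make_symbolic_map(spec: MemSpec = MemSpec()) -> MultilevelEntropyMap:
    """Map whose cell (l, s) holds the value 1000*l + s, so feature
    assembly can be checked index-by-index."""
    values = [
        np.array(
            [1000.0 * level + seg for seg in range(1, spec.n_segments(level) + 1)]
        )
        for level in range(1, spec.levels + 1)
    ]
    flags = [np.zeros(spec.n_segments(l), dtype=bool) for l in range(1, spec.levels + 1)]
    return MultilevelEntropyMap(spec, values, flags, {"participant_id": "sym"})


@pytest.fixture
def symbolic_map():
    return make_symbolic_map()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
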