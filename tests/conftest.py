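"""Shared fixtures: synthetic datasets at two scales.

The small dataset keeps unit/integration tests fast; the benchmark dataset is
the default study condition (500 transcripts, 11% planted frameshifts,
seed 42) used by the acceptance tests.  Both are generated once per session.
"""

import pytest

from prfscan.prf_detect import run_prf_pipeline
from prfscan.synthetic_data import (
    SyntheticConfig,
    evaluate_recovery,
    generate_dataset,
)


@pytest.fixture(scope="session")
def small_ds():
    return generate_dataset(SyntheticConfig(seed=7, n_transcripts=80))


@pytest.fixture(scope="session")
def small_run(small_ds):
    calls, summary = run_prf_pipeline(small_ds.transcripts, small_ds.proteins)
    return calls, summary


@pytest.fixture(scope="session")
def benchmark_ds():
    return generate_dataset(SyntheticConfig())  # seed 42, n=500, 11% PRF


@pytest.fixture(scope="session")
def benchmark_run(benchmark_ds):
    calls, summary = run_prf_pipeline(
        benchmark_ds.transcripts, benchmark_ds.proteins
    )
    metrics = evaluate_recovery(calls, benchmark_ds.truth, pos_tolerance=0)
    return calls, summary, metrics
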