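import pytest

import sse_pssm as sp
from sse_pssm.fixtures import benchmark_preset


@pytest.fixture(scope="session")
def small_family():
    """A conserved-structure family: high identity, no SSE jitter."""
    return sp.generate_family(
        sp.FamilyParams(seed=11, homolog_identity_range=(0.8, 0.9), sse_jitter_prob=0.0)
    )


@pytest.fixture(scope="session")
def benchmark():
    """The seeded synthetic train/test benchmark (shared to save runtime)."""
    return sp.generate_benchmark(benchmark_preset(seed=1), identity_ceiling=0.25)


@pytest.fixture(scope="session")
def benchmark_results(benchmark):
    """SSE-PSSM and AA-PSSM end-to-end results on the shared benchmark."""
    res_sse = sp.run_benchmark(benchmark, "sse", seed=1)
    res_aa = sp.run_benchmark(benchmark, "aa", seed=1)
    return res_sse, res_aa
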