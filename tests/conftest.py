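import numpy as np
import pandas as pd
import pytest

from psimeth.io_formats import MethylomeSet, SampleMeta


@pytest.fixture
def two_sample_ms() -> MethylomeSet:
    """Five genome sites + two spike-in sites for two samples."""
    sites = pd.DataFrame(
        {
            "chrom": ["chr1"] * 5 + ["lambda_spike"] * 2,
            "pos": [100, 200, 300, 400, 500, 10, 20],
            "strand": ["+", "-", "+", "+", "-", "+", "+"],
            "context": ["CG", "CHG", "CHH", "CHH", "CG", "CHH", "CHH"],
        }
    )
    mc = np.array([[5, 1], [3, 0], [0, 2], [2, 2], [10, 5], [1, 0], [1, 0]])
    total = np.array([[10, 10], [10, 5], [10, 10], [4, 10], [20, 10], [200, 150], [200, 250]])
    samples = [
        SampleMeta("s1", "plus_pi", "root", 21, 1),
        SampleMeta("s2", "minus_pi", "root", 21, 1),
    ]
    return MethylomeSet(sites, mc, total, samples, "lambda_spike")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260919)
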