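import logging

import pytest
from hypothesis import HealthCheck, settings

from arfusion import pipeline, synthetic

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

logging.getLogger("arfusion").setLevel(logging.ERROR)

# frozen study-condition seeds for the default benchmark runs
BENCH_SEED = 1
SPLIT_SEED = 1
TRAIN_SEED = 1
EVAL_SEED = 101


@pytest.fixture(scope="session")
def benchmark():
    """The default synthetic benchmark bundle (400 promoters, 2-core elements)."""
    cfg = synthetic.BenchmarkConfig(seed=BENCH_SEED)
    promoters, truth, expression, peaks = synthetic.generate_benchmark(cfg)
    return {
        "config": cfg,
        "promoters": promoters,
        "truth": truth,
        "expression": expression,
        "peaks": peaks,
    }


@pytest.fixture(scope="session")
def trained(benchmark):
    """Model trained on the 70% peak split, with the scored candidate table."""
    train_peaks, test_peaks = pipeline.split_peaks(
        benchmark["peaks"], test_fraction=0.3, seed=SPLIT_SEED
    )
    model = pipeline.train(
        benchmark["promoters"], train_peaks, benchmark["expression"], seed=TRAIN_SEED
    )
    frame = pipeline.score_candidates(benchmark["promoters"], model)
    return {
        "model": model,
        "frame": frame,
        "train_peaks": train_peaks,
        "test_peaks": test_peaks,
    }
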