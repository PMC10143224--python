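"""Shared fixtures: synthetic classes and one session-wide benchmark run.

The heavyweight study-level fixtures (the 10-class suite and its benchmark
report) are session-scoped so that every test asserting a study-level
property reuses one computation.
"""

from __future__ import annotations

import pytest

from potencybench import GeneratorConfig, PotencyBenchmark, generate_activity_class, generate_benchmark_suite

N_SUITE_CLASSES = 10
SUITE_SEED = 1


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(n_compounds=200, seed=7)


@pytest.fixture(scope="session")
def small_class(default_config):
    """One 200-compound synthetic activity class (seed 7)."""
    return generate_activity_class(default_config, class_id="FIX000")


@pytest.fixture(scope="session")
def tiny_class():
    """A 60-compound class for fast predictor tests."""
    cfg = GeneratorConfig(n_compounds=60, n_series=14, seed=11)
    return generate_activity_class(cfg, class_id="TINY00")


@pytest.fixture(scope="session")
def noise_free_class():
    """Small noise-free class with unambiguous ground-truth series."""
    cfg = GeneratorConfig(
        n_compounds=24, n_series=4,
        series_size_distribution={3: 0.3, 4: 0.3, 5: 0.2, 6: 0.2},
        noise_sd=0.0, seed=3,
    )
    return generate_activity_class(cfg, class_id="NF0000")


@pytest.fixture(scope="session")
def suite_classes():
    """The 10-class synthetic benchmark suite at default study conditions."""
    return generate_benchmark_suite(
        N_SUITE_CLASSES, GeneratorConfig(n_compounds=200, seed=SUITE_SEED), seed=SUITE_SEED
    )


@pytest.fixture(scope="session")
def suite_benchmark(suite_classes):
    """The executed 80/20 random-split benchmark over the suite (10 trials)."""
    bench = PotencyBenchmark(suite_classes, n_trials=10, seed=SUITE_SEED)
    report = bench.run()
    return bench, report
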