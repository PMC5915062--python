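import numpy as np
import pandas as pd
import pytest

from lcmproteo.model import ContrastSpec, SampleAnnotation, SpectralCountMatrix
from lcmproteo.simulate import SimulationConfig, simulate_study


def make_matrix(data: dict[str, list[int]], samples: list[str]) -> SpectralCountMatrix:
    return SpectralCountMatrix(
        pd.DataFrame.from_dict(data, orient="index", columns=samples)
    )


@pytest.fixture
def small_study():
    """Tiny hand-built study: 2 early, 2 healthy samples, 3 proteins."""
    samples = ["EC1", "EC2", "HE1", "HE2"]
    matrix = make_matrix(
        {"A": [4, 4, 0, 0], "B": [2, 2, 2, 2], "C": [0, 0, 3, 5]}, samples
    )
    annotations = [
        SampleAnnotation("EC1", "early_cancer"),
        SampleAnnotation("EC2", "early_cancer"),
        SampleAnnotation("HE1", "healthy_epithelium"),
        SampleAnnotation("HE2", "healthy_epithelium"),
    ]
    contrast = ContrastSpec("early_cancer", "healthy_epithelium")
    return matrix, annotations, contrast


@pytest.fixture(scope="session")
def simulated_study():
    """Mid-size seeded simulation shared by recovery tests."""
    config = SimulationConfig(n_proteins=600, seed=20240)
    return config, *simulate_study(config)


def brute_force_bh(p: np.ndarray, q: float) -> np.ndarray:
    """O(m^2) literal step-up: largest i with p_(i) <= i*q/m, reject 1..i."""
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    k = 0
    for i in range(1, m + 1):
        if p[order[i - 1]] <= i * q / m:
            k = i
    reject = np.zeros(m, dtype=bool)
    if k:
        cutoff = p[order[k - 1]]
        reject = p <= cutoff
    return reject
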