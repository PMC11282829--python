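import numpy as np
import pandas as pd
import pytest

import gpcrhunt as gh


@pytest.fixture(scope="session")
def default_collection() -> gh.SimulatedCollection:
    """The default synthetic study: five cancer cohorts (77/9/10/20/35
    samples) plus one healthy cohort (3 peritoneal + 3 fallopian + 3 ovarian
    surface), with 13 planted target receptors."""
    return gh.simulate_collection(gh.SyntheticSpec(seed=42))


@pytest.fixture(scope="session")
def default_result(default_collection) -> gh.PipelineResult:
    coll = default_collection
    return gh.run_pipeline(coll.cohorts, coll.annotation, coll.meta)


@pytest.fixture
def small_counts() -> gh.CountMatrix:
    df = pd.DataFrame([[10, 0], [5, 5], [0, 1]],
                      index=["g1", "g2", "g3"], columns=["s1", "s2"])
    return gh.CountMatrix("tiny", df)


def random_counts(seed: int, n_genes: int = 20, n_samples: int = 4,
                  cohort_id: str = "rnd") -> gh.CountMatrix:
    rng = np.random.default_rng(seed)
    counts = rng.negative_binomial(4, 0.05, size=(n_genes, n_samples)) + 1
    return gh.CountMatrix(cohort_id, pd.DataFrame(
        counts, index=[f"g{i}" for i in range(n_genes)],
        columns=[f"s{j}" for j in range(n_samples)]))


def pct_matrix(values: np.ndarray, genes=None, samples=None) -> gh.ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return gh.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples),
                               "PCT_REF")
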