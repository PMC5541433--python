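import numpy as np
import pandas as pd
import pytest

from micromat.tablesio import AbundanceTable, KoTable, SampleMetadata


@pytest.fixture
def toy_counts() -> AbundanceTable:
    df = pd.DataFrame(
        {"s1": [2, 3, 5], "s2": [1, 0, 9], "s3": [4, 4, 2]},
        index=pd.Index(["taxA", "taxB", "taxC"], name="#ID"),
    )
    return AbundanceTable(df, kind="counts")


@pytest.fixture
def toy_metadata() -> SampleMetadata:
    return SampleMetadata(
        pd.DataFrame(
            {
                "sample_id": ["s1", "s2", "s3"],
                "subject_id": ["c1", "c2", "c3"],
                "group": ["control", "control", "treated"],
                "age_days": [1, 7, 7],
            }
        )
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def random_count_table(rng: np.random.Generator, n_taxa=8, n_samples=6, depth=1000) -> AbundanceTable:
    p = rng.dirichlet(np.ones(n_taxa))
    counts = rng.multinomial(depth, p, size=n_samples).T
    df = pd.DataFrame(
        counts,
        index=pd.Index([f"t{i}" for i in range(n_taxa)], name="#ID"),
        columns=[f"s{j}" for j in range(n_samples)],
    )
    return AbundanceTable(df, kind="counts")
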