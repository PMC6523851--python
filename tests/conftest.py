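import numpy as np
import pandas as pd
import pytest

from komix.io_formats import Design, FeatureTable, GeneContentMatrix


@pytest.fixture
def two_group_design() -> Design:
    groups = {f"A{i}": "A" for i in range(5)} | {f"B{i}": "B" for i in range(5)}
    return Design(groups=groups, contrasts=[("A", "B")])


@pytest.fixture
def small_otu_table() -> FeatureTable:
    values = pd.DataFrame(
        [[10.0, 20.0], [4.0, 0.0], [6.0, 6.0]],
        index=["OTU_1", "OTU_2", "OTU_3"],
        columns=["s1", "s2"],
    )
    meta = pd.DataFrame(
        {
            "taxonomy": [
                "k__Bacteria;p__;c__;o__;f__Prevotellaceae;g__Prevotella;s__",
                "k__Bacteria;p__;c__;o__;f__Prevotellaceae;g__Prevotella;s__",
                "k__Bacteria;p__;c__;o__;f__S24-7;g__;s__",
            ]
        },
        index=values.index,
    )
    return FeatureTable(values=values, scale="counts", feature_meta=meta)


@pytest.fixture
def small_gcm() -> GeneContentMatrix:
    content = pd.DataFrame(
        [[3.0, 0.0], [2.0, 1.0], [0.0, 2.0]],
        index=["OTU_1", "OTU_2", "OTU_3"],
        columns=["K00001", "K00002"],
    )
    cn = pd.Series([2.0, 1.0, 4.0], index=content.index)
    return GeneContentMatrix(content=content, copy_number=cn)


def random_instance(seed: int, n_otus: int = 50, n_kos: int = 20,
                    n_samples: int = 6):
    """Random OTU table + gene content pair for oracle comparisons."""
    rng = np.random.default_rng(seed)
    otus = [f"OTU_{i}" for i in range(n_otus)]
    kos = [f"K{i:05d}" for i in range(n_kos)]
    samples = [f"s{i}" for i in range(n_samples)]
    table = FeatureTable(
        values=pd.DataFrame(
            rng.integers(0, 50, (n_otus, n_samples)).astype(float),
            index=otus, columns=samples),
        scale="counts",
    )
    content = pd.DataFrame(
        np.where(rng.random((n_otus, n_kos)) < 0.3,
                 rng.integers(1, 5, (n_otus, n_kos)), 0).astype(float),
        index=otus, columns=kos,
    )
    gcm = GeneContentMatrix(
        content=content,
        copy_number=pd.Series(rng.integers(1, 8, n_otus).astype(float),
                              index=otus),
    )
    return table, gcm
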