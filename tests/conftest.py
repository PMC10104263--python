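import numpy as np
import pandas as pd
import pytest

from sgscreen import (
    CountTable,
    GuideLibrary,
    GuideRecord,
    ScreenSimConfig,
)


@pytest.fixture
def tiny_library() -> GuideLibrary:
    """Two genes x three guides with fixed, mutually distant sequences."""
    rng = np.random.default_rng(42)
    bases = np.array(list("ACGT"))
    records = []
    for g, gene in enumerate(["ALPHA", "BETA"]):
        for k in range(3):
            seq = "".join(rng.choice(bases, size=20))
            records.append(GuideRecord(f"{gene}_g{k + 1}", seq, gene))
    return GuideLibrary(records)


@pytest.fixture
def small_config() -> ScreenSimConfig:
    """Desk-scale screen config: 30 genes, two planted resistance genes."""
    return ScreenSimConfig(
        n_genes=30,
        planted_genes={"GENE0001": 10, "GENE0002": 5},
        sequencing_depth=200_000,
        seed=123,
    )


def make_count_table(counts: dict[str, list[int]], guide_ids: list[str]) -> CountTable:
    df = pd.DataFrame(counts, index=pd.Index(guide_ids, name="guide_id"))
    return CountTable(counts=df)
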