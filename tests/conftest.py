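import numpy as np
import pytest

from repvar.dms_data import CANONICAL_AA, DmsDataset, DmsRecord, Mutation
from repvar.embeddings import SyntheticProvider


@pytest.fixture(scope="session")
def provider():
    """Small-dimension synthetic provider shared across tests."""
    return SyntheticProvider(seed=21, dim=64)


@pytest.fixture()
def tiny_dataset():
    wt = "ACDEFGHIKL"
    records = [
        DmsRecord(Mutation("A", 1, "G"), 0.5),
        DmsRecord(Mutation("C", 2, "W"), -1.2),
        DmsRecord(Mutation("C", 2, "Y"), 0.0),
        DmsRecord(Mutation("F", 5, "L"), 2.5),
    ]
    return DmsDataset("tiny", wt, records)


def random_dataset(rng: np.random.Generator, n: int, length: int, name: str = "rand") -> DmsDataset:
    """Valid random dataset with n distinct variants over a random sequence."""
    wt = "".join(rng.choice(list(CANONICAL_AA), size=length))
    picks = rng.choice(19 * length, size=n, replace=False)
    records = []
    for code in picks:
        pos = int(code) // 19 + 1
        wt_aa = wt[pos - 1]
        alternatives = [aa for aa in CANONICAL_AA if aa != wt_aa]
        records.append(
            DmsRecord(Mutation(wt_aa, pos, alternatives[int(code) % 19]), float(rng.standard_normal()))
        )
    return DmsDataset(name, wt, records)
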