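import numpy as np
import pandas as pd
import pytest

from panicleqtl import compute_organ_totals
from panicleqtl.io_formats import PanicleDataset
from panicleqtl import simulate as sim


@pytest.fixture()
def toy_dataset() -> PanicleDataset:
    """Two lines x two plants x five branches with hand-picked values."""
    rows = []
    values = {
        ("L1", "p1"): [10.0, 8.0, 6.0, 4.0, 2.0],
        ("L1", "p2"): [9.0, 8.0, 7.0, 5.0, 3.0],
        ("L2", "p1"): [2.0, 4.0, 6.0, 8.0, 10.0],
        ("L2", "p2"): [3.0, 5.0, 6.0, 9.0, 11.0],
    }
    for (line, plant), lengths in values.items():
        for rank, pbl in enumerate(lengths, start=1):
            rows.append(
                {
                    "line": line,
                    "plant": plant,
                    "rank": rank,
                    "primary_branch_length": pbl,
                    "secondary_branch_number": float(rank),
                    "spikelet_number": float(rank * 3),
                }
            )
    return PanicleDataset(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def sim_bundle():
    """One shared synthetic BIL panel with a number and a pattern QTL."""
    cfg = sim.SimConfig(
        seed=11,
        qtls=[
            sim.QTLSpec(chromosome="chr01", position_cm=60.0, kind="number", effect=1.45),
            sim.QTLSpec(chromosome="chr02", position_cm=40.0, kind="pattern"),
        ],
    )
    return sim.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def sim_totals(sim_bundle):
    dataset, _, _, _ = sim_bundle
    return compute_organ_totals(dataset)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
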