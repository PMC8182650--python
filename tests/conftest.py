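import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import zevphen as z
from zevphen.config import SimulationConfig

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        n_strains=30,
        seed=11,
        timepoints=[0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0],
        doses=[0.0, 1.0, 100.0, 1000.0],
        media=["SC"],
    )


@pytest.fixture(scope="session")
def small_panel(small_config):
    return z.make_strain_panel(small_config)


@pytest.fixture(scope="session")
def small_growth(small_config, small_panel):
    return z.simulate_growth(small_panel, small_config)


@pytest.fixture(scope="session")
def uniform_plate_table() -> pd.DataFrame:
    rows = [
        ("p1", "SC", 0.0, 24.0, r, c, f"s{r}_{c}", 100.0)
        for r in range(16)
        for c in range(24)
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "plate_id", "medium", "dose_nM", "time_h", "row", "col", "strain_id", "raw_size",
        ],
    )


def brute_force_hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def oracle_assign(barcode: str, barcodes: dict[str, str], max_mismatch: int = 2):
    """Independent exhaustive-scan assignment oracle for a barcode string."""
    hits = [
        strain
        for strain, bc in barcodes.items()
        if brute_force_hamming(barcode, bc) <= max_mismatch
    ]
    if not hits:
        return None
    if len(hits) > 1:
        return "AMBIGUOUS"
    return hits[0]
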