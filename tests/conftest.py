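import numpy as np
import pandas as pd
import pytest

import mirpress as mp
from mirpress.quant import MatureReference


@pytest.fixture(scope="session")
def small_panel():
    return mp.gen_panel(4, seed=11)


@pytest.fixture(scope="session")
def truth():
    return mp.SyntheticTruth(rng_seed=11)


@pytest.fixture
def three_refs():
    """Hand-built references for arithmetic fixtures."""
    return [
        MatureReference("mirA", "hpA", "5p", "UGAGGUAGUAGGUUGUAUAGUU"),
        MatureReference("mirB", "hpA", "3p", "ACCCGUAGAUCCGAACUUGUGA"),
        MatureReference("mirC", "hpB", "5p", "CAUACUUCUUUACAUUCCAUAG"),
    ]


def make_plates(day_ratios: dict[str, list[float]], empty_rf: float = 1.0) -> pd.DataFrame:
    """Plate table with given per-day construct R/F ratios and an empty
    vector at ratio *empty_rf* (firefly fixed at 1000)."""
    rows = []
    n_days = len(next(iter(day_ratios.values())))
    for d in range(1, n_days + 1):
        rows.append(
            {"construct": "EMPTY", "day": f"day{d}",
             "renilla": 1000.0 * empty_rf, "firefly": 1000.0}
        )
        for c, ratios in day_ratios.items():
            rows.append(
                {"construct": c, "day": f"day{d}",
                 "renilla": 1000.0 * ratios[d - 1], "firefly": 1000.0}
            )
    return pd.DataFrame(rows)


@pytest.fixture
def plate_builder():
    return make_plates
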