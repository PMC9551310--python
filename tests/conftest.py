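import numpy as np
import pandas as pd
import pytest

from periodsurv.lifetable import MAX_AGE, PopulationLifeTable


def make_lifetable(p=0.97, years=(2000, 2025), sexes=("male", "female"),
                   races=("white",), age_p: dict[int, float] | None = None
                   ) -> PopulationLifeTable:
    """Dense constant life table with optional per-age overrides."""
    ages = np.arange(MAX_AGE + 1)
    probs = np.full(MAX_AGE + 1, float(p))
    for age, value in (age_p or {}).items():
        probs[age] = value
    frames = []
    for race in races:
        for sex in sexes:
            for year in range(years[0], years[1] + 1):
                frames.append(pd.DataFrame({
                    "age": ages, "year": year, "sex": sex, "race": race,
                    "surv_prob": probs,
                }))
    return PopulationLifeTable.from_frame(pd.concat(frames, ignore_index=True))


@pytest.fixture(scope="session")
def flat_lifetable() -> PopulationLifeTable:
    """p = 0.97 for every cell, both sexes, two races, 2000-2025."""
    return make_lifetable(races=("white", "black"))
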